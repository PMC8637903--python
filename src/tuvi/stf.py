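"""Spatiotemporal (SVD) clutter filtering of beamformed image stacks.

The stack is reshaped into a Casorati matrix (pixels x frames) and its
leading singular components — spatially coherent, temporally slowly varying
tissue/skull clutter — are removed; optional trailing components can be cut
as a noise floor.  Filtering operates on the complex stack so phase is
preserved for downstream localization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import svd

from .beamform import ImageStack
from .phantom import ValidationError

logger = logging.getLogger("tuvi")


@dataclass
class FilterBand:
    """Which singular components to discard.

    ``low_rank_cut`` leading components (clutter) and, optionally,
    ``high_rank_cut`` trailing components (noise) are zeroed.
    """

    low_rank_cut: int
    high_rank_cut: int = None

    def __post_init__(self):
        if self.low_rank_cut < 0:
            raise ValidationError("low_rank_cut must be >= 0")
        if self.high_rank_cut is not None and self.high_rank_cut < 0:
            raise ValidationError("high_rank_cut must be >= 0")


def casorati(stack: ImageStack) -> np.ndarray:
    """(pixels x frames) view of the stack."""
    nf = stack.n_frames
    return stack.frames.reshape(nf, -1).T


def svd_clutter_filter(stack: ImageStack, band: FilterBand) -> ImageStack:
    """Remove the banded singular components from the stack.

    Energy is conserved across the decomposition: input energy equals
    retained plus removed energy (Parseval over singular values).
    """
    if stack.n_frames < 2:
        raise ValidationError("need >= 2 frames for spatiotemporal filtering")
    C = casorati(stack)
    U, s, Vh = svd(C, full_matrices=False)
    n = len(s)
    lo = band.low_rank_cut
    hi = band.high_rank_cut or 0
    if lo >= n:
        raise ValidationError(f"low_rank_cut {lo} exceeds the {n}-component spectrum")
    if lo + hi >= n:
        raise ValidationError(f"band ({lo} low + {hi} high) exceeds the {n}-component spectrum")
    keep = np.ones(n, dtype=bool)
    keep[:lo] = False
    if hi:
        keep[n - hi:] = False
    filt = (U[:, keep] * s[keep]) @ Vh[keep]
    frames = filt.T.reshape(stack.frames.shape).astype(stack.frames.dtype)
    return ImageStack(frames=frames, grid=stack.grid, frame_rate=stack.frame_rate)


def singular_spectrum(stack: ImageStack) -> np.ndarray:
    C = casorati(stack)
    return svd(C, compute_uv=False)


def select_rank_threshold(stack: ImageStack, min_gap: float = 0.15) -> FilterBand:
    """Pick the clutter cutoff at the elbow of the log singular-value curve.

    The cutoff is placed after the largest drop (second-difference corner)
    of log10(sigma_k) within the leading quarter of the spectrum — the
    corner where the tissue/skull clutter plateau falls off to the
    blood-plus-noise continuum.  Cutting deeper than the corner would eat
    into the microbubble subspace: at a 1500 Hz frame rate bubbles move a
    fraction of a PSF per frame, so their signal is itself slowly varying
    and lives just below the clutter plateau.  A spectrum with no drop of
    at least ``min_gap`` decades (degenerate or pure-noise stack) returns a
    cut of 1 with a warning.
    """
    if stack.n_frames < 8:
        raise ValidationError("need >= 8 frames to estimate a rank threshold")
    s = singular_spectrum(stack)
    s = s[s > 0]
    head = max(3, len(s) // 4)
    gaps = -np.diff(np.log10(s[:head]))
    if len(s) < 3 or len(gaps) == 0 or gaps.max() < min_gap:
        logger.warning("no clear elbow in the singular spectrum; defaulting to low_rank_cut=1")
        return FilterBand(low_rank_cut=1)
    cut = min(int(np.argmax(gaps)) + 1, len(s) - 1)
    return FilterBand(low_rank_cut=cut)
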