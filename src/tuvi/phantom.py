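"""Vessel phantoms, flowing microbubbles, and synthetic chirp plane-wave RF data.

Geometry convention: x is lateral (along the array, origin at the array
center), z is depth, positive away from the array face.  Interfaces use
millimetres; internally the module works in a self-consistent mm / µs / MHz
system in which the speed of sound is ``c`` mm/µs (1.54 by default).

The echo model is a far-field point-scatterer delay-and-sum: each bubble
returns a delayed, attenuated copy of the transmit waveform on every
channel.  This deliberately omits transducer impulse responses, nonlinear
bubble dynamics and elevation focusing — it preserves the timing, spreading
and SNR structure that every downstream stage (compression, beamforming,
clutter filtering, localization, tracking) actually consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
from scipy.signal.windows import tukey

logger = logging.getLogger("tuvi")

SOUND_SPEED_MM_US = 1.54  # water/soft tissue at ~20-37 C


class ValidationError(ValueError):
    """Raised when a phantom / parameter invariant is violated."""


# ---------------------------------------------------------------------------
# Vessel geometry
# ---------------------------------------------------------------------------

@dataclass
class VesselSegment:
    """A tube defined by a 2-D centerline polyline with a circular lumen.

    Parameters
    ----------
    centerline : (N, 2) array of (x, z) points, mm, N >= 2.
    diameter : lumen diameter, mm.
    flow_speed : advection speed along the centerline, mm/s.
    flow_direction : +1 to flow from the first to the last point, -1 reversed.
    """

    centerline: np.ndarray
    diameter: float
    flow_speed: float
    flow_direction: int = 1

    def __post_init__(self):
        self.centerline = np.asarray(self.centerline, dtype=float)
        if self.centerline.ndim != 2 or self.centerline.shape[0] < 2 or self.centerline.shape[1] != 2:
            raise ValidationError("centerline must be an (N>=2, 2) array of (x, z) points")
        if self.diameter <= 0:
            raise ValidationError(f"diameter must be > 0, got {self.diameter}")
        if self.flow_speed < 0:
            raise ValidationError(f"flow_speed must be >= 0, got {self.flow_speed}")
        if self.flow_direction not in (-1, 1):
            raise ValidationError("flow_direction must be +1 or -1")
        d = np.diff(self.centerline, axis=0)
        seglen = np.hypot(d[:, 0], d[:, 1])
        if np.any(seglen == 0):
            raise ValidationError("centerline contains repeated points")
        self._edge_len = seglen
        self._cum = np.concatenate([[0.0], np.cumsum(seglen)])

    @property
    def length(self) -> float:
        """Total arc length of the centerline, mm."""
        return float(self._cum[-1])

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    def point_at(self, s):
        """Centerline point(s) at arc coordinate ``s`` (mm); vectorized."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        s = np.clip(s, 0.0, self.length)
        idx = np.clip(np.searchsorted(self._cum, s, side="right") - 1, 0, len(self._edge_len) - 1)
        t = (s - self._cum[idx]) / self._edge_len[idx]
        p0 = self.centerline[idx]
        p1 = self.centerline[idx + 1]
        return p0 + t[:, None] * (p1 - p0)

    def normal_at(self, s):
        """Unit normal(s) to the centerline at arc coordinate ``s``."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        s = np.clip(s, 0.0, self.length)
        idx = np.clip(np.searchsorted(self._cum, s, side="right") - 1, 0, len(self._edge_len) - 1)
        d = (self.centerline[idx + 1] - self.centerline[idx]) / self._edge_len[idx][:, None]
        return np.stack([-d[:, 1], d[:, 0]], axis=1)


@dataclass
class VesselPhantom:
    """A set of vessel segments inside a rectangular imaging field.

    ``field_extent`` is (x_min, x_max, z_min, z_max) in mm.  The ground-truth
    occupancy map is rendered on demand on the super-resolution grid.
    """

    segments: list
    field_extent: tuple
    name: str = "custom"

    def __post_init__(self):
        if not self.segments:
            raise ValidationError("phantom needs at least one vessel segment")
        x0, x1, z0, z1 = self.field_extent
        if not (x1 > x0 and z1 > z0):
            raise ValidationError(f"degenerate field_extent {self.field_extent}")
        for i, seg in enumerate(self.segments):
            r = seg.radius
            cl = seg.centerline
            if (cl[:, 0].min() - r < x0 or cl[:, 0].max() + r > x1
                    or cl[:, 1].min() - r < z0 or cl[:, 1].max() + r > z1):
                raise ValidationError(
                    f"segment {i} (diameter {seg.diameter} mm) extends outside field_extent {self.field_extent}"
                )

    @property
    def total_length(self) -> float:
        return float(sum(seg.length for seg in self.segments))

    def render_truth_map(self, cell_size: float = 0.01):
        """Binary lumen occupancy on a grid of ``cell_size`` mm cells.

        A cell is 1 exactly when its center lies within ``radius`` of a
        segment's centerline.  Returns (truth[z, x], x_centers, z_centers).
        """
        x0, x1, z0, z1 = self.field_extent
        xc = x0 + cell_size * (0.5 + np.arange(int(round((x1 - x0) / cell_size))))
        zc = z0 + cell_size * (0.5 + np.arange(int(round((z1 - z0) / cell_size))))
        truth = np.zeros((len(zc), len(xc)), dtype=bool)
        for seg in self.segments:
            r = seg.radius
            for a, b in zip(seg.centerline[:-1], seg.centerline[1:]):
                # mark cells within r of the edge a->b, working on the bounding slab only
                xlo, xhi = min(a[0], b[0]) - r, max(a[0], b[0]) + r
                zlo, zhi = min(a[1], b[1]) - r, max(a[1], b[1]) + r
                ix = np.searchsorted(xc, [xlo, xhi])
                iz = np.searchsorted(zc, [zlo, zhi])
                if ix[0] >= ix[1] or iz[0] >= iz[1]:
                    continue
                X, Z = np.meshgrid(xc[ix[0]:ix[1]], zc[iz[0]:iz[1]])
                ab = b - a
                denom = ab @ ab
                t = ((X - a[0]) * ab[0] + (Z - a[1]) * ab[1]) / denom
                t = np.clip(t, 0.0, 1.0)
                d2 = (X - (a[0] + t * ab[0])) ** 2 + (Z - (a[1] + t * ab[1])) ** 2
                truth[iz[0]:iz[1], ix[0]:ix[1]] |= d2 <= r * r
        return truth, xc, zc

    def contains(self, xy) -> np.ndarray:
        """Boolean: does each (x, z) point lie inside some lumen."""
        xy = np.atleast_2d(xy)
        inside = np.zeros(len(xy), dtype=bool)
        for seg in self.segments:
            r2 = seg.radius ** 2
            for a, b in zip(seg.centerline[:-1], seg.centerline[1:]):
                ab = b - a
                denom = ab @ ab
                t = np.clip(((xy - a) @ ab) / denom, 0.0, 1.0)
                proj = a + t[:, None] * ab
                inside |= np.sum((xy - proj) ** 2, axis=1) <= r2
        return inside


def _straight(p0, p1):
    return np.array([p0, p1], dtype=float)


def build_vessel_phantom(spec="two_tube", *, segments=None, field_extent=None,
                         flow_speed: float = 30.0) -> VesselPhantom:
    """Build a phantom from a named preset or an explicit segment list.

    Presets
    -------
    ``two_tube``
        Two parallel horizontal tubes of inner diameter 1.0 mm and 0.7 mm at
        ~30 mm depth — the tube-phantom geometry used for diameter and
        flow-speed readouts.
    ``bifurcation``
        A parent tube splitting into two daughter branches.
    ``depth_ladder``
        Four 0.8 mm tubes at 10, 25, 40 and 55 mm depth, for depth-coverage
        studies (40 mm lateral field).
    """
    if segments is not None:
        if not segments:
            raise ValidationError("empty segment list")
        if field_extent is None:
            raise ValidationError("explicit segments require a field_extent")
        return VesselPhantom(list(segments), tuple(field_extent), name=str(spec))

    v = float(flow_speed)
    if spec == "two_tube":
        segs = [
            VesselSegment(_straight((-8.0, 28.0), (8.0, 28.0)), diameter=1.0, flow_speed=v),
            VesselSegment(_straight((-8.0, 32.0), (8.0, 32.0)), diameter=0.7, flow_speed=v),
        ]
        extent = (-12.0, 12.0, 0.0, 60.0)
    elif spec == "bifurcation":
        segs = [
            VesselSegment(_straight((-8.0, 30.0), (0.0, 30.0)), diameter=1.0, flow_speed=v),
            VesselSegment(_straight((0.0, 30.0), (8.0, 26.0)), diameter=0.7, flow_speed=v),
            VesselSegment(_straight((0.0, 30.0), (8.0, 34.0)), diameter=0.7, flow_speed=v),
        ]
        extent = (-12.0, 12.0, 0.0, 60.0)
    elif spec == "depth_ladder":
        segs = [
            VesselSegment(_straight((-8.0, zd), (8.0, zd)), diameter=0.8, flow_speed=v)
            for zd in (10.0, 25.0, 40.0, 55.0)
        ]
        extent = (-20.0, 20.0, 0.0, 60.0)
    else:
        raise ValidationError(f"unknown phantom preset {spec!r}")
    if field_extent is not None:
        extent = tuple(field_extent)
    return VesselPhantom(segs, extent, name=str(spec))


# ---------------------------------------------------------------------------
# Bubbles
# ---------------------------------------------------------------------------

@dataclass
class Bubble:
    """A point-scatterer contrast microbubble advected along a vessel."""

    position: np.ndarray      # (x, z) mm
    arc_coordinate: float     # mm along the segment centerline
    segment_id: int
    radial_offset: float      # mm, signed offset along the lumen normal
    amplitude: float          # dimensionless scattering strength
    alive: bool = True

    def __post_init__(self):
        if self.amplitude <= 0:
            raise ValidationError("bubble amplitude must be > 0")


def _bubble_at(phantom, seg_id, s, offset, amplitude):
    seg = phantom.segments[seg_id]
    p = seg.point_at(s)[0] + offset * seg.normal_at(s)[0]
    return Bubble(position=p, arc_coordinate=float(s), segment_id=seg_id,
                  radial_offset=float(offset), amplitude=float(amplitude))


def seed_bubbles(phantom: VesselPhantom, concentration: float, seed) -> list:
    """Poisson-seed bubbles along the vessels at ``concentration`` per mm.

    Bubbles are placed uniformly along the total centerline length with a
    uniform random radial offset inside the lumen; amplitudes are mildly
    lognormal around 1 (scattering cross-section variability).
    """
    if concentration < 0:
        raise ValidationError(f"concentration must be >= 0, got {concentration}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = rng.poisson(concentration * phantom.total_length)
    lengths = np.array([seg.length for seg in phantom.segments])
    cum = np.concatenate([[0.0], np.cumsum(lengths)])
    bubbles = []
    for _ in range(n):
        u = rng.uniform(0.0, cum[-1])
        seg_id = int(np.searchsorted(cum, u, side="right") - 1)
        seg_id = min(seg_id, len(phantom.segments) - 1)
        s = u - cum[seg_id]
        seg = phantom.segments[seg_id]
        offset = rng.uniform(-1.0, 1.0) * seg.radius * 0.999
        amp = float(np.exp(rng.normal(0.0, 0.3)))
        bubbles.append(_bubble_at(phantom, seg_id, s, offset, amp))
    return bubbles


def advance_bubbles(bubbles: list, phantom: VesselPhantom, dt: float,
                    rng=None, profile: str = "plug") -> list:
    """Advect every bubble by ``flow_speed * dt`` along its centerline.

    dt is in seconds.  Bubbles leaving the far end of a segment are recycled
    at its entrance with a fresh random radial offset (the constant-flow
    pump loop).  ``profile`` is ``plug`` (uniform speed, the calibration
    mode) or ``poiseuille`` (parabolic, peak 2x mean on the axis).
    """
    if dt <= 0:
        raise ValidationError(f"dt must be > 0, got {dt}")
    rng = np.random.default_rng(0) if rng is None else rng
    out = []
    for b in bubbles:
        seg = phantom.segments[b.segment_id]
        speed = seg.flow_speed
        if profile == "poiseuille":
            speed = 2.0 * speed * (1.0 - (b.radial_offset / seg.radius) ** 2)
        s = b.arc_coordinate + seg.flow_direction * speed * dt
        offset = b.radial_offset
        if s > seg.length or s < 0.0:
            s = s % seg.length
            offset = rng.uniform(-1.0, 1.0) * seg.radius * 0.999
        nb = _bubble_at(phantom, b.segment_id, s, offset, b.amplitude)
        nb.alive = b.alive
        out.append(nb)
    return out


# ---------------------------------------------------------------------------
# Acquisition parameters and chirp synthesis
# ---------------------------------------------------------------------------

@dataclass
class AcquisitionParams:
    """Transmit/receive parameterization of a compounded chirp acquisition.

    Defaults follow the 5-angle compounded chirp protocol: a 128-element
    low-frequency linear array, 1.3-2.7 MHz linear FM sweep over 6 µs,
    steering angles -6..+6 degrees, 1500 Hz compounded frame rate.
    """

    n_channels: int = 128
    pitch: float = 0.3                   # mm
    center_frequency: float = 2.0        # MHz
    sweep_low: float = 1.3               # MHz
    sweep_high: float = 2.7              # MHz
    chirp_duration: float = 6.0          # µs
    angles: tuple = (-6.0, -3.0, 0.0, 3.0, 6.0)   # degrees
    prf: float = 1500.0                  # compounded frames per second
    n_frames: int = 600
    sampling_rate: float = 20.0          # MHz
    speed_of_sound: float = 1540.0       # m/s
    noise_sigma: float = 0.0             # linear amplitude per RF sample
    attenuation_db_per_cm_mhz: float = 0.5
    skull_extra_db: float = 0.0          # bulk transcranial loss, dB (two-way)
    skull_phase_jitter_us: float = 0.0   # per-channel receive delay jitter, µs (std)
    n_static_scatterers: int = 0         # tank-wall / tissue speckle targets
    static_amplitude: float = 5.0
    max_depth: float = 60.0              # mm, sets the RF record length
    seed: int = 0

    def __post_init__(self):
        if self.sweep_low > self.sweep_high:
            raise ValidationError("sweep_low must be <= sweep_high")
        if self.n_channels < 1:
            raise ValidationError("n_channels must be >= 1")
        if len(self.angles) == 0:
            raise ValidationError("angles must be non-empty")
        for nm in ("prf", "sampling_rate", "speed_of_sound", "pitch", "chirp_duration"):
            if getattr(self, nm) <= 0:
                raise ValidationError(f"{nm} must be > 0")

    @property
    def c_mm_us(self) -> float:
        return self.speed_of_sound / 1000.0

    @property
    def element_positions(self) -> np.ndarray:
        """Lateral element centers, mm, centered on x = 0."""
        return (np.arange(self.n_channels) - (self.n_channels - 1) / 2.0) * self.pitch

    @property
    def n_samples(self) -> int:
        x = self.element_positions
        halfspan = max(abs(x[0]), abs(x[-1])) + 20.0
        tmax = 2.0 * np.hypot(self.max_depth, halfspan) / self.c_mm_us + self.chirp_duration
        return int(np.ceil(tmax * self.sampling_rate))

    @classmethod
    def from_duration(cls, prf: float, duration_s: float, **kw) -> "AcquisitionParams":
        """Parameterize an acquisition by frame rate and total duration."""
        return cls(prf=prf, n_frames=int(round(prf * duration_s)), **kw)


def synthesize_chirp(params: AcquisitionParams) -> np.ndarray:
    """Sampled linear-FM transmit waveform, unit peak amplitude.

    Sweeps ``sweep_low`` to ``sweep_high`` MHz over ``chirp_duration`` µs
    with a Tukey (alpha = 0.2) amplitude taper to suppress spectral ripple.
    Degenerates to a tapered tone burst when the sweep is zero-bandwidth.
    """
    if params.sampling_rate <= 2.0 * params.sweep_high:
        raise ValidationError(
            f"sampling_rate {params.sampling_rate} MHz violates the Nyquist bound "
            f"2 x sweep_high = {2.0 * params.sweep_high} MHz"
        )
    n = int(round(params.chirp_duration * params.sampling_rate))
    t = np.arange(n) / params.sampling_rate
    k = (params.sweep_high - params.sweep_low) / params.chirp_duration
    phase = 2.0 * np.pi * (params.sweep_low * t + 0.5 * k * t * t)
    w = np.sin(phase) * tukey(n, alpha=0.2)
    peak = np.abs(w).max()
    return (w / peak if peak > 0 else w).astype(np.float64)


def single_cycle_pulse(params: AcquisitionParams, frequency: float = None) -> np.ndarray:
    """One-cycle sine burst at ``frequency`` MHz (default center_frequency).

    The conventional short-pulse transmit used as the reference against the
    compressed chirp; unit peak amplitude.
    """
    f = params.center_frequency if frequency is None else frequency
    n = max(2, int(round(params.sampling_rate / f)))
    t = np.arange(n) / params.sampling_rate
    return np.sin(2.0 * np.pi * f * t)


# ---------------------------------------------------------------------------
# RF synthesis
# ---------------------------------------------------------------------------

def _scatterer_arrays(bubbles):
    xs = np.array([b.position[0] for b in bubbles])
    zs = np.array([b.position[1] for b in bubbles])
    amps = np.array([b.amplitude for b in bubbles])
    return xs, zs, amps


def simulate_rf_frame(bubbles, element_positions, angle, waveform,
                      params: AcquisitionParams, rng=None,
                      extra_scatterers=None, channel_jitter=None) -> np.ndarray:
    """Synthesize one (channels x time) RF frame for one steering angle.

    For each scatterer the transmit plane-wave delay (z cos θ + x sin θ)/c
    plus the receive element path is applied; amplitude is scaled by 1/r
    spherical spreading (r in mm, referenced to 1 mm) and bulk attenuation
    at the center frequency over the two-way path, plus any transcranial
    skull loss.  White Gaussian noise of ``noise_sigma`` is added.
    """
    if abs(angle) >= 90.0:
        raise ValidationError(f"|angle| must be < 90 degrees, got {angle}")
    elem = np.asarray(element_positions, dtype=float)
    nch = len(elem)
    nt = params.n_samples
    rf = np.zeros((nch, nt), dtype=np.float64)

    xs, zs, amps = ([], [], [])
    if bubbles:
        xs, zs, amps = _scatterer_arrays(bubbles)
        behind = zs <= 0.0
        if np.any(behind):
            logger.warning("excluding %d scatterer(s) at z <= 0 (behind the array)",
                           int(behind.sum()))
            xs, zs, amps = xs[~behind], zs[~behind], amps[~behind]
    if extra_scatterers is not None and len(extra_scatterers):
        ex, ez, ea = (np.asarray(a, dtype=float) for a in extra_scatterers)
        xs = np.concatenate([np.atleast_1d(xs), ex]) if len(xs) else ex
        zs = np.concatenate([np.atleast_1d(zs), ez]) if len(zs) else ez
        amps = np.concatenate([np.atleast_1d(amps), ea]) if len(amps) else ea

    if len(xs):
        c = params.c_mm_us
        th = np.deg2rad(angle)
        tau_tx = (zs * np.cos(th) + xs * np.sin(th)) / c          # (nb,)
        r_rx = np.hypot(xs[:, None] - elem[None, :], zs[:, None])  # (nb, nch) mm
        tau = tau_tx[:, None] + r_rx / c                           # µs
        if channel_jitter is not None:
            tau = tau + channel_jitter[None, :]
        # spreading (1 mm reference) and frequency-independent attenuation
        path_cm = (zs[:, None] + r_rx) / 10.0
        att_db = params.attenuation_db_per_cm_mhz * params.center_frequency * path_cm \
            + params.skull_extra_db
        gain = amps[:, None] / np.maximum(r_rx, 1.0) * 10.0 ** (-att_db / 20.0)

        wl = len(waveform)
        s_idx = tau.ravel() * params.sampling_rate
        i0 = np.floor(s_idx).astype(np.int64)
        frac = s_idx - i0
        g = gain.ravel()
        base = i0[:, None] + np.arange(wl)[None, :]               # (nb*nch, wl)
        vals = g[:, None] * waveform[None, :]
        ch_off = np.repeat(np.arange(nch)[None, :], len(zs), axis=0).ravel() * nt
        idx = (base + ch_off[:, None]).ravel()
        ok = (base.ravel() >= 0) & (base.ravel() < nt - 1)
        idx = idx[ok]
        v = vals.ravel()[ok]
        f = np.repeat(frac, wl)[ok]
        # linear-interpolation insertion via one bincount over both taps
        acc = np.bincount(np.concatenate([idx, idx + 1]),
                          weights=np.concatenate([v * (1.0 - f), v * f]),
                          minlength=nch * nt)
        rf += acc.reshape(nch, nt)

    if params.noise_sigma > 0:
        rng = np.random.default_rng(0) if rng is None else rng
        rf += rng.normal(0.0, params.noise_sigma, size=rf.shape)
    return rf


@dataclass
class RFSequence:
    """Multi-frame, multi-angle channel RF with ground truth for evaluation.

    ``samples`` is [frame][angle][channel][time] float32.  ``truth_tracks``
    holds, per frame, an (n_bubbles, 3) array of (bubble_id, x, z) — used
    only by evaluation code, never by the imaging pipeline.
    """

    samples: np.ndarray
    params: AcquisitionParams
    element_positions: np.ndarray
    truth_tracks: list = field(default_factory=list)

    def __post_init__(self):
        nf, na, nch, nt = self.samples.shape
        if nf != self.params.n_frames or na != len(self.params.angles) \
                or nch != self.params.n_channels:
            raise ValidationError("samples dimensions inconsistent with params")
        if self.truth_tracks and len(self.truth_tracks) != nf:
            raise ValidationError("truth_tracks length must equal n_frames")


def iter_acquisition_frames(phantom: VesselPhantom, params: AcquisitionParams,
                            concentration: float, seed=None,
                            profile: str = "plug"):
    """Generate the acquisition frame by frame.

    Yields (frame_index, truth, rf_per_angle) where ``truth`` is the
    (n_bubbles, 3) array of (bubble_id, x, z) and ``rf_per_angle`` a list of
    (channels, time) float32 arrays, one per steering angle.  Per compounded
    frame every angle fires against the same frozen bubble configuration;
    bubbles then advance by 1/prf seconds.  Static scatterers (tank wall /
    skull speckle) are frozen, so their echo is synthesized once per angle
    and reused.  Fully reproducible for a given seed.
    """
    seed = params.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    s_place, s_motion, s_noise, s_static = ss.spawn(4)
    rng_motion = np.random.default_rng(s_motion)
    rng_noise = np.random.default_rng(s_noise)
    rng_static = np.random.default_rng(s_static)

    waveform = synthesize_chirp(params)
    elem = params.element_positions
    bubbles = seed_bubbles(phantom, concentration, np.random.default_rng(s_place))

    static = None
    if params.n_static_scatterers > 0:
        x0, x1, z0, z1 = phantom.field_extent
        sx = rng_static.uniform(x0, x1, params.n_static_scatterers)
        sz = rng_static.uniform(max(z0, 2.0), z1, params.n_static_scatterers)
        sa = params.static_amplitude * np.exp(rng_static.normal(0.0, 0.5, params.n_static_scatterers))
        static = (sx, sz, sa)

    jitter = None
    if params.skull_phase_jitter_us > 0:
        jitter = rng_static.normal(0.0, params.skull_phase_jitter_us, params.n_channels)

    quiet = replace(params, noise_sigma=0.0)
    static_rf = None
    if static is not None:
        static_rf = [simulate_rf_frame([], elem, ang, waveform, quiet,
                                       extra_scatterers=static,
                                       channel_jitter=jitter).astype(np.float32)
                     for ang in params.angles]
    for fi in range(params.n_frames):
        rf_angles = []
        for ai, ang in enumerate(params.angles):
            frame = simulate_rf_frame(bubbles, elem, ang, waveform, quiet,
                                      channel_jitter=jitter)
            if static_rf is not None:
                frame = frame + static_rf[ai]
            if params.noise_sigma > 0:
                frame = frame + rng_noise.normal(0.0, params.noise_sigma,
                                                 size=frame.shape)
            rf_angles.append(frame.astype(np.float32))
        truth = np.array([[i, b.position[0], b.position[1]]
                          for i, b in enumerate(bubbles) if b.alive],
                         dtype=np.float64).reshape(-1, 3)
        yield fi, truth, rf_angles
        bubbles = advance_bubbles(bubbles, phantom, 1.0 / params.prf,
                                  rng=rng_motion, profile=profile)


def simulate_acquisition(phantom: VesselPhantom, params: AcquisitionParams,
                         concentration: float, seed=None,
                         profile: str = "plug") -> RFSequence:
    """Run the full multi-frame acquisition loop into an RFSequence.

    Materializes every frame of :func:`iter_acquisition_frames`; for long
    multi-channel runs where the raw RF would not fit comfortably in
    memory, consume the generator directly instead.
    """
    nf, na = params.n_frames, len(params.angles)
    samples = np.zeros((nf, na, params.n_channels, params.n_samples), dtype=np.float32)
    truth = []
    for fi, tr, rf_angles in iter_acquisition_frames(phantom, params,
                                                     concentration, seed, profile):
        for ai in range(na):
            samples[fi, ai] = rf_angles[ai]
        truth.append(tr)
    return RFSequence(samples=samples, params=params,
                      element_positions=params.element_positions,
                      truth_tracks=truth)


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

_PARAM_FIELDS = [f for f in AcquisitionParams.__dataclass_fields__]


def save_rf_sequence(path, seq: RFSequence):
    """Persist an RFSequence: HDF5 (.h5/.hdf5) or NPZ fallback."""
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        with h5py.File(path, "w") as f:
            f.create_dataset("rf", data=seq.samples, dtype="float32")
            f.create_dataset("elements", data=seq.element_positions)
            g = f.create_group("truth")
            for i, t in enumerate(seq.truth_tracks):
                g.create_dataset(str(i), data=t)
            for name in _PARAM_FIELDS:
                v = getattr(seq.params, name)
                f.attrs[name] = list(v) if isinstance(v, tuple) else v
    else:
        meta = {name: getattr(seq.params, name) for name in _PARAM_FIELDS}
        np.savez_compressed(
            path, rf=seq.samples, elements=seq.element_positions,
            n_truth=len(seq.truth_tracks),
            **{f"truth_{i}": t for i, t in enumerate(seq.truth_tracks)},
            **{f"param_{k}": np.asarray(v) for k, v in meta.items()})


def load_rf_sequence(path) -> RFSequence:
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        with h5py.File(path, "r") as f:
            kw = {}
            for name in _PARAM_FIELDS:
                v = f.attrs[name]
                fld = AcquisitionParams.__dataclass_fields__[name]
                if fld.type == "tuple" or name == "angles":
                    v = tuple(np.asarray(v).tolist())
                elif isinstance(v, np.generic):
                    v = v.item()
                kw[name] = v
            params = AcquisitionParams(**kw)
            truth = [np.asarray(f["truth"][str(i)]) for i in range(len(f["truth"]))]
            return RFSequence(samples=np.asarray(f["rf"]), params=params,
                              element_positions=np.asarray(f["elements"]),
                              truth_tracks=truth)
    with np.load(path) as d:
        kw = {}
        for name in _PARAM_FIELDS:
            v = d[f"param_{name}"]
            if name == "angles":
                kw[name] = tuple(v.tolist())
            elif v.ndim == 0:
                kw[name] = v.item()
            else:
                kw[name] = v
        params = AcquisitionParams(**kw)
        truth = [d[f"truth_{i}"] for i in range(int(d["n_truth"]))]
        return RFSequence(samples=d["rf"], params=params,
                          element_positions=d["elements"], truth_tracks=truth)
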