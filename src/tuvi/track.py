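"""Multi-target microbubble tracking by MCMC data association.

Detections from all frames are partitioned into tracks plus clutter.  A
partition is scored by a posterior combining, per track, constant-velocity
Kalman-filter innovation likelihoods with birth, detection and missed-
detection priors, and a spatially uniform Poisson model for clutter.  A
Metropolis-Hastings chain explores partition space with reversible moves
(birth/death, extend/reduce, split/merge, switch, update) restricted by a
speed-and-gap gate; the maximum-a-posteriori partition visited is returned.
A greedy nearest-neighbor linker is provided both as a baseline and as the
default chain initializer — at realistic bubble densities a cold chain
would spend its whole budget rediscovering obvious links.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .phantom import ValidationError

logger = logging.getLogger("tuvi")


# ---------------------------------------------------------------------------
# Motion model and containers
# ---------------------------------------------------------------------------

@dataclass
class MotionModel:
    """Constant-velocity motion model plus association priors.

    Units: mm, seconds, mm/s.  ``process_noise_sigma`` is per-frame position
    diffusion; ``velocity_noise_sigma`` is per-frame velocity diffusion.
    ``clutter_rate`` and ``birth_rate`` are expected counts per frame,
    spread uniformly over ``field_area`` (mm^2).
    """

    process_noise_sigma: float = 0.05
    measurement_noise_sigma: float = 0.05
    max_speed: float = 100.0
    p_detect: float = 0.9
    clutter_rate: float = 1.0
    birth_rate: float = 1.0
    field_area: float = 1000.0
    max_gap: int = 2
    min_track_length: int = 5
    velocity_noise_sigma: float = 5.0
    initial_speed_sigma: float = None
    # tracks whose end-to-end displacement rate falls below this are
    # residual stationary clutter, not flowing bubbles, and are dropped
    min_net_speed: float = 5.0

    def __post_init__(self):
        if self.process_noise_sigma <= 0 or self.measurement_noise_sigma <= 0:
            raise ValidationError("noise sigmas must be > 0")
        if not (0.0 < self.p_detect <= 1.0):
            raise ValidationError("p_detect must be in (0, 1]")
        if self.max_speed <= 0:
            raise ValidationError("max_speed must be > 0")
        if self.initial_speed_sigma is None:
            self.initial_speed_sigma = self.max_speed / 2.0

    def gate_mm(self, frame_gap: int, frame_rate: float) -> float:
        """Largest plausible displacement over ``frame_gap`` frames."""
        return (self.max_speed / frame_rate) * frame_gap \
            + 3.0 * self.measurement_noise_sigma


@dataclass
class Track:
    """One recovered trajectory: arrays over its detections."""

    frames: np.ndarray
    x: np.ndarray
    z: np.ndarray
    vx: np.ndarray = None
    vz: np.ndarray = None
    detection_indices: np.ndarray = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=int)
        self.x = np.asarray(self.x, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if len(self.frames) and np.any(np.diff(self.frames) <= 0):
            raise ValidationError("track frame indices must strictly increase")

    def __len__(self):
        return len(self.frames)

    @property
    def speeds(self):
        return np.hypot(self.vx, self.vz)


@dataclass
class TrackSet:
    tracks: list = field(default_factory=list)

    def __len__(self):
        return len(self.tracks)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for tid, t in enumerate(self.tracks):
            for k in range(len(t)):
                rows.append({"track_id": tid, "frame": int(t.frames[k]),
                             "x_mm": t.x[k], "z_mm": t.z[k],
                             "vx_mm_s": np.nan if t.vx is None else t.vx[k],
                             "vz_mm_s": np.nan if t.vz is None else t.vz[k]})
        return pd.DataFrame(rows, columns=["track_id", "frame", "x_mm", "z_mm",
                                           "vx_mm_s", "vz_mm_s"])


def save_tracks(path, trackset: TrackSet, sidecar: dict = None):
    trackset.to_dataframe().to_csv(path, index=False)
    if sidecar is not None:
        with open(str(path) + ".json", "w") as f:
            json.dump(sidecar, f, indent=2, default=str)


def load_tracks(path) -> TrackSet:
    df = pd.read_csv(path)
    tracks = []
    for _, g in df.groupby("track_id"):
        g = g.sort_values("frame")
        tracks.append(Track(frames=g["frame"].values, x=g["x_mm"].values,
                            z=g["z_mm"].values, vx=g["vx_mm_s"].values,
                            vz=g["vz_mm_s"].values))
    return TrackSet(tracks=tracks)


# ---------------------------------------------------------------------------
# Posterior
# ---------------------------------------------------------------------------

def _track_loglik(frames, xs, zs, model: MotionModel, frame_rate: float) -> float:
    """Log-likelihood + priors for one track (indices resolved to arrays).

    Birth prior (uniform position over the field), per-detection detection
    probability, per-gap missed-detection probability, and constant-velocity
    Kalman innovation densities from the second detection on.  The x and z
    axes share one covariance recursion (identical R and Q).
    """
    n = len(frames)
    R = model.measurement_noise_sigma ** 2
    qp = model.process_noise_sigma ** 2
    qv = model.velocity_noise_sigma ** 2
    ll = math.log(model.birth_rate / model.field_area)
    ll += n * math.log(model.p_detect)
    span = int(frames[-1] - frames[0] + 1)
    if model.p_detect < 1.0:
        ll += (span - n) * math.log(1.0 - model.p_detect)
    # Kalman state per axis: position, velocity; shared covariance
    px, pz = float(xs[0]), float(zs[0])
    vx = vz = 0.0
    p00, p01, p11 = R, 0.0, model.initial_speed_sigma ** 2
    log2pi = math.log(2.0 * math.pi)
    for k in range(1, n):
        g = int(frames[k] - frames[k - 1])
        dt = g / frame_rate
        px += vx * dt
        pz += vz * dt
        p00 += 2.0 * dt * p01 + dt * dt * p11 + qp * g
        p01 += dt * p11
        p11 += qv * g
        S = p00 + R
        ix = float(xs[k]) - px
        iz = float(zs[k]) - pz
        ll += -0.5 * (2.0 * (log2pi + math.log(S)) + (ix * ix + iz * iz) / S)
        K0 = p00 / S
        K1 = p01 / S
        px += K0 * ix
        vx += K1 * ix
        pz += K0 * iz
        vz += K1 * iz
        p00, p01, p11 = (1.0 - K0) * p00, (1.0 - K0) * p01, p11 - K1 * p01
    return ll


@dataclass
class Partition:
    """Assignment of every detection to exactly one track or to clutter.

    ``detections`` is the flat detection list; ``tracks`` holds lists of
    indices into it.  Detections in no track are clutter.
    """

    detections: list
    tracks: list = field(default_factory=list)

    def validate(self, model: MotionModel, frame_rate: float):
        seen = set()
        for t in self.tracks:
            if len(t) < 2:
                raise ValidationError("tracks must contain >= 2 detections")
            frames = [self.detections[i].frame_index for i in t]
            for i in t:
                if i in seen:
                    raise ValidationError(f"detection {i} assigned to two tracks")
                seen.add(i)
            for a, b, fa, fb in zip(t[:-1], t[1:], frames[:-1], frames[1:]):
                gap = fb - fa
                if gap <= 0:
                    raise ValidationError("track frame indices must strictly increase")
                if gap > model.max_gap + 1:
                    raise ValidationError(f"frame gap {gap - 1} exceeds max_gap {model.max_gap}")
                da, db = self.detections[a], self.detections[b]
                disp = math.hypot(db.x - da.x, db.z - da.z)
                if disp > model.gate_mm(gap, frame_rate) + 1e-9:
                    raise ValidationError(
                        f"displacement {disp:.3f} mm over {gap} frame(s) violates the speed gate")

    @property
    def clutter(self) -> list:
        assigned = {i for t in self.tracks for i in t}
        return [i for i in range(len(self.detections)) if i not in assigned]


def partition_log_posterior(partition: Partition, model: MotionModel,
                            frame_rate: float) -> float:
    """log P(partition | detections) up to an additive constant.

    Higher is better; an empty detection set scores exactly 0.  Raises on
    partitions violating the track invariants.
    """
    partition.validate(model, frame_rate)
    dets = partition.detections
    score = 0.0
    for t in partition.tracks:
        frames = np.array([dets[i].frame_index for i in t])
        xs = np.array([dets[i].x for i in t])
        zs = np.array([dets[i].z for i in t])
        score += _track_loglik(frames, xs, zs, model, frame_rate)
    score += len(partition.clutter) * math.log(model.clutter_rate / model.field_area)
    return score


# ---------------------------------------------------------------------------
# MCMC sampler
# ---------------------------------------------------------------------------

MOVES = ("birth", "death", "extend", "reduce", "split", "merge", "switch", "update")


class MCMCDASampler:
    """Metropolis-Hastings sampler over detection-to-track partitions.

    Internal state lives in flat arrays (frame, x, z per detection), a
    detection->track assignment vector, and per-track log-likelihood caches,
    so each move rescoring touches only the affected tracks.
    """

    GAMMA = 0.5  # birth-move continuation probability

    def __init__(self, detections, model: MotionModel, frame_rate: float,
                 rng=None, move_probabilities=None):
        self.model = model
        self.frame_rate = frame_rate
        self.rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        self.dets = list(detections)
        n = len(self.dets)
        self.frame = np.array([d.frame_index for d in self.dets], dtype=np.int64)
        self.x = np.array([d.x for d in self.dets], dtype=np.float64)
        self.z = np.array([d.z for d in self.dets], dtype=np.float64)

        if move_probabilities is None:
            move_probabilities = {m: 1.0 / len(MOVES) for m in MOVES}
        probs = np.array([move_probabilities.get(m, 0.0) for m in MOVES], dtype=float)
        if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
            raise ValidationError("move_probabilities must be a distribution over the move set")
        self.move_probs = probs
        self.log_move = {m: (math.log(p) if p > 0 else -math.inf)
                         for m, p in zip(MOVES, probs)}

        self.log_clutter = math.log(model.clutter_rate / model.field_area)
        self._build_gates()

        # partition state
        self.assign = np.full(n, -1, dtype=np.int64)
        self.tracks = {}          # tid -> list of det indices (frame-sorted)
        self.track_ll = {}        # tid -> cached log-likelihood
        self._next_tid = 0
        self.clutter_list = list(range(n))
        self.clutter_pos = {i: k for k, i in enumerate(self.clutter_list)}
        self.total_ll = n * self.log_clutter

    # -- gating ------------------------------------------------------------

    def _build_gates(self):
        """Successor/predecessor candidate lists under the speed/gap gate."""
        n = len(self.dets)
        self.succ = [[] for _ in range(n)]
        self.pred = [[] for _ in range(n)]
        if n == 0:
            return
        frames = np.unique(self.frame)
        by_frame = {f: np.flatnonzero(self.frame == f) for f in frames}
        trees = {f: cKDTree(np.column_stack([self.x[idx], self.z[idx]]))
                 for f, idx in by_frame.items()}
        for f in frames:
            src = by_frame[f]
            for dgap in range(1, self.model.max_gap + 2):
                f2 = f + dgap
                if f2 not in by_frame:
                    continue
                gate = self.model.gate_mm(dgap, self.frame_rate)
                tgt = by_frame[f2]
                pairs = trees[f].query_ball_tree(trees[f2], gate)
                for si, nbrs in zip(src, pairs):
                    for j in nbrs:
                        self.succ[si].append(int(tgt[j]))
                        self.pred[tgt[j]].append(int(si))

    # -- bookkeeping -------------------------------------------------------

    def _clutter_add(self, i):
        self.clutter_pos[i] = len(self.clutter_list)
        self.clutter_list.append(i)

    def _clutter_remove(self, i):
        k = self.clutter_pos.pop(i)
        last = self.clutter_list.pop()
        if last != i:
            self.clutter_list[k] = last
            self.clutter_pos[last] = k

    def _loglik(self, track) -> float:
        idx = np.asarray(track)
        return _track_loglik(self.frame[idx], self.x[idx], self.z[idx],
                             self.model, self.frame_rate)

    def _install_track(self, track) -> int:
        tid = self._next_tid
        self._next_tid += 1
        self.tracks[tid] = list(track)
        ll = self._loglik(track)
        self.track_ll[tid] = ll
        for i in track:
            self.assign[i] = tid
            self._clutter_remove(i)
        self.total_ll += ll - len(track) * self.log_clutter
        return tid

    def _remove_track(self, tid):
        track = self.tracks.pop(tid)
        ll = self.track_ll.pop(tid)
        for i in track:
            self.assign[i] = -1
            self._clutter_add(i)
        self.total_ll += len(track) * self.log_clutter - ll

    def _replace_track(self, tid, new_track):
        old = self.tracks[tid]
        for i in old:
            self.assign[i] = -1
            self._clutter_add(i)
        for i in new_track:
            self.assign[i] = tid
            self._clutter_remove(i)
        ll = self._loglik(new_track)
        self.total_ll += ll - self.track_ll[tid] \
            + (len(old) - len(new_track)) * self.log_clutter
        self.tracks[tid] = list(new_track)
        self.track_ll[tid] = ll

    def _replace_two(self, ta, new_a, tb, new_b):
        """Atomically replace two tracks (they may exchange detections)."""
        old_a, old_b = self.tracks[ta], self.tracks[tb]
        for i in old_a + old_b:
            self.assign[i] = -1
            self._clutter_add(i)
        delta_n = len(old_a) + len(old_b) - len(new_a) - len(new_b)
        for tid, new in ((ta, new_a), (tb, new_b)):
            for i in new:
                self.assign[i] = tid
                self._clutter_remove(i)
            ll = self._loglik(new)
            self.total_ll += ll - self.track_ll[tid]
            self.track_ll[tid] = ll
            self.tracks[tid] = list(new)
        self.total_ll += delta_n * self.log_clutter

    def _clutter_succ(self, i, exclude=()):
        return [j for j in self.succ[i]
                if self.assign[j] == -1 and j not in exclude]

    def _clutter_pred(self, i):
        return [j for j in self.pred[i] if self.assign[j] == -1]

    # -- birth proposal density (shared by birth and death-reverse) --------

    def _birth_logq(self, track, clutter_size, virtual_clutter=frozenset()) -> float:
        """log q of the birth move creating exactly ``track``.

        ``virtual_clutter``: detections to treat as clutter although they
        are currently assigned (used when evaluating the reverse of death).
        """
        def avail(j, picked):
            return (self.assign[j] == -1 or j in virtual_clutter) and j not in picked

        picked = set()
        logq = -math.log(clutter_size)
        picked.add(track[0])
        k1 = sum(1 for j in self.succ[track[0]] if avail(j, picked))
        logq -= math.log(k1)
        picked.add(track[1])
        for step in range(2, len(track)):
            prev = track[step - 1]
            k = sum(1 for j in self.succ[prev] if avail(j, picked))
            logq += math.log(self.GAMMA) - math.log(k)
            picked.add(track[step])
        k_end = sum(1 for j in self.succ[track[-1]] if avail(j, picked))
        if k_end > 0:
            logq += math.log(1.0 - self.GAMMA)
        return logq

    # -- merge/split feasibility counts ------------------------------------

    def _merge_pairs(self):
        """All ordered (tid_a, tid_b) whose concatenation respects the gate.

        Track heads are bucketed by frame so each tail only examines heads
        within its gap window.
        """
        heads = {}
        for tid, t in self.tracks.items():
            heads.setdefault(int(self.frame[t[0]]), []).append(tid)
        pairs = []
        for ta, a in self.tracks.items():
            tail = a[-1]
            f_tail = int(self.frame[tail])
            for gap in range(1, self.model.max_gap + 2):
                gate = self.model.gate_mm(gap, self.frame_rate)
                for tb in heads.get(f_tail + gap, ()):
                    if tb == ta:
                        continue
                    head = self.tracks[tb][0]
                    disp = math.hypot(self.x[head] - self.x[tail],
                                      self.z[head] - self.z[tail])
                    if disp <= gate:
                        pairs.append((ta, tb))
        return pairs

    def _split_edge_count(self) -> int:
        """Cut positions leaving both halves >= 2 detections, over all tracks."""
        return sum(max(0, len(t) - 3) for t in self.tracks.values())

    def _sample_split_edge(self):
        r = int(self.rng.integers(self._split_edge_count()))
        for tid, t in self.tracks.items():
            k = max(0, len(t) - 3)
            if r < k:
                return tid, 2 + r
            r -= k
        raise AssertionError("unreachable")

    # -- proposals ---------------------------------------------------------

    def propose(self):
        """Draw one move; returns (accepted: bool, move_name: str)."""
        m = MOVES[self.rng.choice(len(MOVES), p=self.move_probs)]
        return getattr(self, "_move_" + m)(), m

    def _accept(self, delta, logq_fwd, logq_rev):
        a = delta + logq_rev - logq_fwd
        return a >= 0 or math.log(self.rng.random()) < a

    def _move_birth(self):
        nc = len(self.clutter_list)
        if nc == 0:
            return False
        d1 = self.clutter_list[self.rng.integers(nc)]
        cands = self._clutter_succ(d1)
        if not cands:
            return False
        track = [d1]
        logq = self.log_move["birth"] - math.log(nc) - math.log(len(cands))
        track.append(cands[self.rng.integers(len(cands))])
        while True:
            cands = self._clutter_succ(track[-1], exclude=set(track))
            if not cands:
                break
            if self.rng.random() >= self.GAMMA:
                logq += math.log(1.0 - self.GAMMA)
                break
            logq += math.log(self.GAMMA) - math.log(len(cands))
            track.append(cands[self.rng.integers(len(cands))])
        new_ll = self._loglik(track)
        delta = new_ll - len(track) * self.log_clutter
        logq_rev = self.log_move["death"] - math.log(len(self.tracks) + 1)
        if self._accept(delta, logq, logq_rev):
            self._install_track(track)
            return True
        return False

    def _move_death(self):
        if not self.tracks:
            return False
        tids = list(self.tracks)
        tid = tids[self.rng.integers(len(tids))]
        track = self.tracks[tid]
        logq = self.log_move["death"] - math.log(len(tids))
        logq_rev = self.log_move["birth"] + self._birth_logq(
            track, len(self.clutter_list) + len(track),
            virtual_clutter=set(track))
        delta = len(track) * self.log_clutter - self.track_ll[tid]
        if self._accept(delta, logq, logq_rev):
            self._remove_track(tid)
            return True
        return False

    def _move_extend(self):
        if not self.tracks:
            return False
        tids = list(self.tracks)
        tid = tids[self.rng.integers(len(tids))]
        track = self.tracks[tid]
        tail = self.rng.random() < 0.5
        cands = self._clutter_succ(track[-1]) if tail else self._clutter_pred(track[0])
        if not cands:
            return False
        d = cands[self.rng.integers(len(cands))]
        new_track = track + [d] if tail else [d] + track
        logq = self.log_move["extend"] - math.log(len(tids)) - math.log(2) \
            - math.log(len(cands))
        n3_after = sum(1 for t in self.tracks.values() if len(t) >= 3) \
            + (1 if len(track) == 2 else 0)
        logq_rev = self.log_move["reduce"] - math.log(n3_after) - math.log(2)
        new_ll = self._loglik(new_track)
        delta = new_ll - self.track_ll[tid] - self.log_clutter
        if self._accept(delta, logq, logq_rev):
            self._replace_track(tid, new_track)
            return True
        return False

    def _move_reduce(self):
        long_tids = [tid for tid, t in self.tracks.items() if len(t) >= 3]
        if not long_tids:
            return False
        tid = long_tids[self.rng.integers(len(long_tids))]
        track = self.tracks[tid]
        tail = self.rng.random() < 0.5
        new_track = track[:-1] if tail else track[1:]
        removed = track[-1] if tail else track[0]
        logq = self.log_move["reduce"] - math.log(len(long_tids)) - math.log(2)
        # reverse extend counts clutter candidates in the post-move state
        anchor = new_track[-1] if tail else new_track[0]
        nbrs = self.succ[anchor] if tail else self.pred[anchor]
        k_rev = sum(1 for j in nbrs if self.assign[j] == -1 or j == removed)
        logq_rev = self.log_move["extend"] - math.log(len(self.tracks)) \
            - math.log(2) - math.log(k_rev)
        new_ll = self._loglik(new_track)
        delta = new_ll - self.track_ll[tid] + self.log_clutter
        if self._accept(delta, logq, logq_rev):
            self._replace_track(tid, new_track)
            return True
        return False

    def _move_split(self):
        n_edges = self._split_edge_count()
        if n_edges == 0:
            return False
        tid, cut = self._sample_split_edge()
        track = self.tracks[tid]
        a, b = track[:cut], track[cut:]
        logq = self.log_move["split"] - math.log(n_edges)
        ll_a, ll_b = self._loglik(a), self._loglik(b)
        delta = ll_a + ll_b - self.track_ll[tid]
        # reverse merge: count feasible pairs in the post-split state
        self._replace_track(tid, a)
        tid_b = self._install_track(b)
        n_pairs_after = len(self._merge_pairs())
        logq_rev = self.log_move["merge"] - math.log(n_pairs_after)
        if self._accept(delta, logq, logq_rev):
            return True
        # roll back
        self._remove_track(tid_b)
        self._replace_track(tid, track)
        return False

    def _move_merge(self):
        pairs = self._merge_pairs()
        if not pairs:
            return False
        ta, tb = pairs[self.rng.integers(len(pairs))]
        a, b = self.tracks[ta], self.tracks[tb]
        merged = a + b
        logq = self.log_move["merge"] - math.log(len(pairs))
        ll_m = self._loglik(merged)
        delta = ll_m - self.track_ll[ta] - self.track_ll[tb]
        self._remove_track(tb)
        self._replace_track(ta, merged)
        n_edges_after = self._split_edge_count()
        logq_rev = self.log_move["split"] - math.log(n_edges_after)
        if self._accept(delta, logq, logq_rev):
            return True
        self._replace_track(ta, a)
        self._install_track(b)
        return False

    def _gated(self, i, j) -> bool:
        gap = int(self.frame[j] - self.frame[i])
        if not (1 <= gap <= self.model.max_gap + 1):
            return False
        disp = math.hypot(self.x[j] - self.x[i], self.z[j] - self.z[i])
        return disp <= self.model.gate_mm(gap, self.frame_rate)

    def _switch_partners(self, a, i, b):
        """Positions j in track b giving a valid tail swap with a at i."""
        out = []
        for j in range(-1, len(b)):
            head_b = b[:j + 1]
            tail_b = b[j + 1:]
            new_a = a[:i + 1] + tail_b
            new_b = head_b + a[i + 1:]
            if len(new_a) < 2 or len(new_b) < 2:
                continue
            ok = True
            if tail_b and not self._gated(a[i], tail_b[0]):
                ok = False
            if head_b and len(a) > i + 1 and not self._gated(head_b[-1], a[i + 1]):
                ok = False
            if not head_b and len(a) > i + 1:
                pass  # new_b starts at a[i+1]
            if ok:
                out.append(j)
        return out

    def _move_switch(self):
        if len(self.tracks) < 2:
            return False
        tids = list(self.tracks)
        ia, ib = self.rng.choice(len(tids), size=2, replace=False)
        ta, tb = tids[ia], tids[ib]
        a, b = self.tracks[ta], self.tracks[tb]
        i = int(self.rng.integers(len(a)))
        partners = self._switch_partners(a, i, b)
        if not partners:
            return False
        j = partners[self.rng.integers(len(partners))]
        new_a = a[:i + 1] + b[j + 1:]
        new_b = b[:j + 1] + a[i + 1:]
        if len(new_a) < 2 or len(new_b) < 2:
            return False
        logq = self.log_move["switch"] - math.log(len(tids) * (len(tids) - 1)) \
            - math.log(len(a)) - math.log(len(partners))
        ll_a, ll_b = self._loglik(new_a), self._loglik(new_b)
        delta = ll_a + ll_b - self.track_ll[ta] - self.track_ll[tb]
        # reverse: same ordered pair, a at same position i in new_a
        self._replace_two(ta, new_a, tb, new_b)
        partners_rev = self._switch_partners(new_a, i, new_b)
        logq_rev = self.log_move["switch"] \
            - math.log(len(tids) * (len(tids) - 1)) \
            - math.log(len(new_a)) - math.log(len(partners_rev))
        if self._accept(delta, logq, logq_rev):
            return True
        self._replace_two(ta, a, tb, b)
        return False

    def _move_update(self):
        if not self.tracks:
            return False
        tids = list(self.tracks)
        tid = tids[self.rng.integers(len(tids))]
        track = self.tracks[tid]
        tail = self.rng.random() < 0.5
        anchor = track[-2] if tail else track[1]
        old = track[-1] if tail else track[0]
        cands = self._clutter_succ(anchor) if tail else self._clutter_pred(anchor)
        if not cands:
            return False
        r = cands[self.rng.integers(len(cands))]
        new_track = track[:-1] + [r] if tail else [r] + track[1:]
        logq = self.log_move["update"] - math.log(len(tids)) - math.log(2) \
            - math.log(len(cands))
        nbrs = self.succ[anchor] if tail else self.pred[anchor]
        k_rev = sum(1 for j in nbrs if (self.assign[j] == -1 and j != r) or j == old)
        logq_rev = self.log_move["update"] - math.log(len(tids)) - math.log(2) \
            - math.log(k_rev)
        new_ll = self._loglik(new_track)
        delta = new_ll - self.track_ll[tid]
        if self._accept(delta, logq, logq_rev):
            self._replace_track(tid, new_track)
            return True
        return False

    # -- partition I/O -----------------------------------------------------

    def set_partition(self, tracks):
        """Install an initial partition (list of index lists)."""
        for tid in list(self.tracks):
            self._remove_track(tid)
        for t in tracks:
            if len(t) >= 2:
                self._install_track(t)

    def snapshot(self):
        return [list(t) for t in self.tracks.values()]

    def canonical(self):
        """Hashable canonical form of the current partition."""
        return frozenset(tuple(t) for t in self.tracks.values())


def nn_partition(detections, model: MotionModel, frame_rate: float) -> list:
    """Greedy frame-to-frame nearest-neighbor linking under the gate.

    Deterministic; candidate links are taken in ascending (distance,
    detection index) order.  Returns a list of detection-index lists.
    """
    n = len(detections)
    frame = np.array([d.frame_index for d in detections], dtype=int)
    xs = np.array([d.x for d in detections])
    zs = np.array([d.z for d in detections])
    order = np.argsort(frame, kind="stable")
    tracks = []          # lists of det indices
    active = []          # (track_idx) with last det
    frames_sorted = np.unique(frame)
    by_frame = {f: [i for i in order if frame[i] == f] for f in frames_sorted}
    last_det = {}        # track_idx -> det idx
    for f in frames_sorted:
        dets_here = by_frame[f]
        # candidate (dist, det index, track) triples
        cands = []
        for t in active:
            i = last_det[t]
            gap = int(f - frame[i])
            if gap > model.max_gap + 1:
                continue
            gate = model.gate_mm(gap, frame_rate)
            for j in dets_here:
                dist = math.hypot(xs[j] - xs[i], zs[j] - zs[i])
                if dist <= gate:
                    cands.append((dist, j, t))
        cands.sort(key=lambda c: (c[0], c[1], c[2]))
        used_tracks = set()
        used_dets = set()
        for dist, j, t in cands:
            if t in used_tracks or j in used_dets:
                continue
            tracks[t].append(j)
            last_det[t] = j
            used_tracks.add(t)
            used_dets.add(j)
        for j in dets_here:
            if j not in used_dets:
                t = len(tracks)
                tracks.append([j])
                last_det[t] = j
                active.append(t)
        active = [t for t in active if f - frame[last_det[t]] <= model.max_gap]
    return [t for t in tracks if len(t) >= 2]


def _tracks_from_indices(index_lists, detections, model, frame_rate,
                         smooth_window=1, min_length=None) -> TrackSet:
    min_length = model.min_track_length if min_length is None else min_length
    out = []
    for t in index_lists:
        if len(t) < min_length:
            continue
        tr = Track(frames=[detections[i].frame_index for i in t],
                   x=[detections[i].x for i in t],
                   z=[detections[i].z for i in t],
                   detection_indices=np.asarray(t))
        if model.min_net_speed > 0 and len(tr) >= 2:
            span_s = (tr.frames[-1] - tr.frames[0]) / frame_rate
            net = float(np.hypot(tr.x[-1] - tr.x[0], tr.z[-1] - tr.z[0]))
            if net / span_s < model.min_net_speed:
                continue
        if len(tr) >= 2:
            tr = estimate_velocities(tr, frame_rate, smooth_window=smooth_window,
                                     max_speed=model.max_speed)
        out.append(tr)
    return TrackSet(tracks=out)


def nn_track(detections_by_frame, model: MotionModel, frame_rate: float,
             smooth_window: int = 1) -> TrackSet:
    """Nearest-neighbor baseline tracker; same gate as the MCMC tracker."""
    dets = [d for fr in detections_by_frame for d in fr]
    idx = nn_partition(dets, model, frame_rate)
    return _tracks_from_indices(idx, dets, model, frame_rate, smooth_window)


def mcmcda_track(detections_by_frame, model: MotionModel, frame_rate: float,
                 n_iterations: int = 20000, burn_in: int = 5000,
                 seed: int = 0, move_probabilities=None, init: str = "nn",
                 smooth_window: int = 1, return_sampler: bool = False):
    """MAP multi-target tracking by MCMC data association.

    Runs a Metropolis-Hastings chain over partitions and returns the best
    partition visited as a TrackSet (tracks below ``min_track_length`` are
    dropped from the output but participate in the search).  Reproducible
    for a given seed.  ``init`` is "nn" (nearest-neighbor start) or "cold"
    (all clutter).
    """
    dets = [d for fr in detections_by_frame for d in fr]
    if not dets:
        ts = TrackSet(tracks=[])
        return (ts, None) if return_sampler else ts
    sampler = MCMCDASampler(dets, model, frame_rate, rng=seed,
                            move_probabilities=move_probabilities)
    if init == "nn":
        sampler.set_partition(nn_partition(dets, model, frame_rate))
    elif init != "cold":
        raise ValidationError(f"unknown init {init!r}")
    best_ll = sampler.total_ll
    best = sampler.snapshot()
    for it in range(n_iterations):
        accepted, _ = sampler.propose()
        if accepted and sampler.total_ll > best_ll + 1e-12:
            best_ll = sampler.total_ll
            best = sampler.snapshot()
    ts = _tracks_from_indices(best, dets, model, frame_rate, smooth_window)
    if return_sampler:
        return ts, sampler
    return ts


# ---------------------------------------------------------------------------
# Velocities
# ---------------------------------------------------------------------------

def estimate_velocities(track: Track, frame_rate: float,
                        smooth_window: int = 1, max_speed: float = None) -> Track:
    """Per-detection velocities by finite differencing positions over time.

    ``smooth_window`` = 1 gives central differences at interior detections
    (forward/backward at the ends), dividing by the actual frame spacing
    across gaps.  An odd window >= 3 fits a local linear regression of
    position on time over that many detections — differentiation amplifies
    localization noise by the frame rate, and the windowed fit damps it.
    Speed magnitudes are clipped at ``max_speed``.
    """
    n = len(track)
    if n < 2:
        raise ValidationError("need >= 2 detections to estimate velocities")
    t = track.frames / frame_rate
    vx = np.empty(n)
    vz = np.empty(n)
    if smooth_window <= 1:
        for k in range(n):
            lo = max(0, k - 1)
            hi = min(n - 1, k + 1)
            dt = t[hi] - t[lo]
            vx[k] = (track.x[hi] - track.x[lo]) / dt
            vz[k] = (track.z[hi] - track.z[lo]) / dt
    else:
        h = smooth_window // 2
        for k in range(n):
            lo = max(0, k - h)
            hi = min(n, k + h + 1)
            tt = t[lo:hi] - t[lo:hi].mean()
            denom = float(np.sum(tt * tt))
            if denom == 0:
                vx[k] = vz[k] = 0.0
                continue
            vx[k] = float(np.sum(tt * (track.x[lo:hi] - track.x[lo:hi].mean()))) / denom
            vz[k] = float(np.sum(tt * (track.z[lo:hi] - track.z[lo:hi].mean()))) / denom
    if max_speed is not None:
        speed = np.hypot(vx, vz)
        over = speed > max_speed
        if np.any(over):
            scale = max_speed / speed[over]
            vx[over] *= scale
            vz[over] *= scale
    track.vx = vx
    track.vz = vz
    return track
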