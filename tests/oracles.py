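"""Brute-force oracles used by the tracking tests.

The partition enumerator walks detections in frame order and assigns each
to clutter, to the tail of an existing track, or to a new track, honoring
the same speed/gap gate as the sampler; partitions containing length-1
tracks are discarded at the leaves.  Every valid partition is scored with
the package's posterior, so the oracle checks the *search*, while the
posterior itself is validated separately against closed forms.
"""

import math

from tuvi import Partition, partition_log_posterior


def gated(dets, model, frame_rate, i, j):
    gap = dets[j].frame_index - dets[i].frame_index
    if not (1 <= gap <= model.max_gap + 1):
        return False
    d = math.hypot(dets[j].x - dets[i].x, dets[j].z - dets[i].z)
    return d <= model.gate_mm(gap, frame_rate)


def enumerate_partitions(dets, model, frame_rate):
    """{frozenset of track tuples: log posterior} over all valid partitions."""
    order = sorted(range(len(dets)), key=lambda i: dets[i].frame_index)
    results = {}

    def rec(k, tracks):
        if k == len(order):
            if any(len(t) == 1 for t in tracks):
                return
            p = Partition(detections=dets, tracks=[list(t) for t in tracks])
            key = frozenset(tuple(t) for t in tracks)
            results[key] = partition_log_posterior(p, model, frame_rate)
            return
        i = order[k]
        rec(k + 1, tracks)                       # clutter
        for t in tracks:                          # extend a track
            if gated(dets, model, frame_rate, t[-1], i):
                t.append(i)
                rec(k + 1, tracks)
                t.pop()
        tracks.append([i])                        # start a new track
        rec(k + 1, tracks)
        tracks.pop()

    rec(0, [])
    return results


def best_partition(dets, model, frame_rate):
    """(canonical key, score) of the exhaustive MAP partition."""
    scores = enumerate_partitions(dets, model, frame_rate)
    key = max(scores, key=scores.get)
    return key, scores[key]
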