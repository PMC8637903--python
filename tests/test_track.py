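"""MCMC data association: posterior, moves, MAP search, baselines, velocities."""

import math

import numpy as np
import pytest
from scipy import stats

from tuvi import (Detection, MotionModel, Partition, Track, TrackSet,
                  ValidationError, estimate_velocities, mcmcda_track, nn_track,
                  partition_log_posterior)
from tuvi.localize import detections_to_frame_lists
from tuvi.track import MCMCDASampler, MOVES, nn_partition, save_tracks, load_tracks
from tests.oracles import enumerate_partitions, best_partition

FR = 100.0


def det(frame, x, z):
    return Detection(frame_index=frame, x=x, z=z, intensity=1.0)


@pytest.fixture
def model():
    return MotionModel(field_area=50.0, max_speed=50.0, min_track_length=2,
                       max_gap=1, min_net_speed=0.0)


def linear_dets(n=10, v=(0.1, 0.2), start=(0.0, 5.0)):
    return [det(f, start[0] + v[0] * f, start[1] + v[1] * f) for f in range(n)]


class TestPosterior:
    def test_clutter_only_closed_form(self, model):
        dets = linear_dets(5)
        p = Partition(detections=dets, tracks=[])
        expected = 5 * math.log(model.clutter_rate / model.field_area)
        assert partition_log_posterior(p, model, FR) == pytest.approx(expected)

    def test_linear_track_beats_clutter(self, model):
        dets = linear_dets(5)
        as_track = Partition(detections=dets, tracks=[list(range(5))])
        as_clutter = Partition(detections=dets, tracks=[])
        assert (partition_log_posterior(as_track, model, FR)
                > partition_log_posterior(as_clutter, model, FR))

    def test_empty_detection_set_scores_zero(self, model):
        p = Partition(detections=[], tracks=[])
        assert partition_log_posterior(p, model, FR) == 0.0

    def test_invalid_partition_rejected(self, model):
        dets = [det(0, 0, 0), det(0, 1, 1)]   # same frame in one track
        p = Partition(detections=dets, tracks=[[0, 1]])
        with pytest.raises(ValidationError):
            partition_log_posterior(p, model, FR)

    def test_gate_violation_rejected(self, model):
        dets = [det(0, 0, 0), det(1, 30.0, 0)]  # 30 mm in one frame at 100 Hz
        p = Partition(detections=dets, tracks=[[0, 1]])
        with pytest.raises(ValidationError):
            partition_log_posterior(p, model, FR)


class TestMCMCDA:
    def test_single_bubble_fully_linked(self, model):
        dets = linear_dets(10)
        ts = mcmcda_track(detections_to_frame_lists(dets), model, FR,
                          n_iterations=2000, seed=0)
        assert len(ts) == 1
        assert len(ts.tracks[0]) == 10

    def test_empty_input_empty_trackset(self, model):
        assert len(mcmcda_track([[], []], model, FR, n_iterations=10, seed=0)) == 0

    def test_invalid_move_probabilities_rejected(self, model):
        dets = linear_dets(4)
        with pytest.raises(ValidationError):
            mcmcda_track(detections_to_frame_lists(dets), model, FR,
                         n_iterations=10, seed=0,
                         move_probabilities={m: 1.0 for m in MOVES})

    @pytest.mark.parametrize("init", ["cold", "nn"])
    def test_map_matches_exhaustive_enumeration(self, model, init):
        """On <= 8-detection instances the chain's best partition equals the
        brute-force MAP under the same posterior."""
        rng = np.random.default_rng(5)
        n_checked = 0
        for trial in range(8):
            dets = []
            for f in range(4):
                dets.append(det(f, 0.1 * f + rng.normal(0, 0.03),
                                2.0 - 0.1 * f + rng.normal(0, 0.03)))
                dets.append(det(f, 0.4 - 0.1 * f + rng.normal(0, 0.03),
                                1.6 + 0.1 * f + rng.normal(0, 0.03)))
            n = int(rng.integers(5, 9))
            dets = dets[:n]
            key_best, s_best = best_partition(dets, model, FR)
            smp = MCMCDASampler(dets, model, FR, rng=np.random.default_rng(100 + trial))
            if init == "nn":
                smp.set_partition(nn_partition(dets, model, FR))
            best_ll, best_key = smp.total_ll, smp.canonical()
            for _ in range(6000):
                smp.propose()
                if smp.total_ll > best_ll + 1e-12:
                    best_ll, best_key = smp.total_ll, smp.canonical()
            assert best_key == key_best
            assert best_ll == pytest.approx(s_best, abs=1e-6)
            n_checked += 1
        assert n_checked == 8

    def test_chain_targets_enumerated_posterior(self):
        """Chi-square: long-run visit frequencies match the normalized
        posterior on a flat-landscape instance."""
        model = MotionModel(field_area=4.0, max_speed=60.0, min_track_length=2,
                            max_gap=1, measurement_noise_sigma=0.3,
                            process_noise_sigma=0.2, clutter_rate=2.0,
                            min_net_speed=0.0)
        dets = [det(0, 0.0, 1.0), det(1, 0.1, 1.1), det(1, 0.5, 0.6),
                det(2, 0.2, 1.2), det(3, 0.3, 1.25)]
        probs_raw = enumerate_partitions(dets, model, FR)
        vals = np.array(list(probs_raw.values()))
        Z = np.exp(vals - vals.max()).sum()
        probs = {k: math.exp(v - vals.max()) / Z for k, v in probs_raw.items()}

        smp = MCMCDASampler(dets, model, FR, rng=np.random.default_rng(11))
        counts = {}
        N, burn, thin = 600000, 20000, 25
        for it in range(N):
            smp.propose()
            if it >= burn and it % thin == 0:
                key = smp.canonical()
                counts[key] = counts.get(key, 0) + 1
        tot = sum(counts.values())
        chi2, dof, rest_o, rest_e = 0.0, 0, 0.0, 0.0
        for k, pexp in probs.items():
            E = pexp * tot
            o = counts.get(k, 0)
            if E >= 10:
                chi2 += (o - E) ** 2 / E
                dof += 1
            else:
                rest_o += o
                rest_e += E
        if rest_e > 0:
            chi2 += (rest_o - rest_e) ** 2 / rest_e
            dof += 1
        assert stats.chi2.sf(chi2, dof - 1) > 1e-4
        # and the chain never visits a partition the oracle does not know
        assert all(k in probs for k in counts)

    def test_chain_states_always_valid(self, model):
        """Every accepted move leaves a valid partition (reversible moves
        produce well-formed proposals)."""
        rng = np.random.default_rng(3)
        dets = [det(int(rng.integers(0, 6)), rng.uniform(0, 2), rng.uniform(0, 2))
                for _ in range(14)]
        smp = MCMCDASampler(dets, model, FR, rng=np.random.default_rng(9))
        for it in range(3000):
            smp.propose()
            if it % 100 == 0:
                p = Partition(detections=dets,
                              tracks=[list(t) for t in smp.tracks.values()])
                p.validate(model, FR)  # raises on any invariant violation
                # cached score matches a fresh evaluation
                assert smp.total_ll == pytest.approx(
                    partition_log_posterior(p, model, FR), abs=1e-6)


class TestNNBaseline:
    def test_single_bubble_matches_mcmcda(self, model):
        dets = linear_dets(8)
        by = detections_to_frame_lists(dets)
        ts_nn = nn_track(by, model, FR)
        ts_mc = mcmcda_track(by, model, FR, n_iterations=1000, seed=1)
        assert len(ts_nn) == len(ts_mc) == 1
        assert np.allclose(ts_nn.tracks[0].x, ts_mc.tracks[0].x)

    def test_two_separated_bubbles(self, model):
        dets = (linear_dets(6, start=(0.0, 2.0))
                + linear_dets(6, v=(-0.1, 0.1), start=(5.0, 8.0)))
        ts = nn_track(detections_to_frame_lists(dets), model, FR)
        assert len(ts) == 2
        assert sorted(len(t) for t in ts.tracks) == [6, 6]

    def test_crossing_bubbles_nn_vs_mcmcda(self):
        """At a crossing, greedy NN can swap identities; the MCMC MAP scores
        at least as well under the shared posterior (it is initialized from
        the NN partition and only improves)."""
        model = MotionModel(field_area=50.0, max_speed=80.0, min_track_length=2,
                            max_gap=0, measurement_noise_sigma=0.08,
                            min_net_speed=0.0)
        rng = np.random.default_rng(2)
        dets = []
        for f in range(7):
            dets.append(det(f, 0.2 * f + rng.normal(0, 0.01), 1.0))
            dets.append(det(f, 1.2 - 0.2 * f + rng.normal(0, 0.01), 1.0))
        by = detections_to_frame_lists(dets)
        nn_idx = nn_partition(dets, model, FR)
        p_nn = partition_log_posterior(
            Partition(detections=dets, tracks=nn_idx), model, FR)
        key_best, s_best = best_partition(dets, model, FR)
        ts, smp = mcmcda_track(by, model, FR, n_iterations=8000, seed=4,
                               return_sampler=True)
        assert s_best >= p_nn - 1e-9
        # the MAP keeps the two constant-velocity identities distinct
        assert len(key_best) == 2
        for t in key_best:
            xs = [dets[i].x for i in t]
            assert (np.all(np.diff(xs) > 0) or np.all(np.diff(xs) < 0))

    def test_deterministic(self, model):
        rng = np.random.default_rng(8)
        dets = [det(int(rng.integers(0, 5)), rng.uniform(0, 3), rng.uniform(0, 3))
                for _ in range(20)]
        by = detections_to_frame_lists(dets)
        a = nn_track(by, model, FR).to_dataframe()
        b = nn_track(by, model, FR).to_dataframe()
        assert a.equals(b)


class TestVelocities:
    def test_pump_rate_quotient(self):
        # 0.02 mm per frame at 1500 Hz -> 30 mm/s
        t = Track(frames=np.arange(10), x=0.02 * np.arange(10),
                  z=np.full(10, 30.0))
        t = estimate_velocities(t, 1500.0)
        assert np.allclose(t.speeds, 30.0)

    def test_stationary_detections_zero_velocity(self):
        t = Track(frames=np.arange(6), x=np.full(6, 1.0), z=np.full(6, 2.0))
        t = estimate_velocities(t, 100.0)
        assert np.allclose(t.speeds, 0.0)

    def test_quadratic_trajectory_second_order_accuracy(self):
        # x(t) = a t^2: central difference at interior points is exact
        fr = 100.0
        frames = np.arange(12)
        tt = frames / fr
        a = 5.0
        t = Track(frames=frames, x=a * tt ** 2, z=np.zeros(12))
        t = estimate_velocities(t, fr)
        assert np.allclose(t.vx[1:-1], 2 * a * tt[1:-1], atol=1e-9)

    def test_gap_handled_by_actual_spacing(self):
        t = Track(frames=np.array([0, 1, 4]), x=np.array([0.0, 0.1, 0.4]),
                  z=np.zeros(3))
        t = estimate_velocities(t, 10.0)
        assert t.vx[1] == pytest.approx((0.4 - 0.0) / 0.4)

    def test_speeds_clipped_at_max_speed(self):
        t = Track(frames=np.arange(4), x=np.arange(4) * 1.0, z=np.zeros(4))
        t = estimate_velocities(t, 1000.0, max_speed=100.0)
        assert np.all(t.speeds <= 100.0 + 1e-9)

    def test_single_detection_rejected(self):
        t = Track(frames=np.array([0]), x=np.array([0.0]), z=np.array([0.0]))
        with pytest.raises(ValidationError):
            estimate_velocities(t, 100.0)

    def test_smoothing_window_reduces_noise(self, rng):
        fr = 1500.0
        frames = np.arange(200)
        x = 0.02 * frames + rng.normal(0, 0.02, 200)
        t1 = estimate_velocities(Track(frames=frames, x=x.copy(),
                                       z=np.zeros(200)), fr, smooth_window=1)
        t2 = estimate_velocities(Track(frames=frames, x=x.copy(),
                                       z=np.zeros(200)), fr, smooth_window=21)
        err1 = np.abs(t1.vx - 30.0).mean()
        err2 = np.abs(t2.vx - 30.0).mean()
        assert err2 < err1 / 2


class TestTrackIO:
    def test_csv_roundtrip(self, tmp_path):
        t = Track(frames=np.arange(5), x=np.linspace(0, 1, 5),
                  z=np.linspace(30, 31, 5))
        t = estimate_velocities(t, 100.0)
        ts = TrackSet(tracks=[t])
        save_tracks(tmp_path / "t.csv", ts, sidecar={"note": "test"})
        back = load_tracks(tmp_path / "t.csv")
        assert len(back) == 1
        assert np.allclose(back.tracks[0].x, t.x)
        assert (tmp_path / "t.csv.json").exists()
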