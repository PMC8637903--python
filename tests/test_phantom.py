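"""Vessel phantom geometry, bubble kinematics, chirp synthesis, RF model."""

import numpy as np
import pytest
from scipy.signal import hilbert
from scipy.stats import linregress

import tuvi
from tuvi import (AcquisitionParams, ValidationError, VesselSegment,
                  advance_bubbles, build_vessel_phantom, seed_bubbles,
                  simulate_acquisition, simulate_rf_frame, synthesize_chirp)
from tests.conftest import make_bubble


class TestVesselPhantom:
    def test_two_tube_preset_diameters(self):
        phantom = build_vessel_phantom("two_tube")
        assert len(phantom.segments) == 2
        assert sorted(s.diameter for s in phantom.segments) == [0.7, 1.0]

    def test_empty_segment_list_rejected(self):
        with pytest.raises(ValidationError):
            build_vessel_phantom("custom", segments=[], field_extent=(-5, 5, 0, 40))

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValidationError):
            build_vessel_phantom("no_such_phantom")

    def test_segment_outside_field_rejected(self):
        seg = VesselSegment(np.array([[-30.0, 20.0], [30.0, 20.0]]),
                            diameter=1.0, flow_speed=30.0)
        with pytest.raises(ValidationError, match="segment 0"):
            build_vessel_phantom("custom", segments=[seg],
                                 field_extent=(-10, 10, 0, 40))

    def test_truth_map_area_matches_analytic_rectangle(self):
        # straight 0.7 mm tube of length 10 mm: area = length x diameter
        # plus two half-disc end caps
        seg = VesselSegment(np.array([[-5.0, 20.0], [5.0, 20.0]]),
                            diameter=0.7, flow_speed=30.0)
        phantom = build_vessel_phantom("custom", segments=[seg],
                                       field_extent=(-8, 8, 15, 25))
        truth, xc, zc = phantom.render_truth_map(cell_size=0.01)
        area = truth.sum() * 0.01 ** 2
        expected = 10.0 * 0.7 + np.pi * 0.35 ** 2
        assert area == pytest.approx(expected, rel=0.02)

    def test_depth_ladder_spans_10_to_55mm(self):
        phantom = build_vessel_phantom("depth_ladder")
        depths = sorted(s.centerline[0, 1] for s in phantom.segments)
        assert depths[0] == 10.0 and depths[-1] == 55.0


class TestBubbles:
    @pytest.fixture
    def phantom(self):
        return build_vessel_phantom("two_tube")

    def test_zero_concentration_yields_no_bubbles(self, phantom):
        assert seed_bubbles(phantom, 0.0, seed=0) == []

    def test_negative_concentration_rejected(self, phantom):
        with pytest.raises(ValidationError):
            seed_bubbles(phantom, -1.0, seed=0)

    def test_same_seed_reproduces_population(self, phantom):
        a = seed_bubbles(phantom, 1.0, seed=42)
        b = seed_bubbles(phantom, 1.0, seed=42)
        assert len(a) == len(b)
        for ba, bb in zip(a, b):
            assert np.allclose(ba.position, bb.position)
            assert ba.amplitude == bb.amplitude

    def test_count_within_poisson_interval(self, phantom):
        # 2 bubbles/mm on ~32.6 mm of vessel: lambda ~ 65, check 3 sigma
        lam = 2.0 * phantom.total_length
        n = len(seed_bubbles(phantom, 2.0, seed=7))
        assert abs(n - lam) < 3.0 * np.sqrt(lam)

    def test_bubbles_inside_lumen(self, phantom):
        bubbles = seed_bubbles(phantom, 2.0, seed=3)
        pos = np.array([b.position for b in bubbles])
        assert phantom.contains(pos).all()

    def test_single_step_displacement(self, phantom):
        b = seed_bubbles(phantom, 1.0, seed=1)[0]
        nb = advance_bubbles([b], phantom, 1.0 / 1500.0)[0]
        assert nb.arc_coordinate - b.arc_coordinate == pytest.approx(
            30.0 / 1500.0, abs=1e-12)

    def test_accumulated_displacement_closed_form(self, phantom):
        bubbles = [seed_bubbles(phantom, 1.0, seed=1)[0]]
        s0 = bubbles[0].arc_coordinate
        rng = np.random.default_rng(0)
        for _ in range(100):
            bubbles = advance_bubbles(bubbles, phantom, 1e-3, rng=rng)
        # 100 steps of 1 ms at 30 mm/s -> 3.0 mm (modulo recycling)
        seg = phantom.segments[bubbles[0].segment_id]
        delta = (bubbles[0].arc_coordinate - s0) % seg.length
        assert delta == pytest.approx(3.0 % seg.length, abs=1e-9)

    def test_zero_dt_rejected(self, phantom):
        with pytest.raises(ValidationError):
            advance_bubbles([], phantom, 0.0)

    def test_population_conserved_under_recycling(self, phantom):
        bubbles = seed_bubbles(phantom, 2.0, seed=5)
        rng = np.random.default_rng(1)
        for _ in range(300):
            bubbles = advance_bubbles(bubbles, phantom, 0.02, rng=rng)
        assert len(bubbles) == len(seed_bubbles(phantom, 2.0, seed=5))
        pos = np.array([b.position for b in bubbles])
        assert phantom.contains(pos).all()


class TestChirp:
    def test_sample_count(self):
        p = AcquisitionParams(chirp_duration=6.0, sampling_rate=20.0)
        assert len(synthesize_chirp(p)) == 120

    def test_midpoint_instantaneous_frequency(self):
        # phase-derivative oracle on the sampled waveform
        p = AcquisitionParams(sweep_low=1.3, sweep_high=2.7,
                              chirp_duration=6.0, sampling_rate=40.0)
        w = synthesize_chirp(p)
        phase = np.unwrap(np.angle(hilbert(w)))
        f_inst = np.diff(phase) / (2 * np.pi) * p.sampling_rate
        mid = len(f_inst) // 2
        assert np.mean(f_inst[mid - 3:mid + 3]) == pytest.approx(2.0, abs=0.05)

    def test_nyquist_violation_names_bound(self):
        p = AcquisitionParams(sampling_rate=5.0, sweep_high=2.7)
        with pytest.raises(ValidationError, match="Nyquist"):
            synthesize_chirp(p)

    def test_zero_bandwidth_is_tone_burst(self):
        p = AcquisitionParams(sweep_low=2.0, sweep_high=2.0)
        w = synthesize_chirp(p)
        phase = np.unwrap(np.angle(hilbert(w)))
        f_inst = np.diff(phase) / (2 * np.pi) * p.sampling_rate
        inner = f_inst[20:-20]  # away from the taper
        assert np.allclose(inner, 2.0, atol=0.05)

    def test_unit_peak_amplitude(self):
        w = synthesize_chirp(AcquisitionParams())
        assert np.abs(w).max() == pytest.approx(1.0)


class TestRFFrame:
    def test_geometric_delay_oracle(self, small_params):
        """Compressed peak delay equals the analytic two-way path time."""
        p = small_params
        b = make_bubble(0.0, 30.0)
        w = synthesize_chirp(p)
        rf = simulate_rf_frame([b], p.element_positions, 0.0, w, p)
        from tuvi import pulse_compress
        c = pulse_compress(rf, w)
        for ch in (0, 15, 31):
            env = np.abs(hilbert(c[ch]))
            t_peak = np.argmax(env) / p.sampling_rate
            t_true = (30.0 + np.hypot(p.element_positions[ch], 30.0)) / p.c_mm_us
            assert abs(t_peak - t_true) <= 1.0 / p.sampling_rate

    def test_no_bubbles_zero_noise_gives_zero_frame(self, small_params):
        w = synthesize_chirp(small_params)
        rf = simulate_rf_frame([], small_params.element_positions, 0.0, w,
                               small_params)
        assert not rf.any()

    def test_amplitude_linearity(self, small_params):
        w = synthesize_chirp(small_params)
        elem = small_params.element_positions
        rf1 = simulate_rf_frame([make_bubble(2.0, 25.0, 1.0)], elem, 3.0, w,
                                small_params)
        rf2 = simulate_rf_frame([make_bubble(2.0, 25.0, 2.0)], elem, 3.0, w,
                                small_params)
        assert np.allclose(rf2, 2.0 * rf1)

    def test_superposition_of_bubble_sets(self, small_params):
        w = synthesize_chirp(small_params)
        elem = small_params.element_positions
        b1, b2 = make_bubble(-3.0, 20.0), make_bubble(4.0, 35.0)
        both = simulate_rf_frame([b1, b2], elem, -3.0, w, small_params)
        split = (simulate_rf_frame([b1], elem, -3.0, w, small_params)
                 + simulate_rf_frame([b2], elem, -3.0, w, small_params))
        assert np.allclose(both, split, atol=1e-12)

    def test_bubble_behind_array_excluded_with_warning(self, small_params, caplog):
        w = synthesize_chirp(small_params)
        with caplog.at_level("WARNING", logger="tuvi"):
            rf = simulate_rf_frame([make_bubble(0.0, -5.0)],
                                   small_params.element_positions, 0.0, w,
                                   small_params)
        assert not rf.any()
        assert "behind the array" in caplog.text

    def test_steep_angle_rejected(self, small_params):
        w = synthesize_chirp(small_params)
        with pytest.raises(ValidationError):
            simulate_rf_frame([], small_params.element_positions, 95.0, w,
                              small_params)


class TestAcquisition:
    def test_sample_dimensions(self):
        phantom = build_vessel_phantom("two_tube")
        p = AcquisitionParams(n_channels=16, n_frames=4, noise_sigma=0.01,
                              max_depth=40.0, seed=3)
        seq = simulate_acquisition(phantom, p, concentration=0.5)
        nf, na, nch, nt = seq.samples.shape
        assert (nf, na, nch) == (4, 5, 16)
        assert len(seq.truth_tracks) == 4

    def test_bit_identical_reproducibility(self):
        phantom = build_vessel_phantom("two_tube")
        p = AcquisitionParams(n_channels=8, n_frames=3, noise_sigma=0.02,
                              max_depth=40.0, seed=11)
        a = simulate_acquisition(phantom, p, 0.5)
        b = simulate_acquisition(phantom, p, 0.5)
        assert np.array_equal(a.samples, b.samples)
        for ta, tb in zip(a.truth_tracks, b.truth_tracks):
            assert np.array_equal(ta, tb)

    def test_truth_track_advances_at_flow_speed(self):
        seg = VesselSegment(np.array([[-8.0, 30.0], [8.0, 30.0]]),
                            diameter=0.7, flow_speed=30.0)
        phantom = build_vessel_phantom("custom", segments=[seg],
                                       field_extent=(-10, 10, 25, 35))
        p = AcquisitionParams(n_channels=4, n_frames=30, noise_sigma=0.0,
                              max_depth=36.0, prf=1500.0, seed=2)
        seq = simulate_acquisition(phantom, p, concentration=0.05)
        # follow bubble id 0 while it stays in-field
        xs, ts = [], []
        for fi, tr in enumerate(seq.truth_tracks):
            row = tr[tr[:, 0] == 0]
            if len(row):
                xs.append(row[0, 1])
                ts.append(fi / p.prf)
        slope = linregress(ts, xs).slope
        assert abs(abs(slope) - 30.0) < 0.5

    @pytest.mark.parametrize("suffix", ["h5", "npz"])
    def test_rf_sequence_roundtrip(self, tmp_path, suffix):
        phantom = build_vessel_phantom("two_tube")
        p = AcquisitionParams(n_channels=4, n_frames=2, noise_sigma=0.01,
                              max_depth=40.0, seed=9)
        seq = simulate_acquisition(phantom, p, 0.3)
        path = tmp_path / f"rf.{suffix}"
        tuvi.save_rf_sequence(path, seq)
        back = tuvi.load_rf_sequence(path)
        assert np.allclose(back.samples, seq.samples)
        assert back.params.angles == p.angles
        assert back.params.n_frames == p.n_frames
        assert len(back.truth_tracks) == len(seq.truth_tracks)
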