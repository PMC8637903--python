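"""Pulse compression, delay-and-sum focusing, compounding, eigenspace mode."""

import numpy as np
import pytest
from scipy.signal import hilbert

from tuvi import (AcquisitionParams, ImageGrid, ImageStack, ValidationError,
                  coherent_compound, das_beamform, envelope, esb_beamform,
                  pulse_compress, simulate_rf_frame, synthesize_chirp)
from tests.conftest import make_bubble


def _compound_point_image(params, bubble, grid, angles=None, rng=None,
                          weighting=None):
    w = synthesize_chirp(params)
    imgs = []
    for ang in (angles if angles is not None else params.angles):
        rf = simulate_rf_frame([bubble], params.element_positions, ang, w,
                               params, rng=rng)
        rf = pulse_compress(rf, w, weighting=weighting)
        imgs.append(das_beamform(rf, params.element_positions, ang, grid, params))
    return envelope(coherent_compound(imgs))


class TestPulseCompression:
    def test_zero_input_zero_output(self, small_params):
        w = synthesize_chirp(small_params)
        out = pulse_compress(np.zeros((4, 500)), w)
        assert not out.any()

    def test_waveform_longer_than_record_rejected(self, small_params):
        w = synthesize_chirp(small_params)
        with pytest.raises(ValidationError):
            pulse_compress(np.zeros((4, 50)), w)

    def test_unit_echo_compresses_to_unit_peak(self, small_params):
        w = synthesize_chirp(small_params)
        rec = np.zeros(800)
        rec[300:300 + len(w)] = w
        c = pulse_compress(rec[None, :], w)[0]
        env = np.abs(hilbert(c))
        assert env.max() == pytest.approx(1.0, rel=0.02)
        assert abs(int(np.argmax(env)) - 300) <= 1

    def test_snr_gain_meets_time_bandwidth_benchmark(self, rng):
        """Monte-Carlo: envelope SNR gain from compression >= 10 log10(TB).

        TB = 1.4 MHz x 6 us = 8.4, so the classical benchmark is ~9.2 dB;
        against full-band white noise the matched filter does at least that.
        """
        p = AcquisitionParams()
        w = synthesize_chirp(p)
        tb_db = 10 * np.log10((p.sweep_high - p.sweep_low) * p.chirp_duration)
        gains = []
        for _ in range(30):
            rec = np.zeros(1500)
            rec[600:600 + len(w)] = 0.5 * w
            noisy = rec + rng.normal(0, 0.25, rec.shape)
            raw_env = np.abs(hilbert(noisy))
            c_env = np.abs(hilbert(pulse_compress(noisy[None, :], w)[0]))
            snr_raw = 0.5 / np.sqrt(np.mean(raw_env[:400] ** 2))
            snr_c = c_env[550:750].max() / np.sqrt(np.mean(c_env[:400] ** 2))
            gains.append(20 * np.log10(snr_c / snr_raw))
        assert np.mean(gains) >= tb_db

    def test_compressed_mainlobe_width_near_inverse_bandwidth(self, small_params):
        # -3 dB width of the compressed envelope ~ 1/bandwidth = 0.71 us
        p = small_params
        w = synthesize_chirp(p)
        rec = np.zeros(800)
        rec[300:300 + len(w)] = w
        env = np.abs(hilbert(pulse_compress(rec[None, :], w)[0]))
        half = env.max() / np.sqrt(2.0)
        above = np.flatnonzero(env >= half)
        width_us = (above.max() - above.min()) / p.sampling_rate
        assert width_us == pytest.approx(1.0 / (p.sweep_high - p.sweep_low),
                                         rel=0.45)

    def test_peak_delay_unbiased_under_noise(self, small_params, rng):
        """Matched-filter peak location is noise-invariant in expectation."""
        p = small_params
        w = synthesize_chirp(p)
        rec = np.zeros(1200)
        rec[500:500 + len(w)] = w
        shifts = []
        for _ in range(60):
            noisy = rec + rng.normal(0, 0.15, rec.shape)
            env = np.abs(hilbert(pulse_compress(noisy[None, :], w)[0]))
            shifts.append(int(np.argmax(env[400:700])) + 400 - 500)
        assert abs(np.mean(shifts)) < 1.0

    def test_unknown_weighting_rejected(self, small_params):
        w = synthesize_chirp(small_params)
        with pytest.raises(ValidationError):
            pulse_compress(np.zeros((1, 400)), w, weighting="blackman-nonsense")


class TestDAS:
    @pytest.fixture
    def grid(self):
        return ImageGrid.from_extent((-6.0, 6.0, 24.0, 36.0), 0.19)

    def test_point_focus_within_one_pixel(self, small_params, grid):
        img = _compound_point_image(small_params, make_bubble(1.5, 29.0), grid,
                                    angles=[0.0])
        iz, ix = np.unravel_index(np.argmax(img), img.shape)
        assert abs(grid.x_coords[ix] - 1.5) <= 0.2
        assert abs(grid.z_coords[iz] - 29.0) <= 0.2

    def test_all_zero_rf_gives_zero_image(self, small_params, grid):
        img = das_beamform(np.zeros((32, 1200)), small_params.element_positions,
                           0.0, grid, small_params)
        assert not np.abs(img).any()

    def test_linearity(self, small_params, grid):
        w = synthesize_chirp(small_params)
        elem = small_params.element_positions
        a = simulate_rf_frame([make_bubble(-2.0, 27.0)], elem, 0.0, w, small_params)
        b = simulate_rf_frame([make_bubble(3.0, 31.0)], elem, 0.0, w, small_params)
        img_sum = das_beamform(a + b, elem, 0.0, grid, small_params)
        img_a = das_beamform(a, elem, 0.0, grid, small_params)
        img_b = das_beamform(b, elem, 0.0, grid, small_params)
        assert np.allclose(img_sum, img_a + img_b, atol=1e-6)

    def test_translation_equivariance(self, small_params, grid):
        img1 = _compound_point_image(small_params, make_bubble(-1.0, 30.0), grid,
                                     angles=[0.0])
        img2 = _compound_point_image(small_params, make_bubble(1.0, 30.0), grid,
                                     angles=[0.0])
        p1 = np.unravel_index(np.argmax(img1), img1.shape)
        p2 = np.unravel_index(np.argmax(img2), img2.shape)
        shift_mm = (p2[1] - p1[1]) * grid.spacing[0]
        assert shift_mm == pytest.approx(2.0, abs=0.2)


class TestCompounding:
    def test_identical_images_unchanged(self):
        img = np.ones((4, 5), dtype=complex) * (1 + 2j)
        assert np.allclose(coherent_compound([img] * 5), img)

    def test_single_image_identity(self):
        img = np.arange(12, dtype=complex).reshape(3, 4)
        assert np.allclose(coherent_compound([img]), img)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            coherent_compound([np.zeros((3, 4)), np.zeros((4, 3))])

    def test_empty_list_rejected(self):
        with pytest.raises(ValidationError):
            coherent_compound([])

    def test_five_angle_compounding_narrows_lateral_lobe(self, small_params):
        grid = ImageGrid.from_extent((-6.0, 6.0, 27.0, 33.0), 0.19)
        b = make_bubble(0.0, 30.0)
        img1 = _compound_point_image(small_params, b, grid, angles=[0.0])
        img5 = _compound_point_image(small_params, b, grid)

        def lateral_width(img):
            iz, ix = np.unravel_index(np.argmax(img), img.shape)
            prof = img[iz]
            half = prof.max() / 2
            above = np.flatnonzero(prof >= half)
            return (above.max() - above.min()) * grid.spacing[0]

        assert lateral_width(img5) <= lateral_width(img1) + 1e-9


class TestEnvelope:
    @pytest.mark.parametrize("value,expected", [(1j, 1.0), (3 + 4j, 5.0), (0, 0.0)])
    def test_magnitude(self, value, expected):
        assert envelope(np.array([[value]]))[0, 0] == pytest.approx(expected)


class TestESB:
    def test_peak_position_matches_das_for_single_target(self, small_params):
        grid = ImageGrid.from_extent((-3.0, 3.0, 28.0, 32.0), 0.25)
        p = small_params
        w = synthesize_chirp(p)
        rf = simulate_rf_frame([make_bubble(0.5, 30.0)], p.element_positions,
                               0.0, w, p)
        rf = pulse_compress(rf, w)
        das_img = np.abs(das_beamform(rf, p.element_positions, 0.0, grid, p))
        esb_img = np.abs(esb_beamform(rf, p.element_positions, 0.0, grid, p,
                                      subaperture=8))
        assert (np.unravel_index(np.argmax(esb_img), esb_img.shape)
                == np.unravel_index(np.argmax(das_img), das_img.shape))

    def test_noise_energy_not_above_das(self, small_params, rng):
        grid = ImageGrid.from_extent((-3.0, 3.0, 28.0, 31.0), 0.3)
        p = small_params
        ratios = []
        for _ in range(5):
            rf = rng.normal(0, 1.0, (p.n_channels, 900))
            das_img = das_beamform(rf, p.element_positions, 0.0, grid, p)
            esb_img = esb_beamform(rf, p.element_positions, 0.0, grid, p,
                                   subaperture=8)
            ratios.append(np.sum(np.abs(esb_img) ** 2)
                          / np.sum(np.abs(das_img) ** 2))
        assert np.mean(ratios) <= 1.0

    def test_oversized_subaperture_rejected(self, small_params):
        grid = ImageGrid.from_extent((-2.0, 2.0, 29.0, 31.0), 0.5)
        with pytest.raises(ValidationError):
            esb_beamform(np.zeros((32, 600)), small_params.element_positions,
                         0.0, grid, small_params, subaperture=64)


class TestImageGridStack:
    def test_nonuniform_grid_rejected(self):
        with pytest.raises(ValidationError):
            ImageGrid(np.array([0.0, 1.0, 3.0]), np.array([0.0, 1.0, 2.0]))

    def test_stack_shape_checked(self):
        grid = ImageGrid.from_extent((0, 2, 0, 2), 0.5)
        with pytest.raises(ValidationError):
            ImageStack(frames=np.zeros((3, 2, 2)), grid=grid, frame_rate=100.0)

    def test_stack_roundtrip(self, tmp_path):
        import tuvi
        grid = ImageGrid.from_extent((0, 4, 10, 14), 0.5)
        stack = ImageStack(frames=(np.arange(128).reshape(2, 8, 8)
                                   + 1j * np.ones((2, 8, 8))).astype(np.complex64),
                           grid=grid, frame_rate=250.0)
        tuvi.save_image_stack(tmp_path / "s.h5", stack)
        back = tuvi.load_image_stack(tmp_path / "s.h5")
        assert np.allclose(back.frames, stack.frames)
        assert back.frame_rate == 250.0
        assert np.allclose(back.grid.x_coords, grid.x_coords)
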