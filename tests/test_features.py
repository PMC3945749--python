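"""MFCC, linear prediction / LSF, and RASTA-PLP feature extraction."""

import numpy as np
import pytest
from scipy.fft import idct
from scipy.linalg import toeplitz
from scipy.signal import lfilter

import mimicrank as mr
from mimicrank.features import (
    LOG_FLOOR,
    RASTA_DEN,
    RASTA_NUM,
    autocorrelate,
    bark_filterbank,
    hz_to_bark,
    log_mel_energies,
    mel_filter_centers,
    mel_filterbank,
    n_bark_bands,
)

RATE = 48000


def tone(freq, seconds=1.0, amp=0.9):
    t = np.arange(int(seconds * RATE)) / RATE
    return mr.AudioClip(samples=amp * np.sin(2 * np.pi * freq * t), rate=RATE)


def random_stable_lp(rng, order):
    """LP model from random poles strictly inside the unit circle."""
    poly = np.array([1.0])
    n_pairs = order // 2
    for _ in range(n_pairs):
        r = rng.uniform(0.3, 0.97)
        th = rng.uniform(0.05, np.pi - 0.05)
        poly = np.convolve(poly, [1.0, -2 * r * np.cos(th), r * r])
    if order % 2:
        poly = np.convolve(poly, [1.0, -rng.uniform(-0.95, 0.95)])
    return mr.LPModel(order=order, coefficients=-poly[1:], gain=1.0)


class TestMFCC:
    def test_dimension_is_39(self, tone_clip):
        ff = mr.compute_mfcc(tone_clip)
        assert ff.dim == 39 and ff.kind == "MFCC39"

    def test_stationary_tone_has_zero_dynamics(self):
        # 1 kHz advances an integer number of cycles per 720-sample hop,
        # so successive frames are identical and the dynamics vanish
        ff = mr.compute_mfcc(tone(1000.0))
        interior = ff.values[3:-3]
        assert np.max(np.abs(interior[:, 13:])) < 1e-6

    def test_tone_at_filter_center_dominates_that_band(self):
        centers = mel_filter_centers()
        for idx in (6, 12, 20):
            energies = log_mel_energies(tone(centers[idx]))
            assert np.argmax(energies.mean(axis=0)) == idx

    def test_dct_is_orthonormal(self, tone_clip):
        logmel = log_mel_energies(tone_clip)
        from scipy.fft import dct

        ceps = dct(logmel, type=2, norm="ortho", axis=1)
        assert np.max(np.abs(idct(ceps, type=2, norm="ortho", axis=1) - logmel)) < 1e-9

    def test_filterbank_covers_spectrum(self):
        fb = mel_filterbank()
        assert fb.shape == (32, 601)
        assert np.all(fb >= 0)
        # every filter is unimodal: rises then falls
        for row in fb:
            peak = np.argmax(row)
            assert np.all(np.diff(row[: peak + 1]) >= 0)
            assert np.all(np.diff(row[peak:]) <= 0)

    def test_too_short_clip_rejected(self):
        with pytest.raises(ValueError):
            mr.compute_mfcc(mr.AudioClip(samples=np.zeros(600), rate=RATE))


class TestLevinsonDurbin:
    def test_ar1_autocorrelation_recovers_coefficient(self):
        r = 0.5 ** np.arange(3)
        model = mr.levinson_durbin(r, 1)
        assert np.allclose(model.coefficients, [0.5])
        # order 2 on the same sequence: second coefficient vanishes
        model2 = mr.levinson_durbin(r, 2)
        assert abs(model2.coefficients[1]) < 1e-12

    def test_white_noise_gives_zero_predictor(self):
        model = mr.levinson_durbin(np.array([2.0, 0, 0, 0]), 3)
        assert np.allclose(model.coefficients, 0)
        assert model.gain == 2.0

    @pytest.mark.parametrize("order", [1, 2, 4, 8, 12])
    def test_equals_direct_yule_walker_solve(self, order):
        rng = np.random.default_rng(order)
        # positive-definite autocorrelation from a random power spectrum
        spec = rng.uniform(0.1, 1.0, 64)
        r = np.fft.irfft(spec)[: order + 1]
        model = mr.levinson_durbin(r, order)
        direct = np.linalg.solve(toeplitz(r[:order]), r[1 : order + 1])
        assert np.max(np.abs(model.coefficients - direct)) <= 1e-8

    def test_nonpositive_energy_rejected(self):
        with pytest.raises(ValueError):
            mr.levinson_durbin(np.array([0.0, 0.0]), 1)


class TestLSF:
    def test_trivial_predictor_closed_form(self):
        # A(z) = 1, p = 2: P = 1 + z^-3, Q = 1 - z^-3; non-trivial root
        # angles are pi/3 and 2*pi/3
        model = mr.LPModel(order=2, coefficients=np.zeros(2), gain=1.0)
        lsf = mr.lp_to_lsf(model)
        assert np.allclose(lsf.frequencies, [np.pi / 3, 2 * np.pi / 3])

    def test_interlacing_and_unit_circle_residence(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            model = random_stable_lp(rng, 10)
            lsf = mr.lp_to_lsf(model)
            f = lsf.frequencies
            assert np.all(np.diff(f) > 0)
            assert len(f) == 10
            # sorted union strictly alternates between P-roots and Q-roots
            origin = ["P" if w in lsf.p_frequencies else "Q" for w in f]
            assert all(a != b for a, b in zip(origin, origin[1:]))

    def test_reconstruction_inverts_decomposition(self):
        rng = np.random.default_rng(4)
        for order in (4, 9, 10):
            model = random_stable_lp(rng, order)
            back = mr.lsf_to_lp(mr.lp_to_lsf(model))
            assert np.max(np.abs(back - model.polynomial())) < 1e-6

    def test_unstable_model_rejected(self):
        model = mr.LPModel(order=1, coefficients=np.array([1.5]), gain=1.0)
        with pytest.raises(ValueError, match="stable"):
            mr.lp_to_lsf(model)

    def test_tone_resonance_is_bracketed(self):
        clip = tone(2000.0, 0.5)
        ff = mr.compute_lsf_features(clip)
        target = 2 * np.pi * 2000.0 / RATE
        for row in ff.values[1:-1]:
            assert row[0] < target < row[-1]
            k = np.searchsorted(row, target)
            assert 0 < k < len(row)  # an adjacent LSF pair brackets the tone

    def test_white_noise_lsfs_near_uniform_grid(self):
        rng = np.random.default_rng(5)
        frame = rng.standard_normal(48000)
        model = mr.levinson_durbin(autocorrelate(frame, 12), 12)
        lsf = mr.lp_to_lsf(model)
        grid = np.arange(1, 13) * np.pi / 13
        assert np.max(np.abs(lsf.frequencies - grid)) < 0.3

    def test_frame_count_matches_grid(self, tone_clip):
        ff = mr.compute_lsf_features(tone_clip)
        assert ff.n_frames + ff.n_excluded == 66


class TestPLPAuditorySpectrum:
    def test_zero_frame_floors(self):
        out = mr.plp_auditory_spectrum(np.zeros(601))
        assert np.all(out == LOG_FLOOR)

    def test_cube_root_homogeneity(self):
        rng = np.random.default_rng(6)
        frame = rng.uniform(0.1, 1.0, 601)
        a, b = mr.plp_auditory_spectrum(frame), mr.plp_auditory_spectrum(2 * frame)
        mask = a > LOG_FLOOR
        assert np.allclose(b[mask] / a[mask], 2**0.33, atol=1e-9)

    def test_band_count_from_bark_formula(self):
        # grid points at 1-Bark spacing over [0, Bark(Nyquist)]
        expected = int(np.floor(6 * np.arcsinh(24000 / 600))) + 1
        assert n_bark_bands(RATE) == expected
        assert bark_filterbank().shape[0] == expected

    def test_negative_power_rejected(self):
        with pytest.raises(ValueError):
            mr.plp_auditory_spectrum(np.full(601, -1.0))


class TestRastaFilter:
    def test_constant_trajectory_suppressed(self):
        y = mr.rasta_filter(np.ones(200))
        assert np.max(np.abs(y[50:])) < 1e-6

    def test_additive_offset_invariance(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(200)
        d = mr.rasta_filter(x) - mr.rasta_filter(x + 3.7)
        assert np.max(np.abs(d[50:])) < 1e-6

    def test_impulse_response(self):
        x = np.zeros(50)
        x[0] = 1.0
        y = mr.rasta_filter(x, init="zero")
        expected = lfilter(RASTA_NUM, RASTA_DEN, x)
        assert np.allclose(y, expected)
        # leading numerator taps are visible directly
        assert np.isclose(y[0], 0.2)

    def test_dc_gain_is_zero(self):
        assert abs(RASTA_NUM.sum()) < 1e-15

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError, match="frames"):
            mr.rasta_filter(np.ones(4))


class TestRastaPLPCC:
    def test_dimension_and_frame_count(self, tone_clip):
        ff = mr.compute_rasta_plpcc(tone_clip)
        assert ff.dim == 12
        assert ff.n_frames == 66

    def test_channel_gain_robustness(self, tone_clip):
        loud = mr.AudioClip(samples=np.clip(tone_clip.samples * 10, -1, 1) / 10 * 10, rate=RATE)
        loud.samples = tone_clip.samples * 10
        a = mr.compute_rasta_plpcc(tone_clip).values
        b = mr.compute_rasta_plpcc(loud).values
        steady = slice(10, None)
        pooled_a, pooled_b = a[steady].mean(axis=0), b[steady].mean(axis=0)
        assert np.max(np.abs(pooled_a - pooled_b)) < 1e-3


class TestTranslationTolerance:
    @pytest.mark.parametrize("extractor", ["MFCC39", "LSF", "RASTA_PLPCC12"])
    def test_one_hop_shift_barely_moves_pooled_vector(self, extractor):
        clip = tone(1000.0)
        shifted = mr.AudioClip(samples=np.roll(clip.samples, 720), rate=RATE)
        a = mr.pool_frames(mr.extract_features(clip, extractor)).values
        b = mr.pool_frames(mr.extract_features(shifted, extractor)).values
        assert np.linalg.norm(a - b) < 0.01 * np.linalg.norm(a)
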