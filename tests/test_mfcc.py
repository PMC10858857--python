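"""The MFCC chain: analytic unit fixtures, framing law, oracle equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from melstage import reference as ref
from melstage.mfcc import (
    MfccConfigError,
    MfccParams,
    dct_cepstrum,
    extract_mfcc,
    frame_signal,
    hamming,
    hz_to_mel,
    log_energies,
    mel_filterbank,
    mel_to_hz,
    n_frames_expected,
    power_spectrum,
    pre_emphasis,
)


class TestMelScale:
    def test_analytic_values(self):
        assert hz_to_mel(0.0) == 0.0
        assert abs(hz_to_mel(700.0) - 2595.0 * np.log10(2.0)) < 1e-9

    @pytest.mark.parametrize("f", [50.0, 500.0, 4000.0])
    def test_inverse_identity(self, f):
        assert abs(mel_to_hz(hz_to_mel(f)) - f) / f < 1e-9

    def test_strictly_increasing(self):
        f = np.linspace(0, 64, 1000)
        assert np.all(np.diff(hz_to_mel(f)) > 0)

    def test_negative_frequency_rejected(self):
        with pytest.raises(ValueError):
            hz_to_mel(-1.0)


class TestPreEmphasis:
    def test_constant_sequence(self):
        c = 3.0
        y = pre_emphasis(np.full(6, c), a=0.97)
        expected = np.array([c] + [c - 0.97 * c] * 5)
        np.testing.assert_allclose(y, expected, atol=1e-12)

    def test_zero_coefficient_is_identity(self, rng):
        x = rng.standard_normal(50)
        np.testing.assert_array_equal(pre_emphasis(x, a=0.0), x)

    def test_alternating_sequence_hand_case(self):
        y = pre_emphasis(np.array([1.0, -1.0, 1.0, -1.0]), a=0.97)
        np.testing.assert_allclose(y, [1.0, -1.97, 1.97, -1.97], atol=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pre_emphasis(np.array([]), 0.97)


class TestFraming:
    def test_default_params_on_30s_signal(self):
        # 30 s at 125 Hz, 0.5/0.25 s: frame 62 samples, stride 31 -> 119 frames
        fm = frame_signal(np.zeros(3750), fs=125.0, w=0.5, s=0.25)
        assert fm.n_frames == 119
        assert fm.frame_len == 62

    def test_no_overlap_concatenation(self, rng):
        x = rng.standard_normal(2000)
        fm = frame_signal(x, fs=100.0, w=0.5, s=0.5)
        cat = fm.frames[:10].reshape(-1)
        np.testing.assert_array_equal(cat, x[: 10 * 50])

    def test_exactly_one_frame(self):
        assert frame_signal(np.zeros(62), fs=125.0, w=0.5, s=0.25).n_frames == 1

    def test_short_signal_gives_zero_frames(self):
        assert frame_signal(np.zeros(10), fs=125.0, w=0.5, s=0.25).n_frames == 0

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        n=st.integers(0, 5000),
        frame_len=st.integers(2, 400),
        stride=st.integers(1, 400),
    )
    def test_frame_count_matches_brute_force(self, n, frame_len, stride):
        """Closed form floor((N-T)/s)+1 == explicit start-index enumeration."""
        brute = len([s0 for s0 in range(0, max(n, 1), stride) if s0 + frame_len <= n])
        closed = n_frames_expected(n, frame_len, stride)
        assert closed == brute
        fs = 1.0  # w and s interpreted directly in samples
        fm = frame_signal(np.zeros(n), fs=fs, w=float(frame_len), s=float(stride))
        assert fm.n_frames == brute


class TestHamming:
    def test_endpoints_and_center(self):
        w = hamming(63)
        assert abs(w[0] - 0.08) < 1e-9
        assert abs(w[-1] - 0.08) < 1e-9
        assert abs(w[31] - 1.0) < 1e-9  # odd T: exact centre

    def test_symmetry(self):
        w = hamming(62)
        np.testing.assert_allclose(w, w[::-1], atol=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            hamming(1)


class TestPowerSpectrum:
    def test_zero_frame(self):
        assert np.all(power_spectrum(np.zeros((1, 62)), 64) == 0)

    def test_pure_cosine_at_bin_matches_naive_dft(self):
        nfft, k0 = 64, 7
        n = np.arange(nfft)
        x = np.cos(2 * np.pi * k0 * n / nfft)
        p = power_spectrum(x[None, :], nfft)[0]
        assert p.argmax() == k0
        naive = ref.naive_power_spectrum(x, nfft)
        np.testing.assert_allclose(p, naive, atol=1e-9)

    def test_parseval(self, rng):
        x = rng.standard_normal(64)
        p = power_spectrum(x[None, :], 64)[0]
        two_sided = p[0] + p[-1] + 2 * p[1:-1].sum()
        np.testing.assert_allclose(two_sided / 64, (x**2).sum(), rtol=1e-9)

    def test_odd_nfft_rejected(self):
        with pytest.raises(MfccConfigError):
            power_spectrum(np.zeros((1, 10)), 63)


class TestMelFilterbank:
    def test_unit_peak_at_center_bins(self):
        H = mel_filterbank(40, 256, 128.0, 0.0, 64.0)
        assert H.shape == (40, 129)
        np.testing.assert_allclose(H.max(axis=1), 1.0)

    def test_rows_nonnegative_compact_support(self):
        H = mel_filterbank(40, 256, 125.0, 0.0, 62.5)
        assert np.all(H >= 0)
        for row in H:
            nz = np.flatnonzero(row)
            assert nz.size > 0
            assert np.array_equal(nz, np.arange(nz[0], nz[-1] + 1))  # contiguous

    def test_partition_of_unity_on_interior_bins(self):
        H = mel_filterbank(40, 128, 125.0, 0.0, 62.5)
        rowmax_bins = H.argmax(axis=1)
        first_c, last_c = rowmax_bins[0], rowmax_bins[-1]
        interior = np.arange(first_c + 1, last_c)
        np.testing.assert_allclose(H[:, interior].sum(axis=0), 1.0, atol=1e-12)

    def test_band_too_narrow_raises(self):
        with pytest.raises(MfccConfigError, match="duplicate"):
            mel_filterbank(40, 64, 125.0, 0.0, 62.5)


class TestLogEnergies:
    def test_zero_spectrum_hits_floor(self):
        H = mel_filterbank(10, 128, 128.0)
        s = log_energies(np.zeros((2, 65)), H, eps=1e-10)
        np.testing.assert_allclose(s, np.log(1e-10))

    def test_single_bin_hand_case(self):
        H = mel_filterbank(10, 128, 128.0)
        v, k = 7.5, 20
        power = np.zeros((1, 65))
        power[0, k] = v
        s = log_energies(power, H, eps=1e-10)[0]
        np.testing.assert_allclose(s, np.log(v * H[:, k] + 1e-10), atol=1e-12)

    def test_white_noise_energies_finite_comparable(self, rng):
        x = rng.standard_normal((5, 62))
        p = power_spectrum(x * hamming(62), 256)
        s = log_energies(p, mel_filterbank(40, 256, 125.0), 1e-10)
        assert np.all(np.isfinite(s))
        assert s.max() - s.min() < 15  # no filter collapses to the floor


class TestDctCepstrum:
    def test_constant_row_maps_to_zero(self):
        C = dct_cepstrum(np.full((1, 40), 3.7), L=13)
        np.testing.assert_allclose(C, 0.0, atol=1e-10)

    def test_orthogonality_injects_single_coefficient(self):
        M = 40
        m = np.arange(1, M + 1)
        s = np.cos(np.pi * 1 * (m - 0.5) / M)
        C = dct_cepstrum(s[None, :], L=13)[0]
        assert abs(C[0] - M / 2) < 1e-9
        np.testing.assert_allclose(C[1:], 0.0, atol=1e-9)

    def test_matches_direct_sum_oracle(self, rng):
        s = rng.standard_normal((6, 40))
        C = dct_cepstrum(s, L=20)
        for i in range(6):
            np.testing.assert_allclose(C[i], ref.naive_dct(s[i], 20), atol=1e-10)

    def test_L_exceeding_M_rejected(self):
        with pytest.raises(MfccConfigError):
            dct_cepstrum(np.zeros((1, 10)), L=11)


class TestExtractMfcc:
    def test_deterministic(self, rng):
        x = rng.standard_normal(30 * 128)
        a = extract_mfcc(x, 128.0)
        b = extract_mfcc(x, 128.0)
        assert np.array_equal(a.coeffs, b.coeffs)

    def test_default_frame_count_on_30s_epoch(self, rng):
        for fs in (125.0, 128.0):
            m = extract_mfcc(rng.standard_normal(int(30 * fs)), fs)
            assert m.coeffs.shape == (119, 13)

    def test_amplitude_scaling_invariance(self, rng):
        """x -> 2x shifts every log energy by ln 4, which the DCT (n>=1)
        removes up to floor effects."""
        x = rng.standard_normal(5 * 128) * 10
        a = extract_mfcc(x, 128.0).coeffs
        b = extract_mfcc(2 * x, 128.0).coeffs
        np.testing.assert_allclose(a, b, atol=1e-6)

    def test_full_chain_matches_naive_oracle(self, rng):
        for fs in (64.0, 125.0, 128.0):
            x = rng.standard_normal(int(3 * fs))
            got = extract_mfcc(x, fs).coeffs
            want = ref.naive_mfcc(x, fs, MfccParams())
            assert got.shape == want.shape
            np.testing.assert_allclose(got, want, atol=1e-8)


class TestMfccParams:
    @pytest.mark.parametrize(
        "kw",
        [
            {"a": 1.0},
            {"a": -0.1},
            {"s": 0.6, "w": 0.5},
            {"s": 0.0},
            {"n_filters": 1},
            {"n_coeffs": 41},
            {"n_coeffs": 0},
            {"fmin": -1.0},
        ],
    )
    def test_invalid_params_rejected(self, kw):
        with pytest.raises(MfccConfigError):
            MfccParams(**kw)

    def test_nfft_resolution(self):
        p = MfccParams()
        assert p.resolve_nfft(128.0) == 256
        assert MfccParams(w=3.0, s=1.0).resolve_nfft(128.0) == 512
        with pytest.raises(MfccConfigError):
            MfccParams(nfft=32).resolve_nfft(128.0)  # smaller than the frame
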