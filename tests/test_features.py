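"""Unit tests for the 16 MP-derived features."""

import numpy as np
import pandas as pd
import pytest

import hrvmp
from hrvmp.features import _safe_ratio, features_from_mp
from hrvmp.gabor_mp import GaborAtom, MPResult

from conftest import planted_disjoint_atoms


def _atom_at_hz(f_hz, fs=4.0, n=64):
    w = 2 * np.pi * f_hz / fs
    return GaborAtom(s=16.0, u=32.0, w=w, phi=0.0,
                     waveform=hrvmp.gabor_waveform(16.0, 32.0, w, 0.0, n))


def _fake_mp(coeffs, freqs_hz, residuals=None, fs=4.0, signal_energy=None):
    """Hand-built MPResult with prescribed coefficients and atom bands."""
    coeffs = np.asarray(coeffs, dtype=float)
    atoms = [_atom_at_hz(f, fs) for f in freqs_hz]
    if signal_energy is None:
        signal_energy = float((coeffs**2).sum())
    if residuals is None:
        residuals = signal_energy - np.cumsum(coeffs**2)
    residual_energy = np.concatenate([[signal_energy], residuals])
    return MPResult(coefficients=coeffs, atoms=atoms,
                    residual_energy=residual_energy,
                    signal_energy=signal_energy, fs=fs)


class TestMeanEnergyDecay:
    def test_total_is_mean_of_normalised_residuals(self):
        mp = _fake_mp([1.0, 1.0, 1.0], [0.25, 0.25, 0.25],
                      residuals=[0.5, 0.25, 0.125], signal_energy=1.0)
        assert hrvmp.mean_energy_decay(mp, "total") == pytest.approx(
            (0.5 + 0.25 + 0.125) / 3
        )

    def test_single_atom_signal_scores_zero(self, dict64):
        g = hrvmp.gabor_waveform(8.0, 32.0, np.pi / 4, 0.0, 64)
        mp = hrvmp.mp_decompose(3.0 * g, dict64, M=30)
        assert hrvmp.mean_energy_decay(mp, "total") == pytest.approx(0.0, abs=1e-10)

    def test_band_restricted_decay_bookkeeping(self):
        # atoms: HF(c=2), LF(c=1), HF(c=1); signal energy 6
        mp = _fake_mp([2.0, 1.0, 1.0], [0.25, 0.10, 0.30], signal_energy=6.0)
        # HF total=5; residuals after m=1,2,3: 1, 1, 0 -> mean 2/3; /6
        assert hrvmp.mean_energy_decay(mp, "HF") == pytest.approx((2 / 3) / 6)
        # LF total=1; residuals: 1, 0, 0 -> mean 1/3; /6
        assert hrvmp.mean_energy_decay(mp, "LF") == pytest.approx((1 / 3) / 6)
        assert hrvmp.mean_energy_decay(mp, "VLF") == pytest.approx(0.0)


class TestEntropy:
    def test_single_atom_zero_bits(self):
        mp = _fake_mp([2.0], [0.25])
        assert hrvmp.mp_entropy(mp, "HF") == pytest.approx(0.0)

    def test_two_equal_atoms_one_bit(self):
        mp = _fake_mp([1.0, -1.0], [0.1, 0.1])
        assert hrvmp.mp_entropy(mp, "LF") == pytest.approx(1.0)

    def test_thirty_equal_atoms_log2_30(self):
        mp = _fake_mp([1.0] * 30, [0.25] * 30)
        assert hrvmp.mp_entropy(mp, "HF") == pytest.approx(np.log2(30), abs=1e-9)

    def test_global_normalisation_band_restriction(self):
        # half the energy in HF (two equal atoms), half in LF (one atom)
        mp = _fake_mp([1.0, 1.0, np.sqrt(2)], [0.25, 0.3, 0.1])
        # p = (1/4, 1/4, 1/2): Hw(HF) = 2 * (1/4)*log2(4) = 1
        assert hrvmp.mp_entropy(mp, "HF") == pytest.approx(1.0)
        assert hrvmp.mp_entropy(mp, "LF") == pytest.approx(0.5)

    def test_empty_band_zero(self):
        mp = _fake_mp([1.0], [0.25])
        assert hrvmp.mp_entropy(mp, "VLF") == 0.0


class TestFreqDistribution:
    def test_count_fraction(self):
        freqs = [0.1] * 12 + [0.25] * 18
        mp = _fake_mp([1.0] * 30, freqs)
        assert hrvmp.freq_distribution(mp, "LF") == pytest.approx(0.4)

    def test_all_hf(self):
        mp = _fake_mp([1.0] * 5, [0.2] * 5)
        assert hrvmp.freq_distribution(mp, "HF") == 1.0
        assert hrvmp.freq_distribution(mp, "LF") == 0.0

    def test_band_fractions_sum_at_most_one(self, dict64):
        rng = np.random.default_rng(5)
        for _ in range(5):
            mp = hrvmp.mp_decompose(rng.normal(size=64), dict64, M=20)
            total = sum(
                hrvmp.freq_distribution(mp, b) for b in ("VLF", "LF", "HF")
            )
            assert 0.0 <= total <= 1.0


class TestWelch:
    def test_sinusoid_peak_at_its_frequency(self):
        fs = 4.0
        t = np.arange(1024) / fs
        x = np.sin(2 * np.pi * 0.25 * t)
        spec = hrvmp.welch_psd(x, fs)
        assert spec.frequencies[np.argmax(spec.power)] == pytest.approx(
            0.25, abs=fs / 256
        )

    def test_zero_signal_zero_power(self):
        spec = hrvmp.welch_psd(np.zeros(512), 4.0)
        assert np.all(spec.power == 0)

    def test_white_noise_parseval(self):
        rng = np.random.default_rng(0)
        fs = 4.0
        totals, variances = [], []
        for _ in range(50):
            x = rng.normal(size=1024)
            spec = hrvmp.welch_psd(x, fs)
            df = spec.frequencies[1] - spec.frequencies[0]
            totals.append(spec.power.sum() * df)
            variances.append(x.var())
        assert np.mean(totals) == pytest.approx(np.mean(variances), rel=0.10)

    def test_seg_len_longer_than_signal_rejected(self):
        with pytest.raises(ValueError):
            hrvmp.welch_psd(np.zeros(100), 4.0, seg_len=256)


class TestBandSubsignal:
    def test_empty_band_gives_zero_vector(self):
        mp = _fake_mp([1.0], [0.25])
        assert np.all(hrvmp.band_subsignal(mp, "VLF") == 0)

    def test_all_atoms_in_band_equals_full_reconstruction(self):
        mp = _fake_mp([1.0, 2.0], [0.2, 0.3])
        assert np.allclose(hrvmp.band_subsignal(mp, "HF"),
                           hrvmp.reconstruct(mp, "all"))

    def test_planted_hf_atom_recovered(self, dict128):
        fs = 4.0
        f_hz = 0.25
        w = 2 * np.pi * f_hz / fs  # = pi * 0.125 -> on the s=16 grid (k=2)
        g = hrvmp.gabor_waveform(16.0, 64.0, w, 0.0, 128)
        mp = hrvmp.mp_decompose(2.0 * g, dict128, M=5, fs=fs)
        sub = hrvmp.band_subsignal(mp, "HF")
        assert np.linalg.norm(sub - 2.0 * g) < 1e-6 * 2.0


class TestPsdFeatures:
    def test_hf_only_signal(self, dict128):
        fs = 4.0
        w = 2 * np.pi * 0.25 / fs
        g = hrvmp.gabor_waveform(16.0, 64.0, w, 0.0, 128)
        mp = hrvmp.mp_decompose(5.0 * g, dict128, M=5, fs=fs)
        vlf, lf, hf, ratio, hf_plus_lf = hrvmp.psd_features(mp, seg_len=128)
        assert vlf == 0.0
        assert hf > 0.0
        assert ratio == pytest.approx(min(hf / 1e-12, 1e6))

    def test_planted_lf_atom_concentrates_lf_power(self, dict1024):
        fs = 4.0
        w = 2 * np.pi * 0.09375 / fs  # 0.09375 Hz in LF, on the dyadic grid
        g = hrvmp.gabor_waveform(512.0, 512.0, w, 0.0, 1024)
        mp = hrvmp.mp_decompose(g, dict1024, M=5, fs=fs)
        sub = hrvmp.band_subsignal(mp, "LF")
        spec = hrvmp.welch_psd(sub, fs)
        df = spec.frequencies[1] - spec.frequencies[0]
        total = spec.power.sum() * df
        lf_sel = (spec.frequencies >= 0.04) & (spec.frequencies < 0.15)
        assert spec.power[lf_sel].sum() * df > 0.9 * total


class TestExtractFeatures:
    def test_deterministic_and_finite(self, dict1024):
        rr = hrvmp.generate_rr(hrvmp.nsr_preset())
        seg = hrvmp.preprocess(rr)
        v1 = hrvmp.extract_features(seg, dict1024)
        v2 = hrvmp.extract_features(seg, dict1024)
        assert list(v1.index) == hrvmp.FEATURE_NAMES
        assert np.all(np.isfinite(v1.values))
        assert np.array_equal(v1.values, v2.values)

    def test_zero_segment_rejected(self, dict64):
        seg = hrvmp.UniformHRV(values=np.zeros(64), fs=4.0, duration=16.0)
        with pytest.raises(ValueError):
            hrvmp.extract_features(seg, dict64)

    def test_scale_invariance_exact_for_power_of_two(self, dict1024):
        rr = hrvmp.generate_rr(hrvmp.chf_preset())
        seg = hrvmp.preprocess(rr)
        v1 = hrvmp.extract_features(seg, dict1024)
        seg4 = hrvmp.UniformHRV(values=4.0 * seg.values, fs=seg.fs,
                                duration=seg.duration)
        v4 = hrvmp.extract_features(seg4, dict1024)
        assert np.allclose(v1.values, v4.values, rtol=1e-12, atol=0)


def test_safe_ratio_policy():
    assert _safe_ratio(1.0, 2.0) == 0.5
    assert _safe_ratio(0.0, 0.0) == 0.0
    assert _safe_ratio(5.0, 0.0) == 1e6


def test_class_direction_of_means(cohort69_features):
    """On the study-sized synthetic cohort the class means reproduce the
    qualitative contrasts: heart-failure subjects show faster MP energy
    decay, lower HF/VLF, lower HF entropy and fewer LF atoms."""
    g = cohort69_features.groupby("label")[hrvmp.FEATURE_NAMES].mean()
    for feat in ("E", "HF_over_VLF", "Hw_HF", "D_LF"):
        assert g.loc["CHF", feat] < g.loc["NSR", feat], feat
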