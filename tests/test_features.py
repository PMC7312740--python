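"""Hilbert-Huang features, cross-sample entropy, phase/frequency locking,
and feature-vector assembly."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nodulebci.errors import ValidationError
from nodulebci.features import (FeatureConfig, assemble_features,
                                band_energy_ies, cross_sample_entropy,
                                extract_epoch_features,
                                feature_matrix, frequency_locking_value,
                                hilbert_analytic, hilbert_spectrum,
                                hjorth_mobility, marginal_spectrum,
                                phase_locking_value, EEG_BANDS)
from tests.conftest import make_epoch
from tests.oracles import cross_sample_entropy_bruteforce

FS = 256.0


def tone(f_hz, seconds=2.0, fs=FS, amplitude=1.0):
    t = np.arange(int(seconds * fs)) / fs
    return amplitude * np.cos(2 * np.pi * f_hz * t)


class TestHilbertAnalytic:
    def test_cosine_amplitude_and_frequency(self):
        a = hilbert_analytic(tone(10.0), FS)
        interior = slice(51, -51)
        assert np.allclose(a.amplitude[interior], 1.0, rtol=0.02)
        f_hz = a.inst_freq[interior] / (2 * np.pi)
        assert np.allclose(f_hz, 10.0, rtol=0.01)

    @pytest.mark.parametrize("amp", [0.5, 3.0, 10.0])
    def test_amplitude_linearity(self, amp):
        a = hilbert_analytic(tone(10.0, amplitude=amp), FS)
        assert np.allclose(a.amplitude[51:-51], amp, rtol=0.02)

    def test_two_tone_inst_freq_oscillates(self):
        """A two-tone mixture fed as a single 'IMF' has a non-constant
        instantaneous frequency — why MEMD must precede this step."""
        x = tone(20.0) + tone(5.0)
        a = hilbert_analytic(x, FS)
        f_hz = a.inst_freq[51:-51] / (2 * np.pi)
        assert f_hz.std() > 1.0

    def test_all_zero_flagged(self):
        a = hilbert_analytic(np.zeros(64), FS)
        assert not a.valid
        assert np.all(a.amplitude == 0)


class TestHilbertSpectrum:
    def test_single_tone_mass_in_one_row(self):
        a = hilbert_analytic(tone(10.0), FS)
        spec = hilbert_spectrum([a], FS)
        centers = spec.bin_centers
        row = np.argmin(np.abs(centers - 10.0))
        interior = spec.H[:, 51:-51]
        assert interior[row].sum() / interior.sum() >= 0.95

    def test_zero_signal_zero_spectrum(self):
        a = hilbert_analytic(np.zeros(64), FS)
        spec = hilbert_spectrum([a], FS)
        assert not spec.H.any()

    def test_doubling_amplitude_quadruples_mass(self):
        s1 = hilbert_spectrum([hilbert_analytic(tone(10.0), FS)], FS)
        s2 = hilbert_spectrum([hilbert_analytic(tone(10.0, amplitude=2.0),
                                                FS)], FS)
        assert s2.H.sum() == pytest.approx(4 * s1.H.sum(), rel=1e-6)

    def test_band_energy_localised_in_alpha(self):
        spec = hilbert_spectrum([hilbert_analytic(tone(10.0), FS)], FS)
        alpha = band_energy_ies(spec, EEG_BANDS["alpha"])[51:-51]
        beta = band_energy_ies(spec, EEG_BANDS["beta"])[51:-51]
        total = spec.H[:, 51:-51].sum(axis=0) * spec.bin_width
        assert alpha.sum() / total.sum() > 0.95
        assert beta.sum() / total.sum() < 0.05

    def test_band_partition_additivity_exact(self, rng):
        imfs = [hilbert_analytic(rng.standard_normal(512), FS)
                for _ in range(3)]
        spec = hilbert_spectrum(imfs, FS)
        per_band = sum(band_energy_ies(spec, b) for b in EEG_BANDS.values())
        full = spec.H.sum(axis=0) * spec.bin_width
        assert np.allclose(per_band, full, rtol=0, atol=1e-12)

    def test_marginal_total_mass_equals_spectrum_mass(self, rng):
        imfs = [hilbert_analytic(rng.standard_normal(512), FS)]
        spec = hilbert_spectrum(imfs, FS)
        ms_mass = marginal_spectrum(spec).sum() * spec.bin_width
        assert ms_mass == spec.H.sum() * spec.bin_width * spec.dt

    def test_inverted_band_refused(self, rng):
        spec = hilbert_spectrum([hilbert_analytic(tone(10.0), FS)], FS)
        with pytest.raises(ValidationError):
            band_energy_ies(spec, (13.0, 8.0))


class TestHjorthMobility:
    def test_sinusoid_limit_2pi_f(self):
        mob = hjorth_mobility(tone(10.0, seconds=4.0), FS)
        assert mob == pytest.approx(2 * np.pi * 10.0, rel=0.02)

    @pytest.mark.parametrize("c", [-3.0, 0.1, 100.0])
    def test_scale_invariance(self, c):
        y = tone(7.0)
        assert hjorth_mobility(c * y, FS) == pytest.approx(
            hjorth_mobility(y, FS), rel=1e-9)

    def test_frequency_doubling_doubles_mobility(self):
        m10 = hjorth_mobility(tone(10.0, seconds=4.0), FS)
        m20 = hjorth_mobility(tone(20.0, seconds=4.0), FS)
        assert m20 / m10 == pytest.approx(2.0, rel=0.02)

    def test_constant_series_flagged(self):
        assert math.isnan(hjorth_mobility(np.full(100, 5.0), FS))


class TestCrossSampleEntropy:
    def test_alternating_sequence_matches_oracle(self):
        u = np.array([1.0, 2, 1, 2, 1, 2, 1, 2])
        c = cross_sample_entropy(u, u, m=2, r=0.5)
        expected = cross_sample_entropy_bruteforce(u, u, 2, 0.5)
        assert c == expected == 0.0  # all templates match at both lengths

    @pytest.mark.parametrize("m", [1, 2])
    def test_matches_bruteforce_on_random_pairs(self, m, rng):
        for _ in range(10):
            n = int(rng.integers(20, 80))
            u = rng.standard_normal(n)
            v = rng.standard_normal(n)
            r = 0.2 * math.sqrt((np.var(u) + np.var(v)) / 2)
            fast = cross_sample_entropy(u, v, m=m, r=r)
            slow = cross_sample_entropy_bruteforce(u, v, m, r)
            if math.isnan(slow):
                assert math.isnan(fast)
            else:
                assert fast == pytest.approx(slow, abs=0, rel=1e-12)

    def test_symmetry(self, rng):
        u = rng.standard_normal(100)
        v = rng.standard_normal(100)
        assert cross_sample_entropy(u, v) == pytest.approx(
            cross_sample_entropy(v, u), rel=1e-12)

    def test_identical_with_large_radius_gives_zero(self, rng):
        u = rng.standard_normal(50)
        assert cross_sample_entropy(u, u, r=100.0) == 0.0

    def test_independent_noise_more_entropic_than_identical(self, rng):
        diffs = []
        for _ in range(50):
            u = rng.standard_normal(300)
            v = rng.standard_normal(300)
            c_indep = cross_sample_entropy(u, v)
            c_same = cross_sample_entropy(u, u)
            diffs.append(c_indep - c_same)
        assert np.median(diffs) > 0

    def test_too_short_refused(self):
        with pytest.raises(ValidationError):
            cross_sample_entropy(np.arange(3.0), np.arange(3.0), m=2)


class TestLockingValues:
    def test_identical_phases_give_one(self, rng):
        th = rng.uniform(0, 2 * np.pi, 200)
        assert phase_locking_value(th, th) == pytest.approx(1.0)

    def test_constant_offset_gives_one(self, rng):
        th = rng.uniform(0, 2 * np.pi, 200)
        assert phase_locking_value(th, th + 1.234) == pytest.approx(1.0)

    @given(c=st.floats(-10, 10))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_common_constant_invariance(self, c):
        rng = np.random.default_rng(0)
        t1 = rng.uniform(0, 2 * np.pi, 100)
        t2 = rng.uniform(0, 2 * np.pi, 100)
        assert phase_locking_value(t1 + c, t2 + c) == pytest.approx(
            phase_locking_value(t1, t2), rel=1e-9)

    def test_random_phases_rayleigh_small(self, rng):
        small = sum(
            phase_locking_value(rng.uniform(0, 2 * np.pi, 1000),
                                rng.uniform(0, 2 * np.pi, 1000)) < 0.1
            for _ in range(100)
        )
        assert small >= 95

    def test_frequency_locking_identical_and_offset(self, rng):
        w = rng.uniform(0, 100, 500)
        dt = 1 / FS
        assert frequency_locking_value(w, w, dt) == pytest.approx(1.0)
        delta = 2 * np.pi / dt  # delta * dt == 2*pi: same phasor
        assert frequency_locking_value(w, w + delta, dt) == pytest.approx(1.0)

    def test_length_mismatch_refused(self):
        with pytest.raises(ValidationError):
            phase_locking_value(np.zeros(5), np.zeros(6))
        with pytest.raises(ValidationError):
            frequency_locking_value(np.zeros(5), np.zeros(6), 1 / FS)


class TestAssembly:
    def test_layout_stable_across_epochs(self, rng):
        eps = [make_epoch(rng.standard_normal((3, 256))) for _ in range(2)]
        cfg = FeatureConfig(memd_K=6)
        v0, n0 = extract_epoch_features(eps[0], cfg)
        v1, n1 = extract_epoch_features(eps[1], cfg)
        assert n0 == n1
        assert len(v0) == len(v1)

    def test_flagged_entries_imputed_with_indicator(self):
        vec, names = assemble_features(
            [("ft", {"a_mob_x": float("nan"), "b": 1.5}),
             ("q", {"p": float("nan")})])
        d = dict(zip(names, vec))
        assert d["ft_a_mob_x"] == 0.0
        assert d["flag_ft_a_mob_x"] == 1.0
        assert d["q_p"] == 0.0
        assert d["flag_q_p"] == 1.0
        assert d["ft_b"] == 1.5

    def test_layout_length_formula(self, rng):
        """Length = per-channel time stats + freq stats + 3 per pair +
        flaggable indicators."""
        n_ch = 4
        cfg = FeatureConfig(memd_K=8, pair_channels="all")
        ep = make_epoch(rng.standard_normal((n_ch, 256)))
        vec, names = extract_epoch_features(ep, cfg)
        n_pairs = n_ch * (n_ch - 1) // 2
        n_t = 5 * n_ch          # sig mean/sd, resp amp, mob mean/sd
        n_f = (2 * len(EEG_BANDS) + 2) * n_ch
        n_flag = 2 * n_ch + n_ch + 3 * n_pairs  # mob, resp, pair features
        assert len(vec) == n_t + n_f + 3 * n_pairs + n_flag
        assert len(names) == len(set(names))

    def test_permuting_samples_preserves_mean_features(self, rng):
        data = rng.standard_normal((3, 256))
        cfg = FeatureConfig(memd_K=6)
        ep = make_epoch(data)
        perm = rng.permutation(256)
        ep_perm = make_epoch(data[:, perm])
        v0, names = extract_epoch_features(ep, cfg)
        v1, _ = extract_epoch_features(ep_perm, cfg)
        d0 = dict(zip(names, v0))
        d1 = dict(zip(names, v1))
        for ch in range(3):
            assert d0[f"ft_ch{ch}_sig_mean"] == pytest.approx(
                d1[f"ft_ch{ch}_sig_mean"], rel=1e-9)

    def test_feature_matrix_stacks(self, rng):
        eps = [make_epoch(rng.standard_normal((3, 256)), is_target=i % 2)
               for i in range(4)]
        X, y, names = feature_matrix(eps, FeatureConfig(memd_K=6))
        assert X.shape == (4, len(names))
        assert list(y) == [0, 1, 0, 1]

    def test_empty_epoch_list_refused(self):
        with pytest.raises(ValidationError):
            feature_matrix([])
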