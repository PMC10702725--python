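"""Feature extractors and t-test ROI screening."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bvfusion import (
    CohortSpec,
    ConfigurationError,
    FEATURE_NAMES,
    InputError,
    build_feature_sets,
    extract_alff,
    extract_sample_entropy,
    extract_time_domain,
    extract_vmd_feature,
    feature_matrix,
    generate_cohort,
    select_rois,
    vmd,
)
from oracles import sampen_bruteforce


class TestTimeDomain:
    def test_hand_computed_moments(self):
        mean, var, kurt, skew = extract_time_domain([1, 2, 3, 4])
        assert mean == pytest.approx(2.5)
        assert var == pytest.approx(5.0 / 3.0)  # unbiased
        # population moments: m2 = 1.25, m4 = 2.5625 -> excess kurtosis -1.36
        assert kurt == pytest.approx(-1.36)
        assert skew == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_series_has_zero_skewness(self, rng):
        half = rng.normal(size=50)
        x = np.concatenate([2.0 + half, 2.0 - half])
        assert extract_time_domain(x)[3] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("bad", [[1, 2, 3], [1.0, np.nan, 2.0, 3.0]])
    def test_short_or_nonfinite_rejected(self, bad):
        with pytest.raises(InputError):
            extract_time_domain(bad)


class TestAlff:
    def test_constant_series_zero(self):
        assert extract_alff(np.full(64, 3.0), tr=2.0) == pytest.approx(0.0, abs=1e-12)

    def test_amplitude_linearity_and_band_rejection(self):
        t = np.arange(170) * 2.0
        in_band = np.sin(2 * np.pi * 0.05 * t)
        a1 = extract_alff(in_band, tr=2.0)
        a2 = extract_alff(2.0 * in_band, tr=2.0)
        assert a2 == pytest.approx(2.0 * a1, rel=1e-10)
        out_band = np.sin(2 * np.pi * 0.20 * t)
        assert extract_alff(out_band, tr=2.0) <= 0.02 * a1

    def test_scale_equivariance(self, rng):
        x = rng.normal(size=120)
        a = extract_alff(x, tr=2.0)
        assert extract_alff(-3.5 * x, tr=2.0) == pytest.approx(3.5 * a, rel=1e-10)

    def test_empty_band_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            extract_alff(np.arange(64.0), tr=2.0, band=(0.0101, 0.0102))


class TestVmd:
    def test_two_tone_low_mode_energy(self):
        t = np.arange(170) * 2.0
        low = 2.0 * np.sin(2 * np.pi * 0.02 * t)
        x = low + np.sin(2 * np.pi * 0.2 * t)
        energy = extract_vmd_feature(x, k_modes=2)
        assert energy == pytest.approx(np.var(low), rel=0.10)

    def test_pure_tone_energy_concentrates_in_one_mode(self):
        # moderate bandwidth penalty; at very large penalties VMD is known
        # to duplicate a lone tone across modes
        t = np.arange(170) * 2.0
        modes, _ = vmd(np.sin(2 * np.pi * 0.05 * t), k_modes=2, penalty=100.0)
        energies = (modes**2).sum(axis=1)
        assert energies.max() / energies.sum() >= 0.95

    def test_constant_series_has_no_energy(self):
        assert extract_vmd_feature(np.full(64, 1.7)) == pytest.approx(0.0, abs=1e-10)

    def test_modes_reconstruct_signal_and_frequencies_sorted(self, rng):
        x = rng.normal(size=128)
        modes, omegas = vmd(x, k_modes=3, penalty=200.0)
        assert np.all(np.diff(omegas) >= 0)
        # moderate penalty: the mode sum tracks the signal (Wiener
        # filtering discards some broadband noise, so not exactly 1)
        assert np.corrcoef(modes.sum(axis=0), x)[0, 1] > 0.9

    def test_too_short_series_rejected(self):
        with pytest.raises(InputError):
            vmd(np.arange(5.0), k_modes=4)


class TestSampleEntropy:
    def test_constant_series_zero(self):
        assert extract_sample_entropy(np.full(30, 2.0)) == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_oracle_exactly(self, seed):
        x = np.random.default_rng(seed).normal(size=20)
        assert extract_sample_entropy(x, m=2, r=0.2) == sampen_bruteforce(x, m=2, r=0.2)

    def test_sorted_series_no_more_entropic_than_shuffled(self):
        results = []
        for seed in range(50):
            g = np.random.default_rng(seed)
            x = g.normal(size=60)
            results.append(
                extract_sample_entropy(np.sort(x)) <= extract_sample_entropy(x)
            )
        assert np.mean(results) > 0.5  # median ordering over seeds


class TestBuildFeatureSets:
    def test_shapes_and_mean_feature_definition(self):
        cohort = generate_cohort(
            CohortSpec(n_per_group=2, n_timepoints=40, n_rois=10, seed=5)
        )
        fsets = build_feature_sets(cohort)
        assert len(fsets) == 4
        for fs in fsets:
            assert set(fs.features) == set(FEATURE_NAMES)
            assert all(v.shape == (10,) for v in fs.features.values())
        np.testing.assert_allclose(
            fsets[0].features["mean"], cohort[0].ts.mean(axis=0), atol=1e-12
        )

    def test_mean_shift_recovered_on_affected_rois(self, effect_cohort, effect_features, effect_spec):
        y = np.array([r.label for r in effect_cohort])
        M = feature_matrix(effect_features, "mean")
        diff = M[y == -1].mean(axis=0) - M[y == 1].mean(axis=0)
        np.testing.assert_allclose(
            diff[list(effect_spec.affected_rois)], effect_spec.mean_shift, atol=0.5
        )


class TestSelectRois:
    def test_planted_shift_detected_and_null_rate_nominal(self, rng):
        hits = []
        null_fracs = []
        for seed in range(30):
            g = np.random.default_rng(seed)
            X = g.normal(size=(40, 20))
            y = np.array([1] * 20 + [-1] * 20)
            null_mask = select_rois(X, y, 0.05)
            null_fracs.append(null_mask.selected.mean() if not null_mask.fallback else 0.0)
            X[y == -1, 5] += 2.0
            hits.append(select_rois(X, y, 0.01).selected[5])
        assert np.mean(hits) >= 0.95
        assert abs(np.mean(null_fracs) - 0.05) < 0.04

    def test_fallback_keeps_single_min_p_roi(self, rng):
        X = rng.normal(size=(12, 6))
        y = np.array([1] * 6 + [-1] * 6)
        mask = select_rois(X, y, 1e-12)
        assert mask.fallback
        assert mask.selected.sum() == 1
        assert mask.selected[np.argmin(mask.p_values)]

    def test_single_class_rejected(self, rng):
        with pytest.raises(InputError):
            select_rois(rng.normal(size=(8, 4)), np.ones(8), 0.05)


@settings(derandomize=True, max_examples=25, deadline=None)
@given(st.lists(st.floats(-50, 50), min_size=12, max_size=30), st.integers(0, 10**6))
def test_sampen_oracle_property(values, seed):
    """Vectorised sample entropy equals brute-force counting on arbitrary series."""
    x = np.asarray(values) + np.random.default_rng(seed).normal(scale=0.1, size=len(values))
    assert extract_sample_entropy(x, m=2, r=0.2) == sampen_bruteforce(x, m=2, r=0.2)
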