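"""Standardization, polynomial fitting, and PLA/PSA discretization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import acetowhite as aw
from acetowhite.datasets import AwrfSeries, TissueClass
from acetowhite.representations import (
    design_matrix,
    psa_cuts_from_training,
    segment_means,
    segment_slopes,
)


def _series(baseline, post):
    return AwrfSeries(values=np.concatenate([baseline, post]), n_baseline=len(baseline))


class TestStandardize:
    def test_percent_change_arithmetic(self):
        s = _series([100.0] * 10, [125.0] * 5)
        std = aw.standardize(s)
        assert std.basal == 100.0
        assert np.allclose(std.values, 25.0)

    def test_constant_series_standardizes_to_zero(self):
        std = aw.standardize(_series([80.0] * 10, [80.0] * 20))
        assert np.allclose(std.values, 0.0)

    def test_zero_mean_baseline_perturbation_changes_nothing(self, rng):
        post = rng.normal(110, 3, 30)
        base = np.full(10, 100.0)
        bump = rng.normal(0, 2, 10)
        bump -= bump.mean()
        a = aw.standardize(_series(base, post))
        b = aw.standardize(_series(base + bump, post))
        assert np.allclose(a.values, b.values)

    def test_nonpositive_basal_rejected(self):
        with pytest.raises(ValueError, match="basal"):
            aw.standardize(_series([0.0] * 10, [5.0] * 10))


class TestFitPolynomial:
    def test_exact_recovery_of_known_coefficients(self):
        theta = np.array([1.0, 20.0, -5.0, -10.0, 2.0])
        values = aw.evaluate_polynomial(theta, aw.time_grid(180))
        fit = aw.fit_polynomial(values)
        assert np.allclose(fit.theta, theta, atol=1e-8)
        assert fit.fit_rss < 1e-8

    def test_zero_series_gives_zero_coefficients(self):
        fit = aw.fit_polynomial(np.zeros(50))
        assert np.allclose(fit.theta, 0.0, atol=1e-12)

    def test_residuals_orthogonal_to_basis(self, rng):
        values = rng.normal(0, 5, 180)
        fit = aw.fit_polynomial(values)
        X = design_matrix(aw.time_grid(180))
        resid = values - X @ fit.theta
        assert np.abs(X.T @ resid).max() < 1e-6

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="five"):
            aw.fit_polynomial(np.zeros(4))

    def test_monte_carlo_recovery_under_lighting_noise(self):
        """Mean recovered theta over 100 noisy replicates stays within 3 SE."""
        true = aw.DEFAULT_KINETICS[TissueClass.HSIL].theta
        kin = {c: aw.ClassKinetics(theta=k.theta, noise_sd=2.0, drift_amplitude=0.0)
               for c, k in aw.DEFAULT_KINETICS.items()}
        estimates = []
        for rep in range(100):
            cfg = aw.GeneratorConfig(class_counts={TissueClass.HSIL: 1}, seed=1000 + rep)
            s = aw.generate_series(cfg, kin)[0]
            estimates.append(aw.fit_polynomial(aw.standardize(s)).theta)
        estimates = np.array(estimates)
        se = estimates.std(axis=0, ddof=1) / np.sqrt(len(estimates))
        assert np.all(np.abs(estimates.mean(axis=0) - true) <= 3 * se)


class TestSchemeValidation:
    def test_non_tiling_boundaries_rejected(self):
        scheme = aw.DiscretizationScheme(boundaries=[2, 5], cuts=[0.0])
        with pytest.raises(ValueError, match="boundaries end"):
            aw.discretize_pla(np.zeros(6), scheme)

    def test_degenerate_boundaries_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            aw.DiscretizationScheme(boundaries=[3, 3, 6], cuts=[0.0])
        with pytest.raises(ValueError, match="strictly increasing"):
            aw.DiscretizationScheme(boundaries=[4], cuts=[1.0, 1.0])

    def test_slope_cut_validation(self):
        with pytest.raises(ValueError, match="increasing"):
            aw.DiscretizationScheme(boundaries=[4], slope_cuts=[-3, -2, -2.5, 2.5, 2, 3])
        with pytest.raises(ValueError, match="symmetric"):
            aw.DiscretizationScheme(boundaries=[4], slope_cuts=[-4, -2, -1, 1, 2, 3])

    def test_json_roundtrip(self):
        scheme = aw.DiscretizationScheme(
            boundaries=[5, 9, 12], cuts=[-1.0, 2.5], slope_cuts=[-3, -2, -1, 1, 2, 3]
        )
        back = aw.DiscretizationScheme.from_json(scheme.to_json())
        assert back.boundaries == scheme.boundaries
        assert back.cuts == scheme.cuts
        assert back.slope_cuts == scheme.slope_cuts


class TestPLA:
    def test_segment_means_straddle_cut(self):
        scheme = aw.DiscretizationScheme(boundaries=[2, 4], cuts=[15.0])
        out = aw.discretize_pla(np.array([10.0, 10.0, 20.0, 20.0]), scheme)
        assert list(out.symbols) == [0, 1]
        assert out.mode == "PLA"

    def test_constant_series_single_symbol(self):
        scheme = aw.DiscretizationScheme(boundaries=[3, 6, 9], cuts=[-1.0, 1.0])
        out = aw.discretize_pla(np.full(9, 0.5), scheme)
        assert len(set(out.symbols)) == 1
        assert out.symbols.size == scheme.n_segments

    def test_matches_bruteforce_segment_mean_oracle(self, rng):
        """Oracle: plain-python segment means binned by explicit comparisons."""
        for _ in range(100):
            n = int(rng.integers(8, 40))
            n_seg = int(rng.integers(2, min(6, n)))
            interior = sorted(rng.choice(np.arange(1, n), size=n_seg - 1, replace=False))
            boundaries = [int(b) for b in interior] + [n]
            cuts = sorted(rng.normal(0, 5, size=int(rng.integers(1, 4))))
            scheme = aw.DiscretizationScheme(boundaries=boundaries, cuts=cuts)
            values = rng.normal(0, 5, n)
            got = aw.discretize_pla(values, scheme).symbols
            start = 0
            expected = []
            for end in boundaries:
                mean = sum(values[start:end]) / (end - start)
                sym = 0
                for c in cuts:
                    if mean >= c:
                        sym += 1
                expected.append(sym)
                start = end
            assert list(got) == expected


SLOPE_CUTS = [-3.0, -2.0, -0.5, 0.5, 2.0, 3.0]


class TestPSA:
    def test_flat_segment_maps_to_zero(self):
        scheme = aw.DiscretizationScheme(boundaries=[5, 10], slope_cuts=SLOPE_CUTS)
        out = aw.discretize_psa(np.full(10, 3.3), scheme)
        assert list(out.symbols) == [0, 0]
        assert out.mode == "PSA"

    def test_extreme_slopes_saturate_symmetrically(self):
        t = aw.time_grid(10)
        steep = 100.0 * t
        scheme = aw.DiscretizationScheme(boundaries=[5, 10], slope_cuts=SLOPE_CUTS)
        assert list(aw.discretize_psa(steep, scheme).symbols) == [3, 3]
        assert list(aw.discretize_psa(-steep, scheme).symbols) == [-3, -3]

    def test_matches_per_segment_regression_oracle(self, rng):
        """Oracle: np.polyfit line slope per segment, binned by comparisons."""
        t = aw.time_grid(30)
        for _ in range(100):
            values = rng.normal(0, 5, 30)
            scheme = aw.DiscretizationScheme(boundaries=[7, 15, 22, 30], slope_cuts=SLOPE_CUTS)
            got = aw.discretize_psa(values, scheme).symbols
            start = 0
            expected = []
            for end in scheme.boundaries:
                slope = np.polyfit(t[start:end], values[start:end], 1)[0]
                sym = -3
                for c in SLOPE_CUTS:
                    if slope >= c:
                        sym += 1
                expected.append(sym)
                start = end
            assert list(got) == expected

    @given(seed=st.integers(0, 500))
    @settings(max_examples=20, deadline=None)
    def test_negating_series_negates_symbols(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(0, 4, 24)
        scheme = aw.DiscretizationScheme(boundaries=[6, 12, 18, 24], slope_cuts=SLOPE_CUTS)
        fwd = aw.discretize_psa(values, scheme).symbols
        rev = aw.discretize_psa(-values, scheme).symbols
        assert np.array_equal(rev, -fwd)


class TestCalibrationAndAssembly:
    def test_calibrated_cuts_are_valid_and_cover_training(self, rng):
        X = rng.normal(0, 10, (40, 36))
        scheme = aw.calibrate_scheme(X, aw.uniform_boundaries(36, 6), alphabet_size=4)
        assert scheme.alphabet_size == 4
        validate = aw.DiscretizationScheme(
            boundaries=scheme.boundaries, cuts=scheme.cuts, slope_cuts=scheme.slope_cuts
        )
        assert validate.n_segments == 6
        symbols = aw.discretize_pla(X[0], scheme).symbols
        assert symbols.min() >= 0 and symbols.max() < 4

    def test_psa_cuts_symmetric(self, rng):
        X = rng.normal(0, 10, (20, 24))
        cuts = np.array(psa_cuts_from_training(X, aw.uniform_boundaries(24, 4)))
        assert np.allclose(cuts, -cuts[::-1])
        assert np.all(np.diff(cuts) > 0)

    def test_build_representations_shapes(self, default_series):
        raw = aw.series_to_dataset(default_series[:30])
        from acetowhite.representations import standardize_dataset

        std = standardize_dataset(raw, 10)
        scheme = aw.calibrate_scheme(std.features, aw.uniform_boundaries(180, 12), 5)
        reps = aw.build_representations(raw, 10, scheme)
        assert set(reps) == {"standardized", "adjusted", "parameters", "pla", "psa"}
        assert reps["standardized"].features.shape == (30, 180)
        assert reps["adjusted"].features.shape == (30, 180)
        assert reps["parameters"].features.shape == (30, 5)
        assert reps["pla"].features.shape == (30, 12) and reps["pla"].discrete
        assert reps["psa"].features.shape == (30, 12) and reps["psa"].discrete
        # PSA symbols live in the seven-letter slope alphabet
        assert reps["psa"].features.min() >= -3 and reps["psa"].features.max() <= 3

    def test_uniform_boundaries_tile(self):
        for n_seg in (1, 5, 12, 180):
            b = aw.uniform_boundaries(180, n_seg)
            assert b[-1] == 180
            assert len(b) == n_seg
            assert all(x < y for x, y in zip(b, b[1:]))

    def test_segment_helpers_agree_with_numpy(self, rng):
        values = rng.normal(0, 3, 20)
        scheme = aw.DiscretizationScheme(boundaries=[4, 11, 20], cuts=[0.0])
        means = segment_means(values, scheme)
        assert means == pytest.approx(
            [values[:4].mean(), values[4:11].mean(), values[11:].mean()]
        )
        slopes = segment_slopes(values, scheme)
        assert slopes.shape == (3,)
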