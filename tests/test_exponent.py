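"""Exponent solving, cohort regression, ratio summaries and side comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import least_squares

from bifex import (
    compare_sides,
    filter_low_tortuosity,
    fit_cohort_exponent,
    ica_adjustment,
    mean_individual_exponent,
    sample_cohort,
    solve_exponent,
    solve_exponent_records,
    summarize_ratios,
)


def _grid_scan_root(a, e, lo=0.05, hi=50.0, n_grid=1_000_000):
    """Independent oracle: dense grid scan of g(n) = a^n + e^n - 1 followed
    by linear interpolation across the sign change."""
    n = np.linspace(lo, hi, n_grid)
    g = a**n + e**n - 1.0
    i = np.searchsorted(-g, 0.0)  # g is strictly decreasing
    i = np.clip(i, 1, n_grid - 1)
    n0, n1, g0, g1 = n[i - 1], n[i], g[i - 1], g[i]
    return n0 - g0 * (n1 - n0) / (g1 - g0)


class TestSolveExponent:
    @pytest.mark.parametrize(
        "triple,expected",
        [
            ((5.0, 4.0, 3.0), 2.0),                       # area preservation
            ((1.0, 2 ** (-1 / 3), 2 ** (-1 / 3)), 3.0),   # symmetric cube law
        ],
    )
    def test_worked_triples(self, triple, expected):
        n, status = solve_exponent(*triple)
        assert status == "ok"
        assert n == pytest.approx(expected, abs=1e-9)

    def test_cohort_mean_ratio_triple(self):
        """The (1, 0.67, 0.61) mean-ratio triple solves near n = 1.55."""
        n, status = solve_exponent(1.0, 0.67, 0.61)
        assert status == "ok"
        assert n == pytest.approx(_grid_scan_root(0.67, 0.61), abs=1e-6)
        assert n == pytest.approx(1.55, abs=0.01)

    def test_daughter_larger_than_parent_has_no_root(self):
        n, status = solve_exponent(1.0, 1.1, 0.5)
        assert status == "no_root" and np.isnan(n)
        n, status = solve_exponent(1.0, 1.0, 0.5)
        assert status == "no_root"

    def test_nonpositive_radius_raises(self):
        with pytest.raises(ValueError):
            solve_exponent(1.0, -0.5, 0.5)

    def test_matches_grid_scan_oracle_on_random_triples(self, rng):
        """Brent root equals a 1e6-point grid-scan oracle on 100 triples."""
        for _ in range(100):
            a, e = rng.uniform(0.3, 0.95, size=2)
            n, status = solve_exponent(1.0, a, e)
            if status != "ok":
                continue
            assert n == pytest.approx(_grid_scan_root(a, e), abs=1e-6)

    @pytest.mark.parametrize("c", [0.001, 1.0, 7.3, 1000.0])
    def test_scale_invariance(self, c):
        n0, _ = solve_exponent(4.0, 2.68, 2.44)
        n1, _ = solve_exponent(4.0 * c, 2.68 * c, 2.44 * c)
        assert n1 == pytest.approx(n0, rel=1e-12)


class TestCohortRegression:
    @pytest.mark.parametrize("n_star", [1.2, 1.32, 1.58, 2.0, 3.0])
    def test_noiseless_recovery_both_estimators(self, n_star):
        df = sample_cohort(n_subjects=45, exact_exponent=n_star, noise_sd=0.0, seed=7)
        fit = fit_cohort_exponent(df)
        assert fit.converged
        assert fit.n_hat == pytest.approx(n_star, abs=1e-6)
        ind = mean_individual_exponent(solve_exponent_records(df))
        assert ind.mean == pytest.approx(n_star, abs=1e-6)
        assert ind.n_excluded == 0

    def test_both_model_forms_agree_noiseless(self):
        df = sample_cohort(n_subjects=30, exact_exponent=1.4, noise_sd=0.0, seed=3)
        f1 = fit_cohort_exponent(df, model_form="parent_radius")
        f2 = fit_cohort_exponent(df, model_form="power_sum")
        assert f1.n_hat == pytest.approx(f2.n_hat, abs=1e-6)

    def test_gauss_newton_matches_scipy_least_squares(self):
        """Independent optimizer oracle on a noisy cohort."""
        df = sample_cohort(n_subjects=60, exact_exponent=1.5, noise_sd=0.05, seed=21)
        fit = fit_cohort_exponent(df, model_form="parent_radius")
        c = df.r_cca_mm.to_numpy()
        a = df.r_ica_mm.to_numpy()
        e = df.r_eca_mm.to_numpy()

        def resid(p):
            n = p[0]
            return c - (a**n + e**n) ** (1.0 / n)

        ref = least_squares(resid, x0=[2.0], xtol=1e-14, ftol=1e-14)
        assert fit.n_hat == pytest.approx(float(ref.x[0]), abs=1e-6)

    def test_ci_covers_truth_in_most_replicates(self):
        """Linearized 95% CI contains the generating exponent in >= 90% of
        seeded replicates with 5% relative noise on the parent radius (the
        regression response).  Noise on the daughter radii is an
        errors-in-variables violation and is exercised separately."""
        hits = 0
        reps = 100
        for k in range(reps):
            df = sample_cohort(n_subjects=100, exact_exponent=1.3, noise_sd=0.0,
                               seed=10_000 + k)
            rng = np.random.default_rng(50_000 + k)
            df["r_cca_mm"] *= 1.0 + 0.05 * rng.standard_normal(len(df))
            fit = fit_cohort_exponent(df)
            if fit.ci95[0] <= 1.3 <= fit.ci95[1]:
                hits += 1
        assert hits >= 0.90 * reps

    def test_estimate_stays_near_truth_under_all_radius_noise(self):
        """With jitter on every radius the estimator remains close to the
        generating exponent even though classical CIs are no longer exact."""
        hats = []
        for k in range(20):
            df = sample_cohort(n_subjects=100, exact_exponent=1.3, noise_sd=0.05,
                               seed=20_000 + k)
            hats.append(fit_cohort_exponent(df).n_hat)
        assert np.mean(hats) == pytest.approx(1.3, abs=0.03)

    def test_estimators_differ_on_noisy_cohorts(self):
        """Mean-of-roots and regression weight the data differently; with
        noise they separate, while both approach the truth as noise -> 0."""
        noisy = sample_cohort(n_subjects=200, exact_exponent=1.4, noise_sd=0.08, seed=2)
        fit = fit_cohort_exponent(noisy)
        ind = mean_individual_exponent(solve_exponent_records(noisy))
        assert abs(fit.n_hat - ind.mean) > 1e-3
        clean = sample_cohort(n_subjects=200, exact_exponent=1.4, noise_sd=0.001, seed=2)
        fit_c = fit_cohort_exponent(clean)
        ind_c = mean_individual_exponent(solve_exponent_records(clean))
        assert fit_c.n_hat == pytest.approx(1.4, abs=0.01)
        assert ind_c.mean == pytest.approx(1.4, abs=0.01)

    def test_bootstrap_ci_seeded_and_ordered(self):
        df = sample_cohort(n_subjects=40, exact_exponent=1.5, noise_sd=0.05, seed=4)
        f1 = fit_cohort_exponent(df, ci_method="bootstrap", n_boot=200, seed=11)
        f2 = fit_cohort_exponent(df, ci_method="bootstrap", n_boot=200, seed=11)
        assert f1.ci95 == f2.ci95
        assert f1.ci95[0] <= f1.n_hat <= f1.ci95[1]

    def test_too_few_records_raise(self):
        df = sample_cohort(n_subjects=1, seed=0).head(2)
        with pytest.raises(ValueError, match="at least 3"):
            fit_cohort_exponent(df)


class TestMeanIndividual:
    def test_no_root_records_excluded_and_counted(self):
        df = pd.DataFrame(
            {
                "r_cca_mm": [5.0, 5.0, 4.0],
                "r_ica_mm": [4.0, 6.0, 3.2],
                "r_eca_mm": [3.0, 2.0, 2.4],
            }
        )
        out = mean_individual_exponent(solve_exponent_records(df))
        assert out.n_ok == 2 and out.n_excluded == 1
        assert out.mean == pytest.approx(2.0, abs=1e-9)  # both are 3-4-5 shapes

    def test_all_na_raises(self):
        df = pd.DataFrame(
            {"r_cca_mm": [1.0], "r_ica_mm": [1.2], "r_eca_mm": [0.5]}
        )
        with pytest.raises(ValueError, match="no record"):
            mean_individual_exponent(solve_exponent_records(df))


class TestIcaAdjustment:
    def test_closed_forms_from_mean_ratios(self):
        """Adjustments needed on the cohort mean triple: ~18.3% at n=2 and
        ~37% at n=3 (CCA and ECA held fixed)."""
        adj2 = ica_adjustment(1.0, 0.67, 0.61, n=2.0)
        assert adj2 == pytest.approx(100 * (np.sqrt(1 - 0.61**2) / 0.67 - 1), abs=1e-9)
        assert adj2 == pytest.approx(18.3, abs=0.05)
        adj3 = ica_adjustment(1.0, 0.67, 0.61, n=3.0)
        assert adj3 == pytest.approx(
            100 * ((1 - 0.61**3) ** (1 / 3) / 0.67 - 1), abs=1e-9
        )
        assert adj3 == pytest.approx(37.0, abs=0.05)

    def test_triple_already_on_law_needs_no_change(self):
        n = 2.0
        r_ica = (1.0 - 0.61**n) ** (1 / n)
        assert ica_adjustment(1.0, r_ica, 0.61, n=n) == pytest.approx(0.0, abs=1e-12)

    def test_eca_at_least_parent_raises(self):
        with pytest.raises(ValueError, match="r_eca"):
            ica_adjustment(1.0, 0.67, 1.0, n=2.0)


class TestRatioSummary:
    def test_single_record_values(self):
        df = pd.DataFrame({"r_cca_mm": [1.0], "r_ica_mm": [0.67], "r_eca_mm": [0.61]})
        s = summarize_ratios(df)
        assert s.mean("ica_cca") == pytest.approx(0.67)
        assert s.mean("eca_cca") == pytest.approx(0.61)
        assert s.mean("eca_ica") == pytest.approx(0.910, abs=5e-4)
        assert s.mean("area_ratio_quadratic") == pytest.approx(0.821, abs=5e-4)
        assert s.mean("area_ratio_linear") == pytest.approx(1.28, abs=5e-3)

    def test_identical_records_zero_sd_and_scale_invariance(self):
        one = {"r_cca_mm": 4.0, "r_ica_mm": 2.68, "r_eca_mm": 2.44}
        df = pd.DataFrame([one] * 5)
        s = summarize_ratios(df)
        assert all(s.sd(k) == 0.0 for k in ("ica_cca", "eca_cca", "eca_ica"))
        doubled = summarize_ratios(df * 2.0)
        for key in ("ica_cca", "eca_cca", "eca_ica", "area_ratio_linear"):
            assert doubled.mean(key) == pytest.approx(s.mean(key), rel=1e-12)


class TestCompareSides:
    @staticmethod
    def _paired_cohort(n, offset, rng):
        base = sample_cohort(n_subjects=n, exact_exponent=1.5, noise_sd=0.02,
                             seed=int(rng.integers(2**31)))
        left = base.side == "left"
        base.loc[left, "r_ica_mm"] += offset
        return base

    def test_identical_sides_give_p_one(self):
        df = sample_cohort(n_subjects=10, exact_exponent=1.5, seed=1)
        df.loc[df.side == "right", ["r_cca_mm", "r_ica_mm", "r_eca_mm"]] = (
            df.loc[df.side == "left", ["r_cca_mm", "r_ica_mm", "r_eca_mm"]].to_numpy()
        )
        out = compare_sides(df)
        assert out.ica_radius_t == 0.0 and out.ica_radius_p == 1.0
        assert out.exponent_p == 1.0
        assert out.n_pairs == 10 and out.df == 9

    def test_systematic_offset_detected(self, rng):
        df = self._paired_cohort(20, 0.4, rng)
        out = compare_sides(df)
        assert out.ica_radius_p < 0.05

    def test_single_subject_raises(self):
        df = sample_cohort(n_subjects=1, seed=0)
        with pytest.raises(ValueError, match="at least 2"):
            compare_sides(df)


class TestTortuosityFilter:
    def test_strict_threshold_boundary(self):
        df = pd.DataFrame(
            {
                "r_cca_mm": [4.0] * 3,
                "r_ica_mm": [2.7] * 3,
                "r_eca_mm": [2.4] * 3,
                "ica_tortuosity": [0.099, 0.1, 0.15],
            }
        )
        kept = filter_low_tortuosity(df)
        assert kept.ica_tortuosity.tolist() == [0.099]

    def test_known_labels_retained_exactly(self):
        rng = np.random.default_rng(0)
        tort = np.concatenate([rng.uniform(0.0, 0.08, 40), rng.uniform(0.12, 0.5, 60)])
        df = pd.DataFrame(
            {
                "r_cca_mm": 4.0,
                "r_ica_mm": 2.7,
                "r_eca_mm": 2.4,
                "ica_tortuosity": tort,
            }
        )
        assert len(filter_low_tortuosity(df)) == 40

    def test_missing_column_raises(self):
        with pytest.raises(ValueError, match="ica_tortuosity"):
            filter_low_tortuosity(pd.DataFrame({"r_cca_mm": [4.0]}))
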