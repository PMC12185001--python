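"""Statistics tests: Fisher, chi-square, t-test, regression, ellipses."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from periquant import (
    ContingencyTable2x2,
    DegenerateEllipseError,
    SceneSpec,
    ValidationError,
    analyze_cohort,
    chi_square_independence,
    confidence_ellipse,
    fisher_exact_2x2,
    generate_cohort,
    linear_regression,
    proximity_shift_report,
    r2_strength_label,
    segment_image,
    t_test_unpaired,
    tidy_results,
)
from conftest import (
    fisher_two_sided_enumeration,
    ols_normal_equations,
    pooled_t_oracle,
)


class TestFisherExact:
    def test_empty_outcome_column_gives_p_one(self):
        assert fisher_exact_2x2(ContingencyTable2x2(0, 5, 0, 8)) == 1.0

    def test_epicardial_attachment_table(self):
        """5/7 mutants blistered vs 0/7 controls: exact p ~ 0.021 (< 0.05)."""
        p = fisher_exact_2x2(ContingencyTable2x2(5, 2, 0, 7))
        p_oracle = fisher_two_sided_enumeration(5, 2, 0, 7)
        assert p == pytest.approx(p_oracle, rel=1e-7)
        assert p == pytest.approx(0.0210, abs=5e-4)
        assert p < 0.05

    def test_matches_enumeration_oracle_on_random_tables(self, rng):
        for _ in range(200):
            a, b, c, d = rng.integers(0, 13, size=4)
            if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
                continue
            p = fisher_exact_2x2(np.array([[a, b], [c, d]]))
            assert p == pytest.approx(
                fisher_two_sided_enumeration(a, b, c, d), rel=1e-7
            )

    def test_p_in_unit_interval_and_swap_invariance(self, rng):
        for _ in range(50):
            a, b, c, d = rng.integers(0, 10, size=4) + 1
            p = fisher_exact_2x2(np.array([[a, b], [c, d]]))
            assert 0 < p <= 1
            # swapping rows and swapping columns simultaneously relabels
            # groups and outcomes; the two-sided p is unchanged
            p_swapped = fisher_exact_2x2(np.array([[d, c], [b, a]]))
            assert p == pytest.approx(p_swapped, rel=1e-12)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValidationError):
            ContingencyTable2x2(-1, 2, 3, 4)


class TestChiSquare:
    def test_perfectly_proportional_table(self):
        res = chi_square_independence(np.array([[30, 60], [10, 20]]))
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_formula_on_k_by_2_table(self):
        counts = np.array([[30, 70], [50, 50]], dtype=float)
        res = chi_square_independence(counts)
        expected = np.outer(counts.sum(1), counts.sum(0)) / counts.sum()
        chi2_hand = (((counts - expected) ** 2) / expected).sum()
        assert res.chi2 == pytest.approx(chi2_hand, rel=1e-12)
        assert res.df == 1

    def test_2x2_closed_form_identity(self, rng):
        import warnings as _warnings

        for _ in range(50):
            a, b, c, d = rng.integers(1, 40, size=4)
            n = a + b + c + d
            closed = (
                n * (a * d - b * c) ** 2
                / ((a + b) * (c + d) * (a + c) * (b + d))
            )
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")  # tiny expected counts are fine here
                res = chi_square_independence(np.array([[a, b], [c, d]]))
            assert res.chi2 == pytest.approx(closed, rel=1e-10)

    def test_statistic_invariant_to_row_permutation(self, rng):
        counts = rng.integers(5, 50, size=(5, 2))
        res1 = chi_square_independence(counts)
        res2 = chi_square_independence(counts[::-1])
        assert res1.chi2 == pytest.approx(res2.chi2, rel=1e-12)
        assert res1.df == res2.df == 4

    def test_cluster_alpha_preset_flags_shifted_rows(self):
        from periquant.stats import CLUSTER_ALPHA

        # row 0 strongly shifted; remaining rows share one distribution and
        # are small enough that row-vs-rest stays above the 0.0025 cut
        counts = np.array([[100, 25], [100, 100], [100, 100], [100, 100]])
        res = chi_square_independence(counts, alpha=CLUSTER_ALPHA)
        assert res.alpha == 0.0025
        assert res.row_significant[0]
        assert not res.row_significant[1:].any()

    def test_zero_margin_rejected(self):
        with pytest.raises(ValidationError):
            chi_square_independence(np.array([[0, 0], [5, 5]]))

    def test_low_expected_count_warns(self):
        with pytest.warns(UserWarning, match="expected count"):
            chi_square_independence(np.array([[1, 9], [2, 8]]))


class TestTTest:
    def test_identical_groups(self):
        t, df, p = t_test_unpaired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0
        assert df == 4
        assert p == pytest.approx(1.0)

    def test_matches_pooled_formula_oracle(self, rng):
        a = rng.normal(10, 2, size=12)
        b = rng.normal(11, 3, size=9)
        t, df, p = t_test_unpaired(a, b)
        t_oracle, df_oracle = pooled_t_oracle(a, b)
        assert t == pytest.approx(t_oracle, abs=1e-10)
        assert df == df_oracle

    def test_zero_variance_cases(self):
        t, df, p = t_test_unpaired([5.0, 5.0], [5.0, 5.0])
        assert (t, p) == (0.0, 1.0)
        with pytest.warns(UserWarning):
            t, df, p = t_test_unpaired([5.0, 5.0], [4.0, 4.0])
        assert p == 0.0 and np.isinf(t)

    def test_welch_flag_changes_df(self, rng):
        a = rng.normal(0, 1, 10)
        b = rng.normal(0, 5, 30)
        _, df_student, _ = t_test_unpaired(a, b)
        _, df_welch, _ = t_test_unpaired(a, b, welch=True)
        assert df_student == 38
        assert df_welch != df_student


class TestRegression:
    def test_exact_line_is_substantial(self):
        x = np.arange(10, dtype=float)
        fit = linear_regression(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.strength_label == "substantial"

    @pytest.mark.parametrize(
        "r2,label",
        [(0.80, "substantial"), (0.75, "substantial"), (0.57, "moderate"),
         (0.50, "moderate"), (0.30, "weak"), (0.25, "weak"), (0.10, "below-weak")],
    )
    def test_strength_tiers(self, r2, label):
        assert r2_strength_label(r2) == label

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(20):
            x = rng.uniform(0, 100, size=15)
            y = 0.7 * x + rng.normal(0, 5, size=15)
            fit = linear_regression(x, y)
            slope, intercept, r2 = ols_normal_equations(x, y)
            assert fit.slope == pytest.approx(slope, rel=1e-10)
            assert fit.intercept == pytest.approx(intercept, rel=1e-10, abs=1e-10)
            assert fit.r_squared == pytest.approx(r2, rel=1e-10)

    def test_constant_x_rejected(self):
        with pytest.raises(ValidationError):
            linear_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_recovers_generating_slope(self, rng):
        """y = beta*x + noise: fitted slope within 3 s.e. of beta in >= 99/100."""
        beta, sigma, n = 1.8, 4.0, 100
        hits = 0
        for _ in range(100):
            x = rng.uniform(0, 10, n)
            y = beta * x + rng.normal(0, sigma, n)
            fit = linear_regression(x, y)
            resid = y - fit.slope * x - fit.intercept
            se = np.sqrt(
                (resid**2).sum() / (n - 2) / ((x - x.mean()) ** 2).sum()
            )
            hits += abs(fit.slope - beta) <= 3 * se
        assert hits >= 99


class TestConfidenceEllipse:
    def test_isotropic_unit_covariance_gives_chi2_circle(self, rng):
        pts = rng.normal(0, 1, size=(4000, 2))
        pts = (pts - pts.mean(0)) @ np.linalg.inv(
            np.linalg.cholesky(np.cov(pts, rowvar=False)).T
        )  # whiten so sample covariance is exactly I
        ell = confidence_ellipse(pts, coverage=0.95)
        q = 5.991464547107979  # chi2(2).ppf(0.95)
        assert np.allclose(ell.semi_axes, np.sqrt(q), rtol=1e-6)

    def test_translation_equivariance(self, rng):
        pts = rng.normal(0, 2, size=(50, 2))
        v = np.array([13.0, -4.0])
        e1 = confidence_ellipse(pts)
        e2 = confidence_ellipse(pts + v)
        assert np.allclose(e2.center, e1.center + v)
        assert np.allclose(np.sort(e2.semi_axes), np.sort(e1.semi_axes))

    def test_polygon_lies_on_coverage_contour(self, rng):
        pts = rng.normal(0, 1, size=(200, 2)) @ np.array([[2.0, 0.3], [0.0, 0.5]])
        ell = confidence_ellipse(pts)
        poly = ell.polygon(64)
        inv = np.linalg.inv(ell.covariance)
        m2 = np.einsum("ij,jk,ik->i", poly - ell.center, inv, poly - ell.center)
        assert np.allclose(m2, 5.991464547107979, rtol=1e-8)

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(DegenerateEllipseError):
            confidence_ellipse(pts)


class TestProximityShiftReport:
    @staticmethod
    def _study(retention: float, seed: int):
        control = SceneSpec(height_px=256, width_px=256, n_vessels=8,
                            n_gfp=60, n_nuclei=0)
        mutant = dataclasses.replace(control, interstitial_retention=retention)
        sheet, scenes = generate_cohort(control, mutant, 2, 3, seed=seed)
        objects = {
            i: segment_image(img, channels=("GFP", "CD109"))
            for i, (img, _) in scenes.items()
        }
        return analyze_cohort(objects, sheet)

    def test_identical_genotypes_give_null_result(self):
        study = self._study(retention=1.0, seed=2)
        # same spec both genotypes -> no systematic shift
        report = proximity_shift_report(
            study.summaries, study.threshold.value_px
        )
        assert report["chi_square"]["p"] > 0.05
        assert abs(report["t_tests"]["nn_distance_t_test_image"]["t"]) < 3

    def test_counts_equal_sum_of_per_image_counts(self):
        study = self._study(retention=0.5, seed=3)
        report = proximity_shift_report(study.summaries, study.threshold.value_px)
        table = np.asarray(report["class_count_table"]["counts"])
        by_geno = study.summaries.groupby("genotype")[
            ["n_perivascular", "n_interstitial"]
        ].sum()
        for j, g in enumerate(report["genotypes"]):
            assert table[0, j] == by_geno.loc[g, "n_perivascular"]
            assert table[1, j] == by_geno.loc[g, "n_interstitial"]

    def test_tidy_results_are_one_row_per_test(self):
        study = self._study(retention=0.5, seed=4)
        report = proximity_shift_report(study.summaries, study.threshold.value_px)
        tidy = tidy_results(report)
        assert "chi_square_class_counts" in set(tidy["test"])
        assert {"test", "statistic", "df", "p", "n", "groups"} <= set(tidy.columns)

    def test_missing_genotype_rejected(self):
        study = self._study(retention=1.0, seed=5)
        only_control = study.summaries[study.summaries["genotype"] == "control"]
        with pytest.raises(ValidationError):
            proximity_shift_report(only_control, study.threshold.value_px)
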