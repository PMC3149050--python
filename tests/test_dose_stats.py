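"""Tests of the group-level dose-response statistics."""

import numpy as np
import pytest
from scipy import stats

from ssrdcm.dose_stats import (DoseCurve, build_effect_table,
                               dose_response_curves, fit_dose_polynomial,
                               group_coefficient_test, one_tailed_t,
                               one_way_anova, overall_effect_test)
from ssrdcm.errors import EstimationError
from ssrdcm.inversion import Posterior
from ssrdcm.params import DOSES, EFFECT_PARAMS, REGIONS


def fake_posterior(effect_values):
    """Posterior stub holding named condition effects."""
    names, means = [], []
    for param in EFFECT_PARAMS:
        for region in REGIONS:
            for dose in DOSES[1:]:
                name = f"b_{param}_{region}_{dose:g}"
                names.append(name)
                means.append(effect_values.get(name, 0.0))
    n = len(names)
    return Posterior(names=tuple(names), mean=np.array(means),
                     cov=np.zeros((n, n)), free_energy=0.0, trace=[0.0],
                     converged=True, log_precision=0.0, accuracy=0.0,
                     complexity=0.0)


class TestEffectTable:
    def test_hemisphere_averaging(self):
        recs = [
            {"animal": "a1", "hemisphere": "L", "environment": "noise",
             "posterior": fake_posterior({"b_H_e_A1_1.8": 0.2})},
            {"animal": "a1", "hemisphere": "R", "environment": "noise",
             "posterior": fake_posterior({"b_H_e_A1_1.8": 0.4})},
        ]
        table = build_effect_table(recs)
        val = table[(table["animal"] == "a1") & (table["param"] == "H_e")
                    & (table["region"] == "A1") & (table["dose"] == 1.8)]
        assert val["effect"].item() == pytest.approx(0.3)

    def test_baseline_identically_zero(self):
        recs = [{"animal": "a1", "hemisphere": "L", "environment": "noise",
                 "posterior": fake_posterior({"b_H_i_PAF_2.8": 1.0})}]
        table = build_effect_table(recs)
        assert (table.loc[table["dose"] == 1.4, "effect"] == 0).all()

    def test_study_design_shape(self):
        recs = []
        for i in range(7):
            for env in ("noise", "silence"):
                hemis = ("L", "R") if i < 3 else ("L",)
                for h in hemis:
                    recs.append({"animal": f"a{i}", "hemisphere": h,
                                 "environment": env,
                                 "posterior": fake_posterior({})})
        table = build_effect_table(recs)
        # one row per animal x region x environment in the pivoted view
        pivot = table.pivot_table(index=["animal", "region", "environment"],
                                  columns=["param", "dose"], values="effect")
        assert pivot.shape[0] == 7 * 2 * 2


class TestAnova:
    def test_identical_groups_give_zero(self):
        res = one_way_anova([[1.0, 2.0, 3.0]] * 4)
        assert res.F == 0.0

    def test_study_degrees_of_freedom(self, rng):
        groups = [rng.normal(size=7) for _ in range(4)]
        res = one_way_anova(groups)
        assert res.df == (3, 24)

    def test_matches_explicit_sum_of_squares(self, rng):
        """Brute-force between/within decomposition to 1e-10."""
        groups = [rng.normal(loc=m, size=n)
                  for m, n in ((0.0, 5), (0.5, 7), (-0.3, 6), (1.0, 4))]
        res = one_way_anova(groups)
        allv = np.concatenate(groups)
        grand = allv.mean()
        ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
        k, N = len(groups), allv.size
        F_ref = (ss_between / (k - 1)) / (ss_within / (N - k))
        p_ref = stats.f.sf(F_ref, k - 1, N - k)
        assert res.F == pytest.approx(F_ref, abs=1e-10)
        assert res.p == pytest.approx(p_ref, abs=1e-10)

    def test_equals_squared_t_for_two_groups(self, rng):
        a, b = rng.normal(size=8), rng.normal(0.7, 1.0, size=8)
        res = one_way_anova([a, b])
        t = stats.ttest_ind(a, b).statistic
        assert res.F == pytest.approx(t ** 2, rel=1e-10)

    def test_degenerate_groups_rejected(self):
        with pytest.raises(EstimationError):
            one_way_anova([[1.0], [2.0, 3.0]])


class TestOneTailedT:
    def test_direction_detects_large_effect(self, rng):
        b = rng.normal(size=8)
        a = b + 1.0 + 0.05 * rng.normal(size=8)
        assert one_tailed_t(a, b, "greater").p < 0.05
        assert one_tailed_t(a, b, "less").p > 0.95

    def test_one_tailed_complement(self, rng):
        a, b = rng.normal(size=6), rng.normal(size=6)
        p_g = one_tailed_t(a, b, "greater").p
        p_l = one_tailed_t(a, b, "less").p
        assert p_g + p_l == pytest.approx(1.0, abs=1e-12)

    def test_three_pair_textbook_formula(self):
        a = np.array([1.2, 0.8, 1.5])
        b = np.array([1.0, 0.5, 1.1])
        d = a - b
        t_ref = d.mean() / (d.std(ddof=1) / np.sqrt(3))
        p_ref = stats.t.sf(t_ref, 2)
        res = one_tailed_t(a, b, "greater")
        assert res.t == pytest.approx(t_ref, abs=1e-12)
        assert res.p == pytest.approx(p_ref, abs=1e-12)

    def test_bonferroni_flag(self, rng):
        b = rng.normal(size=8)
        a = b + 0.8 + 0.3 * rng.normal(size=8)
        raw = one_tailed_t(a, b, "greater").p
        adj = one_tailed_t(a, b, "greater", bonferroni=True).p
        assert adj == pytest.approx(min(1.0, raw * 8))

    def test_zero_variance_rejected(self):
        with pytest.raises(EstimationError):
            one_tailed_t([1.0, 2.0, 3.0], [0.5, 1.5, 2.5], "greater")


class TestDosePolynomials:
    def test_exact_linear_recovery(self):
        doses = np.array(DOSES)
        curve = fit_dose_polynomial(doses, 2.0 * doses + 1.0, order=1)
        assert curve.coeffs == pytest.approx([1.0, 2.0], abs=1e-12)

    def test_quadratic_term_vanishes_on_linear_data(self):
        doses = np.array(DOSES)
        curve = fit_dose_polynomial(doses, -0.5 * doses + 0.2, order=2)
        assert abs(curve.quadratic) < 1e-10

    def test_saturating_curve_signs(self):
        """y = −(d−2.8)² expands to −d² + 5.6d − 7.84 on [1.4, 2.8]."""
        doses = np.array(DOSES)
        curve = fit_dose_polynomial(doses, -(doses - 2.8) ** 2, order=2)
        assert curve.quadratic == pytest.approx(-1.0, abs=1e-10)
        assert curve.coeffs[1] == pytest.approx(5.6, abs=1e-10)

    def test_insufficient_points(self):
        with pytest.raises(EstimationError):
            fit_dose_polynomial([1.4, 1.8, 2.4], [0, 1, 2], order=2)


class TestGroupCoefficientTest:
    def curves(self, slopes):
        return [DoseCurve(coeffs=np.array([0.0, s]), order=1,
                          doses=np.array(DOSES), residuals=np.zeros(4))
                for s in slopes]

    def test_consistent_negative_slopes(self, rng):
        res = group_coefficient_test(
            self.curves(-0.5 + 0.05 * rng.normal(size=6)), "slope", "less")
        assert res.p < 0.01
        assert res.mean < 0

    def test_symmetric_coefficients_uninformative(self):
        res = group_coefficient_test(self.curves([-0.4, 0.4, -0.2, 0.2]),
                                     "slope", "less")
        assert res.p == pytest.approx(0.5, abs=1e-10)

    def test_reported_mean_sem(self):
        res = group_coefficient_test(self.curves([-0.4, -0.6, -0.8]),
                                     "slope", "less")
        assert res.mean == pytest.approx(-0.6)
        assert res.sem == pytest.approx(0.2 / np.sqrt(3), abs=1e-10)


class TestPipelineHelpers:
    def test_overall_effect_and_curves(self, rng):
        recs = []
        for i in range(5):
            vals = {}
            for region in REGIONS:
                for dose in DOSES[1:]:
                    u = dose - 1.4
                    vals[f"b_H_e_{region}_{dose:g}"] = \
                        -0.5 * u + 0.02 * rng.normal()
                    vals[f"b_H_i_{region}_{dose:g}"] = \
                        1.2 * u - 0.55 * u ** 2 + 0.02 * rng.normal()
            recs.append({"animal": f"a{i}", "hemisphere": "L",
                         "environment": "noise",
                         "posterior": fake_posterior(vals)})
        table = build_effect_table(recs)
        t_he = overall_effect_test(table, "H_e", "A1", "noise", "less")
        assert t_he.p < 0.01
        curves = dose_response_curves(table, "H_i", "PAF", "noise", order=2)
        res = group_coefficient_test(list(curves.values()), "quadratic",
                                     "less")
        assert res.mean == pytest.approx(-0.55, abs=0.1)
        assert res.p < 0.01
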