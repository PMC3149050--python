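"""Group-level statistics on dose-dependent synaptic parameter estimates.

The posterior-mean (MAP) condition effects — log-scalings of H_e, H_i and
κ_i relative to the lowest-dose baseline — are analysed across animals:
overall direction tests against baseline, one-way ANOVAs with anaesthetic
depth as the single factor, one-tailed post-hoc comparisons (paired across
animals, reflecting the within-animal design), and first/second-order
polynomial dose-response fits whose coefficients are tested for consistent
sign across animals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EstimationError, ParameterError, StructuralError
from .params import DOSES, EFFECT_PARAMS, REGIONS

__all__ = ["build_effect_table", "one_way_anova", "one_tailed_t",
           "fit_dose_polynomial", "group_coefficient_test",
           "AnovaResult", "TTestResult", "DoseCurve", "overall_effect_test"]

#: Bonferroni family size used for the optional post-hoc adjustment.
N_POSTHOC_COMPARISONS = 8


def build_effect_table(records, doses: tuple = DOSES,
                       regions: tuple = REGIONS) -> pd.DataFrame:
    """Tidy table of MAP condition effects, hemisphere-averaged per animal.

    ``records`` is an iterable of per-recording dicts with keys ``animal``,
    ``hemisphere``, ``environment`` and ``posterior`` (a fitted
    :class:`~ssrdcm.inversion.Posterior` whose names include
    ``b_<param>_<region>_<dose>`` entries for every non-baseline dose).
    Output columns: animal, region, environment, param, dose, effect —
    one row per combination, baseline rows identically zero.
    """
    rows = []
    baseline = min(doses)
    for rec in records:
        post = rec["posterior"]
        for region in regions:
            for param in EFFECT_PARAMS:
                for dose in doses:
                    if np.isclose(dose, baseline):
                        effect = 0.0
                    else:
                        name = f"b_{param}_{region}_{dose:g}"
                        try:
                            effect = post[name]
                        except ValueError as exc:
                            raise StructuralError(
                                f"posterior lacks condition effect {name!r}"
                            ) from exc
                    rows.append({
                        "animal": rec["animal"],
                        "hemisphere": rec.get("hemisphere", "L"),
                        "environment": rec.get("environment", "noise"),
                        "region": region,
                        "param": param,
                        "dose": dose,
                        "effect": effect,
                    })
    df = pd.DataFrame(rows)
    # hemisphere-average where animals were recorded bilaterally
    out = (df.groupby(["animal", "environment", "region", "param", "dose"],
                      as_index=False)["effect"].mean())
    return out


@dataclass
class AnovaResult:
    F: float
    df: tuple          # (k-1, N-k)
    p: float


def one_way_anova(groups) -> AnovaResult:
    """Classical one-way ANOVA over dose groups.

    ``groups`` is a sequence of 1-D arrays (one per dose level).  Returns
    the F statistic, its (between, within) degrees of freedom and the
    right-tail p-value.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise EstimationError("ANOVA needs >= 2 groups with >= 2 values each")
    k = len(groups)
    n_total = sum(g.size for g in groups)
    df = (k - 1, n_total - k)
    F, p = stats.f_oneway(*groups)
    if not np.isfinite(F):       # identical data in all cells
        F, p = 0.0, 1.0
    return AnovaResult(F=float(F), df=df, p=float(p))


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    mean: float | None = None
    sem: float | None = None


def one_tailed_t(values_a, values_b, direction: str = "greater",
                 paired: bool = True, bonferroni: bool = False) -> TTestResult:
    """One-tailed t-test of a vs b (paired across animals by default).

    ``direction="greater"`` tests mean(a) > mean(b) (for inhibitory
    increases), ``"less"`` the opposite (excitatory decreases).  With
    ``bonferroni=True`` the p-value is multiplied by the post-hoc family
    size (8 comparisons), capped at 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if direction not in ("greater", "less"):
        raise ParameterError("direction must be 'greater' or 'less'")
    if paired:
        if a.size != b.size:
            raise StructuralError("paired test needs equal-length samples")
        if np.allclose(a - b, (a - b)[0]) and np.isclose(np.std(a - b), 0):
            raise EstimationError("zero variance of paired differences")
        res = stats.ttest_rel(a, b, alternative=direction)
        df = a.size - 1
    else:
        res = stats.ttest_ind(a, b, alternative=direction)
        df = a.size + b.size - 2
    p = float(res.pvalue)
    if bonferroni:
        p = min(1.0, p * N_POSTHOC_COMPARISONS)
    return TTestResult(t=float(res.statistic), df=df, p=p)


def overall_effect_test(effects: pd.DataFrame, param: str, region: str,
                        environment: str, direction: str) -> TTestResult:
    """Overall change relative to baseline: one-sample one-tailed t-test of
    the per-animal mean non-baseline effect against zero."""
    sel = effects[(effects["param"] == param) & (effects["region"] == region)
                  & (effects["environment"] == environment)
                  & (effects["dose"] > min(DOSES))]
    per_animal = sel.groupby("animal")["effect"].mean().to_numpy()
    if per_animal.size < 3:
        raise EstimationError("need >= 3 animals for the overall test")
    res = stats.ttest_1samp(per_animal, 0.0, alternative=direction)
    return TTestResult(t=float(res.statistic), df=per_animal.size - 1,
                       p=float(res.pvalue),
                       mean=float(per_animal.mean()),
                       sem=float(stats.sem(per_animal)))


@dataclass
class DoseCurve:
    """Polynomial dose-response fit on the raw dose scale (% units).

    ``coeffs`` are ascending: (intercept, linear[, quadratic]).
    """

    coeffs: np.ndarray
    order: int
    doses: np.ndarray
    residuals: np.ndarray

    @property
    def slope(self) -> float:
        return float(self.coeffs[1])

    @property
    def quadratic(self) -> float:
        if self.order < 2:
            raise ParameterError("no quadratic coefficient in an order-1 fit")
        return float(self.coeffs[2])


def fit_dose_polynomial(doses, values, order: int = 1) -> DoseCurve:
    """Least-squares polynomial of the dose response (raw, uncentred doses)."""
    doses = np.asarray(doses, dtype=float)
    values = np.asarray(values, dtype=float)
    if order not in (1, 2):
        raise ParameterError("polynomial order must be 1 or 2")
    if doses.size < order + 2:
        raise EstimationError(
            f"need >= {order + 2} dose points for an order-{order} fit")
    coeffs = np.polynomial.polynomial.polyfit(doses, values, order)
    fitted = np.polynomial.polynomial.polyval(doses, coeffs)
    return DoseCurve(coeffs=coeffs, order=order, doses=doses,
                     residuals=values - fitted)


def group_coefficient_test(curves, coefficient: str,
                           direction: str = "less") -> TTestResult:
    """Consistency of a dose-curve coefficient across animals.

    ``curves`` is a sequence of :class:`DoseCurve` (one per animal);
    ``coefficient`` is ``"slope"`` or ``"quadratic"``.  One-sample
    one-tailed t-test against zero, reporting mean ± s.e.m. alongside.
    """
    vals = np.array([getattr(c, coefficient) for c in curves], dtype=float)
    if vals.size < 3:
        raise EstimationError("need >= 3 animals for the group test")
    if np.isclose(vals.std(ddof=1), 0.0):
        raise EstimationError("zero variance of coefficients across animals")
    res = stats.ttest_1samp(vals, 0.0, alternative=direction)
    return TTestResult(t=float(res.statistic), df=vals.size - 1,
                       p=float(res.pvalue), mean=float(vals.mean()),
                       sem=float(stats.sem(vals)))


def dose_response_curves(effects: pd.DataFrame, param: str, region: str,
                         environment: str, order: int = 1) -> dict:
    """Per-animal polynomial fits of one parameter's dose response."""
    sel = effects[(effects["param"] == param) & (effects["region"] == region)
                  & (effects["environment"] == environment)]
    curves = {}
    for animal, grp in sel.groupby("animal"):
        grp = grp.sort_values("dose")
        curves[animal] = fit_dose_polynomial(grp["dose"].to_numpy(),
                                             grp["effect"].to_numpy(), order)
    return curves
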