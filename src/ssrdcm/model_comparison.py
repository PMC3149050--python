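"""Fixed-effects Bayesian model selection over network architectures.

Log-evidences (free-energy bounds) are summed over subjects — assuming
conditionally independent data — to give group log Bayes factors between
architectures.  A Bayes factor above 150 (log Bayes factor ≈ 5) is
conventionally labelled very strong evidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import StructuralError

__all__ = ["VERY_STRONG_LN_BF", "average_hemispheres",
           "group_log_bayes_factor", "select_model", "SelectionResult"]

#: Log Bayes factor above which evidence is conventionally "very strong".
VERY_STRONG_LN_BF = float(np.log(150.0))

MODELS = ("FB", "BF", "LL")


def average_hemispheres(records: pd.DataFrame,
                        models: tuple = MODELS) -> pd.DataFrame:
    """Collapse per-recording log-evidences to one row per animal.

    ``records`` needs columns ``animal``, ``hemisphere``, ``model``,
    ``log_evidence``.  Animals recorded bilaterally contribute the
    arithmetic mean of their two hemisphere log-evidences; single
    recordings pass through.  More than two recordings per animal and
    model is a structural error.
    """
    required = {"animal", "hemisphere", "model", "log_evidence"}
    missing = required - set(records.columns)
    if missing:
        raise StructuralError(f"records missing columns {sorted(missing)}")
    counts = records.groupby(["animal", "model"])["hemisphere"].count()
    if (counts > 2).any():
        bad = counts[counts > 2].index.tolist()
        raise StructuralError(f">2 recordings per animal and model: {bad}")
    table = records.pivot_table(index="animal", columns="model",
                                values="log_evidence", aggfunc="mean")
    present = [m for m in models if m in table.columns]
    table = table[present]
    table.columns.name = None
    return table


def _check_table(table: pd.DataFrame):
    if table.isna().any().any():
        raise StructuralError("evidence table has missing cells")
    if not np.isfinite(table.to_numpy()).all():
        raise StructuralError("evidence table has non-finite entries")


def group_log_bayes_factor(table: pd.DataFrame, model_a: str,
                           model_b: str) -> float:
    """Σ_subjects F_a − Σ_subjects F_b (nats); positive favours ``model_a``."""
    for m in (model_a, model_b):
        if m not in table.columns:
            raise KeyError(f"model {m!r} not in evidence table")
    _check_table(table[[model_a, model_b]])
    return float(table[model_a].sum() - table[model_b].sum())


@dataclass
class SelectionResult:
    """Ranked architectures with pairwise group log Bayes factors."""

    ranking: tuple                 # model tags, best first
    summed_evidence: dict          # model -> Σ F
    pairwise_ln_gbf: dict          # (better, worse) -> lnGBF ≥ 0
    labels: dict                   # (better, worse) -> evidence label
    tied: bool

    @property
    def best(self) -> str:
        return self.ranking[0]


def select_model(table: pd.DataFrame) -> SelectionResult:
    """Rank models by summed log-evidence and label pairwise Bayes factors.

    Ties are broken lexicographically by model tag and flagged.  A pairwise
    comparison is labelled ``"very strong"`` iff its log group Bayes factor
    is at least ln 150, else ``"weak"``.
    """
    _check_table(table)
    sums = {m: float(table[m].sum()) for m in table.columns}
    # sort by evidence descending, lexicographic tag as deterministic tie-break
    ranking = tuple(sorted(sums, key=lambda m: (-sums[m], m)))
    values = sorted(sums.values(), reverse=True)
    tied = any(np.isclose(a, b) for a, b in zip(values, values[1:]))
    pairwise, labels = {}, {}
    for i, better in enumerate(ranking):
        for worse in ranking[i + 1:]:
            ln_gbf = sums[better] - sums[worse]
            pairwise[(better, worse)] = ln_gbf
            labels[(better, worse)] = (
                "very strong" if ln_gbf >= VERY_STRONG_LN_BF else "weak"
            )
    return SelectionResult(ranking=ranking, summed_evidence=sums,
                           pairwise_ln_gbf=pairwise, labels=labels, tied=tied)
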