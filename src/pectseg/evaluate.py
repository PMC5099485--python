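"""Segmentation scoring: FP/FN percentages, concordance, cohort summaries.

With predicted mask ``A`` and reference mask ``M`` (pixel sets):

* ``FP% = 100·|A∖M| / |M|`` — muscle predicted where the reference has none,
* ``FN% = 100·|M∖A| / |M|`` — reference muscle the prediction missed,
* concordance = ``100·|A∩M| / |A∪M|`` (Jaccard; Dice available as an option).

Both FP and FN are normalised by the reference muscle area, the convention
of the mammography segmentation literature.  Concordance above 90% is
"good", above 50% "acceptable", otherwise "unacceptable"; the uncovered
boundary values (exactly 90, exactly 50) fall to the lower category.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError, UndefinedReferenceError
from .types import as_mask

__all__ = [
    "Category",
    "SegEvaluation",
    "CohortSummary",
    "evaluate_pair",
    "classify_concordance",
    "summarize_cohort",
    "write_case_report",
]


class Category(enum.Enum):
    GOOD = "good"
    ACCEPTABLE = "acceptable"
    UNACCEPTABLE = "unacceptable"


@dataclass(frozen=True)
class SegEvaluation:
    fp_pct: float
    fn_pct: float
    concordance_pct: float
    category: Category
    case_id: str = ""


@dataclass(frozen=True)
class CohortSummary:
    """Category counts, FP/FN mean ± sample SD, and the three exclusive
    FP/FN quality bands (both < 5%; otherwise both <= 15%; the remainder)."""

    n_good: int
    n_acceptable: int
    n_unacceptable: int
    fp_mean: float
    fp_sd: float
    fn_mean: float
    fn_sd: float
    band_fractions: tuple[float, float, float]

    @property
    def n_cases(self) -> int:
        return self.n_good + self.n_acceptable + self.n_unacceptable

    def to_dict(self) -> dict:
        return {
            "n_cases": self.n_cases,
            "n_good": self.n_good,
            "n_acceptable": self.n_acceptable,
            "n_unacceptable": self.n_unacceptable,
            "fp_mean_pct": self.fp_mean,
            "fp_sd_pct": self.fp_sd,
            "fn_mean_pct": self.fn_mean,
            "fn_sd_pct": self.fn_sd,
            "band_both_lt_5": self.band_fractions[0],
            "band_both_le_15": self.band_fractions[1],
            "band_worse": self.band_fractions[2],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def classify_concordance(concordance_pct: float) -> Category:
    """Map a concordance percentage to good / acceptable / unacceptable."""
    if not 0.0 <= concordance_pct <= 100.0:
        raise ParameterError("concordance must be a percentage in [0, 100]")
    if concordance_pct > 90.0:
        return Category.GOOD
    if concordance_pct > 50.0:
        return Category.ACCEPTABLE
    return Category.UNACCEPTABLE


def evaluate_pair(pred, ref, metric: str = "jaccard", case_id: str = "") -> SegEvaluation:
    """Score one predicted mask against its reference mask."""
    A = as_mask(pred).astype(bool)
    M = as_mask(ref).astype(bool)
    if A.shape != M.shape:
        raise ParameterError("mask shapes differ")
    m_area = int(M.sum())
    if m_area == 0:
        raise UndefinedReferenceError("reference mask is empty")
    inter = int((A & M).sum())
    union = int((A | M).sum())
    fp = 100.0 * (int(A.sum()) - inter) / m_area
    fn = 100.0 * (m_area - inter) / m_area
    if metric == "jaccard":
        conc = 100.0 * inter / union
    elif metric == "dice":
        conc = 200.0 * inter / (int(A.sum()) + m_area)
    else:
        raise ParameterError(f"unknown concordance metric {metric!r}")
    return SegEvaluation(fp, fn, conc, classify_concordance(conc), case_id)


def summarize_cohort(evals) -> CohortSummary:
    """Aggregate per-case evaluations into the cohort report.

    SD is the sample standard deviation (ddof=1); a single-case cohort
    reports SD 0.  Band fractions use the exclusive cascade (both FP and FN
    < 5%; else both <= 15%; else the remainder) so they sum to 1.
    """
    evals = list(evals)
    if not evals:
        raise ParameterError("cannot summarize an empty cohort")
    fps = np.array([e.fp_pct for e in evals], dtype=np.float64)
    fns = np.array([e.fn_pct for e in evals], dtype=np.float64)
    counts = {cat: 0 for cat in Category}
    for e in evals:
        counts[e.category] += 1
    bands = [0, 0, 0]
    for fp, fn in zip(fps, fns):
        if fp < 5.0 and fn < 5.0:
            bands[0] += 1
        elif fp <= 15.0 and fn <= 15.0:
            bands[1] += 1
        else:
            bands[2] += 1
    n = len(evals)
    sd = (lambda x: float(np.std(x, ddof=1)) if n > 1 else 0.0)
    return CohortSummary(
        n_good=counts[Category.GOOD],
        n_acceptable=counts[Category.ACCEPTABLE],
        n_unacceptable=counts[Category.UNACCEPTABLE],
        fp_mean=float(fps.mean()),
        fp_sd=sd(fps),
        fn_mean=float(fns.mean()),
        fn_sd=sd(fns),
        band_fractions=tuple(b / n for b in bands),
    )


def write_case_report(evals, path) -> pd.DataFrame:
    """Write the per-case CSV report (id, fp, fn, concordance, category)."""
    df = pd.DataFrame(
        {
            "id": [e.case_id for e in evals],
            "fp_pct": [e.fp_pct for e in evals],
            "fn_pct": [e.fn_pct for e in evals],
            "concordance_pct": [e.concordance_pct for e in evals],
            "category": [e.category.value for e in evals],
        }
    )
    df.to_csv(path, index=False)
    return df
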