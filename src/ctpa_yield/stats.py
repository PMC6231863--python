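"""Validation statistics: the 2x2 confusion table against chart review,
Cohen's kappa with an asymptotic 95% CI, McNemar's test, capture accuracy.

Conventions for the 2x2 table (computed classification vs chart review):

=========  ==========  ==========
           chart +     chart -
=========  ==========  ==========
computed+  a           b
computed-  c           d
=========  ==========  ==========

Kappa: with p_o = (a+d)/n and
p_e = [(a+b)(a+c) + (c+d)(b+d)] / n^2,

    kappa = (p_o - p_e) / (1 - p_e),
    se    = sqrt( p_o (1 - p_o) / ( n (1 - p_e)^2 ) ),

and the 95% CI is kappa +/- 1.96 se, truncated to [-1, 1].

Capture accuracy is a/(a+c): the fraction of chart-positive scans the
computerized method identifies (operationally a sensitivity; the field's
reporting convention for this quantity is "accuracy" and that label is kept
in report output). Observed agreement (a+d)/n is reported separately.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Dict, Optional, Sequence, Tuple

from scipy import stats as _sps

from .errors import IntegrityError, UndefinedStatisticError
from .model import GoldStandardLabel
from .pipeline import OrderClassification

__all__ = [
    "ConfusionTable2x2",
    "McNemarVariant",
    "AgreementStats",
    "build_confusion",
    "cohens_kappa",
    "mcnemar_test",
    "capture_accuracy",
    "compute_agreement",
]


@dataclass(frozen=True)
class ConfusionTable2x2:
    """Cell counts: a = both positive, b = computed+/chart-,
    c = computed-/chart+, d = both negative."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("confusion cells must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def transpose(self) -> "ConfusionTable2x2":
        """Swap the two raters (b <-> c)."""
        return ConfusionTable2x2(self.a, self.c, self.b, self.d)


class McNemarVariant(Enum):
    UNCORRECTED = "uncorrected"
    CONTINUITY_CORRECTED = "continuity_corrected"
    EXACT_BINOMIAL = "exact_binomial"


@dataclass(frozen=True)
class AgreementStats:
    table: ConfusionTable2x2
    kappa: float
    kappa_se: float
    kappa_ci95: Tuple[float, float]
    mcnemar_variant: McNemarVariant
    mcnemar_statistic: Optional[float]
    mcnemar_p: float
    capture_accuracy: float
    observed_agreement: float


def build_confusion(
    classifications: Sequence[OrderClassification],
    labels: Sequence[GoldStandardLabel],
) -> ConfusionTable2x2:
    """Cross-tabulate computed classifications against gold-standard labels.

    Only orders present in both sets enter the table — and every label must
    refer to a classified order; an unknown or duplicated label is an
    integrity error, never a silent drop.
    """
    computed: Dict[str, bool] = {}
    for c in classifications:
        if c.order_id in computed:
            raise IntegrityError(f"duplicate classification for order {c.order_id!r}")
        computed[c.order_id] = c.computed_pe_positive
    seen = set()
    a = b = c_ = d = 0
    for lab in labels:
        if lab.order_id in seen:
            raise IntegrityError(f"duplicate gold label for order {lab.order_id!r}")
        seen.add(lab.order_id)
        if lab.order_id not in computed:
            raise IntegrityError(
                f"gold label for unknown order {lab.order_id!r} "
                f"(no classification present)"
            )
        comp, chart = computed[lab.order_id], lab.chart_review_pe_positive
        if comp and chart:
            a += 1
        elif comp and not chart:
            b += 1
        elif not comp and chart:
            c_ += 1
        else:
            d += 1
    return ConfusionTable2x2(a, b, c_, d)


def cohens_kappa(table: ConfusionTable2x2) -> Tuple[float, float, Tuple[float, float]]:
    """Cohen's kappa with large-sample SE and 95% CI truncated to [-1, 1].

    Raises UndefinedStatisticError for n = 0 or degenerate marginals
    (expected agreement 1).
    """
    n = table.n
    if n == 0:
        raise UndefinedStatisticError("kappa undefined for an empty table")
    a, b, c, d = table.a, table.b, table.c, table.d
    p_o = (a + d) / n
    p_e = ((a + b) * (a + c) + (c + d) * (b + d)) / n**2
    if p_e >= 1.0:
        raise UndefinedStatisticError(
            "kappa undefined: degenerate marginals (expected agreement = 1)"
        )
    kappa = (p_o - p_e) / (1 - p_e)
    se = math.sqrt(p_o * (1 - p_o) / (n * (1 - p_e) ** 2))
    lo = max(-1.0, kappa - 1.96 * se)
    hi = min(1.0, kappa + 1.96 * se)
    return kappa, se, (lo, hi)


def mcnemar_test(
    table: ConfusionTable2x2,
    variant: McNemarVariant = McNemarVariant.UNCORRECTED,
) -> Tuple[Optional[float], float]:
    """McNemar's test for marginal homogeneity of the paired classifications.

    Driven entirely by the discordant cells b and c. Returns
    (statistic, p_value); the statistic is None for the exact variant and
    when b + c = 0 (where p = 1 by convention for all variants).
    """
    b, c = table.b, table.c
    m = b + c
    if m == 0:
        return None, 1.0
    if variant is McNemarVariant.UNCORRECTED:
        stat = (b - c) ** 2 / m
        return stat, float(_sps.chi2.sf(stat, df=1))
    if variant is McNemarVariant.CONTINUITY_CORRECTED:
        stat = max(abs(b - c) - 1, 0) ** 2 / m
        return stat, float(_sps.chi2.sf(stat, df=1))
    if variant is McNemarVariant.EXACT_BINOMIAL:
        p = float(_sps.binomtest(b, m, 0.5, alternative="two-sided").pvalue)
        return None, min(p, 1.0)
    raise ValueError(f"unknown McNemar variant: {variant!r}")


def capture_accuracy(table: ConfusionTable2x2) -> float:
    """a/(a+c): fraction of chart-positive scans the method captured."""
    positives = table.a + table.c
    if positives == 0:
        raise UndefinedStatisticError(
            "capture accuracy undefined: no chart-positive scans"
        )
    return table.a / positives


def compute_agreement(
    classifications: Sequence[OrderClassification],
    labels: Sequence[GoldStandardLabel],
    mcnemar_variant: McNemarVariant = McNemarVariant.UNCORRECTED,
) -> AgreementStats:
    """Build the confusion table and compute the full validation panel."""
    table = build_confusion(classifications, labels)
    kappa, se, ci = cohens_kappa(table)
    stat, p = mcnemar_test(table, mcnemar_variant)
    return AgreementStats(
        table=table,
        kappa=kappa,
        kappa_se=se,
        kappa_ci95=ci,
        mcnemar_variant=mcnemar_variant,
        mcnemar_statistic=stat,
        mcnemar_p=p,
        capture_accuracy=capture_accuracy(table),
        observed_agreement=(table.a + table.d) / table.n,
    )
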