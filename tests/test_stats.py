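"""Agreement statistics: confusion table, kappa + CI, McNemar, capture.

Kappa is checked against a brute-force expected-table implementation and
against scikit-learn; McNemar variants against statsmodels and an explicit
binomial enumeration.
"""
import math

import numpy as np
import pytest
from scipy import stats as sps
from sklearn.metrics import cohen_kappa_score
from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

from ctpa_yield.errors import IntegrityError, UndefinedStatisticError
from ctpa_yield.model import GoldStandardLabel
from ctpa_yield.pipeline import OrderClassification
from ctpa_yield.stats import (
    ConfusionTable2x2,
    McNemarVariant,
    build_confusion,
    capture_accuracy,
    cohens_kappa,
    compute_agreement,
    mcnemar_test,
)

STUDY_TABLE = ConfusionTable2x2(27, 0, 1, 321)


def kappa_brute_force(t):
    """Oracle: explicit sum over the 2x2 expected-agreement table."""
    n = t.n
    observed = (t.a + t.d) / n
    row = [t.a + t.b, t.c + t.d]
    col = [t.a + t.c, t.b + t.d]
    expected = sum(row[i] * col[i] for i in range(2)) / n**2
    return (observed - expected) / (1 - expected)


# --- build_confusion ---------------------------------------------------------

def _pairs(n, computed, chart, start=0):
    cls = [
        OrderClassification(f"O{start+i}", "A", f"A{start+i}" if computed else None,
                            computed)
        for i in range(n)
    ]
    labels = [GoldStandardLabel(f"O{start+i}", chart) for i in range(n)]
    return cls, labels


def test_confusion_counts_by_joint_positivity():
    cls, labels = [], []
    for i, (n, comp, chart) in enumerate([(3, True, True), (2, True, False),
                                          (1, False, True), (4, False, False)]):
        c, l = _pairs(n, comp, chart, start=100 * i)
        cls += c
        labels += l
    t = build_confusion(cls, labels)
    assert (t.a, t.b, t.c, t.d) == (3, 2, 1, 4) and t.n == 10


def test_label_for_unknown_order_is_integrity_error():
    cls, labels = _pairs(2, True, True)
    labels.append(GoldStandardLabel("O999", False))
    with pytest.raises(IntegrityError, match="O999"):
        build_confusion(cls, labels)


def test_duplicate_label_is_integrity_error():
    cls, labels = _pairs(2, True, True)
    with pytest.raises(IntegrityError):
        build_confusion(cls, labels + [labels[0]])


def test_empty_sets_give_all_zero_cells_and_downstream_errors():
    t = build_confusion([], [])
    assert (t.a, t.b, t.c, t.d) == (0, 0, 0, 0)
    with pytest.raises(UndefinedStatisticError):
        cohens_kappa(t)
    with pytest.raises(UndefinedStatisticError):
        capture_accuracy(t)


# --- kappa --------------------------------------------------------------------

def test_kappa_on_study_table_matches_hand_derivation():
    kappa, se, (lo, hi) = cohens_kappa(STUDY_TABLE)
    assert round(kappa, 2) == 0.98
    assert round(lo, 2) == 0.94
    assert hi == 1.0  # truncated: kappa + 1.96 se exceeds 1
    assert kappa + 1.96 * se > 1.0


def test_kappa_zero_when_agreement_equals_chance():
    kappa, _, _ = cohens_kappa(ConfusionTable2x2(25, 25, 25, 25))
    assert kappa == pytest.approx(0.0)


def test_kappa_one_on_perfect_nondegenerate_agreement():
    kappa, se, (lo, hi) = cohens_kappa(ConfusionTable2x2(7, 0, 0, 13))
    assert kappa == pytest.approx(1.0) and hi == 1.0


def test_kappa_degenerate_marginals_raise():
    with pytest.raises(UndefinedStatisticError):
        cohens_kappa(ConfusionTable2x2(10, 0, 0, 0))


def test_kappa_matches_brute_force_on_1000_random_tables():
    rng = np.random.default_rng(0)
    checked = 0
    while checked < 1000:
        a, b, c, d = rng.integers(0, 126, size=4)
        t = ConfusionTable2x2(int(a), int(b), int(c), int(d))
        if t.n == 0 or t.n > 500:
            continue
        pe = ((a + b) * (a + c) + (c + d) * (b + d)) / t.n**2
        if pe >= 1.0:
            continue
        kappa, se, (lo, hi) = cohens_kappa(t)
        assert kappa == pytest.approx(kappa_brute_force(t), abs=1e-12)
        assert lo <= kappa <= hi and -1.0 <= lo and hi <= 1.0
        checked += 1


def test_kappa_symmetric_under_rater_swap_and_agrees_with_sklearn():
    rng = np.random.default_rng(1)
    for _ in range(50):
        t = ConfusionTable2x2(*(int(x) for x in rng.integers(1, 40, size=4)))
        kappa, _, _ = cohens_kappa(t)
        kappa_t, _, _ = cohens_kappa(t.transpose())
        assert kappa == pytest.approx(kappa_t)
        r1 = [1] * (t.a + t.b) + [0] * (t.c + t.d)
        r2 = [1] * t.a + [0] * t.b + [1] * t.c + [0] * t.d
        assert kappa == pytest.approx(cohen_kappa_score(r1, r2))


# --- McNemar --------------------------------------------------------------------

def test_mcnemar_uncorrected_on_study_discordance():
    stat, p = mcnemar_test(STUDY_TABLE, McNemarVariant.UNCORRECTED)
    assert stat == pytest.approx(1.0)
    assert p == pytest.approx(0.3173, abs=1e-4)  # prints as P=.32


def test_mcnemar_symmetric_discordance_gives_p_one():
    stat, p = mcnemar_test(ConfusionTable2x2(10, 5, 5, 10),
                           McNemarVariant.UNCORRECTED)
    assert stat == 0.0 and p == pytest.approx(1.0)


def test_mcnemar_no_discordance_convention_p_one():
    for v in McNemarVariant:
        stat, p = mcnemar_test(ConfusionTable2x2(8, 0, 0, 12), v)
        assert stat is None and p == 1.0


def test_mcnemar_exact_single_discordant_pair_is_one():
    _, p = mcnemar_test(ConfusionTable2x2(27, 0, 1, 321),
                        McNemarVariant.EXACT_BINOMIAL)
    assert p == pytest.approx(1.0)


def test_continuity_correction_floors_at_zero():
    stat, p = mcnemar_test(ConfusionTable2x2(0, 1, 0, 0),
                           McNemarVariant.CONTINUITY_CORRECTED)
    assert stat == 0.0 and p == pytest.approx(1.0)


def test_uncorrected_p_is_chi2_survival_for_all_small_tables():
    for b in range(0, 13):
        for c in range(0, 13 - b):
            if b + c == 0:
                continue
            t = ConfusionTable2x2(3, b, c, 5)
            stat, p = mcnemar_test(t, McNemarVariant.UNCORRECTED)
            assert stat == pytest.approx((b - c) ** 2 / (b + c))
            assert p == pytest.approx(float(sps.chi2.sf(stat, 1)))


def test_exact_p_matches_explicit_binomial_enumeration_up_to_bc_12():
    for b in range(0, 13):
        for c in range(0, 13 - b):
            m = b + c
            if m == 0:
                continue
            _, p = mcnemar_test(ConfusionTable2x2(1, b, c, 1),
                                McNemarVariant.EXACT_BINOMIAL)
            # oracle: enumerate the Binomial(m, 1/2) pmf; two-sided =
            # sum of outcomes no more probable than the observed b
            pmf = [math.comb(m, k) * 0.5**m for k in range(m + 1)]
            expected = sum(q for q in pmf if q <= pmf[b] + 1e-12)
            assert p == pytest.approx(min(expected, 1.0), abs=1e-10)


@pytest.mark.parametrize(
    "cells", [(27, 0, 1, 321), (3, 7, 2, 9), (0, 4, 4, 0), (5, 1, 6, 2)]
)
def test_mcnemar_agrees_with_statsmodels(cells):
    t = ConfusionTable2x2(*cells)
    arr = [[t.a, t.b], [t.c, t.d]]
    stat, p = mcnemar_test(t, McNemarVariant.UNCORRECTED)
    ref = sm_mcnemar(arr, exact=False, correction=False)
    assert stat == pytest.approx(ref.statistic) and p == pytest.approx(ref.pvalue)
    if abs(t.b - t.c) >= 1:  # statsmodels does not floor the corrected statistic
        stat, p = mcnemar_test(t, McNemarVariant.CONTINUITY_CORRECTED)
        ref = sm_mcnemar(arr, exact=False, correction=True)
        assert stat == pytest.approx(ref.statistic) and p == pytest.approx(ref.pvalue)
    _, p = mcnemar_test(t, McNemarVariant.EXACT_BINOMIAL)
    ref = sm_mcnemar(arr, exact=True)
    assert p == pytest.approx(float(ref.pvalue))


# --- capture accuracy -------------------------------------------------------------

@pytest.mark.parametrize(
    "cells, expected",
    [((27, 0, 1, 321), 27 / 28), ((9, 0, 0, 100), 1.0), ((1, 0, 1, 0), 0.5)],
)
def test_capture_accuracy_is_positives_only_fraction(cells, expected):
    assert capture_accuracy(ConfusionTable2x2(*cells)) == pytest.approx(expected)


def test_capture_accuracy_without_positives_is_explicit_error():
    with pytest.raises(UndefinedStatisticError):
        capture_accuracy(ConfusionTable2x2(0, 3, 0, 7))


def test_compute_agreement_panel_is_consistent():
    cls, labels = [], []
    spec = [(4, True, True), (0, True, False), (1, False, True), (6, False, False)]
    for i, (n, comp, chart) in enumerate(spec):
        c = [OrderClassification(f"O{100*i+j}", "A",
                                 f"A{100*i+j}" if comp else None, comp)
             for j in range(n)]
        l = [GoldStandardLabel(f"O{100*i+j}", chart) for j in range(n)]
        cls += c
        labels += l
    stats = compute_agreement(cls, labels)
    assert (stats.table.a, stats.table.c) == (4, 1)
    assert stats.observed_agreement == pytest.approx(10 / 11)
    assert stats.capture_accuracy == pytest.approx(4 / 5)
    assert stats.kappa_ci95[0] <= stats.kappa <= stats.kappa_ci95[1]
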