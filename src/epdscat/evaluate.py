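"""Screening classification, predictive values, reliability, and the
false-negative-rate parity fairness audit.

Clinical cutoffs follow routine postpartum practice for the EPDS: a
total of 8-12 indicates moderate risk, 13 or more (or any endorsement of
the suicidal-ideation item) high risk; moderate or high is a positive
screen triggering referral.  The adaptive test's classification uses the
model-implied expected total on the same scale, with the same
suicidal-ideation override applied to the patient's *recorded* answer,
whether or not the adaptive test happened to administer that item.

The fairness audit asks whether the probability that the short form
misses a full-length positive (the false negative rate, FN/(FN+TP))
depends on demographic group: a Pearson chi-square test of homogeneity
on the groups x {FN, TP} table, plus per-group FNR ratios against a
named reference group (FNR parity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "Classification",
    "ConfusionMetrics",
    "FairnessReport",
    "classify_full_test",
    "classify_cat_result",
    "diagnostic_metrics",
    "fnr_parity",
    "cronbach_alpha",
    "score_agreement",
]

MODERATE_CUTOFF = 8
HIGH_CUTOFF = 13


@dataclass(frozen=True)
class Classification:
    tier: str  # "low" | "moderate" | "high"

    @property
    def positive(self) -> bool:
        return self.tier != "low"


def classify_full_test(
    total: int,
    si_response: int,
    moderate_cutoff: int = MODERATE_CUTOFF,
    high_cutoff: int = HIGH_CUTOFF,
) -> Classification:
    """Three-tier classification of an observed full-length total.

    High if total >= 13 or the suicidal-ideation item is endorsed
    (recorded response > 0); moderate if 8 <= total < 13; low otherwise.
    """
    if not 0 <= total <= 30:
        raise ValueError(f"total {total} outside 0..30")
    if not 0 <= si_response <= 3:
        raise ValueError(f"SI response {si_response} outside 0..3")
    if total >= high_cutoff or si_response > 0:
        return Classification("high")
    if total >= moderate_cutoff:
        return Classification("moderate")
    return Classification("low")


def classify_cat_result(
    expected_total: float,
    si_response: int,
    moderate_cutoff: float = MODERATE_CUTOFF,
) -> Classification:
    """Binary screen from the adaptive test's expected total.

    Positive iff expected total >= 8 or the recorded suicidal-ideation
    answer is nonzero; reported as moderate/low tiers for interface
    symmetry (the adaptive screen is used as a binary flag).
    """
    if not 0 <= expected_total <= 30:
        raise ValueError(f"expected total {expected_total} outside [0, 30]")
    if expected_total >= moderate_cutoff or si_response > 0:
        return Classification("moderate")
    return Classification("low")


def _wilson(count: int, nobs: int) -> tuple[float, float] | None:
    if nobs == 0:
        return None
    lo, hi = proportion_confint(count, nobs, alpha=0.05, method="wilson")
    return float(lo), float(hi)


@dataclass
class ConfusionMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    npv: float | None
    ppv: float | None
    fnr: float | None
    sensitivity: float | None
    specificity: float | None
    positive_rate: float
    npv_ci: tuple[float, float] | None = None
    ppv_ci: tuple[float, float] | None = None
    fnr_ci: tuple[float, float] | None = None

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def diagnostic_metrics(truth, predicted) -> ConfusionMetrics:
    """Confusion counts and predictive values of the screen vs the full test.

    ``truth`` and ``predicted`` are boolean (positive) vectors of equal
    length.  Zero-denominator metrics are reported as None rather than
    NaN-propagated.  Wilson 95% intervals accompany NPV, PPV and FNR.
    """
    t = np.asarray(truth, dtype=bool)
    p = np.asarray(predicted, dtype=bool)
    if t.shape != p.shape:
        raise ValueError("truth and predicted must be paired, equal-length vectors")
    tp = int(np.sum(t & p))
    fp = int(np.sum(~t & p))
    tn = int(np.sum(~t & ~p))
    fn = int(np.sum(t & ~p))

    def ratio(num, den):
        return num / den if den else None

    return ConfusionMetrics(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        npv=ratio(tn, tn + fn),
        ppv=ratio(tp, tp + fp),
        fnr=ratio(fn, fn + tp),
        sensitivity=ratio(tp, tp + fn),
        specificity=ratio(tn, tn + fp),
        positive_rate=float(p.mean()) if p.size else 0.0,
        npv_ci=_wilson(tn, tn + fn),
        ppv_ci=_wilson(tp, tp + fp),
        fnr_ci=_wilson(fn, fn + tp),
    )


@dataclass
class FairnessReport:
    groups: list[str]
    fn: dict[str, int]
    tp: dict[str, int]
    fnr: dict[str, float]
    overall_fnr: float
    overall_fnr_ci: tuple[float, float] | None
    chi2: float
    df: int
    p_value: float
    reference_group: str
    parity_ratio: dict[str, float | None]
    dropped_groups: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        return d

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.groups,
                "FN": [self.fn[g] for g in self.groups],
                "TP": [self.tp[g] for g in self.groups],
                "FNR": [self.fnr[g] for g in self.groups],
                "parity_ratio": [self.parity_ratio[g] for g in self.groups],
            }
        )


def fnr_parity(truth, predicted, groups, reference_group: str) -> FairnessReport:
    """False-negative-rate homogeneity test and parity ratios across groups.

    Restricted to full-test positives, counts FN (screen negative) and TP
    per group, runs a Pearson chi-square test of homogeneity (no
    continuity correction) on the groups x {FN, TP} table, and reports
    each group's FNR relative to ``reference_group``.  Groups with no
    full-test positives are dropped (df shrinks accordingly).
    """
    t = np.asarray(truth, dtype=bool)
    p = np.asarray(predicted, dtype=bool)
    g = np.asarray(groups, dtype=object)
    if not (t.shape == p.shape == g.shape):
        raise ValueError("truth, predicted and groups must be equal-length")
    all_groups = list(pd.unique(g))
    if reference_group not in all_groups:
        raise ValueError(f"reference group {reference_group!r} absent from data")

    fn_counts, tp_counts, kept, dropped = {}, {}, [], []
    for grp in all_groups:
        mask = (g == grp) & t
        fn = int(np.sum(mask & ~p))
        tp = int(np.sum(mask & p))
        if fn + tp == 0:
            dropped.append(str(grp))
            warnings.warn(
                f"group {grp!r} has no full-test positives; dropped from the table",
                stacklevel=2,
            )
            continue
        kept.append(str(grp))
        fn_counts[str(grp)] = fn
        tp_counts[str(grp)] = tp
    if len(kept) < 2:
        raise ValueError("need at least two groups with full-test positives")
    if reference_group not in kept:
        raise ValueError(f"reference group {reference_group!r} has no positives")

    table = np.array([[fn_counts[grp], tp_counts[grp]] for grp in kept])
    expected = stats.contingency.expected_freq(table)
    if (expected < 5).any():
        warnings.warn(
            "expected counts below 5 in the FNR table; consider an exact test",
            stacklevel=2,
        )
    if np.any(table.sum(axis=0) == 0):
        chi2, pval, df = 0.0, 1.0, len(kept) - 1
    else:
        chi2, pval, df, _ = stats.chi2_contingency(table, correction=False)
    fnr = {grp: fn_counts[grp] / (fn_counts[grp] + tp_counts[grp]) for grp in kept}
    ref_fnr = fnr[reference_group]
    parity = {
        grp: (fnr[grp] / ref_fnr if ref_fnr > 0 else None) for grp in kept
    }
    total_fn = sum(fn_counts.values())
    total_pos = total_fn + sum(tp_counts.values())
    return FairnessReport(
        groups=kept,
        fn=fn_counts,
        tp=tp_counts,
        fnr=fnr,
        overall_fnr=total_fn / total_pos,
        overall_fnr_ci=_wilson(total_fn, total_pos),
        chi2=float(chi2),
        df=int(df),
        p_value=float(pval),
        reference_group=reference_group,
        parity_ratio=parity,
        dropped_groups=dropped,
    )


def cronbach_alpha(items) -> tuple[float, tuple[float, float]]:
    """Cronbach's alpha with the Feldt F-distribution 95% interval.

    alpha = k/(k-1) (1 - sum item variances / total variance), item
    variances taken with ddof=1.
    """
    X = np.asarray(items, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a respondents x items table with >= 2 items")
    n, k = X.shape
    if n < 3:
        raise ValueError("need at least 3 respondents")
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero total-score variance; alpha undefined")
    alpha = k / (k - 1) * (1 - X.var(axis=0, ddof=1).sum() / total_var)
    df1, df2 = n - 1, (n - 1) * (k - 1)
    lo = 1 - (1 - alpha) * stats.f.ppf(0.975, df1, df2)
    hi = 1 - (1 - alpha) * stats.f.ppf(0.025, df1, df2)
    return float(alpha), (float(lo), float(hi))


def score_agreement(predicted_totals, observed_totals) -> tuple[float, tuple[float, float], float]:
    """Pearson correlation (with Fisher-z 95% CI and p-value) between the
    adaptive test's predicted totals and the observed full-length totals."""
    x = np.asarray(predicted_totals, dtype=float)
    y = np.asarray(observed_totals, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need paired vectors of length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for a constant vector")
    res = stats.pearsonr(x, y)
    ci = res.confidence_interval()
    return float(res.statistic), (float(ci.low), float(ci.high)), float(res.pvalue)
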