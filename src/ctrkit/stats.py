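"""Agreement, correlation, and classification statistics for method comparison.

Conventions (matching the validation-study definitions):

* Bland-Altman in percent mode works on d_i = 100*(a_i - b_i)/((a_i + b_i)/2);
  bias = mean(d), limits of agreement = bias +/- 1.96*SD(d) with the n-1 SD.
* The coefficient of variation (CV) is the SD of the raw (absolute-unit)
  differences divided by the grand mean of all 2n measurements, times 100.
* R^2 categories: poor < 0.5, moderate 0.5-0.75, good 0.75-0.9,
  excellent > 0.9 (boundaries fall in the lower band as written).
* Classification calls positive iff value > cutoff; AUC is the rank
  (Mann-Whitney) statistic with ties counted 1/2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


# ---------------------------------------------------------------------------
# agreement


@dataclass(frozen=True)
class AgreementResult:
    bias: float
    loa_lower: float
    loa_upper: float
    sd_diff: float
    cv: float
    n_pairs: int
    units_mode: str  # "percent_of_pair_mean" | "absolute"

    def __post_init__(self) -> None:
        if not self.loa_lower <= self.bias <= self.loa_upper:
            raise ValueError("limits of agreement must bracket the bias")


def _check_pairs(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired inputs must be 1-D and equal length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("measurements must be positive")


def cv_percent(a: Sequence[float], b: Sequence[float]) -> float:
    """SD of paired differences over the grand mean of all 2n values, as %."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    _check_pairs(a, b)
    sd = float(np.std(a - b, ddof=1))
    grand_mean = float(np.concatenate([a, b]).mean())
    return 100.0 * sd / grand_mean


def bland_altman(
    a: Sequence[float],
    b: Sequence[float],
    units_mode: str = "percent_of_pair_mean",
) -> AgreementResult:
    """Bland-Altman agreement between two paired measurement series."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    _check_pairs(a, b)
    if units_mode == "percent_of_pair_mean":
        d = 100.0 * (a - b) / ((a + b) / 2.0)
    elif units_mode == "absolute":
        d = a - b
    else:
        raise ValueError(f"unknown units_mode {units_mode!r}")
    bias = float(d.mean())
    sd = float(np.std(d, ddof=1))
    return AgreementResult(
        bias=bias,
        loa_lower=bias - 1.96 * sd,
        loa_upper=bias + 1.96 * sd,
        sd_diff=sd,
        cv=cv_percent(a, b),
        n_pairs=int(a.size),
        units_mode=units_mode,
    )


# ---------------------------------------------------------------------------
# correlation


@dataclass(frozen=True)
class CorrelationResult:
    slope: float
    intercept: float
    r2: float
    category: str


def r2_category(r2: float) -> str:
    if r2 < 0.5:
        return "poor"
    if r2 <= 0.75:
        return "moderate"
    if r2 <= 0.9:
        return "good"
    return "excellent"


def linear_fit_r2(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Least-squares line and coefficient of determination with its category."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need equal-length 1-D inputs with n >= 3")
    if np.var(x) == 0:
        raise ValueError("degenerate input: zero variance in x")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return CorrelationResult(float(slope), float(intercept), r2, r2_category(r2))


# ---------------------------------------------------------------------------
# paired t-test


@dataclass(frozen=True)
class PairedTResult:
    t: float
    p: float
    degenerate: bool = False  # zero-variance differences


def paired_t_test(a: Sequence[float], b: Sequence[float]) -> PairedTResult:
    """Two-sided paired Student's t-test on a - b.

    Zero-variance differences are reported explicitly: t = 0, p = 1 when the
    common difference is zero; infinite t, p = 0 otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need equal-length inputs with n >= 2")
    d = a - b
    if np.std(d, ddof=1) == 0.0:
        if d.mean() == 0.0:
            return PairedTResult(0.0, 1.0, degenerate=True)
        return PairedTResult(float(np.inf) * np.sign(d.mean()), 0.0, degenerate=True)
    res = sps.ttest_rel(a, b)
    return PairedTResult(float(res.statistic), float(res.pvalue))


# ---------------------------------------------------------------------------
# classification


@dataclass(frozen=True)
class ClassificationResult:
    cutoff: float
    sensitivity: float  # percent
    specificity: float  # percent
    accuracy: float  # percent
    f1: float  # fraction
    auc: float  # fraction
    cutoff_kind: str = "standard"


def _validate_labels(values: np.ndarray, labels: np.ndarray) -> None:
    if values.shape != labels.shape or values.ndim != 1:
        raise ValueError("values and labels must be 1-D and equal length")
    classes = np.unique(labels)
    if not np.isin(classes, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    if classes.size < 2:
        raise ValueError("both classes must be present")


def rank_auc(values: Sequence[float], labels: Sequence[int]) -> float:
    """AUC as the Mann-Whitney rank statistic; ties count one half."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _validate_labels(values, labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    ranks = sps.rankdata(values)  # average ranks handle ties as 1/2
    rank_sum = float(ranks[labels == 1].sum())
    return (rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def classification_eval(
    values: Sequence[float],
    labels: Sequence[int],
    cutoff: float,
    cutoff_kind: str = "standard",
) -> ClassificationResult:
    """Confusion-matrix metrics at a cutoff (positive iff value > cutoff)."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _validate_labels(values, labels)
    pred = values > cutoff
    pos = labels == 1
    tp = int(np.sum(pred & pos))
    tn = int(np.sum(~pred & ~pos))
    fp = int(np.sum(pred & ~pos))
    fn = int(np.sum(~pred & pos))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    acc = (tp + tn) / labels.size
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    return ClassificationResult(
        cutoff=float(cutoff),
        sensitivity=100.0 * sens,
        specificity=100.0 * spec,
        accuracy=100.0 * acc,
        f1=float(f1),
        auc=rank_auc(values, labels),
        cutoff_kind=cutoff_kind,
    )


def _candidate_cutoffs(values: np.ndarray) -> np.ndarray:
    """Midpoints between adjacent sorted unique values, plus +/-inf sentinels."""
    uniq = np.unique(values)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    return np.concatenate([[-np.inf], mids, [np.inf]])


def find_cutoffs(
    values: Sequence[float], labels: Sequence[int], standard: float = 0.5
) -> dict[str, ClassificationResult]:
    """Evaluate the standard, Youden-optimum, and max-sensitivity cutoffs.

    Optimum maximizes J = sensitivity + specificity - 1 over the candidate
    grid, ties broken toward the lowest cutoff (favoring sensitivity);
    max-sensitivity is the largest candidate at which sensitivity is 100%.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _validate_labels(values, labels)
    candidates = _candidate_cutoffs(values)

    best_j, best_cut = -np.inf, None
    max_sens_cut = -np.inf
    for cut in candidates:
        res = classification_eval(values, labels, cut)
        j = res.sensitivity / 100.0 + res.specificity / 100.0 - 1.0
        if j > best_j + 1e-12:
            best_j, best_cut = j, cut
        if res.sensitivity == 100.0 and cut > max_sens_cut:
            max_sens_cut = cut
    return {
        "standard": classification_eval(values, labels, standard, "standard"),
        "optimum": classification_eval(values, labels, best_cut, "optimum"),
        "max_sensitivity": classification_eval(
            values, labels, max_sens_cut, "max_sensitivity"
        ),
    }


# ---------------------------------------------------------------------------
# comparison driver


@dataclass(frozen=True)
class ComparisonRow:
    label: str
    subset: str
    agreement_pct: AgreementResult
    agreement_abs: AgreementResult
    correlation: CorrelationResult
    t_test: PairedTResult
    n_pairs: int
    n_excluded: int

    def to_dict(self) -> dict:
        return {
            "comparison": self.label,
            "subset": self.subset,
            "n_pairs": self.n_pairs,
            "n_excluded": self.n_excluded,
            "bias_pct": self.agreement_pct.bias,
            "loa_lower_pct": self.agreement_pct.loa_lower,
            "loa_upper_pct": self.agreement_pct.loa_upper,
            "cv_pct": self.agreement_pct.cv,
            "bias_abs": self.agreement_abs.bias,
            "sd_abs": self.agreement_abs.sd_diff,
            "r2": self.correlation.r2,
            "r2_category": self.correlation.category,
            "slope": self.correlation.slope,
            "intercept": self.correlation.intercept,
            "t": self.t_test.t,
            "p": self.t_test.p,
        }


def compare_series(
    a: pd.Series, b: pd.Series, label: str, subset: str = "all"
) -> ComparisonRow:
    """Consolidated agreement + correlation + t-test on two per-case series.

    Series are aligned on case id; cases missing from either side are
    excluded and counted.
    """
    joined = pd.concat({"a": a, "b": b}, axis=1)
    n_total = len(joined)
    joined = joined.dropna()
    if joined.empty:
        raise ValueError(f"no overlapping cases for comparison {label!r}")
    av = joined["a"].to_numpy()
    bv = joined["b"].to_numpy()
    return ComparisonRow(
        label=label,
        subset=subset,
        agreement_pct=bland_altman(av, bv, "percent_of_pair_mean"),
        agreement_abs=bland_altman(av, bv, "absolute"),
        correlation=linear_fit_r2(av, bv),
        t_test=paired_t_test(av, bv),
        n_pairs=len(joined),
        n_excluded=n_total - len(joined),
    )
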