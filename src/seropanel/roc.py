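"""Empirical ROC analysis and 2x2 diagnostic statistics, from first
principles.

The empirical ROC is built over the unique observed values (ties grouped),
its area computed by the trapezoidal rule; that area is identically the
Mann-Whitney statistic U/(n1*n2) with ties counted one half.  AUC standard
errors, confidence intervals and paired marker comparisons use DeLong's
structural-component method.  A 2x2 table yields the full diagnostic metric
row: sensitivity, specificity, accuracy, predictive values, likelihood
ratios, diagnostic odds ratio and relative risk.

Positivity convention throughout: a subject is positive when its value is
*strictly greater* than the cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class MarkerCutoff:
    """A named decision threshold; positive means value > cutoff.

    Concentration cutoffs (ng/mL) are positive by nature and validated
    where they enter (panel rules, panel files); the type itself also
    serves Youden-optimal thresholds on arbitrary score scales.
    """

    marker: str
    cutoff: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.cutoff):
            raise ValueError(f"cutoff must be finite, got {self.cutoff}")


@dataclass
class RocCurve:
    """Empirical ROC curve: thresholds descending from +inf to -inf, with
    (FPR, TPR) per threshold; starts at (0,0), ends at (1,1)."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_cases: int
    n_controls: int

    def youden(self) -> np.ndarray:
        return self.tpr - self.fpr


def _validate_groups(cases: Sequence[float], controls: Sequence[float],
                     min_n: int = 1) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(cases, dtype=float)
    y = np.asarray(controls, dtype=float)
    if x.ndim != 1 or y.ndim != 1:
        raise ValueError("case/control values must be 1-D")
    if len(x) < min_n or len(y) < min_n:
        raise ValueError(f"need at least {min_n} case(s) and {min_n} control(s)")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values present; mask them before ROC analysis")
    return x, y


def empirical_roc(cases: Sequence[float], controls: Sequence[float]) -> RocCurve:
    """ROC curve for "higher value = more disease-like" scores."""
    x, y = _validate_groups(cases, controls)
    values = np.unique(np.concatenate([x, y]))[::-1]  # descending
    thresholds = np.concatenate([[np.inf], values, [-np.inf]])
    tpr = np.array([(x > t).mean() for t in thresholds])
    fpr = np.array([(y > t).mean() for t in thresholds])
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds, fpr, tpr, auc, len(x), len(y))


def mann_whitney_auc(cases: Sequence[float], controls: Sequence[float]) -> float:
    """AUC as the tie-adjusted pairwise probability, computed with
    midranks in O((m+n) log(m+n)); exactly equals the trapezoidal area."""
    x, y = _validate_groups(cases, controls)
    m, n = len(x), len(y)
    ranks = stats.rankdata(np.concatenate([x, y]))
    u = ranks[:m].sum() - m * (m + 1) / 2.0
    return float(u / (m * n))


# ---------------------------------------------------------------------------
# DeLong method
# ---------------------------------------------------------------------------

def _delong_components(x: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus the structural components V10 (per case) and V01 (per
    control) of DeLong's estimator, via midranks."""
    m, n = len(x), len(y)
    all_ranks = stats.rankdata(np.concatenate([x, y]))
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    v10 = (all_ranks[:m] - rx) / n
    v01 = 1.0 - (all_ranks[m:] - ry) / m
    auc = float(v10.mean())
    return auc, v10, v01


@dataclass(frozen=True)
class DelongResult:
    auc: float
    se: float
    ci: tuple[float, float]
    p_vs_half: float
    boundary: bool = False  # degenerate variance at AUC 0 or 1


def auc_ci_delong(cases: Sequence[float], controls: Sequence[float],
                  level: float = 0.95) -> DelongResult:
    """DeLong variance, Wald CI (truncated to [0,1]) and two-sided test of
    AUC = 0.5."""
    x, y = _validate_groups(cases, controls, min_n=2)
    auc, v10, v01 = _delong_components(x, y)
    var = v10.var(ddof=1) / len(x) + v01.var(ddof=1) / len(y)
    se = math.sqrt(max(var, 0.0))
    z = stats.norm.ppf(0.5 + level / 2.0)
    if se == 0.0:
        return DelongResult(auc, 0.0, (auc, auc), math.nan, boundary=True)
    lo = max(0.0, auc - z * se)
    hi = min(1.0, auc + z * se)
    p = 2.0 * stats.norm.sf(abs(auc - 0.5) / se)
    return DelongResult(auc, se, (lo, hi), float(min(p, 1.0)))


@dataclass(frozen=True)
class PairedAucComparison:
    auc_a: float
    auc_b: float
    delta: float
    se: float
    p: float


def compare_auc_paired(values_a: Sequence[float], values_b: Sequence[float],
                       labels: Sequence[int]) -> PairedAucComparison:
    """Paired DeLong comparison of two markers measured on the same
    subjects.  ``labels`` is 1 for cases, 0 for controls; ``delta`` is
    AUC(A) - AUC(B)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    lab = np.asarray(labels)
    if not (len(a) == len(b) == len(lab)):
        raise ValueError("markers must be measured on the same subjects (equal lengths)")
    if set(np.unique(lab)) - {0, 1}:
        raise ValueError("labels must be 0/1")
    case = lab == 1
    if case.sum() < 2 or (~case).sum() < 2:
        raise ValueError("need at least 2 cases and 2 controls")

    auc_a, v10_a, v01_a = _delong_components(a[case], a[~case])
    auc_b, v10_b, v01_b = _delong_components(b[case], b[~case])
    m, n = int(case.sum()), int((~case).sum())
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    delta = auc_a - auc_b
    se = math.sqrt(max(var, 0.0))
    if delta == 0.0:
        return PairedAucComparison(auc_a, auc_b, 0.0, se, 1.0)
    if se == 0.0:
        return PairedAucComparison(auc_a, auc_b, delta, 0.0, 0.0)
    p = 2.0 * stats.norm.sf(abs(delta) / se)
    return PairedAucComparison(auc_a, auc_b, delta, se, float(min(p, 1.0)))


def bootstrap_auc_se(cases: Sequence[float], controls: Sequence[float],
                     n_boot: int = 2000, seed: int = 0) -> float:
    """Stratified-bootstrap AUC standard error (cross-check for DeLong)."""
    x, y = _validate_groups(cases, controls, min_n=2)
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    for i in range(n_boot):
        xs = rng.choice(x, size=len(x), replace=True)
        ys = rng.choice(y, size=len(y), replace=True)
        aucs[i] = mann_whitney_auc(xs, ys)
    return float(aucs.std(ddof=1))


# ---------------------------------------------------------------------------
# cutoffs and 2x2 tables
# ---------------------------------------------------------------------------

def optimal_cutoff(curve: RocCurve, marker: str = "marker") -> tuple[MarkerCutoff, float]:
    """Threshold maximising Youden's J = sensitivity + specificity - 1.

    Ties are broken toward higher specificity (lower FPR).  Returns the
    cutoff and the achieved J; J = 0 everywhere means the marker is
    uninformative at every threshold.
    """
    j = curve.youden()
    finite = np.isfinite(curve.thresholds)
    order = sorted(
        np.flatnonzero(finite),
        key=lambda i: (-j[i], curve.fpr[i], -curve.thresholds[i]),
    )
    if not order:
        raise ValueError("degenerate ROC curve with no finite thresholds")
    best = order[0]
    return MarkerCutoff(marker, float(curve.thresholds[best])), float(j[best])


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def n_cases(self) -> int:
        return self.tp + self.fn

    @property
    def n_controls(self) -> int:
        return self.fp + self.tn

    @property
    def total(self) -> int:
        return self.n_cases + self.n_controls


def confusion_at_cutoff(values: Sequence[float], labels: Sequence[int],
                        cutoff: MarkerCutoff | float) -> ConfusionCounts:
    """2x2 table at a cutoff; positive means value strictly above it."""
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    if len(v) != len(lab):
        raise ValueError("values and labels differ in length")
    if np.isnan(v).any():
        raise ValueError("missing values present; mask them before tabulation")
    if set(np.unique(lab)) - {0, 1}:
        raise ValueError("labels must be 0/1")
    c = cutoff.cutoff if isinstance(cutoff, MarkerCutoff) else float(cutoff)
    pos = v > c
    case = lab == 1
    return ConfusionCounts(
        tp=int((pos & case).sum()),
        fn=int((~pos & case).sum()),
        fp=int((pos & ~case).sum()),
        tn=int((~pos & ~case).sum()),
    )


def reconstruct_confusion(sens_pct: float, spec_pct: float,
                          n_cases: int, n_controls: int) -> ConfusionCounts:
    """Back-calculate the integer 2x2 table behind a published
    sensitivity/specificity pair and the group sizes."""
    tp = round(sens_pct / 100.0 * n_cases)
    tn = round(spec_pct / 100.0 * n_controls)
    return ConfusionCounts(tp=tp, fn=n_cases - tp, fp=n_controls - tn, tn=tn)


@dataclass
class DiagnosticMetrics:
    """The full diagnostic metric row derived from a 2x2 table.

    Rates are percentages at full precision (display rounding is left to
    the caller); likelihood ratios, odds ratio and relative risk are
    dimensionless.  Division by an empty margin yields ``inf``/``nan``
    with the offending quantity listed in ``flags``.
    """

    sensitivity: float
    specificity: float
    accuracy: float
    ppv: float
    npv: float
    plr: float
    nlr: float
    odds_ratio: float
    relative_risk: float
    flags: list[str] = field(default_factory=list)

    def round2(self) -> dict[str, float]:
        return {
            k: round(getattr(self, k), 2)
            for k in ("sensitivity", "specificity", "accuracy", "ppv", "npv",
                      "plr", "nlr", "odds_ratio", "relative_risk")
        }


def _ratio(num: float, den: float, name: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(name)
        return math.inf if num > 0 else math.nan
    return num / den


def metrics_from_confusion(c: ConfusionCounts, haldane: bool = False) -> DiagnosticMetrics:
    """Sensitivity, specificity, accuracy, PPV, NPV, likelihood ratios,
    diagnostic odds ratio and relative risk from a 2x2 table.

    ``haldane`` adds 0.5 to every cell (Haldane-Anscombe) before computing
    the odds ratio and relative risk, avoiding infinities from empty cells.
    """
    if c.n_cases < 1 or c.n_controls < 1:
        raise ValueError("need at least one case and one control")
    flags: list[str] = []
    sens = c.tp / c.n_cases
    spec = c.tn / c.n_controls
    acc = (c.tp + c.tn) / c.total
    ppv = _ratio(c.tp, c.tp + c.fp, "ppv", flags)
    npv = _ratio(c.tn, c.tn + c.fn, "npv", flags)
    plr = _ratio(sens, 1.0 - spec, "plr", flags)
    nlr = _ratio(1.0 - sens, spec, "nlr", flags)
    if haldane:
        tp, fn, fp, tn = (v + 0.5 for v in (c.tp, c.fn, c.fp, c.tn))
        odds = (tp * tn) / (fp * fn)
        rr = (tp / (tp + fp)) / (fn / (fn + tn))
    else:
        odds = _ratio(c.tp * c.tn, c.fp * c.fn, "odds_ratio", flags)
        risk_pos = _ratio(c.tp, c.tp + c.fp, "rr_pos", flags)
        risk_neg = _ratio(c.fn, c.fn + c.tn, "rr_neg", flags)
        rr = _ratio(risk_pos, risk_neg, "relative_risk", flags) \
            if math.isfinite(risk_pos) and math.isfinite(risk_neg) else math.nan
    return DiagnosticMetrics(
        sensitivity=100.0 * sens,
        specificity=100.0 * spec,
        accuracy=100.0 * acc,
        ppv=100.0 * ppv if math.isfinite(ppv) else ppv,
        npv=100.0 * npv if math.isfinite(npv) else npv,
        plr=plr,
        nlr=nlr,
        odds_ratio=odds,
        relative_risk=rr,
        flags=flags,
    )
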