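"""Model/Results interface over the diagnostic machinery.

`MarkerDiagnostics` and `PanelDiagnostics` follow the familiar
model-object pattern: the model is constructed from data (directly or
``from_dataframe``), ``fit()`` performs the estimation and returns a
`DiagnosticResults` carrying the ROC curve, the DeLong AUC inference, the
operating cutoff and the full 2x2 metric row, with a ``summary()`` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import CONTROL_STAGES, HCC_STAGES, Stage
from .panel import PanelRule, combined_score_frame, panel_positive_frame
from .roc import (
    ConfusionCounts,
    DelongResult,
    DiagnosticMetrics,
    MarkerCutoff,
    RocCurve,
    auc_ci_delong,
    compare_auc_paired,
    confusion_at_cutoff,
    empirical_roc,
    metrics_from_confusion,
    optimal_cutoff,
)


def _stage_labels(stages: pd.Series, case_stages: Sequence[Stage],
                  control_stages: Sequence[Stage]) -> pd.Series:
    case_vals = {s.value for s in case_stages}
    ctrl_vals = {s.value for s in control_stages}
    overlap = case_vals & ctrl_vals
    if overlap:
        raise ValueError(f"stages in both arms: {sorted(overlap)}")
    labels = pd.Series(pd.NA, index=stages.index, dtype="object")
    labels[stages.isin(case_vals)] = 1
    labels[stages.isin(ctrl_vals)] = 0
    return labels.dropna().astype(int)


@dataclass
class DiagnosticResults:
    """Fitted diagnostic evaluation of one marker or panel."""

    name: str
    curve: RocCurve
    delong: DelongResult
    cutoff: MarkerCutoff
    youden_j: float
    confusion: ConfusionCounts
    metrics: DiagnosticMetrics
    cutoff_source: str  # "youden" | "fixed"

    @property
    def auc(self) -> float:
        return self.delong.auc

    @property
    def auc_ci(self) -> tuple[float, float]:
        return self.delong.ci

    def summary(self) -> str:
        m = self.metrics.round2()
        ci = self.delong.ci
        lines = [
            f"Diagnostic evaluation: {self.name}",
            "=" * 44,
            f"cases / controls        {self.confusion.n_cases} / {self.confusion.n_controls}",
            f"AUC (DeLong 95% CI)     {self.auc:.3f} ({ci[0]:.3f}-{ci[1]:.3f})",
            f"p vs AUC=0.5            {self._fmt_p(self.delong.p_vs_half)}",
            ("operating point         OR rule at member cutoffs"
             if self.cutoff_source == "panel"
             else f"cutoff ({self.cutoff_source})         {self.cutoff.cutoff:g} ng/mL"),
            f"sensitivity / specificity  {m['sensitivity']:.2f}% / {m['specificity']:.2f}%",
            f"accuracy                {m['accuracy']:.2f}%",
            f"PPV / NPV               {m['ppv']:.2f}% / {m['npv']:.2f}%",
            f"+LR / -LR               {m['plr']:.2f} / {m['nlr']:.2f}",
            f"odds ratio              {m['odds_ratio']:.2f}",
            f"relative risk           {m['relative_risk']:.2f}",
        ]
        if self.metrics.flags:
            lines.append(f"flags: {', '.join(self.metrics.flags)}")
        return "\n".join(lines)

    @staticmethod
    def _fmt_p(p: float) -> str:
        if math.isnan(p):
            return "n/a (degenerate variance)"
        return "<0.0001" if p < 1e-4 else f"{p:.4f}"

    def metric_row(self) -> dict[str, float | str]:
        row: dict[str, float | str] = {"name": self.name, "auc": self.auc,
                                       "auc_ci_low": self.delong.ci[0],
                                       "auc_ci_high": self.delong.ci[1],
                                       "cutoff": self.cutoff.cutoff}
        row.update(self.metrics.round2())
        return row


class MarkerDiagnostics:
    """Single-marker diagnostic model: concentrations vs case/control.

    Parameters
    ----------
    values, labels : aligned arrays; label 1 = case, 0 = control.
    name : marker name used in reports.
    """

    def __init__(self, values: Sequence[float], labels: Sequence[int],
                 name: str = "marker") -> None:
        v = np.asarray(values, dtype=float)
        lab = np.asarray(labels)
        keep = ~np.isnan(v)
        self.values = v[keep]
        self.labels = lab[keep].astype(int)
        if set(np.unique(self.labels)) - {0, 1}:
            raise ValueError("labels must be 0/1")
        self.name = name

    @classmethod
    def from_dataframe(cls, cohort: pd.DataFrame, marker: str,
                       case_stages: Sequence[Stage] = HCC_STAGES,
                       control_stages: Sequence[Stage] = CONTROL_STAGES,
                       ) -> "MarkerDiagnostics":
        """Build from a serum cohort table (``stage`` column plus one
        ng/mL column per marker)."""
        labels = _stage_labels(cohort["stage"], case_stages, control_stages)
        sub = cohort.loc[labels.index]
        return cls(sub[marker].to_numpy(dtype=float), labels.to_numpy(), name=marker)

    @property
    def cases(self) -> np.ndarray:
        return self.values[self.labels == 1]

    @property
    def controls(self) -> np.ndarray:
        return self.values[self.labels == 0]

    def fit(self, cutoff: float | None = None) -> DiagnosticResults:
        """Estimate the ROC/AUC and the metric row.

        With ``cutoff=None`` the operating point is the Youden-optimal
        threshold; otherwise the supplied clinical cutoff is used.
        """
        curve = empirical_roc(self.cases, self.controls)
        delong = auc_ci_delong(self.cases, self.controls)
        if cutoff is None:
            mc, j = optimal_cutoff(curve, marker=self.name)
            source = "youden"
        else:
            mc = MarkerCutoff(self.name, float(cutoff))
            conf_tmp = confusion_at_cutoff(self.values, self.labels, mc)
            j = conf_tmp.tp / conf_tmp.n_cases + conf_tmp.tn / conf_tmp.n_controls - 1.0
            source = "fixed"
        confusion = confusion_at_cutoff(self.values, self.labels, mc)
        metrics = metrics_from_confusion(confusion)
        return DiagnosticResults(self.name, curve, delong, mc, float(j),
                                 confusion, metrics, source)

    def compare(self, other: "MarkerDiagnostics"):
        """Paired DeLong comparison with another marker measured on the
        same subjects (same label vector)."""
        if len(self.values) != len(other.values) or not np.array_equal(self.labels, other.labels):
            raise ValueError("markers must be measured on the same subjects")
        return compare_auc_paired(self.values, other.values, self.labels)


class PanelDiagnostics:
    """Panel diagnostic model: OR-rule positivity at the member cutoffs,
    with the continuous max-log-ratio score used for the combination ROC."""

    def __init__(self, cohort: pd.DataFrame, rule: PanelRule,
                 case_stages: Sequence[Stage] = HCC_STAGES,
                 control_stages: Sequence[Stage] = CONTROL_STAGES) -> None:
        labels = _stage_labels(cohort["stage"], case_stages, control_stages)
        sub = cohort.loc[labels.index].dropna(subset=list(rule.marker_names))
        self.cohort = sub
        self.labels = labels.loc[sub.index]
        self.rule = rule

    def fit(self) -> DiagnosticResults:
        scores = combined_score_frame(self.cohort, self.rule)
        labels = self.labels.to_numpy()
        curve = empirical_roc(scores[self.labels == 1], scores[self.labels == 0])
        delong = auc_ci_delong(scores[self.labels == 1], scores[self.labels == 0])
        # score > 0  <=>  OR-panel positive at the member cutoffs
        confusion = confusion_at_cutoff(scores.to_numpy(), labels, 0.0)
        metrics = metrics_from_confusion(confusion)
        j = confusion.tp / confusion.n_cases + confusion.tn / confusion.n_controls - 1.0
        cutoff = MarkerCutoff(self.rule.name, 1.0)  # placeholder; panels operate at member cutoffs
        return DiagnosticResults(self.rule.name, curve, delong, cutoff, float(j),
                                 confusion, metrics, "panel")
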