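"""Multi-marker panel evaluation.

A panel is a set of (marker, cutoff) pairs combined by the OR rule: a
subject is panel-positive when *any* member marker exceeds its cutoff.
This is the combination logic implied by positive-rate panel analyses —
it can only raise sensitivity relative to each member, at the cost of
specificity.  An AND rule is available for specificity-oriented use.

For combination ROC curves a continuous panel score is needed; since no
published scoring rule exists for the OR panel, the score used here is

    score = max over members of log(value / cutoff)

whose sign agrees with OR positivity and which reduces to a strictly
increasing transform of the raw value for single-member panels (so the
combination AUC then equals the single-marker AUC exactly).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CONTROL_STAGES, HCC_STAGES, Stage
from .roc import MarkerCutoff


@dataclass(frozen=True)
class PanelRule:
    """1-5 distinct marker cutoffs combined by "or" (default) or "and"."""

    members: tuple[MarkerCutoff, ...]
    logic: str = "or"

    def __post_init__(self) -> None:
        if not 1 <= len(self.members) <= 5:
            raise ValueError("panel must have 1-5 members")
        names = [m.marker for m in self.members]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate member markers: {names}")
        if self.logic not in ("or", "and"):
            raise ValueError(f"logic must be 'or' or 'and', got {self.logic!r}")
        bad = [m.marker for m in self.members if m.cutoff <= 0]
        if bad:
            raise ValueError(f"concentration cutoffs must be positive (ng/mL): {bad}")

    @property
    def marker_names(self) -> tuple[str, ...]:
        return tuple(m.marker for m in self.members)

    @property
    def name(self) -> str:
        return "-".join(self.marker_names)


def _member_values(subject: Mapping[str, float], rule: PanelRule) -> list[tuple[float, float]]:
    pairs = []
    for m in rule.members:
        v = subject.get(m.marker)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            raise ValueError(f"subject lacks a value for panel member {m.marker!r}")
        pairs.append((float(v), m.cutoff))
    return pairs


def panel_positive(subject: Mapping[str, float], rule: PanelRule) -> bool:
    """OR rule: positive iff any member value strictly exceeds its cutoff
    (all members for an AND panel)."""
    hits = [v > c for v, c in _member_values(subject, rule)]
    return any(hits) if rule.logic == "or" else all(hits)


def combined_score(subject: Mapping[str, float], rule: PanelRule,
                   floor: float = 1e-9) -> float:
    """Continuous panel score: max (min for AND) of log(value/cutoff).

    Zero values are floored at ``floor`` ng/mL before the log.  The score
    is strictly positive iff the subject is panel-positive.
    """
    ratios = [math.log(max(v, floor) / c) for v, c in _member_values(subject, rule)]
    return max(ratios) if rule.logic == "or" else min(ratios)


def panel_positive_frame(cohort: pd.DataFrame, rule: PanelRule) -> pd.Series:
    """Vectorised positivity over a cohort table (one column per marker).
    Rows missing any member value are dropped first."""
    sub = cohort.dropna(subset=list(rule.marker_names))
    hits = pd.DataFrame({
        m.marker: sub[m.marker] > m.cutoff for m in rule.members
    })
    agg = hits.any(axis=1) if rule.logic == "or" else hits.all(axis=1)
    return agg


def combined_score_frame(cohort: pd.DataFrame, rule: PanelRule,
                         floor: float = 1e-9) -> pd.Series:
    sub = cohort.dropna(subset=list(rule.marker_names))
    logs = pd.DataFrame({
        m.marker: np.log(np.maximum(sub[m.marker].to_numpy(dtype=float), floor) / m.cutoff)
        for m in rule.members
    }, index=sub.index)
    return logs.max(axis=1) if rule.logic == "or" else logs.min(axis=1)


# ---------------------------------------------------------------------------
# rate tables and rescue analysis
# ---------------------------------------------------------------------------

def positive_rate_table(cohort: pd.DataFrame,
                        rules: Sequence[PanelRule | MarkerCutoff],
                        by: str = "stage") -> pd.DataFrame:
    """Positive rates per disease stage for each marker/panel.

    Returns one row per (group, rule) with the denominator (subjects with
    complete member measurements), positive count and percent rate; empty
    groups yield a missing rate.
    """
    rows = []
    for rule in rules:
        if isinstance(rule, MarkerCutoff):
            rule = PanelRule((rule,))
        scored = cohort.dropna(subset=list(rule.marker_names))
        pos = panel_positive_frame(scored, rule)
        for group, idx in scored.groupby(by, sort=False).groups.items():
            n = len(idx)
            npos = int(pos.loc[idx].sum())
            rows.append({
                "group": group, "rule": rule.name, "n": n, "n_positive": npos,
                "rate_pct": 100.0 * npos / n if n else math.nan,
            })
    return pd.DataFrame(rows)


@dataclass
class RescueResult:
    """Per-marker positivity within reference-negative and
    reference-positive case strata (e.g. detection among AFP-negative HCC
    patients)."""

    reference: MarkerCutoff
    n_reference_negative: int
    n_reference_positive: int
    rates_in_negative: dict[str, float]  # marker -> percent (NaN if stratum empty)
    rates_in_positive: dict[str, float]
    flags: list[str] = field(default_factory=list)


def rescue_analysis(cases: pd.DataFrame, reference: MarkerCutoff,
                    markers: Sequence[MarkerCutoff]) -> RescueResult:
    """Stratify cases by reference-marker status and tabulate each
    marker's positive rate within the two strata."""
    needed = [reference.marker] + [m.marker for m in markers]
    scored = cases.dropna(subset=needed)
    ref_pos = scored[reference.marker] > reference.cutoff
    strata = {"negative": scored[~ref_pos], "positive": scored[ref_pos]}
    flags = [f"reference-{k} stratum empty" for k, s in strata.items() if len(s) == 0]
    rates: dict[str, dict[str, float]] = {}
    for key, stratum in strata.items():
        rates[key] = {}
        for m in markers:
            if len(stratum) == 0:
                rates[key][m.marker] = math.nan
            else:
                rates[key][m.marker] = 100.0 * float((stratum[m.marker] > m.cutoff).mean())
    return RescueResult(
        reference=reference,
        n_reference_negative=int((~ref_pos).sum()),
        n_reference_positive=int(ref_pos.sum()),
        rates_in_negative=rates["negative"],
        rates_in_positive=rates["positive"],
        flags=flags,
    )


# ---------------------------------------------------------------------------
# exhaustive combination search
# ---------------------------------------------------------------------------

def search_full_coverage(cases: pd.DataFrame,
                         candidates: Sequence[MarkerCutoff],
                         k: int) -> list[PanelRule]:
    """All size-``k`` OR panels that detect *every* case (100% sensitivity).

    Enumerates every subset of the candidate markers, in lexicographic
    member-name order; cases must be measured on all candidates.
    """
    if k not in (2, 3):
        raise ValueError("panel size k must be 2 or 3")
    names = [c.marker for c in candidates]
    if len(set(names)) != len(names):
        raise ValueError("candidate markers must be distinct")
    if len(candidates) < k:
        return []
    missing_cols = [n for n in names if n not in cases.columns]
    if missing_cols:
        raise ValueError(f"cases lack columns for candidates: {missing_cols}")
    if cases[names].isna().any().any():
        raise ValueError("all cases must be measured on all candidate markers")

    pos = {c.marker: (cases[c.marker] > c.cutoff).to_numpy() for c in candidates}
    winners = []
    for combo in itertools.combinations(sorted(candidates, key=lambda c: c.marker), k):
        covered = np.zeros(len(cases), dtype=bool)
        for c in combo:
            covered |= pos[c.marker]
        if covered.all():
            winners.append(PanelRule(tuple(combo)))
    return winners
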