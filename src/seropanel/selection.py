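"""Candidate secretory-marker selection from a staged expression matrix.

The funnel mirrors the published discovery strategy for serum HCC markers:

1. keep protein-coding genes;
2. keep genes whose protein carries a signal peptide (secretome filter,
   see :mod:`seropanel.signalpep`);
3. call per-stage overexpression vs normal liver (Welch's t test on
   log2(FPKM+1), fold-change and alpha thresholds) and keep genes
   overexpressed in both early and advanced HCC but in neither chronic
   hepatitis nor cirrhosis (Venn exclusion);
4. intersect with an externally supplied HCC-specific gene signature;
5. optionally restrict to an assayable allow-list, then rank by mean
   log2(FPKM+1) over HCC samples and keep the top K.

Counts are recorded at every stage and are non-increasing by construction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import HCC_STAGES, Stage
from .signalpep import GeneRecord, SignalDecision, builtin_signal_call, secretome_filter

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float
    flag: str | None = None  # "degenerate-equal" | "degenerate-separated" | "insufficient-n"


def welch_t(x: Sequence[float], y: Sequence[float]) -> WelchResult:
    """Welch's unequal-variance t test (two-sided) with explicit handling
    of the degenerate cases a screening matrix produces.

    * either group smaller than 2 -> flagged ``insufficient-n`` (NaN stats);
    * both groups constant and equal -> t = 0, p = 1;
    * both groups constant but different -> infinite t, p = 0, flagged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        return WelchResult(math.nan, math.nan, math.nan, flag="insufficient-n")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if x.mean() == y.mean():
            return WelchResult(0.0, float(len(x) + len(y) - 2), 1.0, flag="degenerate-equal")
        sign = 1.0 if x.mean() > y.mean() else -1.0
        return WelchResult(sign * math.inf, float(len(x) + len(y) - 2), 0.0,
                           flag="degenerate-separated")
    res = stats.ttest_ind(x, y, equal_var=False)
    return WelchResult(float(res.statistic), float(res.df), float(res.pvalue))


@dataclass(frozen=True)
class OverexpressionCall:
    gene_id: str
    stage: Stage
    log2_fc: float
    t: float
    p: float
    passed: bool


def _log2p1(values: np.ndarray) -> np.ndarray:
    return np.log2(values + 1.0)


def call_overexpression(
    matrix: pd.DataFrame,
    stages: Mapping[str, str] | pd.Series,
    stage: Stage,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    adjust: str | None = None,
) -> dict[str, OverexpressionCall]:
    """Per-gene overexpression calls for ``stage`` vs normal liver.

    log2 fold change = mean log2(FPKM+1) in ``stage`` minus mean
    log2(FPKM+1) in NL; a gene passes when the fold change reaches
    ``fc_threshold`` (linear scale) and Welch's p is below ``alpha``.
    ``adjust="bh"`` applies Benjamini-Hochberg to the p-values first.
    """
    stages = pd.Series(stages)
    stage_cols = stages.index[stages == stage.value]
    nl_cols = stages.index[stages == Stage.NL.value]
    if len(stage_cols) == 0:
        raise ValueError(f"no samples for stage {stage.value}")
    if len(nl_cols) == 0:
        raise ValueError("no NL reference samples in the matrix")

    a = _log2p1(matrix[stage_cols].to_numpy(dtype=float))
    b = _log2p1(matrix[nl_cols].to_numpy(dtype=float))
    log2_thr = np.log2(fc_threshold)

    raw: list[tuple[str, float, WelchResult]] = []
    for i, gene in enumerate(matrix.index):
        res = welch_t(a[i], b[i])
        lfc = float(a[i].mean() - b[i].mean())
        raw.append((gene, lfc, res))
        if res.flag == "insufficient-n":
            logger.warning("gene %s: insufficient samples for Welch test; excluded", gene)

    pvals = np.array([r.p for _, _, r in raw])
    if adjust == "bh":
        pvals = _benjamini_hochberg(pvals)
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")

    calls: dict[str, OverexpressionCall] = {}
    for (gene, lfc, res), p in zip(raw, pvals):
        passed = bool(not math.isnan(p) and lfc >= log2_thr and p < alpha)
        calls[gene] = OverexpressionCall(gene, stage, lfc, res.t, float(p), passed)
    return calls


def _benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    p = np.asarray(pvals, dtype=float)
    ok = ~np.isnan(p)
    q = np.full_like(p, np.nan)
    m = ok.sum()
    if m:
        order = np.argsort(p[ok])
        ranked = p[ok][order] * m / (np.arange(m) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.clip(ranked, 0, 1)
        q[ok] = out
    return q


def venn_filter(calls_by_stage: Mapping[Stage, Mapping[str, OverexpressionCall]]) -> set[str]:
    """HCC-exclusive genes: overexpressed in both eHCC and aHCC, in
    neither CH nor LC."""
    required = (Stage.CH, Stage.LC, Stage.EHCC, Stage.AHCC)
    missing = [s.value for s in required if s not in calls_by_stage]
    if missing:
        raise ValueError(f"venn_filter needs call sets for CH, LC, eHCC, aHCC; missing {missing}")

    def passing(stage: Stage) -> set[str]:
        return {g for g, c in calls_by_stage[stage].items() if c.passed}

    return (passing(Stage.EHCC) & passing(Stage.AHCC)) - passing(Stage.CH) - passing(Stage.LC)


def intersect_signature(candidates: set[str], signature: Iterable[str]) -> set[str]:
    """Case-normalised intersection with an external gene signature."""
    sig = {s.strip().upper() for s in signature if s.strip()}
    if not sig:
        raise ValueError("signature list is empty")
    kept = {c for c in candidates if c.strip().upper() in sig}
    if candidates and not kept:
        logger.warning("signature intersection is empty (%d candidates in, 0 out)", len(candidates))
    return kept


def rank_candidates(
    matrix: pd.DataFrame,
    stages: Mapping[str, str] | pd.Series,
    genes: Iterable[str],
    k: int,
) -> list[str]:
    """Top-``k`` genes by mean log2(FPKM+1) over HCC (eHCC + aHCC)
    samples, descending; ties broken lexicographically by gene id."""
    if k < 1:
        raise ValueError("k must be >= 1")
    genes = sorted(set(genes))
    missing = [g for g in genes if g not in matrix.index]
    if missing:
        raise ValueError(f"genes not in matrix: {missing[:5]}")
    stages = pd.Series(stages)
    hcc_cols = stages.index[stages.isin([s.value for s in HCC_STAGES])]
    if len(hcc_cols) == 0:
        raise ValueError("no HCC samples to rank on")
    means = _log2p1(matrix.loc[genes, hcc_cols].to_numpy(dtype=float)).mean(axis=1)
    if k > len(genes):
        logger.info("k=%d exceeds candidate count %d; returning all", k, len(genes))
    order = sorted(zip(genes, means), key=lambda gm: (-gm[1], gm[0]))
    return [g for g, _ in order[:k]]


@dataclass
class FunnelReport:
    """Counts along the selection funnel, in filter order."""

    n_total: int
    n_coding: int
    n_secretory: int
    n_after_venn: int
    n_after_signature: int
    n_after_allowlist: int
    n_final: int

    def as_frame(self) -> pd.DataFrame:
        rows = [
            ("total", self.n_total),
            ("coding", self.n_coding),
            ("secretory", self.n_secretory),
            ("hcc_exclusive", self.n_after_venn),
            ("signature", self.n_after_signature),
            ("assayable", self.n_after_allowlist),
            ("final", self.n_final),
        ]
        return pd.DataFrame(rows, columns=["stage", "n_genes"])

    def counts(self) -> list[int]:
        return [self.n_total, self.n_coding, self.n_secretory, self.n_after_venn,
                self.n_after_signature, self.n_after_allowlist, self.n_final]


@dataclass
class FunnelResult:
    candidates: list[str]  # ranked, best first
    report: FunnelReport
    calls_by_stage: dict[Stage, dict[str, OverexpressionCall]]
    secretory: set[str]
    decisions: dict[str, SignalDecision]

    def candidate_table(self, matrix: pd.DataFrame,
                        stages: pd.Series) -> pd.DataFrame:
        stages = pd.Series(stages)
        hcc_cols = stages.index[stages.isin([s.value for s in HCC_STAGES])]
        rows = []
        for rank, gene in enumerate(self.candidates, start=1):
            row: dict[str, object] = {
                "rank": rank,
                "gene_id": gene,
                "mean_hcc_log2": float(
                    _log2p1(matrix.loc[gene, hcc_cols].to_numpy(dtype=float)).mean()),
            }
            for stage, calls in self.calls_by_stage.items():
                call = calls.get(gene)
                if call is not None:
                    row[f"log2fc_{stage.value}"] = call.log2_fc
                    row[f"p_{stage.value}"] = call.p
            rows.append(row)
        return pd.DataFrame(rows)


class SelectionFunnel:
    """End-to-end candidate selection on one expression matrix.

    Parameters
    ----------
    matrix : genes x samples FPKM table.
    stages : sample id -> stage string.
    biotype : gene id -> "coding" / "non-coding".
    proteins : gene id -> amino-acid sequence (coding genes); used by the
        builtin predictor when no ``decisions`` are supplied.
    signature : external HCC-specific gene list.
    allow_list : optional assayable-gene restriction (ELISA availability
        is not computable, so it enters as data).
    """

    def __init__(
        self,
        matrix: pd.DataFrame,
        stages: Mapping[str, str] | pd.Series,
        biotype: Mapping[str, str],
        signature: Iterable[str],
        proteins: Mapping[str, str | None] | None = None,
        decisions: Mapping[str, SignalDecision] | None = None,
        allow_list: Iterable[str] | None = None,
        fc_threshold: float = 2.0,
        alpha: float = 0.05,
        adjust: str | None = None,
    ) -> None:
        if matrix.index.duplicated().any():
            raise ValueError("duplicate gene ids in matrix")
        if matrix.columns.duplicated().any():
            raise ValueError("duplicate sample ids in matrix")
        stages = pd.Series(stages)
        unstaged = [s for s in matrix.columns if s not in stages.index]
        if unstaged:
            raise ValueError(f"samples without a stage label: {unstaged[:5]}")
        if (matrix.to_numpy(dtype=float) < 0).any():
            raise ValueError("FPKM values must be nonnegative")
        self.matrix = matrix
        self.stages = stages.loc[matrix.columns]
        self.biotype = dict(biotype)
        self.proteins = dict(proteins or {})
        self.signature = list(signature)
        self.allow_list = set(allow_list) if allow_list is not None else None
        self.fc_threshold = fc_threshold
        self.alpha = alpha
        self.adjust = adjust
        self._decisions = dict(decisions) if decisions is not None else None

    def records(self) -> list[GeneRecord]:
        return [
            GeneRecord(g, self.biotype.get(g, "coding"), self.proteins.get(g))
            for g in self.matrix.index
        ]

    def signal_decisions(self) -> dict[str, SignalDecision]:
        if self._decisions is not None:
            return dict(self._decisions)
        decisions = {}
        for rec in self.records():
            if rec.biotype == "coding" and rec.protein:
                decisions[rec.gene_id] = builtin_signal_call(rec.protein)
        return decisions

    def run(self, k: int = 10) -> FunnelResult:
        genes = list(self.matrix.index)
        coding = [g for g in genes if self.biotype.get(g) == "coding"]
        decisions = self.signal_decisions()
        secretory = secretome_filter(self.records(), decisions)

        calls_by_stage: dict[Stage, dict[str, OverexpressionCall]] = {}
        sub = self.matrix.loc[sorted(secretory)] if secretory else self.matrix.iloc[:0]
        for stage in (Stage.CH, Stage.LC, Stage.EHCC, Stage.AHCC):
            calls_by_stage[stage] = call_overexpression(
                sub, self.stages, stage,
                fc_threshold=self.fc_threshold, alpha=self.alpha, adjust=self.adjust)
        hcc_exclusive = venn_filter(calls_by_stage)
        in_signature = intersect_signature(hcc_exclusive, self.signature) if hcc_exclusive else set()
        assayable = (in_signature & self.allow_list) if self.allow_list is not None else in_signature
        ranked = rank_candidates(self.matrix, self.stages, assayable, k) if assayable else []

        report = FunnelReport(
            n_total=len(genes),
            n_coding=len(coding),
            n_secretory=len(secretory),
            n_after_venn=len(hcc_exclusive),
            n_after_signature=len(in_signature),
            n_after_allowlist=len(assayable),
            n_final=len(ranked),
        )
        return FunnelResult(ranked, report, calls_by_stage, secretory, decisions)
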