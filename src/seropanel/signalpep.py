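"""Signal-peptide detection for the secretome filter.

Secretory proteins carry an N-terminal signal peptide with a tripartite
architecture: a positively charged n-region, a hydrophobic h-region and a
c-region whose last residues obey the classical von Heijne (-3, -1) rule
(small neutral residues at the third-last and last signal positions).

Two routes produce a per-protein decision:

* :func:`parse_signalp_short` reads the short (tabular) output of the
  external SignalP 4.x predictor, for users who have run it.
* :func:`builtin_signal_call` is a deliberately simple, deterministic
  classical rule built from Kyte-Doolittle hydropathy and a (-3, -1)
  small-residue weight matrix.  It is not a reimplementation of SignalP's
  neural networks; the downstream funnel only needs a boolean per gene.

Cleavage positions are reported as the 1-based index of the *last* signal
residue, i.e. cleavage occurs between ``pos`` and ``pos + 1``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, TextIO

from Bio import SeqIO

#: Kyte-Doolittle hydropathy index.
KYTE_DOOLITTLE: dict[str, float] = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

#: Small neutral residues allowed at the (-3, -1) positions, with weights
#: reflecting their observed preference (Ala strongly favoured).
SMALL_RESIDUE_WEIGHTS: dict[str, float] = {
    "A": 1.0, "G": 0.9, "S": 0.9, "C": 0.8, "T": 0.7, "V": 0.5,
}

POSITIVE_RESIDUES = frozenset("KR")

# Ambiguity/rare codes: hydropathy 0, never accepted at (-3, -1).
_NEUTRAL_UNKNOWN = frozenset("BZXUJO")


@dataclass(frozen=True)
class SignalDecision:
    """Outcome of a signal-peptide call for one protein."""

    has_signal: bool
    cleavage_pos: int | None  # 1-based last signal residue
    score: float
    method: str  # "parsed" | "builtin"
    reason: str | None = None

    def __post_init__(self) -> None:
        if not self.has_signal and self.cleavage_pos is not None:
            raise ValueError("cleavage position must be absent for negative calls")


@dataclass
class GeneRecord:
    """Gene identity plus the annotations the funnel consumes."""

    gene_id: str
    biotype: str  # "coding" | "non-coding"
    protein: str | None = None
    decision: SignalDecision | None = None

    def __post_init__(self) -> None:
        if self.decision is not None and self.decision.has_signal and self.biotype != "coding":
            raise ValueError(f"{self.gene_id}: signal-positive call on a non-coding gene")


def kd_value(residue: str, strict: bool = False) -> float:
    r = residue.upper()
    if r in KYTE_DOOLITTLE:
        return KYTE_DOOLITTLE[r]
    if r in _NEUTRAL_UNKNOWN:
        if strict:
            raise ValueError(f"non-standard residue {residue!r}")
        return 0.0
    raise ValueError(f"unknown residue {residue!r}")


def kd_window_score(sequence: str, start: int, width: int, strict: bool = False) -> float:
    """Mean Kyte-Doolittle hydropathy of ``sequence[start:start+width]``.

    ``start`` is a 0-based index; the window must lie within the sequence.
    Non-standard residues score 0 unless ``strict``.
    """
    if width < 1:
        raise ValueError(f"window width must be >= 1, got {width}")
    if start < 0 or start + width > len(sequence):
        raise ValueError(
            f"window [{start}, {start + width}) outside sequence of length {len(sequence)}")
    window = sequence[start:start + width]
    return sum(kd_value(r, strict=strict) for r in window) / width


def max_kd_window(sequence: str, width: int = 8, search_len: int = 30) -> tuple[float, int]:
    """Best mean-hydropathy window of ``width`` residues whose start lies
    within the first ``search_len`` residues.  Returns (score, 0-based start);
    ties go to the earliest window."""
    limit = min(search_len, len(sequence) - width + 1)
    best, best_start = -float("inf"), -1
    for s in range(limit):
        v = kd_window_score(sequence, s, width)
        if v > best + 1e-12:
            best, best_start = v, s
    return best, best_start


def builtin_signal_call(
    sequence: str,
    hydrophobicity_threshold: float = 1.6,
    h_width: int = 8,
    h_search_len: int = 30,
    cleavage_scan: tuple[int, int] = (15, 45),
) -> SignalDecision:
    """Deterministic classical signal-peptide rule.

    A sequence is called secretory when all three hold:

    1. **h-region** — the maximal ``h_width``-residue mean Kyte-Doolittle
       window starting within the first ``h_search_len`` residues exceeds
       ``hydrophobicity_threshold``;
    2. **n-region** — at least one K/R occurs before that window;
    3. **c-region** — scanning candidate first-mature-residue positions
       ``cleavage_scan`` (1-based, inclusive), some position has small
       neutral residues at both (-3) and (-1); the best weight-matrix score
       wins, earliest position on ties.

    Sequences shorter than 25 residues are negative with a reason, not an
    error.  The reported score is a weighted sum of the three components.
    """
    seq = sequence.strip().rstrip("*").upper()
    if len(seq) < 25:
        return SignalDecision(False, None, 0.0, "builtin", reason="sequence shorter than 25 residues")

    h_score, h_start = max_kd_window(seq, width=h_width, search_len=h_search_len)
    h_pass = h_score > hydrophobicity_threshold

    n_region = seq[:h_start] if h_start > 0 else ""
    n_pass = any(r in POSITIVE_RESIDUES for r in n_region)

    lo, hi = cleavage_scan
    best_c, best_pos = 0.0, None
    for first_mature in range(lo, min(hi, len(seq)) + 1):
        last_signal = first_mature - 1  # 1-based index of -1 residue
        res_m1 = seq[last_signal - 1]
        res_m3 = seq[last_signal - 3]
        if res_m1 in SMALL_RESIDUE_WEIGHTS and res_m3 in SMALL_RESIDUE_WEIGHTS:
            w = 0.5 * (SMALL_RESIDUE_WEIGHTS[res_m1] + SMALL_RESIDUE_WEIGHTS[res_m3])
            if w > best_c + 1e-12:
                best_c, best_pos = w, last_signal
    c_pass = best_pos is not None

    score = (
        0.5 * max(h_score, 0.0) / 4.5
        + 0.2 * float(n_pass)
        + 0.3 * best_c
    )
    if h_pass and n_pass and c_pass:
        return SignalDecision(True, best_pos, score, "builtin")
    reasons = []
    if not h_pass:
        reasons.append("no hydrophobic core")
    if not n_pass:
        reasons.append("no basic n-region residue")
    if not c_pass:
        reasons.append("no (-3,-1) cleavage site")
    return SignalDecision(False, None, score, "builtin", reason="; ".join(reasons))


# ---------------------------------------------------------------------------
# SignalP short-format parsing
# ---------------------------------------------------------------------------

def parse_signalp_short(lines: Iterable[str] | TextIO) -> dict[str, SignalDecision]:
    """Parse SignalP 4.x *short* output into per-sequence decisions.

    Expected data columns: ``name Cmax pos Ymax pos Smax pos Smean D ?
    Dmaxcut Networks-used``; comment lines start with ``#``.  The ``?``
    column decides positivity; the Ymax position is the first mature
    residue, so the stored cleavage position is ``Ymax_pos - 1``.
    """
    decisions: dict[str, SignalDecision] = {}
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 12:
            raise ValueError(f"line {lineno}: expected 12 columns, got {len(fields)}")
        name = fields[0]
        if name in decisions:
            raise ValueError(f"line {lineno}: duplicate sequence id {name!r}")
        try:
            ymax_pos = int(fields[4])
            d_score = float(fields[8])
        except ValueError as exc:
            raise ValueError(f"line {lineno}: malformed numeric field ({exc})") from exc
        flag = fields[9]
        if flag not in ("Y", "N"):
            raise ValueError(f"line {lineno}: '?' column must be Y or N, got {flag!r}")
        if flag == "Y":
            decisions[name] = SignalDecision(True, ymax_pos - 1, d_score, "parsed")
        else:
            decisions[name] = SignalDecision(False, None, d_score, "parsed")
    return decisions


def format_signalp_short(decisions: Mapping[str, SignalDecision],
                         dmaxcut: float = 0.45) -> str:
    """Render decisions in SignalP-4 short format (used to build synthetic
    answer files; labelled as such wherever written to disk)."""
    out = ["# SignalP-4.1 euk predictions (synthetic)",
           "# name Cmax pos Ymax pos Smax pos Smean D ? Dmaxcut Networks-used"]
    for name, d in decisions.items():
        pos = (d.cleavage_pos + 1) if d.cleavage_pos is not None else 1
        flag = "Y" if d.has_signal else "N"
        out.append(
            f"{name} {d.score:.3f} {pos} {d.score:.3f} {pos} {d.score:.3f} {max(pos - 1, 1)} "
            f"{d.score:.3f} {d.score:.3f} {flag} {dmaxcut:.2f} SignalP-noTM")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# secretome filter and sequence I/O
# ---------------------------------------------------------------------------

def secretome_filter(records: Iterable[GeneRecord],
                     decisions: Mapping[str, SignalDecision]) -> set[str]:
    """Coding genes with a positive signal-peptide decision.

    Non-coding genes never pass; coding genes missing from ``decisions``
    are treated as signal-negative.
    """
    secretory: set[str] = set()
    for rec in records:
        if rec.biotype != "coding":
            continue
        decision = decisions.get(rec.gene_id)
        if decision is not None and decision.has_signal:
            secretory.add(rec.gene_id)
    return secretory


def read_protein_fasta(path: str | Path | TextIO) -> dict[str, str]:
    """Protein FASTA reader: id = first whitespace token, sequences
    upper-cased with any terminal '*' stop stripped."""
    if isinstance(path, (str, Path)):
        handle: TextIO = open(path)
        close = True
    else:
        handle, close = path, False
    try:
        seqs: dict[str, str] = {}
        for rec in SeqIO.parse(handle, "fasta"):
            seq = str(rec.seq).strip().upper().rstrip("*")
            if rec.id in seqs:
                raise ValueError(f"duplicate FASTA id {rec.id!r}")
            seqs[rec.id] = seq
        return seqs
    finally:
        if close:
            handle.close()


def write_decisions_tsv(decisions: Mapping[str, SignalDecision], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\thas_signal\tcleavage_pos\tscore\tmethod\n")
        for name, d in decisions.items():
            pos = "" if d.cleavage_pos is None else str(d.cleavage_pos)
            fh.write(f"{name}\t{int(d.has_signal)}\t{pos}\t{d.score:.6g}\t{d.method}\n")
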