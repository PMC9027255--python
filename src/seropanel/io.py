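"""Readers and writers for the package's plain-text interchange formats.

All tables are TSV.  Serum cohorts have columns ``subject_id``, ``stage``
and one ng/mL column per marker (empty cell = missing measurement);
expression data travel as a genes x samples FPKM TSV plus a sample
metadata TSV (``sample_id``, ``stage``); survival tables have
``subject_id``, ``time``, ``event``, ``group``; gene signatures are one
symbol per line; panel definitions are JSON lists of
``{"marker": ..., "cutoff_ng_per_ml": ...}``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import parse_stage
from .roc import MarkerCutoff

_FLOAT_FMT = "%.6g"


def read_serum_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("subject_id", "stage"):
        if col not in df.columns:
            raise ValueError(f"{path}: serum table lacks required column {col!r}")
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ValueError(f"{path}: duplicate subject_id {dup!r}")
    for s in df["stage"]:
        parse_stage(str(s))  # raises on unknown labels
    markers = [c for c in df.columns if c not in ("subject_id", "stage")]
    bad = [c for c in markers if (df[c].dropna() < 0).any()]
    if bad:
        raise ValueError(f"{path}: negative concentrations in columns {bad}")
    return df


def write_serum_tsv(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_expression_tsv(matrix_path: str | Path,
                        metadata_path: str | Path) -> tuple[pd.DataFrame, pd.Series]:
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t")
    for col in ("sample_id", "stage"):
        if col not in meta.columns:
            raise ValueError(f"{metadata_path}: metadata lacks column {col!r}")
    stages = meta.set_index("sample_id")["stage"]
    missing = [s for s in matrix.columns if s not in stages.index]
    if missing:
        raise ValueError(f"{metadata_path}: no stage for samples {missing[:5]}")
    if (matrix.to_numpy(dtype=float) < 0).any():
        raise ValueError(f"{matrix_path}: negative FPKM values")
    return matrix, stages.astype(str)


def write_expression_tsv(matrix: pd.DataFrame, stages: pd.Series,
                         matrix_path: str | Path, metadata_path: str | Path) -> None:
    matrix.to_csv(matrix_path, sep="\t", float_format=_FLOAT_FMT, index_label="gene_id")
    meta = pd.DataFrame({"sample_id": stages.index, "stage": stages.to_numpy()})
    meta.to_csv(metadata_path, sep="\t", index=False)


def write_protein_fasta(proteins: dict[str, str | None], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene, seq in proteins.items():
            if seq:
                fh.write(f">{gene}\n{seq}\n")


def read_gene_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip() and not line.startswith("#")]


def write_gene_list(genes, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_survival_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("subject_id", "time", "event", "group"):
        if col not in df.columns:
            raise ValueError(f"{path}: survival table lacks column {col!r}")
    if (df["time"] < 0).any():
        raise ValueError(f"{path}: negative follow-up times")
    if set(df["event"].unique()) - {0, 1}:
        raise ValueError(f"{path}: event flags must be 0/1")
    return df


def write_survival_tsv(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_panel_json(path: str | Path) -> list[MarkerCutoff]:
    with open(path) as fh:
        entries = json.load(fh)
    if not isinstance(entries, list) or not entries:
        raise ValueError(f"{path}: panel file must be a non-empty JSON list")
    cutoffs = []
    for i, entry in enumerate(entries):
        try:
            cutoff = float(entry["cutoff_ng_per_ml"])
            if cutoff <= 0:
                raise ValueError(f"cutoff must be positive, got {cutoff}")
            cutoffs.append(MarkerCutoff(str(entry["marker"]), cutoff))
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"{path}: bad panel entry #{i + 1}: {exc}") from exc
    return cutoffs


def write_panel_json(cutoffs, path: str | Path) -> None:
    payload = [{"marker": c.marker, "cutoff_ng_per_ml": c.cutoff} for c in cutoffs]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
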