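"""Readers and writers for the pipeline's file formats.

Tabular data moves as TSV; tissue expression as GCT 1.2; gene sets as
GMT; ground truth and run reports as JSON. Readers validate shape and
labels and report offending rows/columns in their error messages.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from exprot.simulate import INTENSITIES, TIMEPOINTS, ProteomeStudy, TruthTable

__all__ = [
    "write_study",
    "read_study",
    "read_gct",
    "write_gct",
    "read_gmt",
    "write_gmt",
    "write_truth",
    "read_truth",
]


def write_study(study: ProteomeStudy, out_dir: str | Path) -> dict[str, Path]:
    """Write abundance matrix, sample sheet and platform map as TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "abundance": out / "abundance.tsv",
        "samples": out / "samples.tsv",
        "proteins": out / "proteins.tsv",
    }
    study.abundance.to_csv(paths["abundance"], sep="\t")
    study.samples.to_csv(paths["samples"], sep="\t", index=False)
    study.proteins.to_csv(paths["proteins"], sep="\t", index=False)
    return paths


def read_study(
    abundance_path: str | Path,
    sample_sheet_path: str | Path,
    proteins_path: str | Path | None = None,
) -> ProteomeStudy:
    """Load and validate a paired study from TSV files."""
    abundance = pd.read_csv(abundance_path, sep="\t", index_col=0)
    samples = pd.read_csv(sample_sheet_path, sep="\t", dtype=str)

    required = {"sample_id", "subject_id", "timepoint", "intensity"}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    if samples["sample_id"].duplicated().any():
        dups = samples.loc[samples["sample_id"].duplicated(), "sample_id"]
        raise ValueError(f"duplicate sample ids: {sorted(set(dups))}")
    bad_tp = set(samples["timepoint"]) - set(TIMEPOINTS)
    if bad_tp:
        raise ValueError(f"unknown timepoint labels: {sorted(bad_tp)}")
    bad_int = set(samples["intensity"]) - set(INTENSITIES)
    if bad_int:
        raise ValueError(f"unknown intensity labels: {sorted(bad_int)}")
    sheet_only = set(samples["sample_id"]) - set(abundance.columns)
    if sheet_only:
        raise ValueError(
            f"samples in sheet absent from abundance matrix: {sorted(sheet_only)}"
        )
    for col in abundance.columns:
        vals = pd.to_numeric(abundance[col], errors="coerce")
        if vals.isna().any():
            row = abundance.index[vals.isna()][0]
            raise ValueError(
                f"nonnumeric abundance at protein {row!r}, sample {col!r}: "
                f"{abundance.loc[row, col]!r}"
            )
        abundance[col] = vals
    if (abundance.to_numpy() <= 0).any():
        idx = np.argwhere(abundance.to_numpy() <= 0)[0]
        raise ValueError(
            f"nonpositive abundance at protein {abundance.index[idx[0]]!r}, "
            f"sample {abundance.columns[idx[1]]!r}"
        )
    abundance = abundance[list(samples["sample_id"])]
    if proteins_path is not None:
        proteins = pd.read_csv(proteins_path, sep="\t", dtype=str)
    else:
        proteins = pd.DataFrame(
            {"protein_id": abundance.index, "gene_symbol": abundance.index}
        )
    study = ProteomeStudy(abundance=abundance, samples=samples, proteins=proteins)
    study.validate()
    return study


def write_gct(expression: pd.DataFrame, path: str | Path) -> Path:
    """Write a genes x samples table as GCT 1.2."""
    path = Path(path)
    body = expression.copy()
    body.insert(0, "Description", body.index)
    body.insert(0, "Name", body.index)
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{expression.shape[0]}\t{expression.shape[1]}\n")
        body.to_csv(fh, sep="\t", index=False)
    return path


def read_gct(path: str | Path) -> pd.DataFrame:
    """Read a GCT 1.2 file into a genes x samples DataFrame."""
    path = Path(path)
    with open(path) as fh:
        version = fh.readline().strip()
        if version not in ("#1.2",):
            raise ValueError(f"unsupported GCT version line: {version!r}")
        dims = fh.readline().split()
        if len(dims) < 2:
            raise ValueError("malformed GCT dimension line")
        n_rows, n_cols = int(dims[0]), int(dims[1])
        df = pd.read_csv(fh, sep="\t")
    if df.shape[0] != n_rows or df.shape[1] - 2 != n_cols:
        raise ValueError(
            f"GCT dimensions {n_rows}x{n_cols} disagree with body "
            f"{df.shape[0]}x{df.shape[1] - 2}"
        )
    df = df.set_index("Name").drop(columns=["Description"])
    df.index.name = "gene_symbol"
    return df.astype(float)


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, name] + sorted(set(members))) + "\n")
    return path


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"GMT line {i} has fewer than 3 fields")
            name = parts[0]
            if name in sets:
                raise ValueError(f"duplicate set name {name!r} at line {i}")
            sets[name] = [g for g in parts[2:] if g]
    return sets


def write_truth(truth: TruthTable, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "responses": truth.responses.reset_index().to_dict(orient="list"),
        "trait_links": (
            truth.trait_links.to_dict(orient="list")
            if truth.trait_links is not None
            else None
        ),
        "planted_enriched_sets": truth.planted_enriched_sets,
    }

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.bool_,)):
            return bool(o)
        if o is pd.NA:
            return None
        raise TypeError(f"cannot serialize {type(o)}")

    with open(path, "w") as fh:
        json.dump(payload, fh, default=_default)
    return path


def read_truth(path: str | Path) -> TruthTable:
    with open(path) as fh:
        payload = json.load(fh)
    responses = pd.DataFrame(payload["responses"]).set_index("protein_id")
    responses["direction"] = responses["direction"].astype("string")
    responses["dependence_class"] = responses["dependence_class"].astype("string")
    trait_links = (
        pd.DataFrame(payload["trait_links"])
        if payload.get("trait_links") is not None
        else None
    )
    return TruthTable(
        responses=responses,
        trait_links=trait_links,
        planted_enriched_sets=payload.get("planted_enriched_sets", []),
    )
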