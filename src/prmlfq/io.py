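"""Readers and writers for the pipeline's flat-file dialects.

Abundance matrices travel as CSV with the protein id in the first column,
reserved metadata columns (``unique_peptides``, ``length_aa``,
``description``) recognized by header, and every remaining column a sample.
Missing cells are written empty and read from empty, ``NA`` or ``NaN``.
PRM reports are long-format CSV with one row per measured ratio. Reports
(volcano tables, curve summaries, concentration grids) are TSV; ranked
lists use the two-column RNK convention; run manifests are JSON.
"""
from __future__ import annotations

import hashlib
import json
import math
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .containers import (
    AbundanceMatrix,
    CalibrationSeries,
    ConcentrationMatrix,
    PROTEIN_META_COLUMNS,
    ProcessedMatrix,
    SampleMetadata,
)

__all__ = [
    "read_abundance_csv",
    "write_abundance_csv",
    "read_sample_metadata_csv",
    "write_sample_metadata_csv",
    "read_prm_report_csv",
    "write_volcano_tsv",
    "write_rnk",
    "write_curve_report_tsv",
    "write_concentration_tsv",
    "write_processing_report_tsv",
    "write_manifest",
]

_MISSING_TOKENS = {"", "NA", "NaN", "nan"}


def read_abundance_csv(
    path, column_map: Optional[dict[str, str]] = None
) -> tuple[AbundanceMatrix, list[str]]:
    """Parse an abundance CSV into a matrix plus parse warnings.

    ``column_map`` renames input headers to the reserved names (e.g.
    ``{"# Unique Peptides": "unique_peptides"}``) so third-party exports can
    be adapted without code changes.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need a protein-id column plus at least one sample")
    if column_map:
        df = df.rename(columns=column_map)

    id_col = df.columns[0]
    ids = df[id_col].astype(str)
    dup = ids[ids.duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate protein id {dup.iloc[0]!r}")
    if pd.Index(df.columns[1:]).has_duplicates:
        raise ValueError(f"{path}: duplicate sample/metadata column headers")

    meta_cols = [c for c in PROTEIN_META_COLUMNS if c in df.columns]
    sample_cols = [c for c in df.columns[1:] if c not in meta_cols]
    if not sample_cols:
        raise ValueError(f"{path}: no sample columns found")

    warnings: list[str] = []
    values = np.empty((len(df), len(sample_cols)))
    for j, col in enumerate(sample_cols):
        for i, raw in enumerate(df[col]):
            token = raw.strip()
            if token in _MISSING_TOKENS:
                values[i, j] = np.nan
                continue
            try:
                v = float(token)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric cell {raw!r} at row {i + 2}, "
                    f"column {col!r}"
                ) from None
            if v < 0:
                raise ValueError(
                    f"{path}: negative intensity {v} at row {i + 2}, column {col!r}"
                )
            values[i, j] = v

    all_missing = np.isnan(values).all(axis=1)
    for pid in ids[all_missing]:
        warnings.append(f"protein {pid!r} has no observed intensities")

    meta = pd.DataFrame(index=pd.Index(ids, name="protein_id"))
    meta["unique_peptides"] = (
        pd.to_numeric(df["unique_peptides"]).astype(int).to_numpy()
        if "unique_peptides" in df
        else 1
    )
    meta["length_aa"] = (
        pd.to_numeric(df["length_aa"]).astype(int).to_numpy()
        if "length_aa" in df
        else 1
    )
    meta["description"] = (
        df["description"].to_numpy() if "description" in df else ""
    )

    matrix = AbundanceMatrix(
        intensity=pd.DataFrame(
            values, index=pd.Index(ids, name="protein_id"), columns=sample_cols
        ),
        protein_meta=meta,
    )
    return matrix, warnings


def write_abundance_csv(m: AbundanceMatrix, path) -> None:
    out = m.protein_meta[list(PROTEIN_META_COLUMNS)].copy()
    out = pd.concat([out, m.intensity], axis=1)
    out.index.name = "protein_id"
    out.to_csv(path, na_rep="")


def read_sample_metadata_csv(path) -> SampleMetadata:
    df = pd.read_csv(path, dtype=str)
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: sample metadata needs a sample_id column")
    return SampleMetadata(table=df.set_index("sample_id"))


def write_sample_metadata_csv(meta: SampleMetadata, path) -> None:
    meta.table.rename_axis("sample_id").to_csv(path)


PRM_COLUMNS = [
    "peptide_id",
    "sample_id",
    "sample_type",
    "nominal_fmol",
    "light_area",
    "heavy_area",
]


def read_prm_report_csv(
    path, sis_fmol: float = 50.0
) -> tuple[list[CalibrationSeries], pd.DataFrame]:
    """Parse a long-format PRM report.

    Rows with ``sample_type`` blank/calibrant feed per-peptide
    :class:`CalibrationSeries`; ``unknown`` rows are returned as a DataFrame
    (peptide_id, sample_id, ratio, detected) for quantification. A zero
    heavy area flags the row as not detected rather than raising.
    """
    df = pd.read_csv(path)
    missing_cols = [c for c in PRM_COLUMNS if c not in df.columns and c != "nominal_fmol"]
    if missing_cols:
        raise ValueError(f"{path}: missing columns {missing_cols}")
    if "nominal_fmol" not in df.columns:
        df["nominal_fmol"] = np.nan

    bad_type = set(df["sample_type"]) - {"blank", "calibrant", "unknown"}
    if bad_type:
        raise ValueError(f"{path}: unknown sample_type values {sorted(bad_type)}")

    def ratio_of(row):
        heavy = float(row["heavy_area"])
        if heavy == 0:
            return np.nan
        return float(row["light_area"]) / heavy

    series: list[CalibrationSeries] = []
    for pid, sub in df.groupby("peptide_id", sort=True):
        cal = sub[sub["sample_type"] == "calibrant"]
        if cal["nominal_fmol"].isna().any():
            raise ValueError(
                f"{path}: calibrant row for peptide {pid!r} lacks nominal_fmol"
            )
        levels, ratios = [], []
        for nominal, rows in sorted(cal.groupby("nominal_fmol"), key=lambda kv: kv[0]):
            r = rows.apply(ratio_of, axis=1).to_numpy(dtype=float)
            levels.append(float(nominal))
            ratios.append(r[~np.isnan(r)])
        blanks = sub[sub["sample_type"] == "blank"].apply(ratio_of, axis=1)
        blanks = blanks.to_numpy(dtype=float) if len(blanks) else np.array([])
        if levels:
            series.append(
                CalibrationSeries(
                    peptide_id=str(pid),
                    level_fmol=np.asarray(levels),
                    ratios=ratios,
                    blank_ratios=blanks[~np.isnan(blanks)],
                    sis_fmol=sis_fmol,
                )
            )

    unk = df[df["sample_type"] == "unknown"].copy()
    if len(unk):
        unk["ratio"] = unk.apply(ratio_of, axis=1)
        unk["detected"] = ~unk["ratio"].isna()
        unknowns = unk[["peptide_id", "sample_id", "ratio", "detected"]].reset_index(
            drop=True
        )
    else:
        unknowns = pd.DataFrame(columns=["peptide_id", "sample_id", "ratio", "detected"])
    return series, unknowns


def write_prm_report_csv(rows: pd.DataFrame, path) -> None:
    rows.to_csv(path, index=False)


def write_volcano_tsv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, sep="\t", index=False)


def write_rnk(ranked: pd.DataFrame, path) -> None:
    ranked.to_csv(path, sep="\t", index=False, header=False)


def write_curve_report_tsv(fits, path) -> None:
    rows = []
    for f in fits:
        rows.append(
            {
                "peptide_id": f.peptide_id_,
                "valid": f.valid_,
                "reason": f.reason_,
                "slope": f.slope_,
                "intercept": f.intercept_,
                "r_squared": f.r_squared_,
                "accepted_levels": ";".join(
                    f"{x:g}" for x in np.atleast_1d(f.accepted_levels_)
                ),
                "lod_fmol": f.lod_fmol_,
                "loq_fmol": f.loq_fmol_,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_concentration_tsv(conc: ConcentrationMatrix, path) -> None:
    """fmol/ug values with the censoring code appended to non-quantified cells."""
    out = conc.values.copy().astype(object)
    for i in range(out.shape[0]):
        for j in range(out.shape[1]):
            code = conc.censoring.iat[i, j]
            v = conc.values.iat[i, j]
            if code == "quantified":
                out.iat[i, j] = f"{v:.6g}"
            elif code == "not_detected" or (isinstance(v, float) and math.isnan(v)):
                out.iat[i, j] = code
            else:
                out.iat[i, j] = f"{v:.6g}[{code}]"
    out.index.name = "peptide_id"
    out.to_csv(path, sep="\t")


def write_processing_report_tsv(pm: ProcessedMatrix, path) -> None:
    report = pd.DataFrame(
        {
            "normalization_factor": pm.factors,
            "imputed_cells": pm.imputed_mask.sum(axis=0),
        }
    )
    report.index.name = "sample_id"
    report.to_csv(path, sep="\t")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(path, config: dict, inputs: list, outputs: list) -> None:
    """Record the run: config snapshot, software version, input digests."""
    from . import __version__

    manifest = {
        "software": {"name": "prmlfq", "version": __version__},
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "config": config,
        "inputs": {
            str(p): _sha256(p) for p in inputs if Path(p).is_file()
        },
        "outputs": [str(p) for p in outputs],
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
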