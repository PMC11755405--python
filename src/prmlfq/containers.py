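"""Core in-memory containers for the LFQ and PRM pipelines.

All matrices are pandas DataFrames oriented proteins (or peptides) x samples,
on a linear intensity scale, with ``NaN`` marking missing cells. Containers
are lightweight dataclasses that validate their invariants at construction.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Lesion-group labels used by the breast-lesion study design
#: (pure lesions, lesions from patients with synchronous disease, and
#: patient-paired lesions). The pipeline itself accepts any label.
STUDY_GROUPS = (
    "pure_DCIS",
    "pure_IDC",
    "mixed_DCIS",
    "mixed_IDC",
    "paired_DCIS",
    "paired_IDC",
)

#: Reserved metadata column names in the abundance CSV dialect.
PROTEIN_META_COLUMNS = ("unique_peptides", "length_aa", "description")


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dupes = index[index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dupes}")


@dataclass
class AbundanceMatrix:
    """Protein x sample grid of linear intensities with per-protein metadata.

    Parameters
    ----------
    intensity
        DataFrame indexed by protein id with sample ids as columns.
        Missing cells are ``NaN``; all present values must be >= 0.
    protein_meta
        DataFrame indexed by protein id with at least ``unique_peptides``
        (int >= 0) and ``length_aa`` (int > 0) columns.
    """

    intensity: pd.DataFrame
    protein_meta: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.intensity.index, "protein ids")
        _check_unique(self.intensity.columns, "sample ids")
        vals = self.intensity.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("negative intensities are not allowed")
        missing_meta = self.intensity.index.difference(self.protein_meta.index)
        if len(missing_meta):
            raise ValueError(
                f"protein metadata missing for: {missing_meta[:5].tolist()}"
            )
        # keep meta aligned to the matrix row order
        self.protein_meta = self.protein_meta.loc[self.intensity.index]

    @property
    def protein_ids(self) -> list[str]:
        return list(self.intensity.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensity.columns)

    @property
    def n_proteins(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensity.shape[1]

    def observed_mask(self) -> pd.DataFrame:
        """Boolean mask of observed cells (non-missing, strictly positive)."""
        return self.intensity.notna() & (self.intensity > 0)

    def subset_proteins(self, protein_ids) -> "AbundanceMatrix":
        return AbundanceMatrix(
            intensity=self.intensity.loc[protein_ids].copy(),
            protein_meta=self.protein_meta.loc[protein_ids].copy(),
        )


@dataclass
class SampleMetadata:
    """Sample -> patient/group mapping defining the comparison cohorts."""

    table: pd.DataFrame  # index sample_id; columns patient_id, group

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "sample ids")
        for col in ("patient_id", "group"):
            if col not in self.table.columns:
                raise ValueError(f"sample metadata lacks required column {col!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def groups(self) -> list[str]:
        return list(pd.unique(self.table["group"]))

    def samples_in(self, group: str) -> list[str]:
        return list(self.table.index[self.table["group"] == group])

    def require_cover(self, sample_ids) -> None:
        missing = pd.Index(sample_ids).difference(self.table.index)
        if len(missing):
            raise ValueError(f"samples without metadata: {missing[:5].tolist()}")


@dataclass
class SpectralCountMatrix:
    """Protein x sample grid of non-negative integer spectral counts."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.counts.index, "protein ids")
        _check_unique(self.counts.columns, "sample ids")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise ValueError("spectral counts must be integers")
            self.counts = self.counts.astype(np.int64)
            vals = self.counts.to_numpy()
        if vals.min(initial=0) < 0:
            raise ValueError("spectral counts must be non-negative")


@dataclass
class ProcessedMatrix:
    """Abundance matrix after normalization and/or imputation.

    Carries the per-sample normalization factors and the imputation mask
    (True where a cell was filled by the imputation rule). After imputation
    no missing cells remain; before it, cells may still be NaN.
    """

    intensity: pd.DataFrame
    protein_meta: pd.DataFrame
    factors: pd.Series  # per-sample scale factor applied (1.0 = untouched)
    imputed_mask: pd.DataFrame  # bool, True where imputed

    def __post_init__(self) -> None:
        if list(self.imputed_mask.index) != list(self.intensity.index) or list(
            self.imputed_mask.columns
        ) != list(self.intensity.columns):
            raise ValueError("imputation mask must be aligned with the matrix")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.intensity.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensity.columns)

    def log2(self) -> pd.DataFrame:
        """Elementwise log2 of the intensity grid.

        Raises on non-positive or missing cells, naming the offending
        protein and sample.
        """
        vals = self.intensity.to_numpy(dtype=float)
        bad = ~(vals > 0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                "log2 undefined for non-positive/missing intensity at "
                f"protein {self.intensity.index[i]!r}, sample "
                f"{self.intensity.columns[j]!r}"
            )
        return pd.DataFrame(
            np.log2(vals), index=self.intensity.index, columns=self.intensity.columns
        )


@dataclass
class CalibrationSeries:
    """One peptide's response-curve data: calibrant levels plus blanks.

    ``ratios[k]`` holds the replicate light/heavy response ratios measured
    at ``level_fmol[k]`` of light peptide against the constant SIS spike.
    ``blank_ratios`` are double-blank replicates (SIS only, no light).
    """

    peptide_id: str
    level_fmol: np.ndarray
    ratios: list  # list of 1-D arrays, one per level
    blank_ratios: np.ndarray
    sis_fmol: float = 50.0

    def __post_init__(self) -> None:
        self.level_fmol = np.asarray(self.level_fmol, dtype=float)
        self.ratios = [np.asarray(r, dtype=float) for r in self.ratios]
        self.blank_ratios = np.asarray(self.blank_ratios, dtype=float)
        if len(self.level_fmol) != len(self.ratios):
            raise ValueError("one replicate-ratio array required per level")
        if self.level_fmol.size and self.level_fmol.min() <= 0:
            raise ValueError("calibrant levels must be positive")
        if np.any(np.diff(self.level_fmol) <= 0):
            raise ValueError("calibrant levels must be strictly increasing")
        if self.sis_fmol <= 0:
            raise ValueError("sis_fmol must be positive")

    @property
    def n_levels(self) -> int:
        return len(self.level_fmol)


@dataclass
class ConcentrationMatrix:
    """Peptide x sample absolute concentrations with censoring codes.

    ``values`` holds fmol per microgram of digested protein input;
    ``censoring`` holds one of ``quantified``, ``below_LOQ``, ``below_LOD``,
    ``not_detected`` per cell. Cells censored as ``not_detected`` carry NaN.
    """

    values: pd.DataFrame
    censoring: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.shape != self.censoring.shape:
            raise ValueError("values and censoring grids must be congruent")
        allowed = {"quantified", "below_LOQ", "below_LOD", "not_detected"}
        seen = set(pd.unique(self.censoring.to_numpy().ravel()))
        unknown = seen - allowed
        if unknown:
            raise ValueError(f"unknown censoring codes: {sorted(unknown)}")


@dataclass
class GroundTruth:
    """Truth record emitted by the simulators for benchmarking."""

    dep_protein_ids: frozenset = field(default_factory=frozenset)
    true_log2fc: dict = field(default_factory=dict)  # protein -> log2FC
    true_slope: dict = field(default_factory=dict)  # peptide -> slope
    true_intercept: dict = field(default_factory=dict)  # peptide -> intercept
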