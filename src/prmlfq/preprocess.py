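"""LFQ data reduction: detection filtering, summed-intensity normalization,
per-sample minimum imputation, log2 transform, and NSAF computation.

The canonical order is filter -> normalize -> impute -> log2. Normalization
factors are computed over observed (pre-imputation) cells only, so imputed
values never influence the loading correction; imputation then uses the
normalized per-sample minima.
"""
from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .containers import (
    AbundanceMatrix,
    ProcessedMatrix,
    SampleMetadata,
    SpectralCountMatrix,
)

__all__ = [
    "DetectionFilter",
    "SumNormalizer",
    "MinImputer",
    "filter_by_detection",
    "normalize_sum",
    "impute_missing",
    "log2_view",
    "compute_nsaf",
    "preprocess_lfq",
    "impute_min_per_sample",
]


class DetectionFilter(BaseEstimator):
    """Retain proteins identified by unique peptides and reproducibly
    quantified in at least one study group.

    A protein is kept iff its unique-peptide count is at least
    ``min_unique_peptides`` and it is observed (non-missing, positive) in at
    least ``min_frac`` of the samples of at least one of the ``groups``.

    Parameters
    ----------
    groups : set of group labels or None
        Groups whose coverage counts toward retention; None means every
        group present in the sample metadata.
    min_frac : float in (0, 1]
        Minimum fraction of a group's samples in which the protein must be
        observed (default 0.6).
    min_unique_peptides : int
        Minimum protein-unique peptides for identification (default 1).
    """

    def __init__(self, groups=None, min_frac: float = 0.6, min_unique_peptides: int = 1):
        self.groups = groups
        self.min_frac = min_frac
        self.min_unique_peptides = min_unique_peptides

    def fit(self, m: AbundanceMatrix, meta: SampleMetadata) -> "DetectionFilter":
        if not (0 < self.min_frac <= 1):
            raise ValueError("min_frac must lie in (0, 1]")
        groups = list(self.groups) if self.groups is not None else meta.groups
        if not groups:
            raise ValueError("no groups to filter on")
        meta.require_cover(m.sample_ids)

        observed = m.observed_mask()
        covered = np.zeros(m.n_proteins, dtype=bool)
        for g in groups:
            members = [s for s in meta.samples_in(g) if s in observed.columns]
            if not members:
                raise ValueError(f"group {g!r} has no samples in the matrix")
            frac = observed[members].sum(axis=1) / len(members)
            covered |= (frac >= self.min_frac).to_numpy()

        identified = (
            m.protein_meta["unique_peptides"].to_numpy() >= self.min_unique_peptides
        )
        self.kept_ids_ = [
            pid for pid, keep in zip(m.protein_ids, covered & identified) if keep
        ]
        return self

    def transform(self, m: AbundanceMatrix) -> AbundanceMatrix:
        return m.subset_proteins(self.kept_ids_)

    def fit_transform(self, m: AbundanceMatrix, meta: SampleMetadata) -> AbundanceMatrix:
        return self.fit(m, meta).transform(m)


class SumNormalizer(BaseEstimator):
    """Correct sample loading by equalizing summed observed intensities.

    Each sample column is scaled by ``median(sums) / sum_s`` where ``sum_s``
    is the sample's total over observed cells, so after scaling every
    per-sample sum equals the cohort median sum. Within-sample ratios are
    untouched. The median reference keeps factors robust to a single
    outlier sample and leaves an already-balanced matrix unchanged.
    """

    def fit(self, m: AbundanceMatrix) -> "SumNormalizer":
        observed = m.observed_mask()
        if not observed.any(axis=0).all():
            bad = m.intensity.columns[~observed.any(axis=0)][0]
            raise ValueError(f"sample {bad!r} has no observed intensities")
        sums = m.intensity.where(observed).sum(axis=0)
        self.reference_ = float(sums.median())
        self.factors_ = self.reference_ / sums
        return self

    def transform(self, m: AbundanceMatrix) -> ProcessedMatrix:
        scaled = m.intensity * self.factors_
        return ProcessedMatrix(
            intensity=scaled,
            protein_meta=m.protein_meta.copy(),
            factors=self.factors_.copy(),
            imputed_mask=pd.DataFrame(
                False, index=m.intensity.index, columns=m.intensity.columns
            ),
        )

    def fit_transform(self, m: AbundanceMatrix) -> ProcessedMatrix:
        return self.fit(m).transform(m)


def impute_min_per_sample(values: pd.DataFrame, factor: float) -> pd.DataFrame:
    """Fill each missing cell with ``factor`` x its sample's observed minimum."""
    if factor <= 0:
        raise ValueError("imputation factor must be positive")
    observed = values.notna() & (values > 0)
    if not observed.any(axis=0).all():
        bad = values.columns[~observed.any(axis=0)][0]
        raise ValueError(f"sample {bad!r} has no observed intensities to impute from")
    minima = values.where(observed).min(axis=0)
    return values.fillna(factor * minima)


class MinImputer(BaseEstimator):
    """Replace missing cells with a multiple of the per-sample minimum.

    The default ``factor=1.5`` places imputed values at 1.5x the minimum
    observed intensity of the same sample — above the observed floor, which
    differs from conventional down-shifted imputation; see the methods note.
    """

    def __init__(self, factor: float = 1.5):
        self.factor = factor

    def fit(self, m: ProcessedMatrix) -> "MinImputer":
        return self

    def transform(self, m: ProcessedMatrix) -> ProcessedMatrix:
        filled = impute_min_per_sample(m.intensity, self.factor)
        newly = m.intensity.isna() & filled.notna()
        return ProcessedMatrix(
            intensity=filled,
            protein_meta=m.protein_meta.copy(),
            factors=m.factors.copy(),
            imputed_mask=m.imputed_mask | newly,
        )

    def fit_transform(self, m: ProcessedMatrix) -> ProcessedMatrix:
        return self.fit(m).transform(m)


def filter_by_detection(
    m: AbundanceMatrix,
    meta: SampleMetadata,
    groups=None,
    min_frac: float = 0.6,
    min_unique_peptides: int = 1,
) -> AbundanceMatrix:
    return DetectionFilter(groups, min_frac, min_unique_peptides).fit_transform(m, meta)


def normalize_sum(m: AbundanceMatrix) -> ProcessedMatrix:
    return SumNormalizer().fit_transform(m)


def impute_missing(m: ProcessedMatrix, factor: float = 1.5) -> ProcessedMatrix:
    return MinImputer(factor).fit_transform(m)


def log2_view(m: ProcessedMatrix) -> pd.DataFrame:
    return m.log2()


def compute_nsaf(
    c: SpectralCountMatrix, lengths: Optional[dict[str, float]] = None
) -> pd.DataFrame:
    """Normalized spectral abundance factors.

    NSAF_{i,s} = (count_{i,s} / length_i) / sum_j (count_{j,s} / length_j);
    every sample column sums to 1. ``lengths`` defaults to nothing and must
    cover every protein in the count matrix.
    """
    counts = c.counts
    if lengths is None:
        raise ValueError("protein lengths are required for NSAF")
    missing = [p for p in counts.index if p not in lengths]
    if missing:
        raise ValueError(f"no length provided for protein {missing[0]!r}")
    lvec = np.asarray([lengths[p] for p in counts.index], dtype=float)
    if np.any(lvec <= 0):
        bad = counts.index[int(np.argmax(lvec <= 0))]
        raise ValueError(f"non-positive length for protein {bad!r}")

    saf = counts.to_numpy(dtype=float) / lvec[:, None]
    totals = saf.sum(axis=0)
    if np.any(totals <= 0):
        bad = counts.columns[int(np.argmax(totals <= 0))]
        raise ValueError(f"sample {bad!r} has zero total spectral counts")
    return pd.DataFrame(saf / totals, index=counts.index, columns=counts.columns)


def preprocess_lfq(
    m: AbundanceMatrix,
    meta: SampleMetadata,
    groups=None,
    min_frac: float = 0.6,
    min_unique_peptides: int = 1,
    impute_factor: float = 1.5,
) -> ProcessedMatrix:
    """Full LFQ reduction chain: filter -> normalize -> impute."""
    filtered = filter_by_detection(m, meta, groups, min_frac, min_unique_peptides)
    return impute_missing(normalize_sum(filtered), impute_factor)
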