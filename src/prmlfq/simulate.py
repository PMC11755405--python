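"""Synthetic LFQ cohorts, spectral counts, and PRM calibration sets.

The generators emulate the statistical structure the downstream analysis
assumes — log-normal protein abundances with per-sample loading offsets,
intensity-dependent (MNAR) dropout, and linear response curves with
proportional (constant-CV) noise — so every pipeline stage is testable
without any raw mass-spectrometry data. All distributional defaults are
stand-ins chosen to be realistic for FFPE label-free proteomics; see
``docs/methods.md`` for what they do and do not emulate.
"""
from __future__ import annotations

from typing import Optional, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.special import expit

from .containers import (
    AbundanceMatrix,
    CalibrationSeries,
    GroundTruth,
    SampleMetadata,
    SpectralCountMatrix,
)

__all__ = [
    "LfqSimConfig",
    "PrmSimConfig",
    "simulate_lfq_dataset",
    "simulate_spectral_counts",
    "simulate_calibration_set",
    "default_calibration_levels",
]


class LfqSimConfig(BaseModel):
    """Configuration of the label-free cohort generator.

    The default cohort mirrors a two-group pure-lesion design
    (29 preinvasive vs 18 invasive cases). ``true_log2fc`` may be a single
    value applied to every differential protein or one value per protein;
    positive values mean higher abundance in ``dep_group`` (by default the
    second group listed, the invasive-like one).
    """

    seed: int = 0
    group_sizes: dict[str, int] = Field(
        default_factory=lambda: {"pure_DCIS": 29, "pure_IDC": 18}
    )
    n_proteins: int = Field(default=2000, gt=0)
    n_true_deps: int = Field(default=100, ge=0)
    true_log2fc: Union[float, list[float]] = 2.0
    dep_group: Optional[str] = None  # default: second group in group_sizes
    baseline_log2_mean: float = 20.0
    between_protein_sd: float = Field(default=4.0, ge=0)
    within_group_sd: float = Field(default=0.5, ge=0)
    loading_sd: float = Field(default=0.25, ge=0)
    dropout_midpoint: Optional[float] = 16.0  # None disables dropout
    dropout_steepness: float = Field(default=0.8, gt=0)

    @model_validator(mode="after")
    def _check(self) -> "LfqSimConfig":
        if self.n_true_deps > self.n_proteins:
            raise ValueError("n_true_deps cannot exceed n_proteins")
        if len(self.group_sizes) == 0:
            raise ValueError("at least one group required")
        for g, n in self.group_sizes.items():
            if n < 2:
                raise ValueError(f"group {g!r} needs >=2 samples, got {n}")
        if self.dep_group is not None and self.dep_group not in self.group_sizes:
            raise ValueError(
                f"dep_group {self.dep_group!r} not among groups "
                f"{list(self.group_sizes)}"
            )
        if isinstance(self.true_log2fc, list) and len(self.true_log2fc) not in (
            1,
            self.n_true_deps,
        ):
            raise ValueError("true_log2fc list must have length n_true_deps")
        return self


def default_calibration_levels(
    low: float = 0.41, high: float = 250.0, n: int = 7
) -> list[float]:
    """Geometric calibrant ladder spanning three orders of magnitude."""
    return [float(x) for x in np.geomspace(low, high, n)]


class PrmSimConfig(BaseModel):
    """Configuration of the PRM response-curve generator.

    Defaults emulate a 90-peptide panel measured over a seven-point
    calibrant ladder from 0.41 to 250 fmol of light peptide against a
    constant 50 fmol SIS spike, in triplicate, with proportional
    (constant-CV) ratio noise and low-signal blank replicates.
    """

    seed: int = 0
    n_peptides: int = Field(default=90, gt=0)
    level_fmol: list[float] = Field(default_factory=default_calibration_levels)
    replicates_per_level: int = Field(default=3, ge=2)
    n_blanks: int = Field(default=3, ge=2)
    sis_fmol: float = Field(default=50.0, gt=0)
    slope_range: tuple[float, float] = (0.01, 0.04)
    intercept: float = 0.0
    ratio_cv: float = Field(default=0.05, ge=0)
    blank_mean_fmol: float = Field(default=0.10, ge=0)
    blank_sd_fmol: float = Field(default=0.05, ge=0)

    @model_validator(mode="after")
    def _check(self) -> "PrmSimConfig":
        lv = np.asarray(self.level_fmol, dtype=float)
        if lv.size < 2 or lv.min() <= 0 or np.any(np.diff(lv) <= 0):
            raise ValueError("level_fmol must be >=2 strictly increasing positives")
        lo, hi = self.slope_range
        if not (0 < lo <= hi):
            raise ValueError("slope_range must be an interval of positive reals")
        return self


def _latent_log2(
    config: LfqSimConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw the latent log2 intensity grid and the sample table.

    latent = baseline + protein effect + group effect (differential
    proteins, in the designated group only) + per-sample loading offset
    + within-group noise.
    """
    n_prot = config.n_proteins
    width = max(4, len(str(n_prot)))
    protein_ids = [f"P{i:0{width}d}" for i in range(1, n_prot + 1)]

    sample_ids, groups = [], []
    for g, n in config.group_sizes.items():
        for k in range(1, n + 1):
            sample_ids.append(f"{g}_{k:02d}")
            groups.append(g)
    samples = pd.DataFrame(
        {
            "patient_id": [f"patient_{i + 1:03d}" for i in range(len(sample_ids))],
            "group": groups,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    protein_effect = rng.normal(0.0, config.between_protein_sd, size=n_prot)
    loading = rng.normal(0.0, config.loading_sd, size=len(sample_ids))

    dep_idx = rng.choice(n_prot, size=config.n_true_deps, replace=False)
    dep_idx.sort()
    fc = config.true_log2fc
    if isinstance(fc, list):
        fc_vec = np.resize(np.asarray(fc, dtype=float), config.n_true_deps)
    else:
        fc_vec = np.full(config.n_true_deps, float(fc))

    dep_group = config.dep_group or list(config.group_sizes)[-1]
    in_dep_group = np.asarray([g == dep_group for g in groups])

    latent = (
        config.baseline_log2_mean
        + protein_effect[:, None]
        + loading[None, :]
        + rng.normal(0.0, config.within_group_sd, size=(n_prot, len(sample_ids)))
    )
    effect_col = np.zeros(n_prot)
    effect_col[dep_idx] = fc_vec
    latent = latent + effect_col[:, None] * in_dep_group[None, :]

    truth = GroundTruth(
        dep_protein_ids=frozenset(protein_ids[i] for i in dep_idx),
        true_log2fc={protein_ids[i]: float(v) for i, v in zip(dep_idx, fc_vec)},
    )
    grid = pd.DataFrame(latent, index=protein_ids, columns=sample_ids)
    return grid, samples, truth


def _dropout_mask(
    latent: np.ndarray, config: LfqSimConfig, rng: np.random.Generator
) -> np.ndarray:
    """True where a cell is missing. P(missing) = expit(k*(midpoint - x))."""
    if config.dropout_midpoint is None:
        return np.zeros(latent.shape, dtype=bool)
    p_missing = expit(config.dropout_steepness * (config.dropout_midpoint - latent))
    return rng.random(latent.shape) < p_missing


def simulate_lfq_dataset(
    config: LfqSimConfig,
) -> tuple[AbundanceMatrix, SampleMetadata, GroundTruth]:
    """Generate a label-free cohort: abundances, sample table, and truth.

    Deterministic given ``config.seed``. Observed linear intensity is
    ``2**latent``; cells drop out with probability increasing as latent
    intensity decreases (missing-not-at-random), mirroring the
    low-abundance censoring that motivates minimum-based imputation.
    """
    rng = np.random.default_rng(config.seed)
    latent, samples, truth = _latent_log2(config, rng)

    missing = _dropout_mask(latent.to_numpy(), config, rng)
    intensity = np.power(2.0, latent.to_numpy())
    intensity[missing] = np.nan

    # plausible identification metadata; a small tail of zero-unique-peptide
    # entries exercises the identification filter
    unique_peptides = rng.poisson(5.0, size=config.n_proteins)
    length_aa = np.maximum(
        50, np.round(np.exp(rng.normal(np.log(450.0), 0.4, config.n_proteins)))
    ).astype(int)
    meta = pd.DataFrame(
        {
            "unique_peptides": unique_peptides,
            "length_aa": length_aa,
            "description": [f"simulated protein {pid}" for pid in latent.index],
        },
        index=latent.index,
    )

    matrix = AbundanceMatrix(
        intensity=pd.DataFrame(
            intensity, index=latent.index, columns=latent.columns
        ),
        protein_meta=meta,
    )
    return matrix, SampleMetadata(table=samples), truth


def simulate_spectral_counts(
    config: LfqSimConfig,
    lengths: dict[str, int],
    abundance: Optional[pd.DataFrame] = None,
    mean_count: float = 20.0,
) -> SpectralCountMatrix:
    """Draw Poisson spectral counts with rate ∝ linear abundance × length.

    If ``abundance`` (linear scale, proteins x samples) is not given, the
    latent abundance grid is regenerated from ``config`` on an independent
    seeded stream. ``mean_count`` sets the grand-mean count used to scale
    the rates to realistic magnitudes.
    """
    rng = np.random.default_rng([config.seed, 1])
    if abundance is None:
        latent, _, _ = _latent_log2(config, rng)
        abundance = np.power(2.0, latent)

    missing = [p for p in abundance.index if p not in lengths]
    if missing:
        raise ValueError(f"no length provided for protein {missing[0]!r}")
    lvec = np.asarray([lengths[p] for p in abundance.index], dtype=float)
    if np.any(lvec <= 0):
        bad = abundance.index[int(np.argmax(lvec <= 0))]
        raise ValueError(f"non-positive length for protein {bad!r}")

    rates = np.nan_to_num(abundance.to_numpy(dtype=float)) * lvec[:, None]
    mean_rate = rates.mean()
    if mean_rate > 0:
        rates = rates * (mean_count / mean_rate)
    counts = rng.poisson(rates)
    return SpectralCountMatrix(
        counts=pd.DataFrame(counts, index=abundance.index, columns=abundance.columns)
    )


def simulate_calibration_set(
    config: PrmSimConfig,
) -> tuple[list[CalibrationSeries], GroundTruth]:
    """Generate one calibration series per peptide plus the ground truth.

    The true response ratio at light amount ``x`` is ``slope*x + intercept``;
    an observed replicate is ``true * (1 + eps)`` with
    ``eps ~ Normal(0, ratio_cv)``, so the replicate SD is proportional to
    the level — the heteroscedasticity that justifies 1/x² regression
    weights. Blank replicates are drawn as small concentrations
    ``Normal(blank_mean_fmol, blank_sd_fmol)`` (floored at 0) mapped
    through the same true curve.
    """
    rng = np.random.default_rng(config.seed)
    levels = np.asarray(config.level_fmol, dtype=float)
    width = max(3, len(str(config.n_peptides)))
    series: list[CalibrationSeries] = []
    truth = GroundTruth()

    for i in range(config.n_peptides):
        pid = f"pep{i + 1:0{width}d}"
        slope = rng.uniform(*config.slope_range)
        intercept = config.intercept
        ratios = []
        for x in levels:
            true = slope * x + intercept
            eps = rng.normal(0.0, config.ratio_cv, size=config.replicates_per_level)
            ratios.append(np.maximum(0.0, true * (1.0 + eps)))
        blank_conc = np.maximum(
            0.0, rng.normal(config.blank_mean_fmol, config.blank_sd_fmol, config.n_blanks)
        )
        blank_ratios = np.maximum(0.0, slope * blank_conc + intercept)
        series.append(
            CalibrationSeries(
                peptide_id=pid,
                level_fmol=levels.copy(),
                ratios=ratios,
                blank_ratios=blank_ratios,
                sis_fmol=config.sis_fmol,
            )
        )
        truth.true_slope[pid] = float(slope)
        truth.true_intercept[pid] = float(intercept)
    return series, truth
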