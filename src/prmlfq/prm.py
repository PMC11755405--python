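"""PRM absolute quantitation: weighted response curves, calibration-level
acceptance, LOD/LOQ, and SIS-normalized concentration estimation.

A response curve relates the light/heavy (analyte/internal-standard)
response ratio to the spiked light-peptide amount. The fit is a linear
regression of per-level mean ratios on nominal fmol with 1/x² weights —
the standard bioanalytical choice when the ratio CV, not the ratio SD, is
constant across the calibration range. Calibration levels must satisfy
per-level precision (<20% CV) and accuracy (80–120% of nominal,
back-calculated) criteria; acceptance is iterated with refitting until the
accepted set is stable, and a curve is valid only if the accepted set
contains at least three consecutive ladder levels.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .containers import CalibrationSeries, ConcentrationMatrix, SampleMetadata
from .diffexp import ComparisonSpec, run_comparison
from .preprocess import impute_min_per_sample

__all__ = [
    "LevelQC",
    "ResponseCurve",
    "PeptideConcentration",
    "weighted_line_fit",
    "fit_response_curve",
    "compute_lod",
    "quantify_endogenous",
    "filter_prm_matrix",
    "prm_differential",
]


@dataclass
class LevelQC:
    """Per-calibration-level precision/accuracy verdict."""

    nominal_fmol: float
    cv_percent: float
    accuracy_percent: float
    accepted: bool


@dataclass
class PeptideConcentration:
    """Absolute concentration of one peptide in one sample."""

    peptide_id: str
    sample_id: str
    fmol_per_ug: float
    censoring: str  # quantified | below_LOQ | below_LOD | not_detected


def weighted_line_fit(x, y, weights) -> tuple[float, float]:
    """Weighted least-squares line y = slope*x + intercept.

    Solved by ordinary least squares on the sqrt(weight)-scaled design.
    Returns (slope, intercept).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two points to fit a line")
    sw = np.sqrt(w)
    design = np.column_stack([x * sw, sw])
    coef, *_ = np.linalg.lstsq(design, y * sw, rcond=None)
    return float(coef[0]), float(coef[1])


def _runs_of_consecutive(indices: list[int]) -> list[list[int]]:
    """Split sorted ladder indices into maximal runs of consecutive ints."""
    runs: list[list[int]] = []
    for i in sorted(indices):
        if runs and i == runs[-1][-1] + 1:
            runs[-1].append(i)
        else:
            runs.append([i])
    return runs


class ResponseCurve(BaseEstimator):
    """Calibration-curve estimator for one peptide.

    Parameters
    ----------
    cv_max_percent : float
        Maximum per-level replicate CV (default 20).
    accuracy_range : (float, float)
        Acceptable back-calculated accuracy window in percent
        (default (80, 120)).
    min_consecutive : int
        Minimum run of consecutive ladder levels for a valid curve
        (default 3).
    max_iter : int
        Cap on the accept/refit iterations (default 10).

    Fitted attributes: ``slope_``, ``intercept_``, ``r_squared_``,
    ``accepted_levels_`` (nominal fmol of the retained consecutive run),
    ``level_qc_`` (list of :class:`LevelQC` under the final fit),
    ``lod_fmol_``, ``loq_fmol_``, ``valid_`` and ``reason_``.
    """

    def __init__(
        self,
        cv_max_percent: float = 20.0,
        accuracy_range: tuple[float, float] = (80.0, 120.0),
        min_consecutive: int = 3,
        max_iter: int = 10,
    ):
        self.cv_max_percent = cv_max_percent
        self.accuracy_range = accuracy_range
        self.min_consecutive = min_consecutive
        self.max_iter = max_iter

    # -- internals -------------------------------------------------------

    def _level_cv(self, ratios: np.ndarray) -> float:
        mean = ratios.mean()
        if mean == 0:
            return math.inf
        return 100.0 * ratios.std(ddof=1) / mean

    def _qc(
        self, series: CalibrationSeries, slope: float, intercept: float
    ) -> list[LevelQC]:
        qcs = []
        lo, hi = self.accuracy_range
        for x, ratios in zip(series.level_fmol, series.ratios):
            cv = self._level_cv(ratios)
            back = (ratios - intercept) / slope
            acc = 100.0 * back.mean() / x
            qcs.append(
                LevelQC(
                    nominal_fmol=float(x),
                    cv_percent=float(cv),
                    accuracy_percent=float(acc),
                    accepted=bool(cv < self.cv_max_percent and lo <= acc <= hi),
                )
            )
        return qcs

    def _fit_levels(self, series: CalibrationSeries, idx: list[int]):
        x = series.level_fmol[idx]
        y = np.asarray([series.ratios[i].mean() for i in idx])
        slope, intercept = weighted_line_fit(x, y, 1.0 / x**2)
        return slope, intercept, x, y

    def _invalid(self, reason: str) -> "ResponseCurve":
        self.valid_ = False
        self.reason_ = reason
        self.accepted_levels_ = np.array([])
        self.slope_ = self.intercept_ = self.r_squared_ = float("nan")
        self.lod_fmol_ = self.loq_fmol_ = float("nan")
        return self

    # -- API -------------------------------------------------------------

    def fit(self, series: CalibrationSeries) -> "ResponseCurve":
        self.series_ = series
        self.sis_fmol_ = series.sis_fmol
        self.peptide_id_ = series.peptide_id
        if series.n_levels < self.min_consecutive:
            return self._invalid("fewer than three calibration levels")
        for k, r in enumerate(series.ratios):
            if r.size < 2:
                return self._invalid(
                    f"level {series.level_fmol[k]} has fewer than two replicates"
                )

        included = list(range(series.n_levels))
        slope = intercept = float("nan")
        for _ in range(self.max_iter):
            if len(included) < 2:
                return self._invalid("fewer than three surviving levels")
            slope, intercept, _, _ = self._fit_levels(series, included)
            if slope <= 0:
                return self._invalid("non-positive slope")
            qcs = self._qc(series, slope, intercept)
            new_included = [i for i, qc in enumerate(qcs) if qc.accepted]
            if new_included == included:
                break
            included = new_included

        runs = [
            r for r in _runs_of_consecutive(included) if len(r) >= self.min_consecutive
        ]
        if not runs:
            return self._invalid(
                "no run of three consecutive accepted calibration levels"
            )
        run = runs[-1]  # the run containing the highest accepted level

        slope, intercept, x, y = self._fit_levels(series, run)
        if slope <= 0:
            return self._invalid("non-positive slope")
        fitted = slope * x + intercept
        ss_res = float(np.sum((y - fitted) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        self.r_squared_ = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        self.slope_ = slope
        self.intercept_ = intercept
        self.level_qc_ = self._qc(series, slope, intercept)
        self.accepted_levels_ = series.level_fmol[run]
        self.loq_fmol_ = float(self.accepted_levels_.min())
        self.valid_ = True
        self.reason_ = "ok"
        self.lod_fmol_ = (
            self._lod(series.blank_ratios) if series.blank_ratios.size >= 2 else float("nan")
        )
        return self

    def _lod(self, blank_ratios: np.ndarray) -> float:
        back = (np.asarray(blank_ratios, dtype=float) - self.intercept_) / self.slope_
        lod = back.mean() + 3.3 * back.std(ddof=1)
        return float(max(lod, 0.0))

    def predict(self, ratios) -> np.ndarray:
        """Back-calculate light-peptide amounts (fmol) from observed ratios."""
        if not getattr(self, "valid_", False):
            raise ValueError("cannot back-calculate from an invalid curve")
        return (np.asarray(ratios, dtype=float) - self.intercept_) / self.slope_

    def quantify(
        self,
        observed_ratio: Optional[float],
        protein_input_ug: float = 1.0,
        sis_spike_fmol: Optional[float] = None,
        sample_id: str = "",
    ) -> PeptideConcentration:
        """Estimate an unknown sample's concentration with censoring.

        ``sis_spike_fmol`` must match the SIS amount the curve was built
        with (curves are SIS-specific); ``protein_input_ug`` is the digested
        protein input the SIS was spiked into (1 ug in the assay design).
        """
        if not getattr(self, "valid_", False):
            raise ValueError("cannot quantify with an invalid curve")
        if self.slope_ == 0:
            raise ValueError("zero slope")
        if protein_input_ug <= 0:
            raise ValueError("protein_input_ug must be positive")
        if sis_spike_fmol is not None and not math.isclose(
            sis_spike_fmol, self.sis_fmol_, rel_tol=1e-9
        ):
            raise ValueError(
                f"SIS spike ({sis_spike_fmol} fmol) differs from the curve's "
                f"({self.sis_fmol_} fmol)"
            )
        if observed_ratio is None or (
            isinstance(observed_ratio, float) and math.isnan(observed_ratio)
        ):
            return PeptideConcentration(
                self.peptide_id_, sample_id, float("nan"), "not_detected"
            )
        fmol = (float(observed_ratio) - self.intercept_) / self.slope_
        if fmol < 0:
            fmol = 0.0
        lod = self.lod_fmol_ if not math.isnan(self.lod_fmol_) else 0.0
        if fmol < lod:
            censoring = "below_LOD"
        elif fmol < self.loq_fmol_:
            censoring = "below_LOQ"
        else:
            censoring = "quantified"
        return PeptideConcentration(
            self.peptide_id_, sample_id, fmol / protein_input_ug, censoring
        )


def fit_response_curve(
    series: CalibrationSeries, **params
) -> tuple[ResponseCurve, list[LevelQC]]:
    """Fit one peptide's response curve; returns (fit, per-level QC)."""
    fit = ResponseCurve(**params).fit(series)
    qcs = fit.level_qc_ if fit.valid_ else []
    return fit, qcs


def compute_lod(fit: ResponseCurve, blank_ratios) -> float:
    """LOD = mean + 3.3 x SD of blank back-calculated concentrations."""
    if not getattr(fit, "valid_", False):
        raise ValueError("LOD requires a valid curve fit")
    blank_ratios = np.asarray(blank_ratios, dtype=float)
    if blank_ratios.size < 2:
        raise ValueError("LOD requires at least two blank replicates")
    return fit._lod(blank_ratios)


def quantify_endogenous(
    fit: ResponseCurve,
    observed_ratio: Optional[float],
    protein_input_ug: float = 1.0,
    sis_spike_fmol: Optional[float] = None,
    sample_id: str = "",
) -> PeptideConcentration:
    return fit.quantify(observed_ratio, protein_input_ug, sis_spike_fmol, sample_id)


def filter_prm_matrix(
    conc: ConcentrationMatrix, max_missing_frac: float = 0.6
) -> ConcentrationMatrix:
    """Drop peptides not detected in more than ``max_missing_frac`` of samples.

    The boundary is strict: a peptide missing in exactly the threshold
    fraction is retained.
    """
    if not (0 < max_missing_frac <= 1):
        raise ValueError("max_missing_frac must lie in (0, 1]")
    missing_frac = (conc.censoring == "not_detected").mean(axis=1)
    keep = missing_frac <= max_missing_frac
    return ConcentrationMatrix(
        values=conc.values.loc[keep].copy(), censoring=conc.censoring.loc[keep].copy()
    )


def prm_differential(
    conc: ConcentrationMatrix,
    meta: SampleMetadata,
    spec: ComparisonSpec,
    impute_factor: float = 1.5,
) -> pd.DataFrame:
    """Differential analysis of PRM concentrations between two groups.

    Cells censored below the LOD or not detected are treated as missing,
    imputed with the per-sample minimum rule, log2-transformed, and passed
    to the standard comparison.
    """
    vals = conc.values.where(~conc.censoring.isin(["below_LOD", "not_detected"]))
    filled = impute_min_per_sample(vals, impute_factor)
    log2 = pd.DataFrame(
        np.log2(filled.to_numpy(dtype=float)),
        index=filled.index,
        columns=filled.columns,
    )
    return run_comparison(log2, meta, spec)
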