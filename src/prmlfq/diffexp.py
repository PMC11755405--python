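"""Per-protein differential expression with adaptive FDR control.

Proteins are compared between two sample groups by unpaired two-tailed
t-tests on log2 intensities, adjusted jointly by the two-stage
Benjamini–Krieger step-up, and called differential when both the q-value
and absolute log2 fold-change thresholds are met (defaults q < 0.01,
|log2FC| > 1). The fold change is the difference of log2 group means,
mean_b − mean_a, so positive values are higher in group_b.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .containers import ProcessedMatrix, SampleMetadata
from .stats import bky_adjust, t_test_matrix

__all__ = [
    "ComparisonSpec",
    "DifferentialExpression",
    "run_comparison",
    "call_deps",
    "build_ranked_list",
]

RECORD_COLUMNS = [
    "protein_id",
    "mean_a",
    "mean_b",
    "log2fc",
    "t_stat",
    "df",
    "p_value",
    "q_value",
    "is_dep",
]


@dataclass
class ComparisonSpec:
    """Which groups to compare and at which thresholds to call DEPs."""

    group_a: str
    group_b: str
    q_threshold: float = 0.01
    log2fc_threshold: float = 1.0
    fdr_level: float = 0.01

    def __post_init__(self) -> None:
        if self.group_a == self.group_b:
            raise ValueError("group_a and group_b must differ")
        if not (0 < self.q_threshold < 1) or not (0 < self.fdr_level < 1):
            raise ValueError("q_threshold and fdr_level must lie in (0, 1)")
        if self.log2fc_threshold < 0:
            raise ValueError("log2fc_threshold must be >= 0")


class DifferentialExpression(BaseEstimator):
    """Two-group differential-expression estimator.

    Parameters mirror :class:`ComparisonSpec`; ``equal_var=True`` selects
    the classic Student pooled-variance t (the default the study's
    statistics tool uses), ``False`` the Welch variant.

    After :meth:`fit`, ``results_`` holds one row per protein
    (columns: protein_id, mean_a, mean_b, log2fc, t_stat, df, p_value,
    q_value, is_dep) sorted by q then p, and ``n_deps_`` the DEP count.
    """

    def __init__(
        self,
        group_a: str,
        group_b: str,
        q_threshold: float = 0.01,
        log2fc_threshold: float = 1.0,
        fdr_level: float = 0.01,
        equal_var: bool = True,
    ):
        self.group_a = group_a
        self.group_b = group_b
        self.q_threshold = q_threshold
        self.log2fc_threshold = log2fc_threshold
        self.fdr_level = fdr_level
        self.equal_var = equal_var

    def _spec(self) -> ComparisonSpec:
        return ComparisonSpec(
            self.group_a,
            self.group_b,
            self.q_threshold,
            self.log2fc_threshold,
            self.fdr_level,
        )

    def fit(
        self, X: Union[ProcessedMatrix, pd.DataFrame], meta: SampleMetadata
    ) -> "DifferentialExpression":
        spec = self._spec()
        log2 = X.log2() if isinstance(X, ProcessedMatrix) else X
        if log2.shape[0] == 0:
            raise ValueError("no proteins left to test")

        cols = set(log2.columns)
        samples_a = [s for s in meta.samples_in(spec.group_a) if s in cols]
        samples_b = [s for s in meta.samples_in(spec.group_b) if s in cols]
        for g, ss in ((spec.group_a, samples_a), (spec.group_b, samples_b)):
            if len(ss) < 2:
                raise ValueError(f"group {g!r} has fewer than two samples")

        a = log2[samples_a].to_numpy(dtype=float)
        b = log2[samples_b].to_numpy(dtype=float)
        if np.isnan(a).any() or np.isnan(b).any():
            raise ValueError("log2 matrix contains missing values; impute first")

        t, df, p, _ = t_test_matrix(a, b, equal_var=self.equal_var)
        adj = bky_adjust(p, fdr_level=spec.fdr_level)
        mean_a = a.mean(axis=1)
        mean_b = b.mean(axis=1)
        log2fc = mean_b - mean_a

        res = pd.DataFrame(
            {
                "protein_id": log2.index,
                "mean_a": mean_a,
                "mean_b": mean_b,
                "log2fc": log2fc,
                "t_stat": t,
                "df": df,
                "p_value": p,
                "q_value": adj.q_values,
            }
        )
        res["is_dep"] = (res["q_value"] < spec.q_threshold) & (
            res["log2fc"].abs() > spec.log2fc_threshold
        )
        res = res.sort_values(
            ["q_value", "p_value", "protein_id"], kind="stable"
        ).reset_index(drop=True)
        self.results_ = res
        self.m0_hat_ = adj.m0_hat
        self.n_deps_ = int(res["is_dep"].sum())
        return self

    def fit_predict(self, X, meta) -> pd.DataFrame:
        return self.fit(X, meta).results_


def run_comparison(
    m: Union[ProcessedMatrix, pd.DataFrame],
    meta: SampleMetadata,
    spec: ComparisonSpec,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Run the full per-protein comparison; one result row per protein."""
    est = DifferentialExpression(
        spec.group_a,
        spec.group_b,
        spec.q_threshold,
        spec.log2fc_threshold,
        spec.fdr_level,
        equal_var,
    )
    return est.fit(m, meta).results_


def call_deps(records: pd.DataFrame, spec: ComparisonSpec) -> pd.DataFrame:
    """(Re-)flag differential proteins at the spec's thresholds."""
    out = records.copy()
    out["is_dep"] = (out["q_value"] < spec.q_threshold) & (
        out["log2fc"].abs() > spec.log2fc_threshold
    )
    return out


def build_ranked_list(records: pd.DataFrame, p_floor: float = 1e-300) -> pd.DataFrame:
    """Signed significance ranking for enrichment tools.

    rank_score = sign(log2fc) * (-log10 p), p floored at ``p_floor``;
    descending by score, ties broken by protein id.
    """
    p = records["p_value"].clip(lower=p_floor)
    score = np.sign(records["log2fc"].to_numpy()) * (-np.log10(p.to_numpy()))
    out = pd.DataFrame(
        {"protein_id": records["protein_id"], "rank_score": score}
    )
    out = out.sort_values(
        ["rank_score", "protein_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return out
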