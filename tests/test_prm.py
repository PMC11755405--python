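"""Response-curve fitting, level acceptance, LOD/LOQ, quantitation,
missingness filtering, and PRM differential analysis."""
import numpy as np
import pandas as pd
import pytest

from prmlfq import (
    ComparisonSpec,
    ConcentrationMatrix,
    PrmSimConfig,
    ResponseCurve,
    compute_lod,
    filter_prm_matrix,
    fit_response_curve,
    prm_differential,
    quantify_endogenous,
    simulate_calibration_set,
    weighted_line_fit,
)
from .conftest import make_metadata, make_series


class TestWeightedFit:
    def test_matches_transformed_ols(self):
        """1/x^2 WLS == OLS on y/x = intercept*(1/x) + slope."""
        import statsmodels.api as sm

        rng = np.random.default_rng(0)
        for _ in range(25):
            x = np.sort(rng.uniform(0.5, 250.0, size=7))
            y = 0.02 * x + 0.1 + rng.normal(0, 0.02 * x)
            slope, intercept = weighted_line_fit(x, y, 1.0 / x**2)
            ref = sm.OLS(y / x, np.column_stack([np.ones_like(x), 1.0 / x])).fit()
            assert slope == pytest.approx(ref.params[0], rel=1e-8)
            assert intercept == pytest.approx(ref.params[1], rel=1e-8)


class TestResponseCurveFit:
    def test_noiseless_line_recovered(self):
        fit, qcs = fit_response_curve(make_series(slope=0.02))
        assert fit.valid_
        assert fit.slope_ == pytest.approx(0.02, rel=1e-12)
        assert fit.intercept_ == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared_ == pytest.approx(1.0)
        assert len(fit.accepted_levels_) == 7
        assert all(qc.accepted for qc in qcs)
        assert fit.loq_fmol_ == pytest.approx(0.41, rel=1e-6)

    def test_high_cv_level_excluded(self):
        noise = [np.zeros(3)] * 7
        noise[0] = np.array([-0.3, 0.0, 0.3])  # ~30% CV at the lowest level
        fit, _ = fit_response_curve(make_series(noise=noise))
        assert fit.valid_
        assert len(fit.accepted_levels_) == 6
        assert fit.loq_fmol_ == pytest.approx(make_series().level_fmol[1])

    def test_inaccurate_level_excluded_and_loq_moves_up(self):
        # a strongly biased lowest level back-calculates far outside 80-120%
        # and is dropped; the LOQ becomes the lowest *accepted* level
        noise = [np.zeros(3)] * 7
        noise[0] = np.full(3, 1.0)
        fit, qcs = fit_response_curve(make_series(noise=noise))
        assert fit.valid_
        levels = make_series().level_fmol
        assert levels[0] not in fit.accepted_levels_
        assert not qcs[0].accepted
        assert not (80.0 <= qcs[0].accuracy_percent <= 120.0)
        assert fit.loq_fmol_ == pytest.approx(fit.accepted_levels_.min())
        assert fit.loq_fmol_ > levels[0]

    def test_highest_run_kept_when_runs_tie(self):
        noise = [np.zeros(3)] * 7
        noise[3] = np.array([-0.4, 0.0, 0.4])  # break the ladder in the middle
        fit, _ = fit_response_curve(make_series(noise=noise))
        levels = make_series().level_fmol
        assert fit.valid_
        np.testing.assert_allclose(fit.accepted_levels_, levels[4:])
        assert fit.loq_fmol_ == pytest.approx(levels[4])

    def test_too_few_surviving_levels_invalid_not_raising(self):
        noise = [np.array([-0.5, 0.0, 0.5])] * 5 + [np.zeros(3)] * 2
        fit, _ = fit_response_curve(make_series(noise=noise))
        assert not fit.valid_

    def test_negative_slope_invalid(self):
        fit = ResponseCurve().fit(make_series(slope=-0.01, blank_conc=(0, 0)))
        assert not fit.valid_
        assert "slope" in fit.reason_

    def test_acceptance_deterministic(self):
        s = make_series(noise=[np.array([0.05, -0.02, 0.01])] * 7)
        a = ResponseCurve().fit(s)
        b = ResponseCurve().fit(s)
        assert np.array_equal(a.accepted_levels_, b.accepted_levels_)
        assert a.slope_ == b.slope_


class TestLod:
    def test_worked_example(self):
        # identity curve: ratio == concentration, blanks 0.9/1.0/1.1 fmol
        fit = ResponseCurve().fit(
            make_series(slope=1.0, levels=[1, 2, 4, 8, 16, 32, 64])
        )
        lod = compute_lod(fit, [0.9, 1.0, 1.1])
        assert lod == pytest.approx(1.0 + 3.3 * 0.1, abs=1e-12)

    def test_zero_variance_blanks(self):
        fit = ResponseCurve().fit(
            make_series(slope=1.0, levels=[1, 2, 4, 8, 16, 32, 64])
        )
        assert compute_lod(fit, [0.5, 0.5, 0.5]) == pytest.approx(0.5)

    def test_monotone_in_blank_sd(self):
        fit = ResponseCurve().fit(
            make_series(slope=1.0, levels=[1, 2, 4, 8, 16, 32, 64])
        )
        narrow = compute_lod(fit, [0.9, 1.0, 1.1])
        wide = compute_lod(fit, [0.8, 1.0, 1.2])
        assert wide > narrow

    def test_fit_carries_lod_from_series_blanks(self):
        fit = ResponseCurve().fit(
            make_series(slope=1.0, levels=[1, 2, 4, 8, 16, 32, 64],
                        blank_conc=(0.9, 1.0, 1.1))
        )
        assert fit.lod_fmol_ == pytest.approx(1.33, abs=1e-12)

    def test_invalid_fit_rejected(self):
        fit = ResponseCurve().fit(make_series(slope=-0.01))
        with pytest.raises(ValueError):
            compute_lod(fit, [0.9, 1.0, 1.1])


class TestQuantify:
    def _fit(self):
        return ResponseCurve().fit(
            make_series(slope=0.02, blank_conc=(0.05, 0.1, 0.15))
        )

    def test_on_line_ratio_recovers_concentration(self):
        fit = self._fit()
        pc = quantify_endogenous(fit, 0.02 * 50.0, 1.0, 50.0, "s1")
        assert pc.fmol_per_ug == pytest.approx(50.0, rel=1e-12)
        assert pc.censoring == "quantified"

    def test_ratio_at_intercept_is_below_lod(self):
        fit = self._fit()
        pc = quantify_endogenous(fit, fit.intercept_, 1.0, 50.0)
        assert pc.fmol_per_ug == 0.0
        assert pc.censoring == "below_LOD"

    def test_between_lod_and_loq_is_censored_below_loq(self):
        fit = self._fit()
        conc = 0.5 * (fit.lod_fmol_ + fit.loq_fmol_)
        pc = quantify_endogenous(fit, fit.slope_ * conc, 1.0, 50.0)
        assert pc.censoring == "below_LOQ"

    def test_missing_ratio_not_detected(self):
        pc = quantify_endogenous(self._fit(), float("nan"), 1.0, 50.0)
        assert pc.censoring == "not_detected"

    def test_protein_input_scales_concentration(self):
        fit = self._fit()
        pc = quantify_endogenous(fit, fit.slope_ * 100.0, 2.0, 50.0)
        assert pc.fmol_per_ug == pytest.approx(50.0)

    def test_sis_mismatch_rejected(self):
        with pytest.raises(ValueError, match="SIS"):
            quantify_endogenous(self._fit(), 1.0, 1.0, 25.0)

    def test_noiseless_simulation_round_trip(self):
        cfg = PrmSimConfig(seed=6, n_peptides=10, ratio_cv=0.0, blank_sd_fmol=0.0)
        series, truth = simulate_calibration_set(cfg)
        for s in series:
            fit = ResponseCurve().fit(s)
            true_slope = truth.true_slope[s.peptide_id]
            for conc in (1.0, 25.0, 180.0):
                pc = fit.quantify(true_slope * conc, 1.0, cfg.sis_fmol)
                assert pc.fmol_per_ug == pytest.approx(conc, rel=1e-9)


class TestMissingnessFilter:
    def _conc(self, missing_per_peptide, n_samples=100):
        ids = list(missing_per_peptide)
        values = pd.DataFrame(1.0, index=ids, columns=range(n_samples))
        cens = pd.DataFrame("quantified", index=ids, columns=range(n_samples))
        for pid, n_missing in missing_per_peptide.items():
            cens.loc[pid, cens.columns[:n_missing]] = "not_detected"
            values.loc[pid, values.columns[:n_missing]] = np.nan
        return ConcentrationMatrix(values=values, censoring=cens)

    def test_boundary_is_strictly_more_than(self):
        conc = self._conc({"pep_61": 61, "pep_60": 60, "pep_00": 0})
        out = filter_prm_matrix(conc, max_missing_frac=0.6)
        assert list(out.values.index) == ["pep_60", "pep_00"]

    def test_below_loq_cells_do_not_count_as_missing(self):
        conc = self._conc({"pep": 0})
        conc.censoring.iloc[0, :80] = "below_LOQ"
        out = filter_prm_matrix(conc)
        assert len(out.values) == 1


class TestPrmDifferential:
    def _meta(self, n=8):
        return make_metadata(
            {**{f"a{i}": "gA" for i in range(n)},
             **{f"b{i}": "gB" for i in range(n)}}
        )

    def test_identical_groups_give_no_hits(self):
        meta = self._meta()
        samples = meta.sample_ids
        values = pd.DataFrame(
            np.tile(np.linspace(1, 5, 10)[:, None], (1, 16)),
            index=[f"pep{i}" for i in range(10)], columns=samples,
        )
        cens = pd.DataFrame("quantified", index=values.index, columns=samples)
        rec = prm_differential(
            ConcentrationMatrix(values, cens), meta, ComparisonSpec("gA", "gB")
        )
        assert not rec["is_dep"].any()

    def test_noise_free_fourfold_difference(self):
        meta = self._meta()
        samples = meta.sample_ids
        values = pd.DataFrame(1.0, index=["pep_eff", "pep_null"], columns=samples)
        values.loc["pep_eff", [s for s in samples if s.startswith("b")]] = 4.0
        cens = pd.DataFrame("quantified", index=values.index, columns=samples)
        rec = prm_differential(
            ConcentrationMatrix(values, cens), meta, ComparisonSpec("gA", "gB")
        ).set_index("protein_id")
        assert rec.loc["pep_eff", "log2fc"] == pytest.approx(2.0, abs=1e-12)

    def test_single_true_effect_found_in_most_seeds(self):
        """90-peptide panel, one 4-fold effect: found at q<0.05 in >=9/10 seeds."""
        hits = 0
        meta = self._meta()
        samples = meta.sample_ids
        b_cols = [s for s in samples if s.startswith("b")]
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            log2 = rng.normal(2.0, 1.0, size=(90, 1)) + rng.normal(
                0.0, 0.3, size=(90, 16)
            )
            values = pd.DataFrame(
                2.0 ** log2, index=[f"pep{i:02d}" for i in range(90)],
                columns=samples,
            )
            values.loc["pep00", b_cols] *= 4.0
            cens = pd.DataFrame("quantified", index=values.index, columns=samples)
            rec = prm_differential(
                ConcentrationMatrix(values, cens), meta,
                ComparisonSpec("gA", "gB", q_threshold=0.05, fdr_level=0.05),
            )
            sig = set(rec.loc[rec["q_value"] < 0.05, "protein_id"])
            if sig == {"pep00"}:
                hits += 1
        assert hits >= 9

    def test_below_lod_cells_are_imputed(self):
        meta = self._meta(n=2)
        samples = meta.sample_ids
        values = pd.DataFrame(
            [[10.0, 10.0, 10.0, 10.0], [5.0, np.nan, 5.0, 5.0]],
            index=["pep1", "pep2"], columns=samples,
        )
        cens = pd.DataFrame(
            [["quantified"] * 4,
             ["quantified", "below_LOD", "quantified", "quantified"]],
            index=values.index, columns=samples,
        )
        rec = prm_differential(
            ConcentrationMatrix(values, cens), meta, ComparisonSpec("gA", "gB")
        )
        assert np.isfinite(rec["log2fc"]).all()
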