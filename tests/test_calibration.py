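"""Monte-Carlo parameter identification, scale calibration and dose matching."""

import numpy as np
import pandas as pd
import pytest

import codeine_pbpk as cp
from codeine_pbpk._data import load_packaged_yaml
from codeine_pbpk.calibration import (FitSpec, calibrate_cyp2d6_scale,
                                      make_simulator, match_dose,
                                      monte_carlo_fit)


def analytic_simulator(params, times_h):
    """One-compartment toy: conc = amplitude * exp(-ke * t)."""
    t = np.asarray(times_h, float)
    conc = params["kcat_2D6"] * np.exp(-0.3 * t)   # amplitude ~ turnover
    return pd.DataFrame({"analyte": "morphine", "time_h": t,
                         "conc_ng_per_ml": conc})


def observed_from(sim_fn, params, times):
    df = sim_fn(params, times)
    df = df.rename(columns={})
    df.insert(0, "study_id", "truth")
    return df


TIMES = np.array([0.5, 1.0, 2.0, 4.0, 8.0])


class TestFitSpec:
    def test_bounds_must_be_ordered(self):
        with pytest.raises(ValueError, match="bounds"):
            FitSpec(parameters={"kcat_2D6": (2.0, 1.0)})

    def test_log_scale_needs_positive_bounds(self):
        with pytest.raises(ValueError, match="positive"):
            FitSpec(parameters={"kcat_2D6": (0.0, 1.0)})

    def test_n_at_least_one(self):
        with pytest.raises(ValueError, match="n"):
            FitSpec(parameters={"kcat_2D6": (0.1, 1.0)}, n=0)


class TestMonteCarloFit:
    def test_single_sample_is_returned(self):
        obs = observed_from(analytic_simulator, {"kcat_2D6": 1.6}, TIMES)
        spec = FitSpec(parameters={"kcat_2D6": (0.1, 5.0)}, n=1, seed=4)
        res = monte_carlo_fit(analytic_simulator, obs, spec)
        assert len(res.objective_trace) == 1
        assert res.best_parameters["kcat_2D6"] == pytest.approx(
            res.sampled_parameters["kcat_2D6"].iloc[0])

    def test_best_is_argmin_of_trace(self):
        obs = observed_from(analytic_simulator, {"kcat_2D6": 1.6}, TIMES)
        spec = FitSpec(parameters={"kcat_2D6": (0.1, 5.0)}, n=200, seed=1)
        res = monte_carlo_fit(analytic_simulator, obs, spec)
        assert res.best_objective == res.objective_trace.min()

    def test_exact_data_gives_near_zero_objective(self):
        obs = observed_from(analytic_simulator, {"kcat_2D6": 1.6}, TIMES)
        spec = FitSpec(parameters={"kcat_2D6": (0.1, 5.0)}, n=500, seed=2)
        res = monte_carlo_fit(analytic_simulator, obs, spec)
        assert res.best_objective < 1e-3
        assert res.best_parameters["kcat_2D6"] == pytest.approx(1.6, rel=0.05)

    def test_seeded_fit_reproducible(self):
        obs = observed_from(analytic_simulator, {"kcat_2D6": 1.6}, TIMES)
        spec = FitSpec(parameters={"kcat_2D6": (0.1, 5.0)}, n=50, seed=9)
        a = monte_carlo_fit(analytic_simulator, obs, spec)
        b = monte_carlo_fit(analytic_simulator, obs, spec)
        assert a.best_parameters == b.best_parameters
        assert np.array_equal(a.objective_trace, b.objective_trace)

    def test_polish_improves_or_keeps_best(self):
        obs = observed_from(analytic_simulator, {"kcat_2D6": 1.6}, TIMES)
        rough = monte_carlo_fit(analytic_simulator, obs, FitSpec(
            parameters={"kcat_2D6": (0.1, 5.0)}, n=20, seed=3))
        polished = monte_carlo_fit(analytic_simulator, obs, FitSpec(
            parameters={"kcat_2D6": (0.1, 5.0)}, n=20, seed=3, polish=True))
        assert polished.best_objective <= rough.best_objective

    def test_empty_observation_rejected(self):
        spec = FitSpec(parameters={"kcat_2D6": (0.1, 5.0)}, n=1)
        with pytest.raises(ValueError, match="non-empty"):
            monte_carlo_fit(analytic_simulator, pd.DataFrame(), spec)


class TestParameterRecoveryPBPK:
    """Noise-free recovery of generating parameters through the full model."""

    @pytest.mark.parametrize("param,truth,bounds,dose", [
        ("dissolution_t50", 5.0, (1.0, 60.0), 30.0),
        ("km_2D6", 100.0, (10.0, 1000.0), 1500.0),  # dose spans Km
    ])
    def test_recovery_within_quarter(self, asian, codeine, morphine,
                                     param, truth, bounds, dose):
        regimen = cp.Regimen(
            dose_mg=dose,
            formulation=cp.FormulationSpec.from_compound(codeine, "tablet"))
        sim = make_simulator(asian, codeine, morphine, regimen)
        times = np.array([0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0])
        obs = sim({param: truth}, times)
        obs.insert(0, "study_id", "truth")
        spec = FitSpec(parameters={param: bounds}, n=400, seed=17)
        res = monte_carlo_fit(sim, obs, spec)
        assert res.best_parameters[param] == pytest.approx(truth, rel=0.25)


class TestScaleCalibration:
    def test_rederived_scale_matches_frozen_constant(self):
        frozen = load_packaged_yaml("constants.yaml")["enzyme_scales"]["CYP2D6"]
        assert calibrate_cyp2d6_scale() == pytest.approx(frozen, rel=0.02)


class TestMatchDose:
    def test_toy_linear_kinetics_closed_form(self):
        # morphine AUC proportional to dose * kcat: matched dose = 30*1.6/kcat
        for score, kcat in [(0.75, 0.6), (1.5, 1.6), (2.75, 2.6)]:
            auc_fn = lambda dose: dose * kcat * 0.01
            ref = 30.0 * 1.6 * 0.01
            matched = match_dose(score, ref, auc_fn=auc_fn, increment_mg=1.0)
            assert matched == pytest.approx(30.0 * 1.6 / kcat, abs=1.0)

    def test_matched_dose_monotone_in_activity_score(self):
        doses = []
        for kcat in (0.6, 1.6, 2.6):
            doses.append(match_dose(1.0, 0.48,
                                    auc_fn=lambda d: d * kcat * 0.01,
                                    increment_mg=1.0))
        assert doses[0] > doses[1] > doses[2]

    def test_em_identity_returns_reference_dose(self, asian, codeine, morphine,
                                                em_result):
        ref_auc = em_result.nca("morphine").auc_0_inf
        matched = match_dose(1.5, ref_auc, individual=asian, parent=codeine,
                             metabolite=morphine)
        assert matched == pytest.approx(30.0, abs=5.0)

    def test_unattainable_target_reports_bounds(self):
        with pytest.raises(ValueError, match="not bracketed"):
            match_dose(1.5, 1e9, auc_fn=lambda d: d * 0.01)

    def test_excessive_dose_warns(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="codeine_pbpk.calibration"):
            match_dose(0.0, 15.0, auc_fn=lambda d: d * 0.01,
                       dose_bounds_mg=(5.0, 3000.0))
        assert any("daily maximum" in r.message for r in caplog.records)
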