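"""Whole-body engine: mass balance, conservation, closed forms, populations."""

import numpy as np
import pytest

import codeine_pbpk as cp
from codeine_pbpk.engine import build_model, michaelis_menten_rate, simulate
from codeine_pbpk.physiology import PopulationSpec, sample_population


def tracer(**kw):
    """Inert codeine-like analyte: no metabolism, no renal elimination."""
    base = dict(name="tracer", molecular_weight=300.0, logP=2.0,
                pKa_acid=None, pKa_base=9.0, ionization_class="base",
                solubility_mg_per_mL_pH7=1.0, fraction_unbound_plasma=0.9,
                blood_to_plasma_ratio=1.0, renal_clearance_mL_min_kg=0.0,
                specific_clearance_per_min=0.0)
    base.update(kw)
    return cp.CompoundParameters(**base)


def iv_regimen(dose_mg):
    return cp.Regimen(dose_mg=dose_mg,
                      formulation=cp.FormulationSpec(kind="iv_bolus"))


class TestMichaelisMenten:
    def test_half_maximal_at_km(self):
        full = michaelis_menten_rate(1e9, 100.0, 1.6, e_ref_umol=2.0)
        assert michaelis_menten_rate(100.0, 100.0, 1.6, e_ref_umol=2.0) \
            == pytest.approx(full / 2, rel=1e-6)

    def test_zero_concentration_zero_rate(self):
        assert michaelis_menten_rate(0.0, 100.0, 1.6) == 0.0

    def test_linear_regime_hand_value(self):
        # Cu=1 uM, Km=100 uM, kcat=1.6/min -> 1.6*E*(1/101)
        assert michaelis_menten_rate(1.0, 100.0, 1.6, e_ref_umol=3.0) \
            == pytest.approx(1.6 * 3.0 / 101.0)


class TestBuildModel:
    def test_reference_score_matches_base_model(self, asian, codeine, morphine):
        a = build_model(asian, codeine, morphine, activity_score=1.5)
        b = build_model(asian, codeine, morphine, activity_score=1.5)
        assert np.array_equal(a.parent.vmax_umol_min, b.parent.vmax_umol_min)
        # AS=1.5 applies the compound's own EM kcat, so capacities equal the
        # unphenotyped decomposition of the specific clearance
        idx_2d6 = [p.enzyme for p in codeine.pathways].index("CYP2D6")
        assert a.parent.vmax_umol_min[idx_2d6] > 0

    def test_pm_um_capacity_ratio(self, asian, codeine, morphine):
        pm = build_model(asian, codeine, morphine, activity_score=0.0)
        um = build_model(asian, codeine, morphine, activity_score=3.0)
        idx = [p.enzyme for p in codeine.pathways].index("CYP2D6")
        ratio = pm.parent.vmax_umol_min[idx] / um.parent.vmax_umol_min[idx]
        assert ratio == pytest.approx(0.03 / 2.8, rel=1e-9)
        others = [i for i in range(len(codeine.pathways)) if i != idx]
        assert np.allclose(pm.parent.vmax_umol_min[others],
                           um.parent.vmax_umol_min[others])

    def test_equal_individuals_equal_systems(self, codeine, morphine):
        a = cp.build_reference_individual("male", 30, "Asian")
        b = cp.build_reference_individual("male", 30, "Asian")
        sa = build_model(a, codeine, morphine, 1.5)
        sb = build_model(b, codeine, morphine, 1.5)
        assert np.array_equal(sa.parent.kp, sb.parent.kp)
        assert np.array_equal(sa.volumes_L, sb.volumes_L)


class TestConservation:
    def test_oral_mass_balance_within_tenth_percent(self, em_result):
        assert em_result.mass_balance_error() < 1e-3

    def test_parent_metabolite_molar_link(self, em_result):
        cum = em_result.cumulative_umol["codeine"]
        assert cum["formed_metabolite"][-1] > 0
        assert np.array_equal(cum["formed_metabolite"], cum["metabolized_CYP2D6"])

    def test_iv_tracer_conserves_total_amount(self, asian):
        system = build_model(asian, tracer(), None)
        res = simulate(system, iv_regimen(10.0), t_end_h=12.0)
        total = res.organ_amounts_umol["tracer"].sum(axis=0)
        dose_umol = 10.0 / 300.0 * 1e3
        assert np.allclose(total, dose_umol, rtol=1e-6)

    def test_zero_dose_all_zero(self, asian, codeine, morphine):
        system = build_model(asian, codeine, morphine)
        reg = cp.Regimen(dose_mg=0.0,
                         formulation=cp.FormulationSpec.from_compound(codeine,
                                                                      "tablet"))
        res = simulate(system, reg, t_end_h=6.0, fast=True)
        assert res.plasma_ng_ml["codeine"].max() == 0.0
        assert res.plasma_ng_ml["morphine"].max() == 0.0


class TestClosedForms:
    def test_hepatic_clearance_well_stirred_closed_form(self, asian):
        """Linear hepatic elimination: venous plasma AUC = D / CL_ws with
        CL_ws = Q_h * fu_b * CLint / (Q_h + fu_b * CLint)."""
        c = tracer(specific_clearance_per_min=1.5)
        system = build_model(asian, c, None)
        # refine the grid over the early venous-mixing spike so the NCA
        # trapezoid resolves it
        grid = np.unique(np.concatenate([np.arange(0, 1.0, 0.002),
                                         np.arange(1.0, 48.001, 0.02)]))
        res = simulate(system, iv_regimen(10.0), t_end_h=48.0,
                       output_grid_h=grid)
        s = res.nca("tracer")
        clint = 1.5 * asian.organs["liver"].volume_L               # L/min
        q_h = (asian.organs["liver"].blood_flow_L_min
               + asian.portal_flow_L_min)
        fu_b = c.fraction_unbound_plasma / c.blood_to_plasma_ratio
        cl_ws = q_h * fu_b * clint / (q_h + fu_b * clint)          # L/min blood
        # plasma clearance = blood clearance * B:P
        auc_expected = (10.0 * 1e6 / (cl_ws * c.blood_to_plasma_ratio)) / 60 / 1e3
        assert s.auc_0_inf == pytest.approx(auc_expected, rel=5e-3)

    def test_renal_only_urine_recovers_dose(self, asian):
        c = tracer(renal_clearance_mL_min_kg=4.0)
        system = build_model(asian, c, None)
        res = simulate(system, iv_regimen(5.0), t_end_h=72.0)
        dose_umol = 5.0 / 300.0 * 1e3
        assert res.cumulative_umol["tracer"]["urine"][-1] \
            == pytest.approx(dose_umol, rel=0.01)


class TestPhenotypeAndDoseResponse:
    def test_morphine_auc_strictly_increasing_in_activity_score(self, phenotype_aucs):
        aucs = [phenotype_aucs[s]["morphine"] for s in (0.0, 0.75, 1.5, 2.75)]
        assert all(b > a for a, b in zip(aucs, aucs[1:]))

    def test_codeine_auc_nonincreasing_in_activity_score(self, phenotype_aucs):
        aucs = [phenotype_aucs[s]["codeine"] for s in (0.0, 0.75, 1.5, 2.75)]
        assert all(b <= a * (1 + 1e-6) for a, b in zip(aucs, aucs[1:]))

    def test_dose_linearity_at_therapeutic_doses(self, asian, codeine, morphine,
                                                 tablet_30mg):
        from dataclasses import replace
        model = cp.PBPKModel(asian, codeine, morphine, 1.5)
        r30 = model.simulate(tablet_30mg, t_end_h=24.0, fast=True)
        r60 = model.simulate(replace(tablet_30mg, dose_mg=60.0),
                             t_end_h=24.0, fast=True)
        for analyte in ("codeine", "morphine"):
            ratio = r60.nca(analyte).auc_0_inf / r30.nca(analyte).auc_0_inf
            assert ratio == pytest.approx(2.0, rel=0.02)


class TestPopulationSimulation:
    def test_identical_individuals_coincident_bands(self, asian, codeine,
                                                    morphine, tablet_30mg):
        systems = [build_model(asian, codeine, morphine, 1.5)] * 3
        bands = cp.simulate_population(systems, tablet_30mg, t_end_h=12.0)
        m = bands.bands["morphine"]
        assert np.allclose(m[5.0], m[95.0])
        assert np.allclose(m[50.0], bands.individual_profiles["morphine"][0])

    def test_sampled_population_band_contains_reference(self, asian, codeine,
                                                        morphine, tablet_30mg):
        pop = sample_population(PopulationSpec(n=8, seed=5), asian)
        systems = [build_model(i, codeine, morphine, 1.5) for i in pop]
        bands = cp.simulate_population(systems, tablet_30mg, t_end_h=12.0)
        ref = cp.PBPKModel(asian, codeine, morphine, 1.5).simulate(
            tablet_30mg, t_end_h=12.0, fast=True)
        m = ref.plasma_ng_ml["morphine"]
        inside = (bands.bands["morphine"][5.0] <= m + 1e-12) \
            & (m <= bands.bands["morphine"][95.0] + 1e-12)
        assert inside[10:].mean() > 0.9   # reference lies within the band

    def test_population_needs_two_individuals(self, asian, codeine, morphine,
                                              tablet_30mg):
        with pytest.raises(ValueError, match="at least 2"):
            cp.simulate_population([build_model(asian, codeine, morphine)],
                                   tablet_30mg)


class TestDeterminism:
    def test_identical_runs_identical_outputs(self, asian, codeine, morphine,
                                              tablet_30mg):
        a = cp.PBPKModel(asian, codeine, morphine, 1.5).simulate(
            tablet_30mg, t_end_h=6.0, fast=True)
        b = cp.PBPKModel(asian, codeine, morphine, 1.5).simulate(
            tablet_30mg, t_end_h=6.0, fast=True)
        assert np.array_equal(a.plasma_ng_ml["morphine"],
                              b.plasma_ng_ml["morphine"])
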