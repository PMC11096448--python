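"""Whole-body parent-metabolite PBPK engine.

The model couples two analytes (parent codeine and its CYP2D6-formed
metabolite morphine) over 18 compartments: 15 perfusion-limited tissues plus
arterial blood, venous blood and the portal vein. Each tissue obeys

    dA/dt = Q * (C_in - C_out),    C_out = (A / V) * (B:P) / Kp

with Kp from the mechanistic partitioning model. The liver receives hepatic
arterial and portal blood and hosts all metabolism; Michaelis-Menten pathway
rates are driven by the unbound liver concentration Cu = fup * A/(V*Kp).
Pathway capacities derive from the compound's specific (intrinsic hepatic)
clearance, decomposed across its enzyme pathways in proportion to their
kinetic ratios; the CYP2D6 capacity additionally carries the activity-score
turnover and a calibrated reference scale. Morphine formation is linked 1:1
molar to the codeine CYP2D6 flux. Renal clearance acts on kidney outflow
plasma. Oral doses pass through Weibull release, gastric emptying and a
segmented intestinal transit chain into the portal vein.

Amounts are integrated in umol (time in minutes) with a stiff solver at
tight tolerances; plasma concentrations are reported in ng/mL (venous
plasma).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from ._data import load_packaged_yaml
from .absorption import (DoseEvent, FormulationSpec, GutModel, Regimen,
                         dose_events, weibull_fraction_dissolved,
                         weibull_release_rate)
from .compound import (CompoundParameters, PlasmaReference, compute_kp,
                       estimate_permeability)
from .phenotype import REFERENCE_ACTIVITY_SCORE, apply_phenotype
from .physiology import BLOOD_COMPARTMENTS, Individual, ORGAN_NAMES

__all__ = ["ModelSystem", "SimulationResult", "PBPKModel",
           "build_model", "simulate", "simulate_population",
           "michaelis_menten_rate", "PopulationBands", "EngineError"]

N_ORG = len(ORGAN_NAMES)
I = {name: k for k, name in enumerate(ORGAN_NAMES)}
I_LUNG, I_LIV, I_KID = I["lung"], I["liver"], I["kidney"]
I_ART, I_VEN, I_PV = I["arterial_blood"], I["venous_blood"], I["portal_vein"]
PORTAL_IDX = np.array([I["gut"], I["stomach"], I["spleen"], I["pancreas"]])
SYSTEMIC_IDX = np.array([k for k, n in enumerate(ORGAN_NAMES)
                         if n not in BLOOD_COMPARTMENTS + ("lung", "liver",
                                                           "gut", "stomach",
                                                           "spleen", "pancreas")])
DEFAULT_GRID_STEP_H = 0.02


class EngineError(RuntimeError):
    """Raised when the ODE solver fails; message carries the solver state."""


def michaelis_menten_rate(c_unbound_uM: float, km_uM: float, kcat_per_min: float,
                          enzyme_abundance_rel: float = 1.0,
                          e_ref_umol: float = 1.0) -> float:
    """Michaelis-Menten pathway rate (umol/min).

    rate = kcat * E_ref * abundance * Cu / (Km + Cu); linear in Cu well below
    Km, saturating at kcat * E_ref * abundance.
    """
    c = max(float(c_unbound_uM), 0.0)
    return kcat_per_min * e_ref_umol * enzyme_abundance_rel * c / (km_uM + c)


@dataclass(frozen=True)
class AnalyteParams:
    """Precomputed per-analyte arrays for the ODE right-hand side."""

    compound: CompoundParameters
    kp: np.ndarray                 # tissue:plasma per organ (blood pools = 1)
    vmax_umol_min: np.ndarray      # per pathway, at this phenotype/abundance
    km_uM: np.ndarray
    product_is_metabolite: np.ndarray   # bool per pathway
    unassigned_clint_L_min: float  # first-order hepatic clearance (no pathway)
    renal_cl_L_min: float
    permeability_cm_min: float

    @property
    def n_pathways(self) -> int:
        return len(self.km_uM)


@dataclass(frozen=True)
class ModelSystem:
    """Assembled parent-metabolite system for one individual."""

    individual: Individual
    parent: AnalyteParams
    metabolite: AnalyteParams
    activity_score: float
    enzyme_scales: dict[str, float]
    volumes_L: np.ndarray
    flows_L_min: np.ndarray
    e_ref: dict[str, float]        # reference enzyme amount per analyte (umol)


def _pathway_weight(p) -> float:
    return p.capacity / p.km_uM


def _analyte_params(compound: CompoundParameters, individual: Individual,
                    reference_compound: CompoundParameters,
                    enzyme_scales: dict[str, float],
                    plasma_ref: PlasmaReference) -> tuple[AnalyteParams, float]:
    kp = np.ones(N_ORG)
    for name, k in I.items():
        if name in BLOOD_COMPARTMENTS:
            continue
        kp[k] = compute_kp(compound, individual.organs[name].composition,
                           plasma_ref)
    v_liver = individual.organs["liver"].volume_L
    clint_total = compound.specific_clearance_per_min * v_liver  # L/min, unbound
    weights = [_pathway_weight(p) for p in reference_compound.pathways]
    wsum = sum(weights)
    abundances = individual.enzyme_abundances
    if compound.pathways:
        e_ref = clint_total / wsum
        vmax = np.array([
            enzyme_scales.get(p.enzyme, 1.0) * abundances.get(p.enzyme, 1.0)
            * p.capacity * e_ref
            for p in compound.pathways])
        unassigned = 0.0
    else:
        e_ref = 0.0
        vmax = np.zeros(0)
        unassigned = clint_total
    params = AnalyteParams(
        compound=compound,
        kp=kp,
        vmax_umol_min=vmax,
        km_uM=np.array([p.km_uM for p in compound.pathways]),
        product_is_metabolite=np.array(
            [p.product != "sink" for p in compound.pathways], dtype=bool),
        unassigned_clint_L_min=unassigned,
        renal_cl_L_min=compound.renal_clearance_mL_min_kg
        * individual.body_weight_kg / 1000.0,
        permeability_cm_min=estimate_permeability(compound),
    )
    return params, e_ref


def _default_enzyme_scales() -> dict[str, float]:
    return dict(load_packaged_yaml("constants.yaml")["enzyme_scales"])


def build_model(individual: Individual, parent: CompoundParameters,
                metabolite: CompoundParameters | None,
                activity_score: float | None = REFERENCE_ACTIVITY_SCORE,
                enzyme_scales: dict[str, float] | None = None,
                reference_parent: CompoundParameters | None = None) -> ModelSystem:
    """Assemble the coupled system: Kp vectors, pathway capacities, clearances.

    The activity score rescales the parent's CYP2D6 turnover through the
    phenotype table (``None`` keeps the compound's own kcat, e.g. during
    parameter identification); pathway capacities are normalised against
    ``reference_parent`` (default: the parent as given, before phenotyping)
    so that phenotyping or fitting changes only the targeted term.
    """
    scales = enzyme_scales if enzyme_scales is not None else _default_enzyme_scales()
    plasma_ref = PlasmaReference.default(individual.hematocrit)
    has_2d6 = any(p.enzyme == "CYP2D6" for p in parent.pathways)
    parent_ph = (apply_phenotype(parent, activity_score)
                 if has_2d6 and activity_score is not None else parent)
    reference = reference_parent if reference_parent is not None else parent
    p_params, e_p = _analyte_params(parent_ph, individual, reference, scales,
                                    plasma_ref)
    if metabolite is not None:
        m_params, e_m = _analyte_params(metabolite, individual, metabolite,
                                        scales, plasma_ref)
    else:
        inert = CompoundParameters(
            name="none", molecular_weight=1.0, logP=0.0, pKa_acid=None,
            pKa_base=None, ionization_class="neutral",
            solubility_mg_per_mL_pH7=1.0, fraction_unbound_plasma=1.0,
            blood_to_plasma_ratio=1.0, renal_clearance_mL_min_kg=0.0,
            specific_clearance_per_min=0.0)
        m_params, e_m = _analyte_params(inert, individual, inert, scales, plasma_ref)
    volumes = np.array([individual.organs[n].volume_L for n in ORGAN_NAMES])
    flows = np.array([individual.organs[n].blood_flow_L_min for n in ORGAN_NAMES])
    return ModelSystem(individual=individual, parent=p_params,
                       metabolite=m_params,
                       activity_score=(float("nan") if activity_score is None
                                       else activity_score),
                       enzyme_scales=scales, volumes_L=volumes,
                       flows_L_min=flows,
                       e_ref={"parent": e_p, "metabolite": e_m})


# ---------------------------------------------------------------------------
# state layout and right-hand side

class _Layout:
    def __init__(self, system: ModelSystem, gut: GutModel):
        np_par = system.parent.n_pathways
        np_met = system.metabolite.n_pathways
        self.p_org = slice(0, N_ORG)
        self.lumen = slice(N_ORG, N_ORG + gut.n_states)
        base = N_ORG + gut.n_states
        # cumulative parent states: absorbed, fecal, urine, unassigned, pathways
        self.p_absorbed = base
        self.p_fecal = base + 1
        self.p_urine = base + 2
        self.p_unassigned = base + 3
        self.p_met = slice(base + 4, base + 4 + np_par)
        base += 4 + np_par
        self.m_org = slice(base, base + N_ORG)
        base += N_ORG
        self.m_urine = base
        self.m_unassigned = base + 1
        self.m_met = slice(base + 2, base + 2 + np_met)
        self.n_states = base + 2 + np_met


def _organ_rhs(y: np.ndarray, dy: np.ndarray, a: AnalyteParams,
               volumes: np.ndarray, flows: np.ndarray,
               co: float, q_ha: float, q_pv: float) -> tuple[float, float, float]:
    """Perfusion-limited organ balance for one analyte.

    Fills dy in place; returns (unbound liver conc uM, renal rate umol/min,
    liver metabolic drain placeholder handled by caller).
    """
    bp = a.compound.blood_to_plasma_ratio
    fup = a.compound.fraction_unbound_plasma
    c_art = y[I_ART] / volumes[I_ART]
    c_ven = y[I_VEN] / volumes[I_VEN]
    c_pv = y[I_PV] / volumes[I_PV]
    c_out = y[:N_ORG] / volumes * (bp / a.kp)   # blood conc leaving each organ

    dy[I_LUNG] = co * (c_ven - c_out[I_LUNG])
    dy[I_ART] = co * (c_out[I_LUNG] - c_art)
    dy[SYSTEMIC_IDX] = flows[SYSTEMIC_IDX] * (c_art - c_out[SYSTEMIC_IDX])
    dy[PORTAL_IDX] = flows[PORTAL_IDX] * (c_art - c_out[PORTAL_IDX])
    dy[I_PV] = float(flows[PORTAL_IDX] @ c_out[PORTAL_IDX]) - q_pv * c_pv
    dy[I_LIV] = q_ha * c_art + q_pv * c_pv - (q_ha + q_pv) * c_out[I_LIV]
    dy[I_VEN] = (float(flows[SYSTEMIC_IDX] @ c_out[SYSTEMIC_IDX])
                 + (q_ha + q_pv) * c_out[I_LIV] - co * c_ven)

    renal = a.renal_cl_L_min * max(c_out[I_KID], 0.0) / bp  # on outflow plasma
    dy[I_KID] -= renal
    cu_liver = max(fup * y[I_LIV] / (volumes[I_LIV] * a.kp[I_LIV]), 0.0)
    return cu_liver, renal


@dataclass
class _OralInput:
    """Time-dependent Weibull release rate summed over past oral doses."""

    events: list[tuple[float, float, FormulationSpec]] = field(default_factory=list)

    def rate(self, t: float) -> float:
        r = 0.0
        for t0, amount, spec in self.events:
            if t > t0:
                r += amount * weibull_release_rate(t - t0, spec)
        return r

    def undissolved(self, t: np.ndarray) -> np.ndarray:
        u = np.zeros_like(t, dtype=float)
        for t0, amount, spec in self.events:
            rel = np.where(t >= t0,
                           weibull_fraction_dissolved(np.clip(t - t0, 0, None), spec),
                           0.0)
            u += amount * np.where(t >= t0, 1.0 - rel, 0.0)
        return u


def _make_rhs(system: ModelSystem, gut: GutModel, lay: _Layout,
              oral: _OralInput, infusion_rate, infusion_windows):
    p, m = system.parent, system.metabolite
    volumes, flows = system.volumes_L, system.flows_L_min
    co = system.individual.cardiac_output_L_min
    q_ha = flows[I_LIV]
    q_pv = system.individual.portal_flow_L_min

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        dy = np.zeros_like(y)
        # parent organs
        yp = y[lay.p_org]
        dyp = np.zeros(N_ORG)
        cu_p, renal_p = _organ_rhs(yp, dyp, p, volumes, flows, co, q_ha, q_pv)
        # parent metabolism
        form_rate = 0.0
        if p.n_pathways:
            rates = p.vmax_umol_min * cu_p / (p.km_uM + cu_p)
            dyp[I_LIV] -= rates.sum()
            dy[lay.p_met] = rates
            form_rate = float(rates[p.product_is_metabolite].sum())
        if p.unassigned_clint_L_min:
            r = p.unassigned_clint_L_min * cu_p
            dyp[I_LIV] -= r
            dy[lay.p_unassigned] = r
        # oral absorption chain
        lumen = y[lay.lumen]
        dl, absorbed, fecal = gut.rates(lumen)
        dl[0] += oral.rate(t)
        dyp[I_PV] += absorbed
        if infusion_rate:
            dyp[I_VEN] += infusion_rate(t)
        dy[lay.lumen] = dl
        dy[lay.p_absorbed] = absorbed
        dy[lay.p_fecal] = fecal
        dy[lay.p_urine] = renal_p
        dy[lay.p_org] = dyp
        # metabolite organs
        ym = y[lay.m_org]
        dym = np.zeros(N_ORG)
        cu_m, renal_m = _organ_rhs(ym, dym, m, volumes, flows, co, q_ha, q_pv)
        if m.n_pathways:
            rates_m = m.vmax_umol_min * cu_m / (m.km_uM + cu_m)
            dym[I_LIV] -= rates_m.sum()
            dy[lay.m_met] = rates_m
        if m.unassigned_clint_L_min:
            r = m.unassigned_clint_L_min * cu_m
            dym[I_LIV] -= r
            dy[lay.m_unassigned] = r
        dym[I_LIV] += form_rate      # 1:1 molar parent -> metabolite
        dy[lay.m_urine] = renal_m
        dy[lay.m_org] = dym
        return dy

    return rhs


# ---------------------------------------------------------------------------
# results

@dataclass
class SimulationResult:
    """Concentration-time profiles and cumulative amount bookkeeping."""

    t_h: np.ndarray
    plasma_ng_ml: dict[str, np.ndarray]
    organ_amounts_umol: dict[str, np.ndarray]      # (N_ORG, T)
    cumulative_umol: dict[str, dict[str, np.ndarray]]
    administered_umol: np.ndarray                  # parent, cumulative at t
    undissolved_umol: np.ndarray
    system: ModelSystem
    regimen: Regimen

    @property
    def analytes(self) -> list[str]:
        return list(self.plasma_ng_ml)

    def profile_frame(self) -> pd.DataFrame:
        """Tidy delimited-table view: time_h, analyte, plasma_conc_ng_per_ml."""
        frames = [pd.DataFrame({"time_h": self.t_h, "analyte": name,
                                "plasma_conc_ng_per_ml": conc})
                  for name, conc in self.plasma_ng_ml.items()]
        return pd.concat(frames, ignore_index=True)

    def nca(self, analyte: str):
        from .pk_metrics import nca
        return nca(self.t_h, self.plasma_ng_ml[analyte])

    def mass_balance_error(self) -> float:
        """Worst relative mass-balance error over all output times.

        Parent: administered = undissolved + lumen + fecal + in-body + urine
        + metabolised. Metabolite: formed = in-body + urine + metabolised.
        """
        parent = self.system.parent.compound.name
        met = self.system.metabolite.compound.name
        cp = self.cumulative_umol[parent]
        in_body = self.organ_amounts_umol[parent].sum(axis=0)
        lumen = cp["lumen"]
        accounted = (self.undissolved_umol + lumen + cp["fecal"] + in_body
                     + cp["urine"] + cp["metabolized_total"])
        dose = np.maximum(self.administered_umol, 1e-300)
        err_p = np.abs(accounted - self.administered_umol) / dose
        err_p[self.administered_umol == 0] = np.abs(
            accounted[self.administered_umol == 0])
        cm = self.cumulative_umol[met]
        formed = cp["formed_metabolite"]
        in_body_m = self.organ_amounts_umol[met].sum(axis=0)
        accounted_m = in_body_m + cm["urine"] + cm["metabolized_total"]
        with np.errstate(invalid="ignore", divide="ignore"):
            err_m = np.where(formed > 1e-12,
                             np.abs(accounted_m - formed) / np.maximum(formed, 1e-300),
                             np.abs(accounted_m - formed))
        return float(max(err_p.max(), err_m.max()))

    def summary(self) -> str:
        from .pk_metrics import nca
        lines = [f"PBPK simulation: {self.regimen.dose_mg:g} mg "
                 f"{self.system.parent.compound.name} "
                 f"({self.regimen.formulation.kind}, n_doses={self.regimen.n_doses}), "
                 f"activity score {self.system.activity_score:g}",
                 f"individual: {self.system.individual.ethnicity} "
                 f"{self.system.individual.sex}, "
                 f"{self.system.individual.body_weight_kg:g} kg",
                 "-" * 72,
                 f"{'analyte':<12}{'AUC_0-t':>12}{'AUC_0-inf':>12}{'Cmax':>10}"
                 f"{'Tmax':>8}{'t1/2':>8}",
                 f"{'':<12}{'ng*h/mL':>12}{'ng*h/mL':>12}{'ng/mL':>10}"
                 f"{'h':>8}{'h':>8}"]
        for analyte in self.analytes:
            s = nca(self.t_h, self.plasma_ng_ml[analyte])
            half = f"{s.half_life_h:8.2f}" if s.half_life_h is not None else "      --"
            inf = (f"{s.auc_0_inf:12.3f}" if s.auc_0_inf is not None
                   else "          --")
            lines.append(f"{analyte:<12}{s.auc_0_t:12.3f}{inf}"
                         f"{s.cmax:10.3f}{s.tmax_h:8.2f}{half}")
        return "\n".join(lines)

    def plot(self, ax=None, log_scale: bool = True):
        """Plot plasma concentration-time profiles (one line per analyte)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        for analyte, conc in self.plasma_ng_ml.items():
            ax.plot(self.t_h, conc, label=analyte)
        if log_scale:
            ax.set_yscale("log")
        ax.set_xlabel("time (h)")
        ax.set_ylabel("plasma concentration (ng/mL)")
        ax.legend()
        return ax


def _solver_opts(fast: bool) -> dict:
    s = load_packaged_yaml("constants.yaml")["solver"]
    if fast:
        return {"rtol": float(s["rtol_fast"]), "atol": float(s["atol_fast"])}
    return {"rtol": float(s["rtol"]), "atol": float(s["atol"])}


def simulate(system: ModelSystem, regimen: Regimen, t_end_h: float = 24.0,
             output_grid_h: np.ndarray | None = None,
             fast: bool = False) -> SimulationResult:
    """Integrate the coupled system under a dosing regimen.

    Integration restarts at every dose event; intravenous boluses enter the
    venous pool as state jumps, oral doses through the dissolution/transit
    chain. Deterministic for fixed inputs and tolerances.
    """
    if t_end_h <= 0:
        raise ValueError("t_end_h must be positive")
    parent_c = system.parent.compound
    GutModel.check_solubility(regimen, parent_c)
    gut = GutModel(system.parent.permeability_cm_min)
    lay = _Layout(system, gut)
    t_end = t_end_h * 60.0
    events = [ev for ev in dose_events(regimen, parent_c.molecular_weight)
              if ev.time_min < t_end - 1e-9]

    if output_grid_h is None:
        output_grid_h = np.round(np.arange(0.0, t_end_h + 1e-9,
                                           DEFAULT_GRID_STEP_H), 9)
    grid = np.asarray(output_grid_h, dtype=float) * 60.0

    oral = _OralInput()
    infusion_windows: list[tuple[float, float, float]] = []
    jumps: list[tuple[float, int, float]] = []
    kind = regimen.formulation.kind
    for ev in events:
        if kind == "iv_bolus":
            jumps.append((ev.time_min, I_VEN, ev.amount_umol))
        elif kind == "iv_infusion":
            dur = regimen.formulation.infusion_duration_min
            infusion_windows.append((ev.time_min, ev.time_min + dur,
                                     ev.amount_umol / dur))
        elif regimen.formulation.is_weibull:
            oral.events.append((ev.time_min, ev.amount_umol, regimen.formulation))
        else:  # solution / IR tablet / CR solution: released at administration
            jumps.append((ev.time_min, N_ORG, ev.amount_umol))  # stomach lumen

    def infusion_rate(t: float) -> float:
        return sum(r for (a, b, r) in infusion_windows if a <= t < b)

    rhs = _make_rhs(system, gut, lay, oral,
                    infusion_rate if infusion_windows else None,
                    infusion_windows)

    breakpoints = sorted({0.0, t_end}
                         | {t for (t, _, _) in jumps}
                         | {t for (t, _, s) in oral.events}
                         | {t for w in infusion_windows for t in w[:2]})
    breakpoints = [b for b in breakpoints if 0.0 <= b <= t_end]

    y = np.zeros(lay.n_states)
    ts: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    opts = _solver_opts(fast)
    for t0, t1 in zip(breakpoints[:-1], breakpoints[1:]):
        for (tj, idx, amt) in jumps:
            if tj == t0:
                y[idx] += amt
        mask = (grid >= t0) & (grid <= t1)
        t_eval = np.unique(np.concatenate([[t0], grid[mask], [t1]]))
        sol = solve_ivp(rhs, (t0, t1), y, method="LSODA", t_eval=t_eval,
                        **opts)
        if not sol.success:
            raise EngineError(
                f"ODE solver failed in [{t0:.2f}, {t1:.2f}] min: {sol.message}; "
                f"state head {np.array2string(y[:6], precision=4)}")
        keep = np.isin(sol.t, grid[mask])
        if t1 < breakpoints[-1]:
            # dose times belong to the next segment (post-jump state)
            keep &= sol.t < t1
        ts.append(sol.t[keep])
        ys.append(sol.y[:, keep])
        y = sol.y[:, -1].copy()

    t_all = np.concatenate(ts)
    y_all = np.concatenate(ys, axis=1)
    t_out, first = np.unique(t_all, return_index=True)
    y_out = y_all[:, first]

    def plasma(org_slice, compound):
        c_ven = y_out[org_slice][I_VEN] / system.volumes_L[I_VEN]
        return np.clip(c_ven / compound.blood_to_plasma_ratio, 0.0, None) \
            * compound.molecular_weight   # uM -> ng/mL

    p_name, m_name = parent_c.name, system.metabolite.compound.name
    p_paths = [p.enzyme for p in parent_c.pathways]
    m_paths = [p.enzyme for p in system.metabolite.compound.pathways]
    p_met = y_out[lay.p_met]
    m_met = y_out[lay.m_met]
    formed = (p_met[system.parent.product_is_metabolite].sum(axis=0)
              if len(p_met) else np.zeros_like(t_out))
    cumulative = {
        p_name: {
            "absorbed": y_out[lay.p_absorbed], "fecal": y_out[lay.p_fecal],
            "urine": y_out[lay.p_urine],
            "lumen": y_out[lay.lumen].sum(axis=0),
            "metabolized_total": (p_met.sum(axis=0) if len(p_met)
                                  else np.zeros_like(t_out))
            + y_out[lay.p_unassigned],
            "formed_metabolite": formed,
            **{f"metabolized_{e}": p_met[k] for k, e in enumerate(p_paths)},
            "metabolized_unassigned": y_out[lay.p_unassigned],
        },
        m_name: {
            "urine": y_out[lay.m_urine],
            "metabolized_total": (m_met.sum(axis=0) if len(m_met)
                                  else np.zeros_like(t_out))
            + y_out[lay.m_unassigned],
            **{f"metabolized_{e}": m_met[k] for k, e in enumerate(m_paths)},
            "metabolized_unassigned": y_out[lay.m_unassigned],
        },
    }
    administered = np.zeros_like(t_out)
    for ev in events:
        administered[t_out >= ev.time_min - 1e-9] += ev.amount_umol
    undissolved = oral.undissolved(t_out)

    return SimulationResult(
        t_h=t_out / 60.0,
        plasma_ng_ml={p_name: plasma(lay.p_org, parent_c),
                      m_name: plasma(lay.m_org, system.metabolite.compound)},
        organ_amounts_umol={p_name: y_out[lay.p_org],
                            m_name: y_out[lay.m_org]},
        cumulative_umol=cumulative,
        administered_umol=administered,
        undissolved_umol=undissolved,
        system=system, regimen=regimen)


@dataclass
class PopulationBands:
    """Per-time percentile bands of plasma concentration per analyte."""

    t_h: np.ndarray
    percentiles: tuple[float, ...]
    bands: dict[str, dict[float, np.ndarray]]
    individual_profiles: dict[str, np.ndarray]     # (n_individuals, T)


def simulate_population(systems: Sequence[ModelSystem], regimen: Regimen,
                        percentiles: tuple[float, ...] = (5.0, 50.0, 95.0),
                        t_end_h: float = 24.0,
                        fast: bool = True) -> PopulationBands:
    """Simulate a set of individuals and summarise percentile bands."""
    if len(systems) < 2:
        raise ValueError("population simulation needs at least 2 individuals")
    results = [simulate(s, regimen, t_end_h=t_end_h, fast=fast) for s in systems]
    t_h = results[0].t_h
    bands: dict[str, dict[float, np.ndarray]] = {}
    profiles: dict[str, np.ndarray] = {}
    for analyte in results[0].analytes:
        mat = np.vstack([r.plasma_ng_ml[analyte] for r in results])
        profiles[analyte] = mat
        bands[analyte] = {q: np.percentile(mat, q, axis=0) for q in percentiles}
    return PopulationBands(t_h=t_h, percentiles=tuple(percentiles),
                           bands=bands, individual_profiles=profiles)


# ---------------------------------------------------------------------------
# model front-end

class PBPKModel:
    """Whole-body codeine/morphine model for one individual.

    The statsmodels-style front door: construct from an individual, a parent
    compound, its metabolite and a CYP2D6 activity score; ``simulate``
    returns a :class:`SimulationResult`, ``fit`` runs Monte-Carlo parameter
    identification against observed concentration-time data.
    """

    def __init__(self, individual: Individual, parent: CompoundParameters,
                 metabolite: CompoundParameters | None = None,
                 activity_score: float = REFERENCE_ACTIVITY_SCORE,
                 enzyme_scales: dict[str, float] | None = None):
        self.individual = individual
        self.parent = parent
        self.metabolite = metabolite
        self.activity_score = activity_score
        self.enzyme_scales = enzyme_scales
        self.system = build_model(individual, parent, metabolite,
                                  activity_score, enzyme_scales)

    @classmethod
    def from_defaults(cls, ethnicity: str = "European",
                      activity_score: float = REFERENCE_ACTIVITY_SCORE,
                      enzyme_scales: dict[str, float] | None = None,
                      sex: str = "male", age_years: float = 30.0) -> "PBPKModel":
        """Packaged codeine/morphine model for a reference individual."""
        from .compound import load_compound
        from .physiology import build_reference_individual
        ind = build_reference_individual(sex, age_years, ethnicity)
        return cls(ind, load_compound("codeine"), load_compound("morphine"),
                   activity_score, enzyme_scales)

    def simulate(self, regimen: Regimen, t_end_h: float = 24.0,
                 output_grid_h: np.ndarray | None = None,
                 fast: bool = False) -> SimulationResult:
        return simulate(self.system, regimen, t_end_h=t_end_h,
                        output_grid_h=output_grid_h, fast=fast)

    def fit(self, observed: pd.DataFrame, fit_spec):
        """Monte-Carlo parameter identification; see codeine_pbpk.calibration."""
        from .calibration import make_simulator, monte_carlo_fit
        simulator = make_simulator(self.individual, self.parent, self.metabolite,
                                   fit_spec.regimen, self.activity_score,
                                   enzyme_scales=self.enzyme_scales)
        return monte_carlo_fit(simulator, observed, fit_spec)
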