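"""Compound physicochemistry/ADME and tissue:plasma partitioning.

``CompoundParameters`` carries the analyte description (lipophilicity,
ionisation, binding, clearances, enzyme pathways, formulations) and is read
from / written to YAML compound files; codeine and morphine ship with the
package.

Partition coefficients follow the Rodgers-Rowland mechanistic scheme for
moderate-to-strong bases and its ampholyte extension: partitioning into
tissue water (pH-dependent ionisation), neutral lipid and neutral
phospholipid, plus electrostatic association of the cationic species with
acidic phospholipids. The acidic-phospholipid association constant is backed
out from the measured blood:plasma ratio via the blood-cell composition.
Cellular permeability comes from a documented lipophilicity/size
correlation with coefficients in the packaged constants file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import yaml

from ._data import load_packaged_yaml
from .physiology import TissueComposition

__all__ = [
    "CompoundParameters", "EnzymePathway", "PlasmaReference",
    "load_compound", "save_compound", "ionized_fractions",
    "compute_kp", "estimate_permeability",
]

IONIZATION_CLASSES = ("base", "ampholyte", "neutral")


@dataclass(frozen=True)
class EnzymePathway:
    """One Michaelis-Menten metabolic pathway of an analyte.

    ``kcat_based`` pathways express capacity as a turnover frequency (1/min)
    per reference enzyme amount; ``vmax_based`` as pmol/min/mg microsomal
    protein. Km is stored in uM. ``product`` names the analyte formed, or
    ``"sink"`` when the metabolite is not tracked.
    """

    enzyme: str
    km_uM: float
    kinetic_mode: str
    kcat_per_min: float | None = None
    vmax_pmol_min_mg: float | None = None
    product: str = "sink"

    def __post_init__(self) -> None:
        if self.km_uM <= 0:
            raise ValueError(f"{self.enzyme}: Km must be positive")
        if self.kinetic_mode == "kcat_based":
            if self.kcat_per_min is None or self.vmax_pmol_min_mg is not None:
                raise ValueError(f"{self.enzyme}: kcat_based needs kcat only")
        elif self.kinetic_mode == "vmax_based":
            if self.vmax_pmol_min_mg is None or self.kcat_per_min is not None:
                raise ValueError(f"{self.enzyme}: vmax_based needs vmax only")
        else:
            raise ValueError(f"unknown kinetic_mode {self.kinetic_mode!r}")

    @property
    def capacity(self) -> float:
        """Turnover value in the pathway's native units (1/min or pmol/min/mg)."""
        return self.kcat_per_min if self.kinetic_mode == "kcat_based" \
            else self.vmax_pmol_min_mg


@dataclass(frozen=True)
class FormulationParams:
    dissolution_t50_min: float
    dissolution_shape: float


@dataclass(frozen=True)
class CompoundParameters:
    """Physicochemical and ADME description of one analyte."""

    name: str
    molecular_weight: float
    logP: float
    pKa_acid: float | None
    pKa_base: float | None
    ionization_class: str
    solubility_mg_per_mL_pH7: float
    fraction_unbound_plasma: float
    blood_to_plasma_ratio: float
    renal_clearance_mL_min_kg: float
    specific_clearance_per_min: float
    total_hepatic_clearance_mL_min_kg: float | None = None
    pathways: tuple[EnzymePathway, ...] = ()
    formulations: dict[str, FormulationParams] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.molecular_weight <= 0:
            raise ValueError("molecular weight must be positive")
        if not 0 < self.fraction_unbound_plasma <= 1:
            raise ValueError("fup must be in (0, 1]")
        if self.blood_to_plasma_ratio <= 0:
            raise ValueError("blood:plasma ratio must be positive")
        if self.renal_clearance_mL_min_kg < 0 or self.specific_clearance_per_min < 0:
            raise ValueError("clearances must be non-negative")
        if self.ionization_class not in IONIZATION_CLASSES:
            raise ValueError(f"unsupported ionization class {self.ionization_class!r}")

    def pathway(self, enzyme: str) -> EnzymePathway:
        for p in self.pathways:
            if p.enzyme == enzyme:
                return p
        raise KeyError(f"{self.name} has no {enzyme} pathway")

    def with_pathway(self, enzyme: str, **changes) -> "CompoundParameters":
        """Copy with one pathway's fields replaced; all else untouched."""
        new = tuple(replace(p, **changes) if p.enzyme == enzyme else p
                    for p in self.pathways)
        if new == self.pathways and not any(p.enzyme == enzyme for p in self.pathways):
            raise KeyError(f"{self.name} has no {enzyme} pathway")
        return replace(self, pathways=new)


@dataclass(frozen=True)
class PlasmaReference:
    """Reference phases for partitioning: plasma, blood cells, pH values."""

    pH_plasma: float
    pH_blood_cells: float
    hematocrit: float
    bc_f_iw: float
    bc_f_nl: float
    bc_f_np: float
    bc_ap_mg_g: float
    plasma_f_water: float
    plasma_f_nl: float
    plasma_f_np: float

    @classmethod
    def default(cls, hematocrit: float = 0.45) -> "PlasmaReference":
        raw = load_packaged_yaml("tissue_composition.yaml")
        bc, pl = raw["blood_cells"], raw["plasma"]
        return cls(
            pH_plasma=float(raw["pH_plasma"]),
            pH_blood_cells=float(raw["pH_blood_cells"]),
            hematocrit=hematocrit,
            bc_f_iw=float(bc["f_iw"]), bc_f_nl=float(bc["f_nl"]),
            bc_f_np=float(bc["f_np"]), bc_ap_mg_g=float(bc["ap_mg_g"]),
            plasma_f_water=float(pl["f_water"]), plasma_f_nl=float(pl["f_nl"]),
            plasma_f_np=float(pl["f_np"]),
        )


# ---------------------------------------------------------------------------
# compound file IO

def _pathway_to_dict(p: EnzymePathway) -> dict:
    d = {"enzyme": p.enzyme, "kinetic_mode": p.kinetic_mode, "km_uM": p.km_uM,
         "product": p.product}
    if p.kinetic_mode == "kcat_based":
        d["kcat_per_min"] = p.kcat_per_min
    else:
        d["vmax_pmol_min_mg"] = p.vmax_pmol_min_mg
    return d


def _compound_from_dict(raw: dict) -> CompoundParameters:
    pathways = tuple(
        EnzymePathway(
            enzyme=p["enzyme"], km_uM=float(p["km_uM"]),
            kinetic_mode=p["kinetic_mode"],
            kcat_per_min=(float(p["kcat_per_min"])
                          if "kcat_per_min" in p else None),
            vmax_pmol_min_mg=(float(p["vmax_pmol_min_mg"])
                              if "vmax_pmol_min_mg" in p else None),
            product=p.get("product", "sink"),
        ) for p in raw.get("pathways", []) or [])
    formulations = {
        k: FormulationParams(float(v["dissolution_t50_min"]),
                             float(v["dissolution_shape"]))
        for k, v in (raw.get("formulations") or {}).items()}
    return CompoundParameters(
        name=raw["name"],
        molecular_weight=float(raw["molecular_weight"]),
        logP=float(raw["logP"]),
        pKa_acid=(None if raw.get("pKa_acid") is None else float(raw["pKa_acid"])),
        pKa_base=(None if raw.get("pKa_base") is None else float(raw["pKa_base"])),
        ionization_class=raw["ionization_class"],
        solubility_mg_per_mL_pH7=float(raw["solubility_mg_per_mL_pH7"]),
        fraction_unbound_plasma=float(raw["fraction_unbound_plasma"]),
        blood_to_plasma_ratio=float(raw["blood_to_plasma_ratio"]),
        renal_clearance_mL_min_kg=float(raw["renal_clearance_mL_min_kg"]),
        specific_clearance_per_min=float(raw["specific_clearance_per_min"]),
        total_hepatic_clearance_mL_min_kg=(
            float(raw["total_hepatic_clearance_mL_min_kg"])
            if raw.get("total_hepatic_clearance_mL_min_kg") is not None else None),
        pathways=pathways, formulations=formulations,
    )


def load_compound(name_or_path: str) -> CompoundParameters:
    """Load a compound file: a packaged name (``"codeine"``) or a YAML path."""
    if name_or_path in ("codeine", "morphine"):
        raw = load_packaged_yaml(f"compounds/{name_or_path}.yaml")
    else:
        with open(name_or_path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    return _compound_from_dict(raw)


def save_compound(compound: CompoundParameters, path: str) -> None:
    """Write a compound to a YAML file that ``load_compound`` reads back."""
    d = {
        "name": compound.name,
        "molecular_weight": compound.molecular_weight,
        "logP": compound.logP,
        "pKa_acid": compound.pKa_acid,
        "pKa_base": compound.pKa_base,
        "ionization_class": compound.ionization_class,
        "solubility_mg_per_mL_pH7": compound.solubility_mg_per_mL_pH7,
        "fraction_unbound_plasma": compound.fraction_unbound_plasma,
        "blood_to_plasma_ratio": compound.blood_to_plasma_ratio,
        "renal_clearance_mL_min_kg": compound.renal_clearance_mL_min_kg,
        "specific_clearance_per_min": compound.specific_clearance_per_min,
        "total_hepatic_clearance_mL_min_kg": compound.total_hepatic_clearance_mL_min_kg,
        "pathways": [_pathway_to_dict(p) for p in compound.pathways],
        "formulations": {k: {"dissolution_t50_min": f.dissolution_t50_min,
                             "dissolution_shape": f.dissolution_shape}
                         for k, f in compound.formulations.items()},
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# ionisation

def ionized_fractions(compound: CompoundParameters, pH: float) -> dict[str, float]:
    """Henderson-Hasselbalch species fractions at a given pH.

    Returns ``neutral``, ``cation`` and ``anion`` fractions summing to one.
    For an ampholyte the cation uses the basic pKa and the anion the acidic
    pKa (microspecies treated independently).
    """
    if not 0.0 <= pH <= 14.0:
        raise ValueError(f"pH {pH} outside [0, 14]")
    cation = anion = 0.0
    if compound.ionization_class == "base":
        cation = 10.0 ** (compound.pKa_base - pH)
    elif compound.ionization_class == "ampholyte":
        cation = 10.0 ** (compound.pKa_base - pH)
        anion = 10.0 ** (pH - compound.pKa_acid)
    denom = 1.0 + cation + anion
    return {"neutral": 1.0 / denom, "cation": cation / denom, "anion": anion / denom}


def _Y(compound: CompoundParameters, pH: float) -> float:
    """1 + ionised:neutral ratio at a pH (1 for neutral compounds)."""
    f = ionized_fractions(compound, pH)
    return 1.0 / f["neutral"]


def _cation_ratio(compound: CompoundParameters, pH: float) -> float:
    """Cation:neutral ratio at a pH (drives acidic-phospholipid binding)."""
    if compound.ionization_class == "neutral":
        return 0.0
    return 10.0 ** (compound.pKa_base - pH)


def _lipid_term(P: float, f_nl: float, f_np: float) -> float:
    return P * f_nl + (0.3 * P + 0.7) * f_np


def ka_acidic_phospholipid(compound: CompoundParameters,
                           ref: PlasmaReference) -> float:
    """Association constant to acidic phospholipids from the blood:plasma ratio.

    Solves the partitioning equation for blood cells, whose unbound
    partition coefficient follows from hematocrit, B/P and fup. Returns 0
    (no cation binding) when the measured B/P leaves no residual affinity.
    """
    if compound.ionization_class == "neutral":
        return 0.0
    hct, fup = ref.hematocrit, compound.fraction_unbound_plasma
    kpu_bc = (hct - 1.0 + compound.blood_to_plasma_ratio) / (hct * fup)
    P = 10.0 ** compound.logP
    Yp = _Y(compound, ref.pH_plasma)
    Ybc = _Y(compound, ref.pH_blood_cells)
    D = ref.plasma_f_water + _lipid_term(P, ref.plasma_f_nl, ref.plasma_f_np) / Yp
    resid = (kpu_bc * D
             - (Ybc / Yp) * ref.bc_f_iw
             - _lipid_term(P, ref.bc_f_nl, ref.bc_f_np) / Yp)
    cat = _cation_ratio(compound, ref.pH_blood_cells)
    if resid <= 0 or cat <= 0 or ref.bc_ap_mg_g <= 0:
        return 0.0
    return resid * Yp / (ref.bc_ap_mg_g * cat)


def compute_kp(compound: CompoundParameters, tissue: TissueComposition,
               plasma_reference: PlasmaReference | None = None) -> float:
    """Tissue:plasma partition coefficient (mechanistic, perfusion-limited).

    Sums distribution into extracellular water, pH-partitioned intracellular
    water, neutral lipid/phospholipid and (for ionisable bases/ampholytes)
    acidic-phospholipid-bound cation, normalised by the plasma phase
    (water + neutral lipid). Multiplying the unbound coefficient by fup
    yields the total tissue:plasma ratio used in the organ equations.
    """
    ref = plasma_reference or PlasmaReference.default()
    P = 10.0 ** compound.logP
    Yp = _Y(compound, ref.pH_plasma)
    Yiw = _Y(compound, tissue.intracellular_pH)
    ka = ka_acidic_phospholipid(compound, ref)
    cat_iw = _cation_ratio(compound, tissue.intracellular_pH)
    num = (tissue.fraction_extracellular_water
           + (Yiw / Yp) * tissue.fraction_intracellular_water
           + _lipid_term(P, tissue.fraction_neutral_lipid,
                         tissue.fraction_neutral_phospholipid) / Yp
           + ka * tissue.acidic_phospholipid_mg_per_g * cat_iw / Yp)
    den = ref.plasma_f_water + _lipid_term(P, ref.plasma_f_nl, ref.plasma_f_np) / Yp
    kp = compound.fraction_unbound_plasma * num / den
    if kp <= 0:
        raise ValueError(f"non-positive Kp computed for {compound.name}")
    return kp


def estimate_permeability(compound: CompoundParameters) -> float:
    """Cellular permeability (cm/min) from lipophilicity and size.

    log10 P_cell = c0 + c1*logP - c2*log10(MW), coefficients from the
    packaged constants file; monotone increasing in logP and decreasing
    in molecular weight.
    """
    c = load_packaged_yaml("constants.yaml")["permeability"]
    exponent = (float(c["c0"]) + float(c["c1"]) * compound.logP
                - float(c["c2"]) * math.log10(compound.molecular_weight))
    return 10.0 ** exponent
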