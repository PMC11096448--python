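"""Reference adult physiology and virtual-population sampling.

The whole-body model uses 18 compartments: 15 perfused tissues/organs plus
arterial blood, venous blood and the portal vein. Reference individuals
(European, Asian, African-American, White-American adult males and their
female counterparts by body-size scaling) are read from packaged YAML files;
a canonical organ table supplies volumes and blood-flow fractions, and each
reference file supplies anthropometry plus a volume scale.

Virtual populations are sampled by independent log-normal perturbation of
organ volumes, blood flows and enzyme abundances around a reference
individual, with blood flows renormalised to cardiac output afterwards.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._data import load_packaged_yaml

__all__ = [
    "TissueComposition",
    "OrganPhysiology",
    "Individual",
    "PopulationSpec",
    "build_reference_individual",
    "sample_population",
    "population_frame",
    "ORGAN_NAMES",
    "TISSUE_ORGANS",
    "BLOOD_COMPARTMENTS",
    "PORTAL_DRAINED",
]

#: Compartment names in canonical order (15 tissues + 3 blood pools).
ORGAN_NAMES = (
    "lung", "liver", "kidney", "gut", "stomach", "spleen", "pancreas",
    "muscle", "adipose", "brain", "heart", "skin", "bone", "gonads", "rest",
    "arterial_blood", "venous_blood", "portal_vein",
)
BLOOD_COMPARTMENTS = ("arterial_blood", "venous_blood", "portal_vein")
TISSUE_ORGANS = tuple(n for n in ORGAN_NAMES if n not in BLOOD_COMPARTMENTS)
PORTAL_DRAINED = ("gut", "stomach", "spleen", "pancreas")

SUPPORTED_ETHNICITIES = {
    "European": "european_male",
    "Asian": "asian_male",
    "AfricanAmerican": "african_american_male",
    "WhiteAmerican": "white_american_male",
}

#: Body-weight ratio applied for female references (reference-woman vs -man).
FEMALE_WEIGHT_RATIO = 0.82


class ConfigurationError(ValueError):
    """Raised when a reference individual cannot be built from the request."""


@dataclass(frozen=True)
class TissueComposition:
    """Volume-fraction composition of one tissue.

    Water sub-fractions must add up to ``fraction_water``; the acidic
    phospholipid content drives cation binding in the partitioning model.
    """

    fraction_water: float
    fraction_intracellular_water: float
    fraction_extracellular_water: float
    fraction_neutral_lipid: float
    fraction_neutral_phospholipid: float
    acidic_phospholipid_mg_per_g: float
    albumin_ratio_tissue_to_plasma: float
    intracellular_pH: float

    def __post_init__(self) -> None:
        for name in ("fraction_water", "fraction_intracellular_water",
                     "fraction_extracellular_water", "fraction_neutral_lipid",
                     "fraction_neutral_phospholipid"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if abs(self.fraction_intracellular_water
               + self.fraction_extracellular_water
               - self.fraction_water) > 1e-9:
            raise ValueError("water sub-fractions do not sum to fraction_water")
        if not 6.0 <= self.intracellular_pH <= 8.0:
            raise ValueError(f"intracellular pH {self.intracellular_pH} outside [6, 8]")


@dataclass(frozen=True)
class OrganPhysiology:
    """One compartment: volume, perfusing blood flow and composition."""

    name: str
    volume_L: float
    blood_flow_L_min: float
    composition: TissueComposition

    def __post_init__(self) -> None:
        if self.volume_L <= 0:
            raise ValueError(f"{self.name}: volume must be positive")
        if self.blood_flow_L_min < 0:
            raise ValueError(f"{self.name}: blood flow must be non-negative")


@dataclass(frozen=True)
class Individual:
    """A virtual human: anthropometry, organ set and enzyme abundances."""

    sex: str
    age_years: float
    ethnicity: str
    body_weight_kg: float
    cardiac_output_L_min: float
    gfr_mL_min: float
    hematocrit: float
    organs: dict[str, OrganPhysiology]
    cyp2d6_abundance: float = 1.0
    cyp3a4_abundance: float = 1.0
    ugt2b7_abundance: float = 1.0

    def __post_init__(self) -> None:
        if set(self.organs) != set(ORGAN_NAMES):
            missing = set(ORGAN_NAMES) ^ set(self.organs)
            raise ValueError(f"individual must have exactly the 18 canonical "
                             f"compartments; mismatch: {sorted(missing)}")
        for a in (self.cyp2d6_abundance, self.cyp3a4_abundance, self.ugt2b7_abundance):
            if a <= 0:
                raise ValueError("enzyme abundances must be positive")
        non_blood = sum(o.volume_L for n, o in self.organs.items()
                        if n not in BLOOD_COMPARTMENTS)
        if non_blood > self.body_weight_kg / 0.95:
            raise ValueError("organ volumes exceed body weight")
        q = self.systemic_flow_L_min
        if abs(q - self.cardiac_output_L_min) > 0.01 * self.cardiac_output_L_min:
            raise ValueError(
                f"tissue blood flows ({q:.3f} L/min) do not balance cardiac "
                f"output ({self.cardiac_output_L_min:.3f} L/min)")

    @property
    def systemic_flow_L_min(self) -> float:
        """Sum of tissue blood flows (lung and blood pools excluded)."""
        return sum(o.blood_flow_L_min for n, o in self.organs.items()
                   if n not in BLOOD_COMPARTMENTS and n != "lung")

    @property
    def portal_flow_L_min(self) -> float:
        return sum(self.organs[n].blood_flow_L_min for n in PORTAL_DRAINED)

    @property
    def enzyme_abundances(self) -> dict[str, float]:
        return {"CYP2D6": self.cyp2d6_abundance,
                "CYP3A4": self.cyp3a4_abundance,
                "UGT2B7": self.ugt2b7_abundance}


@dataclass(frozen=True)
class PopulationSpec:
    """Specification of a virtual population.

    Coefficients of variation are log-normal CVs per parameter class;
    ``body_size_cv`` scales all organ volumes together (cardiac output
    follows allometrically with exponent 0.75). ``age_range`` of ``None``
    keeps the reference age.
    """

    n: int
    seed: int = 0
    age_range: tuple[float, float] | None = None
    body_size_cv: float = 0.0
    cv_volumes: float = 0.10
    cv_flows: float = 0.15
    cv_enzymes: float = 0.35

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("population size n must be >= 1")
        for name in ("body_size_cv", "cv_volumes", "cv_flows", "cv_enzymes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _composition_from_row(row: dict) -> TissueComposition:
    few, fiw = float(row["f_ew"]), float(row["f_iw"])
    return TissueComposition(
        fraction_water=few + fiw,
        fraction_intracellular_water=fiw,
        fraction_extracellular_water=few,
        fraction_neutral_lipid=float(row["f_nl"]),
        fraction_neutral_phospholipid=float(row["f_np"]),
        acidic_phospholipid_mg_per_g=float(row["ap_mg_g"]),
        albumin_ratio_tissue_to_plasma=float(row["albumin_ratio"]),
        intracellular_pH=float(row["pH_iw"]),
    )


def _blood_composition() -> TissueComposition:
    # Blood pools are modelled as plasma-like phases; their composition is a
    # placeholder (partitioning uses the blood:plasma ratio directly).
    return TissueComposition(0.945, 0.0, 0.945, 0.0023, 0.0013, 0.0, 0.0, 7.4)


def tissue_compositions() -> dict[str, TissueComposition]:
    """Packaged tissue-composition table, keyed by organ name."""
    raw = load_packaged_yaml("tissue_composition.yaml")
    return {name: _composition_from_row(row) for name, row in raw["tissues"].items()}


def build_reference_individual(sex: str = "male", age_years: float = 30.0,
                               ethnicity: str = "European") -> Individual:
    """Build the fully populated reference individual for one ethnicity.

    Supported ethnicities are European, Asian, AfricanAmerican and
    WhiteAmerican; age must lie in the adult range [18, 65]. Female
    references are derived by body-size scaling of the male file.
    """
    if ethnicity not in SUPPORTED_ETHNICITIES:
        raise ConfigurationError(
            f"unsupported ethnicity {ethnicity!r}; supported: "
            f"{sorted(SUPPORTED_ETHNICITIES)}")
    if not 18.0 <= age_years <= 65.0:
        raise ConfigurationError(f"unsupported age {age_years}; adult range is [18, 65]")
    if sex not in ("male", "female"):
        raise ConfigurationError(f"unsupported sex {sex!r}")

    ref = load_packaged_yaml(f"physiology/{SUPPORTED_ETHNICITIES[ethnicity]}.yaml")
    table = load_packaged_yaml("physiology/organ_table.yaml")
    comps = tissue_compositions()
    blood_comp = _blood_composition()

    scale = float(ref["volume_scale"])
    bw = float(ref["body_weight_kg"])
    co = float(ref["cardiac_output_L_min"])
    gfr = float(ref["gfr_mL_min"])
    if sex == "female":
        r = FEMALE_WEIGHT_RATIO
        scale *= r
        bw *= r
        co *= r ** 0.75
        gfr *= r ** 0.75

    organs: dict[str, OrganPhysiology] = {}
    portal_flow = sum(float(table["organs"][n]["flow_fraction"]) for n in PORTAL_DRAINED)
    for name in ORGAN_NAMES:
        row = table["organs"][name]
        vol = float(row["volume_L"]) * scale
        if name == "lung":
            flow = co
        elif name == "arterial_blood" or name == "venous_blood":
            flow = co
        elif name == "portal_vein":
            flow = portal_flow * co
        else:
            flow = float(row["flow_fraction"]) * co
        comp = comps.get(name, blood_comp) if name not in BLOOD_COMPARTMENTS else blood_comp
        organs[name] = OrganPhysiology(name, vol, flow, comp)

    ab = ref["enzyme_abundance"]
    return Individual(
        sex=sex, age_years=float(age_years), ethnicity=ethnicity,
        body_weight_kg=bw, cardiac_output_L_min=co, gfr_mL_min=gfr,
        hematocrit=float(ref["hematocrit"]), organs=organs,
        cyp2d6_abundance=float(ab["CYP2D6"]),
        cyp3a4_abundance=float(ab["CYP3A4"]),
        ugt2b7_abundance=float(ab["UGT2B7"]),
    )


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int | None = None):
    """Multiplicative log-normal perturbation with unit median."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=0.0, sigma=sigma, size=size)


def sample_population(spec: PopulationSpec, reference: Individual) -> list[Individual]:
    """Sample ``spec.n`` virtual individuals around a reference.

    Organ volumes, blood flows and enzyme abundances are perturbed by
    independent log-normal factors (per-class CVs from the spec); flows are
    renormalised so their sum matches the (possibly size-scaled) cardiac
    output exactly. Sampling is fully determined by ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    if (spec.age_range is None and spec.body_size_cv == 0
            and spec.cv_volumes == 0 and spec.cv_flows == 0
            and spec.cv_enzymes == 0):
        return [reference] * spec.n        # exact identity at zero variability
    out: list[Individual] = []
    tissue_names = [n for n in ORGAN_NAMES if n not in BLOOD_COMPARTMENTS]
    ref_total_volume = sum(o.volume_L for o in reference.organs.values())
    for _ in range(spec.n):
        size = _lognormal_factor(rng, spec.body_size_cv)
        co = reference.cardiac_output_L_min * size ** 0.75
        age = (reference.age_years if spec.age_range is None
               else float(rng.uniform(*spec.age_range)))

        vol_f = _lognormal_factor(rng, spec.cv_volumes, len(tissue_names))
        flow_f = _lognormal_factor(rng, spec.cv_flows, len(tissue_names))

        # raw flows for systemic organs, then renormalise to cardiac output
        raw = {}
        for name, vf, ff in zip(tissue_names, vol_f, flow_f):
            o = reference.organs[name]
            raw[name] = (o.volume_L * size * vf, o.blood_flow_L_min * ff)
        systemic = [n for n in tissue_names if n != "lung"]
        qsum = sum(raw[n][1] for n in systemic)
        norm = co / qsum

        organs: dict[str, OrganPhysiology] = {}
        for name in tissue_names:
            o = reference.organs[name]
            vol, q = raw[name]
            flow = co if name == "lung" else q * norm
            organs[name] = replace(o, volume_L=vol, blood_flow_L_min=flow)
        portal_flow = sum(organs[n].blood_flow_L_min for n in PORTAL_DRAINED)
        for name in BLOOD_COMPARTMENTS:
            o = reference.organs[name]
            flow = portal_flow if name == "portal_vein" else co
            organs[name] = replace(o, volume_L=o.volume_L * size, blood_flow_L_min=flow)

        enz = _lognormal_factor(rng, spec.cv_enzymes, 3)
        # body weight tracks the sampled total organ volume so the volume
        # invariant (organs fit into the body) is preserved under sampling
        total_volume = sum(o.volume_L for o in organs.values())
        out.append(Individual(
            sex=reference.sex, age_years=age, ethnicity=reference.ethnicity,
            body_weight_kg=reference.body_weight_kg * total_volume / ref_total_volume,
            cardiac_output_L_min=co,
            gfr_mL_min=reference.gfr_mL_min * size ** 0.75,
            hematocrit=reference.hematocrit, organs=organs,
            cyp2d6_abundance=reference.cyp2d6_abundance * enz[0],
            cyp3a4_abundance=reference.cyp3a4_abundance * enz[1],
            ugt2b7_abundance=reference.ugt2b7_abundance * enz[2],
        ))
    return out


def population_frame(individuals: list[Individual]) -> pd.DataFrame:
    """Export a population as one row per individual (sampled parameters)."""
    rows = []
    for i, ind in enumerate(individuals):
        row = {
            "individual": i, "sex": ind.sex, "age_years": ind.age_years,
            "ethnicity": ind.ethnicity, "body_weight_kg": ind.body_weight_kg,
            "cardiac_output_L_min": ind.cardiac_output_L_min,
            "gfr_mL_min": ind.gfr_mL_min,
            "cyp2d6_abundance": ind.cyp2d6_abundance,
            "cyp3a4_abundance": ind.cyp3a4_abundance,
            "ugt2b7_abundance": ind.ugt2b7_abundance,
        }
        for name in ORGAN_NAMES:
            row[f"V_{name}_L"] = ind.organs[name].volume_L
            row[f"Q_{name}_L_min"] = ind.organs[name].blood_flow_L_min
        rows.append(row)
    return pd.DataFrame(rows)
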