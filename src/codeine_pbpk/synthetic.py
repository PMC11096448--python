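"""Synthetic "observed" clinical datasets.

Stands in for digitized literature concentration-time profiles: the ground
truth is simulated with the PBPK engine (optionally with population
variability), sampled at a sparse clinical grid, disturbed by multiplicative
log-normal residual error and averaged arithmetically per time point —
the structure of mean profiles digitized from published figures. The true
parameters are recorded alongside so parameter-recovery tests can compare
against a known truth. Fully seeded and reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .absorption import FormulationSpec, Regimen
from .calibration import make_simulator
from .compound import CompoundParameters, load_compound
from .phenotype import REFERENCE_ACTIVITY_SCORE
from .physiology import (Individual, PopulationSpec, build_reference_individual,
                         sample_population)

__all__ = ["SyntheticStudySpec", "generate_observed_dataset"]

#: Sparse clinical sampling grid (h) mirroring published figure grids.
DEFAULT_TIMES_H = (0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 24.0)


@dataclass(frozen=True)
class SyntheticStudySpec:
    """Design of one synthetic study."""

    regimen: Regimen
    activity_score: float = REFERENCE_ACTIVITY_SCORE
    ethnicity: str = "European"
    times_h: tuple[float, ...] = DEFAULT_TIMES_H
    n_subjects: int = 12
    residual_cv: float = 0.20
    inter_individual: bool = False
    population: PopulationSpec | None = None
    seed: int = 0
    study_id: str | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h)
        if np.any(np.diff(t) <= 0):
            raise ValueError("sampling times must be strictly increasing")
        if self.residual_cv < 0:
            raise ValueError("residual CV must be >= 0")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")


def generate_observed_dataset(spec: SyntheticStudySpec,
                              truth_overrides: dict[str, float] | None = None,
                              individual: Individual | None = None,
                              parent: CompoundParameters | None = None,
                              metabolite: CompoundParameters | None = None,
                              enzyme_scales: dict[str, float] | None = None,
                              out_path: str | Path | None = None
                              ) -> tuple[pd.DataFrame, dict]:
    """Generate one synthetic observed dataset plus its truth record.

    Residual error is log-normal with unit median applied per subject and
    time point; reported concentrations are arithmetic means over subjects.
    With ``inter_individual`` set, each subject is a sampled individual from
    the population spec. Writing ``out_path`` also writes a ``.truth.json``
    sidecar with the generating parameters.
    """
    truth_overrides = dict(truth_overrides or {})
    rng = np.random.default_rng(spec.seed)
    parent = parent or load_compound("codeine")
    metabolite = metabolite or load_compound("morphine")
    individual = individual or build_reference_individual("male", 30, spec.ethnicity)
    times = np.asarray(spec.times_h, dtype=float)

    if spec.inter_individual:
        pop_spec = spec.population or PopulationSpec(n=spec.n_subjects,
                                                     seed=spec.seed)
        subjects = sample_population(pop_spec, individual)
        if len(subjects) != spec.n_subjects:
            raise ValueError("population spec n must equal n_subjects")
    else:
        subjects = [individual] * spec.n_subjects

    sigma = (np.sqrt(np.log1p(spec.residual_cv ** 2))
             if spec.residual_cv > 0 else 0.0)
    study = spec.study_id or f"synthetic-{spec.seed}"

    profiles = []
    cache: dict[int, pd.DataFrame] = {}
    for subj in subjects:
        key = id(subj)
        if key not in cache:
            sim = make_simulator(subj, parent, metabolite, spec.regimen,
                                 spec.activity_score,
                                 t_end_h=float(times[-1]),
                                 enzyme_scales=enzyme_scales)
            cache[key] = sim(truth_overrides, times)
        truth_frame = cache[key].copy()
        noise = (np.exp(rng.normal(0.0, sigma, size=len(truth_frame)))
                 if sigma > 0 else 1.0)
        truth_frame["conc_ng_per_ml"] = truth_frame["conc_ng_per_ml"] * noise
        profiles.append(truth_frame)

    stacked = pd.concat(profiles, ignore_index=True)
    mean = (stacked.groupby(["analyte", "time_h"], as_index=False)
            ["conc_ng_per_ml"].mean())
    mean.insert(0, "study_id", study)
    mean["n_subjects"] = spec.n_subjects
    mean = mean.sort_values(["analyte", "time_h"]).reset_index(drop=True)

    truth = {
        "study_id": study, "seed": spec.seed,
        "activity_score": spec.activity_score,
        "ethnicity": spec.ethnicity,
        "dose_mg": spec.regimen.dose_mg,
        "formulation": spec.regimen.formulation.kind,
        "n_subjects": spec.n_subjects,
        "residual_cv": spec.residual_cv,
        "inter_individual": spec.inter_individual,
        "overrides": truth_overrides,
    }
    if out_path is not None:
        out_path = Path(out_path)
        from .pk_metrics import write_observed
        write_observed(mean, out_path)
        out_path.with_suffix(".truth.json").write_text(
            json.dumps(truth, indent=2), encoding="utf-8")
    return mean, truth
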