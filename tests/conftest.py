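import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import codeine_pbpk as cp

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def codeine():
    return cp.load_compound("codeine")


@pytest.fixture(scope="session")
def morphine():
    return cp.load_compound("morphine")


@pytest.fixture(scope="session")
def european():
    return cp.build_reference_individual("male", 30, "European")


@pytest.fixture(scope="session")
def asian():
    return cp.build_reference_individual("male", 30, "Asian")


@pytest.fixture(scope="session")
def tablet_30mg(codeine):
    return cp.Regimen(dose_mg=30.0,
                      formulation=cp.FormulationSpec.from_compound(codeine, "tablet"))


@pytest.fixture(scope="session")
def em_result(asian, codeine, morphine, tablet_30mg):
    """Accurate-tolerance EM reference simulation (Asian, 30 mg tablet)."""
    model = cp.PBPKModel(asian, codeine, morphine, activity_score=1.5)
    return model.simulate(tablet_30mg, t_end_h=24.0)


@pytest.fixture(scope="session")
def phenotype_aucs(asian, codeine, morphine, tablet_30mg):
    """Morphine/codeine AUC_0-inf at 30 mg across the phenotype scores."""
    out = {}
    for score in (0.0, 0.75, 1.5, 2.75):
        model = cp.PBPKModel(asian, codeine, morphine, activity_score=score)
        res = model.simulate(tablet_30mg, t_end_h=24.0, fast=True)
        out[score] = {"morphine": res.nca("morphine").auc_0_inf,
                      "codeine": res.nca("codeine").auc_0_inf}
    return out
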