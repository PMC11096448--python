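"""Compound parameters, ionisation, partitioning and permeability."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import codeine_pbpk as cp
from codeine_pbpk.compound import (PlasmaReference, compute_kp,
                                   estimate_permeability, ionized_fractions,
                                   load_compound, save_compound)
from codeine_pbpk.physiology import TissueComposition, tissue_compositions


def make_compound(**kw):
    base = dict(name="probe", molecular_weight=300.0, logP=1.0,
                pKa_acid=None, pKa_base=9.0, ionization_class="base",
                solubility_mg_per_mL_pH7=1.0, fraction_unbound_plasma=0.8,
                blood_to_plasma_ratio=1.0, renal_clearance_mL_min_kg=0.0,
                specific_clearance_per_min=0.0)
    base.update(kw)
    return cp.CompoundParameters(**base)


class TestIonizedFractions:
    def test_base_half_ionized_at_pka(self):
        c = make_compound(pKa_base=7.4)
        f = ionized_fractions(c, 7.4)
        assert f["cation"] == pytest.approx(0.5)
        assert f["neutral"] == pytest.approx(0.5)

    def test_codeine_at_plasma_ph(self, codeine):
        # Henderson-Hasselbalch by hand: 10^(9.19-7.4)/(1+10^(9.19-7.4))
        x = 10 ** (9.19 - 7.4)
        f = ionized_fractions(codeine, 7.4)
        assert f["cation"] == pytest.approx(x / (1 + x), rel=1e-12)

    def test_neutral_compound_never_ionized(self):
        c = make_compound(pKa_base=None, ionization_class="neutral")
        for ph in (1.0, 7.4, 13.0):
            f = ionized_fractions(c, ph)
            assert f["neutral"] == 1.0 and f["cation"] == 0.0

    @given(ph=st.floats(0, 14), pka_b=st.floats(4, 12), pka_a=st.floats(4, 12))
    def test_fractions_sum_to_one_all_classes(self, ph, pka_b, pka_a):
        for c in (make_compound(pKa_base=pka_b),
                  make_compound(pKa_base=pka_b, pKa_acid=pka_a,
                                ionization_class="ampholyte"),
                  make_compound(pKa_base=None, ionization_class="neutral")):
            f = ionized_fractions(c, ph)
            assert sum(f.values()) == pytest.approx(1.0, abs=1e-12)

    def test_ph_outside_range_rejected(self):
        with pytest.raises(ValueError, match="pH"):
            ionized_fractions(make_compound(), 14.5)


def kp_oracle(c, t, ref):
    """Independent single-expression partition-coefficient evaluation."""
    P = 10.0 ** c.logP
    ion = lambda ph: (1.0
                      + (10.0 ** (c.pKa_base - ph)
                         if c.ionization_class in ("base", "ampholyte") else 0.0)
                      + (10.0 ** (ph - c.pKa_acid)
                         if c.ionization_class == "ampholyte" else 0.0))
    cat = lambda ph: (10.0 ** (c.pKa_base - ph)
                      if c.ionization_class in ("base", "ampholyte") else 0.0)
    lip = lambda fnl, fnp: P * fnl + (0.3 * P + 0.7) * fnp
    D = ref.plasma_f_water + lip(ref.plasma_f_nl, ref.plasma_f_np) / ion(ref.pH_plasma)
    kpu_bc = (ref.hematocrit - 1 + c.blood_to_plasma_ratio) / (
        ref.hematocrit * c.fraction_unbound_plasma)
    resid = (kpu_bc * D - ion(ref.pH_blood_cells) / ion(ref.pH_plasma) * ref.bc_f_iw
             - lip(ref.bc_f_nl, ref.bc_f_np) / ion(ref.pH_plasma))
    ka = (max(resid, 0.0) * ion(ref.pH_plasma)
          / (ref.bc_ap_mg_g * cat(ref.pH_blood_cells))
          if c.ionization_class != "neutral" and cat(ref.pH_blood_cells) > 0
          and resid > 0 else 0.0)
    return c.fraction_unbound_plasma * (
        t.fraction_extracellular_water
        + ion(t.intracellular_pH) / ion(ref.pH_plasma) * t.fraction_intracellular_water
        + lip(t.fraction_neutral_lipid, t.fraction_neutral_phospholipid)
        / ion(ref.pH_plasma)
        + ka * t.acidic_phospholipid_mg_per_g * cat(t.intracellular_pH)
        / ion(ref.pH_plasma)) / D


class TestPartitionCoefficient:
    def test_symmetric_phases_give_unity(self):
        plasma_like = TissueComposition(
            fraction_water=0.945, fraction_intracellular_water=0.0,
            fraction_extracellular_water=0.945, fraction_neutral_lipid=0.0023,
            fraction_neutral_phospholipid=0.0013,
            acidic_phospholipid_mg_per_g=0.0,
            albumin_ratio_tissue_to_plasma=1.0, intracellular_pH=7.4)
        c = make_compound(logP=0.0, fraction_unbound_plasma=1.0,
                          pKa_base=None, ionization_class="neutral")
        assert compute_kp(c, plasma_like) == pytest.approx(1.0, rel=1e-12)

    def test_matches_independent_oracle_on_random_pairs(self):
        rng = np.random.default_rng(20240502)
        ref = PlasmaReference.default()
        tissues = list(tissue_compositions().values())
        for _ in range(100):
            cls = rng.choice(["base", "ampholyte", "neutral"])
            c = make_compound(
                logP=float(rng.uniform(-1, 4)),
                pKa_base=(float(rng.uniform(7, 11))
                          if cls != "neutral" else None),
                pKa_acid=(float(rng.uniform(7.5, 11))
                          if cls == "ampholyte" else None),
                ionization_class=cls,
                fraction_unbound_plasma=float(rng.uniform(0.05, 1.0)),
                blood_to_plasma_ratio=float(rng.uniform(0.6, 2.0)))
            t = tissues[int(rng.integers(len(tissues)))]
            assert compute_kp(c, t, ref) == pytest.approx(
                kp_oracle(c, t, ref), rel=1e-10)

    def test_codeine_muscle_against_oracle(self, codeine):
        ref = PlasmaReference.default()
        muscle = tissue_compositions()["muscle"]
        assert compute_kp(codeine, muscle, ref) == pytest.approx(
            kp_oracle(codeine, muscle, ref), rel=1e-10)

    def test_kp_nondecreasing_in_logp(self):
        muscle = tissue_compositions()["muscle"]
        kps = [compute_kp(make_compound(logP=lp, pKa_base=None,
                                        ionization_class="neutral"), muscle)
               for lp in np.linspace(-1, 4, 15)]
        assert all(b >= a for a, b in zip(kps, kps[1:]))

    def test_all_packaged_organ_kps_positive(self, codeine, morphine):
        ref = PlasmaReference.default()
        for comp in (codeine, morphine):
            for t in tissue_compositions().values():
                assert compute_kp(comp, t, ref) > 0


class TestPermeability:
    def test_codeine_matches_documented_correlation(self, codeine):
        expected = 10 ** (2.41 + 0.47 * 2.6 - 2.0 * math.log10(299.36))
        assert estimate_permeability(codeine) == pytest.approx(expected, rel=1e-12)

    def test_larger_molecules_are_less_permeable(self):
        small = make_compound(molecular_weight=250.0)
        large = make_compound(molecular_weight=450.0)
        assert estimate_permeability(large) < estimate_permeability(small)

    def test_more_lipophilic_is_more_permeable(self):
        lo = make_compound(logP=0.5)
        hi = make_compound(logP=3.0)
        assert estimate_permeability(hi) > estimate_permeability(lo)

    def test_identical_compounds_identical_permeability(self, codeine):
        assert estimate_permeability(codeine) == estimate_permeability(
            replace(codeine))


class TestCompoundFiles:
    @pytest.mark.parametrize("name", ["codeine", "morphine"])
    def test_roundtrip_preserves_every_field(self, name, tmp_path):
        c = load_compound(name)
        path = tmp_path / f"{name}.yaml"
        save_compound(c, str(path))
        assert load_compound(str(path)) == c

    def test_packaged_codeine_carries_table_values(self, codeine):
        assert codeine.molecular_weight == 299.36
        assert codeine.pathway("CYP2D6").kcat_per_min == 1.6
        assert codeine.pathway("CYP2D6").km_uM == 100.0
        assert codeine.pathway("UGT2B7").km_uM == 2320.0  # 2.32 mM in uM
        assert codeine.formulations["tablet"].dissolution_shape == 0.92

    def test_invalid_fup_rejected(self):
        with pytest.raises(ValueError, match="fup"):
            make_compound(fraction_unbound_plasma=0.0)
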