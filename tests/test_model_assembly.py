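"""Network assembly, characterisation records and model invariants."""

import numpy as np
import pytest

from isogly.model_assembly import (
    TABLE1_ORDER,
    apply_characterisation,
    build_model,
    characterisation_records,
)
from isogly.simulate import Dynamics
from isogly.units import CellGeometry


def test_iteration0_branches_are_first_order(model0):
    from isogly.rate_laws import FirstOrder

    for group in ("Glycogen_branch", "Trehalose_branch", "Succinate_branch"):
        (rx,) = model0.reactions_in(group)
        assert isinstance(rx.law, FirstOrder)
    assert not model0.characterised


def test_empty_queue_equals_iteration0(tables, config, model0):
    other = build_model(0, tables=tables, config=config, queue=[])
    assert other.characterised == model0.characterised == set()
    assert [r.id for r in other.reactions] == [r.id for r in model0.reactions]
    c = model0.initial_concentrations()
    r0, r1 = model0.rates(c), other.rates(c)
    assert r0 == r1


def test_iteration18_has_three_hxk_isoenzymes(model18):
    (hxk,) = model18.reactions_in("HXK")
    assert sorted(e.id for e in hxk.isoenzymes) == ["Glk1p", "Hxk1p", "Hxk2p"]
    assert model18.characterised >= set(TABLE1_ORDER)


def test_characterisation_sequence_matches_published_order(tables, config):
    model = build_model(0, tables=tables, config=config)
    recs = characterisation_records(tables, config, model.geometry)
    for i, group in enumerate(TABLE1_ORDER, start=1):
        model = apply_characterisation(model, group, recs[group])
        assert group in model.characterised
        expected = build_model(0, tables=tables, config=config,
                               queue=TABLE1_ORDER[:i])
        assert model.characterised == expected.characterised


def test_apply_preserves_other_reactions_and_original_model(model0, tables, config):
    recs = characterisation_records(tables, config, model0.geometry)
    before = model0.rates(model0.initial_concentrations())
    new = apply_characterisation(model0, "HXK", recs["HXK"])
    after_original = model0.rates(model0.initial_concentrations())
    assert before == after_original          # original untouched (revertible)
    c = new.initial_concentrations()
    r_new, r_old = new.rates(c), model0.rates(c)
    for rid in r_old:
        if rid != "HXK":
            assert r_new[rid] == pytest.approx(r_old[rid], rel=1e-14)


def test_recharacterisation_rejected(model18, tables, config):
    recs = characterisation_records(tables, config, model18.geometry)
    with pytest.raises(ValueError, match="already characterised"):
        apply_characterisation(model18, "HXK", recs["HXK"])


def test_missing_protein_copy_number_is_a_named_error(tables, config):
    broken = tables.proteins[tables.proteins["isoenzyme"] != "Hxk2p"]
    import dataclasses

    bad = dataclasses.replace(tables, proteins=broken)
    with pytest.raises(KeyError, match="Hxk2p"):
        characterisation_records(bad, config, CellGeometry(5.0))


@pytest.mark.parametrize("iteration", [0, 18])
def test_conserved_moieties_have_zero_net_stoichiometry(tables, config, iteration):
    model = build_model(iteration, tables=tables, config=config)
    dyn = Dynamics(model)
    moieties = dyn.moieties()
    supports = [frozenset(g) for g in moieties]
    assert frozenset({"ATP", "ADP", "AMP"}) in supports
    assert frozenset({"NAD", "NADH"}) in supports
    for g in moieties:
        vec = np.array([g.get(s, 0.0) for s in dyn.species])
        assert np.allclose(vec @ dyn.N, 0.0)


def test_prefit_and_final_volume_defaults(model0, model18):
    assert model0.geometry.cytoplasmic_volume_fl == 20.0
    assert model18.geometry.cytoplasmic_volume_fl == 5.0
    # measured metabolite initials scale with the conversion volume
    assert model0.metabolites["F16bP"].concentration == pytest.approx(
        model18.metabolites["F16bP"].concentration / 4.0, rel=1e-12
    )


def test_fitted_globals_in_final_model(model18, config):
    (atpase,) = model18.reactions_in("ATPase")
    assert atpase.law.V == pytest.approx(config["atpase_fitted_V"])
    (suc,) = model18.reactions_in("Succinate_branch")
    c = model18.full_concentrations({"ACE": 5.0})
    assert suc.rate(c) == 0.0  # branch turned off by the fit


def test_validate_catches_unknown_species(model0):
    bad = model0.copy()
    bad.reactions[0].stoichiometry["NOT_A_METABOLITE"] = 1
    with pytest.raises(ValueError, match="NOT_A_METABOLITE"):
        bad.validate()
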