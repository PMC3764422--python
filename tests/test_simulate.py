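"""Integration, steady-state location and adenylate energy charge."""

import math

import numpy as np
import pytest

from isogly.simulate import Dynamics, energy_charge, integrate, steady_state
from isogly.synthetic_data import make_toy_network


def test_zero_rate_model_has_constant_trajectory():
    m = make_toy_network("linear2", params={"k1": 0.0, "k2": 0.0})
    tr = integrate(m, (0.0, 100.0), n_points=20)
    assert tr.success
    assert np.allclose(tr.concentrations, tr.concentrations[:, [0]], atol=1e-12)


def test_single_reversible_reaction_exponential_approach():
    # A(fixed) <-> B with v = k*(A - B/Keq): B(t) = B_inf + (B0-B_inf)e^{-kt/Keq}
    p = {"A": 2.0, "k1": 0.8, "k2": 0.0, "Keq": 1.5}
    m = make_toy_network("linear2", params=p)
    b0 = m.metabolites["B"].concentration
    b_inf = p["A"] * p["Keq"]
    tr = integrate(m, (0.0, 5.0), n_points=40)
    i = m.internal_species.index("B")  # type: ignore[attr-defined]
    for t, b in zip(tr.times, tr.concentrations[tr.species.index("B")], strict=True):
        expected = b_inf + (b0 - b_inf) * math.exp(-p["k1"] * t / p["Keq"])
        assert b == pytest.approx(expected, rel=1e-6, abs=1e-8)


def test_moiety_conservation_along_trajectory(model18):
    tr = integrate(model18, (0.0, 50.0), n_points=25)
    assert tr.success
    dyn = Dynamics(model18)
    for g in dyn.moieties():
        vec = np.array([g.get(s, 0.0) for s in tr.species])
        totals = vec @ tr.concentrations
        assert np.allclose(totals, totals[0], rtol=1e-6)


def test_linear_chain_steady_state_matches_algebra():
    p = {"A": 3.0, "k1": 1.2, "k2": 0.4, "Keq": 2.0}
    m = make_toy_network("linear2", params=p)
    ss = steady_state(m)
    assert ss.converged and ss.residual < 1e-9
    b_expected = p["k1"] * p["A"] / (p["k2"] + p["k1"] / p["Keq"])
    assert ss.concentrations["B"] == pytest.approx(b_expected, rel=1e-9)
    assert ss.fluxes["R1"] == pytest.approx(ss.fluxes["R2"], abs=1e-10)


def test_steady_state_idempotent(model18, ss18):
    again = steady_state(model18, initial=ss18.concentrations)
    assert again.converged
    for met, c in ss18.concentrations.items():
        assert again.concentrations[met] == pytest.approx(c, rel=1e-8, abs=1e-10)


def test_stoichiometric_balance_at_steady_state(model18, ss18):
    dyn = Dynamics(model18)
    c = np.array([ss18.concentrations[s] for s in dyn.species])
    assert float(np.max(np.abs(dyn.N @ dyn.rate_vector(c)))) < 1e-9


def test_steady_state_invariant_to_starting_column(model18, tables, ss18):
    """Starting from the prior literature concentrations instead of the
    measured ones lands on the same attractor."""
    prior = {
        row.id: float(row.prior_mM)
        for row in tables.metabolites.itertuples(index=False)
        if row.id != "P2G+P3G"
    }
    prior["P2G"] = 0.08
    prior["P3G"] = 1.013 - 0.08
    alt = steady_state(model18, initial=prior)
    assert alt.converged
    for met, c in ss18.concentrations.items():
        assert alt.concentrations[met] == pytest.approx(c, rel=1e-6, abs=1e-9)


def test_all_concentrations_nonnegative(ss18):
    assert all(c >= 0 for c in ss18.concentrations.values())


def test_unconverged_reports_residual_and_last_state():
    # a pure source with no consumer can never reach steady state
    from isogly.model_assembly import KineticModel, Metabolite, Reaction
    from isogly.rate_laws import FirstOrder
    from isogly.units import CellGeometry

    m = KineticModel(
        geometry=CellGeometry(5.0),
        metabolites={
            "A": Metabolite(id="A", boundary=True, concentration=1.0),
            "B": Metabolite(id="B", concentration=0.0),
        },
        reactions=[Reaction(id="R", group="R", stoichiometry={"A": -1, "B": 1},
                            law=FirstOrder(k=1.0, species="A"))],
    )
    m.activities = {"R": 1.0}
    ss = steady_state(m, max_relax=2000.0)
    assert not ss.converged
    assert ss.residual > 0.1
    assert ss.concentrations["B"] > 0  # last good state is reported


class TestEnergyCharge:
    def test_pure_atp(self):
        assert energy_charge({"ATP": 1.0, "ADP": 0.0, "AMP": 0.0}) == 1.0

    def test_pure_adp(self):
        assert energy_charge({"ATP": 0.0, "ADP": 2.0, "AMP": 0.0}) == 0.5

    def test_pure_amp(self):
        assert energy_charge({"ATP": 0.0, "ADP": 0.0, "AMP": 0.7}) == 0.0

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            energy_charge({"ATP": 0.0, "ADP": 0.0, "AMP": 0.0})
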