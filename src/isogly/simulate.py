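"""Time integration and steady-state location for kinetic models.

The ODE system is dS/dt = N·v(S) over the internal (non-boundary)
metabolites, with boundary species held fixed. The adenine-nucleotide
pool (ATP+ADP+AMP) and the pyridine pool (NAD+NADH) are conserved
moieties: their totals are invariants of N, which the steady-state
solver exploits by replacing one balance equation per moiety with the
corresponding conservation relation (otherwise the Newton system would
be singular along the pool directions).

Numerical choices: stiff integrator (BDF) with rtol 1e-8 / atol 1e-10 mM,
Newton residual tolerance 1e-9 mM/s. Solvers may probe slightly negative
concentrations during finite-difference steps; the right-hand side
clamps those to zero for rate evaluation only, and a Newton solution
with a genuinely negative concentration is rejected, never clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import sympy
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .model_assembly import KineticModel

__all__ = [
    "SteadyState",
    "Trajectory",
    "Dynamics",
    "integrate",
    "steady_state",
    "energy_charge",
]

NEWTON_TOL = 1e-9  # mM/s
RTOL = 1e-8
ATOL = 1e-10


@dataclass
class SteadyState:
    """A located steady state of the network."""

    concentrations: dict[str, float]
    fluxes: dict[str, float]
    residual: float  # max |dS/dt|, mM/s
    converged: bool
    method: str

    def flux(self, group: str, model: KineticModel) -> float:
        return model.group_flux(group, self.concentrations)


@dataclass
class Trajectory:
    times: np.ndarray
    species: list[str]
    concentrations: np.ndarray  # (n_species, n_times)
    success: bool
    message: str = ""

    def final(self) -> dict[str, float]:
        return dict(zip(self.species, self.concentrations[:, -1]))


class Dynamics:
    """Compiled ODE right-hand side for one model."""

    def __init__(self, model: KineticModel):
        self.model = model
        self.species = model.internal_species
        self.index = {s: i for i, s in enumerate(self.species)}
        self.reaction_ids = [r.id for r in model.reactions]
        n_s, n_r = len(self.species), len(model.reactions)
        self.N = np.zeros((n_s, n_r))
        for j, r in enumerate(model.reactions):
            for met, coef in r.stoichiometry.items():
                i = self.index.get(met)
                if i is not None:
                    self.N[i, j] = coef
        self._boundary = {
            m.id: m.concentration for m in model.metabolites.values() if m.boundary
        }

    # -- conserved moieties ------------------------------------------------
    def moieties(self) -> list[dict[str, float]]:
        """Integer left-nullspace vectors of N (conserved pools)."""
        mat = sympy.Matrix(self.N.astype(int)).T
        out = []
        for vec in mat.nullspace():
            denom = sympy.lcm([sympy.fraction(x)[1] for x in vec])
            ivec = [int(x * denom) for x in vec]
            if all(v <= 0 for v in ivec):
                ivec = [-v for v in ivec]
            out.append({s: float(v) for s, v in zip(self.species, ivec) if v != 0})
        return out

    # -- evaluation --------------------------------------------------------
    def conc_dict(self, c: np.ndarray) -> dict[str, float]:
        d = dict(self._boundary)
        d.update(zip(self.species, np.maximum(c, 0.0)))
        return d

    def rate_vector(self, c: np.ndarray) -> np.ndarray:
        conc = self.conc_dict(c)
        m = self.model
        return np.array([
            r.rate(conc, m.activities.get(r.group, 1.0), m.iso_activities)
            for r in m.reactions
        ])

    def f(self, t: float, c: np.ndarray) -> np.ndarray:
        return self.N @ self.rate_vector(c)

    def initial(self, initial: Mapping[str, float] | None = None) -> np.ndarray:
        base = self.model.initial_concentrations()
        if initial:
            base.update(initial)
        return np.array([base[s] for s in self.species], dtype=float)


def integrate(
    model: KineticModel,
    t_span: tuple[float, float],
    initial: Mapping[str, float] | None = None,
    n_points: int = 200,
    method: str = "BDF",
) -> Trajectory:
    """Integrate the ODE system over ``t_span`` (seconds)."""
    dyn = Dynamics(model)
    c0 = dyn.initial(initial)
    if np.any(c0 < 0):
        raise ValueError("initial concentrations must be nonnegative")
    t_eval = np.linspace(t_span[0], t_span[1], n_points)
    sol = solve_ivp(dyn.f, t_span, c0, method=method, rtol=RTOL, atol=ATOL,
                    t_eval=t_eval)
    return Trajectory(
        times=sol.t, species=dyn.species, concentrations=sol.y,
        success=sol.success, message=sol.message,
    )


def _newton_polish(
    dyn: Dynamics, c0: np.ndarray, moieties: Sequence[dict[str, float]]
) -> np.ndarray | None:
    """Newton solve of N·v = 0 with one balance per moiety replaced by its
    conservation relation; returns None on failure or negative solution."""
    totals = []
    dep_rows = []
    for g in moieties:
        idx = [dyn.index[s] for s in g]
        totals.append(sum(g[s] * c0[dyn.index[s]] for s in g))
        dep_rows.append(idx[-1])

    def F(c: np.ndarray) -> np.ndarray:
        out = dyn.f(0.0, c)
        for g, total, row in zip(moieties, totals, dep_rows):
            out[row] = sum(g[s] * c[dyn.index[s]] for s in g) - total
        return out

    sol = root(F, c0, method="hybr", options={"xtol": 1e-13})
    if not sol.success:
        return None
    if np.any(sol.x < -1e-12):
        return None  # negative concentrations: reject, never clip
    return np.maximum(sol.x, 0.0)


def steady_state(
    model: KineticModel,
    initial: Mapping[str, float] | None = None,
    t_relax: float = 2000.0,
    max_relax: float = 2e5,
    newton_first: bool = True,
) -> SteadyState:
    """Locate a steady state: Newton on the rate vector, with relaxation
    (long stiff integration) as the fallback and as the globaliser.

    ``initial`` overrides the model's stored initial concentrations; pass
    a previous solution to warm-start (as the control-analysis
    perturbations do).
    """
    dyn = Dynamics(model)
    c0 = dyn.initial(initial)
    moieties = dyn.moieties()
    method = "newton"

    c = None
    if newton_first:
        c = _newton_polish(dyn, c0, moieties)
    t = t_relax
    state = c0
    while c is None and t <= max_relax:
        sol = solve_ivp(dyn.f, (0.0, t), state, method="BDF", rtol=RTOL, atol=ATOL)
        if not sol.success:
            break
        state = np.maximum(sol.y[:, -1], 0.0)
        method = "relaxation"
        c = _newton_polish(dyn, state, moieties)
        if c is None and float(np.max(np.abs(dyn.f(0.0, state)))) < NEWTON_TOL:
            c = state
        t *= 10.0

    if c is None:  # report the last good state, unconverged
        c = state
        converged = False
    else:
        converged = bool(np.max(np.abs(dyn.f(0.0, c))) < NEWTON_TOL)

    residual = float(np.max(np.abs(dyn.f(0.0, c))))
    conc = dict(zip(dyn.species, c))
    fluxes = dict(zip(dyn.reaction_ids, dyn.rate_vector(c)))
    return SteadyState(
        concentrations=conc, fluxes=fluxes, residual=residual,
        converged=converged and residual < NEWTON_TOL, method=method,
    )


def energy_charge(concentrations: Mapping[str, float]) -> float:
    """Adenylate energy charge (ATP + ADP/2)/(ATP+ADP+AMP), in [0, 1]."""
    atp = concentrations["ATP"]
    adp = concentrations["ADP"]
    amp = concentrations["AMP"]
    total = atp + adp + amp
    if total <= 0:
        raise ValueError("adenine nucleotide pool is empty")
    return (atp + adp / 2.0) / total
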