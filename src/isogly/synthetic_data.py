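"""Synthetic data generation for every stage of the pipeline.

Everything the package consumes can be generated here with a known
ground truth: initial-rate assay datasets (to exercise the kinetic
fitting), noisy proteome/metabolome tables (to exercise assembly
robustness), and small toy networks with closed-form steady states and
control coefficients (oracles for the solver and the control analysis).

Noise is multiplicative lognormal throughout — concentrations and rates
are positive quantities, and the assay/omics error columns report
percent coefficients of variation, which calibrate σ via
σ² = ln(1 + CV²). A single integer seed makes every generator
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .assay_fitting import AssayDataset
from .model_assembly import KineticModel, Metabolite, Reaction, Tables
from .rate_laws import (
    FirstOrder,
    IsoenzymeKinetics,
    MassActionReversible,
    MichaelisMenten,
)
from .units import CellGeometry

__all__ = [
    "SynthesisSpec",
    "make_assay",
    "make_omics_tables",
    "make_toy_network",
]


@dataclass
class SynthesisSpec:
    """Reproducible recipe for synthetic measurements.

    ``noise_cv_percent`` is the multiplicative coefficient of variation
    of the assay rates; typical assay campaigns report parameter SEMs in
    the 1–20 % range, and 5 % rate noise reproduces that span.
    """

    seed: int = 0
    s_grid: tuple[float, ...] = (0.05, 0.1, 0.2, 0.5, 1.0, 2.0, 5.0, 10.0)
    replicates: int = 2
    noise_cv_percent: float = 5.0

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with coefficient of
    variation ``cv`` (fraction); CV=0 returns exact ones."""
    if cv <= 0:
        return np.ones(size)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def make_assay(
    truth: IsoenzymeKinetics,
    spec: SynthesisSpec,
    enzyme_conc: float = 1e-3,
    substrate: str | None = None,
) -> AssayDataset:
    """Initial-rate dataset drawn from a true kinetic law.

    The rates come from the law named in ``truth`` (Michaelis–Menten or
    substrate inhibition) at the spec's substrate grid, perturbed by
    unit-mean lognormal noise at the spec's CV.
    """
    rng = spec.rng()
    if substrate is None:
        substrate = next(iter(truth.Km))
    km = truth.Km[substrate]
    points: list[tuple[float, list[float]]] = []
    for s in spec.s_grid:
        if truth.law == "substrate_inhibition":
            from .rate_laws import substrate_inhibition as law
            v_true = law(enzyme_conc, truth.kcat, s, km, truth.Ki)
        else:
            from .rate_laws import mm_irreversible as law
            v_true = law(enzyme_conc, truth.kcat, s, km)
        noise = _lognormal_factor(rng, spec.noise_cv_percent / 100.0,
                                  spec.replicates)
        points.append((s, list(v_true * noise)))
    return AssayDataset(enzyme_conc=enzyme_conc, points=points,
                        law_hint=truth.law)


def make_omics_tables(tables: Tables, spec: SynthesisSpec) -> Tables:
    """Perturb the measured copies-per-cell columns at their reported
    per-row CVs (SEM %). Zeros stay zero (an isoenzyme measured as
    absent remains absent); rows without a reported SEM are left exact.
    """
    rng = spec.rng()

    def perturb(df: pd.DataFrame, col: str) -> pd.DataFrame:
        df = df.copy()
        values = df[col].to_numpy(dtype=float)
        sems = pd.to_numeric(df["sem_percent"], errors="coerce").to_numpy()
        out = values.copy()
        for i, (v, cv) in enumerate(zip(values, sems)):
            if v <= 0 or not np.isfinite(cv) or cv <= 0:
                continue
            out[i] = v * _lognormal_factor(rng, cv / 100.0, None)
        df[col] = out
        return df

    return Tables(
        kinetics=tables.kinetics.copy(),
        proteins=perturb(tables.proteins, "copies_per_cell"),
        metabolites=perturb(tables.metabolites, "copies_per_cell_thousands"),
        iterations=tables.iterations.copy(),
        fcc=tables.fcc.copy(),
    )


def make_toy_network(
    template: str,
    geometry: CellGeometry | None = None,
    params: Mapping[str, float] | None = None,
) -> KineticModel:
    """Small networks with closed-form steady states, for oracle tests.

    Templates
    ---------
    ``linear2``
        A(fixed) ⇌ B → sink, with v1 = k1·(A − B/Keq) and v2 = k2·B.
        Steady state: B* = k1·A/(k2 + k1/Keq); flux J = k2·B*. The flux
        control coefficients are C1 = k2/(k2 + k1/Keq) and C2 = 1 − C1.
    ``linear3``
        A(fixed) ⇌ B ⇌ C → sink, mass action, same construction.
    ``branch``
        A(fixed) + ATP → B + ADP; B + ADP → ATP (+ sink); B → sink.
        Carries a conserved adenine pair for moiety tests.
    """
    geometry = geometry or CellGeometry(5.0)
    p = {"A": 2.0, "k1": 1.0, "k2": 0.5, "k3": 0.25, "Keq": 2.0,
         "ATP0": 1.0, "ADP0": 1.0}
    if params:
        p.update(params)

    def met(mid: str, conc: float, boundary: bool = False) -> Metabolite:
        return Metabolite(id=mid, name=mid, boundary=boundary, concentration=conc)

    if template == "linear2":
        mets = {"A": met("A", p["A"], True), "B": met("B", 0.1),
                "SINK": met("SINK", 0.0, True)}
        rxs = [
            Reaction(id="R1", group="R1", stoichiometry={"A": -1, "B": 1},
                     law=MassActionReversible(kf=p["k1"], Keq=p["Keq"],
                                              substrates={"A": 1},
                                              products={"B": 1})),
            Reaction(id="R2", group="R2", stoichiometry={"B": -1, "SINK": 1},
                     law=FirstOrder(k=p["k2"], species="B")),
        ]
    elif template == "linear3":
        mets = {"A": met("A", p["A"], True), "B": met("B", 0.1),
                "C": met("C", 0.1), "SINK": met("SINK", 0.0, True)}
        rxs = [
            Reaction(id="R1", group="R1", stoichiometry={"A": -1, "B": 1},
                     law=MassActionReversible(kf=p["k1"], Keq=p["Keq"],
                                              substrates={"A": 1},
                                              products={"B": 1})),
            Reaction(id="R2", group="R2", stoichiometry={"B": -1, "C": 1},
                     law=MassActionReversible(kf=p["k2"], Keq=p["Keq"],
                                              substrates={"B": 1},
                                              products={"C": 1})),
            Reaction(id="R3", group="R3", stoichiometry={"C": -1, "SINK": 1},
                     law=FirstOrder(k=p["k3"], species="C")),
        ]
    elif template == "branch":
        mets = {
            "A": met("A", p["A"], True), "B": met("B", 0.2),
            "ATP": met("ATP", p["ATP0"]), "ADP": met("ADP", p["ADP0"]),
            "SINK1": met("SINK1", 0.0, True), "SINK2": met("SINK2", 0.0, True),
        }
        rxs = [
            Reaction(id="R1", group="R1",
                     stoichiometry={"A": -1, "ATP": -1, "B": 1, "ADP": 1},
                     law=MassActionReversible(kf=p["k1"], Keq=1e9,
                                              substrates={"A": 1, "ATP": 1},
                                              products={})),
            Reaction(id="R2", group="R2",
                     stoichiometry={"B": -1, "ADP": -1, "ATP": 1, "SINK1": 1},
                     law=MassActionReversible(kf=p["k2"], Keq=1e9,
                                              substrates={"B": 1, "ADP": 1},
                                              products={})),
            Reaction(id="R3", group="R3", stoichiometry={"B": -1, "SINK2": 1},
                     law=FirstOrder(k=p["k3"], species="B")),
        ]
    else:
        raise ValueError(f"unknown toy template {template!r}")

    model = KineticModel(
        geometry=geometry, metabolites=mets, reactions=rxs,
        meta={"template": template, "params": dict(p)},
    )
    model.activities = {g: 1.0 for g in model.groups}
    model.validate()
    return model
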