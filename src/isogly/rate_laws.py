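"""Kinetic rate laws for the glycolysis model.

Two layers live here:

* Pure functions (:func:`mm_irreversible`, :func:`substrate_inhibition`,
  :func:`mm_reversible`, :func:`first_order`) — the elementary rate
  expressions, used directly by the assay-fitting stage and as the
  numerical ground truth in tests.
* :class:`RateLaw` objects — bound forms that evaluate against a
  dictionary of metabolite concentrations and can emit an equivalent
  symbolic (sympy) expression for SBML export. Model assembly attaches
  these to reactions.

Isoenzymes are represented explicitly: a reaction's rate is the sum of
the rates of its individual gene products, each with its own enzyme
concentration [E] and kinetic parameters, so the limiting rate of every
term decomposes as V = [E]·kcat.

Units: concentrations mM, kcat 1/s, first-order k 1/s, rates mM/s.
"""

from __future__ import annotations

import abc
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import sympy

__all__ = [
    "LAWS",
    "IsoenzymeKinetics",
    "mm_irreversible",
    "substrate_inhibition",
    "mm_reversible",
    "first_order",
    "reaction_rate",
    "RateLaw",
    "MichaelisMenten",
    "ReversibleMM",
    "SubstrateInhibitionLaw",
    "Saturative",
    "InhibitedSaturative",
    "AllostericPFK",
    "FirstOrder",
    "MassActionReversible",
    "FacilitatedDiffusion",
]

#: Recognised kinds of isoenzyme kinetics.
LAWS = (
    "mm_irreversible",
    "mm_reversible",
    "substrate_inhibition",
    "first_order",
    "saturative",
    "hill_modified",
)


# ---------------------------------------------------------------------------
# Elementary rate functions
# ---------------------------------------------------------------------------

def mm_irreversible(E: float, kcat: float, S: float, Km: float) -> float:
    """Irreversible Michaelis–Menten rate v = E·kcat·S/(Km+S) in mM/s."""
    if Km <= 0:
        raise ValueError(f"Km must be positive, got {Km}")
    if E < 0 or S < 0 or kcat < 0:
        raise ValueError("E, S and kcat must be nonnegative")
    return E * kcat * S / (Km + S)


def substrate_inhibition(E: float, kcat: float, S: float, Km: float, Ki: float) -> float:
    """Substrate-inhibited rate v = E·kcat·S/(Km + S·(1+(S/Ki)^4)).

    The quartic inhibition term makes the rate vanish as S → ∞ and gives
    a unique interior maximum; the exponent is fixed at 4.
    """
    if Km <= 0:
        raise ValueError(f"Km must be positive, got {Km}")
    if Ki <= 0:
        raise ValueError(f"Ki must be positive, got {Ki}")
    if E < 0 or S < 0 or kcat < 0:
        raise ValueError("E, S and kcat must be nonnegative")
    return E * kcat * S / (Km + S * (1.0 + (S / Ki) ** 4))


def mm_reversible(
    E: float,
    kcat_f: float,
    S: float,
    P: float,
    KmS: float,
    KmP: float,
    Keq: float,
) -> float:
    """Haldane-constrained reversible Michaelis–Menten (uni-uni).

    v = E·kcat_f·(S − P/Keq)/KmS / (1 + S/KmS + P/KmP); the rate is zero
    exactly at equilibrium P/S = Keq and reduces to the irreversible law
    at P = 0.
    """
    if KmS <= 0 or KmP <= 0:
        raise ValueError("Km values must be positive")
    if Keq <= 0:
        raise ValueError(f"Keq must be positive, got {Keq}")
    if E < 0 or S < 0 or P < 0 or kcat_f < 0:
        raise ValueError("E, concentrations and kcat must be nonnegative")
    return E * kcat_f * (S - P / Keq) / KmS / (1.0 + S / KmS + P / KmP)


def first_order(k: float, S: float) -> float:
    """First-order (linear) rate v = k·S; used for clamped-flux branches."""
    if k < 0 or S < 0:
        raise ValueError("k and S must be nonnegative")
    return k * S


# ---------------------------------------------------------------------------
# Isoenzyme kinetics record
# ---------------------------------------------------------------------------

@dataclass
class IsoenzymeKinetics:
    """Kinetic characterisation of one isoenzyme.

    Parameters
    ----------
    isoenzyme_id:
        Gene-product name (e.g. ``Hxk2p``).
    law:
        One of :data:`LAWS`.
    kcat:
        Turnover number, 1/s. A value of 0 encodes an isoenzyme found to
        be inactive in the assay (e.g. Adh5p, Pyk2p).
    Km:
        Half-saturation constants keyed by metabolite id, mM.
    Ki:
        Substrate-inhibition constant, mM (required for
        ``substrate_inhibition``).
    Keq:
        Equilibrium constant for reversible laws (product/substrate at
        equilibrium, with the reaction's stoichiometric convention).
    hill:
        Hill exponents keyed by metabolite id (≥ 1); e.g. the quadratic
        ADP dependence of phosphoglycerate kinase.
    sem:
        Percent standard errors keyed by parameter name, as reported by
        the assay fits.
    """

    isoenzyme_id: str
    law: str
    kcat: float
    Km: dict[str, float] = field(default_factory=dict)
    Ki: float | None = None
    Keq: float | None = None
    hill: dict[str, float] = field(default_factory=dict)
    sem: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.law not in LAWS:
            raise ValueError(f"unknown law {self.law!r}; expected one of {LAWS}")
        if self.kcat < 0:
            raise ValueError(f"{self.isoenzyme_id}: kcat must be nonnegative")
        for met, km in self.Km.items():
            if km <= 0:
                raise ValueError(f"{self.isoenzyme_id}: Km[{met}] must be positive")
        if self.Ki is not None and self.Ki <= 0:
            raise ValueError(f"{self.isoenzyme_id}: Ki must be positive")
        for met, h in self.hill.items():
            if h < 1:
                raise ValueError(f"{self.isoenzyme_id}: hill[{met}] must be ≥ 1")
        if self.law == "substrate_inhibition" and self.Ki is None:
            raise ValueError(f"{self.isoenzyme_id}: substrate_inhibition requires Ki")
        if self.law in ("mm_reversible", "hill_modified") and self.Keq is None:
            raise ValueError(f"{self.isoenzyme_id}: {self.law} requires Keq")

    def bind(
        self,
        E: float,
        substrates: Sequence[str],
        products: Sequence[str] = (),
    ) -> "RateLaw":
        """Attach this characterisation to a reaction context.

        ``substrates``/``products`` name the metabolites (in the model's
        forward direction) whose Km entries participate in the law.
        """
        km_sub = {m: self.Km[m] for m in substrates if m in self.Km}
        km_prod = {m: self.Km[m] for m in products if m in self.Km}
        if self.law == "mm_irreversible":
            return MichaelisMenten(E=E, kcat=self.kcat, Km=km_sub, hill=dict(self.hill))
        if self.law in ("mm_reversible", "hill_modified"):
            assert self.Keq is not None
            return ReversibleMM(
                E=E, kcat=self.kcat, Km_sub=km_sub, Km_prod=km_prod,
                Keq=self.Keq, hill=dict(self.hill),
            )
        if self.law == "substrate_inhibition":
            assert self.Ki is not None
            if km_prod and self.Keq is not None:
                (p,) = km_prod.keys()
                return SubstrateInhibitionLaw(
                    E=E, kcat=self.kcat, Km_sub=km_sub, Km_prod=km_prod,
                    Ki=self.Ki, inhibitor=p, Keq=self.Keq,
                )
            (s,) = km_sub.keys()
            return SubstrateInhibitionLaw(
                E=E, kcat=self.kcat, Km_sub=km_sub, Km_prod={},
                Ki=self.Ki, inhibitor=s, Keq=None,
            )
        if self.law == "first_order":
            (s,) = substrates
            return FirstOrder(k=E * self.kcat, species=s)
        if self.law == "saturative":
            return Saturative(V=E * self.kcat, Km=km_sub, hill=dict(self.hill))
        raise AssertionError(self.law)


# ---------------------------------------------------------------------------
# Bound rate-law objects
# ---------------------------------------------------------------------------

def _sym(name: str) -> sympy.Symbol:
    return sympy.Symbol(name, nonnegative=True)


class RateLaw(abc.ABC):
    """A rate expression bound to named metabolites."""

    @abc.abstractmethod
    def rate(self, conc: Mapping[str, float]) -> float:
        """Evaluate the rate (mM/s) at the given concentrations (mM)."""

    @abc.abstractmethod
    def expr(self) -> sympy.Expr:
        """Equivalent symbolic expression with metabolite-named symbols."""

    def species(self) -> set[str]:
        return {str(s) for s in self.expr().free_symbols}


@dataclass
class MichaelisMenten(RateLaw):
    """Irreversible (multi-substrate) Michaelis–Menten: E·kcat·Π S/(Km+S)."""

    E: float
    kcat: float
    Km: dict[str, float]
    hill: dict[str, float] = field(default_factory=dict)

    def rate(self, conc: Mapping[str, float]) -> float:
        v = self.E * self.kcat
        for met, km in self.Km.items():
            s = conc[met]
            h = self.hill.get(met, 1.0)
            if h != 1.0:
                v *= s ** h / (km ** h + s ** h)
            else:
                v *= s / (km + s)
        return v

    def expr(self) -> sympy.Expr:
        e: sympy.Expr = sympy.Float(self.E * self.kcat)
        for met, km in self.Km.items():
            s = _sym(met)
            h = self.hill.get(met, 1.0)
            e *= s ** h / (sympy.Float(km) ** h + s ** h)
        return e


@dataclass
class ReversibleMM(RateLaw):
    """Reversible Michaelis–Menten, generalised to several reactants.

    v = E·kcat·(Π S^h − Π P^h / Keq)/Π KmS^h
        / (Π(1+(S/KmS)^h) + Π(1+(P/KmP)^h) − 1)

    The numerator vanishes exactly at thermodynamic equilibrium
    Π P^h / Π S^h = Keq (Haldane-consistent by construction); kcat is
    the forward turnover number.
    """

    E: float
    kcat: float
    Km_sub: dict[str, float]
    Km_prod: dict[str, float]
    Keq: float
    hill: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.Keq <= 0:
            raise ValueError(f"Keq must be positive, got {self.Keq}")

    def _h(self, met: str) -> float:
        return self.hill.get(met, 1.0)

    def rate(self, conc: Mapping[str, float]) -> float:
        fwd = 1.0
        norm = 1.0
        den_s = 1.0
        for met, km in self.Km_sub.items():
            h = self._h(met)
            fwd *= conc[met] ** h
            norm *= km ** h
            den_s *= 1.0 + (conc[met] / km) ** h
        rev = 1.0
        den_p = 1.0
        for met, km in self.Km_prod.items():
            h = self._h(met)
            rev *= conc[met] ** h
            den_p *= 1.0 + (conc[met] / km) ** h
        num = self.E * self.kcat * (fwd - rev / self.Keq) / norm
        return num / (den_s + den_p - 1.0)

    def expr(self) -> sympy.Expr:
        fwd: sympy.Expr = sympy.Integer(1)
        norm: sympy.Expr = sympy.Integer(1)
        den_s: sympy.Expr = sympy.Integer(1)
        for met, km in self.Km_sub.items():
            h = self._h(met)
            s = _sym(met)
            fwd *= s ** h
            norm *= sympy.Float(km) ** h
            den_s *= 1 + (s / sympy.Float(km)) ** h
        rev: sympy.Expr = sympy.Integer(1)
        den_p: sympy.Expr = sympy.Integer(1)
        for met, km in self.Km_prod.items():
            h = self._h(met)
            p = _sym(met)
            rev *= p ** h
            den_p *= 1 + (p / sympy.Float(km)) ** h
        num = sympy.Float(self.E * self.kcat) * (fwd - rev / sympy.Float(self.Keq)) / norm
        return num / (den_s + den_p - 1)


@dataclass
class SubstrateInhibitionLaw(RateLaw):
    """Quartic substrate inhibition, optionally in a reversible frame.

    Irreversible (no products): v = E·kcat·S/(Km + S·(1+(S/Ki)^4)).
    Reversible (triose phosphate isomerase): the inhibiting species is
    the counter-direction substrate (GAP when running DHAP → GAP), and

        v = E·kcat·(S − P/Keq)/Km / (1 + S/Km + (P/KmP)·(1+(P/Ki)^4)).
    """

    E: float
    kcat: float
    Km_sub: dict[str, float]
    Km_prod: dict[str, float]
    Ki: float
    inhibitor: str
    Keq: float | None = None

    def __post_init__(self) -> None:
        if self.Ki <= 0:
            raise ValueError(f"Ki must be positive, got {self.Ki}")
        if len(self.Km_sub) != 1 or len(self.Km_prod) > 1:
            raise ValueError("substrate inhibition law is uni-uni")

    def rate(self, conc: Mapping[str, float]) -> float:
        (s_id, km_s), = self.Km_sub.items()
        s = conc[s_id]
        if not self.Km_prod:
            return substrate_inhibition(self.E, self.kcat, s, km_s, self.Ki)
        (p_id, km_p), = self.Km_prod.items()
        p = conc[p_id]
        assert self.Keq is not None
        num = self.E * self.kcat * (s - p / self.Keq) / km_s
        den = 1.0 + s / km_s + (p / km_p) * (1.0 + (p / self.Ki) ** 4)
        return num / den

    def expr(self) -> sympy.Expr:
        (s_id, km_s), = self.Km_sub.items()
        s = _sym(s_id)
        if not self.Km_prod:
            return (
                sympy.Float(self.E * self.kcat) * s
                / (sympy.Float(km_s) + s * (1 + (s / sympy.Float(self.Ki)) ** 4))
            )
        (p_id, km_p), = self.Km_prod.items()
        p = _sym(p_id)
        num = sympy.Float(self.E * self.kcat) * (s - p / sympy.Float(self.Keq)) / sympy.Float(km_s)
        den = 1 + s / sympy.Float(km_s) + (p / sympy.Float(km_p)) * (1 + (p / sympy.Float(self.Ki)) ** 4)
        return num / den


@dataclass
class Saturative(RateLaw):
    """Vmax-form saturable law V·Π S/(Km+S); used for bulked steps (ATPase)."""

    V: float
    Km: dict[str, float]
    hill: dict[str, float] = field(default_factory=dict)

    def rate(self, conc: Mapping[str, float]) -> float:
        v = self.V
        for met, km in self.Km.items():
            h = self.hill.get(met, 1.0)
            s = conc[met]
            v *= s ** h / (km ** h + s ** h)
        return v

    def expr(self) -> sympy.Expr:
        e: sympy.Expr = sympy.Float(self.V)
        for met, km in self.Km.items():
            h = self.hill.get(met, 1.0)
            s = _sym(met)
            e *= s ** h / (sympy.Float(km) ** h + s ** h)
        return e


@dataclass
class InhibitedSaturative(RateLaw):
    """Saturable law with linear-competitive inhibitors:
    v = V·Π S/(Km+S) / (1 + Σ I/Ki). Used for the glycerol-branch
    dehydrogenase, which the branch literature describes with adenine
    nucleotide and fructose-bisphosphate inhibition."""

    V: float
    Km: dict[str, float]
    Ki: dict[str, float]

    def rate(self, conc: Mapping[str, float]) -> float:
        v = self.V
        for met, km in self.Km.items():
            v *= conc[met] / (km + conc[met])
        return v / (1.0 + sum(conc[m] / ki for m, ki in self.Ki.items()))

    def expr(self) -> sympy.Expr:
        e: sympy.Expr = sympy.Float(self.V)
        for met, km in self.Km.items():
            s = _sym(met)
            e *= s / (sympy.Float(km) + s)
        den = sympy.Integer(1)
        for m, ki in self.Ki.items():
            den += _sym(m) / sympy.Float(ki)
        return e / den


@dataclass
class FirstOrder(RateLaw):
    """v = k·S; the stand-in kinetics for not-yet-characterised branches."""

    k: float
    species: str

    def rate(self, conc: Mapping[str, float]) -> float:
        return first_order(self.k, conc[self.species])

    def expr(self) -> sympy.Expr:
        return sympy.Float(self.k) * _sym(self.species)


@dataclass
class MassActionReversible(RateLaw):
    """kf·(Π S^n − Π P^n / Keq); adenylate kinase and near-equilibrium steps."""

    kf: float
    Keq: float
    substrates: dict[str, int]
    products: dict[str, int]

    def rate(self, conc: Mapping[str, float]) -> float:
        fwd = math.prod(conc[m] ** n for m, n in self.substrates.items())
        if not self.products:  # irreversible mass action
            return self.kf * fwd
        rev = math.prod(conc[m] ** n for m, n in self.products.items())
        return self.kf * (fwd - rev / self.Keq)

    def expr(self) -> sympy.Expr:
        fwd = sympy.Integer(1)
        for m, n in self.substrates.items():
            fwd *= _sym(m) ** n
        if not self.products:
            return sympy.Float(self.kf) * fwd
        rev = sympy.Integer(1)
        for m, n in self.products.items():
            rev *= _sym(m) ** n
        return sympy.Float(self.kf) * (fwd - rev / sympy.Float(self.Keq))


@dataclass
class AllostericPFK(RateLaw):
    """Concerted-transition (MWC) kinetics for phosphofructokinase.

    The two-state model of the prior yeast glycolysis literature:

        v = Vmax · gR·λ1·λ2·R / (R² + L·T²) · (1 − F16bP·ADP/(F6P·ATP·Keq))

    with λ1 = F6P/Kf6p, λ2 = ATP/Katp, R = 1 + λ1λ2·gR + λ1 + λ2,
    T = 1 + c_ATP·λ2, and the allosteric constant

        L = L0 · [(1+ci_ATP·ATP/Ki_ATP)/(1+ATP/Ki_ATP)]²
               · [(1+ci_AMP·AMP/K_AMP)/(1+AMP/K_AMP)]²
               · [(1+ci_F26·F26/K_F26+ci_F16·F16/K_F16)
                  /(1+F26/K_F26+F16/K_F16)]².

    ATP disfavours the active R state (ci_ATP ≫ 1) while AMP and the
    fructose bisphosphates favour it (ci < 1); this energy-charge
    feedback is what lets upper glycolysis throttle down to the
    ATP-consumption-limited flux instead of running away. F26bP is held
    at a fixed regulatory concentration. The trailing factor is a
    thermodynamic reversibility correction (zero at mass-action
    equilibrium), negligible far from it.
    """

    Vmax: float
    Kf6p: float
    Katp: float
    gR: float
    L0: float
    c_atp: float
    Ki_atp: float
    ci_atp: float
    K_amp: float
    ci_amp: float
    K_f26: float
    ci_f26: float
    K_f16: float
    ci_f16: float
    F26bP: float
    Keq: float

    def _terms(self, f6p, atp, amp, f16):
        lam1 = f6p / self.Kf6p
        lam2 = atp / self.Katp
        R = 1.0 + lam1 * lam2 * self.gR + lam1 + lam2
        T = 1.0 + self.c_atp * lam2
        L = self.L0
        L *= ((1.0 + self.ci_atp * atp / self.Ki_atp) / (1.0 + atp / self.Ki_atp)) ** 2
        L *= ((1.0 + self.ci_amp * amp / self.K_amp) / (1.0 + amp / self.K_amp)) ** 2
        f26 = self.F26bP
        L *= (
            (1.0 + self.ci_f26 * f26 / self.K_f26 + self.ci_f16 * f16 / self.K_f16)
            / (1.0 + f26 / self.K_f26 + f16 / self.K_f16)
        ) ** 2
        return lam1, lam2, R, T, L

    def rate(self, conc: Mapping[str, float]) -> float:
        f6p, atp = conc["F6P"], conc["ATP"]
        amp, f16, adp = conc["AMP"], conc["F16bP"], conc["ADP"]
        lam1, lam2, R, T, L = self._terms(f6p, atp, amp, f16)
        # λ1λ2·(1 − Γ/Keq) distributed so the law is defined at zero
        # substrate: λ1λ2 − F16bP·ADP/(Kf6p·Katp·Keq)
        drive = lam1 * lam2 - f16 * adp / (self.Kf6p * self.Katp * self.Keq)
        return self.Vmax * self.gR * drive * R / (R * R + L * T * T)

    def expr(self) -> sympy.Expr:
        f6p, atp = _sym("F6P"), _sym("ATP")
        amp, f16, adp = _sym("AMP"), _sym("F16bP"), _sym("ADP")
        F = sympy.Float
        lam1 = f6p / F(self.Kf6p)
        lam2 = atp / F(self.Katp)
        R = 1 + lam1 * lam2 * F(self.gR) + lam1 + lam2
        T = 1 + F(self.c_atp) * lam2
        L = F(self.L0)
        L *= ((1 + F(self.ci_atp) * atp / F(self.Ki_atp)) / (1 + atp / F(self.Ki_atp))) ** 2
        L *= ((1 + F(self.ci_amp) * amp / F(self.K_amp)) / (1 + amp / F(self.K_amp))) ** 2
        f26 = F(self.F26bP)
        L *= (
            (1 + F(self.ci_f26) * f26 / F(self.K_f26) + F(self.ci_f16) * f16 / F(self.K_f16))
            / (1 + f26 / F(self.K_f26) + f16 / F(self.K_f16))
        ) ** 2
        drive = lam1 * lam2 - f16 * adp / (F(self.Kf6p) * F(self.Katp) * F(self.Keq))
        return F(self.Vmax) * F(self.gR) * drive * R / (R ** 2 + L * T ** 2)


@dataclass
class FacilitatedDiffusion(RateLaw):
    """Carrier-mediated sugar transport across the plasma membrane.

    v = V·(So − Si)/Km / (1 + (So+Si)/Km + Ki·So·Si/Km²); symmetric
    facilitated diffusion with an interactive-binding term Ki, the
    standard form for the yeast hexose transporters.
    """

    V: float
    Km: float
    Ki: float
    outside: str
    inside: str

    def rate(self, conc: Mapping[str, float]) -> float:
        so = conc[self.outside]
        si = conc[self.inside]
        return (
            self.V * (so - si) / self.Km
            / (1.0 + (so + si) / self.Km + self.Ki * so * si / self.Km ** 2)
        )

    def expr(self) -> sympy.Expr:
        so = _sym(self.outside)
        si = _sym(self.inside)
        km = sympy.Float(self.Km)
        return (
            sympy.Float(self.V) * (so - si) / km
            / (1 + (so + si) / km + sympy.Float(self.Ki) * so * si / km ** 2)
        )


@dataclass
class ScaledLaw(RateLaw):
    """A rate law multiplied by an activity factor (used for perturbations)."""

    base: RateLaw
    factor: float

    def rate(self, conc: Mapping[str, float]) -> float:
        return self.factor * self.base.rate(conc)

    def expr(self) -> sympy.Expr:
        return sympy.Float(self.factor) * self.base.expr()


# ---------------------------------------------------------------------------
# Reaction-level aggregation
# ---------------------------------------------------------------------------

def reaction_rate(
    isoenzymes: Sequence[tuple[IsoenzymeKinetics, float]],
    concentrations: Mapping[str, float],
    substrates: Sequence[str] | None = None,
    products: Sequence[str] = (),
) -> float:
    """Total rate of a reaction catalysed by several isoenzymes.

    Each entry pairs a kinetic characterisation with that isoenzyme's
    concentration [E] in mM; the reaction rate is the sum of the
    individual contributions (and is therefore linear in each [E]).
    If ``substrates`` is omitted, each isoenzyme's Km keys are taken as
    its substrates (irreversible laws only).
    """
    total = 0.0
    for kin, E in isoenzymes:
        subs = list(substrates) if substrates is not None else list(kin.Km.keys())
        total += kin.bind(E, subs, products).rate(concentrations)
    return total
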