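"""Kinetic parameter estimation from initial-rate assay data.

Plate-reader assays give initial rates v at a grid of substrate
concentrations S (duplicate or better), with the assay enzyme
concentration E known. Nonlinear least squares on

    v = E·kcat·S/(Km + S)                       (Michaelis–Menten)
    v = E·kcat·S/(Km + S·(1 + (S/Ki)^4))        (substrate inhibition)

yields kcat and Km (and Ki), with per-parameter standard errors from
the covariance of the fit, reported as percentages to match how assay
campaigns tabulate them. Initial guesses come from the Hanes
linearisation S/v = S/Vmax + Km/Vmax, which is robust for noisy data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .rate_laws import mm_irreversible, substrate_inhibition

__all__ = [
    "AssayDataset",
    "KineticFit",
    "fit_michaelis_menten",
    "fit_substrate_inhibition",
    "read_plate_export",
]


@dataclass
class AssayDataset:
    """Initial-rate dataset for one isoenzyme.

    ``points`` maps each substrate concentration (mM) to its replicate
    initial rates (mM/s). At least duplicate determinations per
    concentration and at least five distinct concentrations are
    required for an identifiable fit.
    """

    enzyme_conc: float  # mM
    points: list[tuple[float, list[float]]]
    law_hint: str = "mm_irreversible"

    def __post_init__(self) -> None:
        if self.enzyme_conc <= 0:
            raise ValueError("enzyme concentration must be positive")
        if len({s for s, _ in self.points}) < 5:
            raise ValueError("need at least 5 distinct substrate concentrations")
        for s, reps in self.points:
            if s < 0:
                raise ValueError("substrate concentrations must be nonnegative")
            if len(reps) < 2:
                raise ValueError(
                    f"need at least duplicate rates at each S (S={s} has {len(reps)})"
                )

    def flat(self) -> tuple[np.ndarray, np.ndarray]:
        s = np.array([x for x, reps in self.points for _ in reps])
        v = np.array([r for _, reps in self.points for r in reps])
        return s, v


@dataclass
class KineticFit:
    kcat: float
    Km: float
    Ki: float | None = None
    sem_percent: dict[str, float] = field(default_factory=dict)
    residual_ss: float = 0.0
    warning: str | None = None


def _hanes_init(s: np.ndarray, v: np.ndarray, E: float) -> tuple[float, float]:
    """kcat, Km from the Hanes linearisation (positive-rate points only)."""
    mask = (v > 0) & (s > 0)
    if mask.sum() < 2:
        return max(v.max() / E, 1e-9), max(np.median(s), 1e-9)
    slope, intercept = np.polyfit(s[mask], s[mask] / v[mask], 1)
    vmax = 1.0 / slope if slope > 0 else v[mask].max() * 2
    km = intercept * vmax if intercept > 0 else np.median(s[mask])
    return max(vmax / E, 1e-9), max(km, 1e-9)


def _sems(popt: np.ndarray, pcov: np.ndarray, names: Sequence[str]) -> dict[str, float]:
    err = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    return {
        n: float(100.0 * e / abs(p)) if p != 0 else float("inf")
        for n, p, e in zip(names, popt, err)
    }


def fit_michaelis_menten(data: AssayDataset) -> KineticFit:
    """Least-squares fit of the irreversible Michaelis–Menten law.

    Since v is proportional to E·kcat, rescaling the enzyme
    concentration leaves Km untouched and rescales kcat inversely — the
    fit estimates kcat, not Vmax.
    """
    s, v = data.flat()
    E = data.enzyme_conc
    p0 = _hanes_init(s, v, E)

    def f(s_, kcat, km):
        return E * kcat * s_ / (km + s_)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        popt, pcov = curve_fit(f, s, v, p0=p0, maxfev=10000,
                               bounds=([0, 1e-12], [np.inf, np.inf]))
    kcat, km = popt
    resid = float(np.sum((v - f(s, *popt)) ** 2))
    sems = _sems(popt, pcov, ["kcat", "Km"])
    warning = None
    if s.max() < km:
        warning = (
            "non-identifiable design: all substrate concentrations below the "
            "estimated Km; kcat and Km are strongly correlated"
        )
    return KineticFit(kcat=float(kcat), Km=float(km), sem_percent=sems,
                      residual_ss=resid, warning=warning)


def fit_substrate_inhibition(data: AssayDataset) -> KineticFit:
    """Least-squares fit of the quartic substrate-inhibition law."""
    s, v = data.flat()
    E = data.enzyme_conc
    kcat0, km0 = _hanes_init(s, v, E)
    s_peak = float(s[np.argmax(v)])
    p0 = (max(kcat0, 1e-9), max(km0, 1e-9), max(2.0 * s_peak, 1e-6))

    def f(s_, kcat, km, ki):
        return E * kcat * s_ / (km + s_ * (1.0 + (s_ / ki) ** 4))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        popt, pcov = curve_fit(f, s, v, p0=p0, maxfev=20000,
                               bounds=([0, 1e-12, 1e-12], [np.inf] * 3))
    kcat, km, ki = popt
    resid = float(np.sum((v - f(s, *popt)) ** 2))
    sems = _sems(popt, pcov, ["kcat", "Km", "Ki"])
    warning = None
    if s.max() < ki:
        warning = (
            "inhibition not exercised: no substrate concentration reaches the "
            "estimated Ki; the inhibition constant is weakly identified"
        )
    return KineticFit(kcat=float(kcat), Km=float(km), Ki=float(ki),
                      sem_percent=sems, residual_ss=resid, warning=warning)


def read_plate_export(path) -> AssayDataset:
    """Read a simple delimited plate export: columns S, rate, replicate,
    with the enzyme concentration on a ``# enzyme_mM = <x>`` header line."""
    import pandas as pd

    enzyme = None
    with open(path) as fh:
        head = []
        for line in fh:
            if line.startswith("#"):
                if "enzyme_mM" in line:
                    enzyme = float(line.split("=")[1])
            else:
                head.append(line)
    if enzyme is None:
        raise ValueError("plate export lacks an '# enzyme_mM = <x>' header")
    from io import StringIO

    df = pd.read_csv(StringIO("".join(head)))
    pts: dict[float, list[float]] = {}
    for row in df.itertuples(index=False):
        pts.setdefault(float(row.S), []).append(float(row.rate))
    return AssayDataset(enzyme_conc=enzyme,
                        points=sorted((s, v) for s, v in pts.items()))
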