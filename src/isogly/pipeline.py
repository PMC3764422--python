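"""The "cycle of knowledge" driver.

Three stages live here:

* :func:`fit_metric` — the normalised root-mean-square difference
  between predicted and observed metabolite concentrations (relative
  error per metabolite, so the 30-fold concentration range contributes
  evenly; the unresolved 2-/3-phosphoglycerate pair is compared as a
  lump).
* :func:`run_iterations` — walks the characterisation queue: at each
  step the control profile of the current model is computed, the queued
  reaction is replaced by its characterised kinetics, the steady state
  is re-solved, and the fit and the glucose-uptake flux are recorded,
  both rescaled to 1 at iteration 0. Steady-state failures are recorded
  as diagnostics, not raised: transient fit/flux collapses are part of
  the story this trace tells.
* :func:`fit_parameters` — the constrained greedy fit of the unmeasured
  global parameters (effective volume, ATPase limiting rate, succinate
  branch constant), ranked by local sensitivity: fit one parameter,
  test the acceptance criteria (concentration closeness, no drop in
  glycolytic flux, energy charge ≥ 0.8), and widen the fitted set only
  while a criterion still fails.

Observed metabolite data enter as molecules per cell: their molar
values depend on the effective volume being fitted, so the conversion
happens inside the objective, exactly as the copy-number conversion demands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from .mca import control_profile
from .model_assembly import (
    TABLE1_ORDER,
    KineticModel,
    Tables,
    build_model,
    characterisation_records,
    load_config,
    load_tables,
)
from .simulate import energy_charge, steady_state
from .units import CellGeometry, copies_to_mM

__all__ = [
    "IterationRecord",
    "IterationTrace",
    "FitResult",
    "fit_metric",
    "observed_copies",
    "observed_concentrations",
    "run_iterations",
    "fit_parameters",
]

#: Default "sufficient closeness" threshold on the normalised RMSD.
RMSD_THRESHOLD = 0.5
ENERGY_CHARGE_THRESHOLD = 0.8


# ---------------------------------------------------------------------------
# Fit metric and observed data
# ---------------------------------------------------------------------------

def fit_metric(
    predicted: Mapping[str, float], observed: Mapping[str, float]
) -> float:
    """Normalised RMSD over the metabolites shared by both maps.

    Each term is (predicted − observed)/observed; an observed key
    ``"P2G+P3G"`` is compared against the sum of the predicted P2G and
    P3G. The metric is symmetric in the sense that swapping arguments
    permutes numerator signs only through the normalisation choice; we
    normalise by the second argument.
    """
    diffs = []
    for met, obs in observed.items():
        if met == "P2G+P3G":
            if "P2G" in predicted and "P3G" in predicted:
                pred = predicted["P2G"] + predicted["P3G"]
            elif met in predicted:
                pred = predicted[met]
            else:
                continue
        elif met in predicted:
            pred = predicted[met]
        else:
            continue
        if obs <= 0:
            raise ValueError(f"observed concentration for {met} must be positive")
        diffs.append((pred - obs) / obs)
    if not diffs:
        raise ValueError("no shared metabolites between predicted and observed")
    return float(np.sqrt(np.mean(np.square(diffs))))


def observed_copies(tables: Tables | None = None) -> dict[str, float]:
    """Measured metabolite abundances in molecules per cell (volume-free)."""
    tables = tables or load_tables()
    return {
        row.id: float(row.copies_per_cell_thousands) * 1e3
        for row in tables.metabolites.itertuples(index=False)
    }


def observed_concentrations(
    geometry: CellGeometry, tables: Tables | None = None
) -> dict[str, float]:
    """Measured metabolite concentrations (mM) at a given effective volume."""
    return {
        met: copies_to_mM(c, geometry) for met, c in observed_copies(tables).items()
    }


# ---------------------------------------------------------------------------
# Iteration trace
# ---------------------------------------------------------------------------

@dataclass
class IterationRecord:
    iteration: int
    reaction: str | None
    fit: float          # normalised to 1 at iteration 0
    flux: float         # normalised to 1 at iteration 0
    fit_raw: float
    flux_raw: float
    converged: bool
    top_uncharacterised: str | None = None


@dataclass
class IterationTrace:
    records: list[IterationRecord] = field(default_factory=list)
    diagnostics: list[str] = field(default_factory=list)

    @property
    def fits(self) -> list[float]:
        return [r.fit for r in self.records]

    @property
    def fluxes(self) -> list[float]:
        return [r.flux for r in self.records]


def run_iterations(
    initial_model: KineticModel | None = None,
    queue: Sequence[str] | None = None,
    tables: Tables | None = None,
    config: Mapping | None = None,
    target: str = "HXT",
    rank: bool = True,
) -> tuple[IterationTrace, list[KineticModel]]:
    """Run the iterative characterisation over ``queue`` (the published
    order by default) and return the trace plus the model sequence
    (element i is the model after i characterisations)."""
    tables = tables or load_tables()
    config = config or load_config()
    queue = list(TABLE1_ORDER if queue is None else queue)
    model = initial_model if initial_model is not None else build_model(
        0, tables=tables, config=config
    )
    geometry = model.geometry
    obs = observed_concentrations(geometry, tables)
    recs = characterisation_records(tables, config, geometry)

    trace = IterationTrace()
    models = [model]
    ss = steady_state(model)
    fit0 = fit_metric(ss.concentrations, obs)
    flux0 = model.group_flux(target, ss.concentrations)
    if fit0 <= 0 or flux0 <= 0:
        raise RuntimeError("iteration-0 model has degenerate fit or flux")
    last_conc = ss.concentrations
    trace.records.append(IterationRecord(
        iteration=0, reaction=None, fit=1.0, flux=1.0,
        fit_raw=fit0, flux_raw=flux0, converged=ss.converged,
    ))

    for i, group in enumerate(queue, start=1):
        top = None
        if rank and ss.converged:
            from .mca import rank_uncharacterised
            order = rank_uncharacterised(model, target, base=ss)
            top = order[0] if order else None
        model = build_model(0, tables=tables, config=config, queue=queue[:i])
        models.append(model)
        ss = steady_state(model, initial=last_conc)
        if ss.converged:
            last_conc = ss.concentrations
            fit = fit_metric(ss.concentrations, obs)
            flux = model.group_flux(target, ss.concentrations)
        else:
            trace.diagnostics.append(
                f"iteration {i} ({group}): steady state not converged "
                f"(residual {ss.residual:.3g})"
            )
            fit = float("nan")
            flux = float("nan")
        trace.records.append(IterationRecord(
            iteration=i, reaction=group, fit=fit / fit0, flux=flux / flux0,
            fit_raw=fit, flux_raw=flux, converged=ss.converged,
            top_uncharacterised=top,
        ))
    return trace, models


# ---------------------------------------------------------------------------
# Constrained parameter fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    fitted: dict[str, float]
    objective: float
    criteria: dict[str, bool]
    passed: bool
    start: dict[str, float]
    objective_start: float
    history: list[str] = field(default_factory=list)

    @property
    def fitted_parameters(self) -> list[str]:
        return [k for k in self.fitted if self.fitted[k] != self.start[k]]


_BOUNDS = {
    "volume_fl": (1.0, 40.0),
    "atpase_V": (0.1, 20.0),
    "succinate_k": (0.0, 0.1),
}


def fit_parameters(
    observed: Mapping[str, float] | None = None,
    candidates: Sequence[str] = ("volume_fl", "atpase_V", "succinate_k"),
    start: Mapping[str, float] | None = None,
    tables: Tables | None = None,
    config: Mapping | None = None,
    builder: Callable[[Mapping[str, float]], KineticModel] | None = None,
    rmsd_threshold: float = RMSD_THRESHOLD,
    ec_threshold: float = ENERGY_CHARGE_THRESHOLD,
    target: str = "HXT",
    maxiter: int = 40,
) -> FitResult:
    """Greedy constrained fit of the unmeasured global parameters.

    ``observed`` maps metabolite ids to molecules per cell (the
    combined 2-/3-phosphoglycerate entry under ``"P2G+P3G"``); by
    default the bundled measured table. Candidates are ranked by the
    local sensitivity of the objective and added one at a time until the
    three criteria pass (or the candidate list is exhausted, in which
    case the result carries failure flags).
    """
    tables = tables or load_tables()
    config = config or load_config()
    observed = dict(observed) if observed is not None else observed_copies(tables)
    start = dict(start) if start is not None else {
        "volume_fl": float(config["prefit_volume_fl"]),
        "atpase_V": float(config["atpase"]["V"]),
        "succinate_k": float(config["succinate_k"]),
    }
    if builder is None:
        def builder(params: Mapping[str, float]) -> KineticModel:
            return build_model(
                17, tables=tables, config=config,
                volume_fl=params.get("volume_fl"),
                atpase_V=params.get("atpase_V"),
                succinate_k=params.get("succinate_k"),
            )

    def evaluate(params: Mapping[str, float]) -> tuple[float, dict[str, bool], float, float]:
        # each candidate is judged from the measured initial state at its
        # own volume (no warm starts: the model family is bistable and a
        # carried-over collapsed state would poison neighbouring evaluations)
        model = builder(params)
        geometry = model.geometry
        obs_mM = {m: copies_to_mM(c, geometry) for m, c in observed.items()}
        ss = steady_state(model)
        if not ss.converged:
            return float("inf"), {
                "concentration_closeness": False,
                "flux_maintained": False,
                "energy_charge": False,
            }, float("nan"), float("nan")
        rmsd = fit_metric(ss.concentrations, obs_mM)
        flux = model.group_flux(target, ss.concentrations)
        ec = energy_charge(ss.concentrations)
        crit = {
            "concentration_closeness": rmsd <= rmsd_threshold,
            "flux_maintained": True,   # finalised against pre-fit flux below
            "energy_charge": ec >= ec_threshold,
        }
        return rmsd, crit, flux, ec

    current = dict(start)
    obj0, crit0, flux0, ec0 = evaluate(current)
    history = [f"start: objective={obj0:.4f}"]

    def score(params: Mapping[str, float]) -> float:
        """Criterion-aware objective: the fit metric plus penalties for
        violating the flux-maintenance and energy-charge criteria."""
        rmsd, _, flux, ec = evaluate(params)
        if not np.isfinite(rmsd):
            return 1e6
        pen = 0.0
        if np.isfinite(flux) and flux < flux0:
            pen += 5.0 * (flux0 - flux) / flux0
        if np.isfinite(ec) and ec < ec_threshold:
            pen += 5.0 * (ec_threshold - ec)
        return rmsd + pen

    def criteria_at(params: Mapping[str, float]) -> tuple[float, dict[str, bool]]:
        rmsd, crit, flux, _ = evaluate(params)
        crit = dict(crit)
        crit["flux_maintained"] = bool(np.isfinite(flux) and flux >= flux0 * (1 - 1e-9))
        return rmsd, crit

    # already passing: nothing to fit
    rmsd0, crit_start = criteria_at(current)
    if all(crit_start.values()):
        return FitResult(
            fitted=dict(current), objective=rmsd0, criteria=crit_start,
            passed=True, start=dict(start), objective_start=rmsd0,
            history=history + ["criteria already satisfied; fitted set empty"],
        )

    # rank candidates by local relative sensitivity of the objective
    sens = []
    for name in candidates:
        p = dict(current)
        h = 0.1 * (abs(p[name]) if p[name] != 0 else 0.01)
        p[name] = current[name] + h
        up = score(p)
        p[name] = max(current[name] - h, _BOUNDS[name][0])
        dn = score(p)
        s = abs(up - dn) if np.isfinite(up) and np.isfinite(dn) else 0.0
        sens.append((s, name))
    ranked = [n for _, n in sorted(sens, key=lambda t: -t[0])]
    history.append(f"sensitivity ranking: {ranked}")

    active: list[str] = []
    best = dict(current)
    best_obj = obj0
    best_crit = crit_start
    for name in ranked:
        active.append(name)

        def objective(x: np.ndarray) -> float:
            params = dict(best)
            for n, v in zip(active, x):
                params[n] = float(v)
            return score(params)

        x0 = np.array([best[n] for n in active])
        bounds = [_BOUNDS[n] for n in active]
        res = minimize(objective, x0, method="Nelder-Mead", bounds=bounds,
                       options={"maxiter": maxiter * len(active), "xatol": 1e-3,
                                "fatol": 1e-5})
        trial = dict(best)
        for n, v in zip(active, res.x):
            trial[n] = float(v)
        rmsd, crit = criteria_at(trial)
        history.append(
            f"fit {active}: objective {rmsd:.4f}, criteria {crit}"
        )
        if rmsd <= best_obj or all(crit.values()):
            best, best_obj, best_crit = trial, rmsd, crit
        if all(crit.values()):
            break

    # never worsen the objective relative to the starting point
    if best_obj > obj0:
        best, best_obj, best_crit = dict(start), obj0, crit_start

    return FitResult(
        fitted=best, objective=best_obj, criteria=best_crit,
        passed=all(best_crit.values()), start=dict(start),
        objective_start=obj0, history=history,
    )
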