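# Methods

## The model

The network covers upper and lower glycolysis (HXT, HXK, PGI, PFK,
FBA, TPI, TDH, PGK, GPM, ENO, PYK, PDC, ADH), the bulked ATPase and
adenylate kinase, and five branch fluxes (glycerol, glycogen,
trehalose, succinate, acetate). The state is the vector of internal
metabolite concentrations (mM) in a single well-mixed cytoplasm;
extracellular glucose and all end products (ethanol, glycerol,
glycogen, trehalose, succinate, acetate, CO2) are boundary species
held fixed. Two conserved pools close the network: the adenine
nucleotides (ATP+ADP+AMP, default total 4.1 mM) and the pyridine pair
(NAD+NADH, default 1.59 mM).

Each enzymatic step is the **sum of its isoenzymes**: one rate term per
gene product, with its own kinetic constants and its own concentration
[E] from absolute proteomics, so V_max = [E]·k_cat separately per
isoform and the rate of a step is linear in each [E]. This linearity
is what makes the per-isoenzyme decomposition of control coefficients
exact. An isoenzyme assayed as inactive (k_cat = 0) remains in the
model with zero contribution.

Copy numbers (molecules/cell) convert to mM through the effective
cytoplasmic volume. The effective volume is deliberately a *model
parameter*, not a fixed constant: crowding and the vacuole make the
solvent-accessible volume much smaller than the cell volume, and the
study's fitting stage moved it from a naive 20 fl to 5 fl. Models
built at iterations 0–17 default to the pre-fit 20 fl; the final model
(iteration 18) uses 5 fl together with the other two fitted globals
(ATPase V 5.3 mM/s, succinate branch off).

### Rate laws

* Irreversible multi-substrate Michaelis–Menten for HXK-type steps
  (product of saturation factors).
* Haldane-constrained reversible Michaelis–Menten for PGI, FBA, TDH,
  PGK, GPM, ENO and HXK: the numerator is (ΠS − ΠP/Keq)/ΠKmS, zero
  exactly at thermodynamic equilibrium, with binding denominators
  Π(1+S/KmS) + Π(1+P/KmP) − 1. Hill exponents enter as powers on the
  selected species (PGK carries the quadratic ADP dependence).
* Quartic substrate inhibition for TPI: in the model's reversible
  frame the inhibiting species is the counter-direction substrate
  (GAP), v = E·kcat·(DHAP − GAP/Keq)/Km / (1 + DHAP/Km +
  (GAP/KmGAP)(1+(GAP/Ki)^4)); the pure irreversible form is what the
  assay-fitting stage estimates.
* Concerted two-state (MWC) law for PFK with ATP as the T-state
  ligand and AMP/F16bP/F26bP as R-state ligands, times a
  (1 − Γ/Keq) reversibility factor (distributed algebraically so the
  law is defined at zero substrate). The allosteric constants come
  from the prior literature model; the limiting rate is the in-house
  [E]·k_cat of the co-purified Pfk1p:Pfk2p complex, with [E] set by
  the scarcer subunit. A plain saturative PFK was tried first and
  rejected: without the energy-charge feedback the assembled pathway
  has no steady state (the classic "turbo design" runaway — upper
  glycolysis cannot down-regulate to the ATP-consumption-limited
  flux). This was a genuinely open design point; the allosteric form
  is the package's resolution.
* Facilitated diffusion for HXT with an interactive-binding term:
  v = V(So−Si)/Km / (1 + (So+Si)/Km + Ki·So·Si/Km²).
* First-order stand-ins (k·S) for formerly clamped branch fluxes in
  the uncharacterised model; the characterised branches are lumped
  literature sub-models (two-reaction glycerol branch with adenine
  nucleotide/F16bP inhibition on the dehydrogenase; saturative
  glycogen and trehalose drains; first-order acetate oxidation). The
  succinate branch is first-order in acetaldehyde and oxidises
  2 ACE + 3 NAD per event, following the branch stoichiometry of the
  prior models — a pure pyruvate sink was tried and rejected because
  it hard-locks the glycerol branch's redox balance and acetaldehyde
  then has no finite steady state.

### Parameters that matter

| parameter | unit | default | why |
|---|---|---|---|
| effective volume | fl | 5 (post-fit), 20 (pre-fit) | converts copies/cell to mM for every enzyme and metabolite |
| ATPase V | mM/s | 5.3 (post-fit), 1.1 (pre-fit) | lumped ATP demand; with Km(ATP)=0.3 mM it is near zero-order, so it sets the net ATP turnover and thereby the uptake flux |
| succinate k | 1/s | 0 (post-fit), 0.005 (pre-fit) | the third fitted global |
| HXT Vmax | mM/s | 4.0 | unprinted; reconciled so the post-fit model can satisfy the campaign's own fitting criteria (fitted ATPase V together with energy charge ≥ 0.8 constrain transporter capacity to ≈4 mM/s); Km/Ki are the literature carrier constants |
| adenine / pyridine totals | mM | 4.1 / 1.59 | literature values for fermentative yeast; not measured in-house |
| Keq set | — | per reaction in `model_config.yaml` | apparent equilibrium constants from the literature lineage of the prior model |

Everything in `model_config.yaml` is a quantity the measurement
campaign did not determine. Where the cited branch sub-models could
not be obtained, their lumped capacities were chosen once to be
consistent with the campaign's reported branch operating point (e.g. a
glycerol-branch flux of a few hundredths of mM/s) and are not tuned
thereafter.

## Steady states and control analysis

The ODE system dS/dt = N·v(S) is integrated with a stiff BDF method
(rtol 1e-8, atol 1e-10 mM). Steady states are located by Newton on
the rate vector with the conserved-pool rows replaced by their
conservation relations (the unreduced Jacobian is singular along pool
directions); relaxation by integration globalises the search when the
initial guess is poor. Convergence means max|dS/dt| < 1e-9 mM/s —
chosen because predicted concentrations are reported to 3–4
significant figures. Newton steps that leave the positive orthant are
rejected outright, never clipped; the ODE right-hand side clamps the
tiny negative excursions that finite-difference probing produces, for
rate evaluation only.

Flux control coefficients perturb an activity multiplier on a step
(equivalently, all of its enzyme concentrations at once), so bulked
steps and branches are perturbable on the same footing; per-isoenzyme
coefficients perturb one [E]. The derivative is a central log-difference
at relative step 1e-3, Richardson-extrapolated with a half step to
cancel the O(h²) truncation that is visible in the final model's
large-curvature coefficients. With this scheme the summation theorem
holds to ≤ 1e-6 on every model of the 19-model sequence. Plain central
differences at step 1e-2 are measurably biased (the ATPase coefficient
shifts by ≈0.2), which is why the default step is 1e-3 and the
robustness guarantee is stated for the 1e-4–1e-3 range.

## The characterisation pipeline and the fit

`run_iterations` walks the published characterisation order; at each
step it can also record which step a fresh FCC ranking would have
chosen. Fit quality is the normalised RMSD between predicted and
measured metabolite concentrations — per-metabolite *relative* error,
so the 30-fold concentration range contributes evenly; the
chromatographically unresolved 2-/3-phosphoglycerate pair is compared
as a lump. Fit and flux are rescaled to 1 at iteration 0. Steady-state
failures mid-sequence are recorded as diagnostics and the trace
continues: transient fit/flux collapses are part of what the trace is
for.

`fit_parameters` is a greedy constrained fit of the three unmeasured
globals. Candidates are ranked by the local sensitivity of a
criterion-aware objective (the RMSD plus penalties for flux loss below
the pre-fit value and for energy charge below 0.8); parameters are
added one at a time (Nelder–Mead within bounds) until the three
criteria — concentration closeness (default RMSD ≤ 0.5), no drop in
glycolytic flux, energy charge ≥ 0.8 — all pass or the candidates are
exhausted, in which case the result carries failure flags. Observed
data enter as molecules/cell, so the mM comparison target moves with
the candidate volume, exactly as the conversion demands. Every
candidate is evaluated from the measured initial state (cold start):
the model family is bistable, with a collapsed low-ATP attractor
coexisting with the physiological one, and warm-starting from a
neighbouring candidate's state was found to leak the collapsed basin
across the parameter scan. The fit itself is deterministic.

A note on the closeness threshold: under this package's relative-error
normalisation, the *published* observed-versus-predicted columns score
0.512, so a threshold of 0.5 is marginally infeasible even for the
study's own final predictions. The threshold is configurable; the
default is kept at 0.5 and the fit reports the criterion honestly.

## Synthetic data

The generators emulate the measurement layers with known ground truth:
initial-rate assay datasets (law evaluation times unit-mean
multiplicative lognormal noise, σ² = ln(1+CV²), CV defaulting to 5% to
match the 1–20% parameter SEMs that assay campaigns report), noisy
proteome/metabolome tables (per-row CVs from the published SEM
columns; an isoenzyme measured as absent stays absent), and toy
networks (reversible linear chains and a branch with a conserved
adenine pair) whose steady states and control coefficients have closed
forms. A single integer seed makes every generator bit-reproducible.
What the generators do *not* emulate: assay-plate artefacts (coupling
lags, background drift), correlated errors across metabolites, and any
systematic bias between in vitro and in vivo activity — so passing the
recovery tests shows estimator correctness, not robustness to those
real-data pathologies.

## Problem sizes

The default test suite and the acceptance script run the full 19-model
sequence (18 internal metabolites, 21–26 reactions), complete control
profiles (≈26 coefficients × 4 steady-state solves each), the full
three-parameter fit, and assay simulations of 8 concentrations × 2
replicates; the whole acceptance computation is about two minutes on a
single core.

## Limitations

* This is a *reconstruction*: the deposited exchange files of the
  model series are not redistributed, and the unprinted pieces
  (equilibrium constants, counter-direction Km's, branch kinetics,
  transporter capacity, pool totals) are literature-derived or
  reconciled defaults. The reconstruction reproduces the published
  qualitative results — the same three dominant controllers, the
  Hxk2p ≫ Hxk1p ≫ Glk1p decomposition, the fit-then-plateau trace, the
  post-fit energy charge — but its steady-state concentrations differ
  from the published predictions by tens of percent on most
  metabolites, and its control coefficients are compressed roughly
  two-fold relative to the published final-model column.
* Phosphate is not a state variable (buffered implicitly), enzyme
  channelling is not represented, and the glycogen/trehalose/acetate
  branches are single lumped reactions rather than the multi-reaction
  literature sub-models they stand for.
* GPM's forward turnover is derived from the reverse-direction assay
  through the Haldane relationship; PGK's printed k_cat is taken as
  the forward turnover with literature Km's for the unmeasured
  direction. Both choices are exposed in the configuration.
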