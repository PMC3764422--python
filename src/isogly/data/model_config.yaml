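# Default configuration of the glycolysis model.
#
# Everything here is a quantity that the in-house measurement campaign did
# NOT determine: equilibrium constants, counter-direction and cosubstrate
# Michaelis constants, the transporter and bulked-branch kinetics, and the
# conserved-pool totals. Values are taken from the prior literature models
# of fermentative yeast glycolysis that the network is built on and are
# deliberately kept in one place so that they can be overridden per run.
#
# Units: concentrations mM, Vmax mM/s, first-order k 1/s, Keq with the
# reaction's stated stoichiometric convention.

volume_fl: 5.0          # effective cytoplasmic volume (fitted); 20 fl pre-fit
prefit_volume_fl: 20.0

external:
  GLCx: 100.0           # medium glucose; excess-glucose continuous culture

# Conserved pools (mM) and their initial partition. Not measured in-house;
# literature values for fermentative S. cerevisiae.
moieties:
  adenine_total: 4.1    # ATP + ADP + AMP
  nad_total: 1.59       # NAD + NADH
initial_unmeasured:     # metabolites without a measured copy number
  ATP: 2.5
  ADP: 1.1
  AMP: 0.5
  NAD: 1.55
  NADH: 0.04
  BPG: 0.01
  ACE: 0.17
  P2G: 0.08             # split of the combined P2G+P3G measurement (ENO side)
  P3G: 0.46

# Apparent equilibrium constants (product/substrate convention of the
# model's forward direction).
keq:
  HXK: 3800.0           # G6P*ADP/(GLC*ATP)
  PGI: 0.314            # F6P/G6P
  PFK: 800.0            # effectively irreversible; retained for form
  FBA: 0.069            # DHAP*GAP/F16bP, mM
  TPI: 0.045            # GAP/DHAP
  TDH: 0.0055           # BPG*NADH/(GAP*NAD)
  PGK: 3200.0           # P3G*ATP/(BPG*ADP^2) with the quadratic ADP term
  GPM: 0.19             # P2G/P3G
  ENO: 6.7              # PEP/P2G
  AK: 0.45              # ATP*AMP/ADP^2

# Michaelis constants of directions/cosubstrates that the assays did not
# cover (mM); per reaction, keyed by metabolite.
unmeasured_km:
  HXK: {G6P: 30.0, ADP: 0.23}
  PFK: {F6P: 0.1, ATP: 0.71, F16bP: 4.0, ADP: 1.0}
  FBA: {DHAP: 2.0, GAP: 2.4}
  TDH: {NAD: 0.09, NADH: 0.06, BPG: 0.0098}
  PGK: {BPG: 0.003, ADP: 0.2}
  GPM: {P3G: 1.2}
  ENO: {PEP: 0.5}
  ADH: {NADH: 0.11}

# Allosteric (concerted two-state) phosphofructokinase constants from
# the prior literature model; dimensionless except the binding constants
# (mM). F26bP is the fixed regulatory fructose 2,6-bisphosphate level.
pfk_allosteric:
  Kf6p: 0.1
  Katp: 0.71
  gR: 5.12
  L0: 0.66
  c_atp: 3.0
  Ki_atp: 0.65
  ci_atp: 100.0
  K_amp: 0.0995
  ci_amp: 0.0845
  K_f26: 0.000682
  ci_f26: 0.0174
  K_f16: 0.111
  ci_f16: 0.397
  F26bP: 0.02

# Hexose transporter (characterised at iteration 1 from the
# respiro-fermentative literature parameterisation).
# Vmax is reconciled so that the post-fit model can satisfy the
# campaign's stated fitting criteria (ATPase V 5.3 mM/s with energy charge >= 0.8),
# which jointly constrain the transporter capacity; Km/Ki are the
# literature carrier constants.
hxt:
  V: 4.0
  Km: 1.19
  Ki: 0.91

# Saturative generic ATPase (iteration 3), the lump of all ATP-consuming
# processes: v = V * ATP / (Km + ATP). V is one of the three parameters
# adjusted in the final fitting stage (1.1 -> 5.3).
atpase:
  V: 1.1
  Km: 0.3
atpase_fitted_V: 5.3

# Adenylate kinase: mass action, v = kf*(ADP^2 - ATP*AMP/Keq).
ak:
  kf: 0.75

# First-order rate constant of the succinate branch (first-order in
# acetaldehyde; the lumped branch oxidises 2 acetaldehyde with 3 NAD as
# in the prior literature models). The final fitting stage turned this
# branch off (0.005 -> 0).
succinate_k: 0.005
succinate_fitted_k: 0.0

# Branch reactions. "first_order_k" is the pre-characterisation stand-in
# (first-order in the branch reactant); the "characterised" blocks are the
# lumped versions of the cited branch sub-models.
branches:
  glycerol:
    first_order_k: 0.06          # on DHAP
    # two-reaction branch model: the dehydrogenase is inhibited by the
    # adenine nucleotides and F16bP (competitive terms)
    gpd: {V: 1.17, Km: {DHAP: 0.54, NADH: 0.023},
          Ki: {ATP: 0.73, ADP: 2.0, F16bP: 4.8}}
    gpp: {V: 0.85, Km: {G3P: 3.5}}
  glycogen:
    first_order_k: 0.0374        # on G6P
    characterised: {V: 0.15, Km: {G6P: 1.0}}
  trehalose:
    first_order_k: 0.015         # on G6P
    characterised: {V: 0.05, Km: {G6P: 1.0}}
  acetate:
    first_order_k: 0.0055        # on acetaldehyde
    characterised_k: 0.025       # first-order, non-saturating

# The lumped prior model used at iteration 0 (literature kinetics, no
# isoenzyme resolution). Vmax in mM/s; reversible steps carry the same
# Keq values as above.
iteration0:
  HXT: {V: 1.6211, Km: 1.1918, Ki: 0.91}
  HXK: {V: 3.7742, Km: {GLC: 0.08, ATP: 0.15, G6P: 30.0, ADP: 0.23}}
  PGI: {V: 5.6613, Km: {G6P: 1.4, F6P: 0.3}}
  PFK: {V: 3.0484, Km: {F6P: 0.1, ATP: 0.71}}
  FBA: {V: 5.3710, Km: {F16bP: 0.3, DHAP: 2.0, GAP: 2.4}}
  TPI: {kf: 50.0}                # near-equilibrium mass action
  TDH: {V: 19.742, Km: {GAP: 0.21, NAD: 0.09, BPG: 0.0098, NADH: 0.06}}
  PGK: {V: 21.774, Km: {BPG: 0.003, ADP: 0.2, P3G: 0.53, ATP: 0.3}}
  GPM: {V: 42.097, Km: {P3G: 1.2, P2G: 0.08}}
  ENO: {V: 6.0968, Km: {P2G: 0.04, PEP: 0.5}}
  PYK: {V: 18.145, Km: {PEP: 0.14, ADP: 0.53}}
  PDC: {V: 2.9032, Km: {PYR: 4.33}, hill: 1.9}
  ADH: {V: 13.5, Km: {ACE: 1.11, NADH: 0.11}}
  ATPase_k: 0.6583               # first-order in ATP in the prior model
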