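"""Assembly of the isoenzyme-explicit glycolysis network.

The model is built in the sequence the characterisation campaign followed: an initial
lumped-kinetics network derived from the prior literature model of
fermentative yeast glycolysis (iteration 0, with formerly clamped branch
fluxes re-expressed as first-order drains), followed by seventeen
characterisation steps in which one reaction at a time is replaced by
in-house isoenzyme-resolved kinetics (or, for transport and the bulked
branches, by literature kinetics), ordered by flux control over glucose
uptake. Iteration 18 is the final model after the constrained parameter
fit (effective volume 20 → 5 fl, ATPase V 1.1 → 5.3 mM/s, succinate
branch turned off).

Printed data tables (kinetics, protein copies/cell, metabolite
copies/cell, the iteration order and the published control coefficients)
are bundled as CSV; every quantity the measurement campaign did not
determine lives in ``data/model_config.yaml`` and can be overridden.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from importlib import resources
from typing import Any, Iterable, Mapping

import pandas as pd
import yaml

from .rate_laws import (
    AllostericPFK,
    FacilitatedDiffusion,
    InhibitedSaturative,
    FirstOrder,
    IsoenzymeKinetics,
    MassActionReversible,
    RateLaw,
    ReversibleMM,
    Saturative,
    SubstrateInhibitionLaw,
)
from .units import CellGeometry, copies_to_mM

__all__ = [
    "Metabolite",
    "IsoenzymeEntry",
    "Reaction",
    "KineticModel",
    "Tables",
    "CharacterisationRecord",
    "load_tables",
    "load_config",
    "kinetics_from_tables",
    "characterisation_records",
    "build_model",
    "apply_characterisation",
    "TABLE1_ORDER",
]

#: Characterisation order (iterations 1–17).
TABLE1_ORDER = (
    "HXT", "HXK", "ATPase", "Glycerol_branch", "PFK", "Glycogen_branch",
    "Succinate_branch", "PDC", "TDH", "FBA", "PGI", "ENO", "PGK", "ADH",
    "GPM", "PYK", "TPI",
)

#: Km column names in the kinetics table → metabolite ids.
_KM_SPECIES = {
    "Kglc": "GLC", "Katp": "ATP", "Kacald": "ACE", "Kp2g": "P2G",
    "Kf16bp": "F16bP", "Kg6p": "G6P", "Kf6p": "F6P", "Kpyr": "PYR",
    "Kp3g": "P3G", "Kpep": "PEP", "Kadp": "ADP", "Kgap": "GAP",
    "Kdhap": "DHAP", "Kbpg": "BPG",
}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Metabolite:
    id: str
    name: str = ""
    chebi: str = ""
    copies_per_cell: float | None = None
    sem_percent: float | None = None
    boundary: bool = False
    #: Fixed concentration for boundary species; initial value otherwise (mM).
    concentration: float = 0.0


@dataclass
class IsoenzymeEntry:
    """One isoenzyme bound into a reaction: kinetics + measured abundance."""

    kinetics: IsoenzymeKinetics
    copies_per_cell: float
    E: float  # mM at the model's geometry
    law: RateLaw

    @property
    def id(self) -> str:
        return self.kinetics.isoenzyme_id


@dataclass
class Reaction:
    """A reaction (or branch sub-reaction) of the network.

    ``group`` names the pathway step the reaction belongs to (the unit of
    characterisation and of control analysis); branch sub-models share a
    group, e.g. the two glycerol-branch reactions.
    """

    id: str
    group: str
    stoichiometry: dict[str, int]
    law: RateLaw | None = None
    isoenzymes: list[IsoenzymeEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise ValueError(f"{self.id}: stoichiometry must be nonempty")
        if (self.law is None) == (not self.isoenzymes):
            raise ValueError(f"{self.id}: provide either a bulk law or isoenzymes")

    def rate(
        self,
        conc: Mapping[str, float],
        activity: float = 1.0,
        iso_activities: Mapping[str, float] | None = None,
    ) -> float:
        if self.law is not None:
            return activity * self.law.rate(conc)
        total = 0.0
        for entry in self.isoenzymes:
            a = 1.0 if iso_activities is None else iso_activities.get(entry.id, 1.0)
            total += a * entry.law.rate(conc)
        return activity * total

    def contributions(
        self, conc: Mapping[str, float], activity: float = 1.0
    ) -> dict[str, float]:
        """Per-isoenzyme rates (mM/s); empty for bulk-law reactions."""
        return {e.id: activity * e.law.rate(conc) for e in self.isoenzymes}


@dataclass
class KineticModel:
    """The assembled network at a given iteration of the characterisation sequence."""

    geometry: CellGeometry
    metabolites: dict[str, Metabolite]
    reactions: list[Reaction]
    characterised: set[str] = field(default_factory=set)
    #: Activity multipliers per reaction group (control-analysis handle).
    activities: dict[str, float] = field(default_factory=dict)
    #: Activity multipliers per isoenzyme.
    iso_activities: dict[str, float] = field(default_factory=dict)
    globals: dict[str, float] = field(default_factory=dict)
    meta: dict[str, Any] = field(default_factory=dict)

    # -- structure ---------------------------------------------------------
    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.reactions:
            seen.setdefault(r.group, None)
        return list(seen)

    def reactions_in(self, group: str) -> list[Reaction]:
        out = [r for r in self.reactions if r.group == group]
        if not out:
            raise KeyError(f"no reaction group {group!r}")
        return out

    @property
    def internal_species(self) -> list[str]:
        return [m.id for m in self.metabolites.values() if not m.boundary]

    def initial_concentrations(self) -> dict[str, float]:
        return {m.id: m.concentration for m in self.metabolites.values()}

    # -- kinetics ----------------------------------------------------------
    def full_concentrations(self, conc: Mapping[str, float]) -> dict[str, float]:
        """Extend a (possibly partial) state with boundary concentrations."""
        out = {m.id: m.concentration for m in self.metabolites.values() if m.boundary}
        out.update(conc)
        return out

    def rates(self, conc: Mapping[str, float]) -> dict[str, float]:
        """Rate of every (sub-)reaction, keyed by reaction id (mM/s)."""
        c = self.full_concentrations(conc)
        return {
            r.id: r.rate(c, self.activities.get(r.group, 1.0), self.iso_activities)
            for r in self.reactions
        }

    def group_flux(self, group: str, conc: Mapping[str, float]) -> float:
        """Flux through a step; for multi-reaction branches, its entry reaction."""
        r = self.reactions_in(group)[0]
        c = self.full_concentrations(conc)
        return r.rate(c, self.activities.get(group, 1.0), self.iso_activities)

    def isoenzyme_ids(self, group: str | None = None) -> list[str]:
        rs = self.reactions if group is None else self.reactions_in(group)
        return [e.id for r in rs for e in r.isoenzymes]

    def copy(self) -> "KineticModel":
        return _copy.deepcopy(self)

    # -- consistency -------------------------------------------------------
    def validate(self) -> None:
        ids = [m.id for m in self.metabolites.values()]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate metabolite ids")
        used = {m for r in self.reactions for m in r.stoichiometry}
        missing = [m for m in self.internal_species if m not in used]
        if missing:
            raise ValueError(f"internal metabolites not used by any reaction: {missing}")
        unknown = used - set(ids)
        if unknown:
            raise ValueError(f"reactions reference unknown metabolites: {sorted(unknown)}")


# ---------------------------------------------------------------------------
# Bundled data
# ---------------------------------------------------------------------------

@dataclass
class Tables:
    kinetics: pd.DataFrame
    proteins: pd.DataFrame
    metabolites: pd.DataFrame
    iterations: pd.DataFrame
    fcc: pd.DataFrame


def _read_csv(name: str) -> pd.DataFrame:
    ref = resources.files("isogly.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def load_tables() -> Tables:
    """Load the bundled measurement tables."""
    return Tables(
        kinetics=_read_csv("table_kinetics.csv"),
        proteins=_read_csv("table_proteins.csv"),
        metabolites=_read_csv("table_metabolites.csv"),
        iterations=_read_csv("table_iterations.csv"),
        fcc=_read_csv("table_fcc.csv"),
    )


def _deep_update(base: dict, overrides: Mapping) -> dict:
    for k, v in overrides.items():
        if isinstance(v, Mapping) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v
    return base


def load_config(path: str | None = None, overrides: Mapping | None = None) -> dict:
    """Load the default model configuration, optionally merged with a user file."""
    ref = resources.files("isogly.data").joinpath("model_config.yaml")
    with resources.as_file(ref) as p:
        config = yaml.safe_load(p.read_text())
    if path is not None:
        with open(path) as fh:
            _deep_update(config, yaml.safe_load(fh) or {})
    if overrides:
        _deep_update(config, overrides)
    return config


# ---------------------------------------------------------------------------
# Kinetics records from the printed table
# ---------------------------------------------------------------------------

def kinetics_from_tables(tables: Tables, config: Mapping) -> dict[str, dict[str, IsoenzymeKinetics]]:
    """Parse the kinetics table into per-reaction, per-isoenzyme records.

    Only measured parameters appear here; reversible-direction constants
    are added during binding from the configuration.
    """
    keq = config["keq"]
    out: dict[str, dict[str, IsoenzymeKinetics]] = {}
    for (reaction, iso), grp in tables.kinetics.groupby(["reaction", "isoenzyme"], sort=False):
        params = dict(zip(grp["parameter"], grp["value"]))
        sems = {
            p: s for p, s in zip(grp["parameter"], grp["sem_percent"]) if pd.notna(s)
        }
        kcat = float(params.pop("kcat", 0.0))
        hill: dict[str, float] = {}
        if "nHadp" in params:
            hill["ADP"] = float(params.pop("nHadp"))
        ki = None
        if "Kigap" in params:
            ki = float(params.pop("Kigap"))
        km = {_KM_SPECIES[p]: float(v) for p, v in params.items()}
        law = "mm_irreversible"
        rx_keq = None
        if reaction == "TPI":
            law = "substrate_inhibition"
            rx_keq = float(keq["TPI"])
        elif reaction in ("PGI", "FBA", "TDH", "GPM", "ENO", "PFK", "HXK"):
            law = "mm_reversible"
            rx_keq = float(keq[reaction])
        elif reaction == "PGK":
            law = "hill_modified"
            rx_keq = float(keq["PGK"])
        out.setdefault(reaction, {})[iso] = IsoenzymeKinetics(
            isoenzyme_id=iso, law=law, kcat=kcat, Km=km, Ki=ki, Keq=rx_keq,
            hill=hill, sem=sems,
        )
    return out


# ---------------------------------------------------------------------------
# Network scaffold (metabolites + stoichiometry)
# ---------------------------------------------------------------------------

_STOICH: dict[str, dict[str, int]] = {
    "HXT": {"GLCx": -1, "GLC": 1},
    "HXK": {"GLC": -1, "ATP": -1, "G6P": 1, "ADP": 1},
    "PGI": {"G6P": -1, "F6P": 1},
    "PFK": {"F6P": -1, "ATP": -1, "F16bP": 1, "ADP": 1},
    "FBA": {"F16bP": -1, "DHAP": 1, "GAP": 1},
    "TPI": {"DHAP": -1, "GAP": 1},
    "TDH": {"GAP": -1, "NAD": -1, "BPG": 1, "NADH": 1},
    "PGK": {"BPG": -1, "ADP": -1, "P3G": 1, "ATP": 1},
    "GPM": {"P3G": -1, "P2G": 1},
    "ENO": {"P2G": -1, "PEP": 1},
    "PYK": {"PEP": -1, "ADP": -1, "PYR": 1, "ATP": 1},
    "PDC": {"PYR": -1, "ACE": 1, "CO2": 1},
    "ADH": {"ACE": -1, "NADH": -1, "ETOH": 1, "NAD": 1},
    "ATPase": {"ATP": -1, "ADP": 1},
    "AK": {"ADP": -2, "ATP": 1, "AMP": 1},
    "GPD": {"DHAP": -1, "NADH": -1, "G3P": 1, "NAD": 1},
    "GPP": {"G3P": -1, "GLY": 1},
    "Glycogen_branch": {"G6P": -1, "ATP": -1, "ADP": 1, "GLYCOGEN": 1},
    "Trehalose_branch": {"G6P": -2, "ATP": -1, "ADP": 1, "TRE": 1},
    "Succinate_branch": {"ACE": -2, "NAD": -3, "NADH": 3, "SUC": 1},
    "Acetate_branch": {"ACE": -1, "NAD": -1, "NADH": 1, "ACEx": 1},
}

_BOUNDARY = {
    "GLCx": 100.0, "ETOH": 10.0, "GLY": 0.15, "GLYCOGEN": 0.0, "TRE": 0.0,
    "SUC": 0.0, "ACEx": 0.0, "CO2": 1.0,
}

_BOUNDARY_NAMES = {
    "GLCx": "Extracellular glucose", "ETOH": "Ethanol", "GLY": "Glycerol",
    "GLYCOGEN": "Glycogen", "TRE": "Trehalose", "SUC": "Succinate",
    "ACEx": "Acetate", "CO2": "Carbon dioxide",
}

_UNMEASURED_NAMES = {
    "ATP": "ATP", "ADP": "ADP", "AMP": "AMP", "NAD": "NAD", "NADH": "NADH",
    "BPG": "1,3-bisphosphoglycerate", "ACE": "Acetaldehyde",
}


def _build_metabolites(tables: Tables, config: Mapping, geometry: CellGeometry) -> dict[str, Metabolite]:
    mets: dict[str, Metabolite] = {}
    init_cfg = config["initial_unmeasured"]
    # measured species, converted from copies at the model's own volume
    for row in tables.metabolites.itertuples(index=False):
        copies = float(row.copies_per_cell_thousands) * 1e3
        if row.id == "P2G+P3G":
            # combined measurement: split by the configured ratio
            p2g = float(init_cfg["P2G"])
            p3g = float(init_cfg["P3G"])
            frac = p2g / (p2g + p3g)
            chebi_p2g, chebi_p3g = str(row.chebi).split(";")
            for mid, f, chebi in (("P2G", frac, chebi_p2g), ("P3G", 1 - frac, chebi_p3g)):
                c = copies * f
                mets[mid] = Metabolite(
                    id=mid, name=mid, chebi=chebi, copies_per_cell=c,
                    sem_percent=float(row.sem_percent),
                    concentration=copies_to_mM(c, geometry),
                )
            continue
        mets[row.id] = Metabolite(
            id=row.id, name=str(row.name), chebi=str(row.chebi),
            copies_per_cell=copies, sem_percent=float(row.sem_percent),
            concentration=copies_to_mM(copies, geometry),
        )
    # unmeasured internal species: literature concentrations (mM)
    for mid, name in _UNMEASURED_NAMES.items():
        mets[mid] = Metabolite(id=mid, name=name, concentration=float(init_cfg[mid]))
    # boundary species
    external = config.get("external", {})
    for mid, conc in _BOUNDARY.items():
        mets[mid] = Metabolite(
            id=mid, name=_BOUNDARY_NAMES[mid], boundary=True,
            concentration=float(external.get(mid, conc)),
        )
    return mets


# ---------------------------------------------------------------------------
# Characterisation records
# ---------------------------------------------------------------------------

@dataclass
class CharacterisationRecord:
    """Replacement kinetics for one step, ready to apply to a model.

    ``reactions`` are the new (sub-)reactions of the step;
    ``extra_groups`` lists additional groups introduced or co-replaced by
    the same literature sub-model (e.g. the trehalose branch arriving
    with the glycogen-branch model, or the acetate branch with the
    succinate one).
    """

    group: str
    reactions: list[Reaction]
    extra_groups: tuple[str, ...] = ()


def _protein_mM(tables: Tables, iso: str, geometry: CellGeometry) -> tuple[float, float]:
    row = tables.proteins[tables.proteins["isoenzyme"] == iso]
    if row.empty:
        raise KeyError(f"no protein copy number for isoenzyme {iso!r}")
    copies = float(row["copies_per_cell"].iloc[0])
    return copies, copies_to_mM(copies, geometry)


def _iso_entries(
    tables: Tables,
    kinetics: Mapping[str, IsoenzymeKinetics],
    geometry: CellGeometry,
    substrates: Iterable[str],
    products: Iterable[str] = (),
    km_fill: Mapping[str, float] | None = None,
    kcat_override: Mapping[str, float] | None = None,
) -> list[IsoenzymeEntry]:
    entries = []
    for iso, kin in kinetics.items():
        kin = _copy.deepcopy(kin)
        if km_fill:
            for met, km in km_fill.items():
                kin.Km.setdefault(met, float(km))
        if kcat_override and iso in kcat_override:
            kin.kcat = float(kcat_override[iso])
        copies, e_mM = _protein_mM(tables, iso, geometry)
        law = kin.bind(e_mM, list(substrates), list(products))
        entries.append(IsoenzymeEntry(kinetics=kin, copies_per_cell=copies, E=e_mM, law=law))
    return entries


def characterisation_records(
    tables: Tables,
    config: Mapping,
    geometry: CellGeometry,
    atpase_V: float | None = None,
    succinate_k: float | None = None,
) -> dict[str, CharacterisationRecord]:
    """Build the replacement kinetics for every step in the iteration order."""
    kin = kinetics_from_tables(tables, config)
    ukm = config["unmeasured_km"]
    keq = config["keq"]
    br = config["branches"]
    recs: dict[str, CharacterisationRecord] = {}

    def rx(group: str, law: RateLaw | None = None, isos: list[IsoenzymeEntry] | None = None,
           rid: str | None = None) -> Reaction:
        return Reaction(
            id=rid or group, group=group, stoichiometry=dict(_STOICH[rid or group]),
            law=law, isoenzymes=isos or [],
        )

    hxt = config["hxt"]
    recs["HXT"] = CharacterisationRecord("HXT", [rx(
        "HXT", FacilitatedDiffusion(V=float(hxt["V"]), Km=float(hxt["Km"]),
                                    Ki=float(hxt["Ki"]), outside="GLCx", inside="GLC"),
    )])

    recs["HXK"] = CharacterisationRecord("HXK", [rx(
        "HXK", isos=_iso_entries(tables, kin["HXK"], geometry, ["GLC", "ATP"],
                                 ["G6P", "ADP"], km_fill=ukm["HXK"]),
    )])

    atp_cfg = config["atpase"]
    recs["ATPase"] = CharacterisationRecord("ATPase", [rx(
        "ATPase", Saturative(
            V=float(atpase_V if atpase_V is not None else atp_cfg["V"]),
            Km={"ATP": float(atp_cfg["Km"])},
        ),
    )])

    gpd, gpp = br["glycerol"]["gpd"], br["glycerol"]["gpp"]
    recs["Glycerol_branch"] = CharacterisationRecord("Glycerol_branch", [
        rx("Glycerol_branch", InhibitedSaturative(
            V=float(gpd["V"]),
            Km={k: float(v) for k, v in gpd["Km"].items()},
            Ki={k: float(v) for k, v in gpd.get("Ki", {}).items()}),
           rid="GPD"),
        rx("Glycerol_branch", Saturative(V=float(gpp["V"]),
                                         Km={k: float(v) for k, v in gpp["Km"].items()}),
           rid="GPP"),
    ])

    # PFK: the active enzyme is the co-purified Pfk1p:Pfk2p complex, so the
    # abundance of the complex is limited by the scarcer subunit; the
    # allosteric constants come from the prior model, the limiting rate
    # from the in-house [E]*kcat.
    pfk_kin = _copy.deepcopy(kin["PFK"]["Pfk1p:Pfk2p"])
    for met, km in ukm["PFK"].items():
        pfk_kin.Km.setdefault(met, float(km))
    copies = min(
        float(tables.proteins.loc[tables.proteins["isoenzyme"] == "Pfk1p", "copies_per_cell"].iloc[0]),
        float(tables.proteins.loc[tables.proteins["isoenzyme"] == "Pfk2p", "copies_per_cell"].iloc[0]),
    )
    e_mM = copies_to_mM(copies, geometry)
    pfk_law = _pfk_law(config, Vmax=e_mM * pfk_kin.kcat)
    recs["PFK"] = CharacterisationRecord("PFK", [rx(
        "PFK", isos=[IsoenzymeEntry(pfk_kin, copies, e_mM, pfk_law)],
    )])

    gly_c = br["glycogen"]["characterised"]
    tre_c = br["trehalose"]["characterised"]
    recs["Glycogen_branch"] = CharacterisationRecord(
        "Glycogen_branch",
        [
            rx("Glycogen_branch", Saturative(V=float(gly_c["V"]),
                                             Km={k: float(v) for k, v in gly_c["Km"].items()})),
            rx("Trehalose_branch", Saturative(V=float(tre_c["V"]),
                                              Km={k: float(v) for k, v in tre_c["Km"].items()})),
        ],
        extra_groups=("Trehalose_branch",),
    )

    suc_k = float(succinate_k if succinate_k is not None else config["succinate_k"])
    recs["Succinate_branch"] = CharacterisationRecord(
        "Succinate_branch",
        [
            rx("Succinate_branch", FirstOrder(k=suc_k, species="ACE")),
            rx("Acetate_branch", FirstOrder(
                k=float(br["acetate"]["characterised_k"]), species="ACE")),
        ],
        extra_groups=("Acetate_branch",),
    )

    recs["PDC"] = CharacterisationRecord("PDC", [rx(
        "PDC", isos=_iso_entries(tables, kin["PDC"], geometry, ["PYR"]),
    )])

    recs["TDH"] = CharacterisationRecord("TDH", [rx(
        "TDH", isos=_iso_entries(tables, kin["TDH"], geometry, ["GAP", "NAD"],
                                 ["BPG", "NADH"], km_fill=ukm["TDH"]),
    )])

    recs["FBA"] = CharacterisationRecord("FBA", [rx(
        "FBA", isos=_iso_entries(tables, kin["FBA"], geometry, ["F16bP"],
                                 ["DHAP", "GAP"], km_fill=ukm["FBA"]),
    )])

    recs["PGI"] = CharacterisationRecord("PGI", [rx(
        "PGI", isos=_iso_entries(tables, kin["PGI"], geometry, ["G6P"], ["F6P"]),
    )])

    recs["ENO"] = CharacterisationRecord("ENO", [rx(
        "ENO", isos=_iso_entries(tables, kin["ENO"], geometry, ["P2G"], ["PEP"],
                                 km_fill=ukm["ENO"]),
    )])

    recs["PGK"] = CharacterisationRecord("PGK", [rx(
        "PGK", isos=_iso_entries(tables, kin["PGK"], geometry, ["BPG", "ADP"],
                                 ["P3G", "ATP"], km_fill=ukm["PGK"]),
    )])

    recs["ADH"] = CharacterisationRecord("ADH", [rx(
        "ADH", isos=_iso_entries(tables, kin["ADH"], geometry, ["ACE", "NADH"],
                                 km_fill=ukm["ADH"]),
    )])

    # GPM was measurable only in the reverse (P2G -> P3G) direction; the
    # forward turnover follows from the Haldane relationship
    # kcat_f = kcat_r * Keq * KmS / KmP.
    gpm_keq = float(keq["GPM"])
    gpm_kmf = float(ukm["GPM"]["P3G"])
    gpm_fwd_kcat = {
        iso: k.kcat * gpm_keq * gpm_kmf / k.Km["P2G"] for iso, k in kin["GPM"].items()
    }
    recs["GPM"] = CharacterisationRecord("GPM", [rx(
        "GPM", isos=_iso_entries(tables, kin["GPM"], geometry, ["P3G"], ["P2G"],
                                 km_fill={"P3G": gpm_kmf}, kcat_override=gpm_fwd_kcat),
    )])

    recs["PYK"] = CharacterisationRecord("PYK", [rx(
        "PYK", isos=_iso_entries(tables, kin["PYK"], geometry, ["PEP", "ADP"],
                                 km_fill={"PEP": 0.281, "ADP": 0.243}),
    )])

    recs["TPI"] = CharacterisationRecord("TPI", [rx(
        "TPI", isos=_iso_entries(tables, kin["TPI"], geometry, ["DHAP"], ["GAP"]),
    )])

    return recs


# ---------------------------------------------------------------------------
# Iteration-0 model and assembly
# ---------------------------------------------------------------------------

def _pfk_law(config: Mapping, Vmax: float) -> AllostericPFK:
    a = config["pfk_allosteric"]
    return AllostericPFK(
        Vmax=Vmax, Kf6p=float(a["Kf6p"]), Katp=float(a["Katp"]),
        gR=float(a["gR"]), L0=float(a["L0"]), c_atp=float(a["c_atp"]),
        Ki_atp=float(a["Ki_atp"]), ci_atp=float(a["ci_atp"]),
        K_amp=float(a["K_amp"]), ci_amp=float(a["ci_amp"]),
        K_f26=float(a["K_f26"]), ci_f26=float(a["ci_f26"]),
        K_f16=float(a["K_f16"]), ci_f16=float(a["ci_f16"]),
        F26bP=float(a["F26bP"]), Keq=float(config["keq"]["PFK"]),
    )


def _iteration0_reactions(config: Mapping) -> list[Reaction]:
    it0 = config["iteration0"]
    keq = config["keq"]
    br = config["branches"]

    def sat(group: str, spec: Mapping, rid: str | None = None) -> Reaction:
        hill = {}
        if "hill" in spec:
            hill = {m: float(spec["hill"]) for m in spec["Km"]}
        return Reaction(
            id=rid or group, group=group, stoichiometry=dict(_STOICH[rid or group]),
            law=Saturative(V=float(spec["V"]),
                           Km={k: float(v) for k, v in spec["Km"].items()}, hill=hill),
        )

    def rev(group: str, spec: Mapping, subs: list[str], prods: list[str]) -> Reaction:
        km = {k: float(v) for k, v in spec["Km"].items()}
        return Reaction(
            id=group, group=group, stoichiometry=dict(_STOICH[group]),
            law=ReversibleMM(
                E=1.0, kcat=float(spec["V"]),
                Km_sub={m: km[m] for m in subs}, Km_prod={m: km[m] for m in prods},
                Keq=float(keq[group]),
            ),
        )

    hxt = it0["HXT"]
    rxs = [
        Reaction(id="HXT", group="HXT", stoichiometry=dict(_STOICH["HXT"]),
                 law=FacilitatedDiffusion(V=float(hxt["V"]), Km=float(hxt["Km"]),
                                          Ki=float(hxt["Ki"]), outside="GLCx", inside="GLC")),
        rev("HXK", it0["HXK"], ["GLC", "ATP"], ["G6P", "ADP"]),
        rev("PGI", it0["PGI"], ["G6P"], ["F6P"]),
        Reaction(id="PFK", group="PFK", stoichiometry=dict(_STOICH["PFK"]),
                 law=_pfk_law(config, Vmax=float(it0["PFK"]["V"]))),
        rev("FBA", it0["FBA"], ["F16bP"], ["DHAP", "GAP"]),
        Reaction(id="TPI", group="TPI", stoichiometry=dict(_STOICH["TPI"]),
                 law=MassActionReversible(kf=float(it0["TPI"]["kf"]), Keq=float(keq["TPI"]),
                                          substrates={"DHAP": 1}, products={"GAP": 1})),
        rev("TDH", it0["TDH"], ["GAP", "NAD"], ["BPG", "NADH"]),
        rev("PGK", it0["PGK"], ["BPG", "ADP"], ["P3G", "ATP"]),
        rev("GPM", it0["GPM"], ["P3G"], ["P2G"]),
        rev("ENO", it0["ENO"], ["P2G"], ["PEP"]),
        sat("PYK", it0["PYK"]),
        sat("PDC", it0["PDC"]),
        sat("ADH", it0["ADH"]),
        Reaction(id="ATPase", group="ATPase", stoichiometry=dict(_STOICH["ATPase"]),
                 law=FirstOrder(k=float(it0["ATPase_k"]), species="ATP")),
        Reaction(id="AK", group="AK", stoichiometry=dict(_STOICH["AK"]),
                 law=MassActionReversible(kf=float(config["ak"]["kf"]), Keq=float(keq["AK"]),
                                          substrates={"ADP": 2}, products={"ATP": 1, "AMP": 1})),
        # glycerol branch: kinetic in the prior model (not a clamped flux)
        Reaction(id="GPD", group="Glycerol_branch", stoichiometry=dict(_STOICH["GPD"]),
                 law=InhibitedSaturative(
                     V=float(br["glycerol"]["gpd"]["V"]),
                     Km={k: float(v) for k, v in br["glycerol"]["gpd"]["Km"].items()},
                     Ki={k: float(v) for k, v in br["glycerol"]["gpd"].get("Ki", {}).items()})),
        Reaction(id="GPP", group="Glycerol_branch", stoichiometry=dict(_STOICH["GPP"]),
                 law=FirstOrder(k=float(br["glycerol"].get("gpp_first_order_k", 0.5)),
                                species="G3P")),
        # formerly clamped fluxes, now first-order in their reactants
        Reaction(id="Glycogen_branch", group="Glycogen_branch",
                 stoichiometry=dict(_STOICH["Glycogen_branch"]),
                 law=FirstOrder(k=float(br["glycogen"]["first_order_k"]), species="G6P")),
        Reaction(id="Trehalose_branch", group="Trehalose_branch",
                 stoichiometry=dict(_STOICH["Trehalose_branch"]),
                 law=FirstOrder(k=float(br["trehalose"]["first_order_k"]), species="G6P")),
        Reaction(id="Succinate_branch", group="Succinate_branch",
                 stoichiometry=dict(_STOICH["Succinate_branch"]),
                 law=FirstOrder(k=float(config["succinate_k"]), species="ACE")),
    ]
    return rxs


def build_model(
    iteration: int = 18,
    volume_fl: float | None = None,
    config: Mapping | None = None,
    tables: Tables | None = None,
    atpase_V: float | None = None,
    succinate_k: float | None = None,
    queue: Iterable[str] | None = None,
) -> KineticModel:
    """Assemble the model at a named iteration of the characterisation sequence (0–18).

    Iterations 0–17 default to the pre-fit effective volume (20 fl);
    iteration 18 applies the fitted parameter set (5 fl, ATPase V
    5.3 mM/s, succinate branch off). Pass ``volume_fl``/``atpase_V``/
    ``succinate_k`` to override, or ``queue`` to characterise an
    arbitrary subset (in order) instead of the canonical sequence.
    """
    if not 0 <= iteration <= 18:
        raise ValueError(f"iteration must be in 0..18, got {iteration}")
    tables = tables or load_tables()
    config = dict(config) if config is not None else load_config()

    final = iteration >= 18
    if volume_fl is None:
        volume_fl = float(config["volume_fl"]) if final else float(config["prefit_volume_fl"])
    if final and atpase_V is None:
        atpase_V = float(config["atpase_fitted_V"])
    if final and succinate_k is None:
        succinate_k = float(config["succinate_fitted_k"])

    geometry = CellGeometry(volume_fl)
    model = KineticModel(
        geometry=geometry,
        metabolites=_build_metabolites(tables, config, geometry),
        reactions=_iteration0_reactions(config),
        meta={
            "iteration": iteration, "volume_fl": volume_fl,
            "atpase_V": atpase_V, "succinate_k": succinate_k,
        },
    )
    model.activities = {g: 1.0 for g in model.groups}
    model.validate()

    if queue is None:
        queue = TABLE1_ORDER[: min(iteration, 17)]
    recs = characterisation_records(tables, config, geometry,
                                    atpase_V=atpase_V, succinate_k=succinate_k)
    for group in queue:
        model = apply_characterisation(model, group, recs[group])
    return model


def apply_characterisation(
    model: KineticModel, reaction_id: str, record: CharacterisationRecord
) -> KineticModel:
    """Replace one step's kinetics with its characterised form.

    Returns a new model; the input is untouched. Raises if the step is
    already characterised or unknown.
    """
    if record.group != reaction_id:
        raise ValueError(f"record is for {record.group!r}, not {reaction_id!r}")
    if reaction_id in model.characterised:
        raise ValueError(f"reaction {reaction_id!r} is already characterised")
    model.reactions_in(reaction_id)  # raises KeyError if absent
    new = model.copy()
    groups_replaced = {record.group, *record.extra_groups}
    new.reactions = [r for r in new.reactions if r.group not in groups_replaced]
    # keep the step's position in the reaction list stable where possible
    new.reactions.extend(_copy.deepcopy(record.reactions))
    new.characterised |= groups_replaced
    for g in groups_replaced:
        new.activities.setdefault(g, 1.0)
    new.validate()
    return new
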