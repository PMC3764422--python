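"""SBML Level 2 Version 4 import and export.

The exchange format for the model series is SBML L2V4 with
computer-readable annotations (ChEBI identifiers on species, UniProt
identifiers on the isoenzyme-concentration parameters). This module
reads and writes that dialect directly on top of lxml, with kinetic
laws carried as content MathML and converted to/from sympy
expressions.

Unit convention: the document is written so that concentrations are mM
and rates mM/s — the substance unit is millimole and the compartment
is expressed in litres with size 1, with the physical effective
cytoplasmic volume recorded as the ``cytoplasmic_volume_fl`` parameter
(copy-number conversions happen outside the ODE system, so the ODE
compartment is a unit volume). On import, a compartment of size s ≠ 1
has its kinetic laws divided by s to recover concentration rates.

Constructs outside the supported subset (function definitions, rules,
events) raise :class:`UnsupportedSBMLError` — nothing is dropped
silently.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import sympy
from lxml import etree

from .model_assembly import KineticModel, Metabolite, Reaction, load_tables
from .rate_laws import RateLaw
from .units import CellGeometry

__all__ = [
    "ModelDocument",
    "UnsupportedSBMLError",
    "GenericLaw",
    "write_sbml",
    "read_sbml",
]

SBML_NS = "http://www.sbml.org/sbml/level2/version4"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
RDF_NS = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
BQBIOL_NS = "http://biomodels.net/biology-qualifiers/"
XHTML_NS = "http://www.w3.org/1999/xhtml"


class UnsupportedSBMLError(ValueError):
    """An SBML construct outside the supported subset was encountered."""


@dataclass
class ModelDocument:
    """An SBML L2V4 document wrapping a kinetic model."""

    model_id: str
    xml: bytes
    format: str = "SBML L2V4"

    def write(self, path) -> None:
        with open(path, "wb") as fh:
            fh.write(self.xml)

    def tostring(self) -> str:
        return self.xml.decode()


@dataclass
class GenericLaw(RateLaw):
    """A kinetic law kept as a symbolic expression (imported models)."""

    expression: sympy.Expr

    def __post_init__(self) -> None:
        self._symbols = sorted(self.expression.free_symbols, key=str)
        self._fn = sympy.lambdify(self._symbols, self.expression, "math")

    def rate(self, conc: Mapping[str, float]) -> float:
        return float(self._fn(*(conc[str(s)] for s in self._symbols)))

    def expr(self) -> sympy.Expr:
        return self.expression


# ---------------------------------------------------------------------------
# MathML <-> sympy
# ---------------------------------------------------------------------------

_APPLY_OPS = {
    "plus": lambda *a: sympy.Add(*a),
    "times": lambda *a: sympy.Mul(*a),
    "power": lambda b, e: sympy.Pow(b, e),
    "exp": sympy.exp,
    "ln": sympy.log,
    "root": lambda x: sympy.sqrt(x),
}


def _mathml_to_sympy(node, params: Mapping[str, float]) -> sympy.Expr:
    tag = etree.QName(node).localname
    if tag == "math":
        children = [c for c in node if isinstance(c.tag, str)]
        if len(children) != 1:
            raise UnsupportedSBMLError("math element must have one child")
        return _mathml_to_sympy(children[0], params)
    if tag == "ci":
        name = node.text.strip()
        if name in params:
            return sympy.Float(params[name])
        return sympy.Symbol(name, nonnegative=True)
    if tag == "cn":
        kind = node.get("type", "real")
        if kind == "integer":
            return sympy.Integer(int(node.text.strip()))
        if kind == "rational":
            num = int(node.text.strip())
            sep = node.find(f"{{{MATHML_NS}}}sep")
            den = int(sep.tail.strip())
            return sympy.Rational(num, den)
        if kind in ("real", "double"):
            sep = node.find(f"{{{MATHML_NS}}}sep")
            if sep is not None:  # e-notation: mantissa <sep/> exponent
                return sympy.Float(float(node.text.strip()) * 10 ** int(sep.tail.strip()))
            return sympy.Float(float(node.text.strip()))
        raise UnsupportedSBMLError(f"cn type {kind!r}")
    if tag == "apply":
        children = [c for c in node if isinstance(c.tag, str)]
        op = etree.QName(children[0]).localname
        args = [_mathml_to_sympy(c, params) for c in children[1:]]
        if op == "minus":
            if len(args) == 1:
                return -args[0]
            return args[0] - args[1]
        if op == "divide":
            return args[0] / args[1]
        if op in _APPLY_OPS:
            return _APPLY_OPS[op](*args)
        raise UnsupportedSBMLError(f"MathML operator {op!r}")
    raise UnsupportedSBMLError(f"MathML element {tag!r}")


def _sympy_to_mathml(expr: sympy.Expr):
    """Content-MathML <math> element for a sympy expression."""
    mathml = sympy.printing.mathml(expr)
    root = etree.fromstring(f'<math xmlns="{MATHML_NS}">{mathml}</math>')
    return root


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def _rdf_annotation(parent, meta_id: str, uris: list[str]) -> None:
    ann = etree.SubElement(parent, f"{{{SBML_NS}}}annotation")
    rdf = etree.SubElement(ann, f"{{{RDF_NS}}}RDF", nsmap={
        "rdf": RDF_NS, "bqbiol": BQBIOL_NS,
    })
    desc = etree.SubElement(rdf, f"{{{RDF_NS}}}Description")
    desc.set(f"{{{RDF_NS}}}about", f"#{meta_id}")
    is_ = etree.SubElement(desc, f"{{{BQBIOL_NS}}}is")
    bag = etree.SubElement(is_, f"{{{RDF_NS}}}Bag")
    for uri in uris:
        li = etree.SubElement(bag, f"{{{RDF_NS}}}li")
        li.set(f"{{{RDF_NS}}}resource", uri)


def _notes(parent, lines: list[str]) -> None:
    notes = etree.SubElement(parent, f"{{{SBML_NS}}}notes")
    body = etree.SubElement(notes, f"{{{XHTML_NS}}}body", nsmap={None: XHTML_NS})
    for line in lines:
        p = etree.SubElement(body, f"{{{XHTML_NS}}}p")
        p.text = line


def write_sbml(model: KineticModel, model_id: str = "glycolysis") -> ModelDocument:
    """Serialise a kinetic model to SBML L2V4 with ChEBI/UniProt
    annotations; kinetic laws are emitted as content MathML."""
    uniprot = {}
    try:
        prot = load_tables().proteins
        uniprot = dict(zip(prot["isoenzyme"], prot["uniprot"]))
    except Exception:
        pass

    root = etree.Element(f"{{{SBML_NS}}}sbml", nsmap={None: SBML_NS})
    root.set("level", "2")
    root.set("version", "4")
    mdl = etree.SubElement(root, f"{{{SBML_NS}}}model")
    mdl.set("id", model_id)
    notes_lines = []
    if model.characterised:
        notes_lines.append("characterised: " + ",".join(sorted(model.characterised)))
    if model.meta.get("iteration") is not None:
        notes_lines.append(f"iteration: {model.meta['iteration']}")
    if notes_lines:
        _notes(mdl, notes_lines)

    # millimole substance => initialConcentration and kinetic laws in mM
    units = etree.SubElement(mdl, f"{{{SBML_NS}}}listOfUnitDefinitions")
    ud = etree.SubElement(units, f"{{{SBML_NS}}}unitDefinition")
    ud.set("id", "substance")
    lou = etree.SubElement(ud, f"{{{SBML_NS}}}listOfUnits")
    u = etree.SubElement(lou, f"{{{SBML_NS}}}unit")
    u.set("kind", "mole")
    u.set("scale", "-3")

    comps = etree.SubElement(mdl, f"{{{SBML_NS}}}listOfCompartments")
    comp = etree.SubElement(comps, f"{{{SBML_NS}}}compartment")
    comp.set("id", "cell")
    comp.set("size", "1.0")

    species = etree.SubElement(mdl, f"{{{SBML_NS}}}listOfSpecies")
    for met in model.metabolites.values():
        sp = etree.SubElement(species, f"{{{SBML_NS}}}species")
        sp.set("id", met.id)
        sp.set("metaid", f"meta_{met.id}")
        sp.set("name", met.name or met.id)
        sp.set("compartment", "cell")
        sp.set("initialConcentration", repr(met.concentration))
        sp.set("boundaryCondition", "true" if met.boundary else "false")
        if met.chebi:
            uris = [
                f"http://identifiers.org/chebi/CHEBI:{c.strip()}"
                for c in str(met.chebi).split(";") if c.strip()
            ]
            _rdf_annotation(sp, f"meta_{met.id}", uris)

    params = etree.SubElement(mdl, f"{{{SBML_NS}}}listOfParameters")
    vol = etree.SubElement(params, f"{{{SBML_NS}}}parameter")
    vol.set("id", "cytoplasmic_volume_fl")
    vol.set("value", repr(model.geometry.cytoplasmic_volume_fl))
    vol.set("constant", "true")
    seen = set()
    for rx in model.reactions:
        for entry in rx.isoenzymes:
            pid = f"E_{entry.id.replace(':', '_')}"
            if pid in seen:
                continue
            seen.add(pid)
            par = etree.SubElement(params, f"{{{SBML_NS}}}parameter")
            par.set("id", pid)
            par.set("metaid", f"meta_{pid}")
            par.set("value", repr(entry.E))
            par.set("constant", "true")
            # a co-purified complex (e.g. Pfk1p:Pfk2p) carries every
            # subunit's accession
            accs = [uniprot[sub] for sub in entry.id.split(":") if sub in uniprot]
            if accs:
                _rdf_annotation(par, f"meta_{pid}",
                                [f"http://identifiers.org/uniprot/{a}" for a in accs])

    rxs = etree.SubElement(mdl, f"{{{SBML_NS}}}listOfReactions")
    for rx in model.reactions:
        r = etree.SubElement(rxs, f"{{{SBML_NS}}}reaction")
        r.set("id", rx.id)
        r.set("reversible", "true")
        lines = [f"group: {rx.group}"]
        if rx.isoenzymes:
            lines.append("isoenzymes: " + ",".join(e.id for e in rx.isoenzymes))
        _notes(r, lines)
        reactants = {m: -c for m, c in rx.stoichiometry.items() if c < 0}
        products = {m: c for m, c in rx.stoichiometry.items() if c > 0}
        if reactants:
            lo = etree.SubElement(r, f"{{{SBML_NS}}}listOfReactants")
            for m, c in reactants.items():
                sr = etree.SubElement(lo, f"{{{SBML_NS}}}speciesReference")
                sr.set("species", m)
                sr.set("stoichiometry", repr(float(c)))
        if products:
            lo = etree.SubElement(r, f"{{{SBML_NS}}}listOfProducts")
            for m, c in products.items():
                sr = etree.SubElement(lo, f"{{{SBML_NS}}}speciesReference")
                sr.set("species", m)
                sr.set("stoichiometry", repr(float(c)))
        kl = etree.SubElement(r, f"{{{SBML_NS}}}kineticLaw")
        if rx.law is not None:
            expr = rx.law.expr() * model.activities.get(rx.group, 1.0)
        else:
            expr = sympy.Add(*(
                model.iso_activities.get(e.id, 1.0) * e.law.expr()
                for e in rx.isoenzymes
            )) * model.activities.get(rx.group, 1.0)
        kl.append(_sympy_to_mathml(expr))

    xml = etree.tostring(root, xml_declaration=True, encoding="UTF-8",
                         pretty_print=True)
    return ModelDocument(model_id=model_id, xml=xml)


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _q(tag: str) -> str:
    return f"{{{SBML_NS}}}{tag}"


def read_sbml(source) -> KineticModel:
    """Parse an SBML L2V4 document into a :class:`KineticModel`.

    Kinetic laws are kept as symbolic expressions (:class:`GenericLaw`)
    with global and local parameters substituted numerically; species
    boundary flags, initial concentrations and the recorded effective
    volume are reconstructed. Unsupported constructs raise, never drop.
    """
    if isinstance(source, bytes):
        root = etree.fromstring(source)
    elif isinstance(source, str) and source.lstrip().startswith("<"):
        root = etree.fromstring(source.encode())
    else:
        root = etree.parse(str(source)).getroot()
    if etree.QName(root).namespace != SBML_NS:
        raise UnsupportedSBMLError(
            f"expected SBML level 2 version 4 namespace, got {etree.QName(root).namespace}"
        )
    mdl = root.find(_q("model"))
    if mdl is None:
        raise UnsupportedSBMLError("document has no <model>")
    for construct in ("listOfFunctionDefinitions", "listOfRules", "listOfEvents"):
        if mdl.find(_q(construct)) is not None:
            raise UnsupportedSBMLError(f"{construct} is not supported")

    notes_text = " ".join(mdl.find(_q("notes")).itertext()) if mdl.find(_q("notes")) is not None else ""
    characterised: set[str] = set()
    for line in notes_text.split("\n"):
        line = line.strip()
        if line.startswith("characterised:"):
            characterised = {g.strip() for g in line.split(":", 1)[1].split(",") if g.strip()}
    if "characterised:" in notes_text and not characterised:
        after = notes_text.split("characterised:", 1)[1].split("iteration:")[0]
        characterised = {g.strip() for g in after.split(",") if g.strip()}

    size = 1.0
    comp = mdl.find(f"{_q('listOfCompartments')}/{_q('compartment')}")
    if comp is not None and comp.get("size"):
        size = float(comp.get("size"))

    params: dict[str, float] = {}
    lop = mdl.find(_q("listOfParameters"))
    if lop is not None:
        for p in lop.findall(_q("parameter")):
            params[p.get("id")] = float(p.get("value", "0"))
    volume_fl = params.get("cytoplasmic_volume_fl", 5.0)

    metabolites: dict[str, Metabolite] = {}
    los = mdl.find(_q("listOfSpecies"))
    if los is None:
        raise UnsupportedSBMLError("document has no species")
    for sp in los.findall(_q("species")):
        sid = sp.get("id")
        if sp.get("initialConcentration") is not None:
            conc = float(sp.get("initialConcentration"))
        elif sp.get("initialAmount") is not None:
            conc = float(sp.get("initialAmount")) / size
        else:
            conc = 0.0
        chebi = ""
        for li in sp.iter(f"{{{RDF_NS}}}li"):
            res = li.get(f"{{{RDF_NS}}}resource", "")
            if "CHEBI:" in res:
                chebi = (chebi + ";" if chebi else "") + res.rsplit("CHEBI:", 1)[1]
        metabolites[sid] = Metabolite(
            id=sid, name=sp.get("name", sid), chebi=chebi,
            boundary=sp.get("boundaryCondition", "false") == "true",
            concentration=conc,
        )

    reactions: list[Reaction] = []
    lor = mdl.find(_q("listOfReactions"))
    if lor is None:
        raise UnsupportedSBMLError("document has no reactions")
    for r in lor.findall(_q("reaction")):
        rid = r.get("id")
        stoich: dict[str, int] = {}
        for lo, sign in ((r.find(_q("listOfReactants")), -1),
                         (r.find(_q("listOfProducts")), +1)):
            if lo is None:
                continue
            for sr in lo.findall(_q("speciesReference")):
                coef = float(sr.get("stoichiometry", "1"))
                if coef != int(coef):
                    raise UnsupportedSBMLError(
                        f"non-integer stoichiometry in reaction {rid}"
                    )
                stoich[sr.get("species")] = stoich.get(sr.get("species"), 0) + sign * int(coef)
        group = rid
        rnotes = r.find(_q("notes"))
        if rnotes is not None:
            for line in " ".join(rnotes.itertext()).split("\n"):
                if "group:" in line:
                    group = line.split("group:", 1)[1].split()[0].strip()
        kl = r.find(_q("kineticLaw"))
        if kl is None:
            raise UnsupportedSBMLError(f"reaction {rid} has no kinetic law")
        local = dict(params)
        lolp = kl.find(_q("listOfParameters"))
        if lolp is not None:
            for p in lolp.findall(_q("parameter")):
                local[p.get("id")] = float(p.get("value", "0"))
        local["cell"] = size
        math = kl.find(f"{{{MATHML_NS}}}math")
        if math is None:
            raise UnsupportedSBMLError(f"reaction {rid} kinetic law has no math")
        expr = _mathml_to_sympy(math, local)
        if size != 1.0:  # substance/time -> concentration/time
            expr = expr / size
        reactions.append(Reaction(
            id=rid, group=group, stoichiometry=stoich, law=GenericLaw(expr),
        ))

    model = KineticModel(
        geometry=CellGeometry(volume_fl),
        metabolites=metabolites,
        reactions=reactions,
        characterised=characterised,
        meta={"model_id": mdl.get("id", "model"), "source": "sbml"},
    )
    model.activities = {g: 1.0 for g in model.groups}
    model.validate()
    return model
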