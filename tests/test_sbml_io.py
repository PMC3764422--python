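"""SBML L2V4 export/import: roundtrips, annotations, unit handling."""

import pytest
from lxml import etree

from isogly.sbml_io import (
    MATHML_NS,
    RDF_NS,
    SBML_NS,
    UnsupportedSBMLError,
    read_sbml,
    write_sbml,
)
from isogly.simulate import steady_state
from isogly.synthetic_data import make_toy_network


@pytest.fixture(scope="module")
def doc18(model18):
    return write_sbml(model18, "glycolysis_final")


@pytest.fixture(scope="module")
def reimported18(doc18):
    return read_sbml(doc18.xml)


def test_document_structure(doc18):
    root = etree.fromstring(doc18.xml)
    assert etree.QName(root).namespace == SBML_NS
    assert root.get("level") == "2" and root.get("version") == "4"
    model = root.find(f"{{{SBML_NS}}}model")
    assert model is not None
    for part in ("listOfCompartments", "listOfSpecies", "listOfReactions"):
        assert model.find(f"{{{SBML_NS}}}{part}") is not None
    for rx in model.iter(f"{{{SBML_NS}}}reaction"):
        kl = rx.find(f"{{{SBML_NS}}}kineticLaw")
        assert kl is not None
        assert kl.find(f"{{{MATHML_NS}}}math") is not None


def test_chebi_annotations_on_measured_species(doc18, tables):
    root = etree.fromstring(doc18.xml)
    annotated = set()
    for sp in root.iter(f"{{{SBML_NS}}}species"):
        for li in sp.iter(f"{{{RDF_NS}}}li"):
            if "CHEBI:" in li.get(f"{{{RDF_NS}}}resource", ""):
                annotated.add(sp.get("id"))
    expected = set()
    for row in tables.metabolites.itertuples(index=False):
        expected.update(("P2G", "P3G") if row.id == "P2G+P3G" else (row.id,))
    assert expected <= annotated


def test_uniprot_annotations_on_isoenzyme_parameters(doc18, tables):
    root = etree.fromstring(doc18.xml)
    accessions = set()
    for par in root.iter(f"{{{SBML_NS}}}parameter"):
        for li in par.iter(f"{{{RDF_NS}}}li"):
            res = li.get(f"{{{RDF_NS}}}resource", "")
            if "uniprot" in res:
                accessions.add(res.rsplit("/", 1)[1])
    # every measured isoenzyme carries its accession (the co-purified PFK
    # complex parameter lists both subunits)
    assert set(tables.proteins["uniprot"]) <= accessions


def test_roundtrip_preserves_rates_and_steady_state(model18, ss18, reimported18):
    conc = model18.initial_concentrations()
    r1, r2 = model18.rates(conc), reimported18.rates(conc)
    assert set(r1) == set(r2)
    for rid in r1:
        assert r2[rid] == pytest.approx(r1[rid], rel=1e-9, abs=1e-12)
    ss2 = steady_state(reimported18)
    assert ss2.converged
    for met, c in ss18.concentrations.items():
        assert ss2.concentrations[met] == pytest.approx(c, rel=1e-6, abs=1e-9)


def test_roundtrip_preserves_structure(model18, reimported18):
    assert set(reimported18.metabolites) == set(model18.metabolites)
    assert [r.id for r in reimported18.reactions] == [r.id for r in model18.reactions]
    assert reimported18.characterised == model18.characterised
    for met in model18.metabolites.values():
        other = reimported18.metabolites[met.id]
        assert other.boundary == met.boundary
        assert other.concentration == pytest.approx(met.concentration, rel=1e-12)
    assert reimported18.geometry.cytoplasmic_volume_fl == pytest.approx(
        model18.geometry.cytoplasmic_volume_fl
    )


def test_second_roundtrip_is_fixed_point(reimported18, model18):
    again = read_sbml(write_sbml(reimported18, "again").xml)
    conc = model18.initial_concentrations()
    r1, r2 = reimported18.rates(conc), again.rates(conc)
    for rid in r1:
        assert r2[rid] == pytest.approx(r1[rid], rel=1e-12, abs=1e-15)


def test_toy_model_roundtrip(tmp_path):
    m = make_toy_network("branch")
    path = tmp_path / "branch.xml"
    write_sbml(m, "branch_toy").write(path)
    back = read_sbml(path)
    conc = m.initial_concentrations()
    for rid, v in m.rates(conc).items():
        assert back.rates(conc)[rid] == pytest.approx(v, rel=1e-9, abs=1e-12)


def test_compartment_size_rescales_kinetic_laws():
    """A document in substance/time units over a non-unit compartment
    imports with concentration-rate laws (divided by the size)."""
    xml = f"""<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="{SBML_NS}" level="2" version="4">
  <model id="toy">
    <listOfCompartments><compartment id="c" size="2.0"/></listOfCompartments>
    <listOfSpecies>
      <species id="A" compartment="c" initialConcentration="3.0" boundaryCondition="true"/>
      <species id="B" compartment="c" initialConcentration="0.0" boundaryCondition="false"/>
    </listOfSpecies>
    <listOfReactions>
      <reaction id="R" reversible="false">
        <listOfReactants><speciesReference species="A"/></listOfReactants>
        <listOfProducts><speciesReference species="B"/></listOfProducts>
        <kineticLaw>
          <math xmlns="{MATHML_NS}">
            <apply><times/><cn>4</cn><ci>A</ci></apply>
          </math>
        </kineticLaw>
      </reaction>
    </listOfReactions>
  </model>
</sbml>"""
    model = read_sbml(xml)
    # 4*A substance/time over size 2 -> 2*A concentration/time
    assert model.rates({"B": 0.0})["R"] == pytest.approx(2.0 * 3.0)


def test_unsupported_constructs_raise_not_drop():
    xml = f"""<?xml version="1.0"?>
<sbml xmlns="{SBML_NS}" level="2" version="4">
  <model id="bad">
    <listOfRules/>
    <listOfSpecies>
      <species id="A" compartment="c" initialConcentration="1.0"/>
    </listOfSpecies>
  </model>
</sbml>"""
    with pytest.raises(UnsupportedSBMLError, match="listOfRules"):
        read_sbml(xml)


def test_wrong_namespace_rejected():
    xml = """<sbml xmlns="http://www.sbml.org/sbml/level3/version1/core"
                    level="3" version="1"><model id="x"/></sbml>"""
    with pytest.raises(UnsupportedSBMLError, match="level 2 version 4"):
        read_sbml(xml)
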