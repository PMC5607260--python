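"""Minimal SBML Level 3 export of the reaction network.

Writes species and reactions (stoichiometry only, no kinetic laws) so the
network structure can be exchanged and round-tripped; a matching reader
recovers species/reaction counts and identifiers.
"""

from __future__ import annotations

import re
import xml.etree.ElementTree as ET

from .model import CompiledModel, DOWNSTREAM
from .network import dimer_name

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"


def _sid(name: str) -> str:
    """Sanitize a state/reaction name into a valid SBML SId."""
    s = re.sub(r"[^A-Za-z0-9_]", "_", name)
    return s if re.match(r"[A-Za-z_]", s) else "s_" + s


def _species_reactions(model: CompiledModel):
    spec = model.spec
    species = [_sid(n) for n in model.state_names]
    reactions = []  # (id, reactants, products)

    def add(rid, reactants, products):
        reactions.append((_sid(rid), [_sid(x) for x in reactants], [_sid(x) for x in products]))

    for r in spec.receptors:
        add(f"synthesis_{r}", [], [r])
        add(f"degradation_{r}", [r], [])
    for lig, (rec, _) in spec.ligands.items():
        bound = f"{rec}.{lig}"
        add(f"binding_{lig}", [rec], [bound])
        add(f"unbinding_{lig}", [bound], [rec])
    for pair in spec.dimers:
        n = dimer_name(pair)
        a, b = pair
        add(f"formation_{n}", [a, b], [f"{n}.surf"])
        add(f"dissociation_{n}", [f"{n}.surf"], [a, b])
        add(f"internalization_{n}", [f"{n}.surf"], [f"{n}.int"])
        add(f"recycling_{n}", [f"{n}.int"], [a, b])
        add(f"degradation_{n}", [f"{n}.int"], [])
    for name in DOWNSTREAM:
        add(f"activation_{name}", [], [name])
        add(f"deactivation_{name}", [name], [])
    return species, reactions


def export_model(model: CompiledModel, path) -> None:
    """Write the network as an SBML L3V2 document."""
    species, reactions = _species_reactions(model)
    ET.register_namespace("", SBML_NS)
    root = ET.Element(f"{{{SBML_NS}}}sbml", {"level": "3", "version": "2"})
    mdl = ET.SubElement(root, f"{{{SBML_NS}}}model",
                        {"id": f"ligandtree_{model.spec.variant}"})
    comps = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfCompartments")
    ET.SubElement(comps, f"{{{SBML_NS}}}compartment",
                  {"id": "cell", "constant": "true"})
    los = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfSpecies")
    for s in species:
        ET.SubElement(los, f"{{{SBML_NS}}}species", {
            "id": s, "compartment": "cell", "hasOnlySubstanceUnits": "true",
            "boundaryCondition": "false", "constant": "false",
        })
    lor = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfReactions")
    for rid, reactants, products in reactions:
        rxn = ET.SubElement(lor, f"{{{SBML_NS}}}reaction",
                            {"id": rid, "reversible": "false"})
        if reactants:
            lre = ET.SubElement(rxn, f"{{{SBML_NS}}}listOfReactants")
            for s in reactants:
                ET.SubElement(lre, f"{{{SBML_NS}}}speciesReference",
                              {"species": s, "stoichiometry": "1", "constant": "true"})
        if products:
            lpr = ET.SubElement(rxn, f"{{{SBML_NS}}}listOfProducts")
            for s in products:
                ET.SubElement(lpr, f"{{{SBML_NS}}}speciesReference",
                              {"species": s, "stoichiometry": "1", "constant": "true"})
    tree = ET.ElementTree(root)
    ET.indent(tree)
    try:
        tree.write(path, xml_declaration=True, encoding="unicode")
    except OSError as exc:
        raise IOError(f"could not write SBML to {path!r}: {exc}") from exc


def read_sbml_summary(path) -> dict:
    """Read back an SBML document: species/reaction ids and counts."""
    try:
        tree = ET.parse(path)
    except OSError as exc:
        raise IOError(f"could not read SBML from {path!r}: {exc}") from exc
    root = tree.getroot()
    ns = {"s": SBML_NS}
    species = [e.attrib["id"] for e in root.findall(".//s:listOfSpecies/s:species", ns)]
    reactions = [e.attrib["id"] for e in root.findall(".//s:listOfReactions/s:reaction", ns)]
    return {
        "n_species": len(species),
        "n_reactions": len(reactions),
        "species": species,
        "reactions": reactions,
    }


def expected_reaction_count(model: CompiledModel) -> int:
    return len(_species_reactions(model)[1])
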