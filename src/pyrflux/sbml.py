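"""Minimal SBML Level 3 Version 1 export of the reaction network.

Writes a self-contained SBML document with the nine dynamic metabolites,
the four clamped pools as boundary-condition species, one reaction with a
MathML kinetic law per enzymatic/utilization step, and first-order sink
reactions for growth dilution.  The writer emits only the constructs this
model needs; it is not a general SBML library.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

from .model import FIXED_SPECIES, PARAM_NAMES, SPECIES, ParameterSet, ReactionNetwork

__all__ = ["export_sbml"]

SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"

# expression trees: ("ci", name) | ("cn", value) | (op, arg, arg, ...)
_OPS = {"*": "times", "/": "divide", "+": "plus", "-": "minus"}


def _mathml(node, parent: ET.Element) -> None:
    kind = node[0]
    if kind == "ci":
        ET.SubElement(parent, f"{{{MATHML_NS}}}ci").text = f" {node[1]} "
    elif kind == "cn":
        ET.SubElement(parent, f"{{{MATHML_NS}}}cn").text = f" {node[1]!r} "
    else:
        apply_el = ET.SubElement(parent, f"{{{MATHML_NS}}}apply")
        ET.SubElement(apply_el, f"{{{MATHML_NS}}}{_OPS[kind]}")
        for arg in node[1:]:
            _mathml(arg, apply_el)


def _saturation(species: str, km: str):
    return ("/", ("ci", species), ("+", ("ci", km), ("ci", species)))


def _rate_expression(reaction, config):
    expr = [("ci", reaction.vmax)]
    for sp, km in zip(reaction.substrates, reaction.km):
        expr.append(_saturation(sp, km))
    for _ in reaction.modifiers:  # noncompetitive UTP inhibition
        expr.append(("/", ("ci", "K_utp"), ("+", ("ci", "K_utp"), ("ci", "utp"))))
    if len(expr) == 1:
        return expr[0]
    return ("*", *expr)


def export_sbml(
    network: ReactionNetwork,
    params: ParameterSet,
    path: str | Path,
    model_id: str = "pyrimidine_biosynthesis",
) -> None:
    """Write the network and parameter values as SBML L3V1."""
    ET.register_namespace("", SBML_NS)
    ET.register_namespace("math", MATHML_NS)
    sbml = ET.Element(f"{{{SBML_NS}}}sbml", {"level": "3", "version": "1"})
    model = ET.SubElement(sbml, f"{{{SBML_NS}}}model", {
        "id": model_id, "substanceUnits": "mole", "timeUnits": "second",
        "extentUnits": "mole",
    })

    compartments = ET.SubElement(model, f"{{{SBML_NS}}}listOfCompartments")
    ET.SubElement(compartments, f"{{{SBML_NS}}}compartment", {
        "id": "cell", "size": "1", "constant": "true", "spatialDimensions": "3",
    })

    species_el = ET.SubElement(model, f"{{{SBML_NS}}}listOfSpecies")
    for sp in SPECIES:
        ET.SubElement(species_el, f"{{{SBML_NS}}}species", {
            "id": sp, "compartment": "cell", "initialConcentration": "1e-6",
            "hasOnlySubstanceUnits": "false", "boundaryCondition": "false",
            "constant": "false",
        })
    for sp in FIXED_SPECIES:
        ET.SubElement(species_el, f"{{{SBML_NS}}}species", {
            "id": sp, "compartment": "cell",
            "initialConcentration": repr(params[sp]),
            "hasOnlySubstanceUnits": "false", "boundaryCondition": "true",
            "constant": "true",
        })

    params_el = ET.SubElement(model, f"{{{SBML_NS}}}listOfParameters")
    for name in PARAM_NAMES:
        if name in FIXED_SPECIES:
            continue  # exported as boundary species
        ET.SubElement(params_el, f"{{{SBML_NS}}}parameter", {
            "id": name, "value": repr(params[name]), "constant": "true",
        })
    ET.SubElement(params_el, f"{{{SBML_NS}}}parameter", {
        "id": "dilution_rate", "value": repr(network.config.dilution_rate),
        "constant": "true",
    })

    reactions_el = ET.SubElement(model, f"{{{SBML_NS}}}listOfReactions")

    def add_reaction(rid, reactants, products, modifiers, expr):
        rxn = ET.SubElement(reactions_el, f"{{{SBML_NS}}}reaction", {
            "id": rid, "reversible": "false",
        })
        if reactants:
            lst = ET.SubElement(rxn, f"{{{SBML_NS}}}listOfReactants")
            for sp in reactants:
                ET.SubElement(lst, f"{{{SBML_NS}}}speciesReference", {
                    "species": sp, "stoichiometry": "1", "constant": "true"})
        if products:
            lst = ET.SubElement(rxn, f"{{{SBML_NS}}}listOfProducts")
            for sp in products:
                ET.SubElement(lst, f"{{{SBML_NS}}}speciesReference", {
                    "species": sp, "stoichiometry": "1", "constant": "true"})
        if modifiers:
            lst = ET.SubElement(rxn, f"{{{SBML_NS}}}listOfModifiers")
            for sp in modifiers:
                ET.SubElement(lst, f"{{{SBML_NS}}}modifierSpeciesReference",
                              {"species": sp})
        kl = ET.SubElement(rxn, f"{{{SBML_NS}}}kineticLaw")
        math_el = ET.SubElement(kl, f"{{{MATHML_NS}}}math")
        _mathml(expr, math_el)

    for rxn in network.reactions:
        add_reaction(rxn.id, rxn.substrates, rxn.products, rxn.modifiers,
                     _rate_expression(rxn, network.config))
    if network.config.dilution_rate > 0:
        for sp in SPECIES:
            add_reaction(f"dilution_{sp}", (sp,), (), (),
                         ("*", ("ci", "dilution_rate"), ("ci", sp)))

    tree = ET.ElementTree(sbml)
    ET.indent(tree)
    tree.write(path, xml_declaration=True, encoding="UTF-8")
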