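"""One-way SBML Level 3 export of pathway models.

The export writes SBML L3V2 core documents by direct XML construction:
species (with boundaryCondition/constant flags), reactions with their
stoichiometries, kinetic laws as content MathML rendered from the symbolic
rate-law transcriptions, and conserved moieties as initial assignments
(the last-listed member of each moiety is assigned total minus the other
members, mirroring how the steady-state solver eliminates it).

The export is intended for cross-simulator validation of the models; it is
one-way (no SBML import).
"""

from __future__ import annotations

from pathlib import Path

import sympy as sp
from lxml import etree

from .errors import ConfigurationError
from .pathway import PathwayModel
from .symbolic import SYMBOLIC_LAWS

__all__ = ["export_sbml", "sbml_id"]

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"


def sbml_id(name: str) -> str:
    """A valid SBML SId for a species name (ids cannot start with a digit)."""
    return "_" + name if name[0].isdigit() else name


def _content_mathml(expr: sp.Expr, parent: etree._Element) -> None:
    """Minimal content-MathML writer (symbols emitted verbatim as <ci>)."""
    q = "{%s}" % MATHML_NS
    if isinstance(expr, sp.Symbol):
        etree.SubElement(parent, q + "ci").text = f" {expr.name} "
        return
    if isinstance(expr, (sp.Integer, sp.Float, sp.Rational)):
        if isinstance(expr, sp.Rational) and not isinstance(expr, sp.Integer):
            apply = etree.SubElement(parent, q + "apply")
            etree.SubElement(apply, q + "divide")
            etree.SubElement(apply, q + "cn").text = f" {expr.p} "
            etree.SubElement(apply, q + "cn").text = f" {expr.q} "
        else:
            etree.SubElement(parent, q + "cn").text = f" {expr} "
        return
    apply = etree.SubElement(parent, q + "apply")
    if isinstance(expr, sp.Add):
        etree.SubElement(apply, q + "plus")
        for arg in expr.args:
            _content_mathml(arg, apply)
    elif isinstance(expr, sp.Mul):
        etree.SubElement(apply, q + "times")
        for arg in expr.args:
            _content_mathml(arg, apply)
    elif isinstance(expr, sp.Pow):
        etree.SubElement(apply, q + "power")
        _content_mathml(expr.base, apply)
        _content_mathml(expr.exp, apply)
    else:
        raise ConfigurationError(
            f"cannot render {type(expr).__name__} as content MathML")


def _mathml_element(expr: sp.Expr) -> etree._Element:
    math = etree.Element("{%s}math" % MATHML_NS,
                         nsmap={None: MATHML_NS})
    _content_mathml(sp.sympify(expr), math)
    return math


def _kinetic_law_math(reaction) -> etree._Element:
    try:
        expr = SYMBOLIC_LAWS[reaction.rate_law_id]
    except KeyError:
        raise ConfigurationError(
            f"reaction {reaction.name!r}: rate law "
            f"{reaction.rate_law_id!r} has no symbolic form to export")
    # map generic roles (synthetic chains) and digit-initial species onto
    # their SBML ids
    substitutions = {}
    if reaction.species_map:
        for role, species in reaction.species_map.items():
            substitutions[sp.Symbol(role)] = sp.Symbol(sbml_id(species))
    if substitutions:
        expr = expr.subs(substitutions, simultaneous=True)
    return _mathml_element(expr)


def export_sbml(model: PathwayModel, path=None) -> str:
    """Serialize ``model`` to an SBML L3V2 document; returns the XML text.

    When ``path`` is given the document is also written there.
    """
    nsmap = {None: SBML_NS}
    root = etree.Element("sbml", nsmap=nsmap, level="3", version="2")
    mdl = etree.SubElement(root, "model",
                           id=sbml_id(model.name or "pathway"),
                           substanceUnits="millimole",
                           timeUnits="minute", volumeUnits="litre",
                           extentUnits="millimole")
    compartments = etree.SubElement(mdl, "listOfCompartments")
    etree.SubElement(compartments, "compartment", id="cell", size="1",
                     spatialDimensions="3", constant="true")

    species_list = etree.SubElement(mdl, "listOfSpecies")
    for s in model.species:
        etree.SubElement(
            species_list, "species", id=sbml_id(s.name), name=s.name,
            compartment="cell",
            initialConcentration=repr(float(s.concentration)),
            hasOnlySubstanceUnits="false",
            boundaryCondition="true" if s.is_boundary else "false",
            constant="true" if s.is_boundary else "false")

    if model.moieties:
        params = etree.SubElement(mdl, "listOfParameters")
        assignments = etree.SubElement(mdl, "listOfInitialAssignments")
        for i, (members, total) in enumerate(model.moieties):
            total_id = f"moiety_total_{i}"
            etree.SubElement(params, "parameter", id=total_id,
                             value=repr(float(total)), constant="true")
            ordered = [n for n in model.free_species if n in members]
            dropped, kept = ordered[-1], ordered[:-1]
            assignment = etree.SubElement(assignments, "initialAssignment",
                                          symbol=sbml_id(dropped))
            expr = sp.Symbol(total_id) - sum(
                (sp.Symbol(sbml_id(k)) for k in kept), sp.Integer(0))
            assignment.append(_mathml_element(expr))

    reactions_list = etree.SubElement(mdl, "listOfReactions")
    for rxn in model.reactions:
        rx = etree.SubElement(reactions_list, "reaction",
                              id=sbml_id(rxn.name), reversible="true")
        reactants = [(n, -c) for n, c in rxn.stoichiometry.items() if c < 0]
        products = [(n, c) for n, c in rxn.stoichiometry.items() if c > 0]
        if reactants:
            lst = etree.SubElement(rx, "listOfReactants")
            for name, coeff in reactants:
                etree.SubElement(lst, "speciesReference",
                                 species=sbml_id(name),
                                 stoichiometry=repr(float(coeff)),
                                 constant="true")
        if products:
            lst = etree.SubElement(rx, "listOfProducts")
            for name, coeff in products:
                etree.SubElement(lst, "speciesReference",
                                 species=sbml_id(name),
                                 stoichiometry=repr(float(coeff)),
                                 constant="true")
        law = etree.SubElement(rx, "kineticLaw")
        law.append(_kinetic_law_math(rxn))
        local = etree.SubElement(law, "listOfLocalParameters")
        for symbol, value in rxn.parameters.items():
            value = float(value)
            # xs:double spells infinity INF
            text_value = "INF" if value == float("inf") else repr(value)
            etree.SubElement(local, "localParameter", id=symbol,
                             value=text_value)

    text = etree.tostring(root, pretty_print=True,
                          xml_declaration=True, encoding="UTF-8").decode()
    if path is not None:
        Path(path).write_text(text)
    return text
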