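"""SBML Level 2 Version 4 export/import of reaction networks.

The exported document carries one compartment (the 40 ul reaction well,
size normalised to 1 so concentrations are in nM), every species with its
initial concentration, and one reaction per mass-action step with a MathML
kinetic law ``kf*A*B - kr*C`` and local parameters ``kf``/``kr``.  Species
ids are sanitised (':' -> '_', '*' -> 'star'); the display name preserves
the original.  Every write is immediately re-parsed and cross-checked
against the in-memory model.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

from lxml import etree

from .network import NetworkModel, ReactionDef, Species

__all__ = ["write_sbml", "read_sbml", "sanitize_id"]

SBML_NS = "http://www.sbml.org/sbml/level2/version4"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
NSMAP = {None: SBML_NS}


def sanitize_id(name: str) -> str:
    sid = name.replace(":", "_").replace("*", "star")
    if not (sid[0].isalpha() or sid[0] == "_"):
        sid = "s_" + sid
    return sid


def _math_times(parent, factors):
    math = etree.SubElement(parent, f"{{{MATHML_NS}}}math")
    return math, _apply_times(math, factors)


def _apply_times(parent, factors):
    if len(factors) == 1:
        ci = etree.SubElement(parent, f"{{{MATHML_NS}}}ci")
        ci.text = f" {factors[0]} "
        return ci
    ap = etree.SubElement(parent, f"{{{MATHML_NS}}}apply")
    etree.SubElement(ap, f"{{{MATHML_NS}}}times")
    for f in factors:
        ci = etree.SubElement(ap, f"{{{MATHML_NS}}}ci")
        ci.text = f" {f} "
    return ap


def write_sbml(model: NetworkModel, path: Union[str, Path]) -> None:
    """Serialise ``model`` to SBML L2V4 and validate by re-parsing."""
    root = etree.Element(f"{{{SBML_NS}}}sbml", nsmap=NSMAP, level="2", version="4")
    mdl = etree.SubElement(root, f"{{{SBML_NS}}}model",
                           id="p38_substrate_competition",
                           name=str(model.provenance.get("mechanism", "network")))
    comps = etree.SubElement(mdl, f"{{{SBML_NS}}}listOfCompartments")
    etree.SubElement(comps, f"{{{SBML_NS}}}compartment", id="well", size="1")
    los = etree.SubElement(mdl, f"{{{SBML_NS}}}listOfSpecies")
    for s in model.species:
        etree.SubElement(
            los, f"{{{SBML_NS}}}species",
            id=sanitize_id(s.name), name=s.name, compartment="well",
            initialConcentration=repr(float(s.initial)),
        )
    lor = etree.SubElement(mdl, f"{{{SBML_NS}}}listOfReactions")
    for i, r in enumerate(model.reactions):
        rx = etree.SubElement(
            lor, f"{{{SBML_NS}}}reaction",
            id=f"r{i}", name=r.name or f"r{i}",
            reversible="true" if r.reversible else "false",
        )
        lre = etree.SubElement(rx, f"{{{SBML_NS}}}listOfReactants")
        for nm, nu in r.reactants:
            etree.SubElement(lre, f"{{{SBML_NS}}}speciesReference",
                             species=sanitize_id(nm), stoichiometry=str(nu))
        lpr = etree.SubElement(rx, f"{{{SBML_NS}}}listOfProducts")
        for nm, nu in r.products:
            etree.SubElement(lpr, f"{{{SBML_NS}}}speciesReference",
                             species=sanitize_id(nm), stoichiometry=str(nu))
        kl = etree.SubElement(rx, f"{{{SBML_NS}}}kineticLaw")
        math = etree.SubElement(kl, f"{{{MATHML_NS}}}math")
        fwd_factors = ["kf"] + [sanitize_id(nm) for nm, nu in r.reactants for _ in range(nu)]
        if r.reversible:
            ap = etree.SubElement(math, f"{{{MATHML_NS}}}apply")
            etree.SubElement(ap, f"{{{MATHML_NS}}}minus")
            _apply_times(ap, fwd_factors)
            _apply_times(
                ap,
                ["kr"] + [sanitize_id(nm) for nm, nu in r.products for _ in range(nu)],
            )
        else:
            _apply_times(math, fwd_factors)
        lop = etree.SubElement(kl, f"{{{SBML_NS}}}listOfParameters")
        etree.SubElement(lop, f"{{{SBML_NS}}}parameter", id="kf", value=repr(float(r.kf)))
        if r.reversible:
            etree.SubElement(lop, f"{{{SBML_NS}}}parameter", id="kr", value=repr(float(r.kr)))

    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True)

    back = read_sbml(path)
    if back.names != model.names:
        raise AssertionError("SBML round-trip changed the species list")
    if len(back.reactions) != len(model.reactions):
        raise AssertionError("SBML round-trip changed the reaction count")


def read_sbml(path: Union[str, Path]) -> NetworkModel:
    """Parse an SBML L2V4 file written by :func:`write_sbml` back into a
    :class:`NetworkModel` (species names restored from the name attribute)."""
    tree = etree.parse(str(path))
    ns = {"s": SBML_NS}
    id2name: dict[str, str] = {}
    species = []
    for el in tree.findall(".//s:listOfSpecies/s:species", ns):
        name = el.get("name") or el.get("id")
        id2name[el.get("id")] = name
        species.append(Species(name, initial=float(el.get("initialConcentration", 0.0))))
    reactions = []
    for el in tree.findall(".//s:listOfReactions/s:reaction", ns):
        reactants = tuple(
            (id2name[sr.get("species")], int(float(sr.get("stoichiometry", "1"))))
            for sr in el.findall("s:listOfReactants/s:speciesReference", ns)
        )
        products = tuple(
            (id2name[sr.get("species")], int(float(sr.get("stoichiometry", "1"))))
            for sr in el.findall("s:listOfProducts/s:speciesReference", ns)
        )
        pars = {
            p.get("id"): float(p.get("value"))
            for p in el.findall("s:kineticLaw/s:listOfParameters/s:parameter", ns)
        }
        reversible = el.get("reversible", "true") == "true"
        reactions.append(
            ReactionDef(
                reactants, products, pars["kf"],
                pars.get("kr") if reversible else None,
                el.get("name", ""),
            )
        )
    return NetworkModel(species, reactions, provenance={"source": str(path)})
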