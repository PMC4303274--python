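"""SBML Level 3 serialisation of generated reaction networks.

Documents are written directly as SBML Level 3 Version 1 core XML:
one compartment, every enumerated protein species plus calcium and the
free targets, and one reversible reaction per generated rule instance
with a mass-action kinetic law ``kf * reactants - kr * products`` whose
rate ratio equals the reaction's equilibrium constant.  Species carry
the stable identifiers of the enumeration (e.g. ``CaM_RT_A1B0C1D0_tWFF``)
so re-imported documents reproduce the stoichiometry matrix exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lxml import etree

from .network import CA_ID, Reaction, ReactionNetwork

__all__ = ["export_sbml", "import_sbml", "SBMLModel"]

SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"


def _math_mass_action(reaction: Reaction) -> etree._Element:
    math = etree.Element(f"{{{MATHML_NS}}}math")
    minus = etree.SubElement(math, f"{{{MATHML_NS}}}apply")
    etree.SubElement(minus, f"{{{MATHML_NS}}}minus")
    for name, specs in (("kf", reaction.reactants), ("kr", reaction.products)):
        term = etree.SubElement(minus, f"{{{MATHML_NS}}}apply")
        etree.SubElement(term, f"{{{MATHML_NS}}}times")
        ci = etree.SubElement(term, f"{{{MATHML_NS}}}ci")
        ci.text = f" {name} "
        for sp in specs:
            ci = etree.SubElement(term, f"{{{MATHML_NS}}}ci")
            ci.text = f" {sp} "
    return math


def export_sbml(network: ReactionNetwork, path, model_id: str = "hemiconcerted_calmodulin") -> None:
    """Write the network as an SBML Level 3 Version 1 document."""
    sbml = etree.Element(f"{{{SBML_NS}}}sbml", level="3", version="1")
    model = etree.SubElement(sbml, f"{{{SBML_NS}}}model", id=model_id)

    comps = etree.SubElement(model, f"{{{SBML_NS}}}listOfCompartments")
    etree.SubElement(
        comps, f"{{{SBML_NS}}}compartment", id="cell", size="1", constant="true",
        spatialDimensions="3",
    )

    species_el = etree.SubElement(model, f"{{{SBML_NS}}}listOfSpecies")
    for sid in network.species_ids:
        etree.SubElement(
            species_el, f"{{{SBML_NS}}}species", id=sid, compartment="cell",
            initialConcentration="0", hasOnlySubstanceUnits="false",
            boundaryCondition="false", constant="false",
        )
    for lid in network.ligand_ids:
        # calcium is clamped (boundary species) in titration scenarios
        etree.SubElement(
            species_el, f"{{{SBML_NS}}}species", id=lid, compartment="cell",
            initialConcentration="0", hasOnlySubstanceUnits="false",
            boundaryCondition="true" if lid == CA_ID else "false", constant="false",
        )

    reactions_el = etree.SubElement(model, f"{{{SBML_NS}}}listOfReactions")
    for r in network.reactions:
        rel = etree.SubElement(
            reactions_el, f"{{{SBML_NS}}}reaction", id=r.rid, reversible="true",
            fast="false",
        )
        lor = etree.SubElement(rel, f"{{{SBML_NS}}}listOfReactants")
        for sp in r.reactants:
            etree.SubElement(
                lor, f"{{{SBML_NS}}}speciesReference", species=sp,
                stoichiometry="1", constant="true",
            )
        lop = etree.SubElement(rel, f"{{{SBML_NS}}}listOfProducts")
        for sp in r.products:
            etree.SubElement(
                lop, f"{{{SBML_NS}}}speciesReference", species=sp,
                stoichiometry="1", constant="true",
            )
        kl = etree.SubElement(rel, f"{{{SBML_NS}}}kineticLaw")
        kl.append(_math_mass_action(r))
        lolp = etree.SubElement(kl, f"{{{SBML_NS}}}listOfLocalParameters")
        etree.SubElement(lolp, f"{{{SBML_NS}}}localParameter", id="kf", value=repr(r.kf))
        etree.SubElement(lolp, f"{{{SBML_NS}}}localParameter", id="kr", value=repr(r.kr))

    tree = etree.ElementTree(sbml)
    tree.write(str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True)


@dataclass
class SBMLModel:
    """A re-imported SBML document, sufficient for structural checks."""

    model_id: str
    species: list[str]
    reactions: list[tuple[str, tuple[str, ...], tuple[str, ...], float, float]]

    def equilibrium_constants(self) -> dict[str, float]:
        return {rid: kf / kr for rid, _, _, kf, kr in self.reactions}

    def stoichiometry_matrix(self) -> tuple[list[str], list[str], np.ndarray]:
        idx = {s: i for i, s in enumerate(self.species)}
        mat = np.zeros((len(self.species), len(self.reactions)))
        rids = []
        for j, (rid, reac, prod, _, _) in enumerate(self.reactions):
            rids.append(rid)
            for sp in reac:
                mat[idx[sp], j] -= 1
            for sp in prod:
                mat[idx[sp], j] += 1
        return self.species, rids, mat


def import_sbml(path) -> SBMLModel:
    """Parse an exported document back into species/reaction structure."""
    tree = etree.parse(str(path))
    ns = {"s": SBML_NS}
    model = tree.find("s:model", ns)
    if model is None:
        raise ValueError(f"{path}: no SBML model element")
    species = [el.get("id") for el in model.findall(".//s:listOfSpecies/s:species", ns)]
    reactions = []
    for rel in model.findall(".//s:listOfReactions/s:reaction", ns):
        reac = tuple(
            sr.get("species")
            for sr in rel.findall("s:listOfReactants/s:speciesReference", ns)
        )
        prod = tuple(
            sr.get("species")
            for sr in rel.findall("s:listOfProducts/s:speciesReference", ns)
        )
        params = {
            lp.get("id"): float(lp.get("value"))
            for lp in rel.findall(".//s:localParameter", ns)
        }
        reactions.append((rel.get("id"), reac, prod, params["kf"], params["kr"]))
    return SBMLModel(model_id=model.get("id"), species=species, reactions=reactions)
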