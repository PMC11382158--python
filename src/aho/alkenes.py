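"""Perception of candidate C=C bonds and of the alkene actually hydrogenated.

A hydrogenation substrate may carry several non-aromatic C=C bonds; when the
product structure is available, the reacting bond is the one whose saturation
turns the substrate graph into the product graph. Substitution degree (mono-
to tetrasubstituted) is the number of non-hydrogen substituents on the two
alkene carbons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdkit import Chem

DEGREE_LABELS = {
    1: "monosubstituted",
    2: "disubstituted",
    3: "trisubstituted",
    4: "tetrasubstituted",
}


class NoReductionError(ValueError):
    """No candidate C=C of the substrate is saturated in the product."""


@dataclass
class AlkeneSite:
    """A candidate reacting C=C bond.

    ``ambiguous`` flags sites chosen by the documented priority rule because
    the product was absent and several candidates existed.
    """

    atom_a: int
    atom_b: int
    substituent_count: int
    degree_label: str
    neighbor_elements: tuple[str, ...]
    ambiguous: bool = False

    @property
    def atoms(self) -> frozenset[int]:
        return frozenset((self.atom_a, self.atom_b))


def _mol(substrate) -> Chem.Mol:
    if isinstance(substrate, Chem.Mol):
        return substrate
    mol = Chem.MolFromSmiles(substrate)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {substrate!r}")
    return mol


def _site_from_bond(mol: Chem.Mol, bond: Chem.Bond) -> AlkeneSite:
    a, b = bond.GetBeginAtom(), bond.GetEndAtom()
    neighbors = []
    for atom, other in ((a, b), (b, a)):
        for nbr in atom.GetNeighbors():
            if nbr.GetIdx() != other.GetIdx():
                neighbors.append(nbr.GetSymbol())
    count = len(neighbors)
    return AlkeneSite(
        atom_a=a.GetIdx(),
        atom_b=b.GetIdx(),
        substituent_count=count,
        degree_label=DEGREE_LABELS.get(count, "unsubstituted"),
        neighbor_elements=tuple(sorted(neighbors)),
    )


def _is_cumulated(atom: Chem.Atom) -> bool:
    return sum(1 for b in atom.GetBonds()
               if b.GetBondType() == Chem.BondType.DOUBLE) > 1


def find_candidate_alkenes(substrate) -> list[AlkeneSite]:
    """All non-aromatic C=C bonds of the substrate, in canonical-rank order.

    Aromatic bonds, C=O/C=N etc. and allene (cumulated) units are excluded.
    """
    mol = _mol(substrate)
    ranks = list(Chem.CanonicalRankAtoms(mol))
    sites = []
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.DOUBLE or bond.GetIsAromatic():
            continue
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if a.GetSymbol() != "C" or b.GetSymbol() != "C":
            continue
        if a.GetIsAromatic() or b.GetIsAromatic():
            continue
        if _is_cumulated(a) or _is_cumulated(b):
            continue
        sites.append(_site_from_bond(mol, bond))
    sites.sort(key=lambda s: min(ranks[s.atom_a], ranks[s.atom_b]))
    return sites


def substitution_degree(site: AlkeneSite) -> str:
    """Degree label from the substituent count; pure function."""
    return DEGREE_LABELS.get(site.substituent_count, "unsubstituted")


def saturate_site(substrate, site: AlkeneSite) -> str:
    """Canonical SMILES (stereo stripped) of the substrate with the site's
    C=C reduced to a single bond."""
    mol = Chem.RWMol(_mol(substrate))
    bond = mol.GetBondBetweenAtoms(site.atom_a, site.atom_b)
    bond.SetBondType(Chem.BondType.SINGLE)
    bond.SetStereo(Chem.BondStereo.STEREONONE)
    for idx in (site.atom_a, site.atom_b):
        atom = mol.GetAtomWithIdx(idx)
        atom.SetNumExplicitHs(0)
        atom.SetNoImplicit(False)  # mapped/bracket atoms must regain an H
    out = mol.GetMol()
    Chem.SanitizeMol(out)
    Chem.RemoveStereochemistry(out)
    for atom in out.GetAtoms():
        atom.SetAtomMapNum(0)
    return Chem.MolToSmiles(out)


def identify_reacting_alkene(substrate, product=None) -> AlkeneSite:
    """The C=C bond that is hydrogenated.

    With a product: the unique candidate whose saturation reproduces the
    product graph (stereochemistry is ignored in the comparison, since the
    reduction creates new stereocenters). Without a product: a single
    candidate is returned as-is; with several, the site matching the most
    specific functional class wins (tie: lowest canonical rank) and the
    result is flagged ``ambiguous``.
    """
    mol = _mol(substrate)
    sites = find_candidate_alkenes(mol)
    if not sites:
        raise ValueError("substrate has no candidate alkene")

    if product is None:
        if len(sites) == 1:
            return sites[0]
        from .olefins import classify_olefin, CLASS_PRECEDENCE
        ranked = sorted(
            range(len(sites)),
            key=lambda i: CLASS_PRECEDENCE.index(
                classify_olefin(mol, sites[i]).primary_class),
        )
        chosen = sites[ranked[0]]
        chosen.ambiguous = True
        return chosen

    pmol = _mol(product)
    pmol = Chem.Mol(pmol)
    Chem.RemoveStereochemistry(pmol)
    target = Chem.MolToSmiles(pmol)
    matches = [s for s in sites if saturate_site(mol, s) == target]
    if not matches:
        raise NoReductionError(
            "no reduction detected: no candidate C=C is saturated in product")
    return matches[0]
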