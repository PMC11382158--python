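"""Ligand typing: donor atoms, denticity, donor-set label, ferrocene scaffold.

Donor perception covers the donors that matter for asymmetric hydrogenation
ligands: trivalent P (subtyped by its O/N/C neighbor pattern into phosphine,
phosphinite, phosphonite, phosphite, phosphoramidite, aminophosphine), P=O
(phosphine oxide), sp2 nitrogen (oxazoline, pyridine, thiazole, imidazole,
imine), classical NHC carbenes, and - only when they complete a P,S / P,O
chelate - thioether S and ether O. Amide and nitro N are never donors.

Denticity is operational: the largest set of donors pairwise 2-6 bonds apart
through the ligand skeleton is taken as the chelate set. The ferrocene flag
requires the full Fe + two cyclopentadienyl sandwich, not just an Fe atom.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import networkx as nx
from rdkit import Chem

#: donor-separation window (bonds) accepted for a chelate.
CHELATE_WINDOW = (2, 6)

LIGAND_RULEPACK_VERSION = "1.0"

_ELEMENT_ORDER = {"P": 0, "C": 1, "N": 2, "S": 3, "O": 4}  # C = carbene


@dataclass
class DonorAtom:
    atom_index: int
    element: str        # P, N, S, O, or C (NHC carbene)
    subtype: str


@dataclass
class LigandClass:
    denticity: str                  # monodentate/bidentate/tridentate/other
    donor_set_label: str            # e.g. "P,N", "P,P", "N,N,N", "none"
    subtype_label: str              # e.g. "phosphine-oxazoline", "bisphosphine"
    is_ferrocene: bool
    chelate: tuple[DonorAtom, ...]
    all_donors: tuple[DonorAtom, ...]


def _load_patterns() -> dict[str, dict[str, Chem.Mol]]:
    packs: dict[str, dict[str, Chem.Mol]] = {
        "donor": {}, "exclude": {}, "scaffold": {}}
    text = resources.files("aho.rules").joinpath(
        "ligand_rules.smarts").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        role, rule_id, smarts = line.split("\t")
        pattern = Chem.MolFromSmarts(smarts)
        if pattern is None:
            raise ValueError(f"bad SMARTS in ligand rule pack: {rule_id}")
        packs[role][rule_id] = pattern
    return packs


LIGAND_PATTERNS = _load_patterns()


def _match_first_atoms(mol: Chem.Mol, pattern: Chem.Mol) -> set[int]:
    return {m[0] for m in mol.GetSubstructMatches(pattern)}


def _mol(ligand) -> Chem.Mol:
    if isinstance(ligand, Chem.Mol):
        return ligand
    mol = Chem.MolFromSmiles(ligand)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {ligand!r}")
    return mol


# ---------------------------------------------------------------------------
# subtype perception


def _phosphorus_subtype(atom: Chem.Atom) -> str:
    """P subtype from its heteroatom neighbor pattern."""
    if any(b.GetBondType() == Chem.BondType.DOUBLE
           and b.GetOtherAtom(atom).GetSymbol() == "O"
           for b in atom.GetBonds()):
        return "phosphine_oxide"
    n_o = sum(1 for n in atom.GetNeighbors() if n.GetSymbol() == "O")
    n_n = sum(1 for n in atom.GetNeighbors() if n.GetSymbol() == "N")
    if n_o == 2 and n_n == 1:
        return "phosphoramidite"
    if n_o == 3:
        return "phosphite"
    if n_o == 2:
        return "phosphonite"
    if n_o == 1:
        return "phosphinite"
    if n_n >= 1:
        return "aminophosphine"
    return "phosphine"


def _nitrogen_subtype(mol: Chem.Mol, atom: Chem.Atom) -> str:
    ring_info = mol.GetRingInfo()
    idx = atom.GetIdx()
    if atom.GetIsAromatic():
        for ring in ring_info.AtomRings():
            if idx not in ring:
                continue
            symbols = [mol.GetAtomWithIdx(i).GetSymbol() for i in ring]
            if len(ring) == 6:
                return "pyridine"
            if len(ring) == 5 and "S" in symbols:
                return "thiazole"
            if len(ring) == 5 and symbols.count("N") >= 2:
                return "imidazole"
        return "other"
    # C=N nitrogen: oxazoline when the double-bond carbon sits in a
    # 5-ring containing O
    partner = next((b.GetOtherAtom(atom) for b in atom.GetBonds()
                    if b.GetBondType() == Chem.BondType.DOUBLE), None)
    if partner is not None:
        for ring in ring_info.AtomRings():
            if len(ring) == 5 and partner.GetIdx() in ring and idx in ring:
                if any(mol.GetAtomWithIdx(i).GetSymbol() == "O"
                       for i in ring):
                    return "oxazoline"
        return "imine"
    return "other"


# ---------------------------------------------------------------------------
# donor perception


def find_donor_atoms(ligand) -> list[DonorAtom]:
    """Perceive candidate donor atoms of a ligand.

    S/O donors are admitted only when they complete a P,S / P,O chelate:
    a trivalent P within the chelate window that has no N, carbene or second
    P partner of its own.
    """
    mol = _mol(ligand)
    excluded: set[int] = set()
    for pattern in LIGAND_PATTERNS["exclude"].values():
        excluded |= _match_first_atoms(mol, pattern)

    donors: list[DonorAtom] = []
    pat = LIGAND_PATTERNS["donor"]

    for idx in _match_first_atoms(mol, pat["trivalent_P"]):
        donors.append(DonorAtom(idx, "P",
                                _phosphorus_subtype(mol.GetAtomWithIdx(idx))))
    for idx in _match_first_atoms(mol, pat["phosphine_oxide_P"]):
        donors.append(DonorAtom(idx, "P", "phosphine_oxide"))
    n_idx = (_match_first_atoms(mol, pat["imine_N"])
             | _match_first_atoms(mol, pat["aromatic_azine_N"])) - excluded
    for idx in sorted(n_idx):
        donors.append(DonorAtom(idx, "N",
                                _nitrogen_subtype(mol, mol.GetAtomWithIdx(idx))))
    for idx in _match_first_atoms(mol, pat["nhc_carbene_C"]):
        atom = mol.GetAtomWithIdx(idx)
        in_5ring = any(len(r) == 5 for r in mol.GetRingInfo().AtomRings()
                       if idx in r)
        if in_5ring and atom.GetTotalNumHs() == 0:
            donors.append(DonorAtom(idx, "C", "NHC"))

    # conditional S/O donors
    dmat = Chem.GetDistanceMatrix(mol)
    lo, hi = CHELATE_WINDOW
    p_donors = [d for d in donors if d.element == "P"]
    core_non_p = [d for d in donors if d.element in ("N", "C")]

    def lone_p_within_window(idx: int) -> bool:
        for p in p_donors:
            if lo <= dmat[idx][p.atom_index] <= hi:
                partnered = any(
                    lo <= dmat[p.atom_index][q.atom_index] <= hi
                    for q in donors
                    if q.atom_index != p.atom_index and q.element in "PNC")
                if not partnered:
                    return True
        return False

    for rule_id, element, subtype in (("thioether_S", "S", "thioether"),
                                      ("ether_O", "O", "ether")):
        for idx in sorted(_match_first_atoms(mol, pat[rule_id]) - excluded):
            if any(n.GetSymbol() == "P" for n in
                   mol.GetAtomWithIdx(idx).GetNeighbors()):
                continue  # P-O / P-S linkages belong to the P subtype
            if lone_p_within_window(idx):
                donors.append(DonorAtom(idx, element, subtype))

    donors.sort(key=lambda d: d.atom_index)
    return donors


# ---------------------------------------------------------------------------
# chelate assembly and labeling


def _best_chelate(mol: Chem.Mol, donors: list[DonorAtom]
                  ) -> tuple[DonorAtom, ...]:
    if not donors:
        return ()
    dmat = Chem.GetDistanceMatrix(mol)
    lo, hi = CHELATE_WINDOW
    graph = nx.Graph()
    graph.add_nodes_from(range(len(donors)))
    for i, j in itertools.combinations(range(len(donors)), 2):
        d = dmat[donors[i].atom_index][donors[j].atom_index]
        if lo <= d <= hi:
            graph.add_edge(i, j)

    def score(clique: tuple[int, ...]) -> tuple:
        elems = sorted(donors[i].element for i in clique)
        return (
            len(clique),
            1 if ("P" in elems and "N" in elems) else 0,
            1 if elems.count("P") >= 2 else 0,
            [-donors[i].atom_index for i in clique],
        )

    best = max(nx.find_cliques(graph), key=lambda c: score(tuple(c)))
    return tuple(sorted((donors[i] for i in best),
                        key=lambda d: (_ELEMENT_ORDER.get(d.element, 9),
                                       d.atom_index)))


def is_ferrocene_scaffold(ligand) -> bool:
    """True iff an Fe atom plus two cyclopentadienyl (all-carbon, aromatic or
    anionic 5-membered) rings are present."""
    mol = _mol(ligand)
    if not any(a.GetSymbol() == "Fe" for a in mol.GetAtoms()):
        return False
    cp = 0
    for ring in mol.GetRingInfo().AtomRings():
        if len(ring) != 5:
            continue
        atoms = [mol.GetAtomWithIdx(i) for i in ring]
        if not all(a.GetSymbol() == "C" for a in atoms):
            continue
        if all(a.GetIsAromatic() for a in atoms) or \
                any(a.GetFormalCharge() < 0 for a in atoms):
            cp += 1
    return cp >= 2


_DENTICITY = {0: "other", 1: "monodentate", 2: "bidentate", 3: "tridentate"}


def _subtype_label(chelate: tuple[DonorAtom, ...], donor_set: str) -> str:
    if not chelate:
        return "none"
    subs = [d.subtype for d in chelate]
    if len(chelate) == 1:
        return subs[0]
    if donor_set == "P,P":
        if all(s == "phosphine" for s in subs):
            return "bisphosphine"
        return "-".join(sorted(subs))
    if donor_set == "N,N,N" and sorted(subs) == ["imine", "imine", "pyridine"]:
        return "bis(imino)pyridine"
    # canonical order: P/carbene donors first, then N, S, O; sorted within
    # each element group so the label never depends on atom numbering
    ordered = []
    for elem in ("P", "C", "N", "S", "O"):
        ordered.extend(sorted(d.subtype for d in chelate if d.element == elem))
    return "-".join(ordered)


def classify_ligand(ligand) -> LigandClass:
    """Denticity, donor-set and subtype labels, and the ferrocene flag."""
    mol = _mol(ligand)
    donors = find_donor_atoms(mol)
    chelate = _best_chelate(mol, donors)
    donor_set = ",".join("carbene" if d.element == "C" else d.element
                         for d in chelate) or "none"
    return LigandClass(
        denticity=_DENTICITY.get(len(chelate), "other"),
        donor_set_label=donor_set,
        subtype_label=_subtype_label(
            chelate, ",".join(d.element for d in chelate)),
        is_ferrocene=is_ferrocene_scaffold(mol),
        chelate=chelate,
        all_donors=tuple(donors),
    )


def category_label(lc: LigandClass, ferrocene_separate: bool = True) -> str:
    """Reporting category for a classified ligand.

    With ``ferrocene_separate`` (default) ferrocene-based ligands get their
    own "ferrocenyl ..." buckets while retaining the donor-derived subtype.
    """
    sub = lc.subtype_label
    if sub == "NHC":
        sub = "NHC-carbene"
    if lc.is_ferrocene and ferrocene_separate:
        return f"ferrocenyl {sub}"
    return sub


def ligand_type_label(lc: LigandClass, ferrocene_separate: bool = True) -> str:
    """Coarse ligand-type bucket (denticity + donor set), e.g. "bidentate P,N"."""
    base = f"{lc.denticity} {lc.donor_set_label}" \
        if lc.donor_set_label != "none" else "no donor"
    if lc.is_ferrocene and ferrocene_separate:
        return f"ferrocene-based {base}"
    return base


@lru_cache(maxsize=100_000)
def classify_ligand_cached(smiles: str) -> LigandClass:
    return classify_ligand(smiles)
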