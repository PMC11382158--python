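"""Synthetic AHO reaction datasets with known ground truth.

The generator emulates the statistical shape of the literature-mined
hydrogenation dataset the analysis pipeline targets: metal frequencies
heavily skewed toward Rh and Ir with Co a rare newcomer, per-metal mixes of
olefin substitution degree and functional class, per-metal ligand-category
mixes (P,N-dominated for Ir; monodentate P / bisphosphine / ferrocenyl
bisphosphine for Rh; bisphosphine + N,N,N for Co), metal-conditional
solvent / temperature / pressure distributions, and a %ee distribution with
a heavy mode near 100%.

Every record is assembled from class templates: an olefin scaffold whose
planted C=C is saturated to form the product, optionally decorated at a
remote aromatic position from a closed substituent alphabet (Me, Et, Ph,
OMe, F) so the planted class provably survives; a ligand template drawn from
the sampled category; conditions and %ee sampled from the config. The truth
table records every planted label, so full-pipeline label recovery is exact
by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from rdkit import Chem

from .alkenes import find_candidate_alkenes, saturate_site
from .records import ReactionRecord, ConfigError

# ---------------------------------------------------------------------------
# template library

OLEFIN_TEMPLATES: dict[tuple[str, str], list[str]] = {
    ("disubstituted", "aryl_alkyl"): [
        "C=C(C)c1ccccc1",                # alpha-methylstyrene
        "C/C=C/c1ccccc1",                # beta-methylstyrene
    ],
    ("disubstituted", "enol"): [
        "CC(=O)OC(=C)c1ccccc1",          # 1-phenylvinyl acetate
        "COC(C)=C",                      # 2-methoxypropene
    ],
    ("disubstituted", "enamide_enamine"): [
        "CC(=O)NC(=C)c1ccccc1",          # N-(1-phenylvinyl)acetamide
        "COC(=O)C(=C)NC(C)=O",           # methyl 2-acetamidoacrylate
    ],
    ("disubstituted", "allylic_alcohol_ether"): [
        "OCC(=C)c1ccccc1",               # 2-phenylallyl alcohol
        "OC/C=C/c1ccccc1",               # cinnamyl alcohol
    ],
    ("disubstituted", "ab_unsat_carbonyl"): [
        "COC(=O)/C=C/c1ccccc1",          # methyl cinnamate
        "C/C=C/C(=O)O",                  # crotonic acid
    ],
    ("disubstituted", "other_heteroatom"): [
        "C=C(F)c1ccccc1",                # alpha-fluorostyrene
        "C[Si](C)(C)/C=C/c1ccccc1",      # styryl trimethylsilane
    ],
    ("trisubstituted", "aryl_alkyl"): [
        "CC(C)=Cc1ccccc1",               # 2-methyl-1-phenylpropene
        "CC/C(=C\\c1ccccc1)c1ccccc1",    # alpha-ethylstilbene
    ],
    ("trisubstituted", "enol"): [
        "CC(=O)O/C(C)=C/c1ccccc1",       # 1-phenylpropenyl acetate
        "C[Si](C)(C)O/C(=C/C)c1ccccc1",  # propiophenone TMS enol ether
    ],
    ("trisubstituted", "enamide_enamine"): [
        "COC(=O)/C(NC(C)=O)=C/c1ccccc1",  # dehydrophenylalanine ester
        "COC(=O)/C(NC(C)=O)=C/C",         # dehydroamino ester
    ],
    ("trisubstituted", "allylic_alcohol_ether"): [
        "OCC(C)=Cc1ccccc1",              # 2-methyl-3-phenylprop-2-en-1-ol
        "C/C=C(\\C)CO",                  # 2-methyl-2-buten-1-ol
    ],
    ("trisubstituted", "ab_unsat_carbonyl"): [
        "C/C=C(\\C)C(=O)O",              # tiglic acid
        "CC(=Cc1ccccc1)C(=O)O",          # alpha-methylcinnamic acid
    ],
    ("trisubstituted", "other_heteroatom"): [
        "OC(=O)C(F)=Cc1ccccc1",          # alpha-fluorocinnamic acid
        "C[Si](C)(C)C(C)=Cc1ccccc1",     # trisubstituted vinylsilane
    ],
    ("tetrasubstituted", "aryl_alkyl"): [
        "CC(C)=C(C)C",                   # 2,3-dimethyl-2-butene
        "CC(C)=C(C)c1ccccc1",            # 2-methyl-3-phenyl-2-butene
    ],
    ("tetrasubstituted", "enol"): [
        "COC(C)=C(C)c1ccccc1",           # tetrasubstituted enol ether
        "CC(=O)OC(C)=C(C)C",             # tetrasubstituted enol acetate
    ],
    ("tetrasubstituted", "enamide_enamine"): [
        "COC(=O)C(NC(C)=O)=C(C)C",       # beta,beta-dimethyl dehydroamino ester
        "CC(=O)NC(C)=C(C)c1ccccc1",      # tetrasubstituted enamide
    ],
    ("tetrasubstituted", "allylic_alcohol_ether"): [
        "OCC(C)=C(C)C",                  # 2,3-dimethyl-2-buten-1-ol
        "OCC(c1ccccc1)=C(C)C",           # 3-methyl-2-phenyl-2-buten-1-ol
    ],
    ("tetrasubstituted", "ab_unsat_carbonyl"): [
        "CC(C)=C(C)C(=O)O",              # 2,3-dimethyl-2-butenoic acid
        "COC(=O)C(C)=C(C)c1ccccc1",      # tetrasubstituted cinnamate
    ],
    ("tetrasubstituted", "other_heteroatom"): [
        "OC(=O)C(F)=C(C)c1ccccc1",       # alpha-fluoro tetrasubstituted acid
        "CC(F)=C(C)c1ccccc1",            # tetrasubstituted vinyl fluoride
    ],
}

LIGAND_TEMPLATES: dict[str, list[str]] = {
    # Ir-style bidentate P,N
    "phosphine-oxazoline": [
        "CC1COC(=N1)c1ccccc1P(c1ccccc1)c1ccccc1",
        "CC(C)C1COC(=N1)c1ccccc1P(c1ccccc1)c1ccccc1",
    ],
    "phosphinite-oxazoline": [
        "CC1COC(=N1)c1ccccc1OP(c1ccccc1)c1ccccc1",
        "CC(C)C1COC(=N1)c1ccccc1OP(c1ccccc1)c1ccccc1",
    ],
    "phosphite-oxazoline": [
        "CC1COC(=N1)c1ccccc1OP(Oc1ccccc1)Oc1ccccc1",
        "CC(C)C1COC(=N1)c1ccccc1OP(Oc1ccccc1)Oc1ccccc1",
    ],
    "phosphoramidite-oxazoline": [
        "CC1COC(=N1)c1ccccc1N(C)P1OCCO1",
        "CC(C)C1COC(=N1)c1ccccc1N(C)P1OCCO1",
    ],
    "aminophosphine-oxazoline": [
        "CC1COC(=N1)c1ccccc1N(C)P(c1ccccc1)c1ccccc1",
        "CC(C)C1COC(=N1)c1ccccc1N(C)P(c1ccccc1)c1ccccc1",
    ],
    "phosphine-pyridine": [
        "c1ccc(P(c2ccccc2)c2ccccc2)c(-c2ccccn2)c1",
        "Cc1ccc(P(c2ccccc2)c2ccccc2)c(-c2ccccn2)c1",
    ],
    "phosphine-imine": [
        "CC(C)=Nc1ccccc1P(c1ccccc1)c1ccccc1",
        "CC(c1ccccc1)=Nc1ccccc1P(c1ccccc1)c1ccccc1",
    ],
    "NHC-oxazoline": [
        "CC1COC(=N1)c1ccccc1N1C=CN(C)[C]1",
        "CC(C)C1COC(=N1)c1ccccc1N1C=CN(C)[C]1",
    ],
    "phosphine-thioether": [
        "CSc1ccccc1P(c1ccccc1)c1ccccc1",
        "CCSc1ccccc1P(c1ccccc1)c1ccccc1",
    ],
    "phosphine-ether": [
        "COc1ccccc1P(c1ccccc1)c1ccccc1",
        "CCOc1ccccc1P(c1ccccc1)c1ccccc1",
    ],
    # P,P
    "bisphosphine": [
        "C(CP(c1ccccc1)c1ccccc1)P(c1ccccc1)c1ccccc1",        # dppe-type
        "CC(C(C)P(c1ccccc1)c1ccccc1)P(c1ccccc1)c1ccccc1",    # chiraphos-type
    ],
    "phosphine-phosphite": [
        "c1ccccc1P(c1ccccc1)CCOP(Oc1ccccc1)Oc1ccccc1",
        "c1ccccc1P(c1ccccc1)CC(C)OP(Oc1ccccc1)Oc1ccccc1",
    ],
    # monodentate P
    "phosphine": [
        "c1ccc(P(c2ccccc2)c2ccccc2)cc1",
        "C1CCCCC1P(C2CCCCC2)C3CCCCC3",
    ],
    "phosphite": [
        "c1ccc(OP(Oc2ccccc2)Oc3ccccc3)cc1",
        "COP(OC)OC",
    ],
    "phosphoramidite": [
        "CN(C)P1Oc2ccc3ccccc3c2-c2c(O1)ccc1ccccc21",  # MonoPhos-type
        "CN(C)P1OCCO1",
    ],
    "phosphinite": [
        "CCOP(c1ccccc1)c1ccccc1",
        "COP(c1ccccc1)c1ccccc1",
    ],
    "phosphonite": [
        "c1ccccc1P(OC)OC",
        "c1ccccc1P(OCC)OCC",
    ],
    "phosphine_oxide": [
        "CC(C)(C)P(=O)c1ccccc1",  # secondary phosphine oxide
        "CP(=O)c1ccccc1",
    ],
    # ferrocene-based (Josiphos-like: both donors on the substituted ring)
    "ferrocenyl bisphosphine": [
        "CC(P(C1CCCCC1)C1CCCCC1)c1ccc[c-]1P(c1ccccc1)c1ccccc1"
        ".c1cc[cH-]c1.[Fe+2]",
        "CC(P(c1ccccc1)c1ccccc1)c1ccc[c-]1P(C1CCCCC1)C1CCCCC1"
        ".c1cc[cH-]c1.[Fe+2]",
    ],
    "ferrocenyl phosphine-imine": [
        "CC(/N=C(C)C)c1ccc[c-]1P(c1ccccc1)c1ccccc1.c1cc[cH-]c1.[Fe+2]",
        "CC(/N=C(C)c1ccccc1)c1ccc[c-]1P(c1ccccc1)c1ccccc1"
        ".c1cc[cH-]c1.[Fe+2]",
    ],
    # tridentate (Co chemistry)
    "bis(imino)pyridine": [
        "CC(=Nc1ccccc1)c1cccc(C(C)=Nc2ccccc2)n1",
        "CC(=NC(C)C)c1cccc(C(C)=NC(C)C)n1",
    ],
    "phosphine-oxazoline-pyridine": [
        "CC1COC(=N1)c1cccc(CP(c2ccccc2)c2ccccc2)n1",
        "CC(C)C1COC(=N1)c1cccc(CP(c2ccccc2)c2ccccc2)n1",
    ],
}

#: closed substituent alphabet for remote aromatic decoration
SUBSTITUENTS = ("C", "CC", "c1ccccc1", "OC", "F")

PRECATALYST = {
    "Ir": "[Ir(COD)Cl]2",
    "Rh": "[Rh(COD)2]BF4",
    "Co": "Co(acac)2",
    "Ru": "[RuCl2(p-cymene)]2",
}

_DCM_SYNONYMS = ("DCM", "CH2Cl2", "dichloromethane")


def template_library() -> tuple[dict, dict]:
    """The frozen olefin and ligand template maps (copies)."""
    return ({k: list(v) for k, v in OLEFIN_TEMPLATES.items()},
            {k: list(v) for k, v in LIGAND_TEMPLATES.items()})


# ---------------------------------------------------------------------------
# configuration


def _per_metal_conditions() -> dict:
    return {
        "Ir": {
            "solvent": {"dichloromethane": 0.80, "toluene": 0.05,
                        "methanol": 0.05, "tetrahydrofuran": 0.05,
                        "ethanol": 0.05},
            "temperature": {25.0: 0.72, 0.0: 0.05, 40.0: 0.08, 50.0: 0.06,
                            -20.0: 0.05, 60.0: 0.04},
            "pressure": {50.0: 0.35, 49.0: 0.28, 1.0: 0.08, 5.0: 0.07,
                         10.0: 0.12, 20.0: 0.10},
        },
        "Rh": {
            "solvent": {"dichloromethane": 0.42, "methanol": 0.25,
                        "tetrahydrofuran": 0.15, "ethanol": 0.10,
                        "2-propanol": 0.05, "toluene": 0.03},
            "temperature": {25.0: 0.72, 0.0: 0.06, 40.0: 0.08, 50.0: 0.06,
                            -20.0: 0.04, 60.0: 0.04},
            "pressure": {1.0: 0.20, 5.0: 0.20, 10.0: 0.25, 20.0: 0.15,
                         30.0: 0.12, 40.0: 0.08},
        },
        "Co": {
            "solvent": {"toluene": 0.25, "ethanol": 0.20, "methanol": 0.15,
                        "tert-butanol": 0.10, "trifluoroethanol": 0.10,
                        "tetrahydrofuran": 0.10, "hexane": 0.10},
            "temperature": {25.0: 0.30, 50.0: 0.30, 60.0: 0.10, 80.0: 0.10,
                            40.0: 0.10, 70.0: 0.10},
            "pressure": {1.0: 0.15, 5.0: 0.15, 10.0: 0.15, 30.0: 0.15,
                         50.0: 0.25, 68.0: 0.15},
        },
    }


def _default_class_mix() -> dict:
    """Per-metal joint (degree, class) probabilities, mirroring the reported
    qualitative structure: >60% trisubstituted for Ir and Rh, near-even
    di/tri for Co; Ir dominated by aryl/alkyl alkenes, Rh by unsaturated
    carbonyls and enamides, Co mixing both."""
    degree = {
        "Ir": {"disubstituted": 0.30, "trisubstituted": 0.62,
               "tetrasubstituted": 0.08},
        "Rh": {"disubstituted": 0.33, "trisubstituted": 0.61,
               "tetrasubstituted": 0.06},
        "Co": {"disubstituted": 0.46, "trisubstituted": 0.44,
               "tetrasubstituted": 0.10},
    }
    cls = {
        ("Ir", "disubstituted"): {
            "aryl_alkyl": 0.60, "enamide_enamine": 0.12,
            "ab_unsat_carbonyl": 0.15, "other_heteroatom": 0.05,
            "enol": 0.04, "allylic_alcohol_ether": 0.04},
        ("Ir", "trisubstituted"): {
            "aryl_alkyl": 0.35, "ab_unsat_carbonyl": 0.28,
            "enamide_enamine": 0.15, "other_heteroatom": 0.08,
            "allylic_alcohol_ether": 0.09, "enol": 0.05},
        ("Ir", "tetrasubstituted"): {
            "aryl_alkyl": 0.40, "ab_unsat_carbonyl": 0.30,
            "enamide_enamine": 0.10, "other_heteroatom": 0.12,
            "enol": 0.04, "allylic_alcohol_ether": 0.04},
        ("Rh", "disubstituted"): {
            "ab_unsat_carbonyl": 0.52, "enamide_enamine": 0.25,
            "aryl_alkyl": 0.04, "enol": 0.06,
            "allylic_alcohol_ether": 0.05, "other_heteroatom": 0.08},
        ("Rh", "trisubstituted"): {
            "enamide_enamine": 0.45, "ab_unsat_carbonyl": 0.30,
            "aryl_alkyl": 0.05, "enol": 0.05,
            "allylic_alcohol_ether": 0.05, "other_heteroatom": 0.10},
        ("Rh", "tetrasubstituted"): {
            "enamide_enamine": 0.50, "ab_unsat_carbonyl": 0.28,
            "other_heteroatom": 0.12, "aryl_alkyl": 0.04,
            "enol": 0.03, "allylic_alcohol_ether": 0.03},
        ("Co", "disubstituted"): {
            "aryl_alkyl": 0.55, "ab_unsat_carbonyl": 0.20,
            "enamide_enamine": 0.10, "enol": 0.05,
            "allylic_alcohol_ether": 0.05, "other_heteroatom": 0.05},
        ("Co", "trisubstituted"): {
            "aryl_alkyl": 0.30, "enamide_enamine": 0.30,
            "ab_unsat_carbonyl": 0.30, "enol": 0.03,
            "allylic_alcohol_ether": 0.04, "other_heteroatom": 0.03},
        ("Co", "tetrasubstituted"): {
            "ab_unsat_carbonyl": 0.80, "aryl_alkyl": 0.08,
            "enamide_enamine": 0.06, "other_heteroatom": 0.03,
            "enol": 0.015, "allylic_alcohol_ether": 0.015},
    }
    mix = {}
    for metal, degs in degree.items():
        joint = {}
        for deg, pd_ in degs.items():
            for c, pc in cls[(metal, deg)].items():
                joint[(deg, c)] = pd_ * pc
        mix[metal] = joint
    mix["Ru"] = dict(mix["Rh"])
    return mix


def _default_ligand_mix() -> dict:
    ir = {
        "phosphine-oxazoline": 0.25,
        "phosphinite-oxazoline": 0.06,
        "phosphite-oxazoline": 0.05,
        "phosphoramidite-oxazoline": 0.06,
        "aminophosphine-oxazoline": 0.05,
        "phosphine-pyridine": 0.21,
        "phosphine-imine": 0.14,
        "ferrocenyl phosphine-imine": 0.03,   # bidentate P,N share: 0.85
        "NHC-oxazoline": 0.03,
        "phosphine-thioether": 0.02,
        "phosphine-ether": 0.02,
        "phosphine": 0.02,
        "phosphoramidite": 0.01,
        "bisphosphine": 0.03,
        "ferrocenyl bisphosphine": 0.02,
    }
    rh = {
        "phosphoramidite": 0.21,
        "bisphosphine": 0.27,
        "ferrocenyl bisphosphine": 0.23,
        "phosphine": 0.06,
        "phosphite": 0.06,
        "phosphinite": 0.03,
        "phosphonite": 0.02,
        "phosphine_oxide": 0.02,
        "phosphine-phosphite": 0.04,
        "ferrocenyl phosphine-imine": 0.04,
        "phosphine-oxazoline": 0.02,
    }
    co = {
        "bisphosphine": 0.55,
        "ferrocenyl bisphosphine": 0.12,
        "bis(imino)pyridine": 0.28,
        "phosphine-oxazoline-pyridine": 0.03,
        "phosphine": 0.02,
    }
    ru = {"bisphosphine": 0.70, "phosphine": 0.30}
    return {"Ir": ir, "Rh": rh, "Co": co, "Ru": ru}


@dataclass
class SyntheticConfig:
    """Study conditions for the generator; generation is a pure function of
    this object. Defaults mirror the reported dataset structure."""

    seed: int = 0
    n_reactions: int = 1000
    metal_probs: dict = field(default_factory=lambda: {
        "Rh": 0.531, "Ir": 0.379, "Co": 0.01, "Ru": 0.08})
    class_mix: dict = field(default_factory=_default_class_mix)
    ligand_mix: dict = field(default_factory=_default_ligand_mix)
    condition_model: dict = field(default_factory=_per_metal_conditions)
    ee_model: dict = field(default_factory=lambda: {
        "kind": "high_skew_mixture", "p_high": 0.6, "exp_mean": 4.0,
        "uniform_low": 20.0, "uniform_high": 100.0})
    decorate_prob: float = 0.5

    def validate(self) -> None:
        if self.n_reactions < 1:
            raise ConfigError("n_reactions must be >= 1")
        _check_probs("metal_probs", self.metal_probs)
        for metal in self.metal_probs:
            if metal not in self.class_mix:
                raise ConfigError(f"class_mix missing metal {metal}")
            if metal not in self.ligand_mix:
                raise ConfigError(f"ligand_mix missing metal {metal}")
            _check_probs(f"class_mix[{metal}]", self.class_mix[metal])
            _check_probs(f"ligand_mix[{metal}]", self.ligand_mix[metal])
            for cell in self.class_mix[metal]:
                if tuple(cell) not in OLEFIN_TEMPLATES:
                    raise ConfigError(f"unknown olefin cell {cell}")
            for cat in self.ligand_mix[metal]:
                if cat not in LIGAND_TEMPLATES:
                    raise ConfigError(f"unknown ligand category {cat!r}")
            cond = self.condition_model.get(
                metal, self.condition_model.get("Rh"))
            if cond is None:
                raise ConfigError(f"condition_model missing metal {metal}")
            for sub in ("solvent", "temperature", "pressure"):
                _check_probs(f"condition_model[{metal}][{sub}]", cond[sub])


def _check_probs(name: str, probs: dict) -> None:
    if not probs:
        raise ConfigError(f"{name} is empty")
    total = float(sum(probs.values()))
    if abs(total - 1.0) > 1e-6:
        raise ConfigError(f"{name} probabilities sum to {total}, not 1")


# ---------------------------------------------------------------------------
# variant construction (cached across calls: the decorated space is closed)

_VARIANT_CACHE: dict[tuple, tuple[str, str, str]] = {}
_POSITION_CACHE: dict[str, list[int]] = {}


def _decoration_positions(template: str) -> list[int]:
    """Aromatic C-H atoms at least 4 bonds from both alkene carbons."""
    if template in _POSITION_CACHE:
        return _POSITION_CACHE[template]
    mol = Chem.MolFromSmiles(template)
    site = find_candidate_alkenes(mol)[0]
    dmat = Chem.GetDistanceMatrix(mol)
    positions = [
        a.GetIdx() for a in mol.GetAtoms()
        if a.GetIsAromatic() and a.GetSymbol() == "C"
        and a.GetTotalNumHs() >= 1
        and dmat[a.GetIdx()][site.atom_a] >= 4
        and dmat[a.GetIdx()][site.atom_b] >= 4
    ]
    _POSITION_CACHE[template] = positions
    return positions


def _build_variant(template: str, pos: int | None, sub: str | None
                   ) -> tuple[str, str, str]:
    """(substrate, product, mapped substrate) for a decorated template.

    The mapped substrate carries atom maps 1/2 on the planted alkene carbons;
    the product is the substrate with exactly that C=C saturated.
    """
    key = (template, pos, sub)
    if key in _VARIANT_CACHE:
        return _VARIANT_CACHE[key]
    mol = Chem.RWMol(Chem.MolFromSmiles(template))
    if pos is not None:
        frag = Chem.MolFromSmiles(sub)
        offset = mol.GetNumAtoms()
        combined = Chem.RWMol(Chem.CombineMols(mol, frag))
        combined.AddBond(pos, offset, Chem.BondType.SINGLE)
        mol = combined
        Chem.SanitizeMol(mol)
    site = find_candidate_alkenes(mol)[0]
    for idx, mapnum in ((site.atom_a, 1), (site.atom_b, 2)):
        mol.GetAtomWithIdx(idx).SetAtomMapNum(mapnum)
    mapped = Chem.MolToSmiles(mol)
    for atom in mol.GetAtoms():
        atom.SetAtomMapNum(0)
    substrate = Chem.MolToSmiles(mol)
    product = saturate_site(mol, site)
    _VARIANT_CACHE[key] = (substrate, product, mapped)
    return _VARIANT_CACHE[key]


# ---------------------------------------------------------------------------
# sampling


_LIGAND_CANONICAL: dict[str, str] = {}


def _canonical_ligand(smiles: str) -> str:
    if smiles not in _LIGAND_CANONICAL:
        _LIGAND_CANONICAL[smiles] = Chem.MolToSmiles(
            Chem.MolFromSmiles(smiles))
    return _LIGAND_CANONICAL[smiles]


def _categorical(rng: np.random.Generator, probs: dict):
    keys = sorted(probs, key=str)
    p = np.array([probs[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=p / p.sum())]


def _sample_ee(rng: np.random.Generator, model: dict,
               olefin_template: str) -> float:
    kind = model.get("kind", "high_skew_mixture")
    if kind == "high_skew_mixture":
        if rng.random() < model["p_high"]:
            return float(np.clip(100.0 - rng.exponential(model["exp_mean"]),
                                 0.0, 100.0))
        return float(rng.uniform(model["uniform_low"],
                                 model["uniform_high"]))
    if kind == "per_structure":
        mean = model["means"][olefin_template]
        return float(np.clip(rng.normal(mean, model.get("sd", 3.0)),
                             0.0, 100.0))
    raise ConfigError(f"unknown ee model kind: {kind!r}")


def generate(config: SyntheticConfig
             ) -> tuple[list[ReactionRecord], pd.DataFrame]:
    """Sample a reaction dataset plus its per-record truth table."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    records: list[ReactionRecord] = []
    truth_rows: list[dict] = []

    for i in range(config.n_reactions):
        metal = _categorical(rng, config.metal_probs)
        cell = _categorical(rng, config.class_mix[metal])
        degree, olefin_class = cell
        template = OLEFIN_TEMPLATES[(degree, olefin_class)][
            rng.integers(len(OLEFIN_TEMPLATES[(degree, olefin_class)]))]

        pos = sub = None
        positions = _decoration_positions(template)
        if positions and rng.random() < config.decorate_prob:
            pos = positions[rng.integers(len(positions))]
            sub = SUBSTITUENTS[rng.integers(len(SUBSTITUENTS))]
        substrate, product, mapped = _build_variant(template, pos, sub)

        category = _categorical(rng, config.ligand_mix[metal])
        ligand = _canonical_ligand(LIGAND_TEMPLATES[category][
            rng.integers(len(LIGAND_TEMPLATES[category]))])

        cond = config.condition_model.get(
            metal, config.condition_model.get("Rh"))
        solvent = _categorical(rng, cond["solvent"])
        temperature = float(_categorical(rng, cond["temperature"]))
        pressure = float(_categorical(rng, cond["pressure"]))
        ee = round(_sample_ee(rng, config.ee_model, template), 1)

        rid = f"synth-{i:06d}"
        records.append(ReactionRecord(
            record_id=rid,
            substrate=substrate,
            product=product,
            ligand=ligand,
            metal=metal,
            solvent=solvent,
            pressure=pressure,
            temperature=temperature,
            catalyst_loading=1.0,
            ee=ee,
            reference="synthetic",
        ))
        truth_rows.append({
            "record_id": rid,
            "metal": metal,
            "degree_label": degree,
            "olefin_class": olefin_class,
            "ligand_category": category,
            "olefin_template": template,
            "ligand_smiles": ligand,
            "substrate_mapped": mapped,
            "decoration": f"{pos}:{sub}" if pos is not None else "",
        })

    return records, pd.DataFrame(truth_rows)


def raw_frame(records: list[ReactionRecord],
              seed: int = 0) -> pd.DataFrame:
    """Re-style normalized records as a raw literature-like table: catalyst
    precatalyst strings, solvent synonyms, "rt" temperatures, pressures with
    units - input for exercising the ingest/normalization path."""
    rng = np.random.default_rng(seed)
    rows = []
    for r in records:
        solvent = r.solvent
        if solvent == "dichloromethane":
            solvent = _DCM_SYNONYMS[rng.integers(len(_DCM_SYNONYMS))]
        temperature = r.temperature
        if temperature == 25.0 and rng.random() < 0.5:
            temperature = "rt"
        rows.append({
            "record_id": r.record_id,
            "substrate": r.substrate,
            "product": r.product,
            "ligand": r.ligand,
            "catalyst": PRECATALYST.get(r.metal, r.metal),
            "solvent": solvent,
            "pressure": f"{r.pressure:g} atm",
            "temperature": temperature,
            "catalyst_loading": r.catalyst_loading,
            "ee": r.ee,
            "reference": r.reference,
        })
    return pd.DataFrame(rows)
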