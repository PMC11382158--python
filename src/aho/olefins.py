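"""Functional classification of the reacting alkene.

Six classes, evaluated only relative to the perceived reacting C=C:

* ``enamide_enamine`` - N on a vinylic carbon (enamide when acylated)
* ``enol`` - O on a vinylic carbon (ester/carbamate/phosphinate/phosphonate/
  silyl/ether subtypes by the group on that O)
* ``ab_unsat_carbonyl`` - vinylic carbon conjugated to a carbonyl
* ``other_heteroatom`` - any non-C/H/O/N atom (P, B, F, Si, halogens...) on a
  vinylic carbon
* ``allylic_alcohol_ether`` - O on an sp3 carbon adjacent to the alkene
* ``aryl_alkyl`` - only C/H at the vinylic positions; also the fallback

A molecule may match several classes (dehydroamino esters are both enamide
and conjugated ester); the primary class follows a fixed precedence chosen so
that dehydroamino-acid derivatives count as enamides.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

from rdkit import Chem

from .alkenes import AlkeneSite

OLEFIN_CLASSES = (
    "aryl_alkyl",
    "enol",
    "enamide_enamine",
    "allylic_alcohol_ether",
    "ab_unsat_carbonyl",
    "other_heteroatom",
)

#: Primary-class precedence, most specific first. A vinylic heteroatom other
#: than O/N outranks carbonyl conjugation so that e.g. alpha-fluoro acrylates
#: report as heteroatom-bearing alkenes rather than plain unsaturated esters.
CLASS_PRECEDENCE = (
    "enamide_enamine",
    "enol",
    "other_heteroatom",
    "ab_unsat_carbonyl",
    "allylic_alcohol_ether",
    "aryl_alkyl",
)


@dataclass
class OlefinRule:
    olefin_class: str
    rule_id: str
    smarts: str
    pattern: Chem.Mol


@dataclass
class OlefinClassification:
    degree_label: str
    class_set: frozenset[str]
    primary_class: str
    rule_hits: tuple[str, ...]


def _load_rules() -> tuple[OlefinRule, ...]:
    rules = []
    text = resources.files("aho.rules").joinpath(
        "olefin_rules.smarts").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cls, rule_id, smarts = line.split("\t")
        pattern = Chem.MolFromSmarts(smarts)
        if pattern is None:
            raise ValueError(f"bad SMARTS in olefin rule pack: {rule_id}")
        rules.append(OlefinRule(cls, rule_id, smarts, pattern))
    return tuple(rules)


OLEFIN_RULES = _load_rules()
OLEFIN_RULEPACK_VERSION = "1.0"


def _mapped_indices(pattern: Chem.Mol) -> tuple[int, int]:
    """Query-atom positions carrying atom maps :1 and :2 (the vinylic pair)."""
    pos = {}
    for atom in pattern.GetAtoms():
        if atom.GetAtomMapNum() in (1, 2):
            pos[atom.GetAtomMapNum()] = atom.GetIdx()
    return pos[1], pos[2]


def _site_matches(mol: Chem.Mol, site: AlkeneSite, rule: OlefinRule
                  ) -> list[tuple[int, ...]]:
    """Substructure matches of the rule anchored at the site's carbons."""
    i1, i2 = _mapped_indices(rule.pattern)
    out = []
    for match in mol.GetSubstructMatches(rule.pattern, uniquify=False):
        if {match[i1], match[i2]} == set(site.atoms):
            out.append(match)
    return out


def classify_olefin(substrate, site: AlkeneSite) -> OlefinClassification:
    """Multi-label functional classification of the reacting alkene."""
    mol = substrate if isinstance(substrate, Chem.Mol) \
        else Chem.MolFromSmiles(substrate)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {substrate!r}")

    hits: list[str] = []
    classes: set[str] = set()
    for rule in OLEFIN_RULES:
        matches = _site_matches(mol, site, rule)
        if rule.olefin_class == "allylic_alcohol_ether":
            # the allylic O must not itself sit on a vinylic carbon of the
            # site (then the enol rules already own it)
            i1, i2 = _mapped_indices(rule.pattern)
            o_idx = rule.pattern.GetNumAtoms() - 1
            kept = []
            for match in matches:
                o_atom = mol.GetAtomWithIdx(match[o_idx])
                if not any(n.GetIdx() in site.atoms
                           for n in o_atom.GetNeighbors()):
                    kept.append(match)
            matches = kept
        if matches:
            classes.add(rule.olefin_class)
            hits.append(rule.rule_id)

    if not classes:
        classes = {"aryl_alkyl"}
        hits.append("aryl_alkyl_fallback")
    primary = next(c for c in CLASS_PRECEDENCE if c in classes)
    return OlefinClassification(
        degree_label=site.degree_label,
        class_set=frozenset(classes),
        primary_class=primary,
        rule_hits=tuple(hits),
    )


@lru_cache(maxsize=100_000)
def classify_substrate(substrate: str, product: str | None = None
                       ) -> OlefinClassification:
    """Perceive the reacting alkene of a substrate (using the product when
    available) and classify it. Cached on the SMILES pair."""
    from .alkenes import identify_reacting_alkene
    site = identify_reacting_alkene(substrate, product)
    return classify_olefin(substrate, site)
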