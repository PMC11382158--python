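"""Reaction-record I/O: reading, validating and normalizing AHO reaction tables.

One row of a literature-mined asymmetric-hydrogenation dataset becomes a
:class:`ReactionRecord`: SMILES for substrate / product / ligand, the catalyst
metal, normalized solvent and condition values, and the reaction outcomes
(%ee, yield, conversion). Rows that fail validation are quarantined with a
machine-readable reason, never silently dropped.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, fields, asdict
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

log = logging.getLogger("aho.records")

#: d-block element symbols accepted as catalyst metals.
TRANSITION_METALS = frozenset(
    "Sc Ti V Cr Mn Fe Co Ni Cu Zn "
    "Y Zr Nb Mo Tc Ru Rh Pd Ag Cd "
    "La Hf Ta W Re Os Ir Pt Au Hg".split()
)

# Unit factors to atmospheres.
_ATM_PER_BAR = 0.98692
_ATM_PER_PSI = 0.068046

_ROOM_TEMPERATURE_C = 25.0
_RT_ALIASES = {"rt", "r.t.", "r.t", "room temperature", "room temp", "ambient"}

#: Canonical ReactionRecord field names recognized in input tables.
RECORD_FIELDS = (
    "record_id", "substrate", "product", "ligand", "metal", "solvent",
    "additive", "pressure", "temperature", "catalyst_loading",
    "ee", "yield_pct", "conversion_pct", "reference",
)

_MANDATORY = ("substrate", "ligand")


class ConfigError(ValueError):
    """Raised for malformed schema / configuration input."""


class AmbiguousMetalError(ValueError):
    """Catalyst field contains zero or more than one distinct transition metal."""


@dataclass
class ReactionRecord:
    """A single literature AHO reaction.

    %ee is stored as a magnitude in [0, 100]; the enantiomer sign is out of
    scope. Pressure is in atm, temperature in Celsius, catalyst loading in
    mol%.
    """

    record_id: str
    substrate: str
    ligand: str
    metal: str
    product: str | None = None
    solvent: str | None = None
    additive: str | None = None
    pressure: float | None = None
    temperature: float | None = None
    catalyst_loading: float | None = None
    ee: float | None = None
    yield_pct: float | None = None
    conversion_pct: float | None = None
    reference: str | None = None


@dataclass
class QuarantineEntry:
    row_index: int
    record_id: str
    reason: str


@dataclass
class IngestReport:
    records: list[ReactionRecord]
    quarantine: list[QuarantineEntry]

    @property
    def n_in(self) -> int:
        return len(self.records) + len(self.quarantine)


# ---------------------------------------------------------------------------
# structure handling


def canonical_structure(smiles: str, stereo: bool = True) -> str:
    """Canonical SMILES for deduplication; invariant to atom order.

    With ``stereo=False`` stereodescriptors are stripped first, so E/Z pairs
    and enantiomers collapse onto one string.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    if not stereo:
        Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


def strip_counterions(smiles: str) -> str:
    """Keep the largest organic fragment of a multi-fragment SMILES.

    Ferrocene-containing ligands are the exception: the whole fragment set is
    retained, because the Fe(cp)2 sandwich is usually written as separate
    fragments and classification must see it.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    if any(a.GetSymbol() == "Fe" for a in mol.GetAtoms()):
        return Chem.MolToSmiles(mol)
    frags = Chem.GetMolFrags(mol, asMols=True)
    if len(frags) == 1:
        return Chem.MolToSmiles(mol)

    def key(f: Chem.Mol) -> tuple:
        n_c = sum(1 for a in f.GetAtoms() if a.GetSymbol() == "C")
        return (n_c, f.GetNumHeavyAtoms(), Chem.MolToSmiles(f))

    return Chem.MolToSmiles(max(frags, key=key))


_SYMBOL_RE = re.compile(r"[A-Z][a-z]?")


def extract_metal(catalyst_field: str) -> str:
    """Extract the single transition-metal element symbol from a catalyst
    string (bare symbol, precatalyst name like "[Ir(COD)Cl]2", or SMILES).

    Raises :class:`AmbiguousMetalError` when zero or >=2 distinct transition
    metals occur.
    """
    found = {
        tok for tok in _SYMBOL_RE.findall(catalyst_field or "")
        if tok in TRANSITION_METALS
    }
    if len(found) != 1:
        raise AmbiguousMetalError(
            f"ambiguous metal: found {sorted(found)} in {catalyst_field!r}"
        )
    return found.pop()


# ---------------------------------------------------------------------------
# condition normalization


def _load_solvent_table() -> dict[str, str]:
    with resources.files("aho.data").joinpath("solvents.yaml").open() as fh:
        table = yaml.safe_load(fh)
    lookup: dict[str, str] = {}
    for canonical, synonyms in table.items():
        lookup[canonical.strip().lower()] = canonical
        for syn in synonyms:
            lookup[str(syn).strip().lower()] = canonical
    return lookup


_SOLVENT_LOOKUP = _load_solvent_table()


def normalize_solvent(value: str | None) -> str | None:
    """Map solvent synonyms/abbreviations/SMILES to one canonical label.

    Unknown solvents pass through stripped but otherwise unchanged.
    """
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    text = str(value).strip()
    if not text:
        return None
    return _SOLVENT_LOOKUP.get(text.lower(), text)


def normalize_temperature(value) -> float | None:
    """Temperature to Celsius; "rt"-style strings normalize to 25 C."""
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    if isinstance(value, (int, float)):
        return float(value)
    text = str(value).strip().lower()
    if not text:
        return None
    if text in _RT_ALIASES:
        return _ROOM_TEMPERATURE_C
    text = text.removesuffix("°c").removesuffix("c").strip()
    return float(text)


def normalize_pressure(value) -> float | None:
    """Pressure to atm; accepts bare numbers (atm) or "<x> atm|bar|psi"."""
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    if isinstance(value, (int, float)):
        return float(value)
    text = str(value).strip().lower()
    if not text:
        return None
    m = re.fullmatch(r"([0-9.+-eE]+)\s*(atm|bar|psi)?", text)
    if m is None:
        raise ValueError(f"unparseable pressure: {value!r}")
    num = float(m.group(1))
    unit = m.group(2) or "atm"
    factor = {"atm": 1.0, "bar": _ATM_PER_BAR, "psi": _ATM_PER_PSI}[unit]
    return num * factor


# ---------------------------------------------------------------------------
# dataset reading / writing


def _load_schema(schema) -> dict[str, str]:
    """Schema maps canonical field -> source column name. Accepts a mapping,
    a YAML path, or None (identity)."""
    if schema is None:
        return {f: f for f in RECORD_FIELDS} | {"catalyst": "catalyst"}
    if isinstance(schema, (str, Path)):
        with open(schema) as fh:
            schema = yaml.safe_load(fh)
    if not isinstance(schema, Mapping):
        raise ConfigError("schema must be a mapping of field -> column")
    unknown = set(schema) - set(RECORD_FIELDS) - {"catalyst"}
    if unknown:
        raise ConfigError(f"unknown schema fields: {sorted(unknown)}")
    return dict(schema)


def _get(row, col):
    if col is None or col not in row or pd.isna(row[col]):
        return None
    val = row[col]
    return val.strip() if isinstance(val, str) else val


def _validate_pct(name: str, value) -> float | None:
    if value is None:
        return None
    val = float(value)
    if not 0.0 <= val <= 100.0:
        raise ValueError(f"{name} out of range")
    return val


def row_to_record(row: Mapping, colmap: Mapping[str, str], row_index: int
                  ) -> ReactionRecord:
    """Validate and normalize one raw table row (raises on violation)."""
    substrate = _get(row, colmap.get("substrate"))
    ligand = _get(row, colmap.get("ligand"))
    if substrate is None:
        raise ValueError("missing substrate")
    if ligand is None:
        raise ValueError("missing ligand")
    if Chem.MolFromSmiles(substrate) is None:
        raise ValueError("unparseable substrate")
    if Chem.MolFromSmiles(ligand) is None:
        raise ValueError("unparseable ligand")
    substrate = strip_counterions(substrate)
    ligand = strip_counterions(ligand)

    metal = _get(row, colmap.get("metal"))
    if metal is not None and metal in TRANSITION_METALS:
        metal = str(metal)
    else:
        catalyst = _get(row, colmap.get("catalyst")) or metal
        if catalyst is None:
            raise ValueError("missing metal")
        metal = extract_metal(str(catalyst))

    product = _get(row, colmap.get("product"))
    if product is not None:
        if Chem.MolFromSmiles(product) is None:
            raise ValueError("unparseable product")
        product = canonical_structure(product)

    pressure = normalize_pressure(_get(row, colmap.get("pressure")))
    if pressure is not None and pressure <= 0:
        raise ValueError("pressure not positive")
    temperature = normalize_temperature(_get(row, colmap.get("temperature")))
    if temperature is not None and not -100.0 <= temperature <= 200.0:
        raise ValueError("temperature out of range")
    loading = _get(row, colmap.get("catalyst_loading"))
    if loading is not None:
        loading = float(loading)
        if loading <= 0:
            raise ValueError("catalyst loading not positive")

    ee = _validate_pct("ee", _get(row, colmap.get("ee")))
    if ee is not None:
        ee = abs(ee)  # magnitude only; sign conventions vary by source
    yield_pct = _validate_pct("yield", _get(row, colmap.get("yield_pct")))
    conversion = _validate_pct(
        "conversion", _get(row, colmap.get("conversion_pct")))

    record_id = _get(row, colmap.get("record_id"))
    return ReactionRecord(
        record_id=str(record_id) if record_id is not None else f"row{row_index}",
        substrate=substrate,
        ligand=ligand,
        metal=metal,
        product=product,
        solvent=normalize_solvent(_get(row, colmap.get("solvent"))),
        additive=_get(row, colmap.get("additive")),
        pressure=pressure,
        temperature=temperature,
        catalyst_loading=loading,
        ee=ee,
        yield_pct=yield_pct,
        conversion_pct=conversion,
        reference=_get(row, colmap.get("reference")),
    )


def read_dataset(path, schema=None) -> IngestReport:
    """Read a CSV/TSV reaction table into validated records + quarantine.

    ``schema`` maps canonical field names to source column names (mapping or
    YAML file); by default columns are expected under their canonical names.
    Missing mandatory columns raise :class:`ConfigError`; per-row violations
    are quarantined with a reason.
    """
    colmap = _load_schema(schema)
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [
        f for f in _MANDATORY
        if colmap.get(f) not in df.columns
    ]
    if missing:
        raise ConfigError(f"missing mandatory columns: {missing}")
    if colmap.get("metal") not in df.columns and \
            colmap.get("catalyst") not in df.columns:
        raise ConfigError("missing mandatory columns: ['metal']")

    records: list[ReactionRecord] = []
    quarantine: list[QuarantineEntry] = []
    for idx, row in enumerate(df.to_dict(orient="records")):
        rid = _get(row, colmap.get("record_id")) or f"row{idx}"
        try:
            records.append(row_to_record(row, colmap, idx))
        except (ValueError, AmbiguousMetalError) as exc:
            reason = str(exc)
            if reason.startswith("ambiguous metal"):
                reason = "ambiguous metal"
            quarantine.append(QuarantineEntry(idx, str(rid), reason))
    log.info("read %d rows: %d records, %d quarantined",
             len(df), len(records), len(quarantine))
    return IngestReport(records=records, quarantine=quarantine)


def records_to_frame(records: Iterable[ReactionRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records],
                        columns=[f.name for f in fields(ReactionRecord)])


def write_dataset(records: Sequence[ReactionRecord], path) -> None:
    """Write normalized records as CSV (lossless read->write->read)."""
    records_to_frame(records).to_csv(path, index=False)


def write_quarantine(entries: Sequence[QuarantineEntry], path) -> None:
    pd.DataFrame([asdict(q) for q in entries],
                 columns=["row_index", "record_id", "reason"]
                 ).to_csv(path, index=False)


def dataset_summary(records: Sequence[ReactionRecord],
                    stereo_distinct: bool = True) -> dict:
    """Headline counts: reactions, distinct olefins/ligands, per-metal splits.

    ``stereo_distinct`` controls whether stereoisomers count as distinct
    structures (default: they do).
    """
    olefins = {canonical_structure(r.substrate, stereo=stereo_distinct)
               for r in records}
    ligands = {canonical_structure(r.ligand, stereo=stereo_distinct)
               for r in records}
    per_metal: dict[str, dict] = {}
    n = len(records)
    for metal in sorted({r.metal for r in records}):
        sub = [r for r in records if r.metal == metal]
        per_metal[metal] = {
            "n_reactions": len(sub),
            "n_olefins": len({canonical_structure(
                r.substrate, stereo=stereo_distinct) for r in sub}),
            "n_ligands": len({canonical_structure(
                r.ligand, stereo=stereo_distinct) for r in sub}),
            "share_pct": 100.0 * len(sub) / n if n else 0.0,
        }
    return {
        "n_reactions": n,
        "n_distinct_olefins": len(olefins),
        "n_distinct_ligands": len(ligands),
        "per_metal": per_metal,
    }
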