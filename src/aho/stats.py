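"""Distributions, median-selectivity summaries, top-N lists and the
olefin-ligand combination matrices.

All reports operate on the classified reaction table (a DataFrame produced by
:func:`aho.pipeline.classify_records`) and are invariant to row order. Medians
are exact sample medians (mean of the middle two for even n).
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import ConfigError

#: default %ee regime edges (right-closed bins); an unstated choice of the
#: source analysis, exposed rather than hardcoded downstream.
DEFAULT_EE_EDGES = (70.0, 80.0, 90.0, 95.0, 99.0)

#: classified-table columns usable as a grouping key
CATEGORY_KEYS = {
    "metal": "metal",
    "degree": "degree_label",
    "olefin_class": "primary_olefin_class",
    "ligand_class": "ligand_category",
    "ligand_type": "ligand_type",
    "solvent": "solvent",
    "temperature": "temperature",
    "pressure": "pressure",
}


@dataclass
class DistributionReport:
    key: str
    labels: list
    counts: list[int]
    fractions: list[float]
    n_excluded: int = 0
    metal: str | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "category": self.labels,
            "count": self.counts,
            "fraction": self.fractions,
        })
        if self.metal is not None:
            df.insert(0, "metal", self.metal)
        return df


@dataclass
class CombinationCell:
    metal: str
    degree_label: str
    primary_olefin_class: str
    ligand_category: str
    n_reactions: int
    median_ee: float | None


def _bin_labels(edges: tuple[float, ...]) -> list[str]:
    labels = [f"<={edges[0]:g}"]
    labels += [f"{lo:g}-{hi:g}" for lo, hi in zip(edges, edges[1:])]
    labels.append(f">{edges[-1]:g}")
    return labels


def ee_regime_distribution(df: pd.DataFrame,
                           bin_edges=DEFAULT_EE_EDGES) -> DistributionReport:
    """Reaction counts per %ee regime (right-closed bins).

    Records without an ee value are excluded and counted in ``n_excluded``.
    """
    edges = tuple(float(e) for e in bin_edges)
    if list(edges) != sorted(set(edges)) or not all(0 <= e <= 100 for e in edges):
        raise ConfigError("bin edges must be strictly increasing within [0,100]")
    ee = pd.to_numeric(df.get("ee", pd.Series(dtype=float)), errors="coerce")
    values = ee.dropna().to_numpy()
    n_excluded = len(df) - len(values)
    # right-closed: value v falls in bin i with edges[i-1] < v <= edges[i]
    idx = np.searchsorted(np.asarray(edges), values, side="left")
    counts = np.bincount(idx, minlength=len(edges) + 1)
    total = counts.sum()
    fractions = (counts / total) if total else np.zeros_like(counts, float)
    return DistributionReport(
        key="ee_regime",
        labels=_bin_labels(edges),
        counts=counts.tolist(),
        fractions=fractions.tolist(),
        n_excluded=n_excluded,
    )


def category_distribution(df: pd.DataFrame, key: str, per_metal: bool = False,
                          top_n: int | None = None
                          ) -> DistributionReport | list[DistributionReport]:
    """Counts/fractions per category of ``key``; optionally split per metal
    and truncated to the top-N categories with an "other" remainder."""
    if key not in CATEGORY_KEYS:
        raise ConfigError(f"unknown distribution key: {key!r}")
    col = CATEGORY_KEYS[key]
    if col not in df.columns:
        raise ConfigError(f"column {col!r} missing from classified table")

    if per_metal:
        return [
            _single_distribution(sub, key, col, top_n, metal=metal)
            for metal, sub in sorted(df.groupby("metal"), key=lambda kv: kv[0])
        ]
    return _single_distribution(df, key, col, top_n)


def _single_distribution(df: pd.DataFrame, key: str, col: str,
                         top_n: int | None, metal: str | None = None
                         ) -> DistributionReport:
    series = df[col].dropna()
    n_excluded = len(df) - len(series)
    counts = series.value_counts()
    # deterministic label order: count desc, then label
    items = sorted(counts.items(), key=lambda kv: (-kv[1], str(kv[0])))
    if top_n is not None:
        if top_n <= 0:
            raise ConfigError("top_n must be positive")
        head, tail = items[:top_n], items[top_n:]
        if tail:
            head = head + [("other", sum(c for _, c in tail))]
        items = head
    labels = [k for k, _ in items]
    cnt = [int(c) for _, c in items]
    total = sum(cnt)
    return DistributionReport(
        key=key,
        labels=labels,
        counts=cnt,
        fractions=[c / total for c in cnt] if total else [],
        n_excluded=n_excluded,
        metal=metal,
    )


def exact_median(values) -> float | None:
    vals = [float(v) for v in values if v is not None and not pd.isna(v)]
    return statistics.median(vals) if vals else None


def combination_matrix(df: pd.DataFrame, metal: str) -> list[CombinationCell]:
    """One cell per observed (degree, olefin class, ligand category) for a
    metal: reaction count and exact median %ee. Unobserved combinations are
    absent."""
    sub = df[df["metal"] == metal]
    cells = []
    grouped = sub.groupby(
        ["degree_label", "primary_olefin_class", "ligand_category"],
        sort=True, dropna=False)
    for (deg, ocls, lcat), grp in grouped:
        cells.append(CombinationCell(
            metal=metal,
            degree_label=deg,
            primary_olefin_class=ocls,
            ligand_category=lcat,
            n_reactions=len(grp),
            median_ee=exact_median(grp["ee"]),
        ))
    return cells


def combinations_to_frame(cells: list[CombinationCell]) -> pd.DataFrame:
    return pd.DataFrame([{
        "metal": c.metal,
        "degree": c.degree_label,
        "olefin_class": c.primary_olefin_class,
        "ligand_category": c.ligand_category,
        "n_reactions": c.n_reactions,
        "median_ee": c.median_ee,
    } for c in cells])


def median_ee_by_ligand(df: pd.DataFrame, metal: str) -> pd.DataFrame:
    """Median %ee per ligand category for one metal (ligand-type labels of
    the per-metal ligand charts)."""
    sub = df[df["metal"] == metal]
    rows = [
        {"metal": metal, "ligand_category": cat,
         "n_reactions": len(grp), "median_ee": exact_median(grp["ee"])}
        for cat, grp in sub.groupby("ligand_category", sort=True)
    ]
    return pd.DataFrame(rows)


def top_n(df: pd.DataFrame, key: str, n: int) -> list[tuple[str, int]]:
    """Most frequent distinct structures (``key`` in {"olefin", "ligand"}).

    Ties are broken by lexicographic order of the canonical SMILES so the
    ranking is deterministic.
    """
    if n <= 0:
        raise ConfigError("n must be positive")
    col = {"olefin": "substrate_canonical", "ligand": "ligand_canonical"}.get(key)
    if col is None:
        raise ConfigError(f"unknown top_n key: {key!r}")
    counts = df[col].value_counts()
    items = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(smi, int(c)) for smi, c in items[:n]]
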