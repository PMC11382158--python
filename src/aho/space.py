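"""Chemical-space tooling: MACCS structural keys, 2-D nonlinear embeddings,
cross-metal overlap sets, and per-structure mean-%ee coloring.

Structures are always deduplicated (by canonical SMILES) before embedding;
the embedding is a pure function of (distinct fingerprints, method, seed).
Coordinates are qualitative: hyperparameters are exposed, not tuned to any
published picture.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import MACCSkeys

N_MACCS_BITS = 166


@dataclass
class EmbeddingPoint:
    structure_id: str
    x: float
    y: float
    group: str | None = None
    mean_ee: float | None = None


def fingerprint(structure: str) -> np.ndarray:
    """166-bit MACCS structural-key vector (uint8), atom-order invariant."""
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {structure!r}")
    keys = MACCSkeys.GenMACCSKeys(mol)  # 167 bits; bit 0 is unused padding
    arr = np.zeros(N_MACCS_BITS, dtype=np.uint8)
    for bit in keys.GetOnBits():
        if bit >= 1:
            arr[bit - 1] = 1
    return arr


def fingerprint_matrix(structures) -> tuple[list[str], np.ndarray]:
    """Deduplicated structure ids (first-seen order) and their stacked
    fingerprints."""
    seen: dict[str, None] = {}
    for s in structures:
        seen.setdefault(s)
    ids = list(seen)
    mat = np.stack([fingerprint(s) for s in ids]) if ids else \
        np.empty((0, N_MACCS_BITS), dtype=np.uint8)
    return ids, mat


def embed(structures, method: str = "umap", seed: int = 0,
          n_neighbors: int = 15, min_dist: float = 0.1,
          perplexity: float = 30.0, groups=None) -> list[EmbeddingPoint]:
    """2-D embedding of deduplicated structures.

    ``method`` is "umap" or "tsne"; both emit the same schema and are
    reproducible for a fixed seed. ``groups`` optionally maps structure id ->
    group label carried through to the output.
    """
    ids, mat = fingerprint_matrix(structures)
    n = len(ids)
    if n < 3:
        raise ValueError("insufficient points: need >= 3 distinct structures")
    x = mat.astype(np.float32)
    if method == "umap":
        import umap

        reducer = umap.UMAP(
            n_components=2,
            n_neighbors=min(n_neighbors, n - 1),
            min_dist=min_dist,
            random_state=seed,
            n_jobs=1,
        )
        coords = reducer.fit_transform(x)
    elif method == "tsne":
        from sklearn.manifold import TSNE

        coords = TSNE(
            n_components=2,
            perplexity=min(perplexity, max(1.0, (n - 1) / 3)),
            random_state=seed,
            init="pca",
        ).fit_transform(x)
    else:
        raise ValueError(f"unknown embedding method: {method!r}")

    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise RuntimeError("embedding produced non-finite coordinates")
    groups = groups or {}
    return [
        EmbeddingPoint(structure_id=sid, x=float(cx), y=float(cy),
                       group=groups.get(sid))
        for sid, (cx, cy) in zip(ids, coords)
    ]


def embedding_to_frame(points: list[EmbeddingPoint]) -> pd.DataFrame:
    return pd.DataFrame([{
        "structure_id": p.structure_id, "x": p.x, "y": p.y,
        "group": p.group, "mean_ee": p.mean_ee,
    } for p in points])


def metal_groups(structures_by_metal: dict[str, set]) -> dict[str, str]:
    """Group label per structure: its metal, or "shared:<m1+m2...>" when it
    occurs with several metals."""
    labels: dict[str, str] = {}
    owners: dict[str, list[str]] = {}
    for metal in sorted(structures_by_metal):
        for s in structures_by_metal[metal]:
            owners.setdefault(s, []).append(metal)
    for s, metals in owners.items():
        labels[s] = metals[0] if len(metals) == 1 else \
            "shared:" + "+".join(metals)
    return labels


def overlap_sets(structures_by_metal: dict[str, set]) -> dict[tuple, set]:
    """All pairwise and higher-order intersections of per-metal structure
    sets, keyed by the sorted metal tuple."""
    out: dict[tuple, set] = {}
    metals = sorted(structures_by_metal)
    for r in range(2, len(metals) + 1):
        for combo in itertools.combinations(metals, r):
            inter = set.intersection(
                *(set(structures_by_metal[m]) for m in combo))
            out[combo] = inter
    return out


def overlaps_to_frame(overlaps: dict[tuple, set]) -> pd.DataFrame:
    return pd.DataFrame([
        {"metals": "+".join(combo), "n_common": len(s)}
        for combo, s in sorted(overlaps.items())
    ])


def color_by_mean_ee(df: pd.DataFrame, column: str = "substrate_canonical"
                     ) -> tuple[dict[str, float], int]:
    """Arithmetic mean %ee per distinct structure over all its reactions.

    Returns (structure -> mean ee, count of structures excluded for lacking
    any ee value).
    """
    ee = pd.to_numeric(df["ee"], errors="coerce")
    grouped = ee.groupby(df[column]).mean()
    means = {k: float(v) for k, v in grouped.items() if not pd.isna(v)}
    n_excluded = int(grouped.isna().sum())
    return means, n_excluded
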