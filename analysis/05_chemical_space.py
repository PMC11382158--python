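#!/usr/bin/env python
"""Map the olefin and ligand chemical space: MACCS-key fingerprints, 2-D
UMAP embeddings with per-metal group labels and mean-%ee coloring, and
cross-metal structure overlap tables.

Writes results/{olefin,ligand}_embedding.csv and _overlap.csv. The overlap
counts quantify how little substrate/ligand space the metals share.
"""

import argparse
from pathlib import Path

import pandas as pd

from aho import space

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=7)
parser.add_argument("--outdir", type=Path, default=Path("results"))
args = parser.parse_args()

df = pd.read_csv(args.outdir / "classified.csv")
metals = sorted(df.metal.unique())

for name, col in (("olefin", "substrate_canonical"),
                  ("ligand", "ligand_canonical")):
    by_metal = {m: set(df.loc[df.metal == m, col]) for m in metals}
    overlaps = space.overlap_sets(by_metal)
    space.overlaps_to_frame(overlaps).to_csv(
        args.outdir / f"{name}_overlap.csv", index=False)

    points = space.embed(sorted(set(df[col])), method="umap", seed=args.seed,
                         groups=space.metal_groups(by_metal))
    means, n_no_ee = space.color_by_mean_ee(df, col)
    for p in points:
        p.mean_ee = means.get(p.structure_id)
    space.embedding_to_frame(points).to_csv(
        args.outdir / f"{name}_embedding.csv", index=False)

    n_distinct = len(set(df[col]))
    pair_counts = {"+".join(k): len(v) for k, v in overlaps.items()
                   if len(k) == 2}
    print(f"{name}s: {n_distinct} distinct structures embedded; "
          f"pairwise overlaps {pair_counts}; "
          f"{n_no_ee} structures lack ee for coloring")
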