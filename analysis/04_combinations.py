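#!/usr/bin/env python
"""Build the olefin-ligand combination matrices: per metal, one cell per
observed (degree, olefin class, ligand category) with its reaction count and
exact median %ee.

Writes results/combinations_<metal>.csv and results/median_ee_by_ligand_
<metal>.csv, and prints how sparse the explored combination space is - the
point the matrices make about literature bias.
"""

import argparse
from pathlib import Path

import pandas as pd

from aho.stats import combination_matrix, combinations_to_frame, \
    median_ee_by_ligand

parser = argparse.ArgumentParser()
parser.add_argument("--outdir", type=Path, default=Path("results"))
args = parser.parse_args()

df = pd.read_csv(args.outdir / "classified.csv")

for metal in sorted(df.metal.unique()):
    cells = combination_matrix(df, metal)
    frame = combinations_to_frame(cells)
    frame.to_csv(args.outdir / f"combinations_{metal}.csv", index=False)
    median_ee_by_ligand(df, metal).to_csv(
        args.outdir / f"median_ee_by_ligand_{metal}.csv", index=False)

    sub = df[df.metal == metal]
    possible = (sub.degree_label.nunique()
                * sub.primary_olefin_class.nunique()
                * sub.ligand_category.nunique())
    top = frame.nlargest(1, "n_reactions").iloc[0]
    print(f"{metal}: {len(cells)}/{possible} combinations observed "
          f"({100*len(cells)/possible:.0f}% occupancy); busiest cell "
          f"{top.degree}/{top.olefin_class}/{top.ligand_category} "
          f"(n={top.n_reactions}, median ee {top.median_ee:.1f}%)")
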