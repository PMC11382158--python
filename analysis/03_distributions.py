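#!/usr/bin/env python
"""Aggregate the classified dataset into the headline distributions:
%ee regimes, olefin degree and class per metal, ligand types and categories
per metal, and the top solvents / temperatures / pressures per metal.

Writes one tidy CSV per report under results/ and prints the shares that
characterize the dataset's bias structure.
"""

import argparse
from pathlib import Path

import pandas as pd

from aho import stats

parser = argparse.ArgumentParser()
parser.add_argument("--outdir", type=Path, default=Path("results"))
args = parser.parse_args()

df = pd.read_csv(args.outdir / "classified.csv")

ee = stats.ee_regime_distribution(df)
ee.to_frame().to_csv(args.outdir / "ee_regimes.csv", index=False)
top_bin = 100 * ee.fractions[-1]
print(f"%ee regimes: {top_bin:.1f}% of reactions above 99% ee "
      f"({100*sum(ee.fractions[-2:]):.1f}% above 95%)")

for name, key, top in (
    ("olefin_degree_by_metal", "degree", None),
    ("olefin_class_by_metal", "olefin_class", None),
    ("ligand_type_by_metal", "ligand_type", None),
    ("ligand_category_by_metal", "ligand_class", None),
    ("solvent_by_metal", "solvent", 10),
    ("temperature_by_metal", "temperature", 10),
    ("pressure_by_metal", "pressure", 10),
):
    reports = stats.category_distribution(df, key, per_metal=True, top_n=top)
    pd.concat([r.to_frame() for r in reports]).to_csv(
        args.outdir / f"{name}.csv", index=False)

for metal in ("Ir", "Rh", "Co"):
    sub = df[df.metal == metal]
    if not len(sub):
        continue
    tri = 100 * (sub.degree_label == "trisubstituted").mean()
    dcm = 100 * (sub.solvent == "dichloromethane").mean()
    pn = 100 * ((sub.ligand_denticity == "bidentate")
                & (sub.ligand_donor_set == "P,N")).mean()
    print(f"  {metal}: trisubstituted {tri:.1f}%, DCM {dcm:.1f}%, "
          f"bidentate P,N ligands {pn:.1f}%")
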