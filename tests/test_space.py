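"""Chemical-space tooling: MACCS fingerprints, embeddings, overlap sets,
mean-ee coloring."""

import itertools

import numpy as np
import pandas as pd
import pytest
from rdkit import Chem
from rdkit.Chem import MACCSkeys

from aho.space import (
    color_by_mean_ee, embed, fingerprint, fingerprint_matrix, metal_groups,
    overlap_sets,
)


class TestFingerprint:
    def test_atom_order_invariance(self):
        assert np.array_equal(fingerprint("CCO"), fingerprint("OCC"))

    def test_invariance_over_random_renumberings(self):
        smi = "CC(=O)OC(=C)c1ccccc1"
        ref = fingerprint(smi)
        mol = Chem.MolFromSmiles(smi)
        for variant in Chem.MolToRandomSmilesVect(mol, 100, randomSeed=9):
            assert np.array_equal(fingerprint(variant), ref)

    def test_methane_has_no_ring_or_heteroatom_bits(self):
        assert fingerprint("C").sum() <= 2  # only trivial carbon keys

    def test_benzene_bits_match_per_key_substructure_oracle(self):
        """Each set bit agrees with matching that key's own SMARTS pattern
        directly against the molecule."""
        mol = Chem.MolFromSmiles("c1ccccc1")
        bits = fingerprint("c1ccccc1")
        checked = 0
        for key_idx, (smarts, min_count) in MACCSkeys.smartsPatts.items():
            if smarts in ("?", ""):
                continue
            patt = Chem.MolFromSmarts(smarts)
            if patt is None:
                continue
            expected = len(mol.GetSubstructMatches(patt)) > min_count if \
                min_count else bool(mol.GetSubstructMatches(patt))
            assert bool(bits[key_idx - 1]) == expected, key_idx
            checked += 1
        assert checked > 100

    def test_parse_failure_raises_with_structure(self):
        with pytest.raises(ValueError, match="C1CC"):
            fingerprint("C1CC")

    def test_matrix_deduplicates_first_seen(self):
        ids, mat = fingerprint_matrix(["CCO", "OCC", "CCO", "c1ccccc1"])
        # SMILES strings are ids; graph-level dedup happens upstream via
        # canonicalization
        assert ids == ["CCO", "OCC", "c1ccccc1"]
        assert mat.shape == (3, 166)


class TestEmbed:
    STRUCTURES = ["CCO", "CCCO", "CCCCO", "c1ccccc1", "Cc1ccccc1",
                  "CCN", "CCC", "CCCC"]

    @pytest.mark.parametrize("method", ["umap", "tsne"])
    def test_fixed_seed_determinism(self, method):
        a = embed(self.STRUCTURES, method=method, seed=4)
        b = embed(self.STRUCTURES, method=method, seed=4)
        assert [(p.structure_id, p.x, p.y) for p in a] == \
            [(p.structure_id, p.x, p.y) for p in b]

    def test_duplicates_removed_before_embedding(self):
        points = embed(self.STRUCTURES + self.STRUCTURES[:3], seed=0)
        assert len(points) == len(self.STRUCTURES)

    def test_insufficient_points(self):
        with pytest.raises(ValueError, match="insufficient"):
            embed(["CCO", "CCC"], seed=0)

    def test_unknown_method(self):
        with pytest.raises(ValueError, match="method"):
            embed(self.STRUCTURES, method="pca", seed=0)

    def test_coordinates_finite_and_schema_shared(self):
        for method in ("umap", "tsne"):
            points = embed(self.STRUCTURES, method=method, seed=1)
            assert all(np.isfinite([p.x, p.y]).all() for p in points)


class TestOverlapSets:
    def test_small_example(self):
        overlaps = overlap_sets({"Ir": {"A", "B"}, "Rh": {"B", "C"},
                                 "Co": {"B"}})
        assert overlaps[("Ir", "Rh")] == {"B"}
        assert overlaps[("Co", "Ir", "Rh")] == {"B"}

    def test_disjoint(self):
        overlaps = overlap_sets({"Ir": {"A"}, "Rh": {"B"}, "Co": {"C"}})
        assert all(not s for s in overlaps.values())

    def test_matches_brute_force_on_random_triples(self):
        rng = np.random.default_rng(23)
        universe = [f"S{i}" for i in range(150)]
        for _ in range(100):
            sets = {m: set(rng.choice(universe, 100, replace=False))
                    for m in ("Ir", "Rh", "Co")}
            overlaps = overlap_sets(sets)
            for r in (2, 3):
                for combo in itertools.combinations(sorted(sets), r):
                    brute = set(universe)
                    for m in combo:
                        brute &= sets[m]
                    assert overlaps[combo] == brute
            # triple is contained in every pairwise intersection
            for pair in itertools.combinations(sorted(sets), 2):
                assert overlaps[("Co", "Ir", "Rh")] <= overlaps[pair]

    def test_symmetry_via_sorted_keys(self):
        overlaps = overlap_sets({"Rh": {"A", "B"}, "Ir": {"B"}})
        assert list(overlaps) == [("Ir", "Rh")]


class TestGroupsAndColoring:
    def test_shared_structures_get_shared_label(self):
        groups = metal_groups({"Ir": {"A", "B"}, "Rh": {"B"}})
        assert groups["A"] == "Ir"
        assert groups["B"] == "shared:Ir+Rh"

    def test_mean_ee(self):
        df = pd.DataFrame([
            {"substrate_canonical": "X", "ee": 90.0},
            {"substrate_canonical": "X", "ee": 100.0},
            {"substrate_canonical": "Y", "ee": None},
        ])
        means, n_excluded = color_by_mean_ee(df)
        assert means == {"X": 95.0}
        assert n_excluded == 1

    def test_planted_structure_means_recovered(self):
        """Per-structure ee means planted by the generator's per-structure
        model are recovered within Monte-Carlo error."""
        from aho.synth import SyntheticConfig, generate, OLEFIN_TEMPLATES
        from aho.records import canonical_structure

        means = {t: 50.0 + 2.5 * i for i, (k, ts) in
                 enumerate(sorted(OLEFIN_TEMPLATES.items())) for t in ts}
        cfg = SyntheticConfig(
            seed=3, n_reactions=2000, decorate_prob=0.0,
            ee_model={"kind": "per_structure", "means": means, "sd": 3.0})
        records, truth = generate(cfg)
        df = pd.DataFrame({
            "substrate_canonical": [canonical_structure(r.substrate)
                                    for r in records],
            "ee": [r.ee for r in records],
            "template": truth["olefin_template"],
        })
        got, _ = color_by_mean_ee(df)
        for template, grp in df.groupby("template"):
            canon = canonical_structure(template)
            n = len(grp)
            if n < 20:
                continue
            assert got[canon] == pytest.approx(
                means[template], abs=4 * 3.0 / np.sqrt(n) + 0.1)
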