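"""Reaction-table ingest: validation, quarantine, normalization, metal
extraction and structure canonicalization."""

import math

import pytest
from hypothesis import given, settings, strategies as st
from rdkit import Chem

from aho.records import (
    AmbiguousMetalError, ConfigError, canonical_structure, dataset_summary,
    extract_metal, normalize_pressure, normalize_solvent,
    normalize_temperature, read_dataset, records_to_frame, row_to_record,
    strip_counterions, write_dataset,
)


def _write(tmp_path, text, name="data.csv"):
    path = tmp_path / name
    path.write_text(text)
    return path


HEADER = "record_id,substrate,product,ligand,metal,solvent,pressure,temperature,ee\n"


class TestReadDataset:
    def test_malformed_smiles_quarantined_not_dropped(self, tmp_path):
        csv = HEADER + (
            "r1,C=Cc1ccccc1,,c1ccc(P(c2ccccc2)c2ccccc2)cc1,Rh,DCM,10,25,95\n"
            "r2,C1CC,,c1ccc(P(c2ccccc2)c2ccccc2)cc1,Rh,DCM,10,25,90\n"
            "r3,C=CC(=O)O,,c1ccc(P(c2ccccc2)c2ccccc2)cc1,Ir,MeOH,5,rt,80\n"
        )
        report = read_dataset(_write(tmp_path, csv))
        assert len(report.records) == 2
        assert len(report.quarantine) == 1
        assert report.quarantine[0].reason == "unparseable substrate"
        assert report.n_in == 3

    def test_ee_parsing_and_range(self, tmp_path):
        csv = HEADER + (
            "a,C=Cc1ccccc1,,CP(C)C,Rh,DCM,1,25,99\n"
            "b,C=Cc1ccccc1,,CP(C)C,Rh,DCM,1,25,105\n"
        )
        report = read_dataset(_write(tmp_path, csv))
        assert len(report.records) == 1
        assert report.records[0].ee == 99.0
        assert report.quarantine[0].reason == "ee out of range"

    def test_counts_conserved(self, tmp_path):
        rows = ["%d,C=CC,,CP(C)C,Rh,,,," % i for i in range(5)]
        rows[2] = "2,XYZ,,CP(C)C,Rh,,,,"
        rows[4] = "4,C=CC,,CP(C)C,Rh,,,300,"
        report = read_dataset(_write(tmp_path, HEADER + "\n".join(rows)))
        assert len(report.records) + len(report.quarantine) == 5
        reasons = {q.reason for q in report.quarantine}
        assert reasons == {"unparseable substrate", "temperature out of range"}

    def test_missing_mandatory_column_is_config_error(self, tmp_path):
        path = _write(tmp_path, "record_id,ligand,metal\nr1,CP(C)C,Rh\n")
        with pytest.raises(ConfigError, match="substrate"):
            read_dataset(path)

    def test_metal_extracted_from_catalyst_column(self, tmp_path):
        csv = ("record_id,substrate,ligand,catalyst\n"
               "r1,C=Cc1ccccc1,CP(C)C,[Ir(COD)Cl]2\n")
        report = read_dataset(_write(tmp_path, csv),
                              schema={"record_id": "record_id",
                                      "substrate": "substrate",
                                      "ligand": "ligand",
                                      "catalyst": "catalyst"})
        assert report.records[0].metal == "Ir"

    def test_round_trip_lossless(self, tmp_path, small_dataset):
        records, _ = small_dataset
        out = tmp_path / "normalized.csv"
        write_dataset(records[:200], out)
        back = read_dataset(out)
        assert not back.quarantine
        assert records_to_frame(back.records).equals(
            records_to_frame(records[:200]))


class TestExtractMetal:
    @pytest.mark.parametrize("field,expected", [
        ("[Rh(COD)2]BF4", "Rh"),
        ("Co", "Co"),
        ("[Ir(COD)Cl]2", "Ir"),
        ("Co(acac)2", "Co"),
        ("[RuCl2(p-cymene)]2", "Ru"),
        ("CC(=O)O[Rh]OC(C)=O", "Rh"),
    ])
    def test_single_metal(self, field, expected):
        assert extract_metal(field) == expected

    @pytest.mark.parametrize("field", ["Ir/Rh mixture", "NaBH4", ""])
    def test_ambiguous_or_absent(self, field):
        with pytest.raises(AmbiguousMetalError):
            extract_metal(field)


class TestCanonicalStructure:
    def test_same_molecule_same_string(self):
        assert canonical_structure("OCC") == canonical_structure("CCO")

    def test_stereoisomers_distinct_by_default(self):
        assert canonical_structure("C/C=C/C") != canonical_structure("C/C=C\\C")
        assert canonical_structure("C/C=C/C", stereo=False) == \
            canonical_structure("C/C=C\\C", stereo=False)

    def test_permutation_invariance_oracle(self):
        """1000 random atom-order rewritings collapse to one canonical
        string."""
        smi = "COC(=O)/C(NC(C)=O)=C/c1ccc(OC)cc1"  # 20 heavy atoms
        mol = Chem.MolFromSmiles(smi)
        variants = Chem.MolToRandomSmilesVect(mol, 1000, randomSeed=42)
        assert len({canonical_structure(v) for v in variants}) == 1

    def test_invalid_smiles_raises(self):
        with pytest.raises(ValueError):
            canonical_structure("C1CC")


class TestStripCounterions:
    def test_keeps_largest_organic_fragment(self):
        assert strip_counterions("CCP(CC)CC.[Na+].[Cl-]") == \
            canonical_structure("CCP(CC)CC")

    def test_ferrocene_fragments_retained_whole(self):
        smi = ("CC(P(C1CCCCC1)C1CCCCC1)c1ccc[c-]1P(c1ccccc1)c1ccccc1"
               ".c1cc[cH-]c1.[Fe+2]")
        assert strip_counterions(smi).count(".") == 2


class TestNormalization:
    @pytest.mark.parametrize("raw,expected", [
        ("DCM", "dichloromethane"), ("CH2Cl2", "dichloromethane"),
        ("dichloromethane", "dichloromethane"), ("ClCCl", "dichloromethane"),
        ("MeOH", "methanol"), ("THF", "tetrahydrofuran"),
        ("weird-solvent", "weird-solvent"), (None, None),
    ])
    def test_solvent_synonyms(self, raw, expected):
        assert normalize_solvent(raw) == expected

    @pytest.mark.parametrize("raw,expected", [
        ("rt", 25.0), ("Room Temperature", 25.0), ("25", 25.0),
        ("-20", -20.0), (40, 40.0),
    ])
    def test_temperature(self, raw, expected):
        assert normalize_temperature(raw) == expected

    @pytest.mark.parametrize("raw,expected", [
        ("50", 50.0), ("50 atm", 50.0), ("10 bar", 9.8692),
        ("100 psi", 6.8046), (5, 5.0),
    ])
    def test_pressure_units(self, raw, expected):
        assert normalize_pressure(raw) == pytest.approx(expected)

    @given(st.floats(min_value=0.1, max_value=200))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_pressure_bar_conversion_scales_linearly(self, value):
        assert normalize_pressure(f"{value} bar") == \
            pytest.approx(0.98692 * value)


class TestDatasetSummary:
    def test_counts_match_ground_truth(self, small_dataset):
        records, truth = small_dataset
        summary = dataset_summary(records)
        assert summary["n_reactions"] == len(records)
        for metal, grp in truth.groupby("metal"):
            assert summary["per_metal"][metal]["n_reactions"] == len(grp)
            assert summary["per_metal"][metal]["share_pct"] == pytest.approx(
                100 * len(grp) / len(records))
        # distinct-structure counting is order invariant
        rev = dataset_summary(records[::-1])
        assert rev["n_distinct_olefins"] == summary["n_distinct_olefins"]
        assert rev["n_distinct_ligands"] == summary["n_distinct_ligands"]
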