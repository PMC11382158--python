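"""End-to-end orchestration: ingest -> perceive -> classify -> aggregate ->
embed, with record-count bookkeeping and a machine-readable run manifest.

``classify_records`` is the workhorse: it attaches alkene degree, olefin
class, ligand category and canonical structures to every record, moving
failures into an exclusion list instead of aborting. ``run_all`` drives a
whole reproducible run from one config and writes every report CSV plus a
manifest whose digests make reruns auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import stats as _stats
from . import space as _space
from .ligands import (classify_ligand_cached, category_label,
                      ligand_type_label, LIGAND_RULEPACK_VERSION)
from .olefins import classify_substrate, OLEFIN_RULEPACK_VERSION
from .records import (ReactionRecord, read_dataset, write_dataset,
                      write_quarantine, records_to_frame, canonical_structure,
                      ConfigError)
from .synth import SyntheticConfig, generate

log = logging.getLogger("aho.pipeline")


@dataclass
class RunManifest:
    config_hash: str
    input_digest: str
    rulepack_versions: dict
    seed: int
    counts: dict
    outputs: dict = field(default_factory=dict)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def _sha256_bytes(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def _sha256_file(path: Path) -> str:
    return _sha256_bytes(path.read_bytes())


def classify_records(records: list[ReactionRecord],
                     ferrocene_separate: bool = True
                     ) -> tuple[pd.DataFrame, list[dict]]:
    """Attach classifications to records.

    Returns (classified table, exclusions). Each excluded record carries a
    machine-readable reason; classified + excluded = input.
    """
    rows, excluded = [], []
    for r in records:
        try:
            oc = classify_substrate(r.substrate, r.product)
            lc = classify_ligand_cached(r.ligand)
            rows.append({
                "record_id": r.record_id,
                "metal": r.metal,
                "substrate_canonical": canonical_structure(r.substrate),
                "ligand_canonical": canonical_structure(r.ligand),
                "degree_label": oc.degree_label,
                "primary_olefin_class": oc.primary_class,
                "olefin_class_set": "|".join(sorted(oc.class_set)),
                "ligand_category": category_label(lc, ferrocene_separate),
                "ligand_type": ligand_type_label(lc, ferrocene_separate),
                "ligand_denticity": lc.denticity,
                "ligand_donor_set": lc.donor_set_label,
                "ligand_is_ferrocene": lc.is_ferrocene,
                "solvent": r.solvent,
                "temperature": r.temperature,
                "pressure": r.pressure,
                "ee": r.ee,
            })
        except Exception as exc:  # per-record failure, never aborts the run
            excluded.append({"record_id": r.record_id, "reason": str(exc)})
    return pd.DataFrame(rows), excluded


# ---------------------------------------------------------------------------
# full run


@dataclass
class PipelineConfig:
    """One YAML-loadable config drives all stages; all randomness funnels
    through ``seed``."""

    outdir: str = "aho_run"
    seed: int = 0
    input_path: str | None = None       # CSV/TSV of reactions; None = synthetic
    schema: str | None = None
    synthetic_n: int = 1000
    ee_bin_edges: tuple = _stats.DEFAULT_EE_EDGES
    top_n_conditions: int = 10
    embedding: bool = True
    embedding_method: str = "umap"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        unknown = set(payload) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(**payload)


def run_all(config: PipelineConfig) -> RunManifest:
    """Execute every stage and write all report files plus the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config_hash = _sha256_bytes(
        json.dumps(asdict(config), sort_keys=True, default=str).encode())

    # --- ingest
    if config.input_path is not None:
        report = read_dataset(config.input_path, config.schema)
        records, quarantine = report.records, report.quarantine
        input_digest = _sha256_file(Path(config.input_path))
    else:
        records, truth = generate(SyntheticConfig(
            seed=config.seed, n_reactions=config.synthetic_n))
        truth.to_csv(outdir / "truth.csv", index=False)
        quarantine = []
        input_digest = f"synthetic:n={config.synthetic_n}:seed={config.seed}"
    write_dataset(records, outdir / "normalized.csv")
    write_quarantine(quarantine, outdir / "quarantine.csv")

    # --- classify
    df, excluded = classify_records(records)
    df.to_csv(outdir / "classified.csv", index=False)
    pd.DataFrame(excluded, columns=["record_id", "reason"]).to_csv(
        outdir / "excluded.csv", index=False)

    # --- aggregate
    _stats.ee_regime_distribution(df, config.ee_bin_edges).to_frame().to_csv(
        outdir / "ee_regimes.csv", index=False)
    for name, key, top in (
        ("olefin_degree_by_metal", "degree", None),
        ("olefin_class_by_metal", "olefin_class", None),
        ("ligand_type_by_metal", "ligand_type", None),
        ("ligand_category_by_metal", "ligand_class", None),
        ("solvent_by_metal", "solvent", config.top_n_conditions),
        ("temperature_by_metal", "temperature", config.top_n_conditions),
        ("pressure_by_metal", "pressure", config.top_n_conditions),
    ):
        reports = _stats.category_distribution(df, key, per_metal=True,
                                               top_n=top)
        pd.concat([r.to_frame() for r in reports]).to_csv(
            outdir / f"{name}.csv", index=False)

    metals = sorted(df["metal"].unique())
    for metal in metals:
        cells = _stats.combination_matrix(df, metal)
        _stats.combinations_to_frame(cells).to_csv(
            outdir / f"combinations_{metal}.csv", index=False)
        _stats.median_ee_by_ligand(df, metal).to_csv(
            outdir / f"median_ee_by_ligand_{metal}.csv", index=False)

    # --- chemical space
    for name, col in (("olefin", "substrate_canonical"),
                      ("ligand", "ligand_canonical")):
        by_metal = {m: set(df.loc[df["metal"] == m, col]) for m in metals}
        _space.overlaps_to_frame(_space.overlap_sets(by_metal)).to_csv(
            outdir / f"{name}_overlap.csv", index=False)
        if config.embedding:
            groups = _space.metal_groups(by_metal)
            points = _space.embed(sorted(set(df[col])),
                                  method=config.embedding_method,
                                  seed=config.seed, groups=groups)
            means, _ = _space.color_by_mean_ee(df, col)
            for p in points:
                p.mean_ee = means.get(p.structure_id)
            _space.embedding_to_frame(points).to_csv(
                outdir / f"{name}_embedding.csv", index=False)

    # --- manifest
    counts = {
        "input": len(records) + len(quarantine),
        "accepted": len(records),
        "quarantined": len(quarantine),
        "classified": int(len(df)),
        "excluded": len(excluded),
    }
    assert counts["input"] == counts["accepted"] + counts["quarantined"]
    assert counts["accepted"] == counts["classified"] + counts["excluded"]
    manifest = RunManifest(
        config_hash=config_hash,
        input_digest=input_digest,
        rulepack_versions={"olefin": OLEFIN_RULEPACK_VERSION,
                           "ligand": LIGAND_RULEPACK_VERSION},
        seed=config.seed,
        counts=counts,
    )
    for path in sorted(outdir.glob("*.csv")):
        manifest.outputs[path.name] = _sha256_file(path)
    manifest.write(outdir / "manifest.json")
    log.info("run complete: %s", counts)
    return manifest
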