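"""End-to-end pipeline: dataset -> fingerprints/clusters -> mappings ->
threshold -> pair selection -> predictions -> similarity extension ->
known-pair subtraction -> pathway grouping -> optional benchmark.

Every stage writes its intermediate file into the output directory and the
run finishes with a JSON manifest of per-stage counts and the effective
configuration, so a pipeline run is byte-reproducible and auditable
stage-by-stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import activity, benchmark as benchmark_mod, chem, domains, mapping, propagate

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Effective parameters of a pipeline run (defaults are the method's
    published operating point)."""

    bioactivity: str = ""
    annotations: str = ""
    hierarchy: str | None = None
    reference: str | None = None
    pathways: str | None = None
    out_dir: str = "ligdom_run"

    active_um: float = 10.0
    inactive_um: float = 20.0
    cluster_tanimoto: float = 0.7
    propagate_tanimoto: float = 0.8
    mapping_score: float = 0.5
    min_compound_targets: int = 3
    min_cluster_targets: int = 5
    fingerprint_bits: int = 2048

    use_hierarchy: bool = True
    use_pairs: bool = True
    use_clusters: bool = True
    threshold_metrics: tuple[str, ...] = mapping.SCORE_METRICS
    cluster_mode: str = "seed"
    dedup_scope: str = "global"

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        """Load a flat ``key = value`` config file; keyword overrides win."""
        values: dict[str, object] = {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        with open(path) as handle:
            for line in handle:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, raw = line.partition("=")
                key, raw = key.strip(), raw.strip()
                if key not in fields:
                    raise ValueError(f"unknown config key {key!r}")
                values[key] = _coerce(raw, fields[key].type)
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)


def _coerce(raw: str, annotation: str | type):
    text = str(annotation)
    if "bool" in text:
        return raw.lower() in ("1", "true", "yes", "on")
    if "int" in text and "tuple" not in text:
        return int(raw)
    if "float" in text:
        return float(raw)
    if "tuple" in text:
        return tuple(item.strip() for item in raw.split(","))
    return raw


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full pipeline; returns (and writes) the run manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": _config_dict(cfg), "stages": {}}

    def stage(name: str, **counts) -> None:
        manifest["stages"][name] = counts
        logger.info("stage %-16s %s", name, counts)

    # 1. labeled interaction dataset
    records = activity.read_bioactivity_tsv(cfg.bioactivity)
    dataset = activity.build_dataset(
        records, dedup_scope=cfg.dedup_scope,
        active_threshold=cfg.active_um, inactive_threshold=cfg.inactive_um,
    )
    activity.write_dataset_tsv(dataset, out / "dataset.tsv", out / "dataset_summary.json")
    stage("build_dataset", **dataset.summary)

    proteome = domains.read_annotations_tsv(cfg.annotations)
    hierarchy = domains.read_hierarchy_tsv(cfg.hierarchy) if (cfg.hierarchy and cfg.use_hierarchy) else None
    stage("annotations", n_proteins=len(proteome), n_domains=len(proteome.all_domains()))

    # 2. fingerprints
    smiles = {r.compound_id: r.smiles for r in records if r.smiles}
    fps = chem.fingerprint_table(smiles, n_bits=cfg.fingerprint_bits)
    chem.write_fingerprint_cache(fps, out / "fingerprints.tsv")
    stage("fingerprint", n_compounds=len(fps), n_failed=len(smiles) - len(fps))

    # 3. clusters
    clusters = None
    if cfg.use_clusters:
        clusters = chem.cluster_compounds(fps, threshold=cfg.cluster_tanimoto, mode=cfg.cluster_mode)
        pd.DataFrame(
            [(c.seed, ",".join(sorted(c.members))) for c in clusters],
            columns=["seed", "members"],
        ).to_csv(out / "clusters.tsv", sep="\t", index=False)
        stage("cluster", n_clusters=len(clusters),
              n_multi=sum(1 for c in clusters if len(c.members) > 1))

    # 4. raw mappings
    raw = mapping.map_all(
        dataset, proteome, hierarchy=hierarchy, clusters=clusters,
        include_singles=True, include_pairs=cfg.use_pairs,
    )
    mapping.write_mappings_tsv(raw, out / "mappings_raw.tsv")
    stage("map", n_mappings=len(raw),
          n_singles=sum(1 for m in raw if not m.feature.is_pair),
          n_pairs=sum(1 for m in raw if m.feature.is_pair))

    # 5. score threshold
    filtered = mapping.threshold_filter(raw, cfg.mapping_score, metrics=cfg.threshold_metrics)
    mapping.write_mappings_tsv(filtered, out / "mappings_filtered.tsv")
    stage("filter", n_mappings=len(filtered))

    # 6. positive-pair selection
    final_mappings = mapping.select_positive_pairs(filtered) if cfg.use_pairs else filtered
    mapping.write_mappings_tsv(final_mappings, out / "mappings_final.tsv")
    stage("pairs", n_mappings=len(final_mappings),
          n_positive_pairs=sum(1 for m in final_mappings if m.feature.is_pair))

    # 7-9. predictions
    predictions = propagate.predict_from_mappings(final_mappings, proteome)
    stage("predict", n_predictions=len(predictions))
    predictions = propagate.extend_by_similarity(predictions, fps, threshold=cfg.propagate_tanimoto)
    stage("extend", n_predictions=len(predictions))
    predictions = propagate.remove_known(predictions, dataset)
    propagate.write_predictions_tsv(predictions, out / "predictions.tsv")
    stage("subtract_known", n_predictions=len(predictions),
          n_compounds=len({p.compound_id for p in predictions.values()}),
          n_proteins=len({p.target_accession for p in predictions.values()}))

    # 10. pathway grouping
    if cfg.pathways:
        annotations = propagate.read_pathway_tsv(cfg.pathways)
        summary = propagate.group_by_pathway(predictions, annotations)
        summary.to_csv(out / "pathway_summary.tsv", sep="\t", index=False)
        stage("pathways", n_pathways=len(summary))

    # 11. benchmark against the reference set
    if cfg.reference:
        reference = benchmark_mod.read_reference_tsv(cfg.reference)
        report = benchmark_mod.benchmark_report(raw, reference, metrics=cfg.threshold_metrics)
        report.to_csv(out / "benchmark.tsv", sep="\t", index=False, float_format="%.6g")
        at_t = report[report["threshold"] == cfg.mapping_score]
        stage("benchmark", n_thresholds=len(report),
              **({"mcc_at_threshold": float(at_t["mcc"].iloc[0])} if len(at_t) else {}))

    with open(out / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
    return manifest


def _config_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["threshold_metrics"] = list(cfg.threshold_metrics)
    return d
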