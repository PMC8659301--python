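"""Turning filtered mappings into drug/compound-target interaction predictions.

Each surviving compound-feature mapping licenses the compound against every
protein containing that feature. Predictions are then extended once to
structurally similar compounds (Tanimoto >= 0.8), known pairs (with either
label) are subtracted, and the final set can be summarized per pathway.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .activity import InteractionDataset
from .chem import Fingerprint, PROPAGATE_TANIMOTO, similar_compounds
from .domains import Proteome, proteins_with_feature
from .mapping import CompoundFeatureMapping

logger = logging.getLogger(__name__)


@dataclass
class DTIPrediction:
    compound_id: str
    target_accession: str
    features: set[str] = field(default_factory=set)
    via_compounds: set[str] = field(default_factory=set)

    @property
    def key(self) -> tuple[str, str]:
        return (self.compound_id, self.target_accession)


PredictionSet = dict[tuple[str, str], DTIPrediction]


def _merge(predictions: PredictionSet, new: DTIPrediction) -> None:
    incumbent = predictions.get(new.key)
    if incumbent is None:
        predictions[new.key] = new
    else:
        incumbent.features |= new.features
        incumbent.via_compounds |= new.via_compounds


def predict_from_mappings(
    mappings: Iterable[CompoundFeatureMapping],
    proteome: Proteome,
) -> PredictionSet:
    """Cross each mapping's compound with every protein containing the
    mapped feature; duplicates merge with accumulated provenance."""
    feature_hosts: dict[str, set[str]] = {}
    predictions: PredictionSet = {}
    for m in mappings:
        fkey = str(m.feature)
        if fkey not in feature_hosts:
            feature_hosts[fkey] = proteins_with_feature(proteome, m.feature)
        for acc in feature_hosts[fkey]:
            _merge(predictions, DTIPrediction(m.compound_id, acc, features={fkey}))
    return predictions


def extend_by_similarity(
    predictions: PredictionSet,
    fps: Mapping[str, Fingerprint],
    threshold: float = PROPAGATE_TANIMOTO,
) -> PredictionSet:
    """Single-round propagation of predictions to similar compounds.

    For each predicted (compound, target), every compound at Tanimoto >=
    threshold to the source compound inherits the target. No transitive
    chaining: neighbors of neighbors are not reached.
    """
    out: PredictionSet = {}
    for pred in predictions.values():
        _merge(out, DTIPrediction(pred.compound_id, pred.target_accession,
                                  features=set(pred.features), via_compounds=set(pred.via_compounds)))

    neighbor_cache: dict[str, set[str]] = {}
    source_compounds = sorted({p.compound_id for p in predictions.values()})
    for compound in source_compounds:
        if compound not in fps:
            logger.warning("no fingerprint for %s; skipped in similarity extension", compound)
            neighbor_cache[compound] = set()
            continue
        neighbor_cache[compound] = similar_compounds(compound, fps, threshold)

    for pred in predictions.values():
        for neighbor in neighbor_cache[pred.compound_id]:
            _merge(out, DTIPrediction(neighbor, pred.target_accession,
                                      features=set(pred.features),
                                      via_compounds={pred.compound_id}))
    return out


def remove_known(predictions: PredictionSet, dataset: InteractionDataset) -> PredictionSet:
    """Subtract (compound, target) pairs recorded with either label: actives
    are already known, and inactives are known non-binders."""
    known = dataset.known_pairs()
    return {key: pred for key, pred in predictions.items() if key not in known}


def group_by_pathway(
    predictions: PredictionSet,
    pathway_annotations: Mapping[str, set[str]],
) -> pd.DataFrame:
    """Per-pathway interaction, compound and protein counts.

    Targets annotated to several pathways count in each; targets with no
    annotation fall into the ``unannotated`` bucket.
    """
    rows: dict[str, dict[str, set]] = {}
    for pred in predictions.values():
        pathways = pathway_annotations.get(pred.target_accession) or {"unannotated"}
        for pw in pathways:
            bucket = rows.setdefault(pw, {"pairs": set(), "compounds": set(), "proteins": set()})
            bucket["pairs"].add(pred.key)
            bucket["compounds"].add(pred.compound_id)
            bucket["proteins"].add(pred.target_accession)
    frame = pd.DataFrame(
        [
            (pw, len(b["pairs"]), len(b["compounds"]), len(b["proteins"]))
            for pw, b in sorted(rows.items())
        ],
        columns=["pathway_id", "n_interactions", "n_compounds", "n_proteins"],
    )
    return frame


def read_pathway_tsv(path) -> dict[str, set[str]]:
    """Read target->pathway annotations: ``target_accession  pathway_id``."""
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"target_accession", "pathway_id"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"pathway table {path} lacks columns: {sorted(missing)}")
    out: dict[str, set[str]] = {}
    for row in frame.itertuples(index=False):
        out.setdefault(str(row.target_accession), set()).add(str(row.pathway_id))
    return out


def write_predictions_tsv(predictions: PredictionSet, path) -> None:
    rows = [
        (
            pred.compound_id,
            pred.target_accession,
            ",".join(sorted(pred.features)),
            ",".join(sorted(pred.via_compounds)),
        )
        for pred in sorted(predictions.values(), key=lambda p: p.key)
    ]
    frame = pd.DataFrame(rows, columns=["compound_id", "target_accession", "features", "via_compound"])
    frame.to_csv(path, sep="\t", index=False)


def read_predictions_tsv(path) -> PredictionSet:
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    predictions: PredictionSet = {}
    for row in frame.itertuples(index=False):
        features = set(row.features.split(",")) if row.features else set()
        via = set(row.via_compound.split(",")) if row.via_compound else set()
        _merge(predictions, DTIPrediction(str(row.compound_id), str(row.target_accession), features, via))
    return predictions
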