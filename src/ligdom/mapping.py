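"""Compound-to-domain-feature mapping scores.

The core statistic of the pipeline. For a compound (or a compound cluster,
pooling targets over its members) and a candidate feature (a single domain
or an unordered domain pair), the compound's known active and inactive
target proteins are partitioned into a confusion matrix:

* TP — active targets containing the feature,
* FN — active targets lacking it,
* FP — inactive targets containing it,
* TN — inactive targets lacking it,

from which recall, precision, accuracy, F1 and Matthews correlation are
computed. For single-domain features, containment is hierarchy-aware: an
active (inactive) target carrying a different domain from the same
hierarchy tree as the candidate counts as TP (FP), since same-hierarchy
profiles are near-interchangeable. Pair features require exact containment
of both ids.

Mappings are filtered by eligibility (enough active and inactive evidence)
and by a score threshold applied to the minimum of the five metrics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .activity import InteractionDataset
from .chem import CompoundCluster
from .domains import DomainFeature, DomainHierarchy, Proteome, contains_feature

logger = logging.getLogger(__name__)

MIN_COMPOUND_TARGETS = 3
MIN_CLUSTER_TARGETS = 5
DEFAULT_SCORE_THRESHOLD = 0.5
SCORE_METRICS = ("recall", "precision", "accuracy", "f1", "mcc")


class SubjectKind(Enum):
    COMPOUND = "compound"
    CLUSTER = "cluster"


class PairClass(Enum):
    POSITIVE = "positive"
    NEUTRAL = "neutral"
    NON_POSITIVE = "non_positive"


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def n_active(self) -> int:
        return self.tp + self.fn

    @property
    def n_inactive(self) -> int:
        return self.fp + self.tn


@dataclass(frozen=True)
class MappingScores:
    recall: float
    precision: float
    accuracy: float
    f1: float
    mcc: float

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in SCORE_METRICS}

    def minimum(self, metrics: Sequence[str] = SCORE_METRICS) -> float:
        return min(getattr(self, m) for m in metrics)


def compute_scores(c: ConfusionCounts) -> MappingScores:
    """Recall, precision, accuracy, F1 and MCC from confusion counts.

    Any metric whose denominator is zero is defined as 0, which keeps
    thresholding total for all-positive or all-negative target sets.
    """
    tp, fp, fn, tn = c.tp, c.fp, c.fn, c.tn
    recall = tp / (tp + fn) if tp + fn else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    total = tp + fp + fn + tn
    accuracy = (tp + tn) / total if total else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    denom = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom else 0.0
    return MappingScores(recall, precision, accuracy, f1, mcc)


@dataclass
class CompoundFeatureMapping:
    subject: str
    subject_kind: SubjectKind
    feature: DomainFeature
    counts: ConfusionCounts
    scores: MappingScores

    @property
    def compound_id(self) -> str:
        return self.subject


def _feature_present(
    domain_set: frozenset[str],
    root_set: frozenset[str] | None,
    feature: DomainFeature,
    feature_root: str | None,
) -> bool:
    # Pair features: exact containment only; hierarchy substitution applies
    # to single domains alone.
    if feature.is_pair:
        return contains_feature(domain_set, feature)
    d = feature.domains[0]
    if d in domain_set:
        return True
    return feature_root is not None and root_set is not None and feature_root in root_set


def count_confusion(
    actives: set[str],
    inactives: set[str],
    feature: DomainFeature,
    proteome: Proteome,
    hierarchy: DomainHierarchy | None = None,
) -> ConfusionCounts:
    """Confusion counts for one subject-feature combination.

    ``hierarchy=None`` disables same-hierarchy substitution.
    """
    overlap = actives & inactives
    if overlap:
        raise ValueError(f"targets labeled both active and inactive: {sorted(overlap)}")
    use_hierarchy = hierarchy is not None and not feature.is_pair
    feature_root = hierarchy.root(feature.domains[0]) if use_hierarchy else None

    tp = fp = 0
    for acc in actives:
        dset = proteome.domain_set(acc)
        rset = hierarchy.roots_of(dset) if use_hierarchy else None
        if _feature_present(dset, rset, feature, feature_root):
            tp += 1
    for acc in inactives:
        dset = proteome.domain_set(acc)
        rset = hierarchy.roots_of(dset) if use_hierarchy else None
        if _feature_present(dset, rset, feature, feature_root):
            fp += 1
    return ConfusionCounts(tp=tp, fp=fp, fn=len(actives) - tp, tn=len(inactives) - fp)


def eligible(subject_kind: SubjectKind, n_active: int, n_inactive: int) -> bool:
    """Evidence floor: compounds need >= 3 active and >= 3 inactive targets,
    clusters >= 5 of each."""
    if n_active < 0 or n_inactive < 0:
        raise ValueError("target counts must be nonnegative")
    floor = MIN_COMPOUND_TARGETS if subject_kind is SubjectKind.COMPOUND else MIN_CLUSTER_TARGETS
    return n_active >= floor and n_inactive >= floor


def _candidate_features(
    actives: set[str],
    proteome: Proteome,
    include_singles: bool,
    include_pairs: bool,
) -> set[DomainFeature]:
    # Features absent from every active target have tp == 0 and cannot pass
    # any positive threshold, so candidates are drawn from actives only.
    features: set[DomainFeature] = set()
    for acc in actives:
        dset = sorted(proteome.domain_set(acc))
        if include_singles:
            features.update(DomainFeature.single(d) for d in dset)
        if include_pairs:
            for i, a in enumerate(dset):
                for b in dset[i + 1:]:
                    features.add(DomainFeature.pair(a, b))
    return features


def _score_subject(
    subject: str,
    kind: SubjectKind,
    actives: set[str],
    inactives: set[str],
    proteome: Proteome,
    hierarchy: DomainHierarchy | None,
    include_singles: bool,
    include_pairs: bool,
) -> list[CompoundFeatureMapping]:
    out = []
    for feature in _candidate_features(actives, proteome, include_singles, include_pairs):
        counts = count_confusion(actives, inactives, feature, proteome, hierarchy)
        out.append(CompoundFeatureMapping(subject, kind, feature, counts, compute_scores(counts)))
    return out


def map_all(
    dataset: InteractionDataset,
    proteome: Proteome,
    hierarchy: DomainHierarchy | None = None,
    clusters: Iterable[CompoundCluster] | None = None,
    include_singles: bool = True,
    include_pairs: bool = True,
) -> list[CompoundFeatureMapping]:
    """Score every candidate feature for every eligible subject.

    Individual compounds are scored against their own active/inactive
    targets. When ``clusters`` is given, each cluster pools the targets of
    its members (union semantics; targets with contradictory pooled labels
    are dropped with a warning), is scored as one subject, and its scores
    are propagated to every member compound. A compound holding both an
    individual and a cluster-derived score for the same feature keeps the
    maximum-MCC one.
    """
    best: dict[tuple[str, DomainFeature], CompoundFeatureMapping] = {}

    def keep(mapping: CompoundFeatureMapping) -> None:
        key = (mapping.subject, mapping.feature)
        incumbent = best.get(key)
        if incumbent is None or mapping.scores.mcc > incumbent.scores.mcc:
            best[key] = mapping

    for compound in sorted(dataset.compounds):
        actives = dataset.active_targets(compound)
        inactives = dataset.inactive_targets(compound)
        if not eligible(SubjectKind.COMPOUND, len(actives), len(inactives)):
            continue
        for m in _score_subject(
            compound, SubjectKind.COMPOUND, actives, inactives, proteome, hierarchy,
            include_singles, include_pairs,
        ):
            keep(m)

    for cluster in clusters or ():
        actives: set[str] = set()
        inactives: set[str] = set()
        for member in cluster.members:
            actives |= dataset.active_targets(member)
            inactives |= dataset.inactive_targets(member)
        conflicted = actives & inactives
        if conflicted:
            logger.warning(
                "cluster %s: %d pooled targets carry both labels; dropped", cluster.seed, len(conflicted)
            )
            actives -= conflicted
            inactives -= conflicted
        if not eligible(SubjectKind.CLUSTER, len(actives), len(inactives)):
            continue
        cluster_mappings = _score_subject(
            cluster.seed, SubjectKind.CLUSTER, actives, inactives, proteome, hierarchy,
            include_singles, include_pairs,
        )
        for member in sorted(cluster.members):
            for m in cluster_mappings:
                keep(
                    CompoundFeatureMapping(
                        subject=member,
                        subject_kind=SubjectKind.CLUSTER,
                        feature=m.feature,
                        counts=m.counts,
                        scores=m.scores,
                    )
                )

    return [best[key] for key in sorted(best, key=lambda k: (k[0], str(k[1])))]


def threshold_filter(
    mappings: Iterable[CompoundFeatureMapping],
    t: float,
    metrics: Sequence[str] = SCORE_METRICS,
) -> list[CompoundFeatureMapping]:
    """Keep mappings whose minimum over the chosen metrics is >= t.

    A threshold of 0 keeps the raw set untouched (even mappings with a
    negative MCC), matching the convention that the zero-threshold row of a
    benchmark sweep is the unfiltered mapping corpus.
    """
    if not 0 <= t <= 1:
        raise ValueError(f"threshold must be in [0, 1], got {t}")
    mappings = list(mappings)
    if t == 0:
        return mappings
    return [m for m in mappings if m.scores.minimum(metrics) >= t]


def classify_domain_pair(
    pair_mapping: CompoundFeatureMapping,
    single_mappings: Iterable[CompoundFeatureMapping],
) -> PairClass:
    """Compare a pair mapping with the subject's single-domain mappings.

    POSITIVE: the pair's MCC strictly exceeds the best constituent single
    mapping (the pair adds real specificity). NEUTRAL: equal (one domain
    suffices; the second is inert). NON_POSITIVE: below. A missing
    constituent single mapping is scored as -1.
    """
    if not pair_mapping.feature.is_pair:
        raise ValueError("classify_domain_pair requires a PAIR feature mapping")
    singles = {
        m.feature.domains[0]: m.scores.mcc
        for m in single_mappings
        if not m.feature.is_pair and m.subject == pair_mapping.subject
    }
    best_single = max(singles.get(d, -1.0) for d in pair_mapping.feature.domains)
    pair_mcc = pair_mapping.scores.mcc
    if pair_mcc > best_single:
        return PairClass.POSITIVE
    if pair_mcc == best_single:
        return PairClass.NEUTRAL
    return PairClass.NON_POSITIVE


def select_positive_pairs(mappings: Iterable[CompoundFeatureMapping]) -> list[CompoundFeatureMapping]:
    """Split singles from pairs and keep only POSITIVE pair mappings
    alongside all single-domain mappings."""
    mappings = list(mappings)
    singles = [m for m in mappings if not m.feature.is_pair]
    by_subject: dict[str, list[CompoundFeatureMapping]] = {}
    for m in singles:
        by_subject.setdefault(m.subject, []).append(m)
    kept = list(singles)
    for m in mappings:
        if m.feature.is_pair and classify_domain_pair(m, by_subject.get(m.subject, [])) is PairClass.POSITIVE:
            kept.append(m)
    return kept


MAPPING_COLUMNS = [
    "subject_id", "subject_kind", "feature",
    "tp", "fp", "fn", "tn",
    "recall", "precision", "accuracy", "f1", "mcc",
]


def mappings_to_frame(mappings: Iterable[CompoundFeatureMapping]) -> pd.DataFrame:
    rows = [
        (
            m.subject, m.subject_kind.value, str(m.feature),
            m.counts.tp, m.counts.fp, m.counts.fn, m.counts.tn,
            m.scores.recall, m.scores.precision, m.scores.accuracy, m.scores.f1, m.scores.mcc,
        )
        for m in mappings
    ]
    return pd.DataFrame(rows, columns=MAPPING_COLUMNS)


def write_mappings_tsv(mappings: Iterable[CompoundFeatureMapping], path) -> None:
    mappings_to_frame(mappings).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_mappings_tsv(path) -> list[CompoundFeatureMapping]:
    frame = pd.read_csv(path, sep="\t", comment="#")
    out = []
    for row in frame.itertuples(index=False):
        counts = ConfusionCounts(tp=int(row.tp), fp=int(row.fp), fn=int(row.fn), tn=int(row.tn))
        out.append(
            CompoundFeatureMapping(
                subject=str(row.subject_id),
                subject_kind=SubjectKind(row.subject_kind),
                feature=DomainFeature.parse(str(row.feature)),
                counts=counts,
                scores=compute_scores(counts),
            )
        )
    return out
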