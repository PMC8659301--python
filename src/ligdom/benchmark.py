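"""Benchmarking compound-domain mappings against a reference mapping set.

A reference set of (compound, domain) pairs — typically derived from
co-complex structures, so independent of assay-based evidence — is compared
with the thresholded single-domain mapping set at a grid of score
thresholds. At each threshold the evaluation restricts itself to the
compounds and domains present in *both* sets; over the cross-product
universe of those entities the fourfold counts are:

* TP — pair retrieved and in the reference,
* FP — retrieved only,
* FN — reference only,
* TN — in neither.

Coverage (shared entities over the globally intersecting entity count),
coverage extension (newly mapped entities over the same denominator), fold
enrichment of reference pairs among retrieved pairs, and an upper-tail
hypergeometric p-value complete one report row.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .mapping import (
    CompoundFeatureMapping,
    ConfusionCounts,
    MappingScores,
    SCORE_METRICS,
    compute_scores,
    threshold_filter,
)

DEFAULT_THRESHOLDS = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)


@dataclass
class ReferenceMappingSet:
    pairs: set[tuple[str, str]]

    @property
    def compounds(self) -> set[str]:
        return {c for c, _ in self.pairs}

    @property
    def domains(self) -> set[str]:
        return {d for _, d in self.pairs}


def read_reference_tsv(path) -> ReferenceMappingSet:
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"compound_id", "domain_id"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"reference table {path} lacks columns: {sorted(missing)}")
    return ReferenceMappingSet({(str(r.compound_id), str(r.domain_id)) for r in frame.itertuples(index=False)})


def write_reference_tsv(reference: ReferenceMappingSet, path) -> None:
    frame = pd.DataFrame(sorted(reference.pairs), columns=["compound_id", "domain_id"])
    frame.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class EnrichmentInput:
    """Counts for the fold-enrichment / hypergeometric test at one threshold."""

    m_t: int  # retrieved pairs that are also reference/true pairs
    n_t: int  # retrieved pairs
    M_t: int  # reference/true pairs within the restricted universe
    N_t: int  # size of the restricted universe

    def __post_init__(self) -> None:
        if min(self.m_t, self.n_t, self.M_t, self.N_t) < 0:
            raise ValueError("enrichment counts must be nonnegative")
        if self.m_t > min(self.n_t, self.M_t):
            raise ValueError("m_t cannot exceed n_t or M_t")
        if max(self.n_t, self.M_t) > self.N_t:
            raise ValueError("n_t and M_t cannot exceed the universe size N_t")


def hypergeom_pvalue(m, N: int, M: int, n: int):
    """Upper-tail hypergeometric probability P(X >= m) for X drawn as n
    samples without replacement from a universe of N with M successes.

    ``m`` may be a scalar or an array of counts.
    """
    return hypergeom.sf(np.asarray(m) - 1, N, M, n)


def enrichment(e: EnrichmentInput) -> tuple[float, float]:
    """Fold enrichment (observed/expected) and its hypergeometric p-value."""
    if e.n_t <= 0 or e.M_t <= 0:
        raise ValueError("enrichment requires n_t > 0 and M_t > 0")
    score = (e.m_t / e.n_t) / (e.M_t / e.N_t)
    p = float(hypergeom_pvalue(e.m_t, e.N_t, e.M_t, e.n_t))
    return score, p


def coverage_extension(n_mapped: int, n_shared: int, n_intersecting_total: int) -> float:
    """Fraction of the intersecting entity universe newly covered by the
    mappings but absent from the reference: (mapped - shared) / total."""
    if n_intersecting_total <= 0:
        raise ValueError("n_intersecting_total must be positive")
    if n_shared > n_mapped:
        raise ValueError("n_shared cannot exceed n_mapped")
    return (n_mapped - n_shared) / n_intersecting_total


@dataclass
class BenchmarkRow:
    threshold: float
    n_mappings: int
    n_domains: int
    n_compounds: int
    domain_coverage: float
    compound_coverage: float
    domain_coverage_extension: float
    compound_coverage_extension: float
    counts: ConfusionCounts
    scores: MappingScores
    enrichment_score: float
    p_value: float
    empty_intersection: bool = False


def benchmark_at_threshold(
    mappings: Iterable[CompoundFeatureMapping],
    reference: ReferenceMappingSet,
    t: float,
    intersecting_domains: set[str] | None = None,
    intersecting_compounds: set[str] | None = None,
    metrics: Sequence[str] = SCORE_METRICS,
) -> BenchmarkRow:
    """One benchmark report row at mapping-score threshold ``t``.

    ``intersecting_domains`` / ``intersecting_compounds`` are the global
    intersections between the *raw* mapping corpus and the reference; they
    fix the coverage denominators across thresholds. When omitted they are
    derived from the supplied mappings themselves.
    """
    singles = [m for m in mappings if not m.feature.is_pair]
    if intersecting_domains is None:
        intersecting_domains = {m.feature.domains[0] for m in singles} & reference.domains
    if intersecting_compounds is None:
        intersecting_compounds = {m.compound_id for m in singles} & reference.compounds

    retrieved = threshold_filter(singles, t, metrics=metrics)
    retrieved_pairs = {(m.compound_id, m.feature.domains[0]) for m in retrieved}
    mapped_domains = {d for _, d in retrieved_pairs}
    mapped_compounds = {c for c, _ in retrieved_pairs}

    shared_domains = mapped_domains & reference.domains
    shared_compounds = mapped_compounds & reference.compounds

    n_dom_total = len(intersecting_domains)
    n_cmp_total = len(intersecting_compounds)
    domain_coverage = len(shared_domains) / n_dom_total if n_dom_total else 0.0
    compound_coverage = len(shared_compounds) / n_cmp_total if n_cmp_total else 0.0
    dom_ext = coverage_extension(len(mapped_domains), len(shared_domains), n_dom_total) if n_dom_total else 0.0
    cmp_ext = coverage_extension(len(mapped_compounds), len(shared_compounds), n_cmp_total) if n_cmp_total else 0.0

    # Classification universe: cross product of the entities present in both
    # the thresholded mapping set and the reference.
    universe_compounds = sorted(mapped_compounds & reference.compounds)
    universe_domains = sorted(mapped_domains & reference.domains)
    n_universe = len(universe_compounds) * len(universe_domains)

    if n_universe == 0:
        counts = ConfusionCounts(0, 0, 0, 0)
        return BenchmarkRow(
            threshold=t, n_mappings=len(retrieved_pairs),
            n_domains=len(mapped_domains), n_compounds=len(mapped_compounds),
            domain_coverage=domain_coverage, compound_coverage=compound_coverage,
            domain_coverage_extension=dom_ext, compound_coverage_extension=cmp_ext,
            counts=counts, scores=compute_scores(counts),
            enrichment_score=0.0, p_value=1.0, empty_intersection=True,
        )

    cset = set(universe_compounds)
    dset = set(universe_domains)
    retrieved_in_universe = {(c, d) for c, d in retrieved_pairs if c in cset and d in dset}
    reference_in_universe = {(c, d) for c, d in reference.pairs if c in cset and d in dset}

    tp = len(retrieved_in_universe & reference_in_universe)
    fp = len(retrieved_in_universe - reference_in_universe)
    fn = len(reference_in_universe - retrieved_in_universe)
    tn = n_universe - tp - fp - fn
    counts = ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)

    if retrieved_in_universe and reference_in_universe:
        e_score, p_value = enrichment(
            EnrichmentInput(m_t=tp, n_t=len(retrieved_in_universe),
                            M_t=len(reference_in_universe), N_t=n_universe)
        )
    else:
        e_score, p_value = 0.0, 1.0

    return BenchmarkRow(
        threshold=t, n_mappings=len(retrieved_pairs),
        n_domains=len(mapped_domains), n_compounds=len(mapped_compounds),
        domain_coverage=domain_coverage, compound_coverage=compound_coverage,
        domain_coverage_extension=dom_ext, compound_coverage_extension=cmp_ext,
        counts=counts, scores=compute_scores(counts),
        enrichment_score=e_score, p_value=p_value,
    )


def benchmark_report(
    mappings: Iterable[CompoundFeatureMapping],
    reference: ReferenceMappingSet,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    metrics: Sequence[str] = SCORE_METRICS,
) -> pd.DataFrame:
    """Benchmark rows at each threshold, as a tidy DataFrame."""
    mappings = [m for m in mappings if not m.feature.is_pair]
    intersecting_domains = {m.feature.domains[0] for m in mappings} & reference.domains
    intersecting_compounds = {m.compound_id for m in mappings} & reference.compounds
    rows = []
    for t in thresholds:
        r = benchmark_at_threshold(
            mappings, reference, t,
            intersecting_domains=intersecting_domains,
            intersecting_compounds=intersecting_compounds,
            metrics=metrics,
        )
        rows.append(
            {
                "threshold": r.threshold,
                "n_mappings": r.n_mappings,
                "n_domains": r.n_domains,
                "n_compounds": r.n_compounds,
                "domain_coverage": r.domain_coverage,
                "compound_coverage": r.compound_coverage,
                "domain_coverage_extension": r.domain_coverage_extension,
                "compound_coverage_extension": r.compound_coverage_extension,
                "tp": r.counts.tp, "fp": r.counts.fp, "fn": r.counts.fn, "tn": r.counts.tn,
                "recall": r.scores.recall, "precision": r.scores.precision,
                "accuracy": r.scores.accuracy, "f1": r.scores.f1, "mcc": r.scores.mcc,
                "enrichment": r.enrichment_score, "p_value": r.p_value,
            }
        )
    return pd.DataFrame(rows)
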