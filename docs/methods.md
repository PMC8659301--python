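# Methods

## Model and assumptions

`ligdom` treats drug/compound–target interaction (DTI) prediction as a
domain-association problem. The working assumption is modularity: when a
compound is active against several proteins, the shared structural domain
(or domain pair) among those proteins is the likely interaction region,
and proteins outside the assay panel that carry the same feature are
candidate targets. Two further assumptions follow from standard
ligand-based screening practice: structurally similar compounds
(Tanimoto ≥ 0.8 over ECFP4) tend to share targets, and domains from the
same hierarchy tree (shared root in the hierarchy table) have
near-interchangeable sequence profiles, so one may stand in for another
when counting evidence.

The approach deliberately does not model binding physics, conformational
change, allostery beyond the two-domain case, or features requiring three
or more domains.

## Pipeline stages and their parameters

| Parameter | Default | Units | Why |
|---|---|---|---|
| active threshold | < 10 | μM xC50 | conventional potency bound for a plausible drug candidate |
| inactive threshold | > 20 | μM xC50 | values in (10, 20] are too ambiguous to label; the band is discarded |
| duplicate aggregation | median | — | robust to outlier replicates; even counts use the mean of the central pair |
| compound eligibility | ≥ 3 actives and ≥ 3 inactives | targets | fewer data points produce spuriously perfect scores |
| cluster eligibility | ≥ 5 actives and ≥ 5 inactives | pooled targets | pooled evidence is noisier, so the floor is higher |
| cluster Tanimoto | 0.7 | — | neighborhood radius for pooling targets of similar compounds |
| propagation Tanimoto | 0.8 | — | stricter radius for transferring finished predictions |
| mapping-score threshold | 0.5 | min of 5 metrics | operating point balancing retrieval and reliability |
| fingerprint | ECFP radius 2, 2048 bits | — | the de-facto standard circular fingerprint configuration |

Scoring: recall, precision, accuracy, F1 and Matthews correlation are
computed from the TP/FP/FN/TN partition of a subject's active and
inactive targets by feature containment. Single-domain containment is
hierarchy-aware (a same-root domain on the protein counts as a hit, both
for actives → TP and for inactives → FP); pair containment is exact, since
substituting half of an interface has no comparable justification.

## Design choices where the design was open

- **Zero-denominator metrics return 0.** Subjects whose targets are all
  hits or all misses would otherwise make precision or MCC undefined;
  defining them as 0 keeps threshold filtering total and is conservative
  (such mappings are never kept at positive thresholds).
- **Threshold 0 keeps the raw set.** The minimum-over-metrics rule would
  drop negative-MCC mappings even at t = 0; the zero-threshold row of a
  benchmark sweep is conventionally the unfiltered corpus, so t = 0 is a
  no-op.
- **Threshold filter uses all five metrics** (MCC included) as the
  strictest consistent reading; the metric list is configurable
  (`threshold_metrics`).
- **Clusters are seed-centered neighbor sets** (one overlapping cluster
  per compound), not disjoint partitions: overlap is what lets borderline
  compounds borrow evidence from every neighborhood they belong to. A
  `connected_components` mode is available for users who want disjoint
  clusters.
- **Individual-vs-cluster score conflicts keep the maximum-MCC row.**
  Cluster pooling can only be an alternative estimate of the same
  association; the better-supported one wins.
- **Candidate features are drawn from active targets only.** A feature
  absent from every active target has TP = 0 and cannot pass any positive
  threshold, so the restriction is lossless for t > 0 and avoids scoring
  the full feature universe per subject.
- **Known-pair removal covers both labels.** Predicting a recorded active
  adds nothing; predicting a recorded inactive contradicts evidence.
- **Similarity extension runs exactly one round.** Chaining Tanimoto
  neighborhoods compounds error multiplicatively.
- **Benchmark universe.** At each threshold the classification universe is
  the cross product of compounds and domains present in both the
  thresholded mapping set and the reference; coverage and coverage
  extension use the fixed global intersection (raw mappings ∩ reference)
  as denominator so rows are comparable across thresholds. Fold
  enrichment is (m/n)/(M/N) with an upper-tail hypergeometric p-value.
- **Global deduplication by default.** Taking the median across all
  sources jointly makes contradictory labels impossible by construction;
  `dedup_scope=per_source` reproduces the conservative two-stage merge in
  which contradictory pairs are dropped.
- **Band boundaries are ambiguous.** 10 μM and 20 μM themselves fall in
  the discarded band, making the three-way label partition exhaustive.

## The synthetic-world generator

The generator (`ligdom.simulate`) emulates the *data model* of a curated
bioactivity corpus, not its chemistry. A world has: a proteome with 1–3
domains per protein (average ≈ 2, matching annotated target proteomes); a
domain hierarchy; compounds with drug-like SMILES drawn from 20
hand-written scaffolds × 12 substituents (giving controllable
high-similarity neighborhoods); bioactivity records; and a planted truth
list of (compound, domain) associations.

Reference study conditions (the defaults): 50 compounds, 100 proteins, 30
domains, 25 planted associations, 5% record-level label noise, 5%
ambiguous-band injection. Each planted association is built
constructively: 8 active records (< 10 μM) against proteins containing
the domain and 8 inactive records (> 20 μM) against proteins lacking it —
comfortably above the 3+3 eligibility floor, and enough evidence that 5%
band-flip noise needs four simultaneous flips (probability ≈ 0.3%) to push
the minimum metric below 0.5. Activities are log-normal around 1 μM
(actives) and 100 μM (inactives) with σ_ln = 0.5, redrawn into band so
that *pre-noise* records are guaranteed on the correct side of the
thresholds. The remaining compounds are decoys with 2–6 records against
random proteins, mirroring real corpora in which the large majority of
compounds fall below the eligibility floor. Noise is applied per record:
with probability `ambiguous_fraction` the value is redrawn uniformly in
[10, 20] μM (and later discarded by labeling); otherwise with probability
`label_noise` the record flips to the opposite band's distribution.

Worlds default to a **flat hierarchy** (every domain its own root).
With hierarchy substitution enabled, sibling domains of a planted domain
are indistinguishable from it in the confusion counts, so ground truth
planted at individual-domain resolution is only well-posed when planted
domains have no siblings; hierarchy-aware counting is exercised by
dedicated tests with explicit multi-level hierarchies instead.

What passing tests on these worlds do and do not show: they demonstrate
that the mapping statistic recovers planted signal and rejects chance
co-occurrence under controlled noise, and that every pipeline stage
composes correctly. They do not demonstrate performance on real corpora,
where activity values are assay- and lab-dependent, domain annotations are
incomplete, active/inactive evidence is heavily imbalanced, and reference
sets are themselves partial.

## Numerical and degenerate-input conventions

- Tanimoto of two all-zero fingerprints is 0 (featureless molecules must
  not cluster as identical); unparseable SMILES exclude the compound with
  a warning rather than aborting a run.
- MCC denominators are computed in floating point after integer products;
  counts in realistic use (≤ 10⁵ targets) are far from overflow.
- Malformed bioactivity rows are skipped and counted in the run summary;
  contradictory pooled labels inside a cluster drop the affected targets
  with a warning before eligibility is rechecked.
- Pair features hold exactly two distinct ids in lexicographic order;
  homotypic (repeated-domain) pairs are not enumerated.
- Unknown domain ids are their own hierarchy roots; hierarchy cycles raise
  an error.

## Problem sizes used by the test suite and acceptance script

The acceptance script regenerates 20 replicate worlds at the reference
conditions for recovery rates, and one representative world for the
end-to-end pipeline and benchmark numbers; the structural-invariant suite
uses 100 smaller randomized worlds (12 compounds, 30 proteins, 10
domains, noise drawn in [0, 0.15]). These sizes exercise every code path
while keeping a full run in the order of seconds; scaling the generator
up is a matter of configuration, not code.

## Known limitations

- Associations are correlational: a high mapping score asserts consistency
  with the assay panel, not physical binding.
- Compounds binding domains from unrelated hierarchies are penalized by
  FN counts — the hierarchy substitution only repairs the within-tree
  case.
- The benchmark treats the reference set as ground truth although such
  sets are incomplete; enrichment (rather than raw precision) is the more
  meaningful figure when the reference is sparse.
- Identifier reconciliation between mapping and reference vocabularies is
  assumed done upstream.
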