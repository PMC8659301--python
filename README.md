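# ligdom

Statistical mapping of small-molecule compounds to protein domains — and
propagation of those mappings into large-scale drug/compound–target
interaction (DTI) predictions.

## The problem

Bioactivity databases hold millions of measured compound–protein
activities, but proteins are modular: the part of a target that actually
engages a ligand is usually one structural domain (or a pair of domains
forming an interface). If the domain responsible for binding can be
identified statistically from a compound's known active and inactive
targets, every other protein carrying that domain becomes a candidate
target — including proteins never assayed against the compound. `ligdom`
implements this chemogenomics approach end to end for computational drug
discovery and repurposing work: dataset construction from raw activity
records, compound–domain association scoring, similarity-based
propagation, and benchmarking against an independent reference mapping set.

## The statistic at the core

For a compound *C* with known **active** targets (xC50 < 10 μM) and
**inactive** targets (xC50 > 20 μM; the 10–20 μM band is discarded as
ambiguous), each candidate domain *D* partitions the targets into a
confusion matrix:

- **TP** — active targets containing *D*; **FN** — active targets lacking it;
- **FP** — inactive targets containing *D*; **TN** — inactive targets lacking it,

where "containing" is hierarchy-aware for single domains: a different
domain from the same hierarchy tree (shared root) substitutes for *D*.
From these counts the five mapping-score metrics are computed:

    recall    = TP / (TP + FN)
    precision = TP / (TP + FP)
    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    F1        = 2 · precision · recall / (precision + recall)
    MCC       = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN))

A mapping survives when the minimum of the five metrics reaches the score
threshold (default 0.5). Compounds need ≥ 3 active and ≥ 3 inactive
targets; compound clusters (overlapping Tanimoto ≥ 0.7 neighborhoods over
ECFP4 fingerprints), which pool their members' targets, need ≥ 5 of each.
Unordered domain *pairs* are scored the same way (exact containment of
both domains) and kept only when the pair's MCC strictly beats its best
constituent single-domain mapping. Surviving mappings are crossed with all
proteins containing the feature, extended once to compounds at Tanimoto
≥ 0.8, and stripped of already-recorded pairs.

Benchmarking against a reference (compound, domain) set computes, per
threshold, retrieval confusion counts over the cross product of entities
shared by both sets, coverage and coverage extension, and fold enrichment
with an upper-tail hypergeometric p-value.

## Worked example

No downloads are needed: the package generates synthetic chemogenomics
worlds with planted ground-truth associations.

```bash
ligdom simulate --seed 7 --out demo/world
ligdom run \
    --bioactivity demo/world/bioactivity.tsv \
    --annotations demo/world/domains.tsv \
    --hierarchy   demo/world/hierarchy.tsv \
    --reference   demo/world/reference.tsv \
    --pathways    demo/world/pathways.tsv \
    --out-dir     demo/run
```

The run prints its stage counts (abridged):

```
"build_dataset":  {"n_records": 505, "n_pairs": 482, "n_dropped_ambiguous": 23}
"map":            {"n_mappings": 1344, "n_singles": 525, "n_pairs": 819}
"filter":         {"n_mappings": 42}
"pairs":          {"n_mappings": 41, "n_positive_pairs": 0}
"subtract_known": {"n_predictions": 152, "n_compounds": 24, "n_proteins": 55}
"benchmark":      {"mcc_at_threshold": 0.9235}
```

Reading: 505 activity records collapse to 482 labeled pairs (23 fell in
the ambiguous 10–20 μM band); 1,344 candidate compound–feature mappings
are scored, 42 pass the 0.5 threshold, and one pair mapping is dropped for
not beating its constituent singles. Crossing the survivors with the
proteome and propagating to similar compounds yields 152 novel predicted
interactions after removing known pairs. Benchmarked against the planted
reference, the thresholded mapping set reaches MCC 0.92. The first rows of
`demo/run/mappings_filtered.tsv`:

```
subject_id  subject_kind  feature  tp  fp  fn  tn  recall  precision  accuracy  f1  mcc
SYNC0000    compound      D0000    8   0   0   8   1       1          1         1   1
SYNC0001    compound      D0001    7   0   0   7   1       1          1         1   1
```

Each row asserts that the compound's interaction region lies on the named
domain, with the confusion counts and scores that justify the claim.

Every `run` stage is also available as its own subcommand
(`build-dataset`, `fingerprint`, `cluster`, `map`, `filter`, `pairs`,
`predict`, `extend`, `subtract-known`, `pathways`, `benchmark`); composing
them reproduces the `run` output byte for byte.

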