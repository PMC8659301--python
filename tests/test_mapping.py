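import math
import random

import pytest

from conftest import protein
from ligdom.activity import ActivityLabel, InteractionDataset
from ligdom.chem import CompoundCluster
from ligdom.domains import DomainFeature, DomainHierarchy, Proteome
from ligdom.mapping import (
    CompoundFeatureMapping,
    ConfusionCounts,
    PairClass,
    SubjectKind,
    classify_domain_pair,
    compute_scores,
    count_confusion,
    eligible,
    map_all,
    read_mappings_tsv,
    select_positive_pairs,
    threshold_filter,
    write_mappings_tsv,
)


def dataset(actives: dict, inactives: dict) -> InteractionDataset:
    ds = InteractionDataset()
    for c, targets in actives.items():
        for t in targets:
            ds.add(c, t, ActivityLabel.ACTIVE)
    for c, targets in inactives.items():
        for t in targets:
            ds.add(c, t, ActivityLabel.INACTIVE)
    return ds


class TestComputeScores:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            # single-domain mapping of a demethylase inhibitor panel
            ((3, 1, 0, 2), (1.00, 0.75, 0.83, 0.86, 0.71)),
            # the corresponding domain-pair mapping: perfect separation
            ((3, 0, 0, 3), (1.00, 1.00, 1.00, 1.00, 1.00)),
            # benchmark rows with printed confusion counts
            ((80, 54, 4, 787), (0.95, 0.60, 0.94, 0.73, 0.73)),
            ((36, 3, 0, 81), (1.00, 0.92, 0.98, 0.96, 0.94)),
        ],
    )
    def test_reference_count_quadruples(self, counts, expected):
        s = compute_scores(ConfusionCounts(*counts))
        got = (s.recall, s.precision, s.accuracy, s.f1, s.mcc)
        # agreement to the printed 2-decimal precision
        assert all(abs(g - e) <= 0.005 + 1e-12 for g, e in zip(got, expected))

    def test_zero_denominators_return_zero(self):
        s = compute_scores(ConfusionCounts(0, 0, 0, 5))
        assert (s.recall, s.precision, s.f1, s.mcc) == (0.0, 0.0, 0.0, 0.0)
        assert s.accuracy == 1.0
        empty = compute_scores(ConfusionCounts(0, 0, 0, 0))
        assert empty.accuracy == 0.0

    def test_agrees_with_direct_formulas_on_random_quadruples(self):
        rng = random.Random(12345)
        for _ in range(10_000):
            tp, fp, fn, tn = (rng.randint(0, 500) for _ in range(4))
            s = compute_scores(ConfusionCounts(tp, fp, fn, tn))
            recall = tp / (tp + fn) if tp + fn else 0.0
            precision = tp / (tp + fp) if tp + fp else 0.0
            accuracy = (tp + tn) / (tp + tn + fp + fn) if tp + tn + fp + fn else 0.0
            f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
            d = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
            mcc = (tp * tn - fp * fn) / d if d else 0.0
            for ours, ref in zip(
                (s.recall, s.precision, s.accuracy, s.f1, s.mcc),
                (recall, precision, accuracy, f1, mcc),
            ):
                assert abs(ours - ref) < 1e-12

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 0)


class TestCountConfusion:
    def test_demethylase_panel_single_domain(self, demethylase_like_proteome):
        counts = count_confusion(
            actives={"ACT1", "ACT2", "ACT3"},
            inactives={"INA1", "INA2", "INA3"},
            feature=DomainFeature.single("dA"),
            proteome=demethylase_like_proteome,
        )
        assert (counts.tp, counts.fp, counts.fn, counts.tn) == (3, 1, 0, 2)

    def test_demethylase_panel_domain_pair(self, demethylase_like_proteome):
        counts = count_confusion(
            actives={"ACT1", "ACT2", "ACT3"},
            inactives={"INA1", "INA2", "INA3"},
            feature=DomainFeature.pair("dA", "dB"),
            proteome=demethylase_like_proteome,
        )
        assert (counts.tp, counts.fp, counts.fn, counts.tn) == (3, 0, 0, 3)

    def test_perfect_separation(self):
        proteome = Proteome([protein("A1", "d"), protein("A2", "d"), protein("I1", "x"), protein("I2", "y")])
        counts = count_confusion({"A1", "A2"}, {"I1", "I2"}, DomainFeature.single("d"), proteome)
        assert (counts.tp, counts.fp, counts.fn, counts.tn) == (2, 0, 0, 2)

    def test_hierarchy_sibling_counts_as_hit(self):
        # A2 lacks d but carries its sibling: TP with the hierarchy, FN without
        h = DomainHierarchy({"d": "root", "sib": "root", "root": "root"})
        proteome = Proteome([protein("A1", "d"), protein("A2", "sib"), protein("I1", "x")])
        with_h = count_confusion({"A1", "A2"}, {"I1"}, DomainFeature.single("d"), proteome, h)
        assert (with_h.tp, with_h.fn) == (2, 0)
        without = count_confusion({"A1", "A2"}, {"I1"}, DomainFeature.single("d"), proteome, None)
        assert (without.tp, without.fn) == (1, 1)

    def test_hierarchy_sibling_in_inactive_counts_as_fp(self):
        h = DomainHierarchy({"d": "root", "sib": "root"})
        proteome = Proteome([protein("A1", "d"), protein("I1", "sib")])
        counts = count_confusion({"A1"}, {"I1"}, DomainFeature.single("d"), proteome, h)
        assert (counts.fp, counts.tn) == (1, 0)

    def test_pair_features_ignore_hierarchy_substitution(self):
        h = DomainHierarchy({"d1": "root", "sib": "root"})
        proteome = Proteome([protein("A1", "sib", "d2")])
        counts = count_confusion({"A1"}, set(), DomainFeature.pair("d1", "d2"), proteome, h)
        assert counts.tp == 0 and counts.fn == 1

    def test_hierarchy_monotonicity(self):
        # adding a sibling domain to an active target never decreases tp,
        # and to an inactive target never decreases fp
        h = DomainHierarchy({"d": "root", "sib": "root"})
        base = Proteome([protein("A1", "x"), protein("I1", "y")])
        richer = Proteome([protein("A1", "x", "sib"), protein("I1", "y", "sib")])
        f = DomainFeature.single("d")
        before = count_confusion({"A1"}, {"I1"}, f, base, h)
        after = count_confusion({"A1"}, {"I1"}, f, richer, h)
        assert after.tp >= before.tp and after.fp >= before.fp

    def test_overlapping_labels_rejected(self, demethylase_like_proteome):
        with pytest.raises(ValueError, match="both active and inactive"):
            count_confusion({"ACT1"}, {"ACT1"}, DomainFeature.single("dA"), demethylase_like_proteome)

    def test_unknown_accession_named_in_error(self, demethylase_like_proteome):
        with pytest.raises(KeyError, match="GHOST"):
            count_confusion({"GHOST"}, set(), DomainFeature.single("dA"), demethylase_like_proteome)


class TestEligibility:
    @pytest.mark.parametrize(
        "kind, n_active, n_inactive, expected",
        [
            (SubjectKind.COMPOUND, 3, 3, True),
            (SubjectKind.COMPOUND, 10, 2, False),
            (SubjectKind.COMPOUND, 2, 10, False),
            (SubjectKind.CLUSTER, 5, 5, True),
            (SubjectKind.CLUSTER, 5, 4, False),
            (SubjectKind.CLUSTER, 4, 100, False),
        ],
    )
    def test_floors(self, kind, n_active, n_inactive, expected):
        assert eligible(kind, n_active, n_inactive) is expected

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            eligible(SubjectKind.COMPOUND, -1, 3)


class TestMapAll:
    @pytest.fixture
    def toy(self):
        # actives share the "blue" domain; inactives carry other domains
        proteome = Proteome(
            [
                protein("A1", "blue"), protein("A2", "blue"), protein("A3", "blue", "red"),
                protein("I1", "red"), protein("I2", "red"), protein("I3", "green"),
            ]
        )
        ds = dataset({"c1": {"A1", "A2", "A3"}}, {"c1": {"I1", "I2", "I3"}})
        return proteome, ds

    def test_shared_domain_scores_perfectly(self, toy):
        proteome, ds = toy
        mappings = map_all(ds, proteome, include_pairs=False)
        by_feature = {str(m.feature): m for m in mappings}
        blue = by_feature["blue"]
        assert (blue.counts.tp, blue.counts.fp, blue.counts.fn, blue.counts.tn) == (3, 0, 0, 3)
        assert blue.scores.mcc == 1.0

    def test_single_candidate_world_emits_one_mapping(self):
        proteome = Proteome(
            [protein("A1", "d"), protein("A2", "d"), protein("A3", "d"),
             protein("I1"), protein("I2"), protein("I3")]
        )
        # proteins without hits never appear; give inactives an unrelated domain
        proteome = Proteome(
            [protein("A1", "d"), protein("A2", "d"), protein("A3", "d"),
             protein("I1", "z"), protein("I2", "z"), protein("I3", "z")]
        )
        ds = dataset({"c": {"A1", "A2", "A3"}}, {"c": {"I1", "I2", "I3"}})
        mappings = map_all(ds, proteome, include_pairs=False)
        assert len(mappings) == 1 and str(mappings[0].feature) == "d"

    def test_ineligible_compounds_skipped(self, toy):
        proteome, _ = toy
        ds = dataset({"c1": {"A1", "A2"}}, {"c1": {"I1", "I2", "I3"}})  # only 2 actives
        assert map_all(ds, proteome) == []

    def test_candidates_limited_to_active_domains(self, toy):
        proteome, ds = toy
        features = {str(m.feature) for m in map_all(ds, proteome, include_pairs=False)}
        assert "green" not in features  # occurs only in inactives

    def test_count_conservation(self, toy):
        proteome, ds = toy
        for m in map_all(ds, proteome):
            assert m.counts.tp + m.counts.fn == len(ds.active_targets(m.subject))
            assert m.counts.fp + m.counts.tn == len(ds.inactive_targets(m.subject))

    def test_pair_tp_bounded_by_single_tp(self):
        proteome = Proteome(
            [protein("A1", "g", "r"), protein("A2", "g", "r"), protein("A3", "g"),
             protein("I1", "x"), protein("I2", "x"), protein("I3", "r")]
        )
        ds = dataset({"c": {"A1", "A2", "A3"}}, {"c": {"I1", "I2", "I3"}})
        mappings = {str(m.feature): m for m in map_all(ds, proteome, hierarchy=None)}
        assert mappings["g+r"].counts.tp <= mappings["g"].counts.tp
        assert mappings["g+r"].counts.tp <= mappings["r"].counts.tp

    def test_cluster_pooling_and_propagation(self):
        proteome = Proteome(
            [protein(f"A{i}", "d") for i in range(1, 6)]
            + [protein(f"I{i}", "x") for i in range(1, 6)]
        )
        # each member alone is ineligible; pooled, the cluster reaches 5+5
        ds = dataset(
            {"c1": {"A1", "A2", "A3"}, "c2": {"A3", "A4", "A5"}},
            {"c1": {"I1", "I2", "I3"}, "c2": {"I3", "I4", "I5"}},
        )
        clusters = [CompoundCluster(seed="c1", members={"c1", "c2"})]
        mappings = map_all(ds, proteome, clusters=clusters, include_pairs=False)
        subjects = {(m.subject, m.subject_kind) for m in mappings}
        # individual mappings for both compounds plus cluster-derived nothing new:
        # compounds are eligible individually (3+3) and cluster-derived scores
        # propagate to both members; max-MCC merge keeps one row per (subject, feature)
        assert ("c1", SubjectKind.COMPOUND) in subjects or ("c1", SubjectKind.CLUSTER) in subjects
        per_subject = [m for m in mappings if str(m.feature) == "d"]
        assert {m.subject for m in per_subject} == {"c1", "c2"}
        assert all(m.scores.mcc == 1.0 for m in per_subject)

    def test_cluster_conflicting_pooled_labels_dropped(self, caplog):
        proteome = Proteome(
            [protein(f"A{i}", "d") for i in range(1, 7)] + [protein(f"I{i}", "x") for i in range(1, 7)]
        )
        ds = dataset(
            {"c1": {"A1", "A2", "A3", "A4", "A5"}, "c2": {"I1"}},
            {"c1": {"I1", "I2", "I3", "I4", "I5"}, "c2": {"A1"}},
        )
        clusters = [CompoundCluster(seed="c1", members={"c1", "c2"})]
        with caplog.at_level("WARNING"):
            mappings = map_all(ds, proteome, clusters=clusters, include_pairs=False)
        assert any("both labels" in r.message for r in caplog.records)
        # A1 and I1 carry both pooled labels and are dropped, leaving 4+4:
        # below the 5+5 cluster floor, so no cluster-derived rows survive
        assert [m for m in mappings if m.subject_kind is SubjectKind.CLUSTER] == []
        # c1 stays individually eligible (5+5) and is still mapped
        assert any(m.subject == "c1" and m.subject_kind is SubjectKind.COMPOUND for m in mappings)


class TestThresholdFilter:
    def make(self, counts):
        c = ConfusionCounts(*counts)
        return CompoundFeatureMapping("c", SubjectKind.COMPOUND, DomainFeature.single("d"), c, compute_scores(c))

    def test_perfect_scores_pass_high_threshold(self):
        assert threshold_filter([self.make((3, 0, 0, 3))], 0.9)

    def test_min_rule_drops_on_weakest_metric(self):
        # recall 1.00 but MCC 0.71: the five-metric minimum fails t=0.8
        assert threshold_filter([self.make((3, 1, 0, 2))], 0.8) == []
        # with MCC excluded, min is precision 0.75: still fails 0.8
        assert threshold_filter([self.make((3, 1, 0, 2))], 0.8,
                                metrics=("recall", "precision", "accuracy", "f1")) == []
        assert threshold_filter([self.make((3, 1, 0, 2))], 0.75,
                                metrics=("recall", "precision", "accuracy", "f1")) != []

    def test_zero_threshold_keeps_all(self):
        mappings = [self.make((3, 1, 0, 2)), self.make((0, 5, 5, 0))]
        assert threshold_filter(mappings, 0.0) == mappings

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            threshold_filter([], 1.5)


class TestPairClassification:
    def mapping(self, feature, counts, subject="c"):
        c = ConfusionCounts(*counts)
        return CompoundFeatureMapping(subject, SubjectKind.COMPOUND, feature, c, compute_scores(c))

    def test_pair_beating_both_singles_is_positive(self):
        pair = self.mapping(DomainFeature.pair("dA", "dB"), (3, 0, 0, 3))
        singles = [
            self.mapping(DomainFeature.single("dA"), (3, 1, 0, 2)),
            self.mapping(DomainFeature.single("dB"), (3, 1, 0, 2)),
        ]
        assert classify_domain_pair(pair, singles) is PairClass.POSITIVE

    def test_pair_equal_to_best_single_is_neutral(self):
        pair = self.mapping(DomainFeature.pair("dA", "dB"), (3, 1, 0, 2))
        singles = [self.mapping(DomainFeature.single("dA"), (3, 1, 0, 2))]
        assert classify_domain_pair(pair, singles) is PairClass.NEUTRAL

    def test_pair_below_singles_is_non_positive(self):
        pair = self.mapping(DomainFeature.pair("dA", "dB"), (2, 2, 2, 2))
        singles = [self.mapping(DomainFeature.single("dA"), (3, 0, 0, 3))]
        assert classify_domain_pair(pair, singles) is PairClass.NON_POSITIVE

    def test_missing_singles_score_minus_one(self):
        pair = self.mapping(DomainFeature.pair("dA", "dB"), (1, 3, 3, 1))  # negative MCC
        assert classify_domain_pair(pair, []) is PairClass.POSITIVE

    def test_requires_pair_feature(self):
        single = self.mapping(DomainFeature.single("dA"), (3, 0, 0, 3))
        with pytest.raises(ValueError):
            classify_domain_pair(single, [])

    def test_select_positive_pairs_keeps_singles(self):
        pair_pos = self.mapping(DomainFeature.pair("dA", "dB"), (3, 0, 0, 3))
        pair_neu = self.mapping(DomainFeature.pair("dA", "dC"), (3, 1, 0, 2))
        single = self.mapping(DomainFeature.single("dA"), (3, 1, 0, 2))
        kept = select_positive_pairs([single, pair_pos, pair_neu])
        assert single in kept and pair_pos in kept and pair_neu not in kept


def test_mappings_tsv_round_trip(tmp_path, demethylase_like_proteome):
    ds = dataset({"c": {"ACT1", "ACT2", "ACT3"}}, {"c": {"INA1", "INA2", "INA3"}})
    mappings = map_all(ds, demethylase_like_proteome)
    path = tmp_path / "mappings.tsv"
    write_mappings_tsv(mappings, path)
    back = read_mappings_tsv(path)
    assert len(back) == len(mappings)
    original = {(m.subject, str(m.feature)): m.counts for m in mappings}
    for m in back:
        assert original[(m.subject, str(m.feature))] == m.counts
        assert m.scores == compute_scores(m.counts)
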