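"""Dataset construction: filtering, redundancy, negative sampling, splits."""

import itertools

import numpy as np
import pytest

from sscppi import (
    InteractionPair,
    ProteinRecord,
    STANDARD_RESIDUES,
    degree_threshold_filter,
    filter_proteins,
    global_identity,
    make_splits,
    reduce_redundancy,
    sample_edited_negatives,
    sample_location_negatives,
    sample_random_negatives,
)
from sscppi.dataset import assemble_negatives, pair_key


def seq(n, rng=None, base="ACDEFGHIKLMNPQRSTVWY"):
    if rng is None:
        return (base * (n // 20 + 1))[:n]
    return "".join(rng.choice(list(base), size=n))


class TestLengthFilter:
    def test_boundary_lengths_are_inclusive(self, fixtures):
        kept, log = filter_proteins(fixtures["boundary_records"])
        assert {r.id for r in kept} == {"len20", "len1800"}
        reasons = dict(log)
        assert "too short" in reasons["len19"]
        assert "too long" in reasons["len1801"]

    def test_nonstandard_residue_rejected_with_reason(self):
        rec = ProteinRecord("px", "ACDEFGHIKLMNPQRSTVWX")
        kept, log = filter_proteins([rec])
        assert kept == [] and log == [("px", "nonstandard residue")]

    def test_map_to_zero_policy_keeps_nonstandard(self):
        rec = ProteinRecord("px", "ACDEFGHIKLMNPQRSTVWX")
        kept, _ = filter_proteins([rec], nonstandard_policy="map_to_zero")
        assert kept == [rec]

    def test_empty_collection(self):
        assert filter_proteins([]) == ([], [])


class TestRedundancyReduction:
    def test_identical_sequences_collapse(self):
        a = ProteinRecord("a", seq(40))
        b = ProteinRecord("b", seq(40))
        assert [r.id for r in reduce_redundancy([a, b])] == ["a"]

    def test_50_percent_identity_below_threshold_keeps_both(self):
        # substitution-only difference of an equal-length pair: edit-distance
        # identity equals positional identity
        s1 = "A" * 20 + "C" * 20
        s2 = "A" * 20 + "D" * 20
        assert global_identity(s1, s2) == pytest.approx(0.5)
        kept = reduce_redundancy(
            [ProteinRecord("a", s1), ProteinRecord("b", s2)], 0.60
        )
        assert len(kept) == 2

    def test_greedy_trace_drops_only_the_near_duplicate(self):
        base = seq(40)
        near = base[:35] + "WWWWW"  # ~87% identical to base
        far = "W" * 10 + "Y" * 10 + "H" * 10 + "Q" * 10
        kept = reduce_redundancy(
            [
                ProteinRecord("A", base),
                ProteinRecord("B", near),
                ProteinRecord("C", far),
            ]
        )
        assert {r.id for r in kept} == {"A", "C"}


class TestRandomNegatives:
    def test_complement_enumeration_on_tiny_universe(self):
        prots = [ProteinRecord(i, seq(25)) for i in "abc"]
        pos = [InteractionPair("a", "b", 1)]
        negs = sample_random_negatives(pos, prots, 2, seed=0)
        assert {p.key for p in negs} == {("a", "c"), ("b", "c")}
        assert all(p.label == 0 and p.provenance == "random_neg" for p in negs)

    def test_zero_request_and_overflow(self):
        prots = [ProteinRecord(i, seq(25)) for i in "abc"]
        pos = [InteractionPair("a", "b", 1)]
        assert sample_random_negatives(pos, prots, 0) == []
        with pytest.raises(ValueError):
            sample_random_negatives(pos, prots, 3)

    def test_never_emits_a_recorded_positive_and_reproducible(self, random_records):
        rng = np.random.default_rng(5)
        ids = [r.id for r in random_records]
        pos = [
            InteractionPair(a, b, 1)
            for a, b in itertools.combinations(ids, 2)
            if rng.random() < 0.3
        ]
        negs1 = sample_random_negatives(pos, random_records, 20, seed=9)
        negs2 = sample_random_negatives(pos, random_records, 20, seed=9)
        assert [p.key for p in negs1] == [p.key for p in negs2]
        pos_keys = {p.key for p in pos}
        assert not ({p.key for p in negs1} & pos_keys)
        assert len({p.key for p in negs1}) == 20


class TestLocationNegatives:
    def records(self):
        return [
            ProteinRecord("p1", seq(25), {"nucleus"}),
            ProteinRecord("p2", seq(25), {"membrane"}),
            ProteinRecord("p3", seq(25), {"nucleus", "cytosol"}),
            ProteinRecord("p4", seq(25), {"cytosol"}),
        ]

    def test_disjoint_pairs_match_brute_force(self):
        prots = self.records()
        eligible = {
            pair_key(a.id, b.id)
            for a, b in itertools.combinations(prots, 2)
            if not (a.localization & b.localization)
        }
        got = sample_location_negatives(prots, [], len(eligible), seed=0)
        assert {p.key for p in got} == eligible

    def test_shared_term_pair_is_ineligible(self):
        prots = self.records()
        negs = sample_location_negatives(prots, [], 4, seed=0)
        assert ("p3", "p4") not in {p.key for p in negs}  # share cytosol

    def test_insufficient_pairs_reports_achievable_count(self):
        prots = self.records()[:2]
        with pytest.raises(ValueError, match="only 1"):
            sample_location_negatives(prots, [], 5)


class TestEditedNegatives:
    def make_positive(self, rng):
        a = ProteinRecord("a", seq(20, rng))
        b = ProteinRecord("b", seq(20, rng))
        return [a, b], [InteractionPair("a", "b", 1)]

    def test_hamming_difference_matches_drawn_fraction(self, rng):
        records, pos = self.make_positive(rng)
        by_id = {r.id: r for r in records}
        for f in (0.2, 0.5, 0.8):
            pairs, variants = sample_edited_negatives(
                pos, records, 1, edit_fraction_range=(f, f), seed=3
            )
            v = variants[0]
            original = by_id[v.id.split("__")[0]].sequence
            diffs = sum(x != y for x, y in zip(original, v.sequence))
            assert diffs == round(f * 20)

    def test_substituted_residue_never_equals_original(self, rng):
        records, pos = self.make_positive(rng)
        by_id = {r.id: r for r in records}
        pairs, variants = sample_edited_negatives(pos, records, 1, seed=8)
        v = variants[0]
        original = by_id[v.id.split("__")[0]].sequence
        assert all(
            x == y or (x != y)  # every differing site is a true substitution
            for x, y in zip(original, v.sequence)
        )
        assert len(v.sequence) == len(original)

    def test_labels_and_provenance(self, rng):
        records, pos = self.make_positive(rng)
        pairs, _ = sample_edited_negatives(pos, records, 1, seed=1)
        assert pairs[0].label == 0 and pairs[0].provenance == "edited_neg"

    def test_empty_positive_set_is_an_error(self):
        with pytest.raises(ValueError):
            sample_edited_negatives([], [], 1)


class TestDegreeThresholdFilter:
    def _pairs(self, edges):
        return [InteractionPair(a, b, 1) for a, b in edges]

    def test_star_graph_center_only_has_degree(self):
        pairs = self._pairs([("c", f"l{i}") for i in range(5)])
        assert degree_threshold_filter(pairs, 2) == []
        assert len(degree_threshold_filter(pairs, 1)) == 5
        assert len(degree_threshold_filter(pairs, 0)) == 5

    def test_triangle_survives_threshold_two(self):
        pairs = self._pairs([("a", "b"), ("b", "c"), ("a", "c")])
        assert len(degree_threshold_filter(pairs, 2)) == 3

    @pytest.mark.parametrize("trial", range(5))
    def test_agrees_with_brute_force_on_random_graphs(self, trial):
        rng = np.random.default_rng(100 + trial)
        nodes = [f"n{i}" for i in range(int(rng.integers(5, 30)))]
        edges = [
            (a, b)
            for a, b in itertools.combinations(nodes, 2)
            if rng.random() < 0.15
        ]
        pairs = self._pairs(edges)
        threshold = int(rng.integers(0, 5))
        degree = {n: sum(n in e for e in edges) for n in nodes}
        expected = [
            (a, b)
            for a, b in edges
            if degree[a] >= threshold and degree[b] >= threshold
        ]
        got = [(p.id_a, p.id_b) for p in degree_threshold_filter(pairs, threshold)]
        assert got == expected


class TestSplits:
    def _balanced_pairs(self, n_per_class):
        pos = [InteractionPair(f"p{i}", f"q{i}", 1) for i in range(n_per_class)]
        neg = [
            InteractionPair(f"p{i}", f"r{i}", 0, "random_neg")
            for i in range(n_per_class)
        ]
        return pos + neg

    def test_stratified_80_20_arithmetic(self):
        split = make_splits(self._balanced_pairs(100), seed=4)
        assert len(split.train) == 160 and len(split.test) == 40
        assert sum(p.label for p in split.train) == 80
        assert sum(p.label for p in split.test) == 20

    def test_five_folds_partition_the_training_set(self):
        split = make_splits(self._balanced_pairs(100), seed=4)
        assert [len(f) for f in split.folds] == [32] * 5
        fold_keys = [frozenset((p.id_a, p.id_b) for p in f) for f in split.folds]
        train_keys = {(p.id_a, p.id_b) for p in split.train}
        assert set().union(*fold_keys) == train_keys
        assert sum(len(f) for f in fold_keys) == len(train_keys)

    def test_same_seed_reproduces_identical_splits(self):
        pairs = self._balanced_pairs(50)
        s1 = make_splits(pairs, seed=7)
        s2 = make_splits(pairs, seed=7)
        assert [(p.id_a, p.id_b) for p in s1.train] == [
            (p.id_a, p.id_b) for p in s2.train
        ]

    def test_train_test_disjoint(self):
        split = make_splits(self._balanced_pairs(50), seed=2)
        assert not (
            {(p.id_a, p.id_b) for p in split.train}
            & {(p.id_a, p.id_b) for p in split.test}
        )

    def test_single_class_and_tiny_class_errors(self):
        with pytest.raises(ValueError):
            make_splits([InteractionPair("a", "b", 1)] * 10)
        pairs = self._balanced_pairs(3)  # 3 per class < 5 folds
        with pytest.raises(ValueError):
            make_splits(pairs, k=5)


class TestAssembly:
    def test_balance_and_global_uniqueness(self, random_records):
        ids = [r.id for r in random_records]
        pos = [
            InteractionPair(a, b, 1)
            for a, b in itertools.combinations(ids[:8], 2)
        ]
        negs, variants = assemble_negatives(
            pos, random_records, total=len(pos), seed=3
        )
        assert len(negs) == len(pos)  # exact 1:1 balance
        keys = [p.key for p in negs]
        assert len(set(keys)) == len(keys)
        assert not ({p.key for p in negs} & {p.key for p in pos})
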