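"""Overlap, frequency, consensus, weighted merge, partition, gene mapping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sigmin import (
    AnnotationMap,
    Signature,
    SignatureCollection,
    ValidationError,
    consensus_set,
    endpoint_partition,
    map_probes_to_genes,
    overlap_matrix,
    overlap_rate,
    probe_frequency,
    weighted_merge,
)
from sigmin.similarity import FrequencyTable, endpoint_partition_from_collections


def make_collection(probe_lists, endpoint="D"):
    return SignatureCollection(
        endpoint_id=endpoint,
        signatures=[
            Signature(model_id=f"m{i}", endpoint_id=endpoint, probes=list(ps))
            for i, ps in enumerate(probe_lists)
        ],
    )


probe_list = st.lists(
    st.text(alphabet="abcdefgh", min_size=1, max_size=2), min_size=1, max_size=8
)


class TestOverlapMatrix:
    def test_hand_count(self):
        coll = make_collection([["a", "b", "c"], ["b", "c", "d", "e"]])
        om = overlap_matrix(coll)
        np.testing.assert_array_equal(om.counts, [[3, 2], [2, 4]])

    def test_identical_signatures(self):
        coll = make_collection([["a", "b"], ["a", "b"], ["a", "b"]])
        assert (overlap_matrix(coll).counts == 2).all()

    def test_single_signature_rejected(self):
        with pytest.raises(ValidationError):
            overlap_matrix(make_collection([["a"]]))

    @settings(max_examples=50, derandomize=True)
    @given(lists=st.lists(probe_list, min_size=2, max_size=5))
    def test_matches_brute_force_set_intersection(self, lists):
        coll = make_collection(lists)
        om = overlap_matrix(coll)
        sets = [set(ps) for ps in lists]
        for i in range(len(sets)):
            assert om.counts[i, i] == len(sets[i])
            for j in range(len(sets)):
                assert om.counts[i, j] == len(sets[i] & sets[j])
                assert om.counts[i, j] <= min(om.counts[i, i], om.counts[j, j])


class TestFrequencyAndConsensus:
    def test_hand_supports(self):
        freq = probe_frequency(make_collection([["a", "b"], ["b", "c"]]))
        assert freq.support == {"a": 1, "b": 2, "c": 1}

    def test_single_signature_all_supports_one(self):
        freq = probe_frequency(make_collection([["a", "b", "c"]]))
        assert set(freq.support.values()) == {1}

    @settings(max_examples=50, derandomize=True)
    @given(lists=st.lists(probe_list, min_size=1, max_size=6))
    def test_matches_brute_force_membership_count(self, lists):
        freq = probe_frequency(make_collection(lists))
        allp = set().union(*[set(ps) for ps in lists])
        for p in allp:
            assert freq.support[p] == sum(p in set(ps) for ps in lists)

    def test_consensus_threshold(self):
        freq = FrequencyTable({"a": 1, "b": 2, "c": 1})
        assert consensus_set(freq, 2) == {"b"}
        assert consensus_set(freq, 1) == {"a", "b", "c"}

    def test_consensus_above_max_support_is_empty_with_warning(self):
        freq = FrequencyTable({"a": 1})
        with pytest.warns(UserWarning):
            assert consensus_set(freq, 5) == frozenset()

    @settings(max_examples=50, derandomize=True)
    @given(lists=st.lists(probe_list, min_size=1, max_size=6),
           s1=st.integers(1, 4), s2=st.integers(1, 4))
    def test_consensus_antitone_in_min_support(self, lists, s1, s2):
        import warnings

        freq = probe_frequency(make_collection(lists))
        lo, hi = min(s1, s2), max(s1, s2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert consensus_set(freq, hi) <= consensus_set(freq, lo)

    def test_ranking_breaks_ties_lexicographically(self):
        freq = FrequencyTable({"z": 2, "a": 2, "m": 3})
        assert freq.ranked() == [("m", 3), ("a", 2), ("z", 2)]


class TestOverlapRate:
    @pytest.mark.parametrize(
        "total, overlapped, expected",
        [
            (1747, 345, 19.75),
            (1760, 644, 36.59),
            (100, 100, 100.00),
        ],
    )
    def test_reported_rate(self, total, overlapped, expected):
        assert overlap_rate(total, overlapped) == expected

    def test_zero_total_rejected(self):
        with pytest.raises(ValidationError):
            overlap_rate(0, 0)

    def test_half_up_rounding(self):
        # 0.125% rounds up to 0.13, not banker's 0.12.
        assert overlap_rate(800, 1) == 0.13


class TestWeightedMerge:
    def test_hand_sum(self):
        coll = make_collection([["a", "b"], ["b"]])
        got = weighted_merge(coll, {"m0": 2.0, "m1": 1.0})
        assert got == [("b", 3.0), ("a", 2.0)]

    def test_unit_weights_reduce_to_frequency_order(self):
        coll = make_collection([["a", "b"], ["b", "c"], ["c", "b"]])
        merged = weighted_merge(coll, {"m0": 1.0, "m1": 1.0, "m2": 1.0})
        freq = probe_frequency(coll)
        assert [p for p, _ in merged] == [p for p, _ in freq.ranked()]
        assert all(w == freq.support[p] for p, w in merged)

    def test_missing_weight_rejected(self):
        with pytest.raises(ValidationError):
            weighted_merge(make_collection([["a"], ["b"]]), {"m0": 1.0})

    def test_negative_weight_rejected(self):
        with pytest.raises(ValidationError):
            weighted_merge(make_collection([["a"], ["b"]]), {"m0": 1.0, "m1": -1.0})

    @settings(max_examples=50, derandomize=True)
    @given(lists=st.lists(probe_list, min_size=1, max_size=5), data=st.data())
    def test_matches_brute_force_accumulation(self, lists, data):
        coll = make_collection(lists)
        weights = {
            f"m{i}": data.draw(st.floats(0, 5, allow_nan=False))
            for i in range(len(lists))
        }
        merged = dict(weighted_merge(coll, weights))
        for p in set().union(*[set(ps) for ps in lists]):
            expected = sum(
                weights[f"m{i}"] for i, ps in enumerate(lists) if p in set(ps)
            )
            assert merged[p] == pytest.approx(expected)


class TestEndpointPartition:
    def test_hand_partition(self):
        ps = endpoint_partition({"a", "b"}, {"b", "c"})
        assert ps.common == {"b"}
        assert ps.percentages == (33.33, 33.33, 33.33)

    def test_identical_sets_fully_common(self):
        ps = endpoint_partition({"a", "b"}, {"a", "b"})
        assert ps.percentages == (100.0, 0.0, 0.0)

    def test_empty_union_rejected(self):
        with pytest.raises(ValidationError):
            endpoint_partition(set(), set())

    @settings(max_examples=100, derandomize=True)
    @given(a=st.sets(st.integers(0, 30)), b=st.sets(st.integers(0, 30)))
    def test_blocks_disjoint_and_percentages_sum_to_100(self, a, b):
        if not (a | b):
            return
        ps = endpoint_partition({str(x) for x in a}, {str(x) for x in b})
        assert not (ps.common & ps.unique_a)
        assert not (ps.common & ps.unique_b)
        assert not (ps.unique_a & ps.unique_b)
        assert sum(ps.percentages) == pytest.approx(100, abs=0.011)

    def test_from_collections_at_support_threshold(self):
        coll_a = make_collection([["a", "b"], ["b", "c"]], "D")
        coll_b = make_collection([["b", "d"], ["b", "d"]], "E")
        ps = endpoint_partition_from_collections(coll_a, coll_b)
        assert ps.common == {"b"}
        assert ps.unique_b == {"d"}


class TestProbeGeneMapping:
    ann = AnnotationMap(
        {
            "p1": [("GENE1", "protein-coding")],
            "p2": [("GENE1", "alias-group"), ("GENE1A", "alias-group")],
            "p3": [("PSEUDO", "pseudogene")],
            "p4": [("HYPO", "hypothetical"), ("GENE4", "protein-coding")],
            "p5": [("GENE5", "protein-coding"), ("GENE6", "protein-coding")],
        }
    )

    def test_single_gene_maps_directly(self):
        genes, _ = map_probes_to_genes(["p1"], self.ann)
        assert genes == {"GENE1"}

    def test_alias_group_collapses_to_first(self):
        genes, report = map_probes_to_genes(["p2"], self.ann)
        assert genes == {"GENE1"}
        assert report["alias_collapsed"] == ["p2"]

    def test_pseudogene_excluded_and_reported(self):
        genes, report = map_probes_to_genes(["p3"], self.ann)
        assert genes == frozenset()
        assert report["all_excluded_classes"] == ["p3"]

    def test_hypothetical_dropped_before_mapping(self):
        genes, _ = map_probes_to_genes(["p4"], self.ann)
        assert genes == {"GENE4"}

    def test_ambiguous_probe_policy(self):
        genes, report = map_probes_to_genes(["p5"], self.ann)
        assert genes == frozenset() and report["ambiguous_excluded"] == ["p5"]
        genes_first, _ = map_probes_to_genes(["p5"], self.ann, policy="first")
        assert genes_first == {"GENE5"}

    def test_unannotated_probe_reported_not_fatal(self):
        genes, report = map_probes_to_genes(["zzz"], self.ann)
        assert genes == frozenset() and report["unannotated"] == ["zzz"]

    def test_gene_total_never_exceeds_probe_total(self):
        genes, _ = map_probes_to_genes(["p1", "p2", "p3", "p4", "p5"], self.ann)
        assert len(genes) <= 5
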