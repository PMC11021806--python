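"""Seed clustering, the variant filter, and the merge rules."""

import itertools

import numpy as np
import pytest

from barclust import (
    Params,
    Variant,
    build_neighbor_index,
    build_seed_clusters,
    filter_candidate_variants,
    jaccard,
    merge_all,
    try_merge,
)
from barclust.clustering import _make_cluster
from barclust.extraction import ExtractedRead

from oracles import dfs_components


def _v(pos, qual=93):
    return Variant(pos, "A", "G", qual)


def _read(rid, barcode, variants=()):
    return ExtractedRead(rid, (barcode,), 93, frozenset(variants))


def _cluster(cid, barcode, n_reads, variants=(), params=Params(), prefix=None):
    prefix = prefix or f"{barcode}_{cid}"
    reads = [_read(f"{prefix}_{i:03d}", barcode, variants) for i in range(n_reads)]
    return _make_cluster(cid, reads, [barcode] * n_reads, params)


class TestJaccard:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ({_v(1)}, {_v(1)}, 1.0),
            ({_v(1)}, {_v(2)}, 0.0),
            ({_v(1), _v(2), _v(3)}, {_v(2), _v(3), _v(4)}, 0.5),
            (set(), set(), 1.0),
            (set(), {_v(1)}, 0.0),
        ],
    )
    def test_values(self, a, b, expected):
        assert jaccard(frozenset(a), frozenset(b)) == expected


class TestVariantFilter:
    def test_multi_read_variant_kept_regardless_of_quality(self):
        reads = [_read(f"r{i}", "AAAA", [_v(10, qual=20 + 5 * i)]) for i in range(3)]
        out = filter_candidate_variants(reads, min_var_qual=90)
        assert all(_v(10) in s for s in out)

    def test_single_read_high_quality_variant_kept(self):
        reads = [_read("r0", "AAAA", [_v(10, qual=93)]), _read("r1", "AAAA"), _read("r2", "AAAA")]
        out = filter_candidate_variants(reads, min_var_qual=90)
        assert _v(10) in out[0]

    def test_single_read_low_quality_variant_removed(self):
        reads = [_read("r0", "AAAA", [_v(10, qual=30)]), _read("r1", "AAAA"), _read("r2", "AAAA")]
        out = filter_candidate_variants(reads, min_var_qual=90)
        assert out[0] == frozenset()

    def test_boundary_quality_kept_at_threshold(self):
        reads = [_read("r0", "AAAA", [_v(10, qual=90)]), _read("r1", "AAAA")]
        out = filter_candidate_variants(reads, min_var_qual=90)
        assert _v(10) in out[0]


class TestSeedClusters:
    def test_coherent_reads_group_incoherent_split(self, params):
        reads = [
            _read("rA", "AAAA", [_v(1), _v(2)]),
            _read("rB", "AAAA", [_v(1), _v(2)]),
            _read("rC", "AAAA", [_v(3), _v(4)]),
        ]
        clusters = build_seed_clusters(reads, params, "AAAA")
        members = sorted(tuple(r.read_id for r in c.reads) for c in clusters)
        assert members == [("rA", "rB"), ("rC",)]

    def test_all_wt_reads_form_one_cluster(self, params):
        reads = [_read(f"r{i}", "AAAA") for i in range(4)]
        clusters = build_seed_clusters(reads, params, "AAAA")
        assert len(clusters) == 1 and clusters[0].size == 4
        assert clusters[0].is_wt

    def test_jaccard_half_links_reads(self, params):
        reads = [
            _read("r0", "AAAA", [_v(1), _v(2), _v(3)]),
            _read("r1", "AAAA", [_v(2), _v(3), _v(4)]),
        ]
        clusters = build_seed_clusters(reads, params, "AAAA")
        assert len(clusters) == 1

    @pytest.mark.parametrize("trial", range(30))
    def test_components_match_dfs_oracle(self, trial, params):
        rng = np.random.default_rng(4000 + trial)
        n = int(rng.integers(2, 12))
        # random variant sets over a pool of 6 positions
        reads = []
        for i in range(n):
            pool = rng.random(6) < 0.4
            reads.append(
                _read(f"r{i}", "AAAA", [_v(p) for p in range(6) if pool[p]])
            )
        filt = filter_candidate_variants(reads, params.min_var_qual)
        edges = [
            (i, j)
            for i in range(n)
            for j in range(i + 1, n)
            if (not filt[i] and not filt[j])
            or jaccard(filt[i], filt[j]) >= params.jaccard_min
        ]
        expected = dfs_components(n, edges)
        clusters = build_seed_clusters(reads, params, "AAAA")
        got = sorted(
            sorted(int(r.read_id[1:]) for r in c.reads) for c in clusters
        )
        assert got == expected


class TestTryMerge:
    def _index(self, *barcodes):
        return build_neighbor_index(set(barcodes), max_ed=2)

    def test_divergent_sizes_accept(self, params):
        a = _cluster(0, "AAAAAAAA", 8, [_v(1)])
        b = _cluster(1, "AAAAAAAT", 1, [_v(1)])
        ok, reason = try_merge(a, b, 1, params, self._index("AAAAAAAA", "AAAAAAAT"))
        assert ok, reason  # |log2(8/1)| = 3 > 1

    def test_similar_sizes_reject(self, params):
        a = _cluster(0, "AAAAAAAA", 4, [_v(1)])
        b = _cluster(1, "AAAAAAAT", 3, [_v(1)])
        ok, reason = try_merge(a, b, 1, params, self._index("AAAAAAAA", "AAAAAAAT"))
        assert not ok and reason == "size_divergence"  # |log2(4/3)| ~ 0.415 <= 1

    def test_disjoint_genotypes_reject(self, params):
        a = _cluster(0, "AAAAAAAA", 16, [_v(1)])
        b = _cluster(1, "AAAAAATT", 1, [_v(2)])
        ok, reason = try_merge(a, b, 2, params, self._index("AAAAAAAA", "AAAAAATT"))
        assert not ok and reason == "genotype_mismatch"

    def test_pooled_refilter_rescues_shared_low_quality_variant(self, params):
        # the variant is single-read (low qual) in each cluster, but pooling
        # makes it double-read, so condition (i) sees matching genotypes
        a_reads = [_read("a0", "AAAAAAAA", [_v(5, qual=30)])] + [
            _read(f"a{i}", "AAAAAAAA") for i in range(1, 8)
        ]
        a = _make_cluster(0, a_reads, ["AAAAAAAA"] * 8, params)
        b = _make_cluster(1, [_read("b0", "AAAAAAAT", [_v(5, qual=30)])], ["AAAAAAAT"], params)
        assert a.filtered_genotype == frozenset()
        ok, reason = try_merge(a, b, 1, params, self._index("AAAAAAAA", "AAAAAAAT"))
        assert ok, reason

    def test_diameter_rejection(self, params):
        # a already spans ED 2 (AAAA..CC); b at ED 2 from one key but 4 from the other
        reads = [_read(f"a{i}", "AAAAAAAA") for i in range(8)] + [
            _read("a8", "AAAAAACC")
        ]
        a = _make_cluster(0, reads, ["AAAAAAAA"] * 8 + ["AAAAAACC"], params)
        b = _make_cluster(1, [_read("b0", "AAAATTAA")], ["AAAATTAA"], params)
        idx = build_neighbor_index({"AAAAAAAA", "AAAAAACC", "AAAATTAA"}, max_ed=2)
        ok, reason = try_merge(a, b, 2, params, idx)
        assert not ok and reason == "diameter_exceeded"


class TestMergeAll:
    def test_single_accepted_merge(self, params):
        a = _cluster(0, "AAAAAAAA", 10, [_v(1)])
        b = _cluster(1, "AAAAAAAT", 1, [_v(1)])
        idx = build_neighbor_index({"AAAAAAAA", "AAAAAAAT"}, max_ed=2)
        out = merge_all([a, b], idx, params)
        assert len(out) == 1 and out[0].size == 11

    def test_mutually_distant_input_unchanged(self, params):
        seeds = [
            _cluster(0, "AAAAAAAA", 3, [_v(1)]),
            _cluster(1, "CCCCCCCC", 4, [_v(2)]),
            _cluster(2, "GGGGGGGG", 5, [_v(3)]),
        ]
        idx = build_neighbor_index({c.barcode_key for c in seeds}, max_ed=2)
        out = merge_all(seeds, idx, params)
        assert sorted(c.size for c in out) == [3, 4, 5]

    def _offshoot_instance(self, params):
        parent = _cluster(0, "AAAAAAAAAA", 20, [_v(1)], prefix="p")
        # offshoots at ED 1-2 from the parent and mutually within ED 2, so
        # the final partition is independent of merge order on this instance
        offs = [
            _cluster(1, "AAAAAAAAAT", 1, [_v(1)], prefix="o1"),
            _cluster(2, "AAAAAAAAAC", 1, [_v(1)], prefix="o2"),
            _cluster(3, "AAAAAAAAGT", 1, [_v(1)], prefix="o3"),
        ]
        keys = {c.barcode_key for c in [parent] + offs}
        return [parent] + offs, build_neighbor_index(keys, max_ed=2)

    def test_parent_absorbs_offshoots(self, params):
        seeds, idx = self._offshoot_instance(params)
        out = merge_all(seeds, idx, params)
        assert len(out) == 1 and out[0].size == 23

    def test_exhaustive_merge_order_search_agrees(self, params):
        """Every legal merge order reaches the same final partition here."""
        seeds, idx = self._offshoot_instance(params)

        def signature(clusters):
            return frozenset(
                frozenset(r.read_id for r in c.reads) for c in clusters
            )

        finals = set()

        def explore(clusters, next_id):
            moves = []
            for a, b in itertools.combinations(clusters, 2):
                from barclust.clustering import pair_min_ed

                ed = pair_min_ed(a, b, idx)
                if ed is None or not 1 <= ed <= params.max_ed:
                    continue
                if try_merge(a, b, ed, params, idx)[0]:
                    moves.append((a, b))
            if not moves:
                finals.add(signature(clusters))
                return
            for a, b in moves:
                from barclust.clustering import _merge_clusters

                rest = [c for c in clusters if c is not a and c is not b]
                explore(rest + [_merge_clusters(a, b, next_id, params)], next_id + 1)

        explore(list(seeds), 100)
        assert len(finals) == 1
        out = merge_all(seeds, idx, params)
        assert signature(out) in finals

    def test_partition_and_diameter_invariants(self, params):
        seeds, idx = self._offshoot_instance(params)
        total = sum(c.size for c in seeds)
        out = merge_all(seeds, idx, params)
        all_reads = [r.read_id for c in out for r in c.reads]
        assert len(all_reads) == total and len(set(all_reads)) == total
        from barclust import levenshtein

        for c in out:
            for ka in c.keys:
                for kb in c.keys:
                    assert levenshtein(ka, kb) <= params.max_ed

    def test_read_order_invariance(self, params, rng):
        a = _cluster(0, "AAAAAAAA", 6, [_v(1)], prefix="a")
        b = _cluster(1, "AAAAAAAT", 1, [_v(1)], prefix="b")
        c = _cluster(2, "AAAAAAGG", 2, [_v(9)], prefix="c")
        idx = build_neighbor_index({"AAAAAAAA", "AAAAAAAT", "AAAAAAGG"}, max_ed=2)

        def signature(clusters):
            return sorted(
                (c.barcode_key, tuple(r.read_id for r in c.reads)) for c in clusters
            )

        ref_sig = signature(merge_all([a, b, c], idx, params))
        for perm in itertools.permutations([a, b, c]):
            assert signature(merge_all(list(perm), idx, params)) == ref_sig
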