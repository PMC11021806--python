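"""Read clustering: genotype-coherent seeds, then edit-distance merging.

Reads sharing an identical barcode are first split into *seed clusters*:
after discarding putative sequencing errors (candidate variants seen in only
one read and below the quality threshold), a graph connects two reads when
both are wild-type or their filtered variant sets have Jaccard index at or
above the threshold; each connected component (including singletons) seeds a
cluster.

Clusters with similar but nonidentical barcodes are then merged iteratively.
A candidate pair, taken at the minimum barcode edit distance ``ed`` between
any two member reads (ascending, up to ``max_ed``), is accepted only if

(i)   after re-filtering errors on the pooled reads, both sides are
      wild-type or their genotypes have Jaccard >= threshold,
(ii)  no pair of reads in the pooled cluster exceeds ``max_ed`` barcode
      edit distance, and
(iii) the cluster sizes are sufficiently divergent: |log2(s1/s2)| > ed,
      as expected when one cluster is a satellite of barcode miscalls
      around a better-sampled parent.

Tie-breaking beyond ascending ``ed`` (descending combined size, then
lexicographic barcode keys, then cluster ids) makes the merge order, and
hence the output, deterministic for any input order.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx

from .design_io import Params
from .distance import BarcodeNeighborIndex
from .extraction import ExtractedRead, Variant


def jaccard(a: frozenset, b: frozenset) -> float:
    """Jaccard index of two variant sets; two empty sets count as identical
    (1.0), making the wild-type rule a special case rather than an exception.
    """
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def filter_candidate_variants(
    reads: Sequence[ExtractedRead], min_var_qual: int
) -> list[frozenset[Variant]]:
    """Per-read filtered variant sets.

    A candidate variant is removed iff it occurs in exactly one of the given
    reads AND its quality is below ``min_var_qual``.  Variants seen in two or
    more reads are kept regardless of quality.
    """
    counts: Counter = Counter()
    for r in reads:
        counts.update(r.variants)
    return [
        frozenset(v for v in r.variants if counts[v] >= 2 or v.qual >= min_var_qual)
        for r in reads
    ]


def filtered_union(
    reads: Sequence[ExtractedRead], min_var_qual: int
) -> frozenset[Variant]:
    sets = filter_candidate_variants(reads, min_var_qual)
    out: set = set()
    for s in sets:
        out |= s
    return frozenset(out)


@dataclass(frozen=True)
class Cluster:
    """A set of reads believed to originate from one clone."""

    cluster_id: int
    reads: tuple[ExtractedRead, ...]
    key_counts: tuple[tuple[str, int], ...]  # (barcode key, read count), sorted
    filtered_genotype: frozenset[Variant]

    @property
    def size(self) -> int:
        return len(self.reads)

    @property
    def is_wt(self) -> bool:
        return not self.filtered_genotype

    @property
    def keys(self) -> tuple[str, ...]:
        return tuple(k for k, _ in self.key_counts)

    @property
    def barcode_key(self) -> str:
        """Representative barcode: the most common key, ties to the
        lexicographically smallest."""
        return min(self.key_counts, key=lambda kc: (-kc[1], kc[0]))[0]


def _make_cluster(
    cluster_id: int,
    reads: Sequence[ExtractedRead],
    keys: Sequence[str],
    params: Params,
) -> Cluster:
    order = sorted(range(len(reads)), key=lambda i: reads[i].read_id)
    reads_sorted = tuple(reads[i] for i in order)
    kc = Counter(keys[i] for i in order)
    return Cluster(
        cluster_id=cluster_id,
        reads=reads_sorted,
        key_counts=tuple(sorted(kc.items())),
        filtered_genotype=filtered_union(reads_sorted, params.min_var_qual),
    )


def build_seed_clusters(
    reads: Sequence[ExtractedRead],
    params: Params,
    barcode_key: str,
    id_start: int = 0,
) -> list[Cluster]:
    """Seed clusters for one identical-barcode read set.

    Edges join reads that are both wild-type after filtering or whose
    filtered variant sets reach the Jaccard threshold; connected components
    (and singletons) become clusters.
    """
    reads = sorted(reads, key=lambda r: r.read_id)
    filtered = filter_candidate_variants(reads, params.min_var_qual)
    g = nx.Graph()
    g.add_nodes_from(range(len(reads)))
    for i in range(len(reads)):
        for j in range(i + 1, len(reads)):
            fi, fj = filtered[i], filtered[j]
            if (not fi and not fj) or jaccard(fi, fj) >= params.jaccard_min:
                g.add_edge(i, j)
    comps = sorted((sorted(c) for c in nx.connected_components(g)), key=lambda c: c[0])
    clusters = []
    for offset, comp in enumerate(comps):
        members = [reads[i] for i in comp]
        clusters.append(
            _make_cluster(
                id_start + offset, members, [barcode_key] * len(members), params
            )
        )
    return clusters


def pair_min_ed(a: Cluster, b: Cluster, index: BarcodeNeighborIndex) -> Optional[int]:
    """Minimum barcode edit distance between member reads of two clusters,
    or None when every pair is beyond ``index.max_ed``."""
    best: Optional[int] = None
    for ka in a.keys:
        for kb in b.keys:
            d = index.distance(ka, kb)
            if d is not None and (best is None or d < best):
                best = d
    return best


def try_merge(
    a: Cluster,
    b: Cluster,
    ed: int,
    params: Params,
    index: BarcodeNeighborIndex,
) -> tuple[bool, str]:
    """Evaluate the three merge-acceptance conditions for one cluster pair.

    Error filtering is re-run on the pooled reads, so a variant that is
    single-read in each cluster but double-read when pooled survives.
    """
    pooled = list(a.reads) + list(b.reads)
    filtered = filter_candidate_variants(pooled, params.min_var_qual)
    ga: set = set()
    for s in filtered[: a.size]:
        ga |= s
    gb: set = set()
    for s in filtered[a.size :]:
        gb |= s
    if (ga or gb) and jaccard(frozenset(ga), frozenset(gb)) < params.jaccard_min:
        return False, "genotype_mismatch"
    for ka in a.keys:
        for kb in b.keys:
            if index.distance(ka, kb) is None:
                return False, "diameter_exceeded"
    if abs(math.log2(a.size) - math.log2(b.size)) <= ed:
        return False, "size_divergence"
    return True, "ok"


def merge_all(
    seed_clusters: Sequence[Cluster],
    index: BarcodeNeighborIndex,
    params: Params,
    audit: Optional[list] = None,
) -> list[Cluster]:
    """Iteratively merge clusters until no acceptable candidate remains.

    Candidates are processed in ascending ``ed``, then descending combined
    size, then lexicographic barcode keys; rejected pairs are not retried
    unless one side changes (merging assigns a fresh cluster id).  The output
    clusters partition the input reads.
    """
    clusters: dict[int, Cluster] = {c.cluster_id: c for c in seed_clusters}
    next_id = (max(clusters) + 1) if clusters else 0
    rejected: set[frozenset] = set()

    # map barcode key -> ids of clusters containing it
    def owners() -> dict[str, set[int]]:
        own: dict[str, set[int]] = {}
        for cid, c in clusters.items():
            for k in c.keys:
                own.setdefault(k, set()).add(cid)
        return own

    while True:
        own = owners()
        pair_ids: set[frozenset] = set()
        for k, ids in own.items():
            neigh = index.neighbors_of(k)
            for kn in neigh:
                for cid in ids:
                    for cid2 in own.get(kn, ()):  # pragma: no branch
                        if cid2 != cid:
                            pair_ids.add(frozenset((cid, cid2)))
        candidates = []
        for pid in pair_ids:
            if pid in rejected:
                continue
            ida, idb = sorted(pid)
            a, b = clusters[ida], clusters[idb]
            ed = pair_min_ed(a, b, index)
            if ed is None or not 1 <= ed <= params.max_ed:
                continue
            keys = tuple(sorted((a.barcode_key, b.barcode_key)))
            candidates.append((ed, -(a.size + b.size), keys, ida, idb))
        candidates.sort()
        accepted_any = False
        for ed, _, _, ida, idb in candidates:
            a, b = clusters[ida], clusters[idb]
            ok, reason = try_merge(a, b, ed, params, index)
            if audit is not None:
                audit.append(
                    {
                        "cluster_a": a.barcode_key,
                        "cluster_b": b.barcode_key,
                        "ed": ed,
                        "decision": "accept" if ok else "reject",
                        "reason": reason,
                    }
                )
            if ok:
                merged = _merge_clusters(a, b, next_id, params)
                del clusters[ida], clusters[idb]
                clusters[next_id] = merged
                next_id += 1
                accepted_any = True
                break
            rejected.add(frozenset((ida, idb)))
        if not accepted_any:
            break
    return [clusters[cid] for cid in sorted(clusters)]


def _merge_clusters(a: Cluster, b: Cluster, new_id: int, params: Params) -> Cluster:
    reads = tuple(sorted(a.reads + b.reads, key=lambda r: r.read_id))
    kc: Counter = Counter(dict(a.key_counts))
    kc.update(dict(b.key_counts))
    return Cluster(
        cluster_id=new_id,
        reads=reads,
        key_counts=tuple(sorted(kc.items())),
        filtered_genotype=filtered_union(reads, params.min_var_qual),
    )
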