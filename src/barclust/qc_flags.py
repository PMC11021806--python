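"""Post-clustering quality flags.

Three independent diagnostics on the final cluster set:

* **Nonunique barcodes** — a consensus barcode carried by two or more final
  clusters is associated with multiple genotypes in the library.  It is
  *remediable* when a single clone holds strictly more than two thirds
  (configurable) of the barcode's reads, since that clone would dominate
  downstream readouts for the barcode.
* **PCR crossover chimeras** — with dual flanking barcodes, a recombinant
  molecule shows up as clusters sharing an identical upstream barcode and
  overlapping genotypes but entirely different downstream barcodes
  ("entirely different" operationalized as edit distance beyond merge range,
  ``max_ed + 1`` by default).  Wild-type/wild-type pairs are never linked: a
  crossover between two wild-type clones is unobservable in genotype space.
* **Homopolymer context** — indel calls whose reference position is the 5'
  end of a homopolymer run of length >= 4, the classic false-positive indel
  context of long-read basecalling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .consensus import FinalCluster
from .design_io import Params
from .distance import levenshtein
from .errors import ConfigError, TwoLociRequiredError
from .extraction import Variant

UNIQUE = "unique"
NONUNIQUE_REMEDIABLE = "nonunique_remediable"
NONUNIQUE = "nonunique"


@dataclass(frozen=True)
class BarcodeCollisionReport:
    barcode: str
    cluster_ids: tuple[int, ...]
    total_reads: int
    dominant_fraction: float
    status: str


@dataclass(frozen=True)
class ChimeraSet:
    upstream_barcode: str
    cluster_ids: tuple[int, ...]
    overlap_kind: str  # complete | partial


def detect_nonunique(
    final_clusters: Sequence[FinalCluster], params: Params
) -> list[BarcodeCollisionReport]:
    """Group final clusters by their clustering (consensus) barcode and
    classify each barcode as unique / nonunique / nonunique-but-remediable."""
    groups: dict[str, list[FinalCluster]] = {}
    for fc in final_clusters:
        groups.setdefault(fc.clustering_barcode, []).append(fc)
    reports = []
    for barcode in sorted(groups):
        members = sorted(groups[barcode], key=lambda fc: fc.cluster.cluster_id)
        total = sum(fc.size for fc in members)
        dominant = max(fc.size for fc in members) / total
        if len(members) == 1:
            status = UNIQUE
        elif dominant > params.remediable_fraction:
            status = NONUNIQUE_REMEDIABLE
        else:
            status = NONUNIQUE
        reports.append(
            BarcodeCollisionReport(
                barcode=barcode,
                cluster_ids=tuple(fc.cluster.cluster_id for fc in members),
                total_reads=total,
                dominant_fraction=dominant,
                status=status,
            )
        )
    return reports


def detect_chimeras(
    final_clusters: Sequence[FinalCluster], params: Params
) -> list[ChimeraSet]:
    """Find sets of clusters consistent with PCR crossover events.

    Within each identical-upstream-barcode group, two clusters are linked
    when their genotypes intersect (complete = equal sets, partial =
    nonempty intersection) and their downstream barcodes are at edit
    distance >= ``chimera_downstream_min_ed``.  Connected components of
    linked clusters with >= 2 members form chimera sets; a deterministic
    greedy pass keeps members pairwise beyond the downstream threshold.
    """
    for fc in final_clusters:
        if len(fc.consensus.consensus_barcodes) < 2:
            raise TwoLociRequiredError(
                "chimera detection requires two barcode loci"
            )
    groups: dict[str, list[FinalCluster]] = {}
    for fc in final_clusters:
        groups.setdefault(fc.up_barcode, []).append(fc)
    out = []
    for up in sorted(groups):
        members = sorted(groups[up], key=lambda fc: fc.cluster.cluster_id)
        if len(members) < 2:
            continue
        idx = {fc.cluster.cluster_id: fc for fc in members}
        parent = {cid: cid for cid in idx}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        linked = set()
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                if not (a.genotype & b.genotype):
                    continue
                if (
                    levenshtein(
                        a.down_barcode,
                        b.down_barcode,
                        max_ed=params.chimera_downstream_min_ed,
                    )
                    < params.chimera_downstream_min_ed
                ):
                    continue
                ra, rb = find(a.cluster.cluster_id), find(b.cluster.cluster_id)
                parent[max(ra, rb)] = min(ra, rb)
                linked.add(a.cluster.cluster_id)
                linked.add(b.cluster.cluster_id)
        comps: dict[int, list[int]] = {}
        for cid in idx:
            if cid in linked:
                comps.setdefault(find(cid), []).append(cid)
        for root in sorted(comps):
            cids = comps[root]
            # greedy pairwise-distance enforcement, larger clusters first
            ordered = sorted(cids, key=lambda cid: (-idx[cid].size, cid))
            kept: list[int] = []
            for cid in ordered:
                if all(
                    levenshtein(
                        idx[cid].down_barcode,
                        idx[other].down_barcode,
                        max_ed=params.chimera_downstream_min_ed,
                    )
                    >= params.chimera_downstream_min_ed
                    for other in kept
                ):
                    kept.append(cid)
            if len(kept) < 2:
                continue
            genos = [idx[cid].genotype for cid in kept]
            kind = "complete" if all(g == genos[0] for g in genos) else "partial"
            out.append(
                ChimeraSet(
                    upstream_barcode=up,
                    cluster_ids=tuple(sorted(kept)),
                    overlap_kind=kind,
                )
            )
    return out


def homopolymer_flag(variant: Variant, reference: str, min_run: int = 4) -> bool:
    """True iff the indel's reference position is the first (5'-most) base of
    a maximal single-base run of length >= ``min_run``."""
    if variant.vtype == "SNV":
        raise ConfigError("homopolymer_flag applies to indels only")
    p = variant.ref_pos
    if not 0 <= p < len(reference):
        return False
    base = reference[p]
    if p > 0 and reference[p - 1] == base:
        return False  # not the 5' end of the run
    end = p
    while end < len(reference) and reference[end] == base:
        end += 1
    return end - p >= min_run
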