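"""Per-cluster consensus barcodes, final genotypes, protein consequences.

Consensus barcodes use a center-star multiple alignment: every member
barcode is globally aligned (unit costs, deterministic tie-breaks) to the
most frequent member string, and each alignment column is resolved by
majority, with gap-majority columns deleted and ties going to the
lexicographically smallest non-gap base.

Protein consequences follow a simplified HGVS-style dialect (three-letter
amino acids, ``fs`` without extension length):

* ``p.Ala2Thr`` missense, ``p.Glu2Ter`` nonsense, ``p.Glu2=`` synonymous
  (position-specific; plain ``p.=`` is reserved for wild-type clones),
* ``p.Glu2fs`` frameshift at the first affected codon,
* ``p.Lys3del`` / ``p.Lys3_Leu4ins...`` / ``p....delins...`` for in-frame
  indels,
* ``nc.123A>G`` for variants outside the ORF, and ``boundary:...`` for
  variants straddling an ORF edge.

When several SNVs hit one codon the codon is translated once with all of
them applied and reported as a single combined record.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

from Bio.Data.CodonTable import standard_dna_table
from Bio.SeqUtils import seq3

from .clustering import Cluster, filtered_union
from .design_io import LibraryDesign, Params
from .extraction import Variant

_CODON = standard_dna_table.forward_table  # codon -> 1-letter aa, no stops


def _translate_codon(codon: str) -> str:
    if codon in standard_dna_table.stop_codons:
        return "*"
    return _CODON[codon]


def _aa3(aa1: str) -> str:
    return "Ter" if aa1 == "*" else seq3(aa1)


def _translate(seq: str) -> str:
    """Translate full codons; stops become '*' and translation continues."""
    return "".join(
        _translate_codon(seq[i : i + 3]) for i in range(0, len(seq) - len(seq) % 3, 3)
    )


# ---------------------------------------------------------------------------
# consensus barcode


def _nw_path(s: str, t: str) -> list[int]:
    """Unit-cost global alignment path of s against t.

    Returns op codes: 0 diagonal, 1 gap-in-s (t consumed), 2 gap-in-t
    (s consumed).  Ties prefer diagonal, then gap-in-s.
    """
    n, m = len(s), len(t)
    dist = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        dist[i][0] = i
    for j in range(1, m + 1):
        dist[0][j] = j
    for i in range(1, n + 1):
        si = s[i - 1]
        row, prev = dist[i], dist[i - 1]
        for j in range(1, m + 1):
            row[j] = min(
                prev[j - 1] + (si != t[j - 1]),
                prev[j] + 1,
                row[j - 1] + 1,
            )
    ops: list[int] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and dist[i][j] == dist[i - 1][j - 1] + (s[i - 1] != t[j - 1]):
            ops.append(0)
            i -= 1
            j -= 1
        elif j > 0 and dist[i][j] == dist[i][j - 1] + 1:
            ops.append(1)
            j -= 1
        else:
            ops.append(2)
            i -= 1
    return ops[::-1]


def consensus_barcode(barcodes: Sequence[str]) -> str:
    """Column-majority consensus over a center-star alignment."""
    if not barcodes:
        raise ValueError("consensus of an empty barcode list")
    counts = Counter(barcodes)
    center = min(counts, key=lambda b: (-counts[b], b))
    if len(counts) == 1:
        return center
    n = len(barcodes)
    L = len(center)
    col_counts: list[Counter] = [Counter() for _ in range(L)]
    ins_slots: dict[tuple[int, int], Counter] = {}
    for s, w in sorted(counts.items()):
        ops = _nw_path(s, center)
        i = j = 0
        run = 0
        for op in ops:
            if op == 0:
                col_counts[j][s[i]] += w
                i += 1
                j += 1
                run = 0
            elif op == 1:  # center base with no s base -> implicit gap
                j += 1
                run = 0
            else:  # s base inserted after center position j-1
                ins_slots.setdefault((j - 1, run), Counter())[s[i]] += w
                i += 1
                run += 1

    def resolve(counter: Counter) -> str:
        gap = n - sum(counter.values())
        base, cnt = min(counter.items(), key=lambda kv: (-kv[1], kv[0]))
        return "" if gap > cnt else base

    out = []
    k = 0
    while (-1, k) in ins_slots:  # insertions before the first center column
        out.append(resolve(ins_slots[(-1, k)]))
        k += 1
    for p in range(L):
        out.append(resolve(col_counts[p]))
        k = 0
        while (p, k) in ins_slots:  # insertions after center column p
            out.append(resolve(ins_slots[(p, k)]))
            k += 1
    return "".join(out)


# ---------------------------------------------------------------------------
# genotype and protein consequences


def final_genotype(cluster: Cluster, params: Params) -> list[Variant]:
    """Union of error-filtered variants over the cluster's reads, sorted by
    position then alleles."""
    g = filtered_union(cluster.reads, params.min_var_qual)
    return sorted(g, key=lambda v: (v.ref_pos, v.ref_allele, v.alt_allele))


def translate_variants(
    genotype_nt: Sequence[Variant], design: LibraryDesign
) -> list[str]:
    """Protein-level consequences of a nucleotide genotype.

    Synonymous records are omitted when any other consequence exists; a
    genotype consisting only of synonymous SNVs reports them explicitly so
    that the result is never confused with wild-type (``p.=``).
    """
    s, e = design.orf.start, design.orf.end
    orf_seq = design.reference_seq[s:e]
    snvs_by_codon: dict[int, list[Variant]] = {}
    results: list[tuple[int, str, bool]] = []  # (sort position, string, synonymous)

    for v in sorted(genotype_nt, key=lambda v: (v.ref_pos, v.ref_allele, v.alt_allele)):
        if v.vtype == "SNV":
            if s <= v.ref_pos < e:
                snvs_by_codon.setdefault((v.ref_pos - s) // 3, []).append(v)
            else:
                results.append((v.ref_pos, f"nc.{v.nt_string()}", False))
            continue
        if v.vtype == "insertion":
            if not s < v.ref_pos < e:
                results.append((v.ref_pos, f"nc.{v.nt_string()}", False))
                continue
        else:  # deletion
            if v.end <= s or v.ref_pos >= e:
                results.append((v.ref_pos, f"nc.{v.nt_string()}", False))
                continue
            if v.ref_pos < s or v.end > e:
                results.append((v.ref_pos, f"boundary:{v.nt_string()}", False))
                continue
        results.append((v.ref_pos, _indel_consequence(v, s, orf_seq), False))

    for ci in sorted(snvs_by_codon):
        codon = list(orf_seq[ci * 3 : ci * 3 + 3])
        for v in snvs_by_codon[ci]:
            codon[(v.ref_pos - s) % 3] = v.alt_allele
        aa_ref = _translate_codon(orf_seq[ci * 3 : ci * 3 + 3])
        aa_alt = _translate_codon("".join(codon))
        pos = s + ci * 3
        if aa_alt == aa_ref:
            results.append((pos, f"p.{_aa3(aa_ref)}{ci + 1}=", True))
        else:
            results.append((pos, f"p.{_aa3(aa_ref)}{ci + 1}{_aa3(aa_alt)}", False))

    results.sort(key=lambda r: (r[0], r[1]))
    non_syn = [r for r in results if not r[2]]
    kept = non_syn if non_syn else results
    return [r[1] for r in kept]


def _indel_consequence(v: Variant, orf_start: int, orf_seq: str) -> str:
    """Consequence string for an indel fully inside the ORF."""
    off = v.ref_pos - orf_start
    indel_len = len(v.ref_allele) or len(v.alt_allele)
    ref_aas = _translate(orf_seq)

    def res(ci: int) -> str:
        return f"{_aa3(ref_aas[ci])}{ci + 1}"

    if indel_len % 3 != 0:
        ci = off // 3
        return f"p.{res(ci)}fs"

    if v.vtype == "deletion":
        ci, cj = off // 3, (off + indel_len - 1) // 3
        if off % 3 == 0:
            if ci == cj:
                return f"p.{res(ci)}del"
            return f"p.{res(ci)}_{res(cj)}del"
        window = orf_seq[ci * 3 : off] + orf_seq[off + indel_len : (cj + 1) * 3]
        return f"p.{res(ci)}_{res(cj)}delins{_aa3_str(_translate(window))}"

    # in-frame insertion
    if off % 3 == 0:
        ci = off // 3
        pep = _aa3_str(_translate(v.alt_allele))
        if ci == 0:
            return f"p.{res(0)}ins{pep}"
        return f"p.{res(ci - 1)}_{res(ci)}ins{pep}"
    ci = off // 3
    window = orf_seq[ci * 3 : off] + v.alt_allele + orf_seq[off : (ci + 1) * 3]
    return f"p.{res(ci)}delins{_aa3_str(_translate(window))}"


def _aa3_str(aas: str) -> str:
    return "".join(_aa3(a) for a in aas)


# ---------------------------------------------------------------------------
# cluster finalization


@dataclass(frozen=True)
class ConsensusResult:
    cluster_id: int
    consensus_barcodes: tuple[str, ...]
    genotype_nt: tuple[Variant, ...]
    genotype_aa: tuple[str, ...]

    @property
    def wt(self) -> bool:
        return not self.genotype_nt


@dataclass(frozen=True)
class FinalCluster:
    """A cluster plus its consensus annotations, ready for reporting."""

    cluster: Cluster
    consensus: ConsensusResult
    clustering_barcode: str  # consensus of the key used for clustering

    @property
    def size(self) -> int:
        return self.cluster.size

    @property
    def up_barcode(self) -> str:
        return self.consensus.consensus_barcodes[0]

    @property
    def down_barcode(self) -> str:
        bcs = self.consensus.consensus_barcodes
        return bcs[1] if len(bcs) > 1 else ""

    @property
    def virtual_barcode(self) -> str:
        return "".join(self.consensus.consensus_barcodes)

    @property
    def genotype(self) -> frozenset[Variant]:
        return frozenset(self.consensus.genotype_nt)


def finalize_cluster(
    cluster: Cluster,
    design: LibraryDesign,
    params: Params,
    virtual_barcodes: bool = True,
) -> FinalCluster:
    """Derive consensus barcodes, the final genotype and its translation."""
    per_locus = tuple(
        consensus_barcode([r.barcodes[li] for r in cluster.reads])
        for li in range(design.n_loci)
    )
    nt = final_genotype(cluster, params)
    aa = tuple(translate_variants(nt, design)) if nt else ("p.=",)
    cons = ConsensusResult(
        cluster_id=cluster.cluster_id,
        consensus_barcodes=per_locus,
        genotype_nt=tuple(nt),
        genotype_aa=aa,
    )
    key = "".join(per_locus) if virtual_barcodes else per_locus[0]
    return FinalCluster(cluster=cluster, consensus=cons, clustering_barcode=key)
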