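"""Synthetic barcoded mutagenized libraries with full ground truth.

The generator emulates a MAVE-style clone library sequenced with HiFi-like
long reads: each clone is the reference amplicon with one to a few planted
ORF variants and random barcode(s); reads are drawn per clone at Poisson
depth and corrupted with substitution and indel errors at configurable
per-base rates (barcode bases have their own substitution rate).

Planted pathologies:

* **barcode collisions** — a fraction of barcodes is shared by two clones
  with distinct genotypes (the nonunique-barcode phenomenon);
* **PCR crossovers** — a fraction of clones is built as the upstream barcode
  plus 5' genotype of parent A joined, at a random point 3' of A's first
  variant, to the 3' genotype plus downstream barcode of parent B.  (A
  crossover 5' of every parent-A variant yields a molecule genotypically
  identical to parent B and is undetectable in principle, so planted
  crossovers are always of the detectable kind.)

Quality model (a deliberate two-level caricature, not a HiFi error profile):
correctly called bases get ``qual_correct`` (Q93); erroneous non-barcode
bases and the bases flanking an erroneous deletion get ``qual_error`` (Q30,
below the variant-quality threshold, so single-read errors are filterable);
barcode miscalls get ``barcode_error_qual`` (Q93 — a confident consensus
miscall, the case barcode clustering exists to fix); and a configurable
fraction of reads gets a uniformly low-quality barcode (Q40 < Q62),
emulating multi-occupancy wells caught by the barcode quality gate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .design_io import Interval, LibraryDesign, LongRead, write_long_reads
from .errors import ConfigError
from .extraction import Variant, left_align_indel

_BASES = "ACGT"
_SENSE_CODONS = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in ("TAA", "TAG", "TGA")
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic library.

    Defaults describe a 200-clone dual-barcoded library (25-nt barcodes,
    1-3 ORF variants per clone, Poisson depth 6) with mild HiFi-like error
    rates and no planted pathologies.
    """

    n_clones: int = 200
    barcode_len: int = 25
    min_variants: int = 1
    max_variants: int = 3
    indel_fraction: float = 0.1  # of planted variants; the rest are SNVs
    depth_lambda: float = 6.0
    sub_error_rate: float = 0.001
    indel_error_rate: float = 0.0005
    barcode_error_rate: float = 0.001
    collision_fraction: float = 0.0
    chimera_fraction: float = 0.0
    low_qual_read_fraction: float = 0.0
    qual_correct: int = 93
    qual_error: int = 30
    barcode_error_qual: int = 93
    low_qual_value: int = 40
    rng_seed: int = 0

    def __post_init__(self):
        rates = (
            self.indel_fraction,
            self.sub_error_rate,
            self.indel_error_rate,
            self.barcode_error_rate,
            self.collision_fraction,
            self.chimera_fraction,
            self.low_qual_read_fraction,
        )
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ConfigError("all rates/fractions must be in [0,1]")
        if self.depth_lambda <= 0:
            raise ConfigError("depth_lambda must be > 0")
        if self.n_clones < 1 or self.min_variants < 0:
            raise ConfigError("bad library size parameters")
        if self.max_variants < self.min_variants:
            raise ConfigError("max_variants < min_variants")


@dataclass(frozen=True)
class CloneRecord:
    clone_id: int
    barcodes: tuple[str, ...]
    genotype: frozenset[Variant]
    is_chimera: bool = False
    parent_ids: Optional[tuple[int, int]] = None
    collision_group: Optional[int] = None

    @property
    def virtual_barcode(self) -> str:
        return "".join(self.barcodes)


def default_design(
    barcode_len: int = 25, n_loci: int = 2, n_codons: int = 110, seed: int = 7
) -> LibraryDesign:
    """A synthetic amplicon: flank, upstream barcode, spacer, ORF
    (ATG + sense codons + TAA, no internal stops), and optionally a spacer
    plus downstream barcode and tail."""
    rng = np.random.default_rng(seed)

    def rand_seq(k: int) -> str:
        return "".join(rng.choice(list(_BASES), size=k))

    pre = rand_seq(20)
    up = rand_seq(barcode_len)
    mid = rand_seq(15)
    orf = "ATG" + "".join(rng.choice(_SENSE_CODONS, size=n_codons - 1)) + "TAA"
    parts = [pre, up, mid, orf]
    up_iv = Interval(len(pre), len(pre) + barcode_len)
    orf_iv = Interval(up_iv.end + len(mid), up_iv.end + len(mid) + len(orf))
    loci = [up_iv]
    if n_loci == 2:
        gap = rand_seq(7)
        down = rand_seq(barcode_len)
        parts += [gap, down]
        loci.append(Interval(orf_iv.end + len(gap), orf_iv.end + len(gap) + barcode_len))
    parts.append(rand_seq(25))
    return LibraryDesign(
        reference_seq="".join(parts),
        barcode_loci=tuple(loci),
        orf=orf_iv,
        name="synthetic_amplicon",
    )


def _random_barcode(rng, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def _plant_genotype(rng, design: LibraryDesign, cfg: SimConfig) -> frozenset[Variant]:
    """1 to a few variants inside the ORF, pairwise well separated."""
    k = int(rng.integers(cfg.min_variants, cfg.max_variants + 1))
    lo, hi = design.orf.start + 3, design.orf.end - 3
    positions: list[int] = []
    variants: list[Variant] = []
    attempts = 0
    while len(variants) < k:
        attempts += 1
        if attempts > 1000:
            raise ConfigError("cannot place variants with required spacing")
        p = int(rng.integers(lo, hi))
        if any(abs(p - q) < 12 for q in positions):
            continue
        ref = design.reference_seq
        if rng.random() < cfg.indel_fraction:
            length = int(rng.integers(1, 3))
            if rng.random() < 0.5:
                if p + length > hi:
                    continue
                pos, ra, aa = left_align_indel(p, ref[p : p + length], "", design)
            else:
                ins = _random_barcode(rng, length)
                pos, ra, aa = left_align_indel(p, "", ins, design)
            if pos < lo:
                continue
            v = Variant(pos, ra, aa, cfg.qual_correct)
        else:
            alts = [b for b in _BASES if b != ref[p]]
            v = Variant(p, ref[p], alts[int(rng.integers(0, 3))], cfg.qual_correct)
        positions.append(p)
        variants.append(v)
    return frozenset(variants)


def simulate_library(
    design: LibraryDesign, cfg: SimConfig, rng: Optional[np.random.Generator] = None
) -> list[CloneRecord]:
    """Generate the clone table: independent clones, planted barcode
    collisions (pairs of clones sharing all barcodes), and planted
    crossover chimeras."""
    rng = rng if rng is not None else np.random.default_rng(cfg.rng_seed)
    n = cfg.n_clones
    n_chim = int(round(cfg.chimera_fraction * n))
    n_coll = int(round(cfg.collision_fraction * n))
    n_base = n - n_chim
    if n_coll > 0 and n < 2:
        raise ConfigError("collisions require at least 2 clones")
    if 2 * n_coll > n_base:
        raise ConfigError("collision_fraction too high for library size")
    if n_chim > 0 and design.n_loci != 2:
        raise ConfigError("chimeras require a dual-barcode design")
    if n_chim > 0 and n_base < 2:
        raise ConfigError("chimeras require at least 2 parent clones")

    clones: list[CloneRecord] = []
    seen_virtual: set[str] = set()
    for cid in range(n_base):
        while True:
            bcs = tuple(
                _random_barcode(rng, len(iv)) for iv in design.barcode_loci
            )
            if "".join(bcs) not in seen_virtual:
                break
        seen_virtual.add("".join(bcs))
        clones.append(
            CloneRecord(
                clone_id=cid, barcodes=bcs, genotype=_plant_genotype(rng, design, cfg)
            )
        )

    if n_coll:
        chosen = rng.choice(n_base, size=2 * n_coll, replace=False)
        for g in range(n_coll):
            a, b = int(chosen[2 * g]), int(chosen[2 * g + 1])
            # partners get disjoint genotypes: a shared variant would make the
            # two clones genotype-coherent and the collision undetectable in
            # principle by any clustering that keys on variant overlap
            geno_b = clones[b].genotype
            while geno_b & clones[a].genotype:
                geno_b = _plant_genotype(rng, design, cfg)
            clones[a] = replace(clones[a], collision_group=g)
            clones[b] = replace(
                clones[b],
                barcodes=clones[a].barcodes,
                genotype=geno_b,
                collision_group=g,
            )
        collided = {int(c) for c in chosen}
    else:
        collided = set()

    parents_pool = [c.clone_id for c in clones if c.clone_id not in collided]
    for k in range(n_chim):
        if len(parents_pool) < 2:
            raise ConfigError("not enough independent clones for chimera parents")
        pa, pb = (int(x) for x in rng.choice(parents_pool, size=2, replace=False))
        a, b = clones[pa], clones[pb]
        first_end = min(v.end for v in a.genotype)
        cross = int(rng.integers(first_end, design.barcode_loci[1].start))
        genotype = frozenset(
            {v for v in a.genotype if v.end <= cross}
            | {v for v in b.genotype if v.ref_pos >= cross}
        )
        clones.append(
            CloneRecord(
                clone_id=n_base + k,
                barcodes=(a.barcodes[0], b.barcodes[1]),
                genotype=genotype,
                is_chimera=True,
                parent_ids=(pa, pb),
            )
        )
    return clones


def write_clone_table(clones: Sequence[CloneRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "clone_id\tup_barcode\tdown_barcode\tvirtual_barcode\t"
            "genotype_nt\tis_chimera\tparent_ids\tcollision_group\n"
        )
        for c in clones:
            nt = ";".join(
                v.nt_string()
                for v in sorted(
                    c.genotype, key=lambda v: (v.ref_pos, v.ref_allele, v.alt_allele)
                )
            )
            down = c.barcodes[1] if len(c.barcodes) > 1 else ""
            parents = ",".join(map(str, c.parent_ids)) if c.parent_ids else ""
            coll = "" if c.collision_group is None else str(c.collision_group)
            fh.write(
                f"{c.clone_id}\t{c.barcodes[0]}\t{down}\t{c.virtual_barcode}\t"
                f"{nt or '='}\t{int(c.is_chimera)}\t{parents}\t{coll}\n"
            )


def _clone_sequence(
    design: LibraryDesign, clone: CloneRecord
) -> tuple[str, list[bool]]:
    """Clone molecule sequence and a per-base is-barcode mask."""
    seq = list(design.reference_seq)
    mask = [False] * len(seq)
    edits: list[tuple[int, int, str, bool]] = []
    for iv, bc in zip(design.barcode_loci, clone.barcodes):
        edits.append((iv.start, iv.end, bc, True))
    for v in clone.genotype:
        if v.vtype == "SNV":
            edits.append((v.ref_pos, v.ref_pos + 1, v.alt_allele, False))
        elif v.vtype == "deletion":
            edits.append((v.ref_pos, v.end, "", False))
        else:
            edits.append((v.ref_pos, v.ref_pos, v.alt_allele, False))
    for start, end, repl, is_bc in sorted(edits, key=lambda e: -e[0]):
        seq[start:end] = list(repl)
        mask[start:end] = [is_bc] * len(repl)
    return "".join(seq), mask


def simulate_reads(
    clones: Sequence[CloneRecord],
    design: LibraryDesign,
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
    fastq_path=None,
    truth_path=None,
) -> tuple[list[LongRead], dict[str, int]]:
    """Draw Poisson-depth reads per clone with sequencing errors applied.

    Returns the reads and a read-id -> clone-id truth map; optionally writes
    a FASTQ and a truth TSV.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.rng_seed + 1)
    reads: list[LongRead] = []
    truth: dict[str, int] = {}
    counter = 0
    for clone in clones:
        seq, mask = _clone_sequence(design, clone)
        depth = int(rng.poisson(cfg.depth_lambda))
        for _ in range(depth):
            rid = f"read{counter:06d}"
            counter += 1
            low_qual = rng.random() < cfg.low_qual_read_fraction
            u_indel = rng.random(len(seq))
            u_sub = rng.random(len(seq))
            chars: list[str] = []
            quals: list[int] = []
            deletion_pending = False
            for i, ch in enumerate(seq):
                if u_indel[i] < cfg.indel_error_rate:
                    if rng.random() < 0.5:  # deletion error
                        if quals:
                            quals[-1] = min(quals[-1], cfg.qual_error)
                        deletion_pending = True
                        continue
                    chars.append(_BASES[int(rng.integers(0, 4))])
                    quals.append(cfg.qual_error)
                rate = cfg.barcode_error_rate if mask[i] else cfg.sub_error_rate
                if u_sub[i] < rate:
                    alts = [b for b in _BASES if b != ch]
                    chars.append(alts[int(rng.integers(0, 3))])
                    quals.append(
                        cfg.barcode_error_qual if mask[i] else cfg.qual_error
                    )
                else:
                    chars.append(ch)
                    quals.append(cfg.qual_correct)
                if deletion_pending:
                    quals[-1] = min(quals[-1], cfg.qual_error)
                    deletion_pending = False
                if low_qual and mask[i]:
                    quals[-1] = min(quals[-1], cfg.low_qual_value)
            reads.append(LongRead(rid, "".join(chars), tuple(quals)))
            truth[rid] = clone.clone_id
    if fastq_path is not None:
        write_long_reads(reads, fastq_path)
    if truth_path is not None:
        with open(truth_path, "w") as fh:
            fh.write("read_id\tclone_id\n")
            for rid, cid in truth.items():
                fh.write(f"{rid}\t{cid}\n")
    return reads, truth
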