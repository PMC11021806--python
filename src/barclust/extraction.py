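"""Per-read barcode and candidate-variant extraction.

Each long read is aligned to the reference amplicon with an affine-gap DP
(global in the reference, soft-clipped read ends; see :mod:`barclust._gotoh`).
From the alignment we take

* the read bases aligned inside each barcode locus (insertions strictly
  inside a locus join the barcode; deleted locus positions contribute
  nothing),
* the minimum base quality over all barcode bases, and
* the set of *candidate variants* outside the barcode loci, each carrying a
  phred quality: the base quality for SNVs, the minimum inserted-base quality
  for insertions, and the minimum of the two flanking read bases for
  deletions (which have no read bases of their own).

Indels are left-aligned (shifted maximally 5'-ward within repeat context,
without crossing barcode-locus boundaries) so that the same clone indel seen
in different reads yields an identical variant key.

Variant string dialect (1-based reference positions, stable across releases):

* SNV        ``101A>G``
* deletion   ``101delA`` or ``101_102delAT``
* insertion  ``101_102insTT``  (inserted between positions 101 and 102;
  ``0_1ins...`` would denote an insertion before the first base)
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

from . import _gotoh
from .design_io import LibraryDesign, LongRead, Params
from .errors import ConfigError

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Variant:
    """A single nucleotide-level difference from the reference.

    Equality and hashing ignore ``qual`` so that the same event observed in
    different reads counts as one variant key.
    """

    ref_pos: int  # 0-based; for insertions, the base the insert precedes
    ref_allele: str
    alt_allele: str
    qual: int = field(compare=False)

    def __post_init__(self):
        if not self.ref_allele and not self.alt_allele:
            raise ConfigError("variant with both alleles empty")
        if self.ref_allele and self.alt_allele:
            if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
                raise ConfigError("SNV alleles must have length 1")

    @property
    def vtype(self) -> str:
        if self.ref_allele and self.alt_allele:
            return "SNV"
        return "deletion" if self.ref_allele else "insertion"

    @property
    def end(self) -> int:
        """End (exclusive) of the affected reference interval."""
        return self.ref_pos + len(self.ref_allele)

    def nt_string(self) -> str:
        p = self.ref_pos
        if self.vtype == "SNV":
            return f"{p + 1}{self.ref_allele}>{self.alt_allele}"
        if self.vtype == "deletion":
            if len(self.ref_allele) == 1:
                return f"{p + 1}del{self.ref_allele}"
            return f"{p + 1}_{p + len(self.ref_allele)}del{self.ref_allele}"
        return f"{p}_{p + 1}ins{self.alt_allele}"


_SNV_RE = re.compile(r"^(\d+)([ACGT])>([ACGT])$")
_DEL_RE = re.compile(r"^(\d+)(?:_(\d+))?del([ACGT]+)$")
_INS_RE = re.compile(r"^(\d+)_(\d+)ins([ACGT]+)$")


def parse_nt_string(s: str, qual: int = 0) -> Variant:
    """Inverse of :meth:`Variant.nt_string`."""
    m = _SNV_RE.match(s)
    if m:
        return Variant(int(m.group(1)) - 1, m.group(2), m.group(3), qual)
    m = _INS_RE.match(s)
    if m:
        p = int(m.group(1))
        if int(m.group(2)) != p + 1:
            raise ConfigError(f"bad insertion string {s!r}")
        return Variant(p, "", m.group(3), qual)
    m = _DEL_RE.match(s)
    if m:
        p = int(m.group(1)) - 1
        seq = m.group(3)
        end = int(m.group(2)) if m.group(2) else p + 1
        if end != p + len(seq):
            raise ConfigError(f"bad deletion string {s!r}")
        return Variant(p, seq, "", qual)
    raise ConfigError(f"cannot parse variant string {s!r}")


@dataclass(frozen=True)
class AlnRun:
    """A maximal run of identical alignment operations.

    ``op`` is one of ``clip`` (read bases unaligned at an end), ``diag``
    (read base on reference base), ``del`` (reference base skipped), ``ins``
    (read base between reference bases).
    """

    op: str
    ref_start: int
    read_start: int
    length: int


@dataclass(frozen=True)
class Alignment:
    """One read's alignment in the orientation that scored best."""

    read_id: str
    seq: str  # oriented read sequence (reverse-complemented if strand == "-")
    quals: tuple[int, ...]
    strand: str
    score: int
    ops: tuple[AlnRun, ...]

    def __post_init__(self):
        consumed = sum(r.length for r in self.ops if r.op in ("clip", "diag", "ins"))
        if consumed != len(self.seq):
            raise ConfigError("alignment operations do not tile the read")


@dataclass(frozen=True)
class ReadRejection:
    read_id: str
    reason: str


@dataclass(frozen=True)
class ExtractedRead:
    """Barcode(s), barcode quality, and candidate variants of one read."""

    read_id: str
    barcodes: tuple[str, ...]
    barcode_min_qual: int
    variants: frozenset[Variant]

    @property
    def virtual_barcode(self) -> str:
        return "".join(self.barcodes)


def _runs_from_ops(op_codes, read_start: int, read_end: int, read_len: int):
    runs = []
    if read_start > 0:
        runs.append(AlnRun("clip", 0, 0, read_start))
    i, j = read_start, 0
    names = {_gotoh.OP_DIAG: "diag", _gotoh.OP_DEL: "del", _gotoh.OP_INS: "ins"}
    k = 0
    n_ops = len(op_codes)
    while k < n_ops:
        op = op_codes[k]
        length = 1
        while k + length < n_ops and op_codes[k + length] == op:
            length += 1
        runs.append(AlnRun(names[int(op)], j, i, length))
        if op == _gotoh.OP_DIAG:
            i += length
            j += length
        elif op == _gotoh.OP_DEL:
            j += length
        else:
            i += length
        k += length
    if read_end < read_len:
        runs.append(AlnRun("clip", j, read_end, read_len - read_end))
    return tuple(runs)


def align_read(
    read: LongRead,
    design: LibraryDesign,
    *,
    try_reverse: bool = True,
    min_read_len: int = 30,
) -> Alignment | ReadRejection:
    """Align one read to the reference; both orientations are tried and the
    better score kept (ties prefer forward)."""
    if len(read.seq) < min_read_len:
        return ReadRejection(read.read_id, "too_short")
    # barcode loci are degenerate by design: any read base matches there, so
    # alignment anchors on the flanks instead of mis-scoring random barcodes
    ref_codes = _gotoh.encode(design.reference_seq)
    for iv in design.barcode_loci:
        ref_codes[iv.start : iv.end] = _gotoh.WILDCARD
    fwd = _gotoh.align_codes(_gotoh.encode(read.seq), ref_codes)
    best, strand, seq, quals = fwd, "+", read.seq, read.quals
    if try_reverse:
        rc_seq = revcomp(read.seq)
        rev = _gotoh.align_codes(_gotoh.encode(rc_seq), ref_codes)
        if rev[0] > fwd[0]:
            best, strand, seq, quals = rev, "-", rc_seq, read.quals[::-1]
    score, op_codes, read_start, read_end = best
    return Alignment(
        read_id=read.read_id,
        seq=seq,
        quals=tuple(quals),
        strand=strand,
        score=score,
        ops=_runs_from_ops(op_codes, read_start, read_end, len(seq)),
    )


def _locus_strictly_inside(design: LibraryDesign, pos: int) -> Optional[int]:
    """Index of the locus whose interior contains insertion point *pos*."""
    for idx, iv in enumerate(design.barcode_loci):
        if iv.start < pos < iv.end:
            return idx
    return None


def left_align_indel(
    ref_pos: int, ref_allele: str, alt_allele: str, design: LibraryDesign
) -> tuple[int, str, str]:
    """Shift an indel maximally 5'-ward within repeat context.

    Normalization never crosses a barcode-locus boundary, so a variant
    outside the loci stays outside.
    """
    ref = design.reference_seq
    p = ref_pos
    if ref_allele and not alt_allele:  # deletion
        d = ref_allele
        while p > 0 and ref[p - 1] == d[-1] and not design.in_barcode_locus(p - 1):
            d = ref[p - 1] + d[:-1]
            p -= 1
        return p, d, ""
    if alt_allele and not ref_allele:  # insertion
        s = alt_allele
        while (
            p > 0
            and ref[p - 1] == s[-1]
            and not design.in_barcode_locus(p - 1)
            and _locus_strictly_inside(design, p - 1) is None
        ):
            s = ref[p - 1] + s[:-1]
            p -= 1
        return p, "", s
    return ref_pos, ref_allele, alt_allele


def extract(
    alignment: Alignment, design: LibraryDesign, *, min_ref_coverage: float = 0.5
) -> ExtractedRead | ReadRejection:
    """Extract barcode(s) and candidate variants from one alignment."""
    ref = design.reference_seq
    n_diag = sum(r.length for r in alignment.ops if r.op == "diag")
    if n_diag / len(ref) < min_ref_coverage:
        return ReadRejection(alignment.read_id, "partial_read")

    barcode_parts: list[list[tuple[str, int]]] = [[] for _ in design.barcode_loci]
    locus_diag = [0] * design.n_loci
    raw: list[tuple[int, str, str, int]] = []  # (pos, ref_allele, alt_allele, qual)
    seq, quals = alignment.seq, alignment.quals

    for run in alignment.ops:
        if run.op == "clip":
            continue
        if run.op == "diag":
            for k in range(run.length):
                j = run.ref_start + k
                i = run.read_start + k
                base, q = seq[i], quals[i]
                placed = False
                for li, iv in enumerate(design.barcode_loci):
                    if iv.contains(j):
                        barcode_parts[li].append((base, q))
                        locus_diag[li] += 1
                        placed = True
                        break
                if not placed and base != ref[j]:
                    raw.append((j, ref[j], base, q))
        elif run.op == "ins":
            j = run.ref_start
            bases = seq[run.read_start : run.read_start + run.length]
            qs = quals[run.read_start : run.read_start + run.length]
            li = _locus_strictly_inside(design, j)
            if li is not None:
                barcode_parts[li].extend(zip(bases, qs))
            else:
                raw.append((j, "", bases, min(qs)))
        else:  # del
            # flanking read bases in read coordinates (bounds-checked)
            ql = quals[run.read_start - 1] if run.read_start > 0 else None
            qr = quals[run.read_start] if run.read_start < len(seq) else None
            present = [q for q in (ql, qr) if q is not None]
            flank = min(present) if present else 0
            j0 = run.ref_start
            seg_start = None
            for k in range(run.length + 1):
                j = j0 + k
                outside = k < run.length and not design.in_barcode_locus(j)
                if outside and seg_start is None:
                    seg_start = j
                elif not outside and seg_start is not None:
                    raw.append((seg_start, ref[seg_start:j], "", flank))
                    seg_start = None

    for li, count in enumerate(locus_diag):
        if count == 0:
            return ReadRejection(alignment.read_id, "barcode_not_covered")

    variants = set()
    for pos, ref_a, alt_a, q in raw:
        pos, ref_a, alt_a = left_align_indel(pos, ref_a, alt_a, design)
        variants.add(Variant(pos, ref_a, alt_a, q))

    barcodes = tuple("".join(b for b, _ in parts) for parts in barcode_parts)
    bc_min_qual = min(q for parts in barcode_parts for _, q in parts)
    return ExtractedRead(
        read_id=alignment.read_id,
        barcodes=barcodes,
        barcode_min_qual=bc_min_qual,
        variants=frozenset(variants),
    )


def passes_barcode_quality(er: ExtractedRead, params: Params) -> bool:
    """True iff the worst barcode base reaches the quality threshold."""
    return er.barcode_min_qual >= params.min_barcode_qual
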