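"""Alignment, barcode/variant extraction, and the barcode quality gate."""

import numpy as np
import pytest

from barclust import (
    LongRead,
    Params,
    Variant,
    align_read,
    extract,
    passes_barcode_quality,
)
from barclust._gotoh import align_codes, encode
from barclust.extraction import ReadRejection, left_align_indel, revcomp

from oracles import affine_semiglobal_oracle


def _perfect_read(design, rid="r0", qual=93):
    return LongRead(rid, design.reference_seq, (qual,) * len(design.reference_seq))


def _mutate(seq, pos, base):
    return seq[:pos] + base + seq[pos + 1 :]


class TestAlignRead:
    def test_identity_read_is_all_match(self, small_design):
        aln = align_read(_perfect_read(small_design), small_design)
        assert aln.strand == "+"
        assert [r.op for r in aln.ops] == ["diag"]
        assert aln.ops[0].length == len(small_design.reference_seq)

    def test_single_substitution_keeps_single_diag_run(self, small_design):
        seq = _mutate(small_design.reference_seq, 70, "A" if small_design.reference_seq[70] != "A" else "C")
        aln = align_read(LongRead("r", seq, (93,) * len(seq)), small_design)
        assert [r.op for r in aln.ops] == ["diag"]
        er = extract(aln, small_design)
        assert len(er.variants) == 1

    def test_too_short_read_rejected(self, small_design):
        out = align_read(LongRead("r", "ACGTACGT", (40,) * 8), small_design)
        assert out == ReadRejection("r", "too_short")

    def test_reverse_complement_read_recovers_same_extraction(self, small_design):
        fwd = _perfect_read(small_design)
        rc = LongRead("r0", revcomp(fwd.seq), fwd.quals[::-1])
        aln_f = align_read(fwd, small_design)
        aln_r = align_read(rc, small_design)
        assert aln_r.strand == "-"
        assert extract(aln_f, small_design) == extract(aln_r, small_design)

    def test_partial_read_rejected(self, small_design):
        n = len(small_design.reference_seq)
        frag = small_design.reference_seq[: n // 3]
        out = align_read(LongRead("r", frag, (93,) * len(frag)), small_design)
        er = extract(out, small_design)
        assert er == ReadRejection("r", "partial_read")

    def test_read_missing_downstream_locus_rejected(self, small_design):
        # covers > 50% of the reference but stops before the downstream locus
        end = small_design.barcode_loci[1].start - 2
        frag = small_design.reference_seq[:end]
        aln = align_read(LongRead("r", frag, (93,) * len(frag)), small_design)
        out = extract(aln, small_design)
        assert out == ReadRejection("r", "barcode_not_covered")


class TestAlignmentOracle:
    """The production kernel must equal a full DP oracle, ops and score."""

    @pytest.mark.parametrize("trial", range(40))
    def test_kernel_matches_oracle_on_mutated_reads(self, trial):
        rng = np.random.default_rng(1000 + trial)
        m = int(rng.integers(40, 81))
        ref = "".join(rng.choice(list("ACGT"), size=m))
        read = list(ref)
        for _ in range(int(rng.integers(0, 5))):
            kind = rng.integers(0, 3)
            p = int(rng.integers(1, len(read) - 1))
            if kind == 0:
                read[p] = "ACGT"[int(rng.integers(0, 4))]
            elif kind == 1 and len(read) > 35:
                del read[p : p + int(rng.integers(1, 3))]
            else:
                read[p:p] = list("ACGT"[int(rng.integers(0, 4))] * int(rng.integers(1, 3)))
        read = "".join(read)
        score, ops, rs, re_ = align_codes(encode(read), encode(ref))
        o_score, o_ops, o_rs, o_re = affine_semiglobal_oracle(read, ref)
        assert score == o_score
        assert (rs, re_) == (o_rs, o_re)
        got = "".join("MDI"[int(c)] for c in ops)
        assert got == o_ops

    def test_clipped_read_ends(self):
        ref = "ACGTACGTACGTACGTACGTACGTACGTACGTACGT"
        read = "TTTTT" + ref + "GGGGG"
        score, ops, rs, re_ = align_codes(encode(read), encode(ref))
        o = affine_semiglobal_oracle(read, ref)
        assert (score, rs, re_) == (o[0], o[2], o[3])
        assert rs == 5 and re_ == 5 + len(ref)


class TestExtract:
    def test_error_free_read_recovers_clone_exactly(self, small_design):
        from barclust import SimConfig, simulate_library, simulate_reads

        cfg = SimConfig(
            n_clones=4,
            sub_error_rate=0,
            indel_error_rate=0,
            barcode_error_rate=0,
            rng_seed=5,
            barcode_len=10,
        )
        clones = simulate_library(small_design, cfg)
        reads, truth = simulate_reads(clones, small_design, cfg)
        by_id = {c.clone_id: c for c in clones}
        assert reads, "simulation produced no reads"
        for read in reads:
            er = extract(align_read(read, small_design), small_design)
            clone = by_id[truth[read.read_id]]
            assert er.barcodes == clone.barcodes
            assert er.variants == clone.genotype

    def test_variants_never_inside_barcode_loci(self, small_design, rng):
        ref = small_design.reference_seq
        for _ in range(20):
            seq = list(ref)
            for _ in range(4):
                p = int(rng.integers(0, len(seq)))
                seq[p] = "ACGT"[int(rng.integers(0, 4))]
            read = LongRead("r", "".join(seq), (93,) * len(seq))
            out = extract(align_read(read, small_design), small_design)
            if isinstance(out, ReadRejection):
                continue
            for v in out.variants:
                for iv in small_design.barcode_loci:
                    assert not iv.overlaps(v.ref_pos, max(v.end, v.ref_pos + 1))

    def test_deletion_in_barcode_shortens_barcode(self, small_design):
        iv = small_design.barcode_loci[0]
        ref = small_design.reference_seq
        seq = ref[: iv.start + 4] + ref[iv.start + 5 :]
        er = extract(
            align_read(LongRead("r", seq, (93,) * len(seq)), small_design),
            small_design,
        )
        assert len(er.barcodes[0]) == len(iv) - 1
        assert not er.variants  # the barcode deletion is not a variant

    def test_snv_quality_is_base_quality(self, small_design):
        p = small_design.orf.start + 10
        ref = small_design.reference_seq
        alt = "A" if ref[p] != "A" else "C"
        seq = _mutate(ref, p, alt)
        quals = [93] * len(seq)
        quals[p] = 37
        er = extract(align_read(LongRead("r", seq, tuple(quals)), small_design), small_design)
        (v,) = er.variants
        assert (v.ref_pos, v.ref_allele, v.alt_allele, v.qual) == (p, ref[p], alt, 37)

    def test_deletion_quality_is_min_flank(self, small_design):
        p = small_design.orf.start + 30
        ref = small_design.reference_seq
        seq = ref[:p] + ref[p + 2 :]
        quals = [93] * len(seq)
        quals[p - 1] = 50  # left flank in read coordinates
        er = extract(align_read(LongRead("r", seq, tuple(quals)), small_design), small_design)
        dels = [v for v in er.variants if v.vtype == "deletion"]
        assert len(dels) == 1 and dels[0].qual == 50


class TestLeftAlignment:
    def test_deletion_shifts_to_run_start(self, small_design):
        ref = small_design.reference_seq
        # find a dinucleotide repeat or homopolymer inside the ORF
        for p in range(small_design.orf.start + 1, small_design.orf.end - 2):
            if ref[p] == ref[p + 1]:
                pos, ra, aa = left_align_indel(p + 1, ref[p + 1], "", small_design)
                assert pos <= p
                assert ref[pos] == ra
                break
        else:
            pytest.skip("no homopolymer in ORF")

    def test_same_clone_indel_from_different_reads_same_key(self, small_design):
        # two reads deleting different bases of the same homopolymer run must
        # yield identical left-aligned variants
        ref = small_design.reference_seq
        run = None
        for p in range(small_design.orf.start, small_design.orf.end - 2):
            if ref[p] == ref[p + 1]:
                run = p
                break
        assert run is not None
        keys = set()
        for delpos in (run, run + 1):
            seq = ref[:delpos] + ref[delpos + 1 :]
            er = extract(
                align_read(LongRead("r", seq, (93,) * len(seq)), small_design),
                small_design,
            )
            keys |= {(v.ref_pos, v.ref_allele, v.alt_allele) for v in er.variants}
        assert len(keys) == 1


class TestBarcodeQualityGate:
    @pytest.mark.parametrize(
        "minq,threshold,expected",
        [(93, 62, True), (61, 62, False), (62, 62, True)],
    )
    def test_boundary_semantics(self, minq, threshold, expected):
        from barclust.extraction import ExtractedRead

        er = ExtractedRead("r", ("ACGT",), minq, frozenset())
        assert passes_barcode_quality(er, Params(min_barcode_qual=threshold)) is expected

    def test_low_quality_barcode_base_fails_gate(self, small_design):
        iv = small_design.barcode_loci[0]
        read = _perfect_read(small_design)
        quals = list(read.quals)
        quals[iv.start + 3] = 61
        er = extract(
            align_read(LongRead("r", read.seq, tuple(quals)), small_design),
            small_design,
        )
        assert er.barcode_min_qual == 61
        assert not passes_barcode_quality(er, Params())
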