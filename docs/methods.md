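# Methods

## Model and assumptions

`barclust` assembles a barcode–genotype map for a library of barcoded
mutagenized clones sequenced with high-accuracy long reads (HiFi-like,
per-base qualities up to Q93). The model of the data is:

* every read is one full-length (or near-full-length) amplicon molecule in
  either orientation;
* each molecule derives from one clone: reference sequence + the clone's
  nucleotide variants + its barcode(s) at known, degenerate loci;
* sequencing error adds substitutions and short indels on top, with base
  qualities that are informative but not perfectly calibrated;
* barcode loci are random-mer regions: their reference content is a
  placeholder, and no read/reference mismatch there is meaningful.

Two clones may share a barcode (a ligation *collision*), and PCR crossover
can create molecules joining the upstream barcode and 5' variants of one
clone to the 3' variants and downstream barcode of another.

## Alignment and extraction

Reads are aligned with an affine-gap three-state DP that is global in the
reference and soft-clips read ends for free. Scoring is bwa-like — match
+1, mismatch −4, gap of length L costs 6 + L — scaled ×2 internally so that
**wildcard columns** (barcode loci) can score +1, half a match. The
half-match is deliberate: if wildcard columns scored a full match, an indel
adjacent to a locus could float across the boundary at equal score and
surface as a spurious flank variant; half-matches make the alignment that
anchors real flank bases strictly better. Both orientations are tried and
the better score kept (ties prefer forward). Tie-breaking inside the DP is
fixed (diagonal over deletion over insertion; at the right boundary the
longer-aligned end state wins), so alignments are bit-reproducible; the
test suite checks the kernel against an independent full-matrix oracle.

Reads shorter than 30 bases are rejected (`too_short`); reads covering
< 50% of the reference (`partial_read`) or leaving a barcode locus with no
aligned base (`barcode_not_covered`) likewise. Barcode bases are the read
bases aligned inside each locus (insertions strictly inside a locus join
the barcode; deleted locus positions contribute nothing). Variant
qualities: SNV = base quality; insertion = min inserted-base quality;
deletion = min of the two flanking read bases (deletions have no bases of
their own, so the flanks are a conservative proxy). Indels are left-aligned
within repeat context (never across a locus boundary) so the same clone
indel always produces the same variant key. The barcode quality statistic
is the **minimum** over all barcode bases — with a default gate of Q62 the
intent is to drop any read with even one doubtful barcode base (such reads
often come from multi-occupancy wells), and a minimum implements exactly
that; a mean would not.

## Clustering

Within each identical-(virtual-)barcode read set, candidate variants seen
in exactly one read with quality below `min_var_qual` (default Q90) are
discarded; variants seen in ≥ 2 reads are kept regardless of quality. Reads
are linked when both filtered sets are empty (wild-type) or their Jaccard
index is ≥ `jaccard_min` = 0.2 (inclusive; `J(∅,∅)` is defined as 1.0 so
the WT rule is a special case, not an exception). Connected components —
including singletons — are seed clusters.

Merging considers cluster pairs at the minimum barcode edit distance
between member reads, ascending up to `max_ed` = 2 (exact Levenshtein via
edlib; a banded cutoff at `max_ed`+1 is used for speed and verified against
brute force). A pair merges iff:

1. after re-running the variant filter **on the pooled reads** (so a
   variant single-read in each half but double-read together survives),
   both sides are WT or their genotypes have Jaccard ≥ 0.2;
2. no two reads in the pooled cluster exceed barcode ED `max_ed`;
3. |log₂(s₁/s₂)| > ED (strict, as printed) — sizes must diverge the way a
   parent clone and its barcode-miscall satellites do.

Beyond ascending ED, the merge order (descending combined size, then
lexicographic barcode keys, then cluster ids) is an arbitrary but fixed
tie-break chosen purely for determinism: identical inputs in any read order
yield identical output, and multi-process extraction is collected in input
order so thread count cannot change results. Rejected pairs are not
retried unless a side changes (merged clusters get fresh identities).

Note a consequence of rule 3 worth knowing: two singletons never merge
(|log₂ 1/1| = 0), and a 2-vs-3 pair at ED 1 does not either. Clones with no
error-free read therefore persist as small satellite clusters — the same
behaviour that produces the characteristically large number of small
clusters in real libraries.

## Consensus and translation

Per-locus consensus barcodes use a center-star alignment: every member
barcode is globally aligned (unit costs, fixed tie-breaks) to the most
frequent member string; columns are resolved by strict majority,
gap-majority columns are deleted, and ties go to the lexicographically
smallest non-gap base. At 5% per-base barcode error and cluster size ≥ 5
this recovers the true barcode ≥ 99% of the time; at the extreme of 10%
error with size exactly 5, plain majority has a ~8% per-25-mer failure
rate — an estimator-variance floor, not an implementation defect.

Protein consequences use the standard nuclear codon table on the forward
strand, in a simplified HGVS-style dialect: `p.Ala2Thr`, `p.Glu2Ter`,
`p.Glu2=` (position-specific synonymous; plain `p.=` is reserved for
wild-type clones), `p.Glu2fs` (frameshift at the first affected codon, no
extension length), `p.Lys3del`/`p.Lys3_Leu4ins…`/`…delins…` for in-frame
indels, `nc.123A>G` outside the ORF, and `boundary:` for ORF-edge
stragglers. When several SNVs hit one codon the codon is translated once
with all applied and reported as a single combined record. Synonymous
records are omitted whenever any other consequence exists. Indels touching
the terminator codon are reported as `fs` at Ter without peptide-level
adjudication. A full-ORF retranslation oracle in the test suite defines
truth for all single-variant genotypes.

## QC flags

* **Nonunique barcodes**: final clusters grouped by consensus clustering
  barcode; ≥ 2 clusters → nonunique; *remediable* iff the largest cluster
  holds strictly more than `remediable_fraction` = 2/3 of the barcode's
  reads.
* **Chimera sets** (dual-barcode designs with virtual barcodes on):
  within an identical-upstream-barcode group, clusters are linked when
  their genotypes intersect (complete = equal, partial = proper nonempty
  intersection) and their downstream barcodes differ by
  ≥ `chimera_downstream_min_ed` = `max_ed` + 1 — "entirely different"
  operationalized as *beyond merge range*, since the paper-style rule gives
  no number. WT–WT pairs are never linked: a crossover between two
  wild-type clones is unobservable in genotype space. Components with ≥ 2
  members form chimera sets; a deterministic greedy pass enforces the
  pairwise downstream-distance invariant (with random barcodes it never
  removes anyone).
* **Homopolymer context**: an indel is flagged when its reference position
  is the 5'-most base of a maximal single-base run of length ≥ 4 — the
  classic false-positive indel context of long-read basecalling.

## The simulator

`barclust.simulate` emulates the phenomena the pipeline must handle, with
complete ground truth. Defaults are the study conditions used throughout
the tests: 200 clones, two 25-nt barcodes, 1–3 ORF variants per clone
(10% indels of 1–2 bp, the rest SNVs; planted ≥ 12 bp apart and ≥ 3 bp
inside the ORF so every variant has an unambiguous canonical key), Poisson
depth λ = 6, per-base error rates configurable per scenario.

Deliberate design points:

* **Depth is plain Poisson**, so a clone can receive zero reads
  (P ≈ 0.25% at λ = 6). Recovery statistics are computed over *sampled*
  clones; an unsampled clone is unrecoverable by construction.
* **Quality model is a two-level caricature**, not a HiFi error profile:
  correct bases Q93; erroneous non-barcode bases (and deletion flanks) Q30,
  below the variant filter, so single-read errors are filterable; barcode
  miscalls Q93 — a confident consensus miscall is exactly the case the
  clustering exists to fix, and giving it low quality would let the Q62
  gate solve the problem trivially. A separate `low_qual_read_fraction`
  plants whole-barcode low-quality reads (multi-occupancy-well analogue)
  to exercise the Q62 gate. Passing tests therefore demonstrate the
  clustering logic, not robustness to realistic PacBio error structure.
* **Planted pathologies are the detectable kind.** Collision partners get
  genotype-*disjoint* variant sets: a coincidental shared variant makes the
  pair genotype-coherent and the collision undetectable in principle by any
  overlap-keyed method. Crossover points are drawn 3' of the first
  upstream-parent variant: a crossover 5' of every parent-A variant yields
  a molecule genotypically identical to parent B and is likewise
  undetectable. Both rules define the planted phenomenon so that its truth
  label is decidable.

## Recovery metrics

*Exact recovery* (error-free scenarios): a sampled clone is recovered when
some cluster reproduces its barcodes and genotype exactly; the pipeline is
expected to produce exactly one cluster per sampled clone.

*Lookup-tolerant recovery* (barcode-error scenarios): a sampled clone is
recovered when some cluster carries its exact genotype and a consensus
virtual barcode within `max_ed` of the true barcode — the sense in which a
downstream screen actually queries the map. The exact-consensus variant of
this metric is information-theoretically capped under 2% per-base barcode
error: only 0.98⁵⁰ ≈ 36% of reads are barcode-clean, ~11% of clones have no
clean read at all, and the size-divergence rule (correctly) refuses to
merge their satellites — so ~89% is the ceiling for *any* faithful
implementation, while lookup-tolerant recovery is ≈ 100%.

## Problem sizes and determinism

Tests and the acceptance script run on 200-clone libraries (~1200 reads of
450 bp), chosen to exercise every code path at interactive runtimes; the
pipeline itself is O(reads × reference) in alignment and comfortably
handles larger libraries. All randomness flows through explicit
`numpy.random.Generator` seeds; repeated runs are byte-identical, including
across thread counts.

## Known limitations

* Single-reference, forward-strand-ORF amplicons only; no BAM ingestion.
* The barcode error model in merging is combinatorial (edit distance), not
  probabilistic; quality-weighted distances are out of scope.
* Chimera detection flags but does not correct; no library-wide crossover
  rate is estimated.
* The protein dialect is simplified HGVS (no extension lengths, no
  splice/UTR annotation, single-ORF only).
* Homopolymer annotation marks context; it does not by itself remove
  frameshift calls.
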