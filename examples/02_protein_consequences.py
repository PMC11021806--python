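"""Translate nucleotide genotypes into protein consequences.

Builds a few variants on the synthetic amplicon's ORF and prints their
HGVS-style protein-level calls (simplified dialect: three-letter amino
acids, 'fs' without extension length, 'nc.' for non-coding positions).
"""

from barclust import Variant, default_design, translate_variants

design = default_design()
s = design.orf.start
orf = design.reference_seq[s : design.orf.end]
print(f"ORF at [{s},{design.orf.end}), {len(orf) // 3} codons, starts {orf[:12]}...")

examples = [
    ("missense SNV in codon 2", [Variant(s + 4, orf[4], "T" if orf[4] != "T" else "A", 93)]),
    ("1-bp deletion (frameshift)", [Variant(s + 30, orf[30], "", 93)]),
    ("3-bp in-frame deletion", [Variant(s + 33, orf[33:36], "", 93)]),
    ("variant outside the ORF", [Variant(10, design.reference_seq[10], "A" if design.reference_seq[10] != "A" else "C", 93)]),
]
for label, genotype in examples:
    calls = translate_variants(genotype, design)
    nts = ";".join(v.nt_string() for v in genotype)
    print(f"  {label:28s} {nts:16s} -> {';'.join(calls)}")
# SNVs are reported per affected codon (two SNVs in one codon give a single
# combined record); indels of length not divisible by 3 are frameshifts at
# the first affected codon.
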