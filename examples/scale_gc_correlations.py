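"""How the genetic code couples GC content to protein structural propensities.

For each amino acid, the mean GC fraction of its codons is a fixed property
of the genetic code.  Correlating that value with propensity scales across
the 20 amino acids shows which properties a GC-rich genome pushes its random
ORFs toward: disorder propensity correlates positively with codon GC,
β-sheet propensity negatively.
"""

from gcorf import AMINO_ACIDS, BUILTIN_SCALES, mean_codon_gc, scale_gc_correlation

print("amino acid  codon GC   TOP-IDP")
top_idp = BUILTIN_SCALES["top_idp"]
for aa in sorted(AMINO_ACIDS, key=mean_codon_gc, reverse=True):
    print(f"   {aa}         {mean_codon_gc(aa):.3f}     {top_idp[aa]:+.3f}")

high = [a for a in AMINO_ACIDS if mean_codon_gc(a) > 0.8]
low = [a for a in AMINO_ACIDS if mean_codon_gc(a) < 0.2]
print(f"\nhigh-GC amino acids (>80% codon GC): {', '.join(high)}")
print(f"low-GC amino acids (<20% codon GC): {', '.join(low)}")

print("\nPearson r of each scale with per-amino-acid codon GC:")
for name, scale in BUILTIN_SCALES.items():
    print(f"  {name:15s} {scale_gc_correlation(scale):+.2f}")
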