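# gcorf

Genomic GC content, not selection alone, shapes the amino-acid composition of
young proteins. Because the genetic code assigns GC-rich codons
disproportionately to disorder-promoting residues (Pro, Ala, Gly) and AT-rich
codons to order-promoting ones (Ile, Phe, Tyr), a newborn protein translated
from an essentially random ORF inherits structural tendencies directly from
the local GC level — orphan proteins in GC-poor genomes (yeast) come out
ordered, those in GC-rich genomes (*Drosophila*) disordered. `gcorf`
implements the quantitative machinery behind this argument for researchers
studying de novo gene birth and proteome evolution.

## The model

The probability of selecting a codon at GC frequency *g* factorizes over its
three positions:

    P(codon | g) ∝ ∏_{i=1..3} [ g·δ(N_i ∈ {G,C}) + (1−g)·δ(N_i ∈ {A,T}) ]

normalized over the 61 sense codons. From this single object the package
derives:

- **analytic expectations** — expected amino-acid frequencies of a random
  protein at any *g* (at *g* = 0.5 all sense codons are equiprobable, so a
  two-codon amino acid sits at 2/61 ≈ 3.3%);
- **a Monte-Carlo ORF simulator** — batches of random ORFs on a GC grid
  (default 20–90% in 1% steps, 400 ORFs per level, interior lengths
  300/900/1500/2100 bp), translated to polypeptides;
- **per-protein properties** — CDS GC, amino-acid frequencies, and mean
  propensities on six scales (TOP-IDP disorder, biological hydrophobicity,
  helix/sheet/coil/turn conformational preferences);
- **phylogenetic age assignment** — single-gain MRCA rule on a (polytomy-
  resolved) species tree over an ortholog presence/absence matrix, mapping
  proteins to orphan / genus-orphan / intermediate / ancient groups;
- **trend statistics** — per-species orphan-vs-ancient rank-sum counts,
  per-age-group OLS of property on GC, GC-binned running averages, and
  observed-vs-expected amino-acid curves;
- **a synthetic data generator** — multi-species proteomes whose composition
  interpolates between the GC-driven expectation and a fixed reference via a
  per-age-group dampening parameter λ, with planted truth for validation.

## Worked example

```bash
python examples/expected_composition.py
```

prints

```
GC=30%: P= 2.44%  A= 2.44%  G= 2.44%  K= 6.65%  I=11.31%  E= 2.85%
GC=40%: P= 4.27%  A= 4.27%  G= 4.27%  K= 4.80%  I= 7.68%  E= 3.20%
GC=50%: P= 6.56%  A= 6.56%  G= 6.56%  K= 3.28%  I= 4.92%  E= 3.28%
GC=60%: P= 9.30%  A= 9.30%  G= 9.30%  K= 2.07%  I= 2.89%  E= 3.10%
GC=70%: P=12.49%  A=12.49%  G=12.49%  K= 1.15%  I= 1.49%  E= 2.68%
```

Pro, Ala and Gly (the three amino acids with >80% GC in their codons) more
than double between 40% and 60% GC while Lys and Ile collapse — in a random
ORF the composition is set by GC alone. `examples/scale_gc_correlations.py`
correlates each propensity scale with per-amino-acid codon GC across the 20
amino acids (TOP-IDP +0.39, β-sheet −0.42, hydrophobicity +0.16), and
`examples/synthetic_pipeline.py` runs the whole pipeline on a synthetic
panel, recovering a TOP-IDP-vs-GC slope of ≈0.62 for orphans against ≈0.26
for ancient proteins (dampening λ = 0 vs 0.8) — the "GC dependence weakens
with age" signature. A thin CLI mirrors the library
(`gcorf synth | simulate | ages | properties | trends | regress | curves |
aa-curves | correlate-scales | run`).

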