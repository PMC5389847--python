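# Methods

## The GC-conditioned codon model

The core object is a distribution over the 61 sense codons parameterized by
a single GC frequency `g ∈ [0, 1]`. Each codon's unnormalized weight is the
product over its three positions of `g` for G/C and `1 − g` for A/T;
normalization is over sense codons only, so the three stop codons are
excluded from both the support and the normalizing constant. At `g = 0.5`
all 61 sense codons are equiprobable. Because the weights factorize, the
expected amino-acid composition of a random protein at any `g` is available
in closed form as the summed codon probabilities per synonymous family; this
closed form is the analytic oracle against which the Monte-Carlo simulator
is tested (and the two agree to 1e−12 with independent 61-codon
enumeration).

The model is deliberately minimal: no codon-usage bias beyond GC, no
mutation/selection dynamics, no context dependence. It answers one question
— what composition does GC alone predict — and every deviation of real
proteins from it is then interpretable as selection or history.

## Random-ORF simulator

ORFs are built from i.i.d. sense codons drawn from the model, with an ATG
start and a uniformly chosen stop codon appended *on top of* the stated
interior length. Realized GC and all composition statistics use interior
codons only, so the fixed boundary codons cannot bias short ORFs. The
default batch covers GC 20–90% in 1% steps, 400 ORFs per level equally
divided among interior lengths 300/900/1500/2100 bp — 71 × 400 = 28,400
ORFs. A single integer seed drives the whole batch through per-level
substreams (`numpy` `SeedSequence.spawn`), so any level can be regenerated
alone, reproducibly. Translation keeps the initiator Met; composition
helpers that mirror the simulator's design drop it (the difference is at
most one residue per protein).

## Propensity scales

A protein's score on a scale is the unweighted mean over its residues, i.e.
a pure function of composition. Built-in scales: TOP-IDP disorder propensity
(Campen et al. 2008); the biological hydrophobicity scale of Hessa et al.
(2005) (apparent ΔG of membrane insertion, kcal/mol — hydrophobic residues
negative); normalized conformational frequencies for helix, sheet and turn
from Palau, Argos & Puigdomenech (1981); and the normalized coil frequency
of Nagano (1973). Published β-sheet propensity scales differ somewhat in
how strongly they couple to codon GC (Pearson r of −0.42 for the Palau
normalized frequencies, −0.40 to −0.41 for the Chou–Fasman and
Deléage–Roux variants, −0.20 for the Koehl–Levitt 1999 designed-sequence
propensities); the Palau family is the default, with helix and turn taken
from the same publication for coherence, and any scale can be substituted
via TSV. Per-amino-acid codon GC is the
*unweighted* mean over synonymous codons — matching the one-number-per-amino-
acid convention of scale/GC bar plots — rather than a usage-weighted mean at
some reference `g`. User scales load from two-column TSV with strict 20-row
validation.

Non-standard residues (X, B, Z, U) are excluded from averages and frequency
denominators with logged counts; GC denominators exclude ambiguous bases,
and sequences above 10% ambiguity are flagged. Whole sequences are averaged
(no signal-peptide or initiator-Met trimming).

## Age assignment

Ages follow a single-gain rule: a protein family's gain is placed at the
MRCA of the species that carry the ortholog group, and the protein's age is
the edge count from the focal leaf to that MRCA on a strictly bifurcating
tree. This is a deliberate simplification of asymmetric-cost Wagner
parsimony: when gains are much rarer than losses the most-parsimonious gain
node is exactly the MRCA, so the rule reproduces the behaviour of
full parsimony in the regime the analysis assumes. Multifurcations are
resolved to random bifurcations first (dendropy, deterministic per seed);
species-specific (age-0) calls are provably resolution-invariant, while ages
inside a resolved polytomy are seed-dependent — the known cost of forcing a
binary topology onto an unresolved clade.

Groups: singletons (proteins in no ortholog group) are orphans; age 1 is a
genus orphan; the maximum age on the focal lineage (the root) is ancient;
anything between is intermediate. A per-species `genus_max_age` widens the
genus band to 2 for lineages where collapsed strain-level taxa insert an
extra level — the generalization of the strain-collection special case.
Classification uses only {0, 1, max, other}, so it is robust to the unit in
which ages are counted.

## Statistics

- **Rank-sum**: two-sided Mann-Whitney via scipy; the exact null
  distribution for combined n ≤ 40 without ties, otherwise the normal
  approximation with midrank tie correction. Direction is the sign of
  U − n₁n₂/2 (equivalently the rank-biserial sign). The exact branch is
  tested against full permutation enumeration.
- **Per-species trend counting**: orphan-vs-ancient rank-sum per species;
  species with raw p < α (default 0.01) are counted by direction. No
  multiple-testing correction is applied across species or properties —
  thresholding raw p-values is part of the analysis design this package
  implements, kept deliberately, not endorsed statistically. Type-I
  calibration under a planted null is part of the test suite.
- **Regression**: OLS of property on per-protein GC per age group
  (slope, Pearson r, p). Both per-protein and genome-mean granularities are
  possible; the pipeline reports per-protein fits, and genome-level fits can
  be had by aggregating the property table by species first.
- **Running averages**: binned means over GC with bin width 1% and a
  minimum of 20 points per reported bin (both config-exposed; the source
  analyses state neither). Observed-vs-expected amino-acid curves add the
  closed-form expectation evaluated at bin centers as a pseudo-group
  `expected`.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
with age encoded in ortholog presence/absence:

- **Tree**: species grouped into genera (default size 2, optionally with
  extra species to plant genus-level polytomies), genus clades joined into
  a balanced binary backbone.
- **GC**: species GC means ~ Normal(0.45, 0.08) clipped to [0.25, 0.70]
  (spanning roughly the yeast-to-*Drosophila* range of coding GC);
  per-protein GC jittered with sd 0.05 around the species level, emulating
  isochore-scale within-genome variation.
- **Composition**: per protein, amino-acid frequencies are
  `(1 − λ)·E(g) + λ·π_ref`, with `E(g)` the codon-model expectation at the
  protein's GC and `π_ref` defaulting to `E(0.5)` so λ interpolates toward
  a GC-neutral composition. λ per age group defaults to 0 / 0.25 / 0.5 /
  0.8 (orphan → ancient, enforced non-decreasing), encoding the hypothesis
  that older proteins have decoupled from GC.
- **CDS realization**: each residue's codon is drawn from its synonymous
  family with the GC-conditioned weights renormalized within the family, so
  protein composition and CDS GC are mutually consistent (realized CDS GC
  correlates with the target at r > 0.9 for ≥300-codon proteins).
- **Ages and mixture**: the default age-group mixture follows the reported
  large-panel proportions (0.8% orphan, 0.6% genus orphan, 15%
  intermediate, 83.6% ancient); lengths are lognormal with age-group means
  100/150/300/500 aa. Presence sets are clades of the generator's own
  polytomy resolution (resolution seed = dataset seed), so truth ages are
  recovered exactly when age assignment resolves with the same seed; with
  a different seed only ages inside polytomous clades can shift.
- **Planted effects**: `plant_trend` exponentially tilts one age group's
  composition along a scale gradient so the expected per-protein scale
  average shifts by a stated amount in raw scale units (the tilt parameter
  is solved per protein by root-finding); effect 0 is exactly the null.
  `null_config` gives orphan and ancient identical distributions for
  type-I calibration.

What the generator does *not* emulate: sequence evolution (no
mutation/selection trajectories — proteins are i.i.d. draws), gene loss
dynamics, domain architecture, length–composition coupling, or predictor
noise for external properties. Passing tests on synthetic data therefore
validate the pipeline's statistical machinery and its sensitivity to
planted effects, not the empirical claims about real proteomes.

## Numerical choices and problem sizes

- Analytic/simulator agreement is asserted within 5 binomial standard
  errors per amino acid per GC level on the full 28,400-ORF default batch.
- Chi-square goodness-of-fit of simulated codon counts uses ~40,000 codons
  per GC level at α = 0.001, pooling bins with expectation ≤ 5.
- Parameter-recovery experiments use 6–10 species × 100–150 proteins per
  dataset across 10 seeds; trend-calibration uses 200 species × 80
  proteins under the null, with counts checked against central 99%
  binomial bounds at p = 0.01. These sizes make every validation cheap
  enough to run routinely while keeping Monte-Carlo error far from the
  asserted margins.
- Degenerate inputs fail loudly: constant scales (correlation undefined),
  constant GC (regression undefined), empty samples, all-ambiguous
  sequences, non-multiple-of-3 ORF lengths, singleton rows in the ortholog
  matrix.
- GC values are fractions in [0, 1] everywhere; percentages appear only in
  presentation code.

## Known limitations

- The MRCA rule ignores convergent loss patterns that full asymmetric
  parsimony could in principle resolve differently on unbalanced trees.
- Ages within resolved polytomies depend on the resolution seed; only
  age-0 calls are invariant.
- The per-amino-acid codon GC convention (unweighted over synonymous
  codons) is one of several defensible choices; a usage-weighted variant
  would shift the scale correlations slightly.
- External predictor outputs are validated only as fractions in [0, 1];
  no attempt is made to model predictor disagreement.
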