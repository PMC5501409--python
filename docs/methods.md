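# Methods

This note documents the models, the simulator's assumptions, the numerical
choices, and what the validation suite does and does not establish.

## The population and its simulator

The design is a tri-parental advanced-backcross population: two elite spring
wheat cultivars (Devon, Triso) each crossed to the shared synthetic wild
donor Syn084L; per cross one F₁ plant, a first backcross giving 27 (family
D84) and 18 (family T84) BC₁ plants, a second backcross, then three selfing
generations; 154 + 205 = 359 BC₂F₄ lines genotyped at mapped biallelic SNPs
scored as donor-allele ("exotic") dosage 0/1/2.

The simulator reproduces this pedigree meiosis by meiosis:

- **Mapping function.** Haldane, r = (1 − e^(−2d/100))/2, no crossover
  interference; chromosomes assort independently.  Chosen as the simplest
  function consistent with additive cM distances; the workflow itself never
  depends on the interference model.
- **Line genotype.** The BC₂F₄ plant's genotype is the line genotype.  The
  two bulk-propagation cycles to F₄:₆ and DNA pooling over 12 plants are not
  modelled, because the segregation expectation used throughout
  (0.859375 : 0.03125 : 0.109375) is the BC₂F₄ single-locus expectation:
  the F₁ is fully heterozygous, each backcross halves heterozygosity into
  the recurrent class, each selfing halves it splitting the loss equally
  between both homozygous classes.
- **BC₁ nesting.** Lines are assigned to BC₁ founder plants uniformly at
  random; founders are configurable (default 27/18).  This nesting makes
  lines within a family correlated — see "segregation-test calibration"
  below.
- **Map.** By default ~4,096 loci spread evenly over 21 × 160 cM
  chromosomes (~0.8 cM spacing, the density of a 90k-array consensus map
  after informativeness filtering).  Scaled-down maps used in tests keep
  this per-marker spacing and shorten chromosomes instead, because the
  1 cM cofactor-exclusion window only functions on maps at least as dense
  as the window.
- **Missingness.** Independent per call at a configurable rate (default 2%
  in the study preset).  No other genotyping-error mechanism is modelled.
- **Raw array states and family divergence.** Exotic dosage alone makes the
  two families statistically exchangeable, which contradicts the observed
  population structure (families clearly separated on PC1).  Real arrays
  additionally contain loci where the two elite parents carry different
  alleles and the donor is heterozygous; at such a locus each family's F₁
  fixes one donor allele, and the raw genotype states (what the array
  reports, and what similarity analyses use) become family-asymmetric,
  while exotic dosage keeps its meaning.  The simulator models this with a
  `divergent_fraction` parameter, default 0.65, set once so that the PCA of
  the similarity matrix reproduces the observed geometry (~82% of variance
  on a family-separating PC1, ~12% on PC2); family separation itself is
  robust for any fraction ≳ 0.35.  At a divergent locus the donor transmits
  its recurrent-matching allele with probability 1/2, in which case the
  locus is realized-monomorphic in that family and the QC polymorphism
  filter removes it — so only about a quarter of divergent loci survive
  into the informative set, as in real data where informative markers are a
  small subset of assayed ones.

### Phenotype model

Y = μ_trait + Σ(dosage × a) + G + E + N + G×E + G×N + ε, all random terms
Gaussian, one record per line × environment × N level (default 3
environments × 2 nitrogen levels).  The study preset plants three QTL with
exotic effects (2a) of +0.70 on GPC (grain protein content, %), −8.98 on GH
(grain hardness, %), +7.31 on SED (sedimentation volume, ml), at 6B/5D/4B
positions.  Per-trait means, environment/N effects and variance components
were fixed once to match the published trait summaries — e.g. GPC:
V_G = 0.26, V_G×E = 0.10, V_G×N = 0.05, V_R = 0.60, N effect ±1.16, giving
entry-mean SD ≈ 0.65, within-N SD ≈ 0.75, h² ≈ 0.6, and an N0→N1 mean shift
of 11.4 → 13.7; GH carries a large polygenic background (V_G = 8) plus its
major 5D locus so that h² ≈ 0.93 and the locus explains ~50% of line-mean
variance.  What the generator does *not* emulate: genetic correlation
between traits beyond planted pleiotropy (observed r(GPC, SED) = 0.87 in
the real data has no counterpart), selection during propagation, dominance,
epistasis, spatial field trends.  Passing tests therefore validate the
machinery and its calibration under this additive Gaussian world, not the
full complexity of field data.

## Marker quality control

Filter order: failure rate → polymorphic in both families → non-distorted
segregation → mapped; mean imputation afterwards, on the informative set
only.  The segregation χ² uses family-pooled counts against the
scheme-level expectation with df = 2 (three fully specified classes), no
continuity correction, α = 0.05 per SNP unadjusted.

**Calibration caveat.**  With the real pedigree the per-locus genotype
counts are *not* multinomial: all lines of a family descend from one F₁ and
27/18 BC₁ plants, so founder sampling makes counts overdispersed and about
20% of clean markers exceed the α = 0.05 cut.  This is a genuine feature of
nested backcross designs (and one reason real studies discard a large share
of markers), not an error mechanism.  The test suite therefore checks the
χ²'s nominal α-calibration on an independent-pedigree simulation (one BC₁
plant per line), and treats the overdispersed rejection rate under the
study pedigree as expected behaviour.

## Phenotype statistics

- **Adjusted line means.**  The mixed LSMEANS model (line + environment +
  line×environment with one observation per cell) confounds the interaction
  with the residual, so means are computed from the fixed-effects additive
  two-way model value = line + cell by least squares, where a "cell" is an
  environment (within-N scope) or an environment × N combination (across-N
  scope); the line mean is the fitted value averaged over cells.  Under
  balance this equals plain averaging exactly; under unbalance it is the
  usual LSMEAN.
- **Variance components.**  Estimated by the ANOVA expected-mean-squares
  method on the crossed design (MS_G = V_R + nV_G×E + eV_G×N + enV_G etc.),
  with a closed-form path for complete balanced data and a Type-I
  mean-squares fallback otherwise.  Under balance this coincides with REML
  whenever estimates are interior, and with the classical SAS VARCOMP
  default; it is deterministic and fast enough to repeat over many
  simulation seeds.  Negative estimates are truncated at zero — this is
  what produces h² = 0 for traits without genetic variance (the ratio
  traits in the original study).
- **Heritability.**  Entry-mean broad-sense formulas as printed above, with
  e = number of environments and n = number of N levels; reported on both
  [0,1] and percent scales.
- **Ratio traits.**  Trait ratio = N0 mean / N1 mean per line; lines with a
  missing side or a zero denominator are dropped with a warning.  Ratio
  variance components use the within-N model on per-environment ratios.

## Association scan

- **"Mixed" model as fixed-effects OLS.**  The per-SNP model contains no
  random term beyond ε once line means have absorbed environments, so each
  SNP is tested by ordinary least squares with a t-test on the dosage
  slope.  Family main effect and SNP×Fam interaction enter only in
  across-family scopes; SNP×Fam is estimated and carried in the scan but
  does not gate MTA status (main effects only).
- **Cofactor selection.**  Greedy forward selection, exact incremental RSS
  via orthogonalization, stopping by the *extended* Schwarz criterion with
  per-parameter penalty log n + 2 log p.  The extension matters: each step
  selects the best of p ≈ 300–4,000 markers, whose maximal χ² under a pure
  noise trait is ≈ 2 log p ≈ 12–17 and beats the classical log n ≈ 5.9
  penalty, so classical-BIC forward selection admits noise cofactors and —
  worse — the overfitted residual inflates every downstream test statistic.
  With the extended penalty, null selections are empty or nearly so, and
  the scan's family-wise error holds.  Selection is repeated per trait ×
  model scope on that scope's lines and means.
- **1 cM exclusion window.**  Two-sided, same chromosome; cofactors at
  distance ≤ 1 cM from the tested SNP (always including the tested SNP
  itself) leave that SNP's model, so a cofactor sitting on the QTL cannot
  mask the markers that tag it.
- **Multiple testing.**  Holm step-down Bonferroni within one trait × model
  application (all SNPs scanned in that application form the family);
  no cross-trait correction.  MTAs require p_Bon < 0.05, strict.
- **Explained variance.**  R²_adj of a SNP is its incremental R²
  ((SSE_reduced − SSE_full)/SS_total, the reduced model dropping SNP and
  SNP×Fam), degree-of-freedom-adjusted as R² − (1−R²)·k/(n−k−1) with k the
  number of fitted covariates, clipped to [0, 1].  This is a standard
  approximation to the exact adjusted-variance estimator used in the
  original SAS workflow, whose precise form is not recoverable.
- **Known bias.**  Effect estimates at declared MTAs carry winner's-curse
  inflation (conditioning on significance); the recovery tests therefore
  check sign and ~±10–20% magnitude agreement at the peak, not
  unbiasedness of the selected subset.

## QTL summarization

Single-linkage chaining: MTAs of one trait on one chromosome merge while
consecutive peak positions are < 5 cM apart.  Chaining (rather than
pairwise-complete linkage) is what yields the wide ranges a major locus
accumulates across model applications.  Peak SNP = smallest p_Bon, ties by
position then SNP id.  Stability: a QTL is across-families if any member
comes from an across-family model or from both families' within-family
models (the latter rule is a deliberate choice; such QTL are flagged in the
members table), and analogously across-N.  Co-located QTL of different
traits remain separate records.  Names follow
Q<trait>.<population|family>-<chromosome>[.letter].

## Problem sizes in the validation suite

The test suite runs everything it asserts: the full-scale study (359 lines,
4,096 loci) for genome composition; reduced maps with the same ~1 cM marker
spacing (21 × 13–20 cM chromosomes, 210–420 loci) for the repeated-seed
power, error-rate and separation experiments (100 seeds for QTL recovery
and null family-wise error, 10–60 seeds elsewhere); and closed-form or
brute-force oracles (explicit normal equations, literal Holm rule, textbook
χ², dense eigensolvers) for every numerical kernel.  Reproduction of the
published phenotype tables themselves requires the original per-line
supplementary data, which have no public accession; the corresponding check
runs only when a copy is placed under `data/sw84_supplementary/`.

## Numerical conventions

Tab-separated UTF-8 artifacts with `NA` missing sentinel (`NA`, empty, `.`
accepted on input), `#` headers carrying version, seed and a hash of the
scientific configuration; cM printed at 2 decimals.  Least squares via SVD
pseudo-inverse (rank-deficient designs get minimum-norm solutions and
correct residual df); χ² with an infinite statistic when an impossible
class is observed; all simulator randomness flows from a single
`numpy.random.Generator`.
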