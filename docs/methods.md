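# Methods

This document specifies the statistical models, defaults, and numerical
choices implemented in `mlcqtl`. Units: genetic distance in centimorgan
(cM), variance components in squared trait units, heritability and p_G as
proportions (p_G reported in percent).

## 1. Population type and genotype coding

The package targets sets of **connected biparental DH families**: each line
is fully homozygous, produced from one meiosis of an F1. Marker genotypes
are coded 0/2 (non-reference / reference homozygote; 1 never occurs in DH
material) with NaN for missing. Families may share parents; each family's
allele-substitution effects are estimated separately throughout.

## 2. Linkage and expected allele counts

* Map distances are converted to recombination fractions with the
  **Haldane** function `r = 0.5 (1 − e^(−2d/100))` (Kosambi available).
* At a scan position flanked by informative markers at recombination
  fractions `r1` (left) and `r2` (right), the expected reference-allele
  count in a DH line follows from one-meiosis transmission:
  `P(l, x, r) = 0.5 · T(l→x; r1) · T(x→r; r2)` with `T = 1−r` for equal
  alleles and `r` otherwise, and the count is `2 · P(x = ref | l, r)` —
  e.g. both flanks reference gives `2(1−r1)(1−r2) / (1−r1−r2+2 r1 r2)`.
  A brute-force enumeration of this two-interval space is kept in the test
  suite as an oracle (agreement to 1e-12).
* Missing flanks degrade gracefully: one informative flank gives
  `2(1−r)` / `2r`; no informative flank on either side falls back to twice
  the family's reference-allele frequency at the nearest marker.
* For each line the *nearest informative* flanking markers are used, walking
  outwards over missing genotypes and compounding distances.

## 3. Phenotypic analysis

Field plots follow a p-rep layout: entries appear once or more per
environment plus replicated checks. Two mixed models are fitted per
developmental stage:

1. **Variance components**: genotype, genotype-by-environment and residual
   variances (`σ²_G`, `σ²_GxE`, `σ²_e`) by REML. The solver builds the
   sparse mixed-model equations, profiles out `σ²_e`, and optimises the
   restricted likelihood over the log variance ratios with Nelder–Mead.
   A dense-matrix restricted likelihood (`−2lR = log|V| + log|X'V⁻¹X| +
   y'Py`) is kept in the tests as an independent check that the fitted
   point is a local optimum. On balanced data the REML solution must match
   the closed-form ANOVA expected-mean-square identities
   (`σ²_e = MSE`, `σ²_GxE = (MS_GE − MSE)/R`,
   `σ²_G = (MS_G − MS_GE)/(R·E)`) to rtol 1e-3.
2. **BLUEs**: genotype fixed, environment and genotype-by-environment
   random, giving one adjusted entry mean per line and stage for all
   downstream mapping.

**Heritability** on an entry-mean basis:
`h² = σ²_G / (σ²_G + σ²_GxE/E + σ²_e/(E·R))`, with `E` environments and
mean replication `R`. With the published components of the motivating
study design this gives 0.93 / 0.97 / 0.91 for the three stages; note the
middle value is 0.97 by this formula even where 0.96 has been printed
elsewhere — the formula, not the rounding, is what the package asserts.

## 4. Multi-family composite interval mapping

Scan model at position `q`:

```
Y = J m + X(q) b(q) + Σ_c X(c) b(c) + e
```

* `J` — family incidence (family-specific intercepts).
* `X(q)` — expected allele counts, one column per family **segregating** at
  `q`; non-segregating family columns are dropped (zero extra df).
* Cofactors `X(c)` — marker columns chosen by forward–backward stepwise
  selection under BIC on the full-marker model; during the scan all
  cofactors within **10 cM** of the tested position are excluded.
* Test statistic: `LOD = n · ln(RSS_reduced/RSS_full) / (2 ln 10)` where the
  reduced model omits `X(q)`.

**Thresholds.** Genome-wide significance by permutation: entry means are
permuted **within families** (preserving family structure), cofactors are
re-selected per permutation, and the α-quantile of the max-LOD null
distribution is the threshold (defaults: 2 000 permutations via the CLI
scan command, α = 0.10).

**QTL calling.** LOD local maxima above the threshold; peaks within 10 cM
are merged; support intervals are the LOD − 1 fall-off around each peak.

**Final model and p_G.** All called QTL enter one joint model. The
proportion of genotypic variance of QTL `i` is the drop-one difference in
adjusted R² against a family-means baseline, divided by `h²`; the total p_G
uses the full model's adjusted R². Dividing by `h²` converts phenotypic to
genotypic variance; the family-means baseline removes between-family
variation, so p_G refers to within-family (segregation) variance.

**Stage comparison.** QTL from different stages are matched by union-find
clustering within a 10 cM window, yielding Venn counts of stage-specific
vs shared QTL and per-cluster p_G trajectories.

## 5. Cross-validation

Stratified k-fold (default 5-fold, 20 replicated runs): each family is
split into k near-equal parts, so every estimation set keeps all families.
The *entire* pipeline (cofactor selection, scan, calling, final fit) reruns
on each estimation set; the genome-wide threshold is computed once on the
full data and reused (option to recompute). On the matching test set, p_G
is the squared within-family-centred correlation between predicted
genotypic scores and observed entry means, divided by `h²`. The headline
statistic is the **relative bias** `100 (p_G-ES − p_G-TS) / p_G-ES`
(one decimal; undefined at p_G-ES = 0), plus the frequency with which each
5 cM sliding window is hit across estimation sets.

## 6. Epistasis scan

For locus pairs on a grid (default 5 cM), the additive model is extended
with per-family products of *centred* expected counts
`(X(q) − 1) ⊙ (X(q') − 1)`; in a balanced DH family this column is
orthogonal in expectation to both main effects. The interaction is tested
by LR against the two-locus additive model, `χ²` with df = number of
families segregating at both loci. Same-chromosome pairs closer than
30 cM are skipped (near-collinear expected counts). Significant pairs are
pruned to 2-D local maxima (10 cM in both coordinates).

**Multiplicity.** The per-test threshold is `α / C(2L, 2)` with `L` linkage
groups — the classical "two independently segregating regions per
chromosome" argument. `L` is an explicit input (CLI `--lg`), defaulting to
the map's chromosome count. *Caveat, measured on this implementation*: on
a desk-scale genome (5 chromosomes × 100 cM, 5 cM grid, 647 lines) this
correction controls ~45 region pairs while the scan performs ~5 000
correlated tests; only 11 of 20 pre-registered null genomes produced zero
significant pairs. The corresponding acceptance test asserts the
pre-registered ≥ 18/20 bound and **fails honestly**; users wanting strict
genome-wise control should use a stronger correction (e.g. Bonferroni on
the actual number of grid pairs) via the explicit `threshold` argument.

## 7. Data simulator

`mlcqtl.simpop` generates: a consensus map (even spacing, optional
jitter); DH families by simulating one meiosis per line (recombination
between adjacent markers with probability `r` from the mapping function,
XOR-accumulated phase); genetic values from a truth set of additive QTL
and epistatic pairs (family × stage effect matrices, loci realized at the
nearest marker — `realized_locus()` exposes that mapping); and either
full p-rep field trials (environment effects, GxE, plot error, checks) or
entry means targeting a given within-family `h²` directly.

`standard_truth()` builds the default architecture: one growing locus,
small shared/stage-specific loci, two weak epistatic pairs, and one major
locus segregating in a single family, calibrated analytically (unlinked
loci, `var(z) = 1` within a family) to contribute a target share (default
45%) of the family-mean-centred genotypic variance. Because that
calibration assumes the major locus is unlinked to all other loci, its
chromosome is reserved for it alone whenever the map has ≥ 2 chromosomes;
all loci are kept ≥ 15 cM apart within a chromosome so each claims its own
nearest marker.

Defaults (`default_config`): 21 chromosomes × 120 cM at 5 cM spacing, four
connected families of 131/120/200/196 lines (647 total), 3 stages, 4
environments, `σ²_GxE = 12`, `σ²_e = 6`, `σ²_env = 25`. These sizes are
package choices for a realistic desk-scale study; validation tests use
smaller genomes (3–7 chromosomes) purely for runtime.

## 8. Numerical choices

* **RSS via orthonormal bases.** Each model's column space is reduced to an
  orthonormal basis (QR with column-scaled rank tolerance); `RSS = y'y −
  ‖Q'y‖²`. The scan precomputes reduced/full bases per position, so a
  permutation pass is a single matrix product.
* **Centring for cancellation.** `y` is centred before any `y'y − ‖a‖²`
  computation (scan, interaction test). Since the intercept lies in the
  column space of `J`, this is an exact-arithmetic no-op, but it removes
  catastrophic cancellation for traits with large means (shift invariance
  of LOD holds to < 1e-9).
* **RSS floor.** RSS values are floored at a tiny multiple of `y'y` to keep
  log-ratios finite for noise-free phenotypes.
* **BLUE solver conditioning.** The environment random block is coded with
  sum-to-zero contrasts, which removes the grand-mean confounding between
  the fixed genotype block and environment indicators; variance ratios are
  clipped (`λ_env ≤ 1e12`, `λ_gxe ≤ 1e6`) and one iterative-refinement step
  follows the sparse LU solve. With zero noise, BLUEs equal the true
  entry means to < 1e-8.
* **Permutation reproducibility.** All simulation and permutation seeds
  derive from `numpy.random.SeedSequence`; the CLI derives per-stage child
  seeds from the master seed so stages are independently reproducible.
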