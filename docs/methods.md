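# Methods

This note records the models implemented in `polygs`, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions that were genuinely open.

## Setting

Parent selection in an outbreeding autotetraploid forage crop: candidate
parents are cloned, polycrossed, and judged by the biomass yield of their
half-sib progenies grown in replicated trials. The additive merit inferred
that way (the parent breeding value) is the prediction target. Genotyping is
GBS without a reference genome, which brings three complications the
pipeline is built around: reference-free SNP discovery from sequence tags,
heavy marker-specific missingness, and pseudo-diploid genotype coding forced
by the tetraploid dosage ambiguity of low-depth GBS (all of Aaaa/AAaa/AAAa
are scored as one heterozygote class).

## Tag-pair SNP calling

Reads must begin with a known barcode immediately followed by the
restriction-site remnant (default `CWGC`, the ApeKI signature, IUPAC-aware);
they are trimmed to 64 bp after barcode removal, and reads containing an
ambiguous base in the tag are dropped (the upstream quality-filter criteria
are not standardised; an N-free tag is the minimal surrogate and is recorded
here as such). Identical trimmed reads form a tag; tags with fewer than 10
reads summed over individuals are excluded from pairing; pairs at Hamming
distance exactly 1 define candidate SNPs.

Open choices, fixed as follows:

- **Networks.** A tag with more than one 1-bp neighbour indicates a
  repeat/paralog family; all tags in such networks are discarded and only
  reciprocal-unique pairs are kept. Consequence worth knowing: the emitted
  SNP set is not strictly monotone in the tag-count threshold — removing a
  low-count tag can free a previously ambiguous pair. The guarantee that does
  hold unconditionally is that below-threshold tags never enter any pair.
- **Genotype calls.** The read-depth rule is not standardised for this
  procedure; defaults are total depth < 3 → missing, both alleles with ≥ 2
  reads → heterozygote, otherwise the homozygote of the observed allele.
  Both cut-offs are configurable; at the simulated mean depth of 60 the
  round-trip concordance with the generating genotypes is ≥ 99 %.
- **Naming.** SNP ids are content hashes of the sorted tag pair, so joint
  calling across cohorts yields identical names with no reference genome,
  which is what makes the COMMON intersection well defined.

## QC and imputation

Order is fixed: missing-rate filter (marker kept iff rate ≤ threshold;
supported grid 0.10–0.70), then imputation, then MAF filter (kept iff
MAF ≥ 0.025, with p computed as mean(code)/2). Imputed values are
discretised to the nearest of {0, 1, 2}; exact ties (0.5, 1.5) round to the
heterozygote, which absorbs three of the five tetraploid dosage classes and
is therefore the maximum-prior call.

- **MNI** fills each marker with its observed mean.
- **SVDI** regresses each marker's observed entries on the individuals'
  coordinates along the k leading axes of the mean-filled, column-centred
  matrix (default k = 10, truncated to rank; a conventional scale for this
  family of methods).
- **RFI** is the iterative marker-wise random-forest scheme (100 trees per
  marker, mtry = p/3, visiting markers by increasing missingness), stopped
  when < 0.5 % of imputed cells change between sweeps or after 10 sweeps.
  The forest regressions are scikit-learn; the iteration loop is this
  package's.
- **REF** is a synthetic stand-in for an order-based reference imputer:
  marker columns are randomly permuted before mean imputation and restored
  after. Column-wise imputation is order-invariant, so REF ≡ MNI by
  construction; it exists to keep the four-imputer benchmark grid shape and
  to make the order-irrelevance of unordered panels explicit, and its output
  is labelled as a surrogate.

On block-correlated genotypes with 30 % missingness the cell-error ordering
RFI ≤ SVDI ≤ MNI is reproduced by the acceptance checks; with exchangeable
markers all three collapse toward the mean-imputation error, since there is
no correlation to exploit.

## Progeny-trial BLUP

The trial model is a two-way complete-block ANOVA (progeny + replication).
Expected-mean-squares estimators give S²_e = MS_error and
S²_hs = (MS_progeny − MS_error)/r, the latter truncated at zero (with a
warning) so that h²_B = S²_hs/(S²_hs + S²_e/r) stays in [0, 1]. Adjusted
phenotypes are progeny means shrunk toward the grand mean by h²_B; this
preserves the grand mean exactly, scales the variance by h²_B², and never
reorders progenies. Incomplete-block recovery is deliberately not
implemented: both trial designs are treated as complete blocks, matching the
stated common adjustment procedure.

## Prediction models

All seven models share one contract: a Model built from (y, G), a `fit()`
returning a Results object with the intercept, per-marker effects (linear
models) or the fitted machine (kernel/tree models), `predict(G_new)` and
`summary()`. Marker columns are centred internally (the intercept absorbs
the means); in exact arithmetic this changes nothing, numerically it
conditions the systems.

- **rrBLUP.** y = μ + Gu + ε with u ~ N(0, Iσ²_u). λ = σ²_e/σ²_u is
  estimated by REML: one eigendecomposition of GG′, then bounded 1-D
  optimisation of the restricted log-likelihood over log λ ∈ [−12, 12]
  (tolerance 1e-6). Effects come from the dual closed form
  û = G′(GG′ + λI)⁻¹(y − μ), which the tests verify against the primal
  penalised least-squares solve to 1e-8, and against the equivalent
  kinship-form predictions (GBLUP duality) to 1e-6.
- **Bayes A / Bayes B / Bayesian Lasso.** Single-site Gibbs samplers with
  the usual conditional updates; defaults 5000 iterations, 500 burn-in,
  thinning 5; effects are posterior means of the retained samples. Hyper-priors
  are not printed for the original analyses and are set to conventional
  values, all configurable: Bayes A marker variances scaled-inv-χ²(ν = 4.2)
  with scale solved from the proportion-of-variance heuristic at R² = 0.5;
  Bayes B adds a point mass at zero with prior exclusion π₀ = 0.95 and a
  correspondingly rescaled slab; the Lasso uses the exponential-mixture
  hierarchy with λ² ~ Gamma(1, 10⁻³) updated by Gibbs. Residual variance is
  scaled-inv-χ²(ν = 4) throughout.
- **SVR.** ε-insensitive support vector regression through scikit-learn,
  C = 1, ε = 0.1, solver tolerance 1e-3. The Gaussian bandwidth follows the
  median heuristic (γ = 1/(2σ²), σ = median pairwise distance) — unstated in
  the original setting, standard choice. The linear-kernel machine exposes
  its primal weight vector as marker effects; tests verify it against an
  independent quadratic-programming solve of the dual.
- **RFR.** 500 trees, mtry = ⌈p/3⌉, minimum node size 5, through
  scikit-learn, seeded for reproducibility.

## Accuracy evaluation

Cross-validation draws, per repetition, an independent 90/10 split over
genotypes (validation size = round(0.1 n), sampled without replacement) and
scores Pearson r between predictions and observed validation phenotypes;
500 repetitions by default, all retained in the report alongside their mean
and SD. Repetition seeds derive from the master seed by hashing a counter,
so grids parallelise and reproduce exactly. A repetition whose predictions
are constant scores r = 0 (with a warning) rather than being dropped, which
keeps the report shape deterministic.

Cross-population prediction z-normalises phenotypes within each population,
trains on all genotypes of one population and scores on all of the other,
restricted to the COMMON (name-intersected) marker panel.

The gain comparison is r_A/c_gs vs h_N/c_conv with h_N = √h²_N rounded to
two decimals (as the comparison is conventionally quoted; pass
`round_h=None` for the unrounded value). At r_A = 0.32, h²_N = 0.21,
1-year vs 5-year cycles the ratio is 0.32/(0.46/5) = 3.478 — over
three-fold.

## Kinship and association

Kinship is the centred cross-product K = ZZ′/(2Σp_j(1−p_j)) on the
pseudo-diploid codes, monomorphic columns excluded (the underlying method
reference does not print a formula; this is the standard genomic-relationship
form for {0,1,2} codes). Association is the one-shot variance-component
scheme: (σ²_g, σ²_e) by REML under the no-marker null, then per-marker GLS
Wald tests with those components fixed — O(markers) after one
eigendecomposition. p-values use the t distribution with n − 2 degrees of
freedom, which keeps the null rejection rate at nominal level in the
calibration checks (n = 200, 2000 null markers). With K = I the test reduces
exactly to per-marker ordinary least squares. No multiple-testing correction
is applied; a Bonferroni column is emitted as a labelled convenience
extension. Markers without a map entry are displayed on the fictitious
chromosome "N" with sequential pseudo-positions.

## Synthetic-data generator

What it emulates: two reference populations of the study's sizes (~124 and
~154 genotypes) on a shared marker panel; autotetraploid Hardy–Weinberg
dosages Binomial(4, p) collapsed {1,2,3} → 1; additive polygenic phenotypes
with the target narrow-sense heritability enforced by scaling the residual
SD to the realised genetic variance; per-marker missing rates drawn from
Beta(1.2, 3) so threshold filtering is non-degenerate; half-sib progeny
trials where the progeny effect is ½ × parent breeding value plus a
Mendelian-sampling term of equal variance, rescaled to the requested S²_hs;
negative-binomial read depths (overdispersion typical of GBS) with reads
split between a marker's two tags binomially at the true allele fraction
(dosage/4).

Key defaults and why:

- **n_qtl = 50.** Enough loci for an approximately normal breeding value,
  few enough that a ~300-genotype population resolves the architecture.
  Chosen once as the generator's oligo/polygenic stand-in; no published
  architecture exists for this trait to calibrate against.
- **Haplotype-block LD (`n_blocks`).** Markers are exchangeable by default.
  With `n_blocks` set, markers in a block copy a latent block dosage with
  fidelity ρ = 0.9 and deviate independently otherwise, giving ~`n_blocks`
  effective loci. The accuracy studies use n_blocks = 100 at m = 1000: with
  fully exchangeable markers the rrBLUP accuracy ceiling at n = 300,
  h² = 0.5 is ≈ √(nh²/(nh² + m))·√h² ≈ 0.26, far below what linked real
  genomes support; 100 effective loci put the expected accuracy near
  0.7·√h² ≈ 0.49, the same accuracy-to-√h² ratio the real germplasm shows.
- **Read depth** mean 60 with negative-binomial dispersion 5 for round-trip
  studies. Real GBS depth distributions for these libraries are not
  reported; these are conventional desk-scale values.

What it does not emulate (and therefore what passing tests do not show):
linkage maps and realistic along-chromosome LD decay, selection history,
genotype-by-environment interaction, multi-harvest repeated measures,
non-additive genetic variance, base-quality realism in reads (fixed Q40) and
barcode/sequencing error structure beyond uniform substitution. Accuracies
measured here characterise the implementation under a known additive truth,
not expected field performance.

## Problem sizes used by the reproduction script

`scripts/acceptance.py` uses: 3 populations of 300 × 1000 markers
(100 blocks, 50 QTL, h² = 0.5) for signal recovery (100 CV repetitions each)
and for the permutation null (10 permutations × 50 splits); 200 × 400
(40 blocks) twin populations for cross-population transfer; 100 × 120
(12 blocks, 30 % missing) for the imputation comparison; 24 × 80 at mean
depth 60 for the calling round trip; 200 × 2000 null markers plus a
20 %-variance QTL scan for association calibration; 2000 progenies × 2
replications (×3 trials) for variance-component recovery. These sizes make
each Monte-Carlo standard error small relative to the property being
checked while keeping the whole script in the minutes range on one CPU.

## Known limitations

- The Gibbs samplers are single-site and pure NumPy; chains on tens of
  thousands of markers are slow (seconds per thousand markers per thousand
  iterations). The study-scale defaults are fine; genome-scale Bayesian runs
  would want a compiled inner loop.
- `estimate_variance_components` requires complete blocks; incomplete-block
  (lattice) recovery is out of scope by design.
- Serialisation to the JSON container covers linear-effects models; kernel
  and forest machines refuse with an explicit error rather than pickling.
- The EMMAX approximation holds variance components fixed across markers;
  for markers with very large effects the exact per-marker REML test would
  differ slightly.
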