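# Methods

This note documents the statistical procedures `triadscan` implements,
the design of its synthetic-cohort generator, the numerical choices
behind both, and what the test suite does and does not establish.

## Dose–response model and IC50

Viability as a fraction of untreated control is modelled by the
log-logistic curve

    f(x) = c + (d − c) / (1 + exp(b (ln x − ln e)))

with hill slope `b`, lower asymptote `c`, upper asymptote `d` and
midpoint concentration `e`. The 3-parameter variant fixes `c = 0` (the
standard 3PL; viability is assumed to vanish at saturating dose). IC50 is
reported as the *relative* ED50 — the midpoint parameter `e`, the dose at
which the response is halfway between the asymptotes; an absolute
half-of-control crossing is available as an option.

Fitting is nonlinear least squares in `(b, c, d, ln e)`. The residual
surface is multimodal, so the optimizer ranks a 30-point start grid
(slopes ±0.5, ±1, ±2 × midpoints at five quantiles of the log-dose range)
by raw RSS and polishes the four best starts with Levenberg–Marquardt.
`auto` mode fits both variants and selects by AIC, falling back to the
3PL when the 4PL lower asymptote goes negative or fails to converge.
Curves with essentially flat response (SD < 1e-8, or |d − c| below 1e-6
relative) are flagged non-converged: their midpoint is unidentifiable,
and such samples are excluded downstream (a policy choice; exclusion on
non-convergence is this package's convention).

Accuracy is bounded by the assay design, not the optimizer: with eight
ten-fold dilutions, unit hill slope and viability noise SD 0.05 (the
generator defaults), a dense grid-search global least-squares oracle
attains a median |log₁₀ ÎC50 − log₁₀ IC50| of ≈0.058, and the multi-start
fit lands at ≈0.065–0.07. Denser dose spacing, steeper slopes or
replicate wells would all tighten this; a single ten-fold series cannot.
This is a known limitation.

Phenotype transforms: log₁₀ (gemcitabine-style), or the van der Waerden
rank-normal transform Φ⁻¹(rᵢ/(n+1)) with average ranks for ties
(AraC-style). The vdW output depends only on ranks, hence is invariant
under strictly monotone transforms of the input.

## Genotype QC

Filters run in a fixed order: samples with call rate < 0.95 are dropped
first (so one bad DNA cannot fail many SNPs), then SNPs failing, in
order, call rate < 0.95, exact Hardy–Weinberg P < 0.001, MAF < 5%. The
recorded failure reason is the first failed filter. MAF folds the
alternate-allele frequency into [0, 0.5] over non-missing calls and is
invariant to allele relabelling.

The HWE test is the exact conditional test: given the observed allele
counts, heterozygote counts are distributed hypergeometric-type under
random mating, and P sums the probabilities of all outcomes no more
probable than the observed one (two-sided, non-mid-p). Monomorphic SNPs
return P = 1 by convention. Implementation uses log-factorials with a
per-(n, allele-count) cache; the suite verifies it against a
rational-arithmetic enumeration oracle. Being discrete, the test is
conservative: P(p ≤ α) ≤ α, with realized rejection rates around
0.6–0.7 α at α = 0.001 and n = 174 — the suite checks conservativeness
plus a non-degeneracy floor, not exact uniformity, which no exact test of
this form can deliver.

HWE is tested on the pooled cohort by default, matching the original
flat description; pooling multi-ethnic panels inflates failures (Wahlund
effect), so per-population testing is available but not default.

## Covariate adjustment

Population-stratification eigenvectors are the left singular vectors of
the standardized genotype matrix: each SNP centered by 2f̂ and scaled by
√(2f̂(1−f̂)), missing calls mean-imputed first, monomorphic columns
dropped. Components come in decreasing-eigenvalue order with the sign
fixed so each component's largest-magnitude loading is positive. No LD
pruning is applied before the decomposition (simplest faithful default).

The adjustment design is intercept + reference-coded population dummies +
sex indicator + optionally five eigenvectors: k = 8 non-intercept columns
for a three-population, two-sex cohort when SNPs are involved, k = 3
otherwise. Race dummies and eigenvectors are deliberately allowed to
coexist although correlated in expectation; numerically aliased columns
are dropped with a warning and k adjusted, which also handles
single-population or single-sex cohorts gracefully.

## Association statistics

The core statistic is the partial Pearson correlation: residualize
predictor and response on the design (QR projection) over the per-test
complete cases, then correlate the residuals. Genotypes enter additively
(0/1/2; continuous imputed dosages on the same footing). Significance is
the Wald test t = r√(df/(1−r²)) with df = n − 2 − k on Student's t — the
standard partial-correlation degrees of freedom, with n the per-test
complete-case count. Predictors collinear with the design (zero residual,
relative tolerance 1e-10) are skipped and logged, never aborting a scan.

Storey q-values use the smoother π̂₀: π̂₀(λ) = #{p>λ}/(m(1−λ)) on
λ ∈ {0.05, …, 0.95}, a natural cubic spline through those points
evaluated at λ = 0.95, clipped to [1/m, 1]. Below m = 100 tests the
smoother is unreliable and π̂₀ falls back to 1, the Benjamini–Hochberg
limit (and with π̂₀ = 1 the output equals BH exactly). Downstream
filtering always operates on raw P at 10⁻³/10⁻⁴; q-values are reported,
never used as filters.

Under Gaussian residuals the Wald test is exact for any fixed design and
predictor, so on structured-null simulations (population-differentiated
allele frequencies, population-shifted phenotypes) the adjusted scan's
type-I error is calibrated at α ∈ {0.05, 0.01, 10⁻³}; removing all
adjustment inflates it, which the suite checks as a stratification
sensitivity control.

## SNP loci

A locus is a ±100 kb closed window (1-based coordinates, boundary SNPs
included) around a seed SNP, qualifying with ≥2 member SNPs at P < 10⁻⁴
or one at P < 10⁻⁴ plus ≥3 additional members at P < 10⁻³ (members below
10⁻⁴ count toward the three a fortiori). Seeding is greedy best-first by
P with deterministic tie-breaks (chromosome, position, rsID); members
join at most one locus; a seed whose window fails the predicate is
retired as a seed but stays available as a member. This makes locus
counts well-defined and input-order invariant, and the implementation is
verified against an exhaustive candidate-seed enumeration oracle on
hundreds of randomized instances. Nearest-gene annotation measures
distance from the seed to the gene interval (0 inside), classifying
within/upstream/downstream (strand-aware when strand is given); ties go
to the lexicographically smaller symbol and are logged.

## Integrated (triad) analysis

Starting from SNPs with SNP–IC50 P < 10⁻³ (optionally restricted to
qualifying locus members — the default in the pipeline), join probesets
with SNP–expression P < 10⁻⁴, then keep pairs whose probeset also passes
expression–IC50 P < 10⁻⁴. All three thresholds are configuration values;
the published triad table itself reports expression–IC50 P-values up to
5×10⁻³, so the worked example disables that leg's filter to reproduce it.
Triads are labelled cis when SNP and gene share a chromosome and the SNP
lies within ±200 kb of the gene interval, inclusive, measured from the
gene boundary rather than the TSS (200 kb matching the span used for
imputation around candidate genes); otherwise trans. Pairs lacking gene
coordinates are flagged unclassifiable and excluded from cis counts. An
independent validator re-checks every emitted triad's thresholds.

Supporting operations: imputed-dosage panels are filtered at dosage
R² ≥ 0.3 and MAF ≥ 0.01 (MAF from mean dosage/2, folded); imputation
concordance is the mean squared difference between dosage and genotype
allele counts over paired non-missing entries (range [0, 4], smaller is
better; optional orientation harmonization with a warning); LD is the
composite r² — squared Pearson correlation of unphased 0/1/2 dosages —
since phase is unavailable.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
not any particular biology.

*Genotypes.* Balding–Nichols: per LD block an ancestral frequency
p ~ Uniform(0.05, 0.95), per population a frequency Beta-distributed with
mean p and variance p(1−p)·fst (single fst = 0.02 for all three
populations — the simplest model producing the stratification the
eigenvector adjustment exists to remove), genotypes Binomial(2, p_pop).
LD comes from block-copying: within a block (10 SNPs, never spanning
chromosomes, all sharing the block's frequencies) each allele copies the
previous SNP's allele with probability 0.8, else draws fresh, giving
adjacent-genotype correlation ≈ the copy probability and r² its square.
Cohort: 60 CA / 54 AA / 60 HCA = 174 samples; sex Bernoulli(0.5)
independent of everything; 1% missing calls at random.

*Expression.* Probeset value = baseline + β·genotype for planted eQTL
pairs + per-(population, probe) offsets (SD 0.3) + sex offsets (SD 0.1) +
N(0, 1) residual. Planted cis pairs place the gene interval over the SNP;
trans pairs place it on another chromosome.

*Phenotype.* log₁₀ IC50 = population shift (±0.1) + γ_snp·genotype for
direct pharmacogenomic SNPs + γ_expr·(standardized expression) for the
planted eQTL probesets + N(0, σ_ic50). Defaults (γ_snp = 0.25,
γ_expr = 0.20, β = 1.5, σ_ic50 = 0.12, one cis + one trans eQTL + one
direct SNP, all planted at SNPs with MAF ≥ 0.2 in distinct LD blocks)
come from a closed-form variance budget chosen so the direct SNP's
expected partial correlation with log₁₀ IC50 is ≈0.4 at n = 174 and the
eQTL / expression–IC50 legs sit near |r| ≈ 0.55–0.7 — the magnitude of
the association signals this class of LCL studies reports. Viability
readouts then follow the 4PL curve with midpoint 10^(log₁₀ IC50), unit
hill slope, asymptotes 0/1, Gaussian noise SD 0.05, clipped at zero only
(MTS-style readouts can exceed control but not be negative).

All randomness flows from a single seed through one generator, so
identical configurations give bitwise-identical cohorts including the
truth ledger.

*What the generator does not emulate:* realistic LD maps or allele
frequency spectra, haplotype phase, expression heteroskedasticity or
probe cross-hybridization, batch effects, relatedness, dose–response
heteroskedasticity, or the imputation process itself (dosage panels are
modelled as an external producer's output). Passing recovery tests
therefore demonstrates the statistics behave as designed under the
model's assumptions, not that the pipeline is robust to everything real
arrays do.

## Benchmark experiment sizes

The built-in experiments (`triadscan.evaluation`, also run by
`scripts/acceptance.py`) use: 100 replicate cohorts of 120 SNPs × 10
probesets for planted-SNP power and triad recovery; 200 noisy curves for
IC50 recovery; one 10⁴-SNP LD-free structured-null cohort for type-I
calibration (LD-free so the rejection count is binomial); and 10⁵
single-population SNPs for HWE-filter calibration. These sizes give
Monte-Carlo standard errors comfortably below the effects being checked
while keeping a full run around a minute on one core.

## Known limitations

- IC50 recovery is information-limited by the ten-fold dose ladder (see
  above); median log₁₀ error sits near 0.06–0.07 under the default
  design, as the suite's recovery check documents.
- The exact HWE filter rejects below its nominal rate (discreteness);
  with the 0.001 threshold the realized exclusion rate on null data is
  ≈0.0006–0.0007.
- Locus membership under the greedy rule depends on seed order only
  through deterministic tie-breaks; other resolutions of overlapping
  windows are possible and would give slightly different locus counts.
- Q-value π̂₀ estimation assumes enough tests (≥100) and a roughly
  uniform null tail; heavily filtered inputs fall back to BH.
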