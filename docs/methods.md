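# Methods

## Model

Biallelic SNP dosages x ∈ {0,1,2} are standardized per SNP by the
allele frequency, z = (x − 2p)/√(2p(1−p)), so that E z = 0 and
var z = 1 under Hardy–Weinberg. For two individuals with pedigree
relatedness θ_r = 2^−r, the per-SNP cross-product z₁z₂ has mean θ_r;
averaging over a panel of m markers gives the cross-cohort GRM score.
When markers are correlated, the panel behaves like m_e = m²/Σρ²
independent markers, and m_e replaces m in every variance law.

Encryption multiplies the standardized n×m matrix by a shared random
m×k matrix S with iid N(0, 1/m) entries. Because E[S Sᵀ] = (k/m)·I,
inner products — and hence relatedness — survive the projection in
expectation, while individual genotypes do not survive it at all (k ≪
the number of bits in a genotype row, and the column space is shared
noise). Two estimators operate on the encrypted matrices:

* **encGRM** — (1/k)(z₁S)·(z₂S): unbiased for θ_r, variance
  (1+θ_r²)(1/k + 1/m_e). The 1/k term is the price of encryption.
* **encG-reg** — the slope of the regression of one encrypted row on
  the other, cov(x̂₁, x̂₂)/var(x̂₁) over the k columns (centered sample
  moments; the divisor cancels in the ratio). Same mean, variance
  (1−θ_r²)(1/k + 1/m_e). Conditioning on the regressor converts the
  (1+θ²) factor into (1−θ²), which vanishes for identical pairs — the
  slope is the detector of choice at every θ > 0.

The per-pair reported SD is √((1−b̂²)/k), clipped at 0 for |b̂| ≥ 1:
the standard error of a regression slope over k observations when both
variables have unit variance. The S-entry variance convention (1/m
with a 1/k prefactor in encGRM, versus the equivalent 1/k convention
with a different prefactor) does not affect the slope, which is
invariant to any common positive rescaling of the inputs.

## Study design

Detection is a one-sided test of H₀: θ = 0 against H₁: θ = θ_r, both
approximately normal with the variances above. Requiring type-I error
α (after Bonferroni correction over all N = Σ_{i<j} n_i n_j
cross-cohort pairs) and type-II error β yields lower bounds on m_e and
then on k; both are implemented as the smallest integer strictly
satisfying the inequality. The detection threshold is
z_{1−α/N}·√(1/m_e + 1/k).

Parameters that matter, with defaults:

* **α (0.05, experiment-wise)** and **β (0.1)** — the designed error
  rates. α enters through a far-tail normal quantile (z ≈ 6.2 at
  N ≈ 1.4×10⁸), so the quantile implementation (scipy's `norm.ppf`) is
  required to be accurate to relative error < 1e−6 down to tail mass
  1e−12; the integer k bounds are sensitive to this.
* **θ deflation (0.9)** — designs use θ_eff = 0.9·2^−r rather than the
  pedigree value, absorbing attenuation from imperfect genotypes and
  residual LD. 0.9 is the unique deflation consistent with the
  published design tables; it is configurable (`ThetaConvention`).
* **practical marker budget (2× the m_e bound)** — markers are cheap
  relative to k, and a 2× budget keeps the realized, LD-adjusted m_e
  above the bound after panel imperfections.
* **m_e estimation** — either 1/var(off-diagonal GRM) on a reference
  panel, or m²/(m + Σ_{l₁≠l₂}ρ²) from pairwise SNP correlations. The
  empirical ρ̂² is corrected for its finite-sample bias
  (ρ̂² − (1−ρ̂²)/(n−2)) so that independent SNPs contribute ≈ 0; without
  this the LD route collapses toward n when m ≳ n.

Degree classification: a score must clear the deepest designed
degree's null threshold to be called related; the degree is then the
designed r nearest on the log2 scale, with the identical class gated
by its own (k₀-based) threshold.

## Protocol and trust model

Four steps, two interactions. Cohorts run intra-cohort QC (defaults
MAF > 0.01, HWE p > 1e−7, missingness < 0.05) and send per-SNP summary
reports; the central analyst intersects and allele-aligns panels
(strand-ambiguous A/T and C/G SNPs dropped, frequencies flipped for
swapped allele orders), screens cohorts with fPCA (column-centered
SVD of the cohorts×SNPs frequency matrix — frequencies are
commensurate, so no rescaling) and fStructure (normalized reciprocal
Hudson F_st to reference populations, with an ε = 1e−4 floor before
inversion — the floor regularizes the divergence-free limit), and
issues a SNP list, a projection dimension and a seed. Cohorts
standardize **on their own frequencies** (only summaries cross sites),
regenerate S from the seed with a pinned PRNG (PCG64, row-major fill —
so independently-run sites produce bit-identical projections), and
return encrypted matrices. Shipping a seed instead of S itself reduces
the interchange from m×k doubles to one integer, at no statistical
cost. Artifacts carry a SHA-256 fingerprint of the seed and a hash of
the ordered SNP list; the central side refuses to pair matrices whose
fingerprints or panel hashes differ. Positive-control samples (a
public reference panel merged into every cohort after the summary
stage, so they never distort frequency reports) must be recovered as
cross-cohort identical pairs, else the run fails. Both the exhaustive
design (per-pair panels and projections) and the parsimony design (one
global panel and projection) are supported.

The F_st estimator is Hudson's, ratio-of-averages across SNPs with the
p(1−p)/(n−1) sampling correction (a low-bias standard choice; an
uncorrected variant is available for cross-checks). Ethnicity-
insensitive SNP selection runs an uncorrected 1-df allele-count
chi-square between every pair of reference panels and keeps SNPs
insignificant (p > 0.05) in all pairs.

## Missing data

Missing dosages are mean-imputed (zero after standardization), which
shrinks cross-moments proportionally. Reported scores are adjusted by
dividing score and SD by the pair's joint non-missing fraction, taken
as the product of the two individuals' call rates over the shared
panel (missingness is modelled as completely at random and independent
between sites; each cohort ships its per-individual call rates inside
the encrypted-matrix file). This divisor is exact for inner-product
scores but approximate for the slope, whose bias factor is the
regressand's call rate alone; with two-sided missingness the
joint-fraction divisor over-corrects by the regressor's call rate.
The adjustment is therefore reported alongside, never in place of, the
raw score.

## Synthetic data

The generator emulates the simulation conditions of the validation
studies: independent biallelic SNPs with MAF ~ U(0.05, 0.5), founders
drawn Binomial(2, p), per-cohort missingness completely at random, and
relatives made by gene-dropping — a chain of r meiosis steps, each
transmitting one uniformly-chosen allele from the current ancestor and
drawing the other fresh from the population. Gene-dropping produces
genuine Mendelian segregation: the realized relatedness of an r-th
degree pair fluctuates around 2^−r with a dispersion that shrinks as
the panel grows, exactly as in real pedigrees (r = 1 pairs are
parent–offspring-like, sharing one allele at every locus). What the
generator does **not** emulate: linkage disequilibrium (so m_e ≈ m by
construction and LD-driven m_e deflation is untested against
simulation), genotyping error, allele-frequency misspecification
between sites, and platform-driven (informative) missingness. Passing
tests therefore validate the estimators and the design algebra under
the stated sampling model, not robustness to those real-data
pathologies.

### Where the normal theory is only approximate

Two deviations between simulation and the normal-theory laws are
intrinsic, reproducible, and worth knowing about:

* **GRM variance under binomial genotypes.** The law (1+θ²)/m assumes
  Gaussian z. For Binomial(2,p) genotypes E z⁴ = 1/(2pq) ≥ 2, and
  exact enumeration of the gene-dropping pair distribution under
  MAF ~ U(0.05, 0.5) gives per-locus variance ratios of 1.14 (r = 0),
  1.11 (r = 1), 1.18 (r = 2) and 1.13 (r = 3) relative to (1+θ²).
  Empirical GRM (and, diluted by their exact 1/k terms, encGRM and
  encG-reg) variances sit above theory by those margins — the
  direction and size of the effect also explain why rarer panels
  (small MAF) inflate GRM variance at fixed m.
* **Far-tail undercoverage at small k.** The slope over k columns is
  studentized by a k-sample variance estimate, so its null tails are
  Student-t-like rather than normal. At the identical-pair design
  point of a small study (k ≈ 50) the Bonferroni threshold, derived
  from the normal quantile at ~1e−6, undercovers by roughly an order
  of magnitude in false-positive *rate* (while the absolute count
  stays below one per 40,000 comparisons per run). At the k of a few
  hundred used for 1st/2nd-degree designs the effect is negligible and
  false-positive counts match the nominal α. Designs that must hold
  exact experiment-wise error at very small k should inflate k or use
  a t-quantile threshold.

## Numerical choices

* Dosage convention: count of A1, the first-listed allele of the
  summary report; VCF ALT maps to A1 (documented, overridable by
  editing the summary). One convention must be fixed for cross-cohort
  alignment; none is canonical in the wild.
* Encrypted matrices serialize as TSV with a `#key=value` header and
  17-significant-digit floats; reads use round-trip float parsing, so
  write→read is bit-faithful at double precision. Human-auditable on
  purpose: collaborators can inspect everything that leaves their site.
* Centered sample moments with divisor k in the slope (the ratio is
  divisor-invariant); zero-variance encrypted rows are an error, not a
  NaN.
* Strict-inequality integer bounds: the smallest integer strictly
  greater than the real-valued bound (an exactly-integer bound is
  bumped by one).
* Degenerate inputs: monomorphic frequencies are rejected before
  standardization; all-missing SNP columns are excluded from summaries
  and logged; an m_e below the feasibility bound of the k design
  raises an error naming the bound.

## Problem sizes used in validation

The test suite and the acceptance script run at desk scale, chosen to
keep Monte-Carlo error well inside the asserted tolerances: the
operating-point experiment uses two cohorts of 200 with 10 planted
pairs per degree over 100 replicates; the variance-law grid uses 1,000
pairs per (estimator, r, m, k) cell with m ∈ {1000, 2000} and
k ∈ {4000, 8000}; oracle tests on tiny matrices are exact.

## Known limitations

No dominance GRM (full sibs and parent–offspring are not separated
within degree 1); no LD-aware simulation; no BGEN/PLINK-binary I/O; no
formal cryptographic hardness analysis of the projection (the design
controls statistical resolution, not an adversary with auxiliary LD
information); Bonferroni only (no FDR), matching the design algebra.
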