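# Methods

## The model

`amherit` works within the classical model of positive primary phenotypic
assortative mating (AM): an additive phenotype

y = Z u + e,  e ~ N(0, σ²ₑ) i.i.d.,

where Z is the n×m matrix of standardized causal genotypes with effect
vector u (uᵀu = σ²_{g,0}), and mates are matched so that their phenotypes
correlate at a constant r, with genotypes conditionally independent given
the heritable parts of the phenotypes.  Assortment induces positive
correlations between trait-increasing allele counts at causal loci across
the whole genome.  The genetic variance therefore rises from its panmictic
value σ²_{g,0} toward the equilibrium

σ²_{g,∞} = σ²_{g,0} / (1 − r·h²_∞),

where h²_∞ is the equilibrium heritability, the fixed point of
h = V/(V+σ²ₑ) with V = σ²_{g,0}/(1 − r·h).  `theory.solve_equilibrium`
finds this fixed point by damped iteration (damping 0.5, tolerance 1e-10,
internally iterated well below the tolerance so the returned value is
accurate to it); the quadratic closed form
r·σ²ₑ·h² − (σ²ₑ+σ²_{g,0})·h + σ²_{g,0} = 0 is kept as a test oracle rather
than as the production path, so the solver generalizes to model variants
whose equilibrium is not a quadratic root.

The generation-by-generation approach to equilibrium uses the
infinitesimal-model recursion

V_{t+1} = (V_t/2)(1 + r·h²_t) + σ²_{g,0}/2,

the classical Fisher/Nagylaki form: the first term is the variance of
transmitted parental-average breeding values inflated by the mate
correlation, the second the segregation variance restored by free
recombination.  Its fixed point coincides with the equilibrium above, and
the forward simulator reproduces the whole trajectory within sampling error
(about 40% of the total variance gain arrives in the first generation).

## Estimator biases and corrections

Haseman–Elston (HE) regression regresses the strictly sub-diagonal entries
of the phenotypic outer product ỹỹᵀ on those of the GRM m⁻¹ZZᵀ.  At
equilibrium its expectation is

E[ĥ²_HE] = ( m·uᵀΥ∞Υ∞u / (uᵀΥ∞u · tr[Υ∞Υ∞]) ) · h²_∞,

with Υ∞ the equilibrium causal covariance matrix; under exchangeable loci
this reduces to h²_∞ / (1 − r·h²_∞) ≥ h²_∞ ≥ h²₀.  The inflation arises
because cross-locus covariance feeds the outcome (phenotype products) but
contributes only O(m⁻¹) to the GRM entries.  Inverting the exchangeable
approximation for known r gives the corrected estimators

ĥ²_∞ = ĥ²_HE / (1 + r·ĥ²_HE),
ĥ²₀ = ĥ²_HE / (1 + 2r·ĥ²_HE + r(r−1)·ĥ⁴_HE),

which are exact algebraic inverses of the composed map
h²₀ → h²_∞ → E[ĥ²_HE] (verified to 1e-10 on a grid of (h²₀, r)).  Out of
equilibrium, [ĥ²_∞, ĥ²_HE] bounds the current-generation heritability in
expectation and [ĥ²₀, ĥ²_REML] bounds the panmictic one.  Delta-method
standard errors propagate only the HE sampling uncertainty; r is treated
as known, because the provenance of published standard errors for these
corrections is not specified and no defensible joint variance is available.

REML maximizes the residual likelihood of the projected data; its behavior
is governed by the GRM spectrum.  Because AM perturbs the causal covariance
only by a low-rank term (Υ∞ = D + 2φφᵀ), the limiting spectral distribution
of the GRM is the same Marčenko–Pastur law as under random mating, and
ĥ²_REML is a consistent estimator of the *panmictic* heritability as
n, m → ∞ with n/m → c — while being inflated like HE at small n.  No
closed-form finite-n correction exists for REML, so the package provides
none; the sample-size trend itself (HE flat, REML declining) is the
diagnostic, formalized in the paired small-vs-large subsample divergence
statistic δ̄ with its within-subjects t test (reported as descriptive,
since replicates share the bulk of the data).

The rank-one construction `theory.build_upsilon_equilibrium` uses φ ∝ u
with the scaling chosen so that uᵀΥ∞u equals the equilibrium genetic
variance exactly and the diagonal is one.  The exact φ is a more intricate
function of effects and mate correlation; the construction is therefore
labeled an exchangeable-loci approximation, and the empirical route
(`estimate_upsilon`, the sample correlation of causal genotypes from a
simulated equilibrium population) is the primary vehicle for exercising the
general bias formula.

## The simulator and what it emulates

The forward simulator represents each haplotype as a mosaic of founder
blocks: the genome is tiled by 50 kb intervals and recombination happens
only at interval boundaries, with probabilities from Haldane's map function
and free assortment across chromosomes.  Founder haplotypes come from a
latent AR(1) Gaussian process (autocorrelation exp(−d/25 kb)) thresholded
at each SNP's empirical frequency quantile, giving MAF ~ Uniform(0.05, 0.5)
exactly and LD that decays with physical distance.  A run comprises a
growth phase (non-monogamous random mating expanding the founder pool to
the target population size), five random-mating burn-in generations, and
fifteen AM generations of disjoint monogamous pairs (two offspring each, so
the population size is constant and the final generation consists of N/2
known sibships).  Mates are paired by the sorted-Gaussian-copula scheme:
N/2 bivariate normal draws with correlation r are pooled, and phenotype
ranks are matched to draw ranks, so the two individuals landing in one
copula pair become mates; the realized mate correlation is within ±0.02 of
r for N ≥ 10⁴.

Desk-scale defaults, chosen to emulate the study conditions rather than to
be literally genome-sized:

| parameter | default | why |
| --- | --- | --- |
| genome | 20 chromosomes × 50 blocks of 50 kb | with 1 cM between block boundaries, randomly chosen causal pairs are mostly unlinked, as in a genome-wide polygenic architecture; a two-chromosome toy genome with a literal bp→cM map would leave causal loci nearly fully linked and inflate the equilibrium variance beyond the free-recombination theory |
| founders | 1000 diploid founders | a small founder pool leaves founder-descent structure that GRM principal components pick up, confounding the AM-specific question; 1000 founders make the base population effectively unstructured at desk-scale marker counts |
| population | N = 4000 (8000 where n = 4000 unrelated are needed) | keeps a 10-replicate equilibrium study within minutes on one CPU |
| SNPs / causal | p = 2000, m = 1000 | heritability fully tagged; HE is unbiased to the number of null markers carried along |
| h²₀, r | 0.5, 0.5 | the central simulated condition |
| burn-in / AM generations | 5 / 15 | equilibrium is reached well within 15 generations |

Phenotype construction standardizes causal genotypes by the *founder-panel*
allele frequencies, fixed across generations, so u retains its meaning as
AM reshapes the genotype distribution.  Unrelated estimation samples are
drawn as one offspring per sibship (the pedigree is known), which is exact
at any marker count; the GRM-threshold relative filter (greedy removal at
relatedness ≥ 0.05) is implemented and exposed, but at desk-scale marker
counts (p ≈ 2×10³) the relatedness sampling error (~p^{-1/2} ≈ 0.02) makes
a 0.05 cutoff flag thousands of truly unrelated pairs, so the pipelines
prefer the pedigree route.

What the generator does *not* emulate: mutation, selection, migration,
population stratification beyond AM, X chromosome, variable family size,
dominance, and gene–environment correlation.  Passing tests therefore show
that the estimators and corrections behave as the theory predicts in a
homogeneous, purely additively assorting population — not that real-data
estimates are free of the many other confounds the model excludes.

## Estimators: numerical choices

* **GRM** — columns centered at 2f̂ and scaled by √(2f̂(1−f̂)) with
  within-sample frequencies; zero-variance columns dropped and excluded
  from m.
* **HE regression** — strictly sub-diagonal pairs; intercept-free by
  default for a standardized phenotype (an intercept option exists and
  differs negligibly).  Primary standard error: delete-one-individual
  jackknife, switching to a 100-block grouped jackknife above n = 5000
  (with within-block pair contributions handled exactly); the naive OLS
  standard error is always reported alongside.  Estimates are never
  clamped.
* **REML** — the covariate space (an intercept always included) is
  projected out and simultaneously deflated to eigenvalue −1, so one
  symmetric eigendecomposition yields the exact complement spectrum even
  when the GRM is rank-deficient; the profile residual log-likelihood over
  h² is maximized on [0, 1−1e−6] by bounded scalar minimization (tolerance
  1e-8), endpoints checked explicitly and flagged as boundary solutions;
  standard errors come from the observed information in (σ²_g, σ²_e) via
  the delta method; a spectrum flat to 1e-8 (GRM ≈ identity) is flagged
  unidentifiable rather than returning an arbitrary split.
* **LD scores** — sum of in-sample r² within ±1 cM of the focal SNP
  (self term included), with a SNP-count window fallback when no map
  exists.
* **LDSC** — χ²_j = n·r̂²_jy (the squared-t version differs by O(1/n));
  weighted least squares with weights 1/ℓ and a free intercept;
  ĥ² = slope·M/n.  In-sample scores only; no attenuation or overlap
  corrections.
* **Partitioning** — 2×2 median splits of MAF and LD score, ties to the
  lower bin; degenerate splits warn and empty components are dropped by
  the CLI.
* **Spectral diagnostics** — Marčenko–Pastur comparisons use
  independent-SNP or causal-only GRMs (LD among markers distorts the raw
  MP fit and is not the phenomenon under study); Kolmogorov–Smirnov
  distances exclude the single largest eigenvalue by default because the
  low-rank equilibrium perturbation can detach at most a bounded number of
  outliers without moving the bulk.

## Problem sizes used by the test suite and acceptance runs

Equilibrium parameter-recovery studies use ten replicates of N = 8000
(n = 4000 unrelated), p = 2000, m = 1000, fifteen AM generations; the
sample-size trend study uses pools of 4000 unrelated individuals with
m = 2000 markers and subsamples of 500–4000; spectral comparisons use
n = 1000 against m = 2000 independent SNPs.  These sizes were chosen so
the whole suite runs on a single CPU in minutes while every comparison
against theory is made at matched, simulated scale — never against the
published large-sample magnitudes, which sit outside desk scale.

## Known limitations

* The corrections assume equilibrium AM with known, constant r; under
  disequilibrium they are probabilistic bounds, not point estimates.
* The rank-one Υ∞ construction is calibrated, not exact; only its variance
  contract and sign structure are guaranteed.
* REML standard errors at boundary optima are not reported (NaN) — the
  observed-information approximation is invalid there.
* The δ̄ divergence test reuses the complement sample across replicates,
  exactly as in the original design; its p-values are descriptive.
* LDSC behavior with external (mis-specified) reference LD scores is out
  of scope; only in-sample scores are implemented.
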