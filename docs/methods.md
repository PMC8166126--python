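# Methods

## Model

Allelic imbalance (AI) is treated as a readout of somatic selection on
germline heterozygous variants: when one parental homolog is promoted
(gains copies relative to the other), the alleles it carries rise in tumor
read fraction. Per SNP *i*, the tumor B-allele count given total depth is
beta-binomial,

    y_Bij | n_ij ~ BetaBin(n_ij, p_i, θ_i),     α = p·θ, β = (1−p)·θ,

with mean `p_i` obtained by pushing the allelic allocation `(1−π_i, π_i)`
through a symmetric base-calling error mixer `E(δ)` (off-diagonal δ) and a
reference-mapping bias scaler `M(φ) = diag(2(1−φ), 2φ)`, then taking the
B share; the per-sample depth scale cancels in that ratio. In closed form,
with `b = δ + π(1−2δ)`:

    p_i = φ b / (φ b + (1−φ)(1−b)).

The matched normal sample is balanced (`π = 0.5`), which collapses its mean
to `p′_i = φ_i` — the normal counts therefore identify the mapping bias,
the tumor/normal contrast identifies π, and δ only shrinks the tumor
signal slightly toward 0.5 (it is weakly identified and held near zero by
its prior). A single θ is shared by the tumor and normal terms of a SNP.

The error matrix is written with `1−δ` on the diagonal so that δ = 0 is the
identity (no read-label mixing); the alternative orientation would invert
alleles in the error-free limit, which cannot be the intended model.

π is a *mean* parameter: it is the cohort-average tumor B allocation. A
discrete AI event of magnitude `f` (promoted-homolog fraction) that
promotes the B-carrying homolog with probability `w` produces the marginal
allocation `(1−f) + w(2f−1)` per event, further attenuated by sub-unit
event rates and normal contamination. `SimulationConfig.implied_pi()`
computes this analytic mean; parameter-recovery statements are made against
it, because the promotion probability itself is only identical to the mean
under complete imbalance — a two-point count mixture that lies outside the
beta-binomial family and is deliberately not asserted as recoverable.

## Priors and fitting

The prior boundaries and families are configurable stand-ins:

| parameter | prior | bounds | rationale |
|---|---|---|---|
| π | uniform | [0.01, 0.99] | uninformative over admissible preference |
| δ | Beta(1, 50), truncated | [1e-6, 0.1] | base-calling error is small |
| φ | Beta(20, 20), truncated | [0.2, 0.8] | bias centered on none |
| θ | log-uniform | [1, 1e4] | scale parameter, decades equally likely |

MAP estimation maximizes the log posterior by L-BFGS-B in transformed
coordinates (scaled logit for π, δ, φ; logit on the log scale for θ), with
analytic gradients, from a deterministic multi-start at
π ∈ {0.3, 0.5, 0.7} (δ = 0.005, φ = 0.5, θ = 100); ties go to the start
whose π̂ is closest to 0.5. Convergence uses relative objective reduction
1e-11 plus projected-gradient tolerance 1e-6; a per-SNP fit is flagged
converged when its own gradient inf-norm is below 1e-3 relative to the
objective scale. Because the posterior is separable across SNPs, whole
cohorts (and stacked permutation replicates) are fit as one batched
optimization — identical optima, far less overhead. The fit objective
drops the binomial coefficient (constant in the parameters); reported log
posteriors are recomputed with the full mass at the optimum.

## Permutation null and significance

Under "no allele–promotion association", swapping all A/B labels of one
(patient, arm) — tumor and normal together, all-or-none — is
distribution-preserving: phase within AI events is retained and only the
identity of the promoted homolog is randomized. Each permutation redraws
the swap coin per (patient, arm) and refits all four parameters at every
SNP; the statistics |0.5 − π̂| are pooled across permutations and SNPs.
Permutation refits warm-start from the observed fit's nuisance estimates
(δ̂, θ̂) with π and φ reset to 0.5 — a single informed start, verified in
the tests to match the full multi-start to |Δπ̂| < 1e-3 on an eventful
cohort. Non-converged refits are dropped from the pool and counted.

Empirical p-values use the add-one rule `p = (1 + #{null ≥ stat}) /
(1 + N)`, which keeps p > 0 and valid at any pool size (the difference from
`r/N` vanishes at the pool sizes used). Storey q-values estimate π0 on the
λ grid {0.05, …, 0.95} with a cubic-spline smoother evaluated at the
largest λ, clipped to (0, 1]; with fewer than 10 p-values the estimator
falls back to π0 = 1 (Benjamini–Hochberg). Selection direction is the sign
of π̂ − 0.5; π̂ exactly 0.5 gets no direction.

## Heterozygote calling and filters

Germline heterozygotes: normal coverage strictly greater than 20 and BAF in
the inclusive window [0.2, 0.8] (the window is symmetric, so the call is
invariant under allele relabeling). Locus filters: population MAF ≥ 0.005,
then at least `min_het` (default 10) called heterozygous patients — loci
with few heterozygotes carry almost no information about π and inflate the
permutation pool with noise. Coordinates are 1-based; A ≡ reference,
B ≡ alternate. The per-sample coverage scale (global median depth / sample
median depth) is stored but inert for inference, since the model
conditions on per-site totals.

## Synthetic cohorts

The generator is the forward model: per-site depths are negative binomial
(mean `coverage_mean`, dispersion 0.3 — variance μ + 0.3μ²);
heterozygosity is Bernoulli(`het_prob`) with phase assigned per (SNP,
sample) by a fair coin (no linkage disequilibrium); AI events fire per
(sample, arm) at `event_rate` and promote one homolog consistently across
the arm; the promoted homolog follows the arm's selection driver (one
non-neutral het SNP, chosen uniformly) with probability `pi_true`, else a
fair coin; normal contamination mixes the tumor allele fraction toward 0.5
linearly in 1 − purity before counts are drawn; the same δ/φ mean map used
in inference is applied generatively. Homozygous genotypes split hom-ref /
hom-alt by the population MAF; the analysis-facing het mask is produced by
the same caller used on real data, so low-coverage true heterozygotes can
be missed, as in practice.

What the generator does not emulate: linkage disequilibrium and haplotype
structure, subclonal copy-number mixtures, absolute copy number (events are
pure allele-fraction shifts), GC/batch effects, and locus-specific
mappability. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated generative assumptions, not
robustness to every artifact of real exomes.

Annotation simulation plants associations for the downstream stages:
CADD-like scores are Gamma(2, 4) (≈29% above the deleteriousness cutoff of
10) plus a selection-linked boost; control allele frequencies anchor on the
realized case germline frequency and shift against the selection direction;
per-gene dependency scores are Normal(0, 0.3) lowered for genes carrying
selected-for SNPs. `assoc_strength = 0` plants nothing.

## Study conditions used in validation

Type-I error: 500 null SNPs (no events, δ = 0.002, φ = 0.5, θ = 100),
100 patients, mean depth 60, 200 permutations. Balanced recovery: 50 SNPs,
200 patients, depth 80. Parameter recovery: targets 0.3/0.5/0.7 realized
as implied means under full event rate, promoted fraction 0.8, promotion
probability solved from the target, one SNP per arm (so each SNP is its
own selection driver). Planted end-to-end run: 100 SNPs with 10% at
promotion probability 0.8 (event rate 0.8, promoted fraction 0.8, purity
0.9, depth 80, 200 patients, 100 permutations). Contamination study:
purity 1.0 / 0.7 / 0.4 at 30 planted SNPs, 100 patients, 50 permutations.
These problem sizes keep every simulation exact (no shortcuts) while
running in minutes on a single core.

## Numerical notes and degenerate inputs

* Beta-binomial masses use log-gamma throughout; the public
  `betabinom_logpmf` matches `scipy.stats.betabinom` under the
  mean–precision reparameterization and is exercised against its
  normalization and binomial limit (θ = 1e6 for the 1e-3 log-mass
  tolerance at n = 20, since the gap scales as n²/2θ).
* Expected allele fractions exactly 0 or 1 (parameter underflow) are
  rejected rather than propagated into logs.
* Empty heterozygote sets: `log_likelihood` returns 0 (empty product);
  `fit_map` refuses to fit; cohort-level fits flag such SNPs
  non-converged and they are excluded from calls and the null pool.
* An empty permutation pool or an all-failed permutation raises rather
  than returning a silent empty null.
* Byte-identical reruns: all randomness flows from explicit seeds through
  `numpy.random.default_rng`; TSV writers fix column order, line
  terminator and float formatting.

## Known limitations

π is identified only up to the attenuation described above; with few
heterozygotes per SNP the posterior is prior-dominated and calls should be
restricted to converged fits with adequate `n_het` (the default filter).
The permutation scheme assumes arm labels are correct and AI events do not
span arm boundaries. The case/control frequency test treats control allele
frequencies as exact counts at a stated control cohort size. Multi-allelic
sites, genotype-likelihood het calling and BAM/VCF ingestion are out of
scope; counts are consumed in the documented TSV dialect.
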