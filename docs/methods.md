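# Methods

## The problem

Allele-specific expression (ASE) experiments sequence RNA from a diploid
individual (typically an F1 hybrid) and count, per exonic region and
biological replicate, the reads attributable to the maternal allele
(`x_i`) and the paternal allele (`y_i`).  Allelic imbalance (AI) — a
departure of the true paternal expression proportion θ from 1/2 — is
evidence of *cis*-regulatory divergence.  The naive binomial test of
θ = 1/2 on pooled counts ignores two facts: read counts are random rather
than a fixed number of trials, and read *assignment* is biased — genome
ambiguity, reference quality, hidden variants and aligner behaviour make
the expected paternal read fraction differ from 1/2 even without AI.
This package implements a Bayesian Poisson-Gamma (PG) model in which that
bias enters the model structure explicitly, a negative-binomial (NB)
comparator that carries bias through a DNA-informed prior, the classic
binomial test, a Poisson count simulator, and Monte-Carlo drivers that
measure each method's operating characteristics.

## The Poisson-Gamma model

For one exonic region with replicates `i = 1..I`:

    x_i | μ, β_i      ~ Poisson(μ β_i (1 − q))
    y_i | μ, β_i, α   ~ Poisson(μ β_i q α)

* `μ` — overall mean, a nuisance parameter; `β_i` — replicate effect
  modelling biological replicate variation (only the product `μ β_i` is
  likelihood-identified; both get proper priors).
* `q ∈ (0,1)` — the bias constant: the expected paternal read fraction in
  the *absence* of AI.  It can be 1/2 (no-bias assumption), the paternal
  fraction of simulated-read alignments (`biasutils.q_from_simulation`),
  or the pooled paternal fraction of DNA controls (`q_from_dna`).
* `α > 0` — the treatment effect.  θ = α/(1+α), so α = 1 ⟺ θ = 1/2 and
  the decision rules "CI for α excludes 1" and "CI for θ excludes 1/2"
  coincide.

Priors are Gamma(1/2, 1/2) on μ, each β_i and α, rate-parameterized
(E(η) = a/b).  All full conditionals are Gamma, so posterior sampling is a
systematic-scan Gibbs sampler (μ, then β, then α), compiled with numba;
chains run exon by exon and are bit-reproducible under a fixed seed.

An exon is flagged as in AI when the equal-tailed 95% credible interval
for α excludes 1.  Equal-tailed (not HPD) intervals are used: the choice
is symmetric under the α ↔ 1/α relabelling of alleles, which the decision
rule should respect.

### Identifiability of bias and imbalance

Only the paternal:maternal mean ratio `q α/(1−q)` is identified:
`(q, α, μ) → (q', α q(1−q')/(q'(1−q)), μ(1−q)/(1−q'))` leaves the
likelihood invariant (`pg.loglikelihood` documents the identity, and the
test suite verifies it numerically).  A misspecified q therefore
translates one-for-one into a biased α — which is exactly why the
misspecification experiments (below) behave as they do.

### Allele symmetrization (a design decision)

The one-sided parameterization above is not exchangeable under swapping
the allele labels: the proper Gamma priors on the non-identified (μ, β)
scale interact with whichever channel carries α and shift its marginal
posterior toward that allele by ≈ 0.36 posterior standard deviations —
*independently of coverage*.  We established this against brute-force
grid quadrature (the sampler is exact; the shift is a property of the
model), and it would make the one-sided test anti-conservative
(type I error ≈ 8% at the 5% level) with the direction of the excess
determined arbitrarily by which allele the analyst happens to estimate.

Since which allele is "paternal" is a labelling convention, not evidence,
default inference restores exchangeability: the sampler runs once with the
paternal allele focal and once with the maternal allele focal (counts
swapped, bias complemented), and the two sets of draws are pooled after
inverting the maternal direction onto the paternal α scale.  The pooled
posterior is symmetric under relabelling; its interval is ≈ 11% wider
than either one-sided interval, which makes the test mildly conservative
(measured type I error ≈ 3% at the 5% level under the null — below the
exact binomial's ≈ 4.4-4.9%, matching the ordering this model family is
designed to deliver).  One-sided fits remain available
(`symmetrize=False`, `focal="paternal"|"maternal"`), for the situation
where a global bias direction is known and the analyst deliberately
estimates the unfavoured allele.

### Random bias from DNA controls (cut inference)

Genomic DNA of the same F1 carries both alleles in exactly equal amounts,
so the paternal fraction of DNA-control reads measures pure bias.  The DNA
model (shared with the NB comparator) is, per replicate,
`y*_i | p ~ NegativeBinomial(k = x*_i, ε = 1 − p)` in the
failures-before-k-successes parameterization; with a Jeffreys Beta(1/2,1/2)
prior the posterior of p is Beta(1/2 + Σy*, 1/2 + Σx*) in closed form.

The PG random-ϕ variant performs two-stage ("cut") inference: at each
outer iteration m a bias draw ϕ^m comes from that DNA posterior and is
treated as fixed truth inside the RNA model for one block of Gibbs scans;
the RNA data never feed back into the bias estimate.  A single scan per
bias draw under-disperses the cut posterior (the nuisance chain lags the
bias draws; measured sd(log α) 0.083 vs 0.099 converged), so the default
runs 5 inner scans per draw, which reproduces the many-scan width to
within ~1%.  As DNA coverage → ∞ the variant converges to the fixed-q fit
at q = pooled paternal DNA fraction (tested at DNA totals of 10^5).

## The negative-binomial comparator

RNA model `y_i | θ ~ NB(k = x_i, ε = 1 − θ)` with prior
`θ | p ~ Beta(κ p, κ (1−p))`: the DNA information enters through the
prior, centred at the measured bias and worth κ pseudo-reads.  κ defaults
to the exon's total DNA read count (the prior carries exactly the DNA
evidence); both stages are conjugate, so sampling is exact two-stage Beta
draws.  AI is flagged when the θ interval excludes 1/2.  Replicates with
zero maternal reads but nonzero paternal reads have zero NB likelihood
and are dropped with a warning rather than silently imputed.  With the
default κ this comparator is distinctly conservative (type I error
≈ 1.5-2% at the 5% level); the model family it reconstructs admits other
prior weights, and κ is exposed for exactly that reason.

## The count simulator

Per exon, a baseline per-allele mean λ is drawn once from a coverage
distribution, then

    RNA:  x_i  ~ Poisson(2λ(1−B)),  y_i  ~ Poisson(2λ B R)
    DNA:  x*_i ~ Poisson(2λ(1−B)),  y*_i ~ Poisson(2λ B)

independently over replicates.  B is the true bias (at R = 1 the expected
paternal fraction is exactly B); R is the allelic ratio (paternal:maternal
allele mean ratio; R = 1 is the null of no AI).  DNA controls share the
exon's λ and never carry AI.  Defaults: I = I* = 3 replicates; λ
lognormal with median 150 and log-sd 0.8, emulating skewed exon-level
depth of a bulk RNA-seq library (the coverage family is configurable, and
a fixed-λ mode exists for oracle tests).  Every exon draws from an
independent RNG sub-stream keyed by (seed, exon index), so enlarging a
simulation never perturbs earlier exons.

What the simulator does *not* emulate: overdispersion beyond Poisson,
correlated bias across exons, exon-length effects, and the read-level
processes (alignment, variant calling) that generate bias in real data —
bias here is injected directly as B.  Passing tests therefore demonstrate
the statistical operating characteristics of the estimators under their
own generative assumptions, not robustness to real alignment artefacts.

## Experiments

`experiments.type1_error` simulates a null data set (R = 1), fits one
method to every exon and reports the flagged fraction with its binomial
Monte-Carlo standard error; `power` does the same at R ≠ 1.  Decisions
are per exon at the 5% level (credible level 0.95) with no multiplicity
correction, since the type I error rate is defined per test
(`binomial.bh_fdr` exists as a separate utility).  `bias_sweep` maps the
axis x to B = 0.5(1 + x/100) and compares methods along it;
`misspec_surface` fits the PG model with q = (1 + pct/100)·B over a
(bias, pct) grid.  The same simulation seed is reused across grid cells
(common random numbers) to sharpen orderings.  Measured behaviour, which
the acceptance suite asserts: the symmetrized PG at q = 1/2 stays below
the binomial test at every bias level while both grow with bias; q = B
holds the rate at ≈ 3% across B ∈ (0.35, 0.65); and the rate climbs
steeply with pct — at large B even a 5% misspecification of q produces
large type I error, asymmetrically (1% of 0.65 is more absolute bias than
1% of 0.35).

## Numerical choices and problem sizes

* Sampler defaults: 10,000 draws per direction after 2,000 burn-in;
  credible level 0.95 (so rejections correspond to the 5% level used by
  the binomial comparison).  Conjugate chains forget the (β = 1, α = 1,
  μ = mean replicate total) initialization within a few scans; effective
  sample sizes are ≈ 30% of draws for α.
* The full studies run 10,000 exons (scripts/acceptance.py); the test
  suite runs the same comparisons at 2,000 exons and 4,000 draws with
  tolerances widened to ±1.5 percentage points, a scale at which the
  Monte-Carlo standard error is ≈ 0.5 pp.
* Oracles: posterior means and intervals are checked against grid
  quadrature (β integrated analytically, μ on a grid; the Beta posteriors
  of p and θ against direct likelihood-product quadrature), with
  agreement required within 3 ESS-adjusted Monte-Carlo standard errors.
* Degenerate inputs: exons with zero total reads are reported untestable,
  never as balanced; q outside (0,1) and malformed tables raise typed
  errors with row context.

## Known limitations

* The symmetrized interval is mildly conservative by construction; power
  is correspondingly a little below the one-sided parameterization's.
* The NB comparator's prior weight κ is a modelling choice with no single
  canonical value; its default makes it more conservative than the PG
  variants.
* Bias is treated as exon-local and exact (fixed q) or exactly
  DNA-measured (random ϕ); uncertainty in a simulation-derived q is not
  propagated (the fixed-q interval conditions on q).
* The binomial z variant uses the conventional cutoff 1.965 on |z|, kept
  literal for comparability.
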