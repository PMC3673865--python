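# Methods

`crossgs` simulates genomic selection of purebred parents for crossbred
performance when the trait shows dominant gene action, and compares three
Bayesian marker-effect models inside a two-way crossbreeding program.  This
note records the model, the simulation conventions, the numerical choices,
and the places where the design was genuinely open.

## Population history

The genome consists of `n_chromosomes` chromosomes of 1 Morgan.  Candidate
loci are laid out per chromosome as 500 uniformly placed candidate QTL and
5000 candidate SNPs on an even grid with ±10 % jitter — five times the final
panel, so that the minor-allele-frequency filter at panel selection always
has enough loci to choose from.  All loci start at allele frequency 0.5 in a
base population of 500 unrelated individuals, which random-mates
(monoecious, selfing allowed, discrete generations) for 1000 generations to
build linkage disequilibrium.  Recombination follows a binomial map with
interference: the crossover count per chromosome is Binomial(N, L/N) with
N = 4 by default (N is not identified by the study design; the Haldane limit
is available as `interference=0`), and mutation is a symmetric allele flip
at 2.5 × 10⁻⁵ per allele copy per meiosis, active in every phase including
the breeding program (toggleable).

In the founder generation the trait QTL (100/chromosome) and the marker
panel (1000/chromosome) are drawn from candidates with founder MAF > 0.1;
markers are assigned to even grid targets by nearest qualifying candidate,
which preserves the near-even spacing under the MAF filter.  Two breeds then
split off as independent samples of 100 founders and drift apart for 54
generations at constant size 100.  At that point each breed shows mean
marker heterozygosity ≈ 0.3 and mean absolute between-breed frequency
difference ≈ 0.26–0.3, the regime the study design targets.

Generation 0 expands each breed to 1000 selection candidates by one round of
random mating of the generation −1 animals (the expansion rule is not
dictated by the design; this is the simplest choice consistent with it).

## Trait architecture

Additive effects: |a| ~ Exponential(rate 5.81), sign ± with probability ½.
Dominance depends on the scenario:

| scenario | d distribution            | P(d < 0) | V_A : V_D target |
|----------|---------------------------|----------|------------------|
| 1        | |d| ~ Exp(5.81), indep.   | 0.30     | 2 : 1            |
| 2        | |d| ~ Exp(5.81), indep.   | 0.30     | 4 : 1            |
| 3        | |d| ~ U(0, |a|)           | 0.20     | 4 : 1 (V_A only) |
| 4        | d = 0                     | —        | 1 : 0            |

Residual variance is fixed at V_E = 1 (standard-normal residuals) and the
genetic variance is scaled to V_G = 1 so broad-sense heritability is 0.5 in
the purebred founders; that fixes V_A* and V_D* from the ratio.  Scenarios
with overdominance scale d by s = √(V_D*/V_D) and a by the positive root t
of the quadratic obtained by expanding V_A* = Σ 2pq (t·a + (q−p)·s·d)²;
effects are re-sampled if no positive real root exists (rare).  Scenario 3/4
use the common factor c = √(V_A*/V_A), which cannot create overdominance.

**Scaling reference.** The variance components are evaluated against the
two generation −1 breeds *jointly* (per-breed components averaged over the
two frequency vectors).  Pooling the breeds into one frequency vector
instead inflates 2pq (Wahlund effect) and depresses within-breed variance by
roughly 15 %; the joint-breed reference makes the per-breed dominance
variance average ≈ 16.7 % of phenotypic variance in scenario 1 and the
narrow-sense heritabilities 0.33 / 0.4 / 0.5 across scenarios, which is the
design intent.

The dominance-coefficient spectrum after scaling is checked with *signed*
coefficients: positive overdominance d > |a| carries roughly a third of the
QTL, partial dominance 0 < d ≤ |a| a similar share.  (With unsigned |d|/|a|
the overdominant share is larger, ~0.5–0.7, because scaling shrinks a
relative to d when V_D is large.)

## Marker-effect models

All three models are fitted by systematic-scan Gibbs sampling with a chain
of 11000 samples, 1000 discarded as burn-in, on 1000 crossbred records.

* **Additive (BayesCπ).** y = μ + Xα + e with spike-and-slab priors
  α_j = 0 with probability Π, else N(0, σ_α²); Π uniform, updated as
  Beta(#null + 1, #nonzero + 1); σ_α² and σ_e² scaled-inverse-χ² with ν = 4.
* **Dominance.** y = μ + Xa + Wd + e with W the (centered) heterozygosity
  indicator.  Each SNP has separate inclusion indicators for a and d.  The
  d slab has an unknown nonzero mean μ_d ~ N(η, σ_d²/φ) with φ = 10, which
  captures directional dominance; η derives from the realized heterosis H of
  the training cross: η = H / (k (1 − Π_d,0) E(Δ²)) with Π_d,0 = 0.9 and Δ
  the generation-0 breed frequency differences.
* **BSAM.** y = μ + X^A α^A + X^B α^B + e on the 0/1 breed-of-origin allele
  dosages of the crossbreds (origin is known exactly from the simulation),
  with breed-specific slab variances and null proportions.

Per SNP and class, the indicator is sampled from its marginal (effect
integrated out; the log Bayes factor is computed on the log scale), then the
effect from N(b̂ + λμ/C, σ_e²/C) with C = x'x + λ, λ = σ_e²/σ_effect².
The residual vector is updated incrementally in float32 and re-derived in
float64 every 500 iterations to cancel drift.  Monomorphic (zero-variance)
columns are excluded and pinned to zero.

Prior scales come from S² = E(σ²)(ν − 2)/ν with E(σ_α²) =
V_A / (k (1 − Π₀) E(2pq)) (training-crossbred frequencies; Π₀ = 0.9 for
every class, configurable), σ_d² from the heterosis/dominance-variance
relation, and σ_a² by subtracting the dominance contribution
E[(1 − 2p)²](σ_d² + η²).  True values of V_A, V_D, V_E and H feed these
derivations.  BSAM uses the additive derivation with per-origin allele
variances E(p_r q_r).

**μ_d and σ_d² conditionals.** The full conditionals are evaluated over the
effects *currently in the model* (k_in replacing k in the shrinkage
denominators); summing over all k effects — zeros included — is available as
`mu_d_sum_all` and pulls μ_d towards zero by a factor ≈ k_in/k.  The
included-only convention matches the prior's role as the mean of the slab.

**Degenerate dominance slab.** When the derived σ_d² is non-positive (no
dominance variance, or η² too large), the slab scale falls back to the
additive per-effect scale rather than to ~0.  A near-zero slab is not a
stronger prior but a broken one: the slab collapses onto the spike, the
inclusion Bayes factor tends to 1, and the nonzero-effect count becomes a
random-walk artifact of the Π update.  With the fallback, a trait without
dominance yields the intended behaviour — a handful of false inclusions
(order 10 of 1000).

## Breeding program

GEBV are Σ_j Z_ij α̂_j with Z the 0/1/2 marker genotypes.  For crossbreeding,
substitution effects are breed-specific: α_j = a_j + (1 − 2p′_j) d_j with p′
the allele frequency in the *other* breed.  The dominance model recomputes
them each generation from the current opposite-breed candidate frequencies
(all 1000 unselected candidates by default; a post-selection option exists);
additive and BSAM effects are trained once and reused, as in a program
without retraining.

Each cycle: rank candidates by GEBV (ties broken uniformly at random), top
100 are males and ranks 101–600 females; 1000 purebred replacements per
breed and 1000 A×B crossbreds are produced with sires and dams drawn
uniformly with replacement from the selected sets.  The AB₀ training
crossbreds use the same 100-sire/500-dam design with *random* (unselected)
parents; this matches the program's family structure and is what makes the
two origin-specific BSAM effect counts asymmetric.  Cumulative response is
R_i = (μ_i − μ_0)/σ_0 with μ_i the crossbred phenotypic mean and σ_0 the
phenotypic SD of the shared AB₀.  Every repetition restarts from the
identical generation-0 candidates and the identical trained model; only
selection/mating randomness differs.  `run_program(fit=None, ...)` selects
on true breeding values instead — the upper bound for marker-based
selection.

## Replicate analysis

Crossbred response is partitioned as CR = BA + H with BA the change in the
midparent purebred candidate mean (phenotypic, in σ_0 units, relative to
generation 0) and H = CR − BA, so the identity is exact.  Midparent (rather
than a single breed's mean) is what makes the partition exact.  Model
comparisons use 100 (mean R₁ − mean R₂)/mean R₂ and the mixed model
y_ij = μ + m_i + b_j + e_ij with a random simulation block; the balanced
layout is solved in closed form (model/block means; block effects cancel
from every contrast, SE² = 2·MSE/(n_sims·n_reps)), unbalanced data fall
back to REML via statsmodels.

## Reproducibility and problem sizes

All randomness derives from one master seed through `SeedSequence` spawn
keys of the form (simulation, phase, scenario, model, repetition), so
results are identical whatever the order in which models, scenarios or
repetitions run.  The two hot loops (meiosis, Gibbs sweep) are numba
kernels; a full 11000-iteration training takes a few seconds, a complete
simulated history about ten.

The package's own experiments run at desk scale: `scripts/acceptance.py`
uses 4 simulations × 10 repetitions of the 20-generation scenario
experiments (plus 6 genome-only simulations for the breed-formation
statistics), and the test suite's end-to-end fixture 4 × 15 for scenario 1.
The full 16-simulation × 100-repetition, ten-chromosome study is supported
through `ExperimentConfig` but is a batch run of several hours.

## What the generator does and does not emulate

The simulator reproduces the study conditions: drift-generated LD, recent
breed divergence, exponential effect sizes, directional dominance, and the
no-retraining program structure.  It does not model epistasis, imprinting,
genotype-by-environment interaction, sequence-level variation, variable
recombination maps, overlapping generations or inbreeding management, so
conclusions about those forces cannot be drawn from passing tests here.
At desk scale the between-simulation drift variance is substantial: small
model contrasts (e.g. BSAM versus additive, a few percent at full
replication) are within noise of a handful of simulations, while the large
contrasts (dominance versus additive under strong dominance) are stable.

## Known limitations

* Posterior nonzero-effect counts reproduce the qualitative pattern
  (dominance-effect count collapsing when dominance is absent; additive
  count highest under large V_D at the end points) but sit below the
  published magnitudes for the additive and BSAM models under strong LD;
  the posterior is insensitive to the prior scale and chain length, so this
  reflects the realized marker–QTL signal structure of the simulated data.
* The Π update uses the conjugate Beta draw; no Metropolis alternative is
  provided.
* Convergence diagnostics are limited to the per-iteration nonzero-count
  and μ_d traces.
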