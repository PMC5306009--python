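# Methods

## The estimation problem

Endosymbiont screening surveys report, for each species (or morphospecies),
how many individuals were tested and how many were positive. Within-species
prevalence is wildly heterogeneous: transmission dynamics push most species
toward either near-zero or near-fixation prevalence, so counts pooled across
species are far more variable than any binomial. The quantity of interest is
not the pooled fraction of positive individuals but the fraction of
*species* infected at all — operationalized here, as is conventional in this
literature, as a within-species prevalence of at least 1/1,000.

## Model

Counts are beta-binomial: prevalence `p_i` of species *i* is drawn from
Beta(a, b) with mean `p̄` and concentration `θ` (a = p̄θ, b = (1−p̄)θ), and
`I_i ~ Binomial(n_i, p_i)`. Marginally,

    P(I | n, p̄, θ) = C(n, I) · B(I + a, n − I + b) / B(a, b),

evaluated throughout via differences of log-beta functions, which is stable
for `n` well past 10⁴ (ratios of gamma values overflow long before that).
The group structure enters through a logit link, `logit(p̄_i) = α + β·x_i`
with aquatic coded 0 and terrestrial 1, so `logistic(α)` is the aquatic mean
prevalence directly. Per-order fits drop the β term. Priors are
Normal(0, 3) on α and β and Exponential(1) on θ: weak on the logit scale
(±6 covers prevalences from 0.002 to 0.998) and weakly favouring the small
concentrations real surveys exhibit while keeping the posterior proper when
an order has few records.

Incidence for a group is the beta tail mass above the threshold
`t = 0.001`:

    incidence(p̄, θ) = 1 − I_t(p̄θ, (1−p̄)θ),

computed with the regularized incomplete beta function (`scipy.special.
betainc`), never by numerical integration of the density.

### Per-draw versus plug-in summaries

The statistic is a nonlinear functional of (α, β, θ), so two summaries
differ slightly: evaluating it at every posterior draw and averaging
(per-draw), or evaluating it once at the posterior means (plug-in). The
per-draw path is primary because it is the only one that yields a credible
interval on incidence itself; the plug-in value is computed and reported
alongside as a degenerate-interval row, and a regression test keeps the two
within two percentage points on well-concentrated posteriors. A third
conceivable reading — averaging the beta densities across draws and taking
that mixture's tail mass — is intermediate between the two and is not
implemented. Intervals are equal-tailed quantile intervals at 95% by
default; highest-posterior-density intervals are available behind a flag but
are not the default because equal-tailed intervals are the convention in
this literature.

## Sampler

The kernel is an adaptive random-walk Metropolis sampler on the
unconstrained vector (α[, β], log θ). Sampling on log θ avoids the θ → 0
boundary; the Jacobian term `+log θ` is added to the target so the prior
remains Exponential(1) on natural θ. Warmup adaptation has two phases:
Robbins–Monro tuning of a global step size toward ~30% acceptance (decay
exponent 0.6), then, from the midpoint of warmup, a proposal covariance
estimated from the warmup history (plus 10⁻⁶·I for numerical safety) with
the step size re-tuned around the classical 2.38/√d scaling. The proposal is
frozen after warmup, so retained draws come from a genuine Markov chain with
the correct invariant distribution. A 2–3 dimensional posterior mixes easily
under this kernel; correctness is enforced by comparison against dense 2-D
grid integration of the same posterior (built independently on
`scipy.stats.betabinom`), with agreement required within 3 Monte-Carlo
standard errors for means and quantiles.

Defaults follow the four-chain protocol: 1,000 warmup plus 2,000 retained
iterations per chain, 8,000 retained draws total. Initial values are drawn
from Normal(0, 1) for α and β and Normal(0, 0.5) for log θ, with up to 50
re-draws if the log-posterior is non-finite. All chain randomness derives
from one integer seed via `numpy.random.SeedSequence` spawning; identical
(seed, config, data) reproduce draws bit-for-bit.

Convergence is gated on the split-chain potential scale reduction factor
(split-R̂) being below 1.1 for every parameter: each chain is halved, and
R̂ = √(((n−1)/n·W + B/n)/W) over the resulting 2m half-chains. A
rank-normalized variant is available behind a flag. Effective sample size
uses FFT autocovariances combined across chains with Geyer's
initial-monotone-sequence truncation. When the gate fails, incidence
summaries are suppressed but draws and diagnostics are still written — a
non-converged run should be inspectable, never silently summarized.

## Database reduction and sensitivity analyses

`reduce_one_per_species` keeps, per species, the record with the largest
number tested. Ties keep the record with more positives, then the earliest
in file order: the rule must be deterministic for manifests to reproduce
runs, and preferring the larger count keeps the most informative record.
The full-versus-reduced comparison is the survey's control for targeted
resampling of known-infected species; the with/without-family comparison
(default family Culicidae) controls for the heavy over-sampling of
mosquitoes in aquatic data. Sensitivity runs use distinct seeds derived by
hashing the base seed with a role label, both recorded. Per-order fits are
intercept-only, restricted to aquatic records by default (a flag lifts the
restriction), with per-order seeds derived from the order name so results
are independent of execution order; orders with fewer than two records are
reported as unfittable rather than fitted. The order-representation
diagnostic regresses species-tested on species-described counts across
orders (ordinary least squares on raw counts, log-log behind a flag) and
needs at least three orders with catalogue totals, which are user-supplied
external reference data.

## Synthetic data

The generator draws from the model's generative form exactly, so recovery
tests have a sharp target; the truth sidecar records parameters, per-group
true incidence and per-species prevalences. Defaults are one record per
species for 500 aquatic and 500 terrestrial species, α = 0, β = 0.5,
θ = 1.5, with tested-per-species counts resampled from a built-in
empirical-shaped pool (heavy at 1–10 individuals with a long tail to 250),
stressing the estimator where most real species contribute little data. The
recovery study uses 500 species × 10 tested at p̄ = 0.5, θ = 1.5; the
bias-direction study uses 228 aquatic species (the aquatic species count of
the motivating survey) at θ = 0.5 — wide, bimodal prevalence spread — with
repeat records injected for half the species, chosen proportionally to true
prevalence.

What the generator does *not* emulate: phylogenetic correlation of
prevalence among related species, spatial or population structure within
species, screening false negatives/positives, and taxonomic misassignment.
Passing recovery tests therefore demonstrates correctness of the inference
machinery under the model's own assumptions plus the two modeled survey
biases, not robustness to every failure mode of real screening data.

## Numerical choices and edge cases

- Linked mean prevalences are clipped to [10⁻¹², 1 − 10⁻¹²] inside the
  likelihood so extreme logit values cannot produce beta shapes of exactly
  zero.
- `betabinom_log_pmf` checks 0 ≤ I ≤ n and raises on violation; θ ≤ 0 in
  the prior returns −∞ (outside support) rather than raising, which lets
  the sampler reject rather than crash.
- Empty tables summarize to zeros and have log-likelihood 0 (empty
  product); sampling an empty table is an error.
- Trace exports write floats as `%.17g` and are read back with
  round-trip parsing, so draw files reproduce arrays bit-exactly.
- Summaries with fewer than 100 retained draws carry a warning note.
- Reported problem sizes (50 replicates for the recovery and bias studies;
  2 chains × 1,000 or 600 retained draws per replicate fit) are chosen so
  the whole verification chain runs in a few minutes on a single core while
  keeping Monte-Carlo error far below the tolerances being checked.

## Known limitations

- The habitat contrast is a two-level fixed effect; no hierarchical
  order-within-habitat pooling is provided.
- Only the logit link is implemented.
- The sampler is serial; chains are cheap enough here that parallelism is
  not worth the determinism risk.
- Incidence summaries treat the threshold as fixed; uncertainty in the
  1/1,000 convention itself is not propagated (a sensitivity can be run by
  refitting with a different threshold flag).
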