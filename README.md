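# wolbsurvey

Bayesian estimation of *Wolbachia* incidence — the proportion of insect
species carrying the endosymbiont — from species-level screening surveys.

*Wolbachia* is an intracellular bacterium that manipulates the reproduction
of its arthropod hosts and is a leading candidate agent for mosquito-borne
disease biocontrol. Screening surveys test a handful of individuals from
each of many species, so the data are rows of (species, habitat, number
tested, number positive). Because within-species prevalence varies
enormously — many species are essentially uninfected while others are nearly
fixed — infected counts are strongly overdispersed relative to a binomial,
and naive pooling badly misestimates how many *species* are infected. This
package is for ecologists and symbiont biologists who need defensible
species-level incidence estimates (with credible intervals) from such
surveys, including the comparison of aquatic versus terrestrial insects and
the survey-bias sensitivity analyses that comparison requires.

## Model

For species *i* with `n_i` individuals tested and `I_i` positive:

```
I_i   ~ BetaBinomial(n_i, p̄_i, θ)
logit(p̄_i) = α + β·x_i          x_i = 0 aquatic, 1 terrestrial
α, β  ~ Normal(0, 3)
θ     ~ Exponential(1)
```

The beta distribution Beta(p̄θ, (1−p̄)θ) describes how prevalence varies
across species: `p̄` is its mean and `θ` its concentration (small `θ` ⇒
bimodal, all-or-nothing infection). A species is called *infected* if at
least 1 in 1,000 of its individuals carries the symbiont, so incidence is
the beta tail mass

```
incidence = 1 − I₀.₀₀₁(p̄θ, (1−p̄)θ)
```

with `I_t` the regularized incomplete beta function. Posteriors are drawn
with an adaptive random-walk Metropolis sampler on (α, β, log θ) — four
chains, 1,000 warmup plus 2,000 retained iterations each by default — gated
on split-R̂ < 1.1 for every parameter. The incidence statistic is evaluated
at every retained draw, yielding a posterior mean and equal-tailed 95%
credible interval (a plug-in estimate at the posterior means is reported
alongside).

Survey-bias controls mirror how these databases are actually assembled:
a *reduced* variant keeps one record per species (the one with the most
individuals tested) to guard against targeted resampling of known-infected
species, and any over-represented family (mosquitoes, Culicidae, being the
canonical case) can be excluded in a paired sensitivity run.

## Worked example

Simulate a 600-species survey with known truth, then fit the habitat
contrast on the reduced database:

```
$ wolbsurvey simulate --out demo.csv --seed 42 \
    --n-aquatic 300 --n-terrestrial 300 \
    --alpha -0.85 --beta 0.4 --theta 0.3
wrote demo.csv (600 records) and demo.csv.truth

$ wolbsurvey fit --data demo.csv --variant reduced --seed 1 --out demo_fit
aquatic [per_draw]: 0.610 (0.535-0.685)
aquatic [plug_in]: 0.611 (0.611-0.611)
terrestrial [per_draw]: 0.711 (0.644-0.776)
terrestrial [plug_in]: 0.713 (0.713-0.713)
outputs in demo_fit
```

The generator's truth sidecar (`demo.csv.truth`) records true incidences of
0.614 (aquatic) and 0.719 (terrestrial): both per-draw posterior means land
within 0.01 of truth and the 95% credible intervals bracket it. The numbers
read as "an estimated 61% of aquatic species carry the symbiont (95% CrI
54–69%) versus 71% of terrestrial species (64–78%)". `demo_fit/` holds the
summary table, the full posterior draws in long format, per-parameter R̂ and
effective-sample-size diagnostics, and a JSON manifest (seed, configuration,
data checksum) from which the run can be reproduced exactly.

Other subcommands: `validate`, `summarize` (database counts and family
shares), `reduce`, `per-order` (independent intercept-only fits per aquatic
order), `sensitivity` (paired with/without-family runs), `report`
(point-interval chart). The library API (`wolbsurvey.*`) exposes the same
operations programmatically.

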