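# Methods

This note documents the models implemented in `fossilbd`, their
assumptions, the defaults and why they were chosen, what the synthetic
record generator does and does not emulate, and the numerical and design
choices made where more than one reasonable option existed.

## Conventions

Ages are in Ma before present (present = 0, larger = older); rates are
per lineage per Myr.  All time bins and piecewise-constant segments are
half-open `(younger, older]`: an age exactly on a boundary belongs to
the bin whose older edge it is, and the youngest bin is additionally
closed at 0.  This one convention is shared by stage binning
(`bin_ages`), epoch assignment in the TPP likelihood, covariate grids,
and rate step functions, so boundary ages can never be double-counted
or dropped.

## Preservation models

Occurrences of a lineage with lifespan [Te, Ts], duration d = Ts − Te,
follow a Poisson process conditioned on at least one occurrence (an
unsampled lineage is invisible, so all likelihoods carry the
`− ln(1 − e^{−qd})` correction; it is evaluated with a `log1p`/`expm1`
branch at x = ln 2 and is accurate down to qd ≈ 1e−300):

* **HPP** — constant q: `k ln q − qd − ln(1 − e^{−qd})`.
* **NHPP** — q varying over the lifespan.  The intensity is
  q·f(u; shape), with u = (Ts − t)/d the normalized position and f the
  symmetric Beta(shape, shape) density, shape ≥ 1.  At shape = 1 this
  reduces *exactly* to the HPP; for shape > 1 preservation peaks
  mid-lifespan, which captures the classic observation that taxa are
  found less often near their true endpoints.  The symmetric-Beta form
  is this package's concrete choice for "preservation varying over a
  lifespan"; it is deliberately the simplest one-parameter family with
  the HPP as an interior boundary case.
* **TPP** — q piecewise constant across geological epochs:
  `Σ_j k_j ln q_j − Σ_j q_j d_j − ln(1 − e^{−Σ_j q_j d_j})`, with d_j
  the lifespan/epoch overlap.  A built-in Cenozoic epoch table
  (66, 56, 33.9, 23.03, 5.333, 2.58, 0 Ma, Holocene merged into the
  Pleistocene) is the default; any descending boundary set works.

### Model selection

`model_test` maximizes each model's total likelihood (1 parameter for
HPP, 2 for NHPP, one rate per data-spanning epoch for TPP; epochs with
zero exposure are dropped) and reports both AICc and BIC.  **Selection
defaults to BIC.**  These are nested models: the NHPP contains the HPP
on its shape boundary and the TPP contains it at equal rates, so a
fixed AIC-type penalty retains an irreducible, sample-size-independent
overparameterization rate (roughly the half-χ²₁ tail beyond 2 for the
NHPP plus the χ²_{E−1} tail beyond 2(E−1) for the TPP — of order 15%
combined).  BIC's log-n penalty is model-selection consistent and, in
the simulation study run by `scripts/acceptance.py`, recovers the
generating regime essentially always while the strong rate contrasts
that matter biologically (e.g., a doubling of q across an epoch
boundary) exceed its penalty by an order of magnitude.  AICc remains in
every report and `criterion="aicc"` restores it.

When inferred lifespans are not yet available, observed ranges padded
by max(10% of range, 0.5 Myr) serve as proxies.  A caveat discovered in
validation and worth knowing: padded proxy ranges create artificial
occurrence-free margins at both lifespan ends, which mimics a
mid-lifespan preservation hump and biases selection toward the NHPP.
Reliable three-way selection therefore wants lifespans that are either
known (simulations) or estimated (`sample_lifespans`); with proxies,
treat an NHPP selection with fitted shape close to 1 with suspicion.

## Birth–death inference

### Likelihood

Lifespans are treated as completely observed point events: every Ts is
a speciation event at rate λ(Ts), every Te > 0 an extinction event at
rate μ(Te), and the exposure integral ∫(λ+μ)·N(t)dt is computed exactly
(piecewise-constant rates × piecewise-constant N).  There is no
conditioning on clade survival.  Because the exposure decomposes into
per-lineage integrals, the conditional posterior of one lineage's
(Ts, Te) given rates and preservation parameters factorizes across
lineages — the joint sampler exploits this for vectorized per-lineage
accept/reject updates.

### Priors and moves

Rates and preservation rates carry Gamma(1.1, 1) priors (weakly
informative, mode near 0.1, mean 1.1); the number of shifts per rate is
Poisson(1) by default; shift times are uniform over the data span; the
NHPP shape has a Uniform(1, 50) prior.  The reversible-jump move set
is: birth (insert a shift at a uniform position; the older sub-segment
keeps the current rate, the younger draws from the prior), death
(remove a shift, keeping the older segment's rate), shift-time slide,
and log-scale rate updates.  Because birth draws the new rate from its
prior and death mirrors it deterministically, the acceptance ratio
collapses to the likelihood ratio times the Poisson count ratio — no
explicit Jacobian bookkeeping is needed.  Within-model proposal scales
default to values giving 20–50% acceptance on a constant-rate
simulation of a few hundred lineages.

In joint mode (`sample_lifespans`) the sampler also updates blocks of
(Ts, Te) under hard constraints Ts ≥ oldest occurrence,
0 ≤ Te ≤ youngest occurrence (Te ≡ 0 for extant species), and the
preservation parameters.  Under the TPP, sampled Ts values are capped
at the oldest epoch boundary, since preservation before the first epoch
would otherwise be implicitly zero.

### Convergence and summaries

Effective sample sizes use the initial-positive-sequence rule
(ESS = n / (1 + 2Σρ), the autocorrelation sum truncated at the first
adjacent pair with negative sum); constant traces report ESS = n with a
zero-variance flag.  ESS ≥ 200 on the log-likelihood and on λ, μ probed
at four span quantiles is a warning gate, not a failure.  Credible
intervals are shortest-interval HPDs; rate summaries report per-age
median and 95% HPD of λ, μ and r = λ − μ, computed sample-wise.

### Workflow

The full pipeline mirrors the large-dataset workflow: species are split
into near-equal random subsets (default 11), occurrence ages are
resampled uniformly within their stratigraphic bounds (default 50
replicates), lifespans are estimated per subset and replicate, medians
are merged across subsets (per replicate and overall), and the merged
medians feed a fixed-lifespan rjMCMC run for the headline rates.
Taking medians discards lifespan uncertainty at the merge step; the
pipeline keeps the per-replicate lifespan sets as well, and the MBD
stage runs once per replicate and pools posteriors, which restores the
age-uncertainty component.

## Trajectories and per-capita rates

Range-through diversity counts lineages whose closed interval [Te, Ts]
covers a grid age (default 0.1 Myr; ties count as present).  Slopes are
D(younger) − D(older) per step, assigned to the younger age.  The
binned cross-check classifies species per 1-Myr bin into Foote's
boundary-crosser categories from their first/last appearance bins; the
per-capita rates are p̂ = ln((N_bt+N_Ft)/N_bt)/Δt and
q̂ = ln((N_bt+N_bL)/N_bt)/Δt, with singletons excluded from both
numerator and denominator and bins without both-boundary crossers
flagged undefined rather than raised.

## The multivariate birth–death model

Covariates (other clades' range-through diversity, environmental
series) live on a common descending age grid, each value extending from
its own grid age toward younger ages, and are min–max rescaled to
[0, 1] (constant series map to zeros with a flag).  Links:

* exponential: λ(t) = λ₀·exp(Σⱼ γ_λⱼ xⱼ(t)), likewise μ;
* linear: λ₀·(1 + Σⱼ γ_λⱼ xⱼ(t)), floored at 1e−5 per Myr.

The likelihood reuses the birth–death form with cell-wise exact
exposure integrals; sufficient statistics (per-cell exposures and event
counts) are precomputed once, so a likelihood evaluation is a handful
of vector operations.

### Horseshoe prior and sampling

γⱼ ~ N(0, localScaleⱼ²·globalScale²) with half-Cauchy(0,1) local and
global scales, sampled by exact Gibbs through the inverse-gamma
auxiliary-variable scheme.  One global scale is shared between the
speciation and extinction blocks by default (`shared_global=False`
splits them).  The γ's are updated by slice sampling: their conditional
scale spans many orders of magnitude during a run, and a fixed-step
Metropolis kernel demonstrably freezes in the "funnel" when the global
scale collapses (γ becomes immovable, leaving the local scales stuck at
arbitrary values and the shrinkage weights meaningless).  The slice
kernel adapts its bracket to the current prior scale and cannot freeze.
Baseline rates get multiplier Metropolis updates under Gamma(1.1, 1)
priors.  One "generation" is one full sweep.

### Shrinkage weights

The exposed primitive is `shrinkage_weight(local, global) =
1 − 1/(1 + local²·global²)`.  The per-covariate weights recorded by the
sampler evaluate it with the **local scale alone** (global scale 1),
i.e. the local scale measured in units of the global scale.  The
reasoning: the global scale encodes the overall sparsity level and, in
the exact horseshoe posterior, the *product* local·global concentrates
near |γ| itself — a weight built on the product is therefore just a
monotone transform of the effect magnitude (≈0.5 at γ = 1) and can
never approach 1 for moderate but decisively supported effects.  The
local scale, by contrast, measures how far a covariate must escape the
global shrinkage to accommodate its effect: it stays at or below its
half-Cauchy prior for noise (w ≤ 0.5) and inflates like |γ|/globalScale
for genuine signals (w → 1).  This reproduces the intended reading —
noise near 0, signal near 1, significance at median w > 0.7 — and under
the prior alone gives the characteristic bath-tub shape with ≥20% of
mass below 0.1 and above 0.9 (exactly (2/π)·atan(1/3) ≈ 0.205 on each
side).  Turnover effects are per-sample sums T_j = γ_λj + γ_μj; a
fold-change reading exp(T_j·Δx) with Δx = 1 is one plausible
convention, reported as such.  Linear-vs-exponential link comparison
uses posterior harmonic means of the log-likelihoods
(−logmeanexp(−logL), max-shift stabilized) — kept for fidelity to
standard practice despite the estimator's notorious variance.

## Synthetic records

`simulate_bd` is an exact event-driven birth–death simulation with
piecewise-constant rates.  Waiting times are drawn by inverting the
integrated total hazard, so the realized history depends only on the
rate functions as functions — refining breakpoints (as the coupled-clade
wrapper does) leaves matched-seed histories bit-identical, which is what
makes the γ = 0 coupling identity exactly testable.  Preservation
sampling drops unobserved lineages from the occurrence output but keeps
them in the truth table, so preservation-induced bias is itself
measurable.  Stage-style age uncertainty comes from `bin_ages` (1-Myr
bins or the epoch table).  Coupled clades: clade A simulated
independently, its rescaled range-through diversity D_A(t) driving
clade B's rates through the chosen link.

What the generator does *not* emulate: spatial structure (site ids are
random groupings, sufficient only for co-occurrence filtering),
taxonomic error beyond the aff./cf. qualifier flags, per-lineage
preservation heterogeneity, and correlated age errors across
occurrences of a collection.  Passing tests therefore demonstrate
correctness of the inference machinery under the stated models, not
robustness to every bias of real compilations.

## Study scales used in tests and the acceptance script

Chain lengths are reduced relative to production settings (tens of
millions of generations) to desk scale: 200k generations for rate
recovery and shift detection, 50k for per-replicate lifespan estimation,
2–6k sweeps for MBD runs; simulated clades run from ~200 observed
species (single-family scale) to ~1500 (all-families scale, used where
extinction-event counts set the power of diversity-dependence
recovery).  Degenerate simulated histories — e.g. a "driver" clade whose
founders die immediately, leaving nothing to drive — are redrawn with an
incremented seed, because the scenario under test presumes a radiating,
extant driver.  The driver's diversity follows a radiate-then-saturate
trajectory (a rate shift at 10 Ma), giving multi-Myr covariate contrast
that survives 1-Myr age binning; a purely exponential radiation
concentrates all contrast in the youngest couple of bins, where binned
age noise is largest, and is a genuinely harder (weaker-powered) design.

## Known limitations

* The harmonic-mean marginal-likelihood estimator has infinite variance
  in general; its link comparisons are indicative, not decisive.
* Median-merged lifespans understate terminal uncertainty in the
  fixed-lifespan rate stage (mitigated by the per-replicate path).
* The NHPP/proxy-lifespan interaction biases model selection toward
  NHPP (see above).
* MBD effect estimates from observed-range lifespans are attenuated
  toward zero; use sampler-estimated lifespans per age replicate, as
  the pipeline does.
* No per-clade rate multipliers within a single rjMCMC run, no
  fossilized-birth–death tree inference, no sampling standardization
  (SQS/rarefaction) of binned diversity.
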