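# fossilbd

Bayesian diversification analysis of fossil occurrence records — for
paleobiologists and macroevolution researchers who want to estimate
speciation and extinction dynamics, reconstruct diversity trajectories,
and test for cross-clade diversity dependence directly from
Paleobiology-Database-style occurrence tables, without a phylogeny.

## What it does

The fossil record of a clade is a set of dated occurrences per species,
each with a stratigraphic age range. `fossilbd` models this record in
three layers:

1. **Preservation.** Each species' occurrences are a Poisson process
   with rate *q* (occurrences per lineage per Myr) over its true
   lifespan [*Te*, *Ts*], conditioned on the species being sampled at
   least once.  Three variants — *q* constant (HPP), varying over the
   lifespan (NHPP), or varying across geological epochs (TPP) — are
   compared by maximum likelihood (`model_test`).

2. **Birth–death dynamics.** Per-species origination (*Ts*) and
   extinction (*Te*) ages are estimated jointly with the preservation
   parameters and with piecewise-constant speciation λ(t) and extinction
   μ(t), via reversible-jump MCMC that also samples the number and
   position of rate shifts (`sample_lifespans`, `rj_mcmc_rates`).  The
   lifespan likelihood is

   ln L = Σᵢ ln λ(Tsᵢ) + Σ_{i extinct} ln μ(Teᵢ) − ∫ (λ(t)+μ(t)) N(t) dt,

   with N(t) the number of coexisting lineages; net diversification is
   r(t) = λ(t) − μ(t).  Range-through diversity trajectories on a
   0.1-Myr grid, slope series, and discrete-bin per-capita (Foote)
   origination/extinction rates provide method cross-checks
   (`range_through`, `foote_rates`).

3. **Diversity dependence.** A multivariate birth–death (MBD) model
   links λ(t) and μ(t) to covariate time series — other clades'
   rescaled diversity trajectories, paleotemperature, sea level, rate of
   sea-level change — through a linear or exponential link, e.g.
   λ(t) = λ₀·exp(Σⱼ γ_λⱼ xⱼ(t)).  A horseshoe prior on the correlation
   parameters γ separates signal from noise; each covariate gets a
   shrinkage weight *w* ∈ [0, 1] (noise → 0, signal → 1), with a
   conservative significance rule of median *w* > 0.7
   (`mbd_mcmc`, `build_effect_network`).

A first-class synthetic-record generator (`simulate_bd`,
`simulate_preservation`, `simulate_coupled_clades`, `bin_ages`) produces
PBDB-style tables with known ground truth, so every inference stage is
validated end-to-end against simulations.

## Worked example

```python
import numpy as np
import fossilbd as fb

# simulate a clade with known rates and an imperfect fossil record
params = fb.SimParams(t_root=22, lam=0.35, mu=0.2, n0=5, seed=3, family="Demo")
history = fb.simulate_bd(params)
record = fb.simulate_preservation(history, fb.PreservationModel("HPP", q=2.0), seed=53)
print(f"{len(history)} true lineages, {record['species'].nunique()} sampled, "
      f"{len(record)} occurrences")

# which preservation model does the record support?
lineages = [fb.LineageOccurrences(sp, g["min_ma"].to_numpy(), bool(g["extant"].any()))
            for sp, g in record.groupby("species")]
spans = history.lineages.set_index("species")
names = [ln.species for ln in lineages]
test = fb.model_test(lineages, lifespans=(spans.loc[names, "ts"].to_numpy(),
                                          spans.loc[names, "te"].to_numpy()))
print("preservation model selected:", test.selected)

# jointly estimate lifespans, preservation and birth-death rates
cfg = fb.MCMCConfig(n_generations=50_000, sample_every=100, seed=9)
post = fb.sample_lifespans(record, cfg, model="HPP")
summary = fb.summarize_rates(post, step=1.0)
row = summary.iloc[len(summary) // 2]
print(f"lambda at {row['age']:.0f} Ma: {row['lambda_med']:.3f} "
      f"[{row['lambda_lo']:.3f}, {row['lambda_hi']:.3f}]  (truth 0.35)")
print(f"mu     at {row['age']:.0f} Ma: {row['mu_med']:.3f} "
      f"[{row['mu_lo']:.3f}, {row['mu_hi']:.3f}]  (truth 0.20)")

# range-through diversity from the posterior-median lifespans
traj = fb.range_through(post.median_lifespans(), step=0.1)
print("diversity at 5 Ma:", traj.counts[np.argmin(np.abs(traj.ages - 5.0))])
```

Output:

```
276 true lineages, 227 sampled, 1544 occurrences
preservation model selected: HPP
lambda at 11 Ma: 0.303 [0.259, 0.353]  (truth 0.35)
mu     at 11 Ma: 0.179 [0.144, 0.213]  (truth 0.20)
diversity at 5 Ma: 50
```

The record was generated under a homogeneous preservation process, and
the model test recovers that; the posterior medians of λ and μ sit
within ~15% of the generating rates with 95% credibility intervals that
cover the truth; the range-through count is the number of estimated
lifespans spanning 5 Ma.

## Command line

`fossilbd` exposes the pipeline as subcommands — `simulate`, `filter`,
`replicate`, `modeltest`, `lifespans`, `rates`, `ltt`, `slopes`,
`divdyn`, `mbd`, `network`, and `run` (full pipeline from a YAML
config).  `fossilbd <cmd> --help` describes each.

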