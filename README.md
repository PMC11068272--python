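# coalsky

Bayesian coalescent skyline plot inference of demographic histories from
dated genealogies.

Population geneticists and phylodynamicists routinely reconstruct how the
effective population size Ne(t) of a single panmictic population changed
through time from a genealogy of sampled sequences — isochronous
(everything sampled now) or heterochronous (ancient DNA, serially sampled
pathogens).  Many flavours of "skyline plot" priors exist for the
trajectory, scattered across different software with incompatible
defaults.  `coalsky` separates the coalescent probability density of the
genealogy from the prior on the trajectory, so that nine classic models —
**constant**, **skyline**, **BSP**, **EBSP**, **skyride**, **skygrid**,
**GMRF**, **HSMRF** and the reversible-jump **skyfish** — are
interchangeable in front of the same likelihood, fitted with the same
MCMC machinery, and comparable with the same stepping-stone marginal
likelihoods.

## The model

Backward in time, with k(t) active lineages (sampling events increment k,
coalescences decrement it), two lineages coalesce at rate

    c(t) = k(t) (k(t) − 1) / (2 Ne(t)).

For an ordered timeline u of all sampling events, coalescent events and
trajectory change-points, the log-density of a genealogy is

    log P(t | Ne) = Σ_j −∫_{u_{j−1}}^{u_j} c(s) ds  +  Σ_{coal} −log Ne(u_j),

with Ne piecewise constant or piecewise linear over intervals whose
change-points either coincide with coalescent events (skyline/BSP/EBSP/
skyride) or are placed independently of them (skygrid/GMRF/HSMRF/
skyfish).  Every integral is analytic.  The priors range from iid
Uniform(0, 1e8) sizes to log-scale Gaussian random walks with global and
local shrinkage (γ, σ_i ~ Half-Cauchy, sd γζ), to skyfish's Poisson(10)
number of change-points explored by birth/death reversible-jump MCMC.
Multi-locus data and sequential inference from a posterior sample of
genealogies are supported for the models whose change-points do not
depend on the gene tree.  See `docs/methods.md` for the full model
catalogue and numerical choices.

## Worked example

Simulate a 36-tip isochronous genealogy under a constant Ne = 50,000
history, then let the skyfish model infer the trajectory:

```python
import numpy as np
import coalsky as ck
from coalsky.simulate import simulate_genealogy, CONSTANT_TRUTH

rng = np.random.default_rng(7)
g = simulate_genealogy(np.zeros(36), CONSTANT_TRUTH, rng)

model = ck.CoalescentSkylineModel(g, prior="skyfish")
res = model.fit(iterations=20_000, thinning=10, seed=7)
print(res.summary())
```

```
Coalescent skyline plot model results
=====================================================
prior model:        skyfish
interval function:  constant
retained samples:   3600
iterations:         20000 x 2 replicates, thinning 10, burn-in 10%
change-points:      mean 9.91 (95% CI 5-16)
-----------------------------------------------------
        time     Ne median         2.5%        97.5%
           0         45405        33464        66190
        9.64         45405        33464        66190
       112.2         45408        33464        66190
        1203         45405        33518        66143
   1.281e+04         47330        34109        81454
   1.364e+05         45534       3265.8   3.1559e+05
=====================================================
```

The posterior median stays flat near the true 45–50 k with a tight 95%
credible band through the data-rich recent past; towards the root, where
few coalescent events remain, the band widens toward the prior — exactly
the behaviour a well-calibrated skyline should show on constant-size
data.  `res.trajectory_summary()` returns the median/2.5%/97.5% envelope
on a 500-point grid spaced uniformly in log(1 + t), `res.convergence()`
reports the per-time Kolmogorov–Smirnov distance between the two
replicates, and `res.plot()` draws the skyline.
`model.log_marginal_likelihood()` runs the stepping-stone sampler for
Bayes-factor model comparison.

The same functionality is available from the shell:

```sh
coalsky fixture  --scenario isochronous36 --seed 1 --out-dir data/
coalsky infer    --trees data/isochronous36.trees \
                 --ages data/isochronous36_rep1_ages.tsv \
                 --config config.yaml --out trace.tsv
coalsky summarize --trace trace.tsv --t-max 500000 --out summary.tsv
coalsky compare  --trees data/isochronous36.trees \
                 --ages data/isochronous36_rep1_ages.tsv --config config.yaml
```

with `simulate` and `seqsim` to generate genealogies and Jukes–Cantor
alignments under arbitrary piecewise trajectories.

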