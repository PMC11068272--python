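# Methods

## The coalescent density

`coalsky` infers the effective population size trajectory Ne(t) from dated
genealogies under Kingman's coalescent for a single panmictic population.
Time runs backward from the present (t = 0) in the genealogy's own units —
generations or calendar years — and the package never rescales: if the
genealogy is calibrated in years, Ne is estimated directly rather than as
the compound parameter θ = 2Neμ.  Sampling may be heterochronous; tips
simply enter the process at their ages, incrementing the active lineage
count k, while coalescences decrement it.  At any instant the coalescent
rate is c(t) = k(t)(k(t)−1) / (2 Ne(t)) (haploid convention; multiply Ne
by the ploidy externally if desired).

The log-density of a genealogy is assembled on a merged timeline of
sampling events, coalescent events and trajectory change-points: for every
pair of consecutive events the no-event probability contributes
−∫ c(t) dt, and every coalescent event contributes the point factor
log[2/(k(k−1)) · c(u)] = −log Ne(u).  Because Ne is piecewise constant or
piecewise linear, every segment integral is analytic — constant:
k(k−1)(b−a)/(2ρ); linear: k(k−1)/(2α) · ln(Ne(b)/Ne(a)) — so no quadrature
appears outside the test oracles.  The n = 2 normalization property
(the density integrates to 1 over the root time) pins down the event
bookkeeping: the sums run over *all* consecutive event pairs and *all*
coalescent events.  Note the density is that of the *labelled genealogy*:
the marginal density of the coalescent times alone is larger by the
number of labelled histories, ∏ k(k−1)/2 over the coalescent events
(a factor 3 already for three tips), which matters when comparing against
time-marginal simulations.

Intervals are left-closed/right-open, [x_i, x_{i+1}), so Ne(0) = ρ_1 is
always defined and an event lying exactly on a change-point is priced at
the older interval's size.  This choice is arbitrary at measure zero for
continuous data but matters for the events-method layout, where
change-points coincide with coalescent times by construction; it is
covered by a regression test.

Multi-locus data multiply the per-locus densities under the shared
trajectory; this requires change-points placed independently of
coalescent events, since event-based change-points are locus-specific.
Sequential inference reuses a posterior sample of genealogies from an
earlier (typically constant-size) analysis: the pseudo-likelihood is the
log of the average of density ratios exp(log p(g_j | trajectory) − log
p_ref(g_j)), computed with a max-shift.

## The nine trajectory priors

All priors sit in front of the same likelihood and differ in two respects:
where change-points go (at coalescent events vs independent of them) and
how sizes are smoothed across intervals.  Defaults follow the standard
published configurations:

- **constant** — one interval, ρ ~ Uniform(0, 1e8); the reference model.
- **skyline** — iid Uniform sizes, one interval per five coalescent
  events (⌈(n−1)/5⌉ intervals, the final group absorbing the remainder).
- **bsp** — ρ_1 ~ Loguniform(1e−2, 1e8), then autocorrelated
  ρ_{i+1} ~ Exponential with mean ρ_i; same five-event grouping.  The
  grouping is fixed rather than random: the implicit multinomial over
  events per interval that the original formulation carries is ignored in
  practice, and modelling it would make the probabilistic graph cyclic.
- **ebsp** — one candidate change-point per coalescent event; each is
  either active (a fresh Exponential(λ) size) or tied to its predecessor.
  The tie probability α_eq defaults to 0.5 and the active count is
  Binomial(n−2, 1−α_eq).  λ is given a hyperprior by placing
  Loguniform(1e−2, 1e8) on the mean 1/λ, consistent with the size ranges
  of the other models.  The RJ toggle move draws activations from the
  exponential prior so the proposal density cancels exactly.
- **skyride / skygrid** — lognormal random walk on sizes with precision τ
  ~ Gamma(0.001, 0.001); "1/τ" is read as the variance of the log-scale
  normal (the precision convention that the Gamma(0.001, 0.001)
  hyperprior classically accompanies).  Skyride uses one interval per
  coalescent event; skygrid an equal grid (default 50 intervals) on
  [0, t_max].
- **gmrf / hsmrf** — Gaussian random walk on log sizes with sd γζ
  (hsmrf additionally per-increment local scales σ_i, all Half-Cauchy(0,1)),
  ρ_1 ~ Uniform(0, 1e8) as printed.  The smoothing constants ζ = 0.0195
  (gmrf) and ζ = 0.0051 (hsmrf) calibrate the a-priori expected variation
  for 50 intervals; they are plain configuration constants here and are
  *not* re-derived for other interval counts.
- **skyfish** — κ ~ Poisson(10) change-points at sorted Uniform(0, tMAX)
  positions, ρ_1 ~ Lognormal(median tMAX/4, sd 2H) with H = 0.587405
  (ln(100)/(4 z_{0.975}); 95% prior mass across two orders of magnitude),
  and log-size jumps Normal(0, σ·Δξ) where Δξ is the gap between
  consecutive change-points (the origin counts as change-point zero; the
  printed indexing leaves this ambiguous).  σ ~ Exponential with *rate*
  tMAX/8 (mean 8/tMAX): with sd = σ·Δξ this gives order-one log jumps
  over horizon-scale gaps, whereas the mean-tMAX/8 reading produces
  absurd jumps of hundreds of log units.  The increment sd is the literal
  product σ·Δξ, not √Δξ Brownian scaling — kept as printed.

All priors are proper (every uniform and loguniform carries finite
bounds), which is a precondition for marginal-likelihood comparison and is
enforced by the stepping-stone code.

### Numerical handling of heavy-tailed hyperpriors

Gamma(0.001, 0.001) is so diffuse that about half its mass lies below the
smallest positive normal double, and Half-Cauchy tails reach far enough
that a generative draw of the size chain can overflow exp().  Ancestral
sampling therefore draws tiny-shape gammas in log space (Marsaglia–Tsang
boost) with a floor at e⁻⁶⁶⁷ ≈ 1e−290, and clamps log sizes to ±700.
Both cut-offs sit hundreds of log-units outside any posterior mass; they
only keep generative draws representable.

## MCMC

One sweep applies a multiplier (scale) move to every free positive
parameter — proposal x·exp(tuning·(u−½)), log-Hastings equal to the
exponent — then, for skyfish, a reflected sliding move on each
change-point position and one reversible-jump birth/death move, or, for
ebsp, one activation toggle.  Birth draws ξ* ~ Uniform(0, tMAX) and a new
log size from a Normal centred on the current log Ne at ξ*; death removes
a uniformly chosen change-point and its size; the dimension map is the
identity, so the Jacobian is 1 and the acceptance ratio is the posterior
ratio times the proposal densities.  Proposal windows adapt toward 44%
acceptance in batches of 50 during burn-in only and are frozen afterward,
preserving detailed balance for every retained sample.  Initial states
are drawn from the prior (up to 1,000 attempts before giving up).

Default run settings are 100,000 iterations × 2 replicates, sampling
every 10th iteration with 10% burn-in removed per replicate before
pooling — 18,000 retained samples.  Seeded runs are reproducible
(replicates get independent child seeds from one seed sequence).  The
likelihood for fixed change-points in constant mode is collapsed to
per-interval sufficient statistics (A_i, c_i) so a proposal costs O(L);
variable change-points (skyfish) re-merge the timeline per evaluation
with vectorized searchsorted.

Replicate agreement is checked with the Kolmogorov–Smirnov distance
between the two replicates' log-Ne samples at each grid time; the
threshold is configurable (default 0.05, appropriate for the default
9,000 samples per replicate — shorter chains need a looser value since
the KS noise floor scales as n^(−1/2)).

## Stepping-stone marginal likelihoods

Powers β_i = (i/(K−1))^(1/0.3) — quantiles of Beta(0.3, 1), the customary
ladder — run from prior to posterior; the default is 128 stones × 5,000
iterations, each warm-started from the previous stone with the first 25%
used as stone burn-in.  The log marginal likelihood is the sum of
stone-wise log E_{β_k}[L^{β_{k+1}−β_k}] terms.  With two stones the
estimator collapses to the prior arithmetic mean, which is the degenerate
case used for testing.  Bayes factors are differences of log marginal
likelihoods.

## The simulator and what the fixtures emulate

Genealogies are simulated by exact inversion of the integrated hazard:
a unit exponential deviate is spent segment by segment, restarting at
every sampling event and change-point (valid by memorylessness), with the
constant-segment inverse w = 2ρE/(k(k−1)) and the linear-segment inverse
w = Ne(a)(exp(2αE/(k(k−1))) − 1)/α.  A thinning-based rejection sampler
exists only as an independent test oracle.  Sequences evolve
site-independently under Jukes–Cantor; the substitution model is
deliberately minimal since the package does not compute sequence
likelihoods, and is pluggable if richer models are ever needed.

The fixture scenarios mirror the shapes of a typical ancient-DNA
mitochondrial study: 36 isochronous tips, or 173 tips of which 137 have ages drawn
uniformly on (0, 50,000) years; truth trajectories are a constant
Ne = 50,000 and a "recent peak" piecewise history (20,000 → 100,000 →
30,000 → 60,000 across change-points at 5, 20, 50 and 250 kyr).  The
default locus is 16 kb with a clock of 2×10⁻⁷/site/year, chosen to give
roughly 2% expected pairwise diversity.  These are package choices: the
fixtures emulate the *shape* of such data (sample sizes, time scales,
diversity), not any real dataset, so passing tests demonstrate internal
statistical correctness — simulator/density consistency, posterior and
prior recovery, calibrated credible intervals — and not agreement with
any empirical curve.  Real data add alignment error, rate variation,
selection, structure and aDNA damage, none of which are modelled.

Test and acceptance runs use deliberately scaled problem sizes — tens of
thousands of MCMC sweeps, 32 stepping stones, 10 simulation replicates —
which are ample for the single- to ten-parameter posteriors involved;
the same code paths run unchanged at the full default settings.

## Known limitations

- No joint inference of the genealogy from sequence alignments: the
  genealogy (or a posterior sample of genealogies) is data.
- No multifurcations, unrooted trees or sampled ancestors.
- Only constant and linear per-interval demographic functions.
- The exact birth/death proposal densities of other RJ implementations
  are not replicated; the sampler is validated by prior recovery and by
  posterior agreement with quadrature, not by output matching another
  program.
- ζ defaults are valid for 50 intervals only; choosing another grid size
  requires supplying a recalibrated ζ.
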