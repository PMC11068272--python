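"""The nine skyline trajectory prior models.

Every model is a prior over the per-interval population sizes ρ (plus, for
some models, latent hyperparameters), interchangeable in front of the same
coalescent density:

========  ==============================  ====================================
model     change-points                   prior on ρ
========  ==============================  ====================================
constant  none (one interval)             ρ ~ Uniform(0, 1e8)
skyline   coalescent events, groups of 5  ρ_i iid Uniform(0, 1e8)
bsp       coalescent events, groups of 5  ρ_1 ~ Loguniform, ρ_{i+1} ~ Exp(1/ρ_i)
ebsp      coalescent events, number and   ρ_i either tied to ρ_{i-1} or a fresh
          position estimated (RJ-MCMC)    Exponential(λ) draw
skyride   one per coalescent event        ρ_{i+1} ~ Lognormal(ln ρ_i, 1/√τ)
skygrid   equal grid (specified)          identical to skyride
gmrf      equal grid (specified)          ln ρ_{i+1} ~ Normal(ln ρ_i, γζ)
hsmrf     equal grid (specified)          ln ρ_{i+1} ~ Normal(ln ρ_i, σ_i γζ)
skyfish   number κ ~ Poisson(10) and      ln ρ_{i+1} ~ Normal(ln ρ_i, σ·Δξ),
          positions ξ ~ U(0, tMAX) (RJ)   ρ_1 ~ Lognormal(ln(tMAX/4), 2H)
========  ==============================  ====================================

The smoothing constants ζ = 0.0195 (gmrf) and ζ = 0.0051 (hsmrf) calibrate
the a-priori expected variation for 50 intervals and are exposed as plain
configuration constants; they are not re-derived for other interval counts.
All priors are proper (bounded uniforms/loguniforms), which is what makes
marginal-likelihood model comparison legitimate.

A model state is a plain dict of arrays/floats; ``log_prior`` returns the
joint log-density of the state (including hyperprior terms, with densities
over ρ on the natural scale, i.e. log-scale normals appear as lognormals)
and ``sample_prior`` draws an exact ancestral sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, ndtri

from .demography import DemographicTrajectory

__all__ = [
    "MODEL_NAMES",
    "PriorSpec",
    "default_hyperparams",
    "lognormal_spread_constant",
    "make_prior_model",
    "log_prior",
    "sample_prior",
    "skyfish_trajectory_from_state",
]

MODEL_NAMES = (
    "constant",
    "skyline",
    "bsp",
    "ebsp",
    "skyride",
    "skygrid",
    "gmrf",
    "hsmrf",
    "skyfish",
)

_LN2PI = math.log(2.0 * math.pi)


def lognormal_spread_constant(orders_of_magnitude: float = 2.0, mass: float = 0.95) -> float:
    """The half-sd constant H such that a lognormal with sd = 2H places the
    given central prior mass across the given number of orders of magnitude.

    The central ``mass`` interval of a lognormal spans a factor
    exp(2 z sd) with z the standard-normal quantile at (1+mass)/2; solving
    exp(2 z · 2H) = 10^orders gives H = orders·ln(10)/(4z).  The defaults
    yield H = 0.587405 (95% mass across two orders of magnitude).
    """
    z = ndtri(0.5 * (1.0 + mass))
    return orders_of_magnitude * math.log(10.0) / (4.0 * z)


# -- elementary log densities (hand-coded for speed in the MCMC hot path) ----


def _lpdf_uniform(x, lo, hi):
    x = np.asarray(x, float)
    if np.any(x <= lo) or np.any(x >= hi):
        return -np.inf
    return -x.size * math.log(hi - lo)


def _lpdf_loguniform(x, lo, hi):
    x = np.asarray(x, float)
    if np.any(x < lo) or np.any(x > hi):
        return -np.inf
    return float(-np.log(x).sum() - x.size * math.log(math.log(hi / lo)))


def _lpdf_exponential(x, rate):
    x = np.asarray(x, float)
    if np.any(x < 0) or rate <= 0:
        return -np.inf
    return float(x.size * math.log(rate) - rate * x.sum())


def _lpdf_gamma(x, shape, rate):
    if x <= 0:
        return -np.inf
    return shape * math.log(rate) - gammaln(shape) + (shape - 1) * math.log(x) - rate * x


def _lpdf_halfcauchy(x, scale=1.0):
    x = np.asarray(x, float)
    if np.any(x < 0):
        return -np.inf
    return float(
        x.size * math.log(2.0 / (math.pi * scale)) - np.log1p((x / scale) ** 2).sum()
    )


def _lpdf_lognormal(x, meanlog, sdlog):
    """Density of x on the natural scale when ln x ~ Normal(meanlog, sdlog)."""
    x = np.asarray(x, float)
    sdlog = np.asarray(sdlog, float)
    if np.any(x <= 0) or np.any(sdlog <= 0):
        return -np.inf
    lx = np.log(x)
    return float(
        np.sum(-lx - np.log(sdlog) - 0.5 * _LN2PI - (lx - meanlog) ** 2 / (2 * sdlog**2))
    )


def _lpmf_poisson(k, mean):
    if k < 0:
        return -np.inf
    return k * math.log(mean) - mean - gammaln(k + 1)


# The classic Gamma(0.001, 0.001) precision hyperprior is so diffuse that
# roughly half its mass lies below the smallest normal double; ancestral
# sampling therefore works in log space with an explicit floor, and log
# population sizes are clamped to +/-700 (the exp() overflow boundary) so that a
# generative draw from a heavy-tailed hyperprior still yields a finite,
# evaluable state.  The floors sit far outside any posterior mass.
_LN_FLOOR = -667.0   # exp(-667) ~ 1e-290
_LN_RHO_CLAMP = 700.0


def _sample_gamma_log(rng, shape, rate):
    """Gamma(shape, rate) draw that stays positive for tiny shapes."""
    if shape >= 0.1:
        return float(rng.gamma(shape, 1.0 / rate))
    # Marsaglia–Tsang boost: X = G(shape+1) * U^(1/shape), done in logs
    lng = (
        math.log(rng.gamma(shape + 1.0, 1.0))
        + math.log(rng.random()) / shape
        - math.log(rate)
    )
    return math.exp(max(lng, _LN_FLOOR))


def _lognormal_walk(rng, rho1, sds):
    """ρ chain with ln ρ_{i+1} = ln ρ_i + N(0, sd_i), logs clamped."""
    ln_rho = np.empty(len(sds) + 1)
    ln_rho[0] = math.log(rho1)
    for i, sd in enumerate(sds):
        step = np.clip(ln_rho[i] + rng.normal(0.0, sd), -_LN_RHO_CLAMP, _LN_RHO_CLAMP)
        ln_rho[i + 1] = step
    return np.exp(ln_rho)


# -- defaults ----------------------------------------------------------------


def default_hyperparams(model: str, n_intervals: int | None = None, t_max: float | None = None) -> dict:
    """Default hyperparameter configuration for a model.

    The ζ values for gmrf/hsmrf are calibrated for 50 intervals; the
    skyfish σ prior is Exponential with *rate* tMAX/8 (mean 8/tMAX), so
    typical log-population jumps across tMAX-scale gaps are order one.
    """
    if model in ("constant", "skyline"):
        return {"lower": 0.0, "upper": 1e8}
    if model == "bsp":
        return {"rho1_lower": 1e-2, "rho1_upper": 1e8}
    if model == "ebsp":
        return {"alpha_eq": 0.5, "mean_lower": 1e-2, "mean_upper": 1e8}
    if model in ("skyride", "skygrid"):
        return {
            "tau_shape": 0.001,
            "tau_rate": 0.001,
            "rho1_lower": 1e-2,
            "rho1_upper": 1e8,
        }
    if model == "gmrf":
        return {"zeta": 0.0195, "gamma_scale": 1.0, "rho1_lower": 0.0, "rho1_upper": 1e8}
    if model == "hsmrf":
        return {"zeta": 0.0051, "gamma_scale": 1.0, "rho1_lower": 0.0, "rho1_upper": 1e8}
    if model == "skyfish":
        hyper = {"poisson_mean": 10.0, "H": 0.587405}
        if t_max is not None:
            hyper["t_max"] = float(t_max)
            hyper["sigma_rate"] = float(t_max) / 8.0
            hyper["rho1_median"] = float(t_max) / 4.0
        return hyper
    raise ValueError(f"unknown model {model!r}")


@dataclass
class PriorSpec:
    """A model name plus its hyperparameter configuration."""

    model: str
    hyper: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.model!r}")

    def resolved_hyper(self, n_intervals=None, t_max=None) -> dict:
        h = default_hyperparams(self.model, n_intervals, t_max)
        h.update(self.hyper)
        return h


# -- model classes -----------------------------------------------------------


class _PriorModel:
    """Interchangeable log-density + sampler pair over a model state."""

    #: state keys holding positive parameters updated by multiplier moves
    scalar_keys: tuple[str, ...] = ()
    array_keys: tuple[str, ...] = ("rho",)

    def __init__(self, spec: PriorSpec, n_intervals: int, t_max: float | None):
        self.spec = spec
        self.L = int(n_intervals)
        self.t_max = t_max
        self.hyper = spec.resolved_hyper(n_intervals, t_max)

    def log_prior(self, state: dict) -> float:
        raise NotImplementedError

    def sample_prior(self, rng: np.random.Generator) -> dict:
        raise NotImplementedError

    def rho_vector(self, state: dict) -> np.ndarray:
        """Effective per-interval population sizes (length L)."""
        return state["rho"]

    def scale_components(self, state: dict):
        for key in self.scalar_keys:
            yield key, None
        for key in self.array_keys:
            for i in range(len(state[key])):
                yield key, i


class _UniformModel(_PriorModel):
    """constant (L = 1) and skyline: iid Uniform(0, 1e8) sizes."""

    def log_prior(self, state):
        h = self.hyper
        return _lpdf_uniform(state["rho"], h["lower"], h["upper"])

    def sample_prior(self, rng):
        h = self.hyper
        return {"rho": rng.uniform(h["lower"], h["upper"], size=self.L)}


class _BSPModel(_PriorModel):
    """Loguniform start, then autocorrelated Exponential(mean ρ_i) steps."""

    def log_prior(self, state):
        rho = state["rho"]
        h = self.hyper
        lp = _lpdf_loguniform(rho[:1], h["rho1_lower"], h["rho1_upper"])
        if lp == -np.inf or (rho[1:] <= 0).any():
            return -np.inf
        prev, nxt = rho[:-1], rho[1:]
        return lp + float(np.sum(-np.log(prev) - nxt / prev))

    def sample_prior(self, rng):
        h = self.hyper
        rho = np.empty(self.L)
        rho[0] = math.exp(rng.uniform(math.log(h["rho1_lower"]), math.log(h["rho1_upper"])))
        for i in range(1, self.L):
            rho[i] = rng.exponential(scale=rho[i - 1])
        return {"rho": rho}


class _MarkovLognormalModel(_PriorModel):
    """skyride and skygrid: lognormal random walk with precision τ."""

    scalar_keys = ("tau",)

    def log_prior(self, state):
        rho, tau = state["rho"], state["tau"]
        h = self.hyper
        if tau <= 0 or (rho <= 0).any():
            return -np.inf
        lp = _lpdf_gamma(tau, h["tau_shape"], h["tau_rate"])
        lp += _lpdf_loguniform(rho[:1], h["rho1_lower"], h["rho1_upper"])
        if len(rho) > 1:
            lp += _lpdf_lognormal(rho[1:], np.log(rho[:-1]), tau**-0.5)
        return lp

    def sample_prior(self, rng):
        h = self.hyper
        tau = _sample_gamma_log(rng, h["tau_shape"], h["tau_rate"])
        rho1 = math.exp(rng.uniform(math.log(h["rho1_lower"]), math.log(h["rho1_upper"])))
        rho = _lognormal_walk(rng, rho1, np.full(self.L - 1, tau**-0.5))
        return {"rho": rho, "tau": float(tau)}


class _GMRFModel(_PriorModel):
    """Gaussian Markov random field on log sizes, global scale γ·ζ."""

    scalar_keys = ("gamma",)

    def _sds(self, state):
        return state["gamma"] * self.hyper["zeta"]

    def log_prior(self, state):
        rho = state["rho"]
        h = self.hyper
        if (rho <= 0).any():
            return -np.inf
        lp = _lpdf_halfcauchy(state["gamma"], h["gamma_scale"])
        lp += _lpdf_uniform(rho[:1], h["rho1_lower"], h["rho1_upper"])
        if len(rho) > 1:
            lp += _lpdf_lognormal(rho[1:], np.log(rho[:-1]), self._sds(state))
        return lp

    def sample_prior(self, rng):
        h = self.hyper
        state = {"gamma": float(abs(rng.standard_cauchy()) * h["gamma_scale"])}
        if "sigma" in self.array_keys:
            state["sigma"] = np.abs(rng.standard_cauchy(self.L - 1)) * h["gamma_scale"]
        sds = np.broadcast_to(np.asarray(self._sds(state), float), (self.L - 1,))
        rho1 = rng.uniform(h["rho1_lower"], h["rho1_upper"])
        state["rho"] = _lognormal_walk(rng, rho1, np.maximum(sds, 1e-300))
        return state


class _HSMRFModel(_GMRFModel):
    """Horseshoe variant: per-increment local scales σ_i on top of γ·ζ."""

    array_keys = ("rho", "sigma")

    def _sds(self, state):
        return state["sigma"] * state["gamma"] * self.hyper["zeta"]

    def log_prior(self, state):
        lp = super().log_prior(state)
        return lp + _lpdf_halfcauchy(state["sigma"], self.hyper["gamma_scale"])


class _EBSPModel(_PriorModel):
    """Stochastic-variable-selection skyline: each candidate change-point
    (one per coalescent event after the first interval) is either active —
    the size is a fresh Exponential(λ) draw — or tied to its predecessor.

    State: ``mean`` (the exponential mean 1/λ, itself loguniform),
    ``active`` (bool per candidate), ``values`` (per-slot sizes; only the
    first slot and active slots carry probability mass, dormant entries
    are ignored).  α_eq is the prior probability that a slot is *tied*.
    """

    scalar_keys = ("mean",)
    array_keys = ()

    def _free_mask(self, state):
        return np.concatenate([[True], state["active"]])

    def log_prior(self, state):
        h = self.hyper
        m = state["mean"]
        lp = _lpdf_loguniform(np.array([m]), h["mean_lower"], h["mean_upper"])
        free = self._free_mask(state)
        lp += _lpdf_exponential(state["values"][free], 1.0 / m)
        n_active = int(state["active"].sum())
        k = len(state["active"])
        a = h["alpha_eq"]
        if 0.0 < a < 1.0:
            lp += n_active * math.log1p(-a) + (k - n_active) * math.log(a)
        elif a == 1.0 and n_active > 0:
            return -np.inf
        elif a == 0.0 and n_active < k:
            return -np.inf
        return lp

    def sample_prior(self, rng):
        h = self.hyper
        m = math.exp(rng.uniform(math.log(h["mean_lower"]), math.log(h["mean_upper"])))
        active = rng.random(self.L - 1) < (1.0 - h["alpha_eq"])
        values = rng.exponential(scale=m, size=self.L)
        return {"mean": float(m), "active": active, "values": values}

    def rho_vector(self, state):
        free = self._free_mask(state)
        src = np.maximum.accumulate(np.where(free, np.arange(self.L), 0))
        return state["values"][src]

    def scale_components(self, state):
        yield "mean", None
        free = self._free_mask(state)
        for i in np.flatnonzero(free):
            yield "values", int(i)


class _SkyfishModel(_PriorModel):
    """Poisson number of change-points, uniform positions, autocorrelated
    lognormal sizes with sd σ·(gap between consecutive change-points)."""

    scalar_keys = ("sigma",)

    def __init__(self, spec, n_intervals, t_max):
        super().__init__(spec, n_intervals, t_max)
        if self.t_max is None:
            self.t_max = self.hyper.get("t_max")
        if self.t_max is None:
            raise ValueError("the skyfish model needs t_max")
        self.hyper.setdefault("sigma_rate", self.t_max / 8.0)
        self.hyper.setdefault("rho1_median", self.t_max / 4.0)

    def log_prior(self, state):
        h = self.hyper
        kappa = int(state["kappa"])
        xi, rho, sigma = state["xi"], state["rho"], state["sigma"]
        if len(xi) != kappa or len(rho) != kappa + 1 or sigma <= 0:
            return -np.inf
        if (rho <= 0).any():
            return -np.inf
        if kappa:
            if xi[0] < 0 or xi[-1] > self.t_max:
                return -np.inf
            gaps = np.empty(kappa)
            gaps[0] = xi[0]
            if kappa > 1:
                d = np.diff(xi)
                if (d < 0).any():
                    return -np.inf
                gaps[1:] = d
        mean = h["poisson_mean"]
        rate = h["sigma_rate"]
        # the Poisson κ! cancels the ordered-uniform κ! of the sorted ξ
        lp = (
            kappa * (math.log(mean) - math.log(self.t_max))
            - mean
            + math.log(rate)
            - rate * sigma
        )
        ln_rho = np.log(rho)
        sd1 = 2.0 * h["H"]
        z1 = (ln_rho[0] - math.log(h["rho1_median"])) / sd1
        lp += -ln_rho[0] - math.log(sd1) - 0.5 * _LN2PI - 0.5 * z1 * z1
        if kappa:
            sds = sigma * gaps
            if (sds <= 0).any():
                return -np.inf
            dln = np.diff(ln_rho)
            lp += float(
                np.sum(
                    -ln_rho[1:] - np.log(sds) - 0.5 * _LN2PI - dln * dln / (2.0 * sds * sds)
                )
            )
        return lp

    def sample_prior(self, rng):
        h = self.hyper
        kappa = int(rng.poisson(h["poisson_mean"]))
        xi = np.sort(rng.uniform(0.0, self.t_max, size=kappa))
        sigma = float(rng.exponential(scale=1.0 / h["sigma_rate"]))
        rho1 = math.exp(rng.normal(math.log(h["rho1_median"]), 2.0 * h["H"]))
        gaps = np.diff(np.concatenate([[0.0], xi]))
        rho = _lognormal_walk(rng, rho1, sigma * gaps)
        return {"kappa": kappa, "xi": xi, "sigma": sigma, "rho": rho}

    def changepoints(self, state) -> np.ndarray:
        return np.concatenate([[0.0], state["xi"]])


_MODEL_CLASSES = {
    "constant": _UniformModel,
    "skyline": _UniformModel,
    "bsp": _BSPModel,
    "ebsp": _EBSPModel,
    "skyride": _MarkovLognormalModel,
    "skygrid": _MarkovLognormalModel,
    "gmrf": _GMRFModel,
    "hsmrf": _HSMRFModel,
    "skyfish": _SkyfishModel,
}


def make_prior_model(spec: PriorSpec, n_intervals: int, t_max: float | None = None) -> _PriorModel:
    return _MODEL_CLASSES[spec.model](spec, n_intervals, t_max)


def log_prior(spec: PriorSpec, state: dict, n_intervals: int | None = None, t_max: float | None = None) -> float:
    """Joint log prior density of a model state (hyperpriors included)."""
    if n_intervals is None:
        n_intervals = len(state["rho"]) if "rho" in state else len(state["values"])
    return make_prior_model(spec, n_intervals, t_max).log_prior(state)


def sample_prior(spec: PriorSpec, rng: np.random.Generator, n_intervals: int = 1, t_max: float | None = None) -> dict:
    """Exact ancestral-sampling draw from a model's prior."""
    return make_prior_model(spec, n_intervals, t_max).sample_prior(rng)


def skyfish_trajectory_from_state(state: dict, t_max: float, mode: str = "constant") -> DemographicTrajectory:
    """Piecewise trajectory with change-points {0} ∪ ξ and κ+1 sizes."""
    xi = np.asarray(state["xi"], float)
    if np.any(xi < 0) or np.any(xi > t_max):
        raise ValueError("change-points outside [0, t_max]")
    x = np.concatenate([[0.0], xi])
    return DemographicTrajectory(x, state["rho"], mode=mode)
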