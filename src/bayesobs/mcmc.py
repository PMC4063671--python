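"""Bayesian estimation of observer parameters by slice sampling.

Per (subject, model) we sample the posterior over the observer's free
parameters with coordinate-wise slice sampling (stepping-out and shrinkage),
run three parallel chains from jittered starting points, monitor convergence
with the Gelman-Rubin potential scale reduction statistic, and summarize
each fit with a DIC score and a robust (trimmed-mean) point estimate.

Parameter priors: informative log-normal priors on the motor SD and the
cue-measurement SD of factor S (hyperparameters from the config layer);
Uniform[0, 1] on likelihood SDs and lapse rates (screen units /
probabilities); Uniform[0, 4] on the prior-noise Weber fraction eta; and the
decision-noise exponent parameterized as xi = 1/kappa ~ Uniform(0, 1],
equivalent to p(kappa) proportional to kappa^-2 on kappa >= 1 (integrable,
avoiding the marginalization paradox of improper priors in model
comparison).  The sample-average count K of PSA uses the same 1/K scheme.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import lognorm

from .config import FitConfig, TaskConfig
from .observers import (
    LikelihoodEngine,
    ObserverParams,
    ObserverSpec,
    RelTrial,
    free_param_names,
    make_rel_trials,
)

__all__ = [
    "McmcResult",
    "log_prior",
    "slice_sample",
    "gelman_rubin",
    "dic",
    "trimmed_mean",
    "fit_subject",
    "map_search",
    "ParamSpace",
]

_RECIPROCAL = ("kappa_train", "kappa_test", "psa_k_train", "psa_k_test")
_LOGNORMAL = ("motor_sd", "cue_est_sd_train", "cue_est_sd_test")
_UNIT_INTERVAL = (
    "lik_sd_short_train", "lik_sd_long_train", "lik_sd_short_test",
    "lapse_train", "lapse_test",
)
_ETA = ("weber_prior_train", "weber_prior_test")


@dataclass
class McmcResult:
    """Chains and summaries of one (subject, model) fit.

    ``chains`` are in the natural parameterization, shape
    (n_chains, n_samples, n_params); ``log_liks`` matches on the first two
    axes.  ``theta_hat`` is the per-parameter trimmed mean across all
    retained samples.
    """

    model: str
    param_names: list
    chains: np.ndarray
    log_liks: np.ndarray
    rhat: np.ndarray
    dic: float
    p_d: float
    theta_hat: np.ndarray

    def params(self, spec: ObserverSpec) -> ObserverParams:
        return ObserverParams.from_vector(spec, self.theta_hat)

    def credible_interval(self, level: float = 0.95) -> np.ndarray:
        """Central posterior intervals, shape (n_params, 2)."""
        flat = self.chains.reshape(-1, self.chains.shape[-1])
        a = 100.0 * (1.0 - level) / 2.0
        return np.stack(
            [np.percentile(flat, a, axis=0), np.percentile(flat, 100.0 - a, axis=0)], axis=1
        )


class ParamSpace:
    """Maps between natural parameters and the sampling space.

    kappa-like parameters are sampled as xi = 1/kappa in (0, 1]; everything
    else is sampled in natural units.  Also owns the per-coordinate prior
    terms and initial slice widths.
    """

    def __init__(self, spec: ObserverSpec, fit_cfg: FitConfig,
                 free_loss_width: bool = False):
        self.spec = spec
        self.names = free_param_names(spec, free_loss_width)
        self.fit_cfg = fit_cfg
        self.bounds = []
        self.widths = []
        for n in self.names:
            if n in _RECIPROCAL:
                self.bounds.append((1e-3, 1.0))  # xi
                self.widths.append(0.25)
            elif n in _LOGNORMAL:
                self.bounds.append((1e-5, 1.0))
                self.widths.append(0.01)
            elif n in _ETA:
                self.bounds.append((0.0, 4.0))
                self.widths.append(0.25)
            elif n == "loss_sd":
                self.bounds.append((1e-3, 0.3))
                self.widths.append(0.02)
            else:
                self.bounds.append((1e-4, 1.0))
                self.widths.append(0.03 if n.startswith("lik") else 0.02)

    def to_natural(self, u: np.ndarray) -> np.ndarray:
        v = np.array(u, dtype=float)
        for i, n in enumerate(self.names):
            if n in _RECIPROCAL:
                v[i] = 1.0 / u[i]
        return v

    def to_sampling(self, v: np.ndarray) -> np.ndarray:
        u = np.array(v, dtype=float)
        for i, n in enumerate(self.names):
            if n in _RECIPROCAL:
                u[i] = 1.0 / v[i]
        return u

    def log_prior_sampling(self, u: np.ndarray) -> float:
        """Log prior density in the sampling parameterization."""
        lp = 0.0
        for i, n in enumerate(self.names):
            lo, hi = self.bounds[i]
            if not lo <= u[i] <= hi:
                return -np.inf
            if n == "motor_sd":
                lp += lognorm.logpdf(
                    u[i], self.fit_cfg.motor_log_shape,
                    scale=np.exp(self.fit_cfg.motor_log_scale),
                )
            elif n in ("cue_est_sd_train", "cue_est_sd_test"):
                lp += lognorm.logpdf(
                    u[i], self.fit_cfg.cue_est_log_shape,
                    scale=np.exp(self.fit_cfg.cue_est_log_scale),
                )
            # uniform terms contribute a constant
        return float(lp)


def log_prior(spec: ObserverSpec, params: ObserverParams,
              fit_cfg: FitConfig = FitConfig()) -> float:
    """Log prior of natural parameters (including the xi = 1/kappa Jacobian,
    so p(kappa) is proportional to kappa^-2 on kappa >= 1)."""
    space = ParamSpace(spec, fit_cfg)
    v = params.to_vector(spec)
    u = space.to_sampling(v)
    lp = space.log_prior_sampling(u)
    if not np.isfinite(lp):
        return -np.inf
    for i, n in enumerate(space.names):
        if n in _RECIPROCAL:
            lp += -2.0 * np.log(v[i])  # |d xi / d kappa| = kappa^-2
    return float(lp)


def slice_sample(
    log_target,
    init: np.ndarray,
    n_chains: int = 3,
    burn_in: int = 500,
    n_samples: int = 2000,
    seed: int = 0,
    widths=None,
    bounds=None,
    jitter: float = 0.05,
    max_stepout: int = 200,
):
    """Coordinate-wise slice sampling with stepping-out and shrinkage.

    Runs ``n_chains`` parallel chains from jittered copies of ``init``.
    Returns (chains, log_targets) with shapes (C, S, P) and (C, S).
    """
    init = np.asarray(init, dtype=float)
    d = init.size
    widths = np.full(d, 1.0) if widths is None else np.asarray(widths, dtype=float)
    if bounds is None:
        bounds = [(-np.inf, np.inf)] * d
    chains = np.empty((n_chains, n_samples, d))
    logts = np.empty((n_chains, n_samples))
    for c in range(n_chains):
        rng = np.random.default_rng([seed, c])
        x = init.copy()
        if c > 0:  # different starting points per chain
            for i in range(d):
                lo, hi = bounds[i]
                span = widths[i]
                x[i] = np.clip(x[i] + rng.normal(0.0, jitter * max(span, 1e-6) / 0.05),
                               lo + 1e-12 if np.isfinite(lo) else -np.inf,
                               hi - 1e-12 if np.isfinite(hi) else np.inf)
        fx = log_target(x)
        if not np.isfinite(fx):
            x = init.copy()
            fx = log_target(x)
        if not np.isfinite(fx):
            raise ValueError("log target not finite at the initial point")
        for s in range(-burn_in, n_samples):
            for i in range(d):
                y = fx - rng.exponential(1.0)
                lo_b, hi_b = bounds[i]
                u = rng.uniform()
                left = x[i] - widths[i] * u
                right = left + widths[i]
                j = 0
                xi_old = x[i]

                def f_at(val):
                    x[i] = val
                    return log_target(x)

                while j < max_stepout and left > lo_b and f_at(left) > y:
                    left -= widths[i]
                    j += 1
                left = max(left, lo_b)
                j = 0
                while j < max_stepout and right < hi_b and f_at(right) > y:
                    right += widths[i]
                    j += 1
                right = min(right, hi_b)
                while True:
                    cand = rng.uniform(left, right)
                    fc = f_at(cand)
                    if fc > y:
                        x[i] = cand
                        fx = fc
                        break
                    if cand < xi_old:
                        left = cand
                    else:
                        right = cand
                    if right - left < 1e-300:
                        x[i] = xi_old
                        fx = log_target(x)
                        break
            if s >= 0:
                chains[c, s] = x
                logts[c, s] = fx
    return chains, logts


def gelman_rubin(chains: np.ndarray) -> np.ndarray:
    """Potential scale reduction R-hat per parameter.

    chains: (n_chains, n_samples, n_params), n_chains >= 2, n_samples >= 10.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 3 or chains.shape[0] < 2 or chains.shape[1] < 10:
        raise ValueError("need >= 2 chains with >= 10 samples each")
    m, n, _ = chains.shape
    means = chains.mean(axis=1)  # (m, p)
    w = chains.var(axis=1, ddof=1).mean(axis=0)  # within
    b_over_n = means.var(axis=0, ddof=1)  # between / n
    out = np.empty(w.shape)
    degenerate = w <= 0
    if degenerate.any():
        warnings.warn("zero within-chain variance: R-hat undefined for some parameters")
    var_hat = (n - 1) / n * w + b_over_n
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.sqrt(var_hat / w)
    out[degenerate] = np.nan
    return out


def trimmed_mean(x: np.ndarray, fraction: float = 0.10, axis: int = 0) -> np.ndarray:
    """Mean after discarding ``fraction`` of values from each side."""
    x = np.sort(np.asarray(x, dtype=float), axis=axis)
    n = x.shape[axis]
    k = int(np.floor(fraction * n))
    sl = [slice(None)] * x.ndim
    sl[axis] = slice(k, n - k if k > 0 else n)
    return x[tuple(sl)].mean(axis=axis)


def dic(chains: np.ndarray, log_lik_fn, trim_fraction: float = 0.10):
    """Deviance information criterion from MCMC output.

    D(theta) = -2 log L; DIC = 2 mean(D) - D(theta_hat);
    p_D = mean(D) - D(theta_hat); theta_hat = per-parameter trimmed mean.
    ``log_lik_fn`` maps a parameter vector to a log likelihood.
    """
    flat = np.asarray(chains, dtype=float).reshape(-1, chains.shape[-1])
    theta_hat = trimmed_mean(flat, trim_fraction, axis=0)
    devs = np.asarray([-2.0 * log_lik_fn(t) for t in flat])
    mean_dev = float(devs.mean())
    dev_hat = float(-2.0 * log_lik_fn(theta_hat))
    return 2.0 * mean_dev - dev_hat, mean_dev - dev_hat, theta_hat


def dic_from_samples(log_liks: np.ndarray, dev_hat: float):
    mean_dev = float((-2.0 * np.asarray(log_liks)).mean())
    return 2.0 * mean_dev - dev_hat, mean_dev - dev_hat


def fit_subject(
    spec: ObserverSpec,
    trials,
    task_cfg: TaskConfig = TaskConfig(),
    fit_cfg: FitConfig = FitConfig(),
    seed: int = 0,
    init: ObserverParams | None = None,
) -> McmcResult:
    """Sample the posterior over observer parameters for one dataset.

    ``trials`` may be TrialRecords or RelTrials.  The likelihood is the
    regularized product over non-excluded trials; the posterior is sampled
    in the transformed space (xi = 1/kappa) and reported in natural units.
    """
    if trials and not isinstance(trials[0], RelTrial):
        trials = make_rel_trials(trials)
    space = ParamSpace(spec, fit_cfg, task_cfg.free_loss_width)
    engine = LikelihoodEngine(spec, trials, task_cfg, fit_cfg.gauss_hermite_order,
                              param_names=space.names)
    init_p = init if init is not None else ObserverParams()
    init_v = np.asarray([getattr(init_p, n) for n in space.names])
    if "loss_sd" in space.names and not np.isfinite(init_v[space.names.index("loss_sd")]):
        init_v[space.names.index("loss_sd")] = task_cfg.loss.loss_sd
    u0 = space.to_sampling(init_v)
    u0 = np.clip(u0, [b[0] + 1e-9 for b in space.bounds], [b[1] - 1e-9 for b in space.bounds])

    cache = {}

    def log_post(u):
        lp = space.log_prior_sampling(u)
        if not np.isfinite(lp):
            return -np.inf
        ll = engine.loglik_vector(space.to_natural(u))
        cache["ll"] = ll
        return lp + ll

    chains_u, _ = slice_sample(
        log_post, u0,
        n_chains=fit_cfg.n_chains, burn_in=fit_cfg.burn_in,
        n_samples=fit_cfg.n_samples, seed=seed,
        widths=np.asarray(space.widths), bounds=space.bounds,
    )
    # natural-space chains and per-sample log likelihoods
    nat = np.empty_like(chains_u)
    lls = np.empty(chains_u.shape[:2])
    for c in range(chains_u.shape[0]):
        for s in range(chains_u.shape[1]):
            v = space.to_natural(chains_u[c, s])
            nat[c, s] = v
            lls[c, s] = engine.loglik_vector(v)
    rhat = gelman_rubin(nat)
    flat = nat.reshape(-1, nat.shape[-1])
    theta_hat = trimmed_mean(flat, fit_cfg.trim_fraction, axis=0)
    dev_hat = -2.0 * engine.loglik_vector(theta_hat)
    dic_val, p_d = dic_from_samples(lls.ravel(), dev_hat)
    return McmcResult(
        model=str(spec),
        param_names=space.names,
        chains=nat,
        log_liks=lls,
        rhat=rhat,
        dic=float(dic_val),
        p_d=float(p_d),
        theta_hat=theta_hat,
    )


def map_search(
    spec: ObserverSpec,
    trials,
    task_cfg: TaskConfig = TaskConfig(),
    fit_cfg: FitConfig = FitConfig(),
    seed: int = 0,
    restarts: int | None = None,
):
    """Multi-start MAP sanity search (Nelder-Mead from random draws).

    Used as an optional pre-fit check that the chains are not stuck in a
    local optimum; returns (best natural vector, best log posterior).
    """
    from scipy.optimize import minimize

    if trials and not isinstance(trials[0], RelTrial):
        trials = make_rel_trials(trials)
    engine = LikelihoodEngine(spec, trials, task_cfg, fit_cfg.gauss_hermite_order)
    space = ParamSpace(spec, fit_cfg)
    rng = np.random.default_rng(seed)
    n = restarts if restarts is not None else fit_cfg.map_restarts

    def neg_log_post(u):
        lp = space.log_prior_sampling(u)
        if not np.isfinite(lp):
            return 1e12
        return -(lp + engine.loglik_vector(space.to_natural(u)))

    best_u, best_v = None, np.inf
    for _ in range(n):
        u0 = np.asarray([rng.uniform(lo, hi) for lo, hi in space.bounds])
        res = minimize(neg_log_post, u0, method="Nelder-Mead",
                       options={"maxiter": 200 * len(u0), "fatol": 1e-6})
        if res.fun < best_v:
            best_u, best_v = res.x, res.fun
    return space.to_natural(best_u), -best_v
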