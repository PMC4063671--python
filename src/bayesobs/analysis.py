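"""Model-free analyses and nonparametric prior reconstruction.

Model-free: robust (Tukey bisquare) linear fits of response vs cue per
condition (the slope is the empirical cue weight, to be compared with the
Bayes-optimal shrinkage weight), per-condition optimality-index summaries
with cue-only and prior-only baselines, and Nadaraya-Watson kernel
regression for smooth trend displays.

Reconstruction: the group prior of a condition is represented as a mixture
of many narrow, equally spaced Gaussian components whose mixing weights are
free; with each subject's observer parameters fixed (model SPK-L), the
weights are slice-sampled under the pooled likelihood, yielding a posterior
over smooth priors together with their first four central moments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .config import FitConfig, TaskConfig
from .gmm import GaussianMixture1D, optimal_target, optimality_index, posterior_update
from .mcmc import gelman_rubin, slice_sample
from .observers import ObserverParams, ObserverSpec, RelTrial, REG_EPSILON
from .task import TrialRecord, to_relative

__all__ = [
    "robust_linear_fit",
    "condition_slopes",
    "optimality_summary",
    "kernel_regression",
    "ReconstructionSpec",
    "ReconstructionResult",
    "reconstruct_priors",
]


def robust_linear_fit(x, y):
    """Iteratively reweighted least squares with Tukey's bisquare weights.

    Returns (slope, intercept, standard errors (slope_se, intercept_se)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("rank-deficient design: x is constant")
    design = sm.add_constant(x)
    fit = sm.RLM(y, design, M=sm.robust.norms.TukeyBiweight()).fit()
    intercept, slope = fit.params
    int_se, slope_se = fit.bse
    return float(slope), float(intercept), (float(slope_se), float(int_se))


def condition_slopes(trials: list[TrialRecord], cfg: TaskConfig = TaskConfig()):
    """Cue weight (slope) and bias (intercept) per Gaussian condition.

    Works in relative coordinates; rows carry the Bayes-optimal weight
    w = sd_p^2 / (sd_p^2 + sd_cue^2) for comparison.  Returns a list of
    dicts, one per (prior_sd, cue_level).
    """
    groups: dict = {}
    for t in trials:
        if t.prior_class != "gaussian" or t.edge_excluded or t.response_x is None:
            continue
        sd = float(t.prior.mixture.sds[0])
        key = (round(sd, 10), t.cue_level)
        cue = float(to_relative(t.cue_x, t.prior))
        r = float(to_relative(t.response_x, t.prior))
        groups.setdefault(key, []).append((cue, r))
    rows = []
    for (sd, level), pts in sorted(groups.items()):
        arr = np.asarray(pts)
        slope, intercept, ses = robust_linear_fit(arr[:, 0], arr[:, 1])
        sig = cfg.true_sigma(level)
        rows.append(
            {
                "prior_sd": sd,
                "cue_level": level,
                "slope": slope,
                "intercept": intercept,
                "slope_se": ses[0],
                "optimal_weight": sd**2 / (sd**2 + sig**2),
                "n_trials": len(pts),
            }
        )
    return rows


def optimality_summary(trials: list[TrialRecord], cfg: TaskConfig = TaskConfig()):
    """Mean optimality index per condition, with cue-only and prior-only
    baselines (the two extremal observers: response = cue position, and
    response = optimal target ignoring the cue)."""
    from .gmm import PosteriorMixture, max_success_probability, success_probability

    loss = cfg.loss
    acc: dict = {}
    for t in trials:
        if t.edge_excluded or t.response_x is None:
            continue
        prior = t.prior.realized()
        sig = cfg.true_sigma(t.cue_level)
        pmax = max_success_probability(prior, t.cue_x, sig, loss)
        if pmax <= 0:
            continue
        # prior-only observer: ignores the cue, aims at the prior's best target
        prior_only_resp = optimal_target(PosteriorMixture(prior, 0.0), loss)
        idx = success_probability(prior, t.cue_x, sig, t.response_x, loss) / pmax
        cue_idx = success_probability(prior, t.cue_x, sig, t.cue_x, loss) / pmax
        prior_idx = success_probability(prior, t.cue_x, sig, prior_only_resp, loss) / pmax
        key = (t.session, t.prior_class, t.prior_id, t.cue_level)
        acc.setdefault(key, []).append((idx, cue_idx, prior_idx))
    rows = []
    for key, vals in sorted(acc.items()):
        arr = np.asarray(vals)
        rows.append(
            {
                "session": key[0],
                "prior_class": key[1],
                "prior_id": key[2],
                "cue_level": key[3],
                "mean_index": float(arr[:, 0].mean()),
                "cue_only_index": float(arr[:, 1].mean()),
                "prior_only_index": float(arr[:, 2].mean()),
                "n_trials": len(vals),
            }
        )
    return rows


def kernel_regression(x, y, bandwidth: float | None = None):
    """Nadaraya-Watson estimator with a Gaussian kernel.

    Bandwidth defaults to Silverman's rule of thumb,
    1.06 sd(x) n^(-1/5).  Returns (predict function, bandwidth).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 points")
    h = bandwidth if bandwidth is not None else 1.06 * x.std() * x.size ** (-0.2)
    if h <= 0:
        raise ValueError("bandwidth must be positive")

    def predict(xq):
        xq = np.atleast_1d(np.asarray(xq, dtype=float))
        w = np.exp(-0.5 * ((xq[:, None] - x[None, :]) / h) ** 2)
        return (w @ y) / w.sum(axis=1)

    return predict, float(h)


# ---------------------------------------------------------------------------
# nonparametric prior reconstruction


@dataclass(frozen=True)
class ReconstructionSpec:
    """Configuration of the mixture-of-many-Gaussians prior representation.

    Component means are equally spaced over ``grid_bounds``; component SD
    equals the grid spacing (``component_sd`` overrides).  With the symmetry
    constraint, mirrored components share a weight.  ``fixed_theta`` holds
    each subject's (fixed) observer parameters; ``spec`` is the observer
    model, SPK-L by default.
    """

    grid_size: int = 30
    grid_bounds: tuple = (-0.45, 0.45)
    component_sd: float | None = None
    symmetry_constraint: bool = False
    fixed_theta: dict = field(default_factory=dict)
    spec: ObserverSpec = field(
        default_factory=lambda: ObserverSpec("SPK", lapse_L=True)
    )

    def __post_init__(self):
        if self.grid_size < 2:
            raise ValueError("grid_size must be >= 2")
        if self.grid_bounds[1] <= self.grid_bounds[0]:
            raise ValueError("invalid grid bounds")

    @property
    def component_means(self) -> np.ndarray:
        return np.linspace(self.grid_bounds[0], self.grid_bounds[1], self.grid_size)

    @property
    def spacing(self) -> float:
        return (self.grid_bounds[1] - self.grid_bounds[0]) / (self.grid_size - 1)

    @property
    def sd(self) -> float:
        return self.component_sd if self.component_sd is not None else self.spacing


@dataclass
class ReconstructionResult:
    weight_samples: np.ndarray  # (n_samples, M), rows on the simplex
    component_means: np.ndarray
    component_sd: float
    mean_prior: GaussianMixture1D
    moment_samples: np.ndarray  # (n_samples, 4): mean, var, skew, exkurt
    rhat: np.ndarray
    converged: bool

    @property
    def mean_sd(self) -> float:
        return float(np.sqrt(self.moment_samples[:, 1]).mean())


class _ReconLikelihood:
    """Pooled SPK-L likelihood of the mixture weights, everything else fixed.

    For fixed observer parameters, the posterior components induced by each
    reconstruction component are fixed per trial; only the posterior weights
    move with the prior weights.  All trial-level quantities are therefore
    precomputed: Z (likelihood of the cue under each component), the
    component pdf tensor on the response grid, and the motor kernel at the
    observed response.
    """

    def __init__(self, trials, rspec: ReconstructionSpec,
                 cfg: TaskConfig, grid_step: float):
        from scipy.stats import norm as _norm

        m = rspec.component_means
        s = rspec.sd
        pad = 0.25
        x = np.arange(m.min() - pad, m.max() + pad + grid_step, grid_step)
        self.x = x
        self.dx = grid_step
        self.m = m
        self.s = s
        Z, P, K, lam, kap, A = [], [], [], [], [], []
        for t, th in trials:
            sig = th.internal_lik_sd(t.session, t.cue_level)
            v = s**2 + sig**2
            z = _norm.pdf(t.cue, loc=m, scale=np.sqrt(v))
            tau = float(np.sqrt(s**2 * sig**2 / v))
            thet = (m * sig**2 + t.cue * s**2) / v
            P.append(_norm.pdf(x[None, :], loc=thet[:, None], scale=tau))
            Z.append(z)
            K.append(_norm.pdf(t.response - x, scale=th.motor_sd) * grid_step)
            lam.append(th.lapse(t.session) if rspec.spec.lapse_L else 0.0)
            kap.append(th.kappa(rspec.spec, t.session))
            A.append(_norm.pdf(t.response, loc=m, scale=np.hypot(s, th.motor_sd)))
        self.Z = np.asarray(Z)  # (T, M)
        # single precision for the large tensors: the per-trial densities are
        # O(1)-scaled and enter through a log of a ~350-term product, so
        # float32 relative error (~1e-7) is far below the MCMC noise floor
        self.P = np.asarray(P, dtype=np.float32)  # (T, M, G)
        self.K = np.asarray(K, dtype=np.float32)  # (T, G)
        self.lam = np.asarray(lam)
        self.kappa = np.asarray(kap, dtype=np.float32)[:, None]
        self.A = np.asarray(A)  # (T, M) lapse-density components

    def __call__(self, w: np.ndarray) -> float:
        wz = w[None, :] * self.Z  # (T, M) unnormalized posterior weights
        wz_sum = wz.sum(axis=1, keepdims=True)
        if np.any(wz_sum <= 0):
            return -np.inf
        wz = (wz / wz_sum).astype(np.float32)
        mix = (wz[:, None, :] @ self.P)[:, 0, :]  # (T, G)
        mx = mix.max(axis=1, keepdims=True)
        # floor the ratio: keeps pow off the slow subnormal path; the floored
        # tail contributes < 1e-16 of the normalized density mass
        powd = np.maximum(mix / mx, np.float32(1e-8)) ** self.kappa
        powd /= powd.sum(axis=1, keepdims=True) * np.float32(self.dx)
        p = (powd * self.K).sum(axis=1).astype(np.float64)
        p_lapse = self.A @ w
        p = (1.0 - self.lam) * p + self.lam * p_lapse
        return float(np.log(p + REG_EPSILON).sum())


def reconstruct_priors(
    datasets: dict,
    recon_spec: ReconstructionSpec,
    mcmc_budget: FitConfig = FitConfig(n_chains=5, burn_in=300, n_samples=600),
    seed: int = 0,
    cfg: TaskConfig = TaskConfig(),
    grid_step: float = 2e-3,
) -> ReconstructionResult:
    """Sample the posterior over the mixing weights of the group prior.

    ``datasets`` maps subject id -> list of RelTrials sharing the condition;
    each subject's observer parameters come from ``recon_spec.fixed_theta``
    (ObserverParams, typically the robust means of that subject's SPK-L
    fit).  Weights are sampled through unconstrained log-weights (flat
    prior, one weight pinned for identifiability; mirrored components tied
    when the symmetry constraint is on) and mapped to the simplex by
    normalization.  Returns weight samples, the posterior-mean prior and
    per-sample central moments.
    """
    pairs = []
    for sid, trials in datasets.items():
        th = recon_spec.fixed_theta[sid]
        for t in trials:
            if t.response is None:
                continue
            pairs.append((t, th))
    if not pairs:
        raise ValueError("no trials to reconstruct from")
    like = _ReconLikelihood(pairs, recon_spec, cfg, grid_step)
    m = recon_spec.grid_size
    if recon_spec.symmetry_constraint:
        half = (m + 1) // 2
        idx = np.minimum(np.arange(m), m - 1 - np.arange(m))
        n_free = half - 1
    else:
        idx = np.arange(m)
        n_free = m - 1

    def weights_from(u: np.ndarray) -> np.ndarray:
        full_u = np.concatenate([[0.0], u])[idx]
        w = np.exp(full_u - full_u.max())
        return w / w.sum()

    def log_target(u):
        return like(weights_from(u))

    chains, _ = slice_sample(
        log_target,
        np.zeros(n_free),
        n_chains=mcmc_budget.n_chains,
        burn_in=mcmc_budget.burn_in,
        n_samples=mcmc_budget.n_samples,
        seed=seed,
        widths=np.full(n_free, 1.5),
        bounds=[(-12.0, 12.0)] * n_free,
        jitter=0.3,
    )
    rhat = gelman_rubin(chains) if mcmc_budget.n_chains >= 2 else np.full(n_free, np.nan)
    converged = bool(np.all(np.nan_to_num(rhat, nan=1.0) < 1.1))
    if not converged:
        warnings.warn("prior reconstruction: R-hat >= 1.1, increase the budget")
    flat = chains.reshape(-1, n_free)
    w_samples = np.apply_along_axis(weights_from, 1, flat)
    means = recon_spec.component_means
    sd = recon_spec.sd
    moments = np.empty((w_samples.shape[0], 4))
    for i, w in enumerate(w_samples):
        gm = GaussianMixture1D(w, means, np.full(m, sd))
        moments[i] = gm.moments()
    mean_w = w_samples.mean(axis=0)
    mean_prior = GaussianMixture1D(mean_w / mean_w.sum(), means, np.full(m, sd))
    return ReconstructionResult(
        weight_samples=w_samples,
        component_means=means,
        component_sd=sd,
        mean_prior=mean_prior,
        moment_samples=moments,
        rhat=rhat,
        converged=converged,
    )
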