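"""Factorial family of suboptimal Bayesian observer models.

Every observer builds a posterior over target location by Bayes' rule, with
internal likelihood widths that may mismatch the true cue noise, and then
acts on the posterior in one of several ways:

* decision-making levels — ``BDT`` (deterministic minimization of the
  expected narrow loss), ``SPK`` (stochastic posterior: target choice
  proportional to posterior^kappa), ``PPM`` (posterior probability matching,
  the kappa = 1 case), ``PSA`` (mean of K posterior draws, an implicit
  quadratic-loss rule);
* optional Gaussian approximations applied before deciding — ``MV``
  (moment-matched Gaussian) or ``LA`` (Laplace approximation at the mode);
* optional factors — ``S`` (Gaussian sensory noise on the internal cue
  measurement, Weber-scaled with cue distance), ``P`` (log-normal noise on
  the prior's width, or on the two mixing weights for two-component priors),
  ``L`` (occasional lapses drawn from the displayed prior).

Response probabilities are the target-choice distributions convolved with
Gaussian motor noise and, for factors S and P, marginalized over the latent
internal measurements by Gauss-Hermite quadrature.  For single-Gaussian
priors everything is analytic, which is the fast path used in fitting.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields, replace
from itertools import product

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm

from .config import TaskConfig
from .gmm import (
    GaussianMixture1D,
    GridDensity,
    PosteriorMixture,
    default_grid,
    laplace_approx,
    optimal_target,
    posterior_update,
    power_density,
    sample_average_density,
    success_probability,
)
from .task import TrialRecord, to_relative

__all__ = [
    "ObserverSpec",
    "ObserverParams",
    "RelTrial",
    "param_count",
    "free_param_names",
    "parse_model_string",
    "basic_model_set",
    "extended_model_set",
    "derive_extended_equivalences",
    "target_choice_density",
    "response_density",
    "response_probability",
    "gaussian_closed_form_response",
    "log_likelihood",
    "LikelihoodEngine",
    "make_rel_trials",
    "REG_EPSILON",
    "PSA_EXACT_MAX",
]

DECISIONS = ("BDT", "SPK", "PPM", "PSA")
APPROXIMATIONS = ("none", "MV", "LA")

# regularization floor: standard-normal pdf at 5 SDs from the mean
REG_EPSILON = float(norm.pdf(5.0))
PSA_EXACT_MAX = 8


@dataclass(frozen=True)
class ObserverSpec:
    """A point in the factorial model space."""

    decision: str
    gauss_approx: str = "none"
    cue_noise_S: bool = False
    prior_noise_P: bool = False
    lapse_L: bool = False
    # variants outside the factorial acceptance surface (reported worse in
    # the source study; kept as switches only)
    lapse_uniform: bool = False
    discrete_prior: bool = False

    def __post_init__(self):
        if self.decision not in DECISIONS:
            raise ValueError(f"unknown decision level {self.decision!r}")
        if self.gauss_approx not in APPROXIMATIONS:
            raise ValueError(f"unknown Gaussian approximation {self.gauss_approx!r}")
        if self.lapse_uniform and not self.lapse_L:
            raise ValueError("lapse_uniform requires the lapse factor")

    def __str__(self) -> str:
        parts = [self.decision]
        if self.gauss_approx != "none":
            parts.append(self.gauss_approx)
        if self.cue_noise_S:
            parts.append("S")
        if self.prior_noise_P:
            parts.append("P")
        if self.lapse_L:
            parts.append("L")
        return "-".join(parts)


def parse_model_string(s: str) -> ObserverSpec:
    """Parse a canonical model string such as ``"SPK-P-L"`` or ``"PSA-MV-L"``."""
    parts = s.strip().split("-")
    if not parts or parts[0] not in DECISIONS:
        raise ValueError(f"model string must start with a decision level: {s!r}")
    spec = {"decision": parts[0]}
    for tok in parts[1:]:
        if tok in ("MV", "LA"):
            if spec.get("gauss_approx", "none") != "none":
                raise ValueError(f"duplicate Gaussian approximation in {s!r}")
            spec["gauss_approx"] = tok
        elif tok == "S":
            spec["cue_noise_S"] = True
        elif tok == "P":
            spec["prior_noise_P"] = True
        elif tok == "L":
            spec["lapse_L"] = True
        else:
            raise ValueError(f"unknown model token {tok!r} in {s!r}")
    return ObserverSpec(**spec)


def basic_model_set() -> list[ObserverSpec]:
    """The 24 basic models: {BDT, SPK, PPM} x S x P x L."""
    return [
        ObserverSpec(dec, cue_noise_S=s, prior_noise_P=p, lapse_L=lp)
        for dec in ("BDT", "SPK", "PPM")
        for s in (False, True)
        for p in (False, True)
        for lp in (False, True)
    ]


@dataclass(frozen=True)
class ObserverParams:
    """Free-parameter vector theta of an observer, screen units throughout.

    Sharing rules across the training and test sessions: the motor SD is
    shared; the internal long-cue likelihood SD in the test session is tied
    to the short-cue one by the training-session ratio; the long-cue
    measurement SD of factor S is tied to the short-cue one by the ratio of
    cue distances (Weber scaling); kappa/K, eta and lambda are free per
    session.
    """

    lik_sd_short_train: float = 0.06
    lik_sd_long_train: float = 0.14
    lik_sd_short_test: float = 0.06
    motor_sd: float = 0.01
    kappa_train: float = 2.0
    kappa_test: float = 2.0
    psa_k_train: float = 2.0
    psa_k_test: float = 2.0
    cue_est_sd_train: float = 0.01
    cue_est_sd_test: float = 0.01
    weber_prior_train: float = 0.25
    weber_prior_test: float = 0.25
    lapse_train: float = 0.03
    lapse_test: float = 0.03
    # free loss width of the extended BDT variant; NaN -> use the task loss
    loss_sd: float = float("nan")

    @property
    def lik_ratio(self) -> float:
        return self.lik_sd_long_train / self.lik_sd_short_train

    def internal_lik_sd(self, session: str, cue_level: str) -> float:
        if session == "training":
            return self.lik_sd_short_train if cue_level == "short" else self.lik_sd_long_train
        if cue_level == "short":
            return self.lik_sd_short_test
        return self.lik_sd_short_test * self.lik_ratio

    def kappa(self, spec: ObserverSpec, session: str) -> float:
        if spec.decision == "BDT":
            return math.inf
        if spec.decision == "PPM":
            return 1.0
        if spec.decision == "SPK":
            return self.kappa_train if session == "training" else self.kappa_test
        raise ValueError("kappa undefined for PSA (use psa_k)")

    def psa_k(self, session: str) -> float:
        return self.psa_k_train if session == "training" else self.psa_k_test

    def cue_est_sd(self, session: str, cue_level: str, cfg: TaskConfig) -> float:
        base = self.cue_est_sd_train if session == "training" else self.cue_est_sd_test
        return base if cue_level == "short" else base * cfg.weber_distance_ratio

    def weber_prior(self, session: str) -> float:
        return self.weber_prior_train if session == "training" else self.weber_prior_test

    def lapse(self, session: str) -> float:
        return self.lapse_train if session == "training" else self.lapse_test

    # -- vector interface --------------------------------------------------
    def to_vector(self, spec: ObserverSpec) -> np.ndarray:
        return np.asarray([getattr(self, n) for n in free_param_names(spec)])

    @classmethod
    def from_vector(cls, spec: ObserverSpec, vec) -> "ObserverParams":
        names = free_param_names(spec)
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (len(names),):
            raise ValueError(f"expected vector of length {len(names)}")
        return cls(**dict(zip(names, vec)))

    def to_json(self, spec: ObserverSpec) -> str:
        payload = {
            "model": str(spec),
            "units": "screen units (window width 1.0)",
            "params": {n: getattr(self, n) for n in free_param_names(spec)},
        }
        return json.dumps(payload, indent=2)

    def replace(self, **kw) -> "ObserverParams":
        return replace(self, **kw)


def free_param_names(spec: ObserverSpec, free_loss_width: bool = False) -> list[str]:
    names = ["lik_sd_short_train", "lik_sd_long_train", "lik_sd_short_test", "motor_sd"]
    if spec.decision == "SPK":
        names += ["kappa_train", "kappa_test"]
    elif spec.decision == "PSA":
        names += ["psa_k_train", "psa_k_test"]
    if spec.cue_noise_S:
        names += ["cue_est_sd_train", "cue_est_sd_test"]
    if spec.prior_noise_P:
        names += ["weber_prior_train", "weber_prior_test"]
    if spec.lapse_L:
        names += ["lapse_train", "lapse_test"]
    if free_loss_width and spec.decision == "BDT":
        names += ["loss_sd"]
    return names


def param_count(spec: ObserverSpec, free_loss_width: bool = False) -> int:
    """Number of free parameters across training + test under the sharing rules."""
    return len(free_param_names(spec, free_loss_width))


# ---------------------------------------------------------------------------
# relative-frame trials


@dataclass(frozen=True)
class RelTrial:
    """A trial mapped into the prior's canonical (relative) frame."""

    prior: GaussianMixture1D
    prior_class: str
    session: str
    cue_level: str
    cue: float
    response: float | None = None

    @property
    def is_gaussian(self) -> bool:
        return self.prior.n_components == 1


def make_rel_trials(
    trials: list[TrialRecord], drop_edge: bool = True, require_response: bool = True
) -> list[RelTrial]:
    out = []
    for t in trials:
        if drop_edge and t.edge_excluded:
            continue
        if require_response and t.response_x is None:
            continue
        resp = None if t.response_x is None else float(to_relative(t.response_x, t.prior))
        out.append(
            RelTrial(
                prior=t.prior.mixture,
                prior_class=t.prior_class,
                session=t.session,
                cue_level=t.cue_level,
                cue=float(to_relative(t.cue_x, t.prior)),
                response=resp,
            )
        )
    return out


# ---------------------------------------------------------------------------
# latent-variable nodes (factors S and P)

_gh_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _gh(order: int):
    if order not in _gh_cache:
        z, w = np.polynomial.hermite.hermgauss(order)
        _gh_cache[order] = (z, w / np.sqrt(np.pi))
    return _gh_cache[order]


def _perturb_prior(prior: GaussianMixture1D, z: float, eta: float) -> GaussianMixture1D:
    """Apply one latent draw of factor P, standardized normal deviate ``z``.

    Single component: log-normal width (Weber noise on the prior SD).
    Two components: independent log-normal weight noise, equivalent to
    normal noise of SD sqrt(2) * eta on the log weight ratio.
    More components (the platykurtic prior): log-normal overall scale.
    """
    if eta <= 0:
        return prior
    if prior.n_components == 1:
        sd_hat = prior.sds[0] * math.exp(eta * z)
        return GaussianMixture1D([1.0], prior.means.copy(), [sd_hat])
    if prior.n_components == 2:
        delta = math.log(prior.weights[0] / prior.weights[1]) + math.sqrt(2.0) * eta * z
        w1 = 1.0 / (1.0 + math.exp(-delta))
        return GaussianMixture1D([w1, 1.0 - w1], prior.means.copy(), prior.sds.copy())
    scale = math.exp(eta * z)
    return prior.scaled(scale)


def _latent_nodes(spec, params, trial: RelTrial, cfg: TaskConfig, gh_order: int):
    """Yield (weight, prior', cue') over the tensor grid of latent draws."""
    s_nodes = [(1.0, trial.cue)]
    if spec.cue_noise_S:
        sd = params.cue_est_sd(trial.session, trial.cue_level, cfg)
        if sd > 0:
            z, w = _gh(gh_order)
            s_nodes = [(wi, trial.cue + math.sqrt(2.0) * sd * zi) for zi, wi in zip(z, w)]
    p_nodes = [(1.0, trial.prior)]
    if spec.prior_noise_P:
        eta = params.weber_prior(trial.session)
        if eta > 0:
            z, w = _gh(gh_order)
            # GH abscissas enter the log-normal via exp(sqrt(2) sigma z)
            p_nodes = [
                (wi, _perturb_prior(trial.prior, math.sqrt(2.0) * zi, eta))
                for zi, wi in zip(z, w)
            ]
    for (ws, cue) in s_nodes:
        for (wp, prior) in p_nodes:
            yield ws * wp, prior, cue


# ---------------------------------------------------------------------------
# target-choice and response densities


@dataclass(frozen=True)
class TargetChoice:
    """Target-choice distribution in one of three representations."""

    kind: str  # delta | normal | grid
    point: float = 0.0
    sd: float = 0.0
    grid: GridDensity | None = None

    def response_prob(self, r: float, motor_sd: float) -> float:
        """Density of the motor-noise-convolved choice at response r."""
        if self.kind == "delta":
            return float(norm.pdf(r, loc=self.point, scale=motor_sd))
        if self.kind == "normal":
            return float(norm.pdf(r, loc=self.point, scale=math.hypot(self.sd, motor_sd)))
        g = self.grid
        kern = norm.pdf(r - g.x, scale=motor_sd)
        return float(np.trapezoid(g.pdf * kern, dx=g.dx))

    def to_grid(self, x0: float, dx: float, n: int) -> np.ndarray:
        x = x0 + dx * np.arange(n)
        if self.kind == "delta":
            pdf = np.zeros(n)
            i = int(round((self.point - x0) / dx))
            if 0 <= i < n:
                pdf[i] = 1.0 / dx
            return pdf
        if self.kind == "normal":
            return norm.pdf(x, loc=self.point, scale=self.sd)
        return self.grid.eval(x)

    def sample(self, rng: np.random.Generator) -> float:
        if self.kind == "delta":
            return self.point
        if self.kind == "normal":
            return float(rng.normal(self.point, self.sd))
        return float(self.grid.sample(rng, 1)[0])


def _approximate(post: PosteriorMixture, approx: str) -> PosteriorMixture:
    if approx == "none" or post.base.n_components == 1:
        return post
    if approx == "MV":
        mean, var, _, _ = post.base.moments()
        return PosteriorMixture(
            GaussianMixture1D([1.0], [mean], [math.sqrt(var)]), post.log_norm
        )
    if approx == "LA":
        return PosteriorMixture(laplace_approx(post), post.log_norm)
    raise ValueError(f"unknown approximation {approx!r}")


def _decision_choice(
    spec: ObserverSpec, params: ObserverParams, post: PosteriorMixture,
    session: str, cfg: TaskConfig,
) -> TargetChoice:
    """Target-choice distribution for the (possibly approximated) posterior."""
    post = _approximate(post, spec.gauss_approx)
    gm = post.base
    if spec.decision == "BDT":
        loss = cfg.loss
        if math.isfinite(params.loss_sd):  # extended variant: free loss width
            from .gmm import LossModel

            loss = LossModel(params.loss_sd, cfg.window)
        return TargetChoice("delta", point=optimal_target(post, loss))
    if spec.decision in ("SPK", "PPM"):
        kappa = params.kappa(spec, session)
        if gm.n_components == 1:
            return TargetChoice("normal", point=float(gm.means[0]),
                                sd=float(gm.sds[0]) / math.sqrt(kappa))
        if kappa == 1.0:
            x0, dx, n = default_grid(gm.means, gm.sds)
            return TargetChoice("grid", grid=GridDensity(x0, dx, gm.pdf(x0 + dx * np.arange(n))).normalize())
        return TargetChoice("grid", grid=power_density(post, kappa))
    # PSA
    k = params.psa_k(session)
    if gm.n_components == 1:
        m, sd = float(gm.means[0]), float(gm.sds[0])
        if k > PSA_EXACT_MAX or k == int(k):
            return TargetChoice("normal", point=m, sd=sd / math.sqrt(k))
        # interpolation between adjacent integer counts -> two-normal mixture
        lo, hi = int(math.floor(k)), int(math.ceil(k))
        frac = k - lo
        x0, dx, n = default_grid(gm.means, gm.sds)
        x = x0 + dx * np.arange(n)
        pdf = (1 - frac) * norm.pdf(x, m, sd / math.sqrt(lo)) + frac * norm.pdf(
            x, m, sd / math.sqrt(hi)
        )
        return TargetChoice("grid", grid=GridDensity(x0, dx, pdf).normalize())
    return TargetChoice("grid", grid=sample_average_density(post, k, exact_max=PSA_EXACT_MAX))


def _lapse_density(trial: RelTrial, r: float, motor_sd: float) -> float:
    """Lapse response density: the displayed prior convolved with motor noise."""
    p = trial.prior
    sd = np.sqrt(p.sds**2 + motor_sd**2)
    return float(p.weights @ norm.pdf(r, loc=p.means, scale=sd))


def target_choice_density(
    spec: ObserverSpec,
    params: ObserverParams,
    trial: RelTrial,
    cfg: TaskConfig = TaskConfig(),
    gh_order: int = 20,
) -> TargetChoice:
    """Marginal target-choice distribution for a trial (latents integrated out,
    lapse included).  Deterministic single-node cases keep their exact
    representation; anything marginalized is returned on a grid."""
    sigma = params.internal_lik_sd(trial.session, trial.cue_level)
    nodes = list(_latent_nodes(spec, params, trial, cfg, gh_order))
    lam = params.lapse(trial.session) if spec.lapse_L else 0.0
    if len(nodes) == 1 and lam == 0.0:
        post = posterior_update(trial.prior, nodes[0][2], sigma)
        return _decision_choice(spec, params, post, trial.session, cfg)
    # mixture over latent nodes on a common grid
    pad = float(np.max(trial.prior.sds)) + sigma
    x0, dx, n = default_grid(trial.prior.means, trial.prior.sds, pad=pad)
    acc = np.zeros(n)
    for w, prior, cue in nodes:
        post = posterior_update(prior, cue, sigma)
        choice = _decision_choice(spec, params, post, trial.session, cfg)
        acc += w * choice.to_grid(x0, dx, n)
    if lam > 0.0:
        x = x0 + dx * np.arange(n)
        acc = (1.0 - lam) * acc + lam * trial.prior.pdf(x)
    return TargetChoice("grid", grid=GridDensity(x0, dx, acc).normalize())


def response_probability(
    spec: ObserverSpec,
    params: ObserverParams,
    trial: RelTrial,
    r: float,
    cfg: TaskConfig = TaskConfig(),
    gh_order: int = 20,
) -> float:
    """Probability density of response ``r`` (relative frame), marginalized
    over latent measurements, lapse-mixed, motor-convolved.  Unregularized."""
    sigma = params.internal_lik_sd(trial.session, trial.cue_level)
    prior = trial.prior
    if spec.discrete_prior:
        prior = _discretize_for_observer(prior, cfg)
        trial = replace(trial, prior=prior)
    p_nolapse = 0.0
    for w, prior_l, cue in _latent_nodes(spec, params, trial, cfg, gh_order):
        post = posterior_update(prior_l, cue, sigma)
        choice = _decision_choice(spec, params, post, trial.session, cfg)
        p_nolapse += w * choice.response_prob(r, params.motor_sd)
    lam = params.lapse(trial.session) if spec.lapse_L else 0.0
    if lam == 0.0:
        return p_nolapse
    if spec.lapse_uniform:
        lo, hi = trial.prior.ppf(0.005), trial.prior.ppf(0.995)
        p_lapse = 1.0 / (hi - lo) if lo <= r <= hi else 0.0
    else:
        p_lapse = _lapse_density(trial, r, params.motor_sd)
    return (1.0 - lam) * p_nolapse + lam * p_lapse


def response_density(
    spec: ObserverSpec,
    params: ObserverParams,
    trial: RelTrial,
    cfg: TaskConfig = TaskConfig(),
    gh_order: int = 20,
) -> GridDensity:
    """Full response density on a grid (target choice ⊕ motor noise)."""
    choice = target_choice_density(spec, params, trial, cfg, gh_order)
    if choice.kind == "grid":
        return choice.grid.convolve_gaussian(params.motor_sd)
    pad = float(np.max(trial.prior.sds)) + params.motor_sd
    x0, dx, n = default_grid(trial.prior.means, trial.prior.sds, pad=pad)
    x = x0 + dx * np.arange(n)
    if choice.kind == "delta":
        pdf = norm.pdf(x, loc=choice.point, scale=params.motor_sd)
    else:
        pdf = norm.pdf(x, loc=choice.point, scale=math.hypot(choice.sd, params.motor_sd))
    return GridDensity(x0, dx, pdf).normalize()


def _discretize_for_observer(prior: GaussianMixture1D, cfg: TaskConfig) -> GaussianMixture1D:
    """Variant 'D': the prior as a hundred narrow Gaussians at the dot positions."""
    qs = [(i + 0.5) / cfg.n_targets for i in range(cfg.n_targets)]
    dots = np.asarray([prior.ppf(q) for q in qs])
    dot_sd = 0.1 / 30.0  # dot radius in screen units
    return GaussianMixture1D(
        np.full(cfg.n_targets, 1.0 / cfg.n_targets), dots, np.full(cfg.n_targets, dot_sd)
    )


def gaussian_closed_form_response(
    spec: ObserverSpec,
    params: ObserverParams,
    trial: RelTrial,
    cfg: TaskConfig = TaskConfig(),
):
    """Closed-form response distribution N(mean, sd) for a single-Gaussian
    prior and decision level in {BDT, SPK, PPM, PSA at integer/large K},
    optionally with factor S (no factor P, no lapse term).

    mean = w * cue with the shrinkage weight w = sd_p^2 / (sd_p^2 + sd~^2);
    var  = w^2 sd_s^2 + w sd~^2 / kappa + motor^2.
    """
    if spec.prior_noise_P:
        raise ValueError("no closed form with factor P; integrate numerically")
    if not trial.is_gaussian:
        raise ValueError("closed form requires a single-Gaussian prior")
    sigma = params.internal_lik_sd(trial.session, trial.cue_level)
    sp2 = float(trial.prior.sds[0]) ** 2
    w = sp2 / (sp2 + sigma**2)
    if spec.decision == "PSA":
        kappa = params.psa_k(trial.session)
        if kappa <= PSA_EXACT_MAX and kappa != int(kappa):
            raise ValueError("closed form requires integer or large K for PSA")
    else:
        kappa = params.kappa(spec, trial.session)
    var = w * sigma**2 / kappa if np.isfinite(kappa) else 0.0
    if spec.cue_noise_S:
        ssd = params.cue_est_sd(trial.session, trial.cue_level, cfg)
        var += w**2 * ssd**2
    var += params.motor_sd**2
    return w * trial.cue, math.sqrt(var)


# ---------------------------------------------------------------------------
# likelihood


def log_likelihood(
    spec: ObserverSpec,
    params: ObserverParams,
    trials: list[RelTrial] | list[TrialRecord],
    cfg: TaskConfig = TaskConfig(),
    gh_order: int = 20,
):
    """Regularized log likelihood of a dataset (sum and per-trial vector).

    Each trial's response density is floored by epsilon = phi(5), the
    standard-normal density five SDs out, bounding single-trial influence.
    """
    if trials and isinstance(trials[0], TrialRecord):
        trials = make_rel_trials(trials)
    engine = LikelihoodEngine(spec, trials, cfg, gh_order)
    return engine.loglik_params(params, per_trial=True)


class LikelihoodEngine:
    """Precompiled likelihood for one (model, dataset) pair.

    Single-Gaussian-prior trials are evaluated in a fully vectorized closed
    form (including factors S, P, L); mixture-prior trials go through the
    per-trial numerical path.  Used by the MCMC fitter, where the same
    dataset is evaluated tens of thousands of times.
    """

    def __init__(self, spec: ObserverSpec, trials: list[RelTrial],
                 cfg: TaskConfig = TaskConfig(), gh_order: int = 20,
                 param_names: list[str] | None = None):
        self.spec = spec
        self.cfg = cfg
        self.gh_order = gh_order
        self.param_names = param_names or free_param_names(
            spec, cfg.free_loss_width
        )
        gtr = [t for t in trials if t.is_gaussian and not spec.discrete_prior]
        self.mix_trials = [t for t in trials if not (t.is_gaussian and not spec.discrete_prior)]
        self.n_trials = len(gtr) + len(self.mix_trials)
        self.g = None
        if gtr:
            self.g = {
                "sigma_p": np.asarray([float(t.prior.sds[0]) for t in gtr]),
                "cue": np.asarray([t.cue for t in gtr]),
                "r": np.asarray([t.response for t in gtr]),
                "is_test": np.asarray([t.session != "training" for t in gtr]),
                "is_long": np.asarray([t.cue_level == "long" for t in gtr]),
            }

    def loglik_vector(self, vec: np.ndarray) -> float:
        return self.loglik_params(ObserverParams(**dict(zip(self.param_names, vec))))

    def loglik_params(self, params: ObserverParams, per_trial: bool = False):
        parts = []
        if self.g is not None:
            parts.append(self._gaussian_block(params))
        for t in self.mix_trials:
            p = response_probability(self.spec, params, t, t.response, self.cfg, self.gh_order)
            parts.append(np.asarray([p]))
        if parts:
            p_all = np.concatenate(parts)
        else:
            p_all = np.zeros(0)
        logp = np.log(p_all + REG_EPSILON)
        total = float(logp.sum())
        return (total, logp) if per_trial else total

    # vectorized closed-form block for single-Gaussian-prior trials
    def _gaussian_block(self, params: ObserverParams) -> np.ndarray:
        spec, cfg, g = self.spec, self.cfg, self.g
        sigma_p, cue, r = g["sigma_p"], g["cue"], g["r"]
        is_test, is_long = g["is_test"], g["is_long"]
        sig = np.where(
            is_test,
            np.where(is_long, params.lik_sd_short_test * params.lik_ratio,
                     params.lik_sd_short_test),
            np.where(is_long, params.lik_sd_long_train, params.lik_sd_short_train),
        )
        if spec.decision == "BDT":
            inv_kappa = 0.0
        elif spec.decision == "PPM":
            inv_kappa = 1.0
        elif spec.decision == "SPK":
            inv_kappa = np.where(is_test, 1.0 / params.kappa_test, 1.0 / params.kappa_train)
        else:  # PSA: interpolated between integer anchors below
            inv_kappa = None
        s2 = 0.0
        if spec.cue_noise_S:
            ssd = np.where(is_test, params.cue_est_sd_test, params.cue_est_sd_train)
            ssd = np.where(is_long, ssd * cfg.weber_distance_ratio, ssd)
            s2 = ssd**2
        motor2 = params.motor_sd**2
        inv_sqrt2pi = 1.0 / math.sqrt(2.0 * math.pi)

        def npdf(x, mean, var):
            return np.exp(-0.5 * (x - mean) ** 2 / var) * inv_sqrt2pi / np.sqrt(var)

        def nolapse_prob(sp, rr, cc, ss):
            """Response density given prior SD sp; sp may carry a trailing
            Gauss-Hermite node axis, in which case per-trial vectors gain a
            matching column axis."""
            two_d = np.ndim(sp) == 2

            def col(a):
                a = np.asarray(a)
                return a[:, None] if (two_d and a.ndim == 1) else a

            w = sp**2 / (sp**2 + ss**2)
            s2c = col(s2)
            if spec.decision == "PSA":
                k = col(np.where(is_test, params.psa_k_test, params.psa_k_train))
                klo = np.floor(k)
                frac = k - klo
                large = k > PSA_EXACT_MAX
                base = w**2 * s2c + motor2
                p_lo = npdf(rr, w * cc, w * ss**2 / np.where(large, k, klo) + base)
                p_hi = npdf(rr, w * cc, w * ss**2 / np.where(large, k, np.ceil(k)) + base)
                p = (1 - frac) * p_lo + frac * p_hi
                p_clt = npdf(rr, w * cc, w * ss**2 / k + base)
                return np.where(large, p_clt, p)
            var = w * ss**2 * col(inv_kappa) + w**2 * s2c + motor2
            return npdf(rr, w * cc, var)

        eta = None
        if spec.prior_noise_P:
            eta = np.where(is_test, params.weber_prior_test, params.weber_prior_train)
        if eta is not None and np.any(eta > 0):
            z, wgh = _gh(self.gh_order)
            sp = sigma_p[:, None] * np.exp(math.sqrt(2.0) * eta[:, None] * z[None, :])
            p = nolapse_prob(sp, r[:, None], cue[:, None], sig[:, None]) @ wgh
        else:
            p = nolapse_prob(sigma_p, r, cue, sig)
        if spec.lapse_L:
            lam = np.where(is_test, params.lapse_test, params.lapse_train)
            p_lapse = npdf(r, 0.0, sigma_p**2 + motor2)
            p = (1.0 - lam) * p + lam * p_lapse
        return p


# ---------------------------------------------------------------------------
# extended model set and its equivalences


def _extended_battery(cfg: TaskConfig):
    """Non-Gaussian posteriors probing the decision variants: bimodal-session
    priors (closed-form construction) at both noise levels and several cues."""
    from .task import prior_set

    battery = []
    for p in prior_set("bimodal", cfg)[:6]:
        for lik in (cfg.sigma_short, cfg.sigma_long):
            for cue in (-0.12, 0.0, 0.08, 0.18):
                post = posterior_update(p.mixture, cue, lik)
                battery.append(post)
    return battery


def derive_extended_equivalences(cfg: TaskConfig = TaskConfig(), tol_density: float = 1e-8,
                                 tol_behavior: float = 5e-3):
    """Find which (decision, approximation) pairs define the same model.

    Stochastic levels are compared by their target-choice densities at
    matched decision-noise anchors (kappa = K on integers): on Gaussian-
    approximated posteriors the power family and the sample-average family
    coincide exactly.  Deterministic (BDT-style) levels are compared by the
    objective success probability of their choices: rules whose choices are
    of equal objective value on the whole battery (mean gap below
    ``tol_behavior``) are behaviorally one decision rule — this identifies
    the narrow-loss minimizer with the Laplace-approximated MAP chooser,
    while the quadratic-loss (mean) chooser remains distinct.

    Returns a dict mapping each merged (decision, approx) pair to its
    canonical representative.
    """
    battery = _extended_battery(cfg)
    grids = [default_grid(p.base.means, p.base.sds, pad=0.05) for p in battery]
    anchors = (1.0, 2.0, 4.0, 8.0)
    params = ObserverParams()
    levels = [(d, a) for d in DECISIONS for a in APPROXIMATIONS]

    def stochastic_signature(dec, approx):
        sigs = []
        for post, (x0, dx, n) in zip(battery, grids):
            apost = _approximate(post, approx)
            for c in anchors:
                if dec == "PPM" and c != 1.0:
                    continue
                pp = params.replace(kappa_train=c, psa_k_train=c)
                ch = _decision_choice(
                    ObserverSpec(dec, gauss_approx="none"), pp, apost, "training", cfg
                )
                sigs.append(ch.to_grid(x0, dx, n))
        return sigs

    def det_choices(dec, approx):
        out = []
        for post in battery:
            apost = _approximate(post, approx)
            out.append(optimal_target(apost, cfg.loss))
        return np.asarray(out)

    merged = {}
    det = [lv for lv in levels if lv[0] == "BDT"]
    sto = [lv for lv in levels if lv[0] != "BDT"]
    # deterministic: compare objective value of choices
    det_sp = {}
    for lv in det:
        choices = det_choices(*lv)
        vals = []
        for post, c in zip(battery, choices):
            # objective success probability of the choice under the true posterior
            gm = post.base
            a = cfg.window / 2.0
            from scipy.special import ndtr
            vals.append(float(gm.weights @ (
                ndtr((c + a - gm.means) / gm.sds) - ndtr((c - a - gm.means) / gm.sds))))
        det_sp[lv] = np.asarray(vals)
    for i, lv1 in enumerate(det):
        for lv2 in det[i + 1:]:
            if lv2 in merged:
                continue
            if float(np.mean(np.abs(det_sp[lv1] - det_sp[lv2]))) < tol_behavior:
                merged[lv2] = merged.get(lv1, lv1)
    # stochastic: compare densities at matched anchors
    sto_sig = {lv: stochastic_signature(*lv) for lv in sto}
    for i, lv1 in enumerate(sto):
        for lv2 in sto[i + 1:]:
            if lv2 in merged:
                continue
            s1, s2 = sto_sig[lv1], sto_sig[lv2]
            if len(s1) != len(s2):
                continue
            gap = max(float(np.max(np.abs(a - b))) for a, b in zip(s1, s2))
            if gap < tol_density:
                merged[lv2] = merged.get(lv1, lv1)
    return merged


def extended_model_set(cfg: TaskConfig = TaskConfig()):
    """Distinct models of the decision-variant comparison:
    {BDT, SPK, PPM, PSA} x {none, MV, LA} x {no lapse, lapse}, with
    equivalent factor combinations collapsed (see
    :func:`derive_extended_equivalences`)."""
    merged = derive_extended_equivalences(cfg)
    out = []
    seen = set()
    for dec, app, lap in product(DECISIONS, APPROXIMATIONS, (False, True)):
        canon = merged.get((dec, app), (dec, app))
        key = (canon, lap)
        if key in seen:
            continue
        seen.add(key)
        out.append(ObserverSpec(canon[0], gauss_approx=canon[1], lapse_L=lap))
    return out
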