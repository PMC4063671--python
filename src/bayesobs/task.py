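"""Generative model of the target-estimation experiment.

A session shows, on each trial, a discretized 'prior' over target locations
(100 dots obtained by a regular sample of the inverse cdf), plus a noisy cue
whose vertical distance from the target line signals its noise level.  Three
session classes exist: Gaussian priors with SDs evenly spread on
[0.04, 0.18]; unimodal priors of fixed SD and varying skewness/kurtosis
(two-Gaussian entropy-maximizing mixtures, one 11-component platykurtic
member, one Gaussian member); and two-Gaussian bimodal priors of fixed SD
and varying separation/relative weight.  Trial-level randomness: the prior's
location is uniform (bounded so the dots stay on screen), asymmetric priors
are flipped left-right with probability 1/2, the true target is uniform over
the dots, and the cue is Gaussian around the true target.

All modelling happens in relative coordinates (location subtracted, flip
undone), which is exact under the task's translational invariance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize

from .config import TaskConfig
from .gmm import GaussianMixture1D, _gmm_modes, kl_nongaussianity, posterior_update

__all__ = [
    "PriorSpec",
    "TrialRecord",
    "SessionPlan",
    "make_gaussian_priors",
    "make_bimodal_prior",
    "make_unimodal_prior",
    "make_platykurtic_prior",
    "prior_set",
    "discretize_prior",
    "build_session_plan",
    "sample_trial",
    "edge_filter",
    "nongaussian_trial_filter",
    "to_relative",
    "from_relative",
    "PriorConstructionError",
]

PRIOR_CLASSES = ("gaussian", "unimodal", "bimodal")


class PriorConstructionError(ValueError):
    """A requested prior shape is infeasible under the configured constraints."""


@dataclass(frozen=True)
class PriorSpec:
    """A trial prior: canonical zero-mean mixture plus trial-level placement."""

    prior_class: str
    prior_id: int
    mixture: GaussianMixture1D  # canonical (zero-mean) form
    flipped: bool = False
    location: float = 0.0

    def __post_init__(self):
        if self.prior_class not in PRIOR_CLASSES:
            raise ValueError(f"unknown prior class {self.prior_class!r}")
        mean = float(self.mixture.weights @ self.mixture.means)
        if abs(mean) > 1e-9:
            raise ValueError("canonical prior mixture must have zero mean")

    def realized(self) -> GaussianMixture1D:
        gm = self.mixture.reflected() if self.flipped else self.mixture
        return gm.shifted(self.location)

    @property
    def is_asymmetric(self) -> bool:
        _, _, skew, _ = self.mixture.moments()
        return abs(skew) > 1e-9

    def placed(self, location: float, flipped: bool) -> "PriorSpec":
        return replace(self, location=location, flipped=flipped)


@dataclass
class TrialRecord:
    """One experimental trial."""

    session: str  # training | test
    prior_class: str
    prior_id: int
    cue_level: str  # short | long
    prior: PriorSpec
    targets: np.ndarray  # 100 dot positions, sorted
    target_x: float
    cue_x: float
    cue_distance: float  # cm
    response_x: float | None = None
    edge_excluded: bool = False

    @property
    def condition(self):
        return (self.session, self.prior_class, self.prior_id, self.cue_level)


@dataclass(frozen=True)
class SessionPlan:
    session: str
    prior_class: str
    repetitions: int
    conditions: tuple  # ordered (prior_id, cue_level) pairs, randomized

    def __post_init__(self):
        if not 36 <= self.repetitions <= 40:
            raise ValueError("repetitions must lie in [36, 40]")

    @property
    def n_trials(self) -> int:
        return len(self.conditions)


# ---------------------------------------------------------------------------
# prior construction


def make_gaussian_priors(cfg: TaskConfig = TaskConfig()) -> list[PriorSpec]:
    """Eight zero-mean Gaussians with SDs evenly spread on [0.04, 0.18]."""
    return [
        PriorSpec("gaussian", i + 1, GaussianMixture1D([1.0], [0.0], [sd]))
        for i, sd in enumerate(cfg.gaussian_sds())
    ]


def make_bimodal_prior(
    separation: float, relative_weight: float, total_sd: float, prior_id: int = 0
) -> PriorSpec:
    """Two equal-variance Gaussians with given total SD, separation (distance
    between component means in total-SD units) and left-component weight.

    The zero-mean equal-variance parameterization has the closed-form
    solution mu1 = -(1-p) D, mu2 = p D with D = separation * total_sd and
    component variance total_sd^2 - p (1-p) D^2.
    """
    if separation < 0:
        raise PriorConstructionError("separation must be nonnegative")
    if not 0.0 < relative_weight < 1.0:
        raise PriorConstructionError("relative_weight must lie in (0, 1)")
    p = relative_weight
    d = separation * total_sd
    comp_var = total_sd**2 - p * (1.0 - p) * d**2
    if comp_var <= 0:
        raise PriorConstructionError(
            f"separation {separation} infeasible for total SD {total_sd}"
        )
    if separation == 0:
        gm = GaussianMixture1D([1.0], [0.0], [total_sd])
    else:
        gm = GaussianMixture1D(
            [p, 1.0 - p],
            [-(1.0 - p) * d, p * d],
            [np.sqrt(comp_var)] * 2,
        )
    return PriorSpec("bimodal", prior_id, gm)


def make_platykurtic_prior(
    excess_kurtosis: float, total_sd: float, prior_id: int = 0, n_components: int = 11
) -> PriorSpec:
    """Symmetric platykurtic prior: equal-weight Gaussians on a regular grid.

    For 11 equally spaced equal-SD components the variance and fourth moment
    give two equations in (grid spacing, component SD) with a closed-form
    solution; feasible for excess kurtosis in (-1.22, 0).
    """
    if n_components != 11:
        raise PriorConstructionError("the platykurtic construction uses 11 components")
    if not -1.22 < excess_kurtosis < 0:
        raise PriorConstructionError("platykurtic prior needs excess kurtosis in (-1.22, 0)")
    v = total_sd**2
    # grid indices -5..5: sum j^2 = 110, sum j^4 = 1958
    # m4 = 3 v^2 - 122 c^4  =>  c^4 = -excess_kurtosis v^2 / 122
    c = np.sqrt(v) * (-excess_kurtosis / 122.0) ** 0.25
    s2 = v - 10.0 * c**2
    if s2 <= 0:
        raise PriorConstructionError("platykurtic spacing leaves no component variance")
    j = np.arange(-5, 6, dtype=float)
    gm = GaussianMixture1D(np.full(11, 1.0 / 11.0), j * c, np.full(11, np.sqrt(s2)))
    return PriorSpec("unimodal", prior_id, gm)


def _mixture_entropy_grid(gm: GaussianMixture1D) -> float:
    lo = float(np.min(gm.means) - 8.0 * np.max(gm.sds))
    hi = float(np.max(gm.means) + 8.0 * np.max(gm.sds))
    x = np.linspace(lo, hi, 2001)
    p = gm.pdf(x)
    mask = p > 0
    return float(-np.trapezoid(np.where(mask, p * np.log(np.where(mask, p, 1.0)), 0.0), x))


def _is_unimodal(gm: GaussianMixture1D) -> bool:
    pts, ok = _gmm_modes(gm.weights, gm.means, gm.sds**2)
    modes = np.unique(np.round(pts[ok], 7))
    return modes.size <= 1


def _solve_two_gaussian_moments(p: float, skew: float, exkurt: float, floor: float):
    """Solve the standardized (var=1) moment equations for (mu1, s1, s2) at
    fixed weight p; mu2 follows from the zero-mean constraint."""

    def resid(u):
        mu1, ls1, ls2 = u
        s1, s2 = np.exp(ls1), np.exp(ls2)
        mu2 = -p * mu1 / (1.0 - p)
        m2 = p * (mu1**2 + s1**2) + (1 - p) * (mu2**2 + s2**2)
        m3 = p * (mu1**3 + 3 * mu1 * s1**2) + (1 - p) * (mu2**3 + 3 * mu2 * s2**2)
        m4 = p * (mu1**4 + 6 * mu1**2 * s1**2 + 3 * s1**4) + (1 - p) * (
            mu2**4 + 6 * mu2**2 * s2**2 + 3 * s2**4
        )
        return [m2 - 1.0, m3 - skew, m4 - (exkurt + 3.0)]

    sols = []
    for mu1_0 in (-0.5, 0.3):
        for s0 in (0.5, 1.0):
            res = optimize.least_squares(
                resid, [mu1_0, np.log(s0), np.log(s0 * 0.7)], xtol=1e-14, ftol=1e-14
            )
            if res.cost < 1e-18:
                mu1, ls1, ls2 = res.x
                s1, s2 = np.exp(ls1), np.exp(ls2)
                if s1 >= floor and s2 >= floor:
                    sols.append((mu1, s1, s2))
    return sols


def make_unimodal_prior(
    target_skewness: float,
    target_kurtosis: float,
    total_sd: float,
    component_sd_floor: float = 0.02,
    prior_id: int = 0,
) -> PriorSpec:
    """Two-Gaussian mixture matching (0, total_sd^2, skewness, kurtosis) that
    locally maximizes differential entropy, subject to a floor on the
    component SDs and a unimodality check.

    The four moment constraints leave a one-parameter family (indexed by the
    mixture weight); the weight is scanned and the entropy-maximal feasible
    solution returned.
    """
    if target_skewness == 0.0 and target_kurtosis == 0.0:
        return PriorSpec("unimodal", prior_id, GaussianMixture1D([1.0], [0.0], [total_sd]))
    floor_std = component_sd_floor / total_sd

    def candidates(p):
        out = []
        for mu1, s1, s2 in _solve_two_gaussian_moments(
            p, target_skewness, target_kurtosis, floor_std
        ):
            mu2 = -p * mu1 / (1.0 - p)
            gm = GaussianMixture1D([p, 1.0 - p], [mu1, mu2], [s1, s2])
            if _is_unimodal(gm):
                out.append((_mixture_entropy_grid(gm), gm))
        return out

    best = None
    best_p = None
    for p in np.linspace(0.05, 0.95, 19):
        for ent, gm in candidates(p):
            if best is None or ent > best[0]:
                best, best_p = (ent, gm), p
    if best is not None:  # refine the weight around the best grid point
        for dp in (-0.033, -0.017, 0.017, 0.033):
            p = float(np.clip(best_p + dp, 0.02, 0.98))
            for ent, gm in candidates(p):
                if ent > best[0]:
                    best = (ent, gm)
    if best is None:
        raise PriorConstructionError(
            f"no feasible unimodal two-Gaussian mixture for skewness "
            f"{target_skewness}, excess kurtosis {target_kurtosis} "
            f"(component-SD floor {component_sd_floor})"
        )
    gm = best[1].scaled(total_sd)
    return PriorSpec("unimodal", prior_id, gm)


_prior_cache: dict = {}


def prior_set(prior_class: str, cfg: TaskConfig = TaskConfig()) -> list[PriorSpec]:
    """The eight canonical priors of a session class (cached per config)."""
    key = (prior_class, cfg)
    if key in _prior_cache:
        return _prior_cache[key]
    if prior_class == "gaussian":
        out = make_gaussian_priors(cfg)
    elif prior_class == "unimodal":
        out = []
        for i, (skew, kurt) in enumerate(cfg.unimodal_table):
            if skew == 0.0 and kurt < 0.0:
                out.append(make_platykurtic_prior(kurt, cfg.test_total_sd, prior_id=i + 1))
            else:
                out.append(
                    make_unimodal_prior(
                        skew, kurt, cfg.test_total_sd, cfg.component_sd_floor, prior_id=i + 1
                    )
                )
    elif prior_class == "bimodal":
        out = [
            make_bimodal_prior(sep, wt, cfg.test_total_sd, prior_id=i + 1)
            for i, (sep, wt) in enumerate(cfg.bimodal_table)
        ]
    else:
        raise ValueError(f"unknown prior class {prior_class!r}")
    _prior_cache[key] = out
    return out


# ---------------------------------------------------------------------------
# discretization and trials


_dots_cache: dict = {}


def _canonical_dots(gm: GaussianMixture1D, n: int) -> np.ndarray:
    """Quantiles at (i - 1/2)/n of a zero-mean mixture, cached."""
    key = (gm.weights.tobytes(), gm.means.tobytes(), gm.sds.tobytes(), n)
    if key not in _dots_cache:
        _dots_cache[key] = np.asarray([gm.ppf((i + 0.5) / n) for i in range(n)])
    return _dots_cache[key]


def discretize_prior(prior: PriorSpec, n: int = 100) -> np.ndarray:
    """Dot positions: quantiles of the realized prior at (i - 1/2)/n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    canon = prior.mixture.reflected() if prior.flipped else prior.mixture
    return _canonical_dots(canon, n) + prior.location


def build_session_plan(
    session: str, prior_class: str, repetitions: int, rng: np.random.Generator
) -> SessionPlan:
    """16 conditions (8 priors x 2 cue levels) x repetitions, shuffled."""
    conds = [
        (pid, lvl) for pid in range(1, 9) for lvl in ("short", "long")
    ] * repetitions
    order = rng.permutation(len(conds))
    return SessionPlan(session, prior_class, repetitions, tuple(conds[i] for i in order))


def _location_bounds(canonical_dots: np.ndarray):
    lo = -float(canonical_dots.min())
    hi = 1.0 - float(canonical_dots.max())
    if lo > hi:  # prior wider than the free span: center it
        lo = hi = 0.5
    return lo, hi


def sample_trial(
    session: str,
    prior_spec: PriorSpec,
    cue_level: str,
    rng: np.random.Generator,
    cfg: TaskConfig = TaskConfig(),
) -> TrialRecord:
    """Draw one trial: place and possibly flip the prior, discretize it,
    pick the true target uniformly among the dots, draw the noisy cue."""
    flipped = bool(prior_spec.is_asymmetric and rng.uniform() < 0.5)
    canon = prior_spec.mixture.reflected() if flipped else prior_spec.mixture
    canon_dots = _canonical_dots(canon, cfg.n_targets)
    lo, hi = _location_bounds(canon_dots)
    location = float(rng.uniform(lo, hi)) if hi > lo else lo
    placed = prior_spec.placed(location, flipped)
    targets = canon_dots + location
    target_x = float(rng.choice(targets))
    sigma = cfg.true_sigma(cue_level)
    cue_x = float(rng.normal(target_x, sigma))
    distance = cfg.d_short_cm if cue_level == "short" else cfg.d_long_cm
    trial = TrialRecord(
        session=session,
        prior_class=prior_spec.prior_class,
        prior_id=prior_spec.prior_id,
        cue_level=cue_level,
        prior=placed,
        targets=targets,
        target_x=target_x,
        cue_x=cue_x,
        cue_distance=distance,
    )
    trial.edge_excluded = edge_filter(trial)
    return trial


def edge_filter(trial: TrialRecord) -> bool:
    """True (exclude) iff the cue fell outside the closed dot range."""
    return bool(trial.cue_x < trial.targets[0] or trial.cue_x > trial.targets[-1])


def nongaussian_trial_filter(
    trial: TrialRecord, cfg: TaskConfig = TaskConfig(), threshold: float | None = None
) -> bool:
    """True (keep for the decision-variant comparison) iff the true-parameter
    posterior is sufficiently non-Gaussian (KL >= threshold, default 0.02 nats)."""
    thr = cfg.kl_threshold if threshold is None else threshold
    post = posterior_update(
        trial.prior.realized(), trial.cue_x, cfg.true_sigma(trial.cue_level)
    )
    if post.base.n_components == 1:
        return False
    kl, _ = kl_nongaussianity(post)
    return bool(kl >= thr)


# ---------------------------------------------------------------------------
# coordinates


def to_relative(x, prior: PriorSpec):
    """Map screen coordinates into the prior's canonical frame."""
    rel = np.asarray(x, dtype=float) - prior.location
    return -rel if prior.flipped else rel


def from_relative(x_rel, prior: PriorSpec):
    rel = np.asarray(x_rel, dtype=float)
    rel = -rel if prior.flipped else rel
    return rel + prior.location
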