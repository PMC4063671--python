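"""One-dimensional Gaussian-mixture machinery.

Everything downstream — task priors, observer posteriors, target-choice
distributions, the loss model — is built on mixtures of 1-D Gaussians, for
which Bayesian updating, expected loss under an inverted-Gaussian loss, and
success probabilities all have closed forms.  The only genuinely numerical
primitives are mixture mode-finding (a fixed-point iteration), quantiles
(root finding on the cdf), and a handful of quadratures used as checks.

Positions are measured in standardized screen units (window width 1.0;
0.01 screen units = 3 mm in the workspace).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize
from scipy.special import logsumexp, ndtr
from scipy.stats import norm

__all__ = [
    "GaussianMixture1D",
    "PosteriorMixture",
    "LossModel",
    "GridDensity",
    "ModeFindingError",
    "DegeneratePosteriorError",
    "gm_eval",
    "gm_moments",
    "posterior_update",
    "expected_loss",
    "optimal_target",
    "mixture_mode",
    "power_density",
    "laplace_approx",
    "sample_average_density",
    "success_probability",
    "max_success_probability",
    "optimality_index",
    "kl_nongaussianity",
    "fit_loss_sd",
]

_WEIGHT_TOL = 1e-12
GRID_STEP = 5e-4  # default grid step, screen units
GRID_HALFWIDTH_SDS = 6.0


class ModeFindingError(RuntimeError):
    """Fixed-point mode search failed to converge; carries the best iterate."""

    def __init__(self, message: str, best_iterate: float):
        super().__init__(message)
        self.best_iterate = best_iterate


class DegeneratePosteriorError(RuntimeError):
    """Raised when a Laplace approximation is requested at a flat/convex mode."""


@dataclass(frozen=True)
class GaussianMixture1D:
    """Finite mixture of 1-D Gaussians: sum_i w_i N(x; mu_i, sd_i^2).

    Parameters
    ----------
    weights : array_like
        Nonnegative mixture weights summing to one (within 1e-12).
    means : array_like
        Component means, screen units.
    sds : array_like
        Component standard deviations, strictly positive, screen units.
    """

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray

    def __init__(self, weights, means, sds):
        w = np.atleast_1d(np.asarray(weights, dtype=float))
        m = np.atleast_1d(np.asarray(means, dtype=float))
        s = np.atleast_1d(np.asarray(sds, dtype=float))
        if not (w.shape == m.shape == s.shape) or w.ndim != 1 or w.size < 1:
            raise ValueError("weights, means, sds must be equal-length 1-D vectors")
        if np.any(w < 0):
            raise ValueError("mixture weights must be nonnegative")
        if abs(w.sum() - 1.0) > _WEIGHT_TOL:
            raise ValueError(f"mixture weights must sum to 1 (got {w.sum()!r})")
        if np.any(s <= 0):
            raise ValueError("component SDs must be strictly positive")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "means", m)
        object.__setattr__(self, "sds", s)

    @property
    def n_components(self) -> int:
        return self.weights.size

    # -- densities ---------------------------------------------------------
    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        z = (x[..., None] - self.means) / self.sds
        comp = np.exp(-0.5 * z * z) / (np.sqrt(2.0 * np.pi) * self.sds)
        return comp @ self.weights

    def logpdf(self, x):
        x = np.asarray(x, dtype=float)
        z = (x[..., None] - self.means) / self.sds
        logcomp = (
            -0.5 * z * z
            - np.log(self.sds)
            - 0.5 * np.log(2.0 * np.pi)
            + np.log(np.maximum(self.weights, 1e-300))
        )
        return logsumexp(logcomp, axis=-1)

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        z = (x[..., None] - self.means) / self.sds
        return ndtr(z) @ self.weights

    def ppf(self, q: float) -> float:
        """Exact quantile by root finding on the cdf (|cdf(x) - q| <= 1e-12)."""
        if not 0.0 < q < 1.0:
            raise ValueError(f"quantile level must lie in (0, 1), got {q}")
        lo = float(np.min(self.means - 12.0 * self.sds))
        hi = float(np.max(self.means + 12.0 * self.sds))
        # widen until bracketed (cheap; cdf tails decay like a Gaussian)
        while self.cdf(lo) > q:
            lo -= 10.0 * float(np.max(self.sds))
        while self.cdf(hi) < q:
            hi += 10.0 * float(np.max(self.sds))
        return float(optimize.brentq(lambda x: self.cdf(x) - q, lo, hi, xtol=1e-14, rtol=8.9e-16))

    def rvs(self, rng: np.random.Generator, size: int) -> np.ndarray:
        idx = rng.choice(self.n_components, size=size, p=self.weights / self.weights.sum())
        return rng.normal(self.means[idx], self.sds[idx])

    # -- moments and transforms -------------------------------------------
    def moments(self):
        """Exact (mean, variance, skewness, excess kurtosis)."""
        w, mu, sd = self.weights, self.means, self.sds
        mean = float(w @ mu)
        d = mu - mean
        var = float(w @ (sd**2 + d**2))
        m3 = float(w @ (d**3 + 3.0 * d * sd**2))
        m4 = float(w @ (d**4 + 6.0 * d**2 * sd**2 + 3.0 * sd**4))
        skew = m3 / var**1.5
        exkurt = m4 / var**2 - 3.0
        return mean, var, skew, exkurt

    def entropy(self) -> float:
        """Differential entropy in nats, by quadrature (no closed form for mixtures)."""
        lo = float(np.min(self.means - 10.0 * self.sds))
        hi = float(np.max(self.means + 10.0 * self.sds))

        def integrand(x):
            p = self.pdf(np.asarray([x]))[0]
            return -p * np.log(p) if p > 0 else 0.0

        val, _ = integrate.quad(integrand, lo, hi, limit=200)
        return float(val)

    def shifted(self, c: float) -> "GaussianMixture1D":
        return GaussianMixture1D(self.weights, self.means + c, self.sds)

    def reflected(self, about: float = 0.0) -> "GaussianMixture1D":
        return GaussianMixture1D(self.weights, 2.0 * about - self.means, self.sds)

    def scaled(self, factor: float) -> "GaussianMixture1D":
        """Scale the distribution about zero by ``factor`` (> 0)."""
        return GaussianMixture1D(self.weights, self.means * factor, self.sds * factor)


@dataclass(frozen=True)
class PosteriorMixture:
    """Product of a mixture prior with a Gaussian likelihood, renormalized.

    ``base`` holds the posterior mixture (weights Z_i-normalized); ``log_norm``
    is the log of the normalization constant of prior x likelihood, i.e. the
    log marginal probability of the cue position.
    """

    base: GaussianMixture1D
    log_norm: float

    def __post_init__(self):
        if not np.isfinite(self.log_norm):
            raise ValueError("log_norm must be finite")


@dataclass(frozen=True)
class LossModel:
    """Inverted-Gaussian loss of width ``loss_sd`` approximating the task's
    square-well (hit-or-miss) loss with success window ``window`` (the cursor
    diameter), both in screen units."""

    loss_sd: float
    window: float

    def __post_init__(self):
        if self.loss_sd <= 0 or self.window <= 0:
            raise ValueError("loss_sd and window must be positive")


@dataclass
class GridDensity:
    """Probability density tabulated on a uniform grid."""

    x0: float
    dx: float
    pdf: np.ndarray
    _cdf: np.ndarray | None = field(default=None, repr=False)

    @property
    def x(self) -> np.ndarray:
        return self.x0 + self.dx * np.arange(self.pdf.size)

    def normalize(self) -> "GridDensity":
        z = np.trapezoid(self.pdf, dx=self.dx)
        if not np.isfinite(z) or z <= 0:
            raise ValueError("cannot normalize grid density: nonpositive mass")
        self.pdf = self.pdf / z
        self._cdf = None
        return self

    def integral(self) -> float:
        return float(np.trapezoid(self.pdf, dx=self.dx))

    def mean(self) -> float:
        return float(np.trapezoid(self.x * self.pdf, dx=self.dx))

    def var(self) -> float:
        m = self.mean()
        return float(np.trapezoid((self.x - m) ** 2 * self.pdf, dx=self.dx))

    def eval(self, xq) -> np.ndarray:
        return np.interp(np.asarray(xq, dtype=float), self.x, self.pdf, left=0.0, right=0.0)

    def cdf_grid(self) -> np.ndarray:
        if self._cdf is None:
            c = integrate.cumulative_trapezoid(self.pdf, dx=self.dx, initial=0.0)
            self._cdf = c / c[-1]
        return self._cdf

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        u = rng.uniform(size=size)
        return np.interp(u, self.cdf_grid(), self.x)

    def convolve_gaussian(self, sd: float) -> "GridDensity":
        """Convolve with N(0, sd^2); the grid is extended so no mass is lost."""
        if sd <= 0:
            return GridDensity(self.x0, self.dx, self.pdf.copy())
        half = int(np.ceil(6.0 * sd / self.dx))
        k = norm.pdf(np.arange(-half, half + 1) * self.dx, scale=sd) * self.dx
        out = np.convolve(self.pdf, k, mode="full")
        return GridDensity(self.x0 - half * self.dx, self.dx, out).normalize()


def default_grid(means, sds, step: float = GRID_STEP, pad: float = 0.0):
    """Uniform grid covering [min mu - 6 max sd, max mu + 6 max sd] (+pad)."""
    lo = float(np.min(means) - GRID_HALFWIDTH_SDS * (np.max(sds) + pad))
    hi = float(np.max(means) + GRID_HALFWIDTH_SDS * (np.max(sds) + pad))
    n = int(np.ceil((hi - lo) / step)) + 1
    return lo, step, n


# ---------------------------------------------------------------------------
# operations


def gm_eval(gm: GaussianMixture1D, value: float, mode: str = "pdf") -> float:
    """Evaluate pdf/cdf at ``value`` or the quantile at level ``value``."""
    if mode == "pdf":
        return float(gm.pdf(np.asarray([value]))[0])
    if mode == "cdf":
        return float(gm.cdf(np.asarray([value]))[0])
    if mode == "quantile":
        return gm.ppf(value)
    raise ValueError(f"unknown mode {mode!r}")


def gm_moments(gm: GaussianMixture1D):
    return gm.moments()


def posterior_update(prior: GaussianMixture1D, cue_x: float, lik_sd: float) -> PosteriorMixture:
    """Multiply a mixture prior with a Gaussian likelihood N(cue_x; x, lik_sd^2).

    Each prior component N(mu_i, s_i^2) times the likelihood is
    Z_i * N(theta_i, tau_i^2) with

        Z_i     = N(cue_x; mu_i, s_i^2 + lik_sd^2)
        tau_i^2 = s_i^2 lik_sd^2 / (s_i^2 + lik_sd^2)
        theta_i = (mu_i lik_sd^2 + cue_x s_i^2) / (s_i^2 + lik_sd^2)

    For a single-Gaussian prior this reduces to the familiar linear-weight
    rule: posterior mean = w * cue_x (relative to the prior mean) with
    w = s_p^2 / (s_p^2 + lik_sd^2).
    """
    if lik_sd <= 0:
        raise ValueError("lik_sd must be positive")
    mu, s2 = prior.means, prior.sds**2
    v = s2 + lik_sd**2
    log_z = norm.logpdf(cue_x, loc=mu, scale=np.sqrt(v))
    tau = np.sqrt(s2 * lik_sd**2 / v)
    theta = (mu * lik_sd**2 + cue_x * s2) / v
    logw = np.log(np.maximum(prior.weights, 1e-300)) + log_z
    log_norm = float(logsumexp(logw))
    w = np.exp(logw - log_norm)
    w = w / w.sum()
    return PosteriorMixture(GaussianMixture1D(w, theta, tau), log_norm)


def expected_loss(post: PosteriorMixture, action, loss: LossModel):
    """Closed-form expected inverted-Gaussian loss of ``action``.

    integral p(x|...) * (-exp(-(x - a)^2 / (2 sigma_l^2))) dx is itself a
    (negated, scaled) Gaussian mixture in the action, with component
    variances inflated by sigma_l^2.
    """
    gm = post.base
    sd = np.sqrt(gm.sds**2 + loss.loss_sd**2)
    a = np.asarray(action, dtype=float)
    z = (a[..., None] - gm.means) / sd
    val = -(np.exp(-0.5 * z * z) * (loss.loss_sd / sd)) @ gm.weights
    return val if val.ndim else float(val)


def _gmm_modes(weights, means, variances, tol: float = 1e-10, max_iter: int = 1000):
    """All fixed points of the GMM mean-shift iteration, started from every
    component mean.  Returns (converged points, converged mask, last iterates)."""
    pts = []
    ok = []
    for x0 in means:
        x = float(x0)
        converged = False
        for _ in range(max_iter):
            z2 = (x - means) ** 2 / variances
            r = weights * np.exp(-0.5 * z2) / np.sqrt(variances) / variances
            denom = r.sum()
            if denom <= 0 or not np.isfinite(denom):
                break
            x_new = float((r @ means) / denom)
            if abs(x_new - x) <= tol:
                x = x_new
                converged = True
                break
            x = x_new
        pts.append(x)
        ok.append(converged)
    return np.asarray(pts), np.asarray(ok)


def mixture_mode(gm: GaussianMixture1D, tol: float = 1e-10, max_iter: int = 1000) -> float:
    """Global mode of a Gaussian mixture by fixed-point (mean-shift) iteration
    from every component mean; exact ties break to the smaller coordinate."""
    w, mu, v = gm.weights, gm.means, gm.sds**2
    pts, ok = _gmm_modes(w, mu, v, tol=tol, max_iter=max_iter)
    if not ok.any():
        best = pts[np.argmax(gm.pdf(pts))]
        raise ModeFindingError("mode search did not converge from any start", float(best))
    pts = pts[ok]
    vals = gm.pdf(pts)
    best = np.max(vals)
    # ties within relative 1e-12 -> smallest coordinate
    cand = pts[vals >= best * (1.0 - 1e-12)]
    return float(np.min(cand))


def optimal_target(post: PosteriorMixture, loss: LossModel) -> float:
    """Action minimizing the expected inverted-Gaussian loss.

    Equivalent to the global mode of the posterior mixture smoothed by the
    loss kernel (component variances inflated by loss_sd^2); for a
    single-Gaussian posterior this is its mean.
    """
    gm = post.base
    if gm.n_components == 1:
        return float(gm.means[0])
    smoothed = GaussianMixture1D(gm.weights, gm.means, np.sqrt(gm.sds**2 + loss.loss_sd**2))
    return mixture_mode(smoothed)


def power_density(post: PosteriorMixture, kappa: float, step: float = GRID_STEP) -> GridDensity:
    """Normalized density proportional to posterior(x)^kappa on a grid.

    kappa = 1 reproduces the posterior (posterior matching); for a
    single-Gaussian posterior the result is N(mean, var / kappa).
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    gm = post.base
    x0, dx, n = default_grid(gm.means, gm.sds, step=step)
    x = x0 + dx * np.arange(n)
    if kappa == 1.0:  # posterior matching: already normalized analytically
        return GridDensity(x0, dx, gm.pdf(x))
    logp = gm.logpdf(x)
    logp = kappa * (logp - logp.max())
    return GridDensity(x0, dx, np.exp(logp)).normalize()


def laplace_approx(post: PosteriorMixture) -> GaussianMixture1D:
    """Gaussian at the global posterior mode with variance set by the local
    curvature of the log posterior, -1 / (d^2 log p / dx^2)."""
    gm = post.base
    if gm.n_components == 1:
        return GaussianMixture1D([1.0], [gm.means[0]], [gm.sds[0]])
    m = mixture_mode(gm)
    w, mu, v = gm.weights, gm.means, gm.sds**2
    phi = w * np.exp(-0.5 * (m - mu) ** 2 / v) / np.sqrt(2.0 * np.pi * v)
    p = phi.sum()
    dp = float((phi * (mu - m) / v).sum())
    d2p = float((phi * (((mu - m) / v) ** 2 - 1.0 / v)).sum())
    curv = d2p / p - (dp / p) ** 2
    if curv >= 0:
        raise DegeneratePosteriorError("non-negative log-posterior curvature at the mode")
    return GaussianMixture1D([1.0], [m], [np.sqrt(-1.0 / curv)])


def sample_average_density(
    post: PosteriorMixture, k: float, step: float = GRID_STEP, exact_max: int = 8
) -> GridDensity:
    """Density of the mean of k i.i.d. posterior draws.

    Integer k <= ``exact_max``: exact multinomial expansion over component
    assignments (the mean conditioned on counts is Gaussian).  Non-integer k:
    linear interpolation of the densities at floor(k) and ceil(k).  Larger k:
    CLT Gaussian N(posterior mean, posterior var / k).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    gm = post.base
    mean, var, _, _ = gm.moments()
    x0, dx, n = default_grid(gm.means, gm.sds, step=step)
    x = x0 + dx * np.arange(n)

    def exact(ki: int) -> np.ndarray:
        if ki == 1:
            return gm.pdf(x)
        from itertools import combinations_with_replacement
        from math import factorial

        logw = np.log(np.maximum(gm.weights, 1e-300))
        out = np.zeros_like(x)
        for combo in combinations_with_replacement(range(gm.n_components), ki):
            counts = np.bincount(np.asarray(combo), minlength=gm.n_components)
            logcoef = np.log(float(factorial(ki)))
            for c in counts:
                logcoef -= np.log(float(factorial(int(c))))
            logcoef += float(counts @ logw)
            m = float(counts @ gm.means) / ki
            sd = np.sqrt(float(counts @ gm.sds**2)) / ki
            out += np.exp(logcoef) * norm.pdf(x, loc=m, scale=sd)
        return out

    if k > exact_max:
        pdf = norm.pdf(x, loc=mean, scale=np.sqrt(var / k))
    else:
        lo_k, hi_k = int(np.floor(k)), int(np.ceil(k))
        if lo_k == hi_k:
            pdf = exact(lo_k)
        else:
            frac = k - lo_k
            pdf = (1.0 - frac) * exact(lo_k) + frac * exact(hi_k)
    # the expansion is analytically normalized; avoid re-normalization error
    return GridDensity(x0, dx, pdf)


def success_probability(
    prior: GaussianMixture1D,
    cue_x: float,
    cue_sd: float,
    response: float,
    loss: LossModel,
) -> float:
    """Probability that the true target lies within ``window``/2 of the
    response, under the generative posterior, via Gaussian cdf differences."""
    post = posterior_update(prior, cue_x, cue_sd).base
    a = loss.window / 2.0
    hi = (response + a - post.means) / post.sds
    lo = (response - a - post.means) / post.sds
    return float(post.weights @ (ndtr(hi) - ndtr(lo)))


def max_success_probability(
    prior: GaussianMixture1D, cue_x: float, cue_sd: float, loss: LossModel
) -> float:
    """Maximum of the success probability over responses.

    The objective is the posterior convolved with a box of width ``window``;
    candidates are the modes of the loss-smoothed posterior plus the
    component means, each polished by a local 1-D optimization.
    """
    post = posterior_update(prior, cue_x, cue_sd).base
    a = loss.window / 2.0

    def h(r: float) -> float:
        hi = (r + a - post.means) / post.sds
        lo = (r - a - post.means) / post.sds
        return float(post.weights @ (ndtr(hi) - ndtr(lo)))

    smoothed = GaussianMixture1D(
        post.weights, post.means, np.sqrt(post.sds**2 + loss.loss_sd**2)
    )
    pts, ok = _gmm_modes(smoothed.weights, smoothed.means, smoothed.sds**2)
    cands = set(np.round(np.concatenate([pts[ok], post.means]), 12))
    best = -np.inf
    for c in cands:
        res = optimize.minimize_scalar(
            lambda r: -h(r), bounds=(c - loss.window, c + loss.window), method="bounded",
            options={"xatol": 1e-10},
        )
        best = max(best, -res.fun, h(float(c)))
    return best


def optimality_index(
    prior: GaussianMixture1D,
    cue_x: float,
    cue_sd: float,
    response: float,
    loss: LossModel,
) -> float:
    """Success probability of the response divided by the maximal success
    probability; 1 iff the response is optimal."""
    pmax = max_success_probability(prior, cue_x, cue_sd, loss)
    if pmax <= 0:
        raise ValueError("degenerate trial: maximal success probability is zero")
    return success_probability(prior, cue_x, cue_sd, response, loss) / pmax


def kl_nongaussianity(post: PosteriorMixture, threshold: float = 0.02):
    """KL(moment-matched Gaussian || posterior) in nats, with the
    'non-Gaussian trial' flag at the given threshold (default 0.02 nats)."""
    gm = post.base
    mean, var, _, _ = gm.moments()
    sd = np.sqrt(var)

    def integrand(x):
        xq = np.asarray([x])
        q = norm.pdf(x, loc=mean, scale=sd)
        if q <= 0:
            return 0.0
        return q * (norm.logpdf(x, loc=mean, scale=sd) - gm.logpdf(xq)[0])

    val, _ = integrate.quad(integrand, mean - 10 * sd, mean + 10 * sd, epsabs=1e-10, limit=400)
    if val < -1e-9:
        raise RuntimeError(f"KL quadrature returned {val}, below tolerance")
    val = max(val, 0.0)
    return float(val), bool(val >= threshold)


def fit_loss_sd(window: float) -> float:
    """Least-squares best inverted-Gaussian width for the square well of the
    given window (the objective has a closed-form in the width; the minimum
    is found numerically once and cached by the config layer)."""
    a = window / 2.0

    def sqerr(sd: float) -> float:
        # integral over R of (1{|x|<=a} - exp(-x^2/(2 sd^2)))^2 dx
        return (
            2.0 * a
            - 2.0 * sd * np.sqrt(2.0 * np.pi) * (2.0 * ndtr(a / sd) - 1.0)
            + sd * np.sqrt(np.pi)
        )

    res = optimize.minimize_scalar(
        sqerr, bounds=(a / 10.0, 10.0 * a), method="bounded", options={"xatol": 1e-12}
    )
    return float(res.x)
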