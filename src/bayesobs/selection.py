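"""Group-level model comparison.

Two complementary routes: a hierarchical random-effects Bayesian model
selection (BMS) that treats both subjects and models as random factors —
variational updates on a Dirichlet over model frequencies, reporting the
probability that each model generated a random subject's data and the
exceedance probability that it is more frequent than any other — and a
fixed-effects group-DIC comparison in which every subject contributes
equally to each model's evidence.

Model evidence enters as an approximation of the log marginal likelihood
from DIC: log evidence = -DIC/2 (deviance scale; configurable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import digamma

__all__ = ["EvidenceTable", "bms_fit", "factor_aggregate", "gdic", "factor_partition"]

GDIC_SIGNIFICANCE = 10.0  # conservative DIC-difference threshold


@dataclass(frozen=True)
class EvidenceTable:
    """Subjects x models matrix of log model evidence."""

    subjects: tuple
    models: tuple
    log_evidence: np.ndarray

    def __post_init__(self):
        le = np.asarray(self.log_evidence, dtype=float)
        if le.shape != (len(self.subjects), len(self.models)):
            raise ValueError("log_evidence shape must be (n_subjects, n_models)")
        if not np.all(np.isfinite(le)):
            raise ValueError("log evidence entries must be finite")
        if len(set(self.models)) != len(self.models):
            raise ValueError("model names must be unique")
        object.__setattr__(self, "log_evidence", le)

    @classmethod
    def from_dic(cls, subjects, models, dic_matrix, evidence_scale: float = -0.5):
        dic_matrix = np.asarray(dic_matrix, dtype=float)
        keep = ~np.any(np.isnan(dic_matrix), axis=1)
        dic_matrix = dic_matrix[keep]
        subjects = tuple(s for s, k in zip(subjects, keep) if k)
        return cls(subjects, tuple(models), evidence_scale * dic_matrix)


def bms_fit(
    table: EvidenceTable,
    alpha0: float = 0.3,
    n_dirichlet_draws: int = 100_000,
    seed: int = 0,
    max_iter: int = 10_000,
    tol: float = 1e-8,
):
    """Variational random-effects model selection.

    Iterates responsibilities u_nk proportional to
    exp(log_evidence_nk + digamma(alpha_k) - digamma(sum alpha)) and
    alpha_k = alpha0 + sum_n u_nk until convergence.  Returns
    (alpha, model_probs, exceedance_probs); model_probs = alpha / sum(alpha)
    is the probability that a given model generated the data of a randomly
    chosen subject, and exceedance probabilities come from Monte-Carlo
    sampling of the fitted Dirichlet.
    """
    if alpha0 <= 0:
        raise ValueError("alpha0 must be positive")
    le = table.log_evidence
    n, k = le.shape
    alpha = np.full(k, alpha0 + n / k)
    for it in range(max_iter):
        logu = le + digamma(alpha) - digamma(alpha.sum())
        logu -= logu.max(axis=1, keepdims=True)
        u = np.exp(logu)
        u /= u.sum(axis=1, keepdims=True)
        alpha_new = alpha0 + u.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    else:
        raise RuntimeError(f"BMS did not converge in {max_iter} iterations")
    probs = alpha / alpha.sum()
    exceed = _exceedance(alpha, n_dirichlet_draws, seed)
    return alpha, probs, exceed


def _exceedance(alpha: np.ndarray, n_draws: int, seed: int) -> np.ndarray:
    if alpha.size == 1:
        return np.ones(1)
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=n_draws)
    winners = np.argmax(draws, axis=1)
    return np.bincount(winners, minlength=alpha.size) / n_draws


def factor_partition(models, factor: str) -> dict:
    """Partition model strings by the level of a named factor.

    ``factor`` is one of 'decision', 'approx', 'S', 'P', 'L'.
    """
    from .observers import parse_model_string

    out: dict[str, list] = {}
    for m in models:
        spec = parse_model_string(m)
        if factor == "decision":
            level = spec.decision
        elif factor == "approx":
            level = spec.gauss_approx
        elif factor == "S":
            level = "S" if spec.cue_noise_S else "no-S"
        elif factor == "P":
            level = "P" if spec.prior_noise_P else "no-P"
        elif factor == "L":
            level = "L" if spec.lapse_L else "no-L"
        else:
            raise ValueError(f"unknown factor {factor!r}")
        out.setdefault(level, []).append(m)
    return out


def factor_aggregate(
    table: EvidenceTable,
    partition: dict,
    alpha0: float = 0.3,
    n_dirichlet_draws: int = 100_000,
    seed: int = 0,
):
    """Cumulative evidence for groups of models (levels within a factor).

    The partition must cover all models exactly once.  Runs the BMS on the
    full table, then sums member model probabilities per level; level
    exceedance probabilities are computed from the same Dirichlet draws by
    summing member frequencies before taking the argmax.
    """
    listed = [m for ms in partition.values() for m in ms]
    if sorted(listed) != sorted(table.models):
        raise ValueError("partition must cover all models exactly once")
    alpha, probs, _ = bms_fit(table, alpha0, n_dirichlet_draws=1, seed=seed)
    idx = {m: j for j, m in enumerate(table.models)}
    levels = list(partition)
    level_probs = {
        lv: float(sum(probs[idx[m]] for m in partition[lv])) for lv in levels
    }
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=n_dirichlet_draws)
    level_mass = np.stack(
        [draws[:, [idx[m] for m in partition[lv]]].sum(axis=1) for lv in levels], axis=1
    )
    winners = np.argmax(level_mass, axis=1)
    freq = np.bincount(winners, minlength=len(levels)) / n_dirichlet_draws
    level_exceed = {lv: float(freq[i]) for i, lv in enumerate(levels)}
    return level_probs, level_exceed


def gdic(dic_matrix, models=None):
    """Fixed-effects group comparison: column sums of DIC, differences to the
    best model, and a conservative significance flag at delta >= 10."""
    dic_matrix = np.asarray(dic_matrix, dtype=float)
    if not np.all(np.isfinite(dic_matrix)):
        raise ValueError("DIC entries must be finite")
    sums = dic_matrix.sum(axis=0)
    delta = sums - sums.min()
    out = {
        "group_dic": sums,
        "delta_dic": delta,
        "significant": delta >= GDIC_SIGNIFICANCE,
        "best_index": int(np.argmin(sums)),
    }
    if models is not None:
        out["models"] = list(models)
        out["best_model"] = list(models)[out["best_index"]]
    return out
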