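"""Synthetic subjects: full datasets simulated from any observer model.

A simulated subject performs the same two-session protocol as the study
population: a training session with the eight Gaussian priors followed by a
test session with the subject group's priors (Gaussian, unimodal or
bimodal), 16 conditions per session and 36-40 repetitions per condition.
Responses are drawn from the observer's full generative process — latent
cue/prior measurements (factors S and P), the decision rule's stochasticity,
lapses, and motor noise — so that simulation and likelihood are two views of
the same model (checked against each other in the tests).

Randomness is split into named streams: the session-level stream is seeded
with (seed, subject_index, session_index) and consumed trial by trial, so a
dataset regenerates bit-identically from its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import FitConfig, TaskConfig
from .gmm import posterior_update
from .observers import (
    ObserverParams,
    ObserverSpec,
    RelTrial,
    _approximate,
    _decision_choice,
    _perturb_prior,
    PSA_EXACT_MAX,
    free_param_names,
    make_rel_trials,
)
from .task import (
    PriorSpec,
    TrialRecord,
    build_session_plan,
    from_relative,
    prior_set,
    sample_trial,
    to_relative,
)

__all__ = [
    "SubjectSim",
    "simulate_response",
    "simulate_subject",
    "simulate_group",
    "default_population",
    "recovery_experiment",
    "RecoveryReport",
]

SESSIONS = (("training", "gaussian", 0), ("test", None, 1))


@dataclass
class SubjectSim:
    subject_id: str
    group: str
    generating_spec: ObserverSpec
    theta: ObserverParams
    seed: int
    dataset: list  # TrialRecords with responses


def simulate_response(
    spec: ObserverSpec,
    params: ObserverParams,
    trial: TrialRecord,
    rng: np.random.Generator,
    cfg: TaskConfig = TaskConfig(),
) -> float:
    """Draw one response (screen coordinates) from the observer's generative
    process for a sampled trial."""
    prior = trial.prior.mixture  # canonical frame
    cue = float(to_relative(trial.cue_x, trial.prior))
    session = trial.session
    lam = params.lapse(session) if spec.lapse_L else 0.0
    if lam > 0.0 and rng.uniform() < lam:
        choice = float(prior.rvs(rng, 1)[0])
        r_rel = choice + rng.normal(0.0, params.motor_sd)
        return float(from_relative(r_rel, trial.prior))
    x_m = cue
    if spec.cue_noise_S:
        x_m = cue + rng.normal(0.0, params.cue_est_sd(session, trial.cue_level, cfg))
    prior_l = prior
    if spec.prior_noise_P:
        prior_l = _perturb_prior(prior, float(rng.normal()), params.weber_prior(session))
    sigma = params.internal_lik_sd(session, trial.cue_level)
    post = _approximate(posterior_update(prior_l, x_m, sigma), spec.gauss_approx)
    gm = post.base
    if spec.decision == "BDT":
        choice = _decision_choice(spec, params, post, session, cfg).point
    elif spec.decision == "PPM":
        choice = float(gm.rvs(rng, 1)[0])
    elif spec.decision == "SPK":
        kappa = params.kappa(spec, session)
        if gm.n_components == 1:
            choice = float(rng.normal(gm.means[0], gm.sds[0] / math.sqrt(kappa)))
        else:
            choice = _decision_choice(spec, params, post, session, cfg).sample(rng)
    else:  # PSA: mean of K draws; non-integer K mixes adjacent integers,
        # matching the density-interpolation rule of the likelihood
        k = params.psa_k(session)
        if k > PSA_EXACT_MAX:
            mean, var, _, _ = gm.moments()
            choice = float(rng.normal(mean, math.sqrt(var / k)))
        else:
            ki = int(k) if k == int(k) else int(k) + int(rng.uniform() < (k - int(k)))
            choice = float(np.mean(gm.rvs(rng, ki)))
    r_rel = choice + rng.normal(0.0, params.motor_sd)
    return float(from_relative(r_rel, trial.prior))


def simulate_subject(
    group: str,
    spec: ObserverSpec,
    theta: ObserverParams,
    seed: int,
    cfg: TaskConfig = TaskConfig(),
    subject_index: int = 0,
    subject_id: str | None = None,
) -> SubjectSim:
    """Simulate a full two-session dataset (training Gaussian + group test)."""
    priors_by_class = {"gaussian": prior_set("gaussian", cfg)}
    if group not in priors_by_class:
        priors_by_class[group] = prior_set(group, cfg)
    dataset = []
    for session, prior_class, sess_idx in SESSIONS:
        pclass = prior_class or group
        rng = np.random.default_rng([seed, subject_index, sess_idx])
        plan = build_session_plan(session, pclass, cfg.repetitions, rng)
        priors = {p.prior_id: p for p in priors_by_class[pclass]}
        for prior_id, cue_level in plan.conditions:
            trial = sample_trial(session, priors[prior_id], cue_level, rng, cfg)
            trial.response_x = simulate_response(spec, theta, trial, rng, cfg)
            dataset.append(trial)
    return SubjectSim(
        subject_id=subject_id or f"sim{subject_index:02d}",
        group=group,
        generating_spec=spec,
        theta=theta,
        seed=seed,
        dataset=dataset,
    )


def default_population(spec: ObserverSpec) -> dict:
    """Population distributions for each free parameter of ``spec``.

    Log-normal for scale-like parameters, uniform for rates; magnitudes are
    synthetic defaults chosen to represent a plausible moderately suboptimal
    population (likelihood widths scattered around the true cue noise,
    decision noise kappa around 2-3, Weber fraction around 0.2-0.3, small
    motor noise and lapse rates).
    """
    pop = {
        "lik_sd_short_train": ("lognormal", 0.06, 0.25),
        "lik_sd_long_train": ("lognormal", 0.14, 0.25),
        "lik_sd_short_test": ("lognormal", 0.06, 0.25),
        "motor_sd": ("lognormal", 0.01, 0.25),
        "kappa_train": ("lognormal", 2.5, 0.3),
        "kappa_test": ("lognormal", 2.5, 0.3),
        "psa_k_train": ("lognormal", 2.5, 0.3),
        "psa_k_test": ("lognormal", 2.5, 0.3),
        "cue_est_sd_train": ("lognormal", 0.01, 0.3),
        "cue_est_sd_test": ("lognormal", 0.01, 0.3),
        "weber_prior_train": ("lognormal", 0.25, 0.3),
        "weber_prior_test": ("lognormal", 0.25, 0.3),
        "lapse_train": ("uniform", 0.01, 0.06),
        "lapse_test": ("uniform", 0.01, 0.06),
    }
    return {n: pop[n] for n in free_param_names(spec)}


def _draw_param(dist, rng: np.random.Generator) -> float:
    kind = dist[0]
    if kind == "lognormal":
        _, med, shape = dist
        return float(med * np.exp(rng.normal(0.0, shape)))
    if kind == "uniform":
        _, lo, hi = dist
        return float(rng.uniform(lo, hi))
    if kind == "fixed":
        return float(dist[1])
    raise ValueError(f"unknown population distribution {dist!r}")


def simulate_group(
    n_subjects: int,
    spec: ObserverSpec,
    theta_population: dict | None = None,
    seed: int = 0,
    group: str = "gaussian",
    cfg: TaskConfig = TaskConfig(),
) -> list[SubjectSim]:
    """Independent subjects with parameters drawn from the population."""
    pop = theta_population if theta_population is not None else default_population(spec)
    subjects = []
    for i in range(n_subjects):
        rng = np.random.default_rng([seed, i, 999])
        theta = ObserverParams(**{n: _draw_param(d, rng) for n, d in pop.items()})
        subjects.append(
            simulate_subject(group, spec, theta, seed, cfg, subject_index=i)
        )
    return subjects


@dataclass
class RecoveryReport:
    """Outcome of a simulate -> fit -> compare round trip."""

    generating_model: str
    candidate_models: list
    n_subjects: int
    seed: int
    dic_matrix: np.ndarray  # (subjects, candidates)
    model_probs: np.ndarray
    exceedance_probs: np.ndarray
    winner: str
    coverage: dict = field(default_factory=dict)  # param -> fraction covered
    failures: list = field(default_factory=list)

    @property
    def generating_model_top(self) -> bool:
        return self.winner == self.generating_model


def recovery_experiment(
    generating_spec: ObserverSpec,
    candidate_specs: list[ObserverSpec],
    n_subjects: int = 8,
    seed: int = 0,
    group: str = "gaussian",
    cfg: TaskConfig = TaskConfig(),
    fit_cfg: FitConfig = FitConfig(),
    bms_cfg=None,
    theta_population: dict | None = None,
    ci_level: float = 0.95,
    max_trials: int | None = None,
) -> RecoveryReport:
    """Simulate a group, fit every candidate to every subject, and run the
    random-effects model comparison; also report 95%-interval coverage of
    the generating parameters under the generating model's fits.

    ``max_trials`` subsamples each subject's dataset (deterministically per
    seed) before fitting, for reduced-budget recovery runs.
    """
    from .mcmc import fit_subject
    from .selection import EvidenceTable, bms_fit

    subjects = simulate_group(n_subjects, generating_spec, theta_population, seed, group, cfg)
    names = [str(s) for s in candidate_specs]
    dic_mat = np.full((n_subjects, len(candidate_specs)), np.nan)
    covered: dict[str, list] = {n: [] for n in free_param_names(generating_spec)}
    failures = []
    for i, subj in enumerate(subjects):
        rel = make_rel_trials(subj.dataset)
        if max_trials is not None and len(rel) > max_trials:
            sub_rng = np.random.default_rng([seed, i, 777])
            keep = sub_rng.choice(len(rel), size=max_trials, replace=False)
            rel = [rel[k] for k in sorted(keep)]
        for j, cand in enumerate(candidate_specs):
            try:
                res = fit_subject(cand, rel, cfg, fit_cfg, seed=int(1e6) + 97 * i + j)
            except Exception as exc:  # recorded, not fatal
                failures.append((subj.subject_id, str(cand), repr(exc)))
                continue
            dic_mat[i, j] = res.dic
            if str(cand) == str(generating_spec):
                ci = res.credible_interval(ci_level)
                truth = subj.theta.to_vector(generating_spec)
                for name, t, (lo, hi) in zip(res.param_names, truth, ci):
                    covered[name].append(bool(lo <= t <= hi))
    table = EvidenceTable.from_dic([s.subject_id for s in subjects], names, dic_mat)
    from .config import BmsConfig

    bcfg = bms_cfg if bms_cfg is not None else BmsConfig()
    _, probs, exceed = bms_fit(table, alpha0=bcfg.alpha0,
                               n_dirichlet_draws=bcfg.n_dirichlet_draws, seed=seed)
    winner = names[int(np.argmax(probs))]
    coverage = {k: float(np.mean(v)) for k, v in covered.items() if v}
    return RecoveryReport(
        generating_model=str(generating_spec),
        candidate_models=names,
        n_subjects=n_subjects,
        seed=seed,
        dic_matrix=dic_mat,
        model_probs=probs,
        exceedance_probs=exceed,
        winner=winner,
        coverage=coverage,
        failures=failures,
    )
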