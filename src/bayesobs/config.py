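"""Task and analysis configuration.

All experiment constants live here with validated defaults, so that the
generative model, the observer likelihoods and the analysis drivers agree on
a single source of numbers.  Defaults can be overridden from a YAML file via
:func:`config_load`.

Units: positions in standardized screen units (window width 1.0; 0.01 screen
units = 3 mm, so 1 screen unit = 30 cm of workspace).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np
import yaml

from .gmm import LossModel, fit_loss_sd

CM_PER_SCREEN_UNIT = 30.0

# Eight unimodal test priors: (skewness, excess kurtosis), fixed total SD.
# Entry 4 is the platykurtic prior (realized as an 11-component mixture);
# entry 8 is a single Gaussian.  Shapes span the unimodal-feasible region.
DEFAULT_UNIMODAL_TABLE = (
    (0.0, 1.5),
    (0.7, 0.8),
    (-0.7, 0.8),
    (0.0, -0.7),
    (1.1, 2.2),
    (-1.1, 2.2),
    (0.4, 0.3),
    (0.0, 0.0),
)

# Eight bimodal test priors: (separation in total-SD units, relative weight
# of the left component), fixed total SD.  Entry 8 is a single Gaussian.
DEFAULT_BIMODAL_TABLE = (
    (1.9, 0.5),
    (1.9, 0.3),
    (1.7, 0.5),
    (1.6, 0.35),
    (1.4, 0.5),
    (1.2, 0.4),
    (0.9, 0.5),
    (0.0, 0.5),
)


@dataclass(frozen=True)
class TaskConfig:
    """Constants of the target-estimation task.

    The printed sources specify the structure of the task (counts, SD grid
    bounds, trial plan) but not every numeric constant; cue-noise SDs, cue
    distances, the test-session total SD, the component-SD floor and the two
    shape tables are package defaults, editable here or via YAML.
    """

    n_targets: int = 100
    # true cue-noise SDs for short/long-distance cues, screen units (defaults)
    sigma_short: float = 0.06
    sigma_long: float = 0.14
    # cue distances from the target line, cm (sets the Weber ratio of factor S)
    d_short_cm: float = 6.0
    d_long_cm: float = 14.0
    cursor_radius_cm: float = 1.25
    # success window = cursor diameter, screen units
    window: float = 2.0 * 1.25 / CM_PER_SCREEN_UNIT
    # inverted-Gaussian loss SD; None -> least-squares fit to the square well
    loss_sd: float | None = None
    # Gaussian-session prior SDs: evenly spread on [0.04, 0.18]
    gaussian_sd_min: float = 0.04
    gaussian_sd_max: float = 0.18
    n_priors: int = 8
    # fixed total SD of unimodal/bimodal test priors (default; not printed)
    test_total_sd: float = 0.11
    # lower bound on component SDs in the unimodal entropy maximization
    component_sd_floor: float = 0.02
    unimodal_table: tuple = DEFAULT_UNIMODAL_TABLE
    bimodal_table: tuple = DEFAULT_BIMODAL_TABLE
    repetitions: int = 36  # trials per condition (36-40)
    # KL threshold (nats) for the non-Gaussian-trial filter
    kl_threshold: float = 0.02
    # extended-BDT variant with free loss width (off by default)
    free_loss_width: bool = False

    def __post_init__(self):
        positives = (
            "sigma_short", "sigma_long", "d_short_cm", "d_long_cm", "window",
            "gaussian_sd_min", "gaussian_sd_max", "test_total_sd",
            "component_sd_floor", "kl_threshold",
        )
        for name in positives:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_targets < 1 or self.n_priors < 1:
            raise ValueError("n_targets and n_priors must be >= 1")
        if not 36 <= self.repetitions <= 40:
            raise ValueError("repetitions must lie in [36, 40]")
        if self.gaussian_sd_max <= self.gaussian_sd_min:
            raise ValueError("gaussian_sd_max must exceed gaussian_sd_min")
        if len(self.unimodal_table) != self.n_priors or len(self.bimodal_table) != self.n_priors:
            raise ValueError("shape tables must have one entry per prior")

    @property
    def loss(self) -> LossModel:
        sd = self.loss_sd if self.loss_sd is not None else _fitted_loss_sd(self.window)
        return LossModel(sd, self.window)

    @property
    def weber_distance_ratio(self) -> float:
        """sigma_s(long) / sigma_s(short) for factor S (error grows with distance)."""
        return self.d_long_cm / self.d_short_cm

    def true_sigma(self, cue_level: str) -> float:
        if cue_level == "short":
            return self.sigma_short
        if cue_level == "long":
            return self.sigma_long
        raise ValueError(f"unknown cue level {cue_level!r}")

    def gaussian_sds(self) -> np.ndarray:
        return np.linspace(self.gaussian_sd_min, self.gaussian_sd_max, self.n_priors)


@dataclass(frozen=True)
class FitConfig:
    """MCMC fitting budget and hyperparameters (reduced-scale defaults)."""

    n_chains: int = 3
    burn_in: int = 500
    n_samples: int = 2000
    trim_fraction: float = 0.10  # trimmed-mean fraction per side
    # log-normal hyperpriors for motor_sd and cue_est_sd (stand-in defaults)
    motor_log_scale: float = float(np.log(0.01))
    motor_log_shape: float = 0.5
    cue_est_log_scale: float = float(np.log(0.01))
    cue_est_log_shape: float = 0.5
    gauss_hermite_order: int = 20
    map_restarts: int = 30

    def __post_init__(self):
        if self.n_chains < 1 or self.burn_in < 0 or self.n_samples < 1:
            raise ValueError("invalid MCMC budget")
        if not 0.0 <= self.trim_fraction < 0.5:
            raise ValueError("trim_fraction must lie in [0, 0.5)")


@dataclass(frozen=True)
class BmsConfig:
    """Random-effects model-selection settings."""

    alpha0: float = 0.3
    n_dirichlet_draws: int = 100_000
    evidence_scale: float = -0.5  # log evidence = evidence_scale * DIC

    def __post_init__(self):
        if self.alpha0 <= 0:
            raise ValueError("alpha0 must be positive")
        if self.n_dirichlet_draws < 1:
            raise ValueError("n_dirichlet_draws must be >= 1")


@dataclass(frozen=True)
class RunConfig:
    task: TaskConfig = field(default_factory=TaskConfig)
    fit: FitConfig = field(default_factory=FitConfig)
    bms: BmsConfig = field(default_factory=BmsConfig)
    seed: int = 0


_loss_sd_cache: dict[float, float] = {}


def _fitted_loss_sd(window: float) -> float:
    if window not in _loss_sd_cache:
        _loss_sd_cache[window] = fit_loss_sd(window)
    return _loss_sd_cache[window]


def _build(cls, data: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    for key in ("unimodal_table", "bimodal_table"):
        if key in data:
            data[key] = tuple(tuple(row) for row in data[key])
    return cls(**data)


def config_load(path) -> RunConfig:
    """Load a RunConfig from YAML; unknown keys raise (no silent typos)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")
    unknown = set(raw) - {"task", "fit", "bms", "seed"}
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    return RunConfig(
        task=_build(TaskConfig, dict(raw.get("task", {}))),
        fit=_build(FitConfig, dict(raw.get("fit", {}))),
        bms=_build(BmsConfig, dict(raw.get("bms", {}))),
        seed=int(raw.get("seed", 0)),
    )


def config_replace(cfg, **kwargs):
    """Functional update helper (dataclasses.replace re-export)."""
    return replace(cfg, **kwargs)
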