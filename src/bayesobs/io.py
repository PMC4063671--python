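"""Dataset and fit-result serialization.

Trial datasets travel as CSV, one row per trial, with the canonical prior
identified by (prior_class, prior_id) and reconstructed from the task
configuration on read — the dot positions regenerate deterministically from
the placed prior, so the round trip is lossless.  Fit results are JSON plus
gzip-compressed CSV chains.  A thin import helper maps the study's
deposited MATLAB container onto the same trial table.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import TaskConfig
from .mcmc import McmcResult
from .observers import ObserverParams, ObserverSpec, free_param_names
from .task import TrialRecord, discretize_prior, edge_filter, prior_set

__all__ = [
    "TRIAL_COLUMNS",
    "trials_to_frame",
    "frame_to_trials",
    "write_dataset",
    "read_dataset",
    "save_fit",
    "load_fit",
    "load_matlab_dataset",
]

# documented CSV dialect, one row per trial
TRIAL_COLUMNS = [
    "session",        # training | test
    "prior_class",    # gaussian | unimodal | bimodal
    "prior_id",       # 1-8
    "cue_level",      # short | long
    "flipped",        # 0/1: prior reflected about its location
    "location",       # prior mean, screen units
    "target_x",       # true target, screen units
    "cue_x",          # cue position, screen units
    "cue_distance",   # cue distance from the target line, cm
    "response_x",     # response, screen units (empty if missing)
    "edge_excluded",  # 0/1: cue outside the dot range
]


def trials_to_frame(trials: list[TrialRecord]) -> pd.DataFrame:
    rows = []
    for t in trials:
        rows.append(
            {
                "session": t.session,
                "prior_class": t.prior_class,
                "prior_id": t.prior_id,
                "cue_level": t.cue_level,
                "flipped": int(t.prior.flipped),
                "location": t.prior.location,
                "target_x": t.target_x,
                "cue_x": t.cue_x,
                "cue_distance": t.cue_distance,
                "response_x": t.response_x,
                "edge_excluded": int(t.edge_excluded),
            }
        )
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def frame_to_trials(
    df: pd.DataFrame, cfg: TaskConfig = TaskConfig(), apply_edge_filter: bool = False
) -> list[TrialRecord]:
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns and c != "response_x"]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    priors = {
        (cls, p.prior_id): p
        for cls in df["prior_class"].unique()
        for p in prior_set(cls, cfg)
    }
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            base = priors[(row.prior_class, int(row.prior_id))]
            placed = base.placed(float(row.location), bool(row.flipped))
            targets = discretize_prior(placed, cfg.n_targets)
            resp = getattr(row, "response_x", None)
            resp = None if resp is None or (isinstance(resp, float) and np.isnan(resp)) else float(resp)
            trial = TrialRecord(
                session=str(row.session),
                prior_class=str(row.prior_class),
                prior_id=int(row.prior_id),
                cue_level=str(row.cue_level),
                prior=placed,
                targets=targets,
                target_x=float(row.target_x),
                cue_x=float(row.cue_x),
                cue_distance=float(row.cue_distance),
                response_x=resp,
                edge_excluded=bool(row.edge_excluded),
            )
        except (KeyError, ValueError, TypeError) as exc:
            raise ValueError(f"malformed trial row {i}: {exc}") from exc
        if apply_edge_filter and edge_filter(trial):
            continue
        out.append(trial)
    return out


def write_dataset(path, trials: list[TrialRecord]) -> None:
    # default float formatting is repr-based and round-trips exactly
    trials_to_frame(trials).to_csv(path, index=False)


def read_dataset(path, cfg: TaskConfig = TaskConfig(),
                 apply_edge_filter: bool = False) -> list[TrialRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    return frame_to_trials(df, cfg, apply_edge_filter)


# ---------------------------------------------------------------------------
# fit results


def save_fit(prefix, result: McmcResult, spec: ObserverSpec) -> None:
    """JSON summary at <prefix>.json, chains at <prefix>.chains.csv.gz."""
    prefix = Path(prefix)
    summary = {
        "model": result.model,
        "param_names": list(result.param_names),
        "theta_hat": result.theta_hat.tolist(),
        "rhat": result.rhat.tolist(),
        "dic": result.dic,
        "p_d": result.p_d,
        "n_chains": int(result.chains.shape[0]),
        "n_samples": int(result.chains.shape[1]),
        "units": "screen units",
    }
    prefix.with_suffix(".json").write_text(json.dumps(summary, indent=2))
    flat = result.chains.reshape(-1, result.chains.shape[-1])
    ll = result.log_liks.reshape(-1, 1)
    header = ",".join(list(result.param_names) + ["log_lik"])
    with gzip.open(prefix.with_suffix(".chains.csv.gz"), "wt") as fh:
        fh.write(header + "\n")
        np.savetxt(fh, np.hstack([flat, ll]), delimiter=",")


def load_fit(prefix) -> McmcResult:
    prefix = Path(prefix)
    summary = json.loads(prefix.with_suffix(".json").read_text())
    with gzip.open(prefix.with_suffix(".chains.csv.gz"), "rt") as fh:
        df = pd.read_csv(fh)
    n_c, n_s = summary["n_chains"], summary["n_samples"]
    names = summary["param_names"]
    chains = df[names].to_numpy().reshape(n_c, n_s, len(names))
    lls = df["log_lik"].to_numpy().reshape(n_c, n_s)
    return McmcResult(
        model=summary["model"],
        param_names=names,
        chains=chains,
        log_liks=lls,
        rhat=np.asarray(summary["rhat"]),
        dic=summary["dic"],
        p_d=summary["p_d"],
        theta_hat=np.asarray(summary["theta_hat"]),
    )


def load_matlab_dataset(path, cfg: TaskConfig = TaskConfig()) -> dict:
    """Import the deposited MATLAB container of subject datasets.

    Expects a .mat file whose variables are per-subject structs (or a cell
    array) with per-trial vectors named like the CSV dialect columns
    (``session``, ``prior_class``, ``prior_id``, ``cue_level``, ``flipped``,
    ``location``, ``target_x``, ``cue_x``, ``cue_distance``,
    ``response_x``).  Returns {subject_id: list of TrialRecord}.
    """
    from scipy.io import loadmat

    raw = loadmat(path, squeeze_me=True, struct_as_record=False)
    out = {}
    for key, val in raw.items():
        if key.startswith("__"):
            continue
        entries = np.atleast_1d(val)
        for i, entry in enumerate(entries):
            fields = {}
            for col in TRIAL_COLUMNS:
                if hasattr(entry, col):
                    fields[col] = np.atleast_1d(getattr(entry, col))
            if not fields:
                continue
            required = set(TRIAL_COLUMNS) - {"response_x", "edge_excluded"}
            missing = required - set(fields)
            if missing:
                raise ValueError(
                    f"MATLAB entry {key}[{i}] lacks fields {sorted(missing)}"
                )
            n = len(fields["cue_x"])
            if "edge_excluded" not in fields:
                fields["edge_excluded"] = np.zeros(n, dtype=int)
            if "response_x" not in fields:
                fields["response_x"] = np.full(n, np.nan)
            df = pd.DataFrame({c: fields[c] for c in TRIAL_COLUMNS})
            out[f"{key}{i:02d}"] = frame_to_trials(df, cfg)
    if not out:
        raise ValueError("no subject datasets found in the MATLAB file")
    return out
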