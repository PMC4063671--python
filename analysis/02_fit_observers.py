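#!/usr/bin/env python
"""Fit observer models to the Gaussian-group cohort by slice-sampling MCMC.

For each simulated subject, fits a focused candidate set around the
generating model (SPK-P-L and its main rivals) at a reduced chain budget
and writes per-fit summaries (DIC, effective parameters, robust point
estimate, R-hat) plus compressed chains under results/fits/.

Run 01_simulate_cohort.py first.  Fitting is the expensive step: with the
default budget expect a few minutes per (subject, model) pair.
"""

import argparse
import json
from pathlib import Path

from bayesobs.config import FitConfig, TaskConfig
from bayesobs.io import read_dataset, save_fit
from bayesobs.mcmc import fit_subject
from bayesobs.observers import parse_model_string

ROOT = Path(__file__).resolve().parents[1]
DEFAULT_MODELS = "SPK-P-L,SPK-P,BDT-P-L,PPM-P-L,SPK-L,SPK-S-P-L"


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--models", default=DEFAULT_MODELS)
    ap.add_argument("--group", default="gaussian")
    ap.add_argument("--burn-in", type=int, default=200)
    ap.add_argument("--samples", type=int, default=600)
    ap.add_argument("--max-subjects", type=int, default=None)
    args = ap.parse_args()

    cfg = TaskConfig()
    fit_cfg = FitConfig(n_chains=3, burn_in=args.burn_in, n_samples=args.samples)
    cohort_dir = ROOT / "results" / "cohort"
    out = ROOT / "results" / "fits"
    out.mkdir(parents=True, exist_ok=True)
    subjects = sorted(cohort_dir.glob(f"{args.group}_*.csv"))
    if not subjects:
        raise SystemExit("no cohort files found; run 01_simulate_cohort.py first")
    if args.max_subjects:
        subjects = subjects[: args.max_subjects]
    for path in subjects:
        trials = read_dataset(path, cfg)
        for i, model in enumerate(args.models.split(",")):
            spec = parse_model_string(model)
            res = fit_subject(spec, trials, cfg, fit_cfg,
                              seed=args.seed * 1000 + i)
            save_fit(out / f"{path.stem}__{model}", res, spec)
            print(f"{path.stem} {model}: DIC {res.dic:.1f} "
                  f"p_D {res.p_d:.1f} max R-hat {max(res.rhat):.3f}")


if __name__ == "__main__":
    main()
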