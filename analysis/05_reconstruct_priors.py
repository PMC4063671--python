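#!/usr/bin/env python
"""Nonparametric reconstruction of the group priors (Gaussian test session).

Represents each prior as a mixture of 11 equally spaced narrow Gaussians
spanning the range of its discrete on-screen representation, fixes every
subject's SPK-L observer parameters, and slice-samples the mixing weights
under the pooled likelihood.  Compares the posterior-mean reconstructed SD
with the generating SD per prior and plots the reconstructed densities.

Run 01_simulate_cohort.py first.  Uses the generating parameters from the
cohort manifest as the fixed per-subject observer parameters (in a full
pipeline these would be the robust means of each subject's SPK-L fit from
02_fit_observers.py, which takes considerably longer).
"""

import argparse
import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from bayesobs.analysis import ReconstructionSpec, reconstruct_priors
from bayesobs.config import FitConfig, TaskConfig
from bayesobs.io import read_dataset
from bayesobs.observers import ObserverParams, make_rel_trials

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--priors", default="1,3,5,8",
                    help="prior ids to reconstruct (all 8 takes ~10 min)")
    args = ap.parse_args()

    cfg = TaskConfig()
    cohort = ROOT / "results" / "cohort"
    manifest = json.loads((cohort / "manifest.json").read_text())
    out = ROOT / "results" / "reconstruction"
    out.mkdir(parents=True, exist_ok=True)

    subjects = {}
    for f in sorted(cohort.glob("gaussian_*.csv")):
        subjects[f.stem] = read_dataset(f, cfg)
    if not subjects:
        raise SystemExit("no cohort files; run 01_simulate_cohort.py first")

    rows = []
    fig, axes = plt.subplots(1, len(args.priors.split(",")),
                             figsize=(3 * len(args.priors.split(",")), 3),
                             squeeze=False)
    for ax, pid_s in zip(axes[0], args.priors.split(",")):
        pid = int(pid_s)
        true_sd = float(cfg.gaussian_sds()[pid - 1])
        datasets, thetas = {}, {}
        for sid, trials in subjects.items():
            rel = make_rel_trials(
                [t for t in trials if t.session == "test" and t.prior_id == pid]
            )
            datasets[sid] = rel
            theta_map = manifest[sid]["theta"]
            thetas[sid] = ObserverParams(**{
                k: v for k, v in theta_map.items()
                if k in ObserverParams.__dataclass_fields__
            })
        rspec = ReconstructionSpec(
            grid_size=11, grid_bounds=(-2.576 * true_sd, 2.576 * true_sd),
            symmetry_constraint=True, fixed_theta=thetas,
        )
        res = reconstruct_priors(
            datasets, rspec,
            mcmc_budget=FitConfig(n_chains=2, burn_in=100, n_samples=250),
            seed=args.seed, cfg=cfg, grid_step=5e-3,
        )
        rows.append({
            "prior_id": pid, "true_sd": true_sd, "recovered_sd": res.mean_sd,
            "ratio": res.mean_sd / true_sd, "converged": res.converged,
        })
        x = np.linspace(-3 * true_sd, 3 * true_sd, 300)
        from scipy.stats import norm

        ax.plot(x, norm.pdf(x, 0, true_sd), "k--", label="true")
        ax.plot(x, res.mean_prior.pdf(x), "purple", label="reconstructed")
        ax.set_title(f"prior {pid}", fontsize=9)
        ax.set_yticks([])
        print(f"prior {pid}: true SD {true_sd:.3f} "
              f"recovered {res.mean_sd:.3f} (ratio {res.mean_sd/true_sd:.3f})")
    axes[0][0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out / "reconstructed_priors.png", dpi=130)
    plt.close(fig)
    pd.DataFrame(rows).to_csv(out / "recovered_sds.csv", index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
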