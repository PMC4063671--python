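#!/usr/bin/env python
"""Model-free summaries of the simulated cohort.

For the Gaussian sessions: robust linear fits of relative response against
relative cue position per (prior SD, cue level) condition — the slope is
the empirical cue weight, overlaid with the Bayes-optimal shrinkage weight
w = sd_p^2/(sd_p^2 + sd_c^2).  For every session: per-condition mean
optimality index with cue-only and prior-only baselines, and a kernel-
regression trend of the index against posterior SD.  Writes CSV tables and
PNG figures under results/model_free/.
"""

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from bayesobs.analysis import condition_slopes, kernel_regression, optimality_summary
from bayesobs.config import TaskConfig
from bayesobs.gmm import posterior_update
from bayesobs.io import read_dataset

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--max-subjects", type=int, default=4)
    args = ap.parse_args()

    cfg = TaskConfig()
    cohort = ROOT / "results" / "cohort"
    out = ROOT / "results" / "model_free"
    out.mkdir(parents=True, exist_ok=True)
    files = sorted(cohort.glob("gaussian_*.csv"))[: args.max_subjects]
    if not files:
        raise SystemExit("no cohort files; run 01_simulate_cohort.py first")
    trials = [t for f in files for t in read_dataset(f, cfg)]
    print(f"{len(trials)} trials from {len(files)} subjects")

    slopes = pd.DataFrame(condition_slopes(trials, cfg))
    slopes.to_csv(out / "condition_slopes.csv", index=False)
    fig, ax = plt.subplots(figsize=(5, 4))
    for level, sub in slopes.groupby("cue_level"):
        ax.plot(sub["prior_sd"], sub["slope"], "o-", label=f"{level} cue")
        ax.plot(sub["prior_sd"], sub["optimal_weight"], "k--", alpha=0.5)
    ax.set_xlabel("prior SD (screen units)")
    ax.set_ylabel("cue weight (robust slope)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "cue_weights.png", dpi=130)
    plt.close(fig)
    print("cue weights vs optimal:")
    print(slopes[["prior_sd", "cue_level", "slope", "optimal_weight"]]
          .round(3).to_string(index=False))

    idx = pd.DataFrame(optimality_summary(trials[: 4 * 576], cfg))
    idx.to_csv(out / "optimality_index.csv", index=False)
    fig, ax = plt.subplots(figsize=(6, 4))
    for (session, level), sub in idx.groupby(["session", "cue_level"]):
        ax.plot(sub["prior_id"], sub["mean_index"], "o-",
                label=f"{session}/{level}")
        ax.plot(sub["prior_id"], sub["cue_only_index"], ":", alpha=0.6)
        ax.plot(sub["prior_id"], sub["prior_only_index"], "--", alpha=0.6)
    ax.set_xlabel("prior id")
    ax.set_ylabel("mean optimality index")
    ax.set_ylim(0, 1.05)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out / "optimality_index.png", dpi=130)
    plt.close(fig)

    # kernel-regression trend: per-trial optimality index vs posterior SD
    from bayesobs.gmm import max_success_probability, success_probability

    xs, ys = [], []
    for t in trials[:1500]:
        if t.edge_excluded or t.response_x is None:
            continue
        prior = t.prior.realized()
        sig = cfg.true_sigma(t.cue_level)
        post = posterior_update(prior, t.cue_x, sig)
        pmax = max_success_probability(prior, t.cue_x, sig, cfg.loss)
        if pmax <= 0:
            continue
        xs.append(float(np.sqrt(post.base.moments()[1])))
        ys.append(success_probability(prior, t.cue_x, sig, t.response_x,
                                      cfg.loss) / pmax)
    f, h = kernel_regression(np.asarray(xs), np.asarray(ys))
    grid = np.linspace(min(xs), max(xs), 50)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(xs, ys, ".", ms=2, alpha=0.3)
    ax.plot(grid, f(grid), "r-", lw=2)
    ax.set_xlabel("posterior SD (screen units)")
    ax.set_ylabel("optimality index")
    fig.tight_layout()
    fig.savefig(out / "index_vs_posterior_sd.png", dpi=130)
    plt.close(fig)
    print(f"kernel regression bandwidth (rule of thumb): {h:.4f}")
    print(f"grand mean optimality index: {idx['mean_index'].mean():.3f}")


if __name__ == "__main__":
    main()
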