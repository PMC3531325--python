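#!/usr/bin/env python
"""Cohort-level behavioral statistics.

Level-stratified investment trajectories, the earnings comparison across
fitted depth-of-thought levels (ANOVA + Tukey HSD), Fisher's exact test on
the investor level distributions induced by healthy vs uncooperative
trustees, and the chi-square test on the joint investor/trustee level table.
"""

import argparse
from pathlib import Path

import pandas as pd

from tomtrust.fitting import FitResult
from tomtrust.game import GameConfig
from tomtrust.io import read_exchange_log
from tomtrust.stats import (
    earnings_comparison,
    joint_classification_test,
    level_distribution_test,
    trajectory_summary,
)


def _as_fitresults(df: pd.DataFrame) -> list[FitResult]:
    return [
        FitResult(
            r.dyad_id, r.role, int(r.level), r.guilt, r.noise, r.loglik, [],
            r.baseline_loglik, 10,
        )
        for r in df.itertuples(index=False)
    ]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=str, default="results")
    args = ap.parse_args()
    cfg = GameConfig()
    out = Path(args.out)
    fits = pd.read_csv(out / "fits.tsv", sep="\t")
    inv = fits[fits.role == "investor"]

    healthy = read_exchange_log(out / "logs" / "healthy.tsv", cfg)
    h_inv = inv[inv.cohort == "healthy"].set_index("dyad_id")
    h_fits = _as_fitresults(h_inv.reset_index().assign(role="investor"))
    order = {f.dyad_id: f for f in h_fits}
    h_fits = [order[h.dyad_id] for h in healthy]

    traj = trajectory_summary(healthy, h_fits)
    traj.table.to_csv(out / "trajectories.tsv", sep="\t", index=False)

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for level, sub in traj.table.groupby("level"):
        ax.errorbar(
            sub["round"], sub["mean"], yerr=sub["se"], label=f"level {level}"
        )
    ax.set_xlabel("round")
    ax.set_ylabel("mean investment fraction")
    ax.set_ylim(0, 1)
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "trajectories.png", dpi=120)
    plt.close(fig)

    try:
        earn = earnings_comparison(healthy, h_fits)
        earn["tukey"].to_csv(out / "earnings_tukey.tsv", sep="\t", index=False)
        print(f"earnings ANOVA: F={earn['F']:.2f}, p={earn['p']:.3g}")
        for r in earn["tukey"].itertuples(index=False):
            print(
                f"  Tukey level {r.level_a} vs {r.level_b}: "
                f"diff {r.mean_diff:.1f} points, adjusted p={r.p_adj:.3g}"
            )
    except ValueError as exc:
        print(f"earnings comparison skipped: {exc}")

    counts = {}
    for cohort, sub in inv.groupby("cohort"):
        counts[cohort] = [int((sub.level == k).sum()) for k in (0, 1, 2)]
        print(f"{cohort}: level counts {counts[cohort]}")
    if set(counts) >= {"healthy", "uncooperative"}:
        p = level_distribution_test(counts["healthy"], counts["uncooperative"])
        print(f"Fisher's exact (healthy vs uncooperative level shift): p={p:.3g}")

    tru = fits[(fits.role == "trustee") & (fits.cohort == "healthy")]
    merged = h_inv.join(tru.set_index("dyad_id"), rsuffix="_tr").dropna(
        subset=["level_tr"]
    )
    try:
        jt = joint_classification_test(
            merged.level.astype(int), merged.level_tr.astype(int)
        )
        print(
            f"joint investor/trustee classification: chi2={jt['chi2']:.1f}, "
            f"dof={jt['dof']}, p={jt['p']:.3g}"
        )
    except ValueError as exc:
        print(f"joint classification test skipped: {exc}")


if __name__ == "__main__":
    main()
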