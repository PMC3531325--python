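"""End-to-end pipeline: simulate -> fit (ToM + RL) -> prediction errors ->
quintile contrasts -> cohort report, with a manifest for reproducibility.

Every artifact is delimited text regenerated bit-identically from the same
configuration and seed; the manifest records the configuration hash, the
seed and the per-stage outputs so any stage can be re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import classify_cohort
from .game import GameConfig, total_earnings
from .io import RunConfig, write_exchange_log
from .prediction_errors import extract_pe_series, membership_audit, quintile_split
from .rl import fit_rl
from .simulate import generate_cohort
from .stats import earnings_comparison, level_distribution_test, trajectory_summary

log = logging.getLogger("tomtrust.pipeline")

__all__ = ["run_pipeline"]


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _fits_frame(fits, rl_rows=None) -> pd.DataFrame:
    rows = []
    for f in fits:
        rows.append(
            {
                "dyad_id": f.dyad_id,
                "role": f.role,
                "level": f.best_level,
                "guilt": f.best_guilt,
                "noise": f.best_noise,
                "loglik": f.log_likelihood,
                "baseline_loglik": f.baseline_loglik,
                "identifiable": f.identifiable,
            }
        )
    df = pd.DataFrame(rows)
    if rl_rows is not None:
        df = df.merge(pd.DataFrame(rl_rows), on="dyad_id", how="left")
    return df


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the artifact bundle under ``out_dir``.

    Returns the manifest (also written as ``manifest.json``).
    """
    t_start = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    game = config.game
    manifest: dict = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": {},
    }

    def stage(name):
        log.info("stage %s ...", name)
        return time.time()

    # -- simulate -----------------------------------------------------------
    t0 = stage("simulate")
    histories = []
    for k, spec in enumerate(config.cohorts):
        spec = dataclasses.replace(spec, seed=spec.seed + config.seed)
        histories.extend(generate_cohort(spec, game))
    if not histories:
        raise RuntimeError("stage simulate: no cohorts configured")
    log_path = out / "exchange_log.tsv"
    write_exchange_log(histories, log_path, game)
    manifest["stages"]["simulate"] = {
        "n_dyads": len(histories),
        "output": str(log_path),
        "seconds": round(time.time() - t0, 2),
    }

    # -- fit ----------------------------------------------------------------
    t0 = stage("fit")
    table, fits = classify_cohort(histories, game, role="investor")
    rl_rows = []
    for h in histories:
        params, ll = fit_rl(h, "investor", game)
        rl_rows.append(
            {
                "dyad_id": h.dyad_id,
                "rl_loglik": ll,
                "rl_learning_rate": params.learning_rate,
                "rl_slope": params.slope,
                "rl_mixing": params.mixing,
                "rl_guilt": params.guilt,
            }
        )
    fits_df = _fits_frame(fits, rl_rows)
    fits_path = out / "fits.tsv"
    fits_df.to_csv(fits_path, sep="\t", index=False)
    table.counts.to_csv(out / "cohort_levels.tsv", sep="\t")
    manifest["stages"]["fit"] = {
        "output": str(fits_path),
        "mean_tom_loglik": float(fits_df["loglik"].mean()),
        "mean_rl_loglik": float(fits_df["rl_loglik"].mean()),
        "seconds": round(time.time() - t0, 2),
    }

    # -- prediction errors --------------------------------------------------
    t0 = stage("pe")
    pe_rows = []
    for h, f in zip(histories, fits):
        series = extract_pe_series(h, f.best_level, f.best_noise, game, f.best_guilt)
        for t in range(len(h.rounds)):
            pe_rows.append(
                {
                    "dyad_id": h.dyad_id,
                    "group": h.group_label,
                    "level": f.best_level,
                    "round": t + 1,
                    "pe1": series.pe1[t],
                    "pe2": series.pe2[t],
                }
            )
    pe_df = pd.DataFrame(pe_rows)
    quint = []
    for level, sub in pe_df.dropna(subset=["pe1"]).groupby("level"):
        labels = quintile_split(sub["pe1"].to_numpy(), sub["dyad_id"].to_numpy())
        q = sub[["dyad_id", "round"]].copy()
        q["quintile"] = labels.quintile
        q["pe1_group"] = labels.group
        quint.append(q)
    pe_df = pe_df.merge(
        pd.concat(quint, ignore_index=True), on=["dyad_id", "round"], how="left"
    )
    pe_path = out / "prediction_errors.tsv"
    pe_df.to_csv(pe_path, sep="\t", index=False)
    audits = {}
    for level, sub in pe_df.dropna(subset=["pe1"]).groupby("level"):
        labels = quintile_split(sub["pe1"].to_numpy(), sub["dyad_id"].to_numpy())
        audits[int(level)] = membership_audit(labels)
    manifest["stages"]["pe"] = {
        "output": str(pe_path),
        "n_rows": len(pe_df),
        "membership_audit": audits,
        "seconds": round(time.time() - t0, 2),
    }

    # -- report -------------------------------------------------------------
    t0 = stage("report")
    report: dict = {}
    traj = trajectory_summary(histories, fits)
    traj.table.to_csv(out / "trajectories.tsv", sep="\t", index=False)
    level_counts = fits_df["level"].value_counts().to_dict()
    if sum(1 for v in level_counts.values() if v >= 2) >= 2:
        earn = earnings_comparison(histories, fits)
        earn["tukey"].to_csv(out / "earnings_tukey.tsv", sep="\t", index=False)
        report["earnings_anova_F"] = earn["F"]
        report["earnings_anova_p"] = earn["p"]
    else:
        log.warning("skipping earnings tests: too few members per level")
    groups = fits_df.groupby(
        pd.Series([h.group_label for h in histories], name="group")
    )["level"]
    counts = {
        g: [int((lv == k).sum()) for k in (0, 1, 2)] for g, lv in groups
    }
    if len(counts) == 2:
        a, b = counts.values()
        report["fisher_p_level_distributions"] = level_distribution_test(a, b)
    elif len(counts) > 2:
        log.warning("more than two cohorts; skipping pairwise Fisher test")
    report["mean_total_earnings"] = float(
        np.mean([total_earnings(h)[0] for h in histories])
    )
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    manifest["stages"]["report"] = {
        "output": str(out / "report.json"),
        "seconds": round(time.time() - t0, 2),
    }

    manifest["total_seconds"] = round(time.time() - t_start, 2)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
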