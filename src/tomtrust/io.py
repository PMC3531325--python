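"""Exchange-log and configuration I/O.

The exchange-log format is delimited text (tab-separated), one row per
round: ``dyad_id, round (1-based), investment_amount`` (dollars),
``repayment_amount`` (dollars, empty on zero-investment rounds) and
``group_label``.  The reader discretizes raw dollar amounts onto the action
grids; the writer emits dollars, so logs round-trip bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from .game import (
    ExchangeHistory,
    GameConfig,
    discretize_amount,
    play_round,
)
from .simulate import CohortSpec

__all__ = [
    "read_exchange_log",
    "write_exchange_log",
    "RunConfig",
    "load_run_config",
]

_COLUMNS = ["dyad_id", "round", "investment_amount", "repayment_amount", "group_label"]


class ExchangeLogError(ValueError):
    """A malformed exchange-log file (reported with row numbers)."""


def write_exchange_log(
    histories: list[ExchangeHistory], path: str | Path, config: GameConfig
) -> None:
    rows = []
    for h in histories:
        for t, rnd in enumerate(h.rounds, start=1):
            inv_amt = rnd.investment_fraction * config.endowment
            if rnd.repayment_fraction is None:
                rep_amt = ""
            else:
                pot = config.multiplier * rnd.investment_fraction * config.endowment
                rep_amt = f"{rnd.repayment_fraction * pot:.6f}"
            rows.append((h.dyad_id, t, f"{inv_amt:.6f}", rep_amt, h.group_label))
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, sep="\t", index=False)


def read_exchange_log(path: str | Path, config: GameConfig) -> list[ExchangeHistory]:
    """Parse and validate an exchange log, discretizing onto the grids."""
    df = pd.read_csv(path, sep="\t", dtype={"dyad_id": str, "group_label": str})
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ExchangeLogError(f"missing columns: {missing}")
    df["group_label"] = df["group_label"].fillna("")
    histories: dict[str, ExchangeHistory] = {}
    errors: list[str] = []
    for pos, row in enumerate(df.itertuples(index=False), start=2):
        try:
            t = int(row.round)
            if not 1 <= t <= config.num_rounds:
                raise ValueError(f"round {t} outside 1..{config.num_rounds}")
            h = histories.setdefault(
                row.dyad_id, ExchangeHistory(row.dyad_id, [], row.group_label)
            )
            if t != len(h.rounds) + 1:
                raise ValueError(
                    f"non-consecutive round {t} (expected {len(h.rounds) + 1})"
                )
            inv_amt = float(row.investment_amount)
            inv = discretize_amount(inv_amt, config.endowment, config.investor_grid)
            rep_raw = row.repayment_amount
            has_rep = not (rep_raw is None or (isinstance(rep_raw, float) and pd.isna(rep_raw)) or str(rep_raw).strip() == "")
            if inv == 0.0:
                if has_rep:
                    raise ValueError("repayment reported on a zero investment")
                rep = None
            else:
                if not has_rep:
                    raise ValueError("missing repayment on a positive investment")
                pot = config.multiplier * inv * config.endowment
                rep = discretize_amount(float(rep_raw), pot, config.trustee_grid)
            h.rounds.append(play_round(inv, rep, config))
        except ValueError as exc:
            errors.append(f"line {pos}: {exc}")
    if errors:
        raise ExchangeLogError("; ".join(errors))
    return list(histories.values())


@dataclass
class RunConfig:
    """Validated top-level configuration for an end-to-end pipeline run."""

    game: GameConfig = field(default_factory=GameConfig)
    cohorts: list[CohortSpec] = field(default_factory=list)
    out_dir: str = "results/pipeline"
    seed: int = 0
    fit_trustees: bool = False


def _check_unknown(d: dict, cls, where: str) -> None:
    known = {f.name for f in fields(cls)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown keys in {where}: {sorted(unknown)}")


def load_run_config(path: str | Path) -> RunConfig:
    """Read a YAML run configuration; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    _check_unknown(raw, RunConfig, "run config")
    game_block = raw.get("game", {})
    _check_unknown(game_block, GameConfig, "game block")
    for key in ("investor_grid", "trustee_grid", "guilt_grid", "noise_grid"):
        if key in game_block:
            game_block[key] = tuple(game_block[key])
    game = GameConfig(**game_block)
    cohorts = []
    for i, cb in enumerate(raw.get("cohorts", [])):
        _check_unknown(cb, CohortSpec, f"cohorts[{i}]")
        for key in ("investor_level_proportions", "investor_guilt_mixture"):
            if key in cb:
                cb[key] = tuple(cb[key])
        cohorts.append(CohortSpec(**cb))
    return RunConfig(
        game=game,
        cohorts=cohorts,
        out_dir=raw.get("out_dir", "results/pipeline"),
        seed=raw.get("seed", 0),
        fit_trustees=raw.get("fit_trustees", False),
    )
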