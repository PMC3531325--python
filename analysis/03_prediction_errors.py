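#!/usr/bin/env python
"""Extract interpersonal prediction errors and the quintile contrast.

Replays each healthy-cohort history through its fitted investor model,
collects the first-order (repayment-reveal) and second-order
(investment-submission) prediction errors, pools them within each fitted
depth-of-thought level, splits them into quintiles, audits subject
membership in the high (>60%) and low (<=40%) groups, and reports the
high-minus-low contrast per level on the percent scale.
"""

import argparse
from pathlib import Path

import pandas as pd

from tomtrust.game import GameConfig
from tomtrust.io import read_exchange_log
from tomtrust.prediction_errors import (
    extract_pe_series,
    high_low_contrast,
    membership_audit,
    quintile_split,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=str, default="results")
    args = ap.parse_args()
    cfg = GameConfig()
    out = Path(args.out)
    fits = pd.read_csv(out / "fits.tsv", sep="\t")
    fits = fits[(fits.role == "investor") & (fits.cohort == "healthy")]
    fits = fits.set_index("dyad_id")
    histories = read_exchange_log(out / "logs" / "healthy.tsv", cfg)

    rows = []
    for h in histories:
        f = fits.loc[h.dyad_id]
        series = extract_pe_series(
            h, int(f.level), float(f.noise), cfg, float(f.guilt)
        )
        for t in range(len(h.rounds)):
            rows.append(
                {
                    "dyad_id": h.dyad_id,
                    "level": int(f.level),
                    "round": t + 1,
                    "event_pe1": "repayment_reveal",
                    "event_pe2": "investment_submission",
                    "pe1": series.pe1[t],
                    "pe2": series.pe2[t],
                }
            )
    pe = pd.DataFrame(rows)

    audit_rows, contrast_rows = [], []
    labeled = []
    for level, sub in pe.dropna(subset=["pe1"]).groupby("level"):
        labels = quintile_split(sub.pe1.to_numpy(), sub.dyad_id.to_numpy())
        sub = sub.assign(quintile=labels.quintile, pe1_group=labels.group)
        labeled.append(sub)
        audit = membership_audit(labels)
        audit_rows.append({"level": level, **audit})
        diff, se = high_low_contrast(sub.pe1.to_numpy(), labels)
        contrast_rows.append(
            {"level": level, "pe1_high_minus_low_pct": 100 * diff, "se_pct": 100 * se}
        )
    pe = pe.merge(
        pd.concat(labeled)[["dyad_id", "round", "quintile", "pe1_group"]],
        on=["dyad_id", "round"],
        how="left",
    )
    pe.to_csv(out / "prediction_errors.tsv", sep="\t", index=False)
    pd.DataFrame(audit_rows).to_csv(out / "pe_membership_audit.tsv", sep="\t", index=False)
    contrasts = pd.DataFrame(contrast_rows)
    contrasts.to_csv(out / "pe_contrasts.tsv", sep="\t", index=False)

    for r in audit_rows:
        print(
            f"level {r['level']}: {r['both']}/{r['total']} investors contribute to "
            f"both high and low PE groups"
        )
    for _, r in contrasts.iterrows():
        print(
            f"level {int(r.level)}: high-minus-low 1st-order PE "
            f"{r.pe1_high_minus_low_pct:.1f} (percent scale)"
        )


if __name__ == "__main__":
    main()
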