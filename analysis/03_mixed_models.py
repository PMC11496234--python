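#!/usr/bin/env python
"""Longitudinal course by diagnosis: random-intercept mixed models.

Fits one REML model per outcome (nine cognitive domain Z-scores and log10
CRP; sex/age covariates, plus BMI for CRP) and reports which domains change
over time and whether any time-by-group interaction survives Bonferroni.
"""

import argparse
from pathlib import Path

import pandas as pd

from inflamcog.lmm import fit_all_outcomes


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    work = pd.read_csv(args.results / "preprocessed.csv")
    _, table = fit_all_outcomes(work)
    table.to_csv(args.results / "lmm.tsv", sep="\t", index=False)

    time_rows = table[table["term"] == "time"].set_index("outcome")
    improving = time_rows[
        (time_rows["estimate"] > 0) & (time_rows["p_bonferroni"] < 0.05)
    ].index.tolist()
    print("domains improving over time (HC slope, Bonferroni-significant):")
    print(" ", improving or "none")
    crp = time_rows.loc["crp_log10"]
    print(
        f"CRP time effect: {crp['estimate']:+.3f} log10 mg/L "
        f"(p={crp['p']:.3f}) -> {'stable' if crp['p_bonferroni'] > 0.05 else 'changing'}"
    )
    inter = table[table["term"].str.startswith("time:group")]
    sig = inter[inter["p_bonferroni"] < 0.05]
    print(f"time-by-group interactions surviving Bonferroni: {len(sig)}")
    if len(sig):
        print(sig[["outcome", "term", "estimate", "p_bonferroni"]].to_string(index=False))


if __name__ == "__main__":
    main()
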