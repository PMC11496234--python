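#!/usr/bin/env python
"""Derive analysis variables: exclusions, Z-scores, composite, features.

Reads results/cohort.csv, applies the preprocessing chain (log10 CRP,
CRP>10 exclusion, HC-baseline Z-standardization, >=5-domain composite) and
writes the working table, the audit trail and the n x 2 clustering feature
matrix (log10 CRP, cognitive composite; unit-variance scaled).
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from inflamcog.pipeline import read_cohort_csv
from inflamcog.preprocess import preprocess


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    table = read_cohort_csv(args.results / "cohort.csv")
    work, audit, fm = preprocess(table)
    work.to_csv(args.results / "preprocessed.csv", index=False)
    with open(args.results / "preprocess_audit.json", "w") as fh:
        json.dump(audit, fh, indent=2, sort_keys=True)
    pd.DataFrame(fm.X, columns=list(fm.columns)).assign(
        participant_id=fm.participant_ids
    ).to_csv(args.results / "feature_matrix.csv", index=False)

    print(f"excluded for acute infection: {audit['excluded_acute_infection']}")
    print(f"complete-case clustering sample: n = {fm.n}")
    base = work[work["timepoint"] == 0]
    by_diag = base.groupby("diagnosis")["composite"].agg(["mean", "std", "count"])
    print("\nbaseline composite by diagnosis (HC-referenced s.d. units):")
    print(by_diag.round(2).to_string())

    from inflamcog.comparisons import diagnosis_comparisons

    char = diagnosis_comparisons(work, seed=0)
    char.to_csv(args.results / "sample_characteristics.tsv", sep="\t", index=False)
    omni = char[char["test"].isin(["kruskal_wallis", "chi_squared"])]
    print("\nbaseline characteristics across SZ/BD/HC (omnibus, Bonferroni):")
    print(
        omni[["variable", "test", "statistic", "p_bonferroni"]].round(4).to_string(index=False)
    )


if __name__ == "__main__":
    main()
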