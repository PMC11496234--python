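#!/usr/bin/env python
"""Validate the cluster solution: existence test and bootstrap stability.

The Gaussian-null simulation test asks whether the observed mean silhouette
could arise from a single multivariate Gaussian; bootstrap Jaccard asks
whether the same clusters reappear under resampling (>0.7 = stable).
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from inflamcog.cluster_validity import bootstrap_stability, gaussian_null_test
from inflamcog.rng import stage_rng


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--m-null", type=int, default=999)
    ap.add_argument("--b-boot", type=int, default=100)
    args = ap.parse_args()

    fmat = pd.read_csv(args.results / "feature_matrix.csv")
    X = fmat[["crp_log10", "composite"]].to_numpy()
    meta = json.loads((args.results / "clustering.json").read_text())
    k, linkage = meta["chosen_k"], meta["chosen_linkage"]

    null = gaussian_null_test(
        X, k, linkage, M=args.m_null, seed=args.seed, scale=False,
        rng=stage_rng(args.seed, "null_test"),
    )
    print(
        f"Gaussian-null test: observed mean silhouette "
        f"{null.observed_mean_silhouette:.3f}, p = {null.p_value:.4g} (M={null.M})"
    )
    stab = bootstrap_stability(
        X, k, linkage, B=args.b_boot, seed=args.seed, scale=False,
        rng=stage_rng(args.seed, "bootstrap"),
    )
    for c, (j, s) in enumerate(zip(stab.mean_jaccard, stab.stable), start=1):
        print(f"cluster {c}: mean Jaccard {j:.3f} -> {'stable' if s else 'NOT stable'}")

    with open(args.results / "validation.json", "w") as fh:
        json.dump(
            {
                "null_test": {
                    "observed_mean_silhouette": null.observed_mean_silhouette,
                    "p_value": null.p_value,
                    "M": null.M,
                    "seed": null.seed,
                },
                "stability": {
                    "mean_jaccard": [float(v) for v in stab.mean_jaccard],
                    "stable": [bool(v) for v in stab.stable],
                    "jaccard_trajectories": stab.jaccard_matrix.round(6).tolist(),
                    "B": stab.B,
                    "seed": stab.seed,
                },
            },
            fh, indent=2, sort_keys=True,
        )


if __name__ == "__main__":
    main()
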