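#!/usr/bin/env python
"""Discover inflammatory-cognitive subgroups by hierarchical clustering.

Builds the Euclidean distance matrix over (log10 CRP, composite), picks the
linkage by agglomerative coefficient, the number of clusters by average
silhouette, cuts the tree and writes labels plus the dendrogram exports.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from inflamcog.hclust import (
    DistanceMatrix,
    agglomerate,
    cluster_solution,
    select_k,
    select_linkage,
)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    fmat = pd.read_csv(args.results / "feature_matrix.csv")
    X = fmat[["crp_log10", "composite"]].to_numpy()
    ids = fmat["participant_id"].to_numpy()

    D = DistanceMatrix.from_points(X)
    linkage, ac = select_linkage(D)
    print("agglomerative coefficients:", {k: round(v, 4) for k, v in ac.items()})
    print(f"selected linkage: {linkage}")

    history = agglomerate(D, linkage)
    k, curve = select_k(D, history)
    print("mean silhouette by k:", {kk: round(v, 3) for kk, v in curve.items()})
    sol = cluster_solution(D, history, k)
    print(f"selected k = {k} (mean silhouette {sol.mean_silhouette:.3f})")

    labels = pd.Series(sol.labels, index=ids, name="cluster").rename_axis("participant_id")
    print("cluster sizes:", labels.value_counts().sort_index().to_dict())
    labels.to_frame().to_csv(args.results / "cluster_labels.tsv", sep="\t")
    with open(args.results / "clustering.json", "w") as fh:
        json.dump(
            {
                "ac_by_linkage": ac,
                "chosen_linkage": linkage,
                "silhouette_by_k": {str(kk): v for kk, v in curve.items()},
                "chosen_k": k,
                "mean_silhouette": sol.mean_silhouette,
            },
            fh, indent=2, sort_keys=True,
        )
    pd.DataFrame(
        history.to_merge_table(), columns=["child_a", "child_b", "height", "size"]
    ).to_csv(args.results / "dendrogram_merges.tsv", sep="\t", index=False)
    (args.results / "dendrogram.nwk").write_text(history.to_newick(list(ids)) + "\n")


if __name__ == "__main__":
    main()
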