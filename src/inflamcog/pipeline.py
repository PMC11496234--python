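"""End-to-end orchestration: simulate/ingest -> preprocess -> mixed models ->
cluster -> validate -> subgroup profile, with machine-readable reports.

Every randomized stage draws from its own seed-derived substream (see
:mod:`inflamcog.rng`), so the report is bit-identical under a fixed
(config, seed) pair and independent of unrelated stage settings.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from .cluster_validity import (
    NullTestResult,
    StabilityResult,
    adjusted_rand_index,
    bootstrap_stability,
    gaussian_null_test,
)
from .comparisons import subgroup_profile
from .config import COGNITIVE_DOMAINS, GeneratorConfig, PipelineConfig
from .hclust import (
    DistanceMatrix,
    agglomerate,
    cluster_solution,
    select_k,
    select_linkage,
)
from .lmm import fit_all_outcomes
from .preprocess import preprocess
from .rng import stage_rng

MANDATORY_COLUMNS = (
    "participant_id",
    "diagnosis",
    "timepoint",
    "sex",
    "age",
    "bmi",
    "crp",
) + COGNITIVE_DOMAINS


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunReport:
    """All stage outputs of one pipeline run (deterministic content only)."""

    config: dict
    seed: int
    exclusions: dict
    lmm_table: pd.DataFrame
    ac_by_linkage: Dict[str, float]
    chosen_linkage: str
    silhouette_by_k: Dict[int, float]
    chosen_k: int
    solution_labels: pd.Series
    cluster_sizes: Dict[int, int]
    mean_silhouette: float
    null_test: Optional[NullTestResult]
    stability: Optional[StabilityResult]
    profile: Optional[pd.DataFrame]
    merge_history: object
    feature_ids: np.ndarray
    ari_vs_truth: Optional[float] = None
    timings: Dict[str, float] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        """Canonical JSON form with deterministic numeric rounding."""

        def r(x, nd=12):
            if isinstance(x, float):
                return round(x, nd)
            return x

        d = {
            "config": self.config,
            "seed": self.seed,
            "exclusions": self.exclusions,
            "lmm": [
                {k: r(v) for k, v in row.items()}
                for row in self.lmm_table.to_dict("records")
            ],
            "clustering": {
                "ac_by_linkage": {k: r(v) for k, v in self.ac_by_linkage.items()},
                "chosen_linkage": self.chosen_linkage,
                "silhouette_by_k": {str(k): r(v) for k, v in self.silhouette_by_k.items()},
                "chosen_k": self.chosen_k,
                "cluster_sizes": {str(k): v for k, v in self.cluster_sizes.items()},
                "mean_silhouette": r(self.mean_silhouette),
            },
            "ari_vs_truth": r(self.ari_vs_truth) if self.ari_vs_truth is not None else None,
        }
        if self.null_test is not None:
            d["null_test"] = {
                "observed_mean_silhouette": r(self.null_test.observed_mean_silhouette),
                "p_value": r(self.null_test.p_value),
                "M": self.null_test.M,
                "seed": self.null_test.seed,
            }
        if self.stability is not None:
            d["stability"] = {
                "mean_jaccard": [r(float(v)) for v in self.stability.mean_jaccard],
                "stable": [bool(v) for v in self.stability.stable],
                "B": self.stability.B,
                "seed": self.stability.seed,
                "threshold": self.stability.threshold,
            }
        if self.profile is not None:
            d["profile"] = [
                {k: (r(v) if isinstance(v, float) else (None if pd.isna(v) else v)) for k, v in row.items()}
                for row in self.profile.to_dict("records")
            ]
        return d


def run_pipeline(
    config: PipelineConfig,
    table: Optional[pd.DataFrame] = None,
    latent: Optional[pd.DataFrame] = None,
    run_validation: bool = True,
    run_profile: bool = True,
    run_lmm: bool = True,
) -> RunReport:
    """Execute the full analysis in the canonical stage order."""
    timings: Dict[str, float] = {}
    t0 = time.perf_counter()

    if table is None:
        if config.cohort_csv is not None:
            table = read_cohort_csv(
                config.cohort_csv, detection_limit_rule=config.detection_limit_rule
            )
        else:
            gen = config.generator or GeneratorConfig(seed=config.seed)
            table, latent_assignments = cohort_mod.generate_cohort(gen)
            table = cohort_mod.inject_missingness(table, gen)
            latent = cohort_mod.latent_frame(latent_assignments)
    timings["input"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    try:
        work, audit, fm = preprocess(
            table,
            detection_limit_rule=config.detection_limit_rule,
            scale_features=config.scale_features,
        )
    except Exception as exc:
        raise PipelineError("preprocess", str(exc)) from exc
    timings["preprocess"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    lmm_table = pd.DataFrame()
    if run_lmm:
        try:
            _, lmm_table = fit_all_outcomes(
                work, bonferroni_family=config.lmm_bonferroni_family
            )
        except Exception as exc:
            raise PipelineError("lmm", str(exc)) from exc
    timings["lmm"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    D = DistanceMatrix.from_points(fm.X)
    if config.linkage is None:
        chosen_linkage, ac_table = select_linkage(D, config.ward_dialect)
    else:
        chosen_linkage, ac_table = config.linkage, select_linkage(D, config.ward_dialect)[1]
    history = agglomerate(D, chosen_linkage, config.ward_dialect)
    chosen_k, sil_curve = select_k(D, history, config.k_range)
    solution = cluster_solution(D, history, chosen_k)
    labels = pd.Series(solution.labels, index=fm.participant_ids, name="cluster")
    sizes = labels.value_counts().sort_index().to_dict()
    timings["cluster"] = time.perf_counter() - t0

    ari = None
    if latent is not None:
        truth = latent.set_index("participant_id")["true_subgroup"]
        common = labels.index.intersection(truth.index)
        ari = adjusted_rand_index(labels.loc[common], truth.loc[common])

    null_res = stab_res = None
    if run_validation:
        t0 = time.perf_counter()
        null_res = gaussian_null_test(
            fm.X,
            chosen_k,
            chosen_linkage,
            M=config.n_null_sim,
            seed=config.seed,
            ward_dialect=config.ward_dialect,
            scale=False,  # fm.X is already on the clustering scale
            covariance=config.null_covariance,
            reselect_k=config.reselect_k_in_null,
            rng=stage_rng(config.seed, "null_test"),
        )
        stab_res = bootstrap_stability(
            fm.X,
            chosen_k,
            chosen_linkage,
            B=config.n_bootstrap,
            seed=config.seed,
            ward_dialect=config.ward_dialect,
            scale=False,
            rng=stage_rng(config.seed, "bootstrap"),
        )
        timings["validate"] = time.perf_counter() - t0

    profile = None
    if run_profile:
        if (
            run_validation
            and null_res is not None
            and null_res.p_value > config.alpha
            and not config.force_profile
        ):
            raise PipelineError(
                "profile",
                f"Gaussian-null test did not reject (p={null_res.p_value:.4f} > "
                f"alpha={config.alpha}); pass force_profile/--force to profile anyway",
            )
        t0 = time.perf_counter()
        profile = subgroup_profile(work, labels, alpha=config.alpha)
        timings["profile"] = time.perf_counter() - t0

    return RunReport(
        config=config.to_dict(),
        seed=config.seed,
        exclusions=audit,
        lmm_table=lmm_table,
        ac_by_linkage=ac_table,
        chosen_linkage=chosen_linkage,
        silhouette_by_k=sil_curve,
        chosen_k=chosen_k,
        solution_labels=labels,
        cluster_sizes={int(k): int(v) for k, v in sizes.items()},
        mean_silhouette=solution.mean_silhouette,
        null_test=null_res,
        stability=stab_res,
        profile=profile,
        merge_history=history,
        feature_ids=fm.participant_ids,
        ari_vs_truth=ari,
        timings=timings,
    )


def read_cohort_csv(
    path: str | Path, detection_limit_rule: bool = False
) -> pd.DataFrame:
    """Read a long-format cohort CSV, validating the column dictionary.

    Unknown columns produce a warning; missing mandatory columns and
    duplicated (participant, timepoint) pairs are fatal. CRP must be
    non-negative mg/L (or a "<L" censored string when the detection-limit
    rule is enabled).
    """
    df = pd.read_csv(path, dtype={"participant_id": str})
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise PipelineError("read", f"missing mandatory columns: {missing}")
    known = {name for name, _ in cohort_mod.COHORT_COLUMNS} | {"crp_log10", "composite"}
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        warnings.warn(f"ignoring unknown columns: {unknown}")
    dup = df.duplicated(subset=["participant_id", "timepoint"], keep=False)
    if dup.any():
        dupes = df.loc[dup, ["participant_id", "timepoint"]].drop_duplicates()
        raise PipelineError(
            "read", f"duplicated (participant, timepoint) rows: {dupes.to_dict('records')}"
        )
    crp = df["crp"]
    numeric = pd.to_numeric(crp, errors="coerce")
    censored = crp.astype(str).str.strip().str.startswith("<") & crp.notna()
    if not detection_limit_rule and censored.any():
        raise PipelineError(
            "read", "censored CRP values present; enable the detection-limit rule"
        )
    bad = numeric.notna() & (numeric < 0)
    if bad.any():
        raise PipelineError("read", "negative CRP values present")
    if not censored.any():
        df["crp"] = numeric
    return df


def write_cohort_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def write_report(report: RunReport, out_dir: str | Path) -> List[Path]:
    """Write the JSON report, stage TSVs, dendrogram exports and timing file."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    p = out / "report.json"
    with open(p, "w") as fh:
        json.dump(report.to_json_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append(p)

    if len(report.lmm_table):
        p = out / "lmm.tsv"
        report.lmm_table.to_csv(p, sep="\t", index=False)
        written.append(p)
    if report.profile is not None and len(report.profile):
        p = out / "subgroup_profile.tsv"
        report.profile.to_csv(p, sep="\t", index=False)
        written.append(p)

    p = out / "cluster_labels.tsv"
    report.solution_labels.rename_axis("participant_id").to_frame().to_csv(
        p, sep="\t"
    )
    written.append(p)

    hist = report.merge_history
    p = out / "dendrogram_merges.tsv"
    pd.DataFrame(
        hist.to_merge_table(), columns=["child_a", "child_b", "height", "size"]
    ).to_csv(p, sep="\t", index=False)
    written.append(p)
    p = out / "dendrogram.nwk"
    p.write_text(hist.to_newick(list(report.feature_ids)) + "\n")
    written.append(p)

    p = out / "timings.json"  # wall-clock; intentionally outside report.json
    with open(p, "w") as fh:
        json.dump(report.timings, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append(p)
    return written
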