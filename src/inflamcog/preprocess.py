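"""Derivation of analysis variables from the raw cohort table.

Order of operations in the pipeline: log10-transform CRP, exclude
acute-infection participants (CRP > 10 mg/L at either visit), Z-standardize
the nine cognitive domains against the healthy-control baseline mean and
s.d., form the cognitive composite (mean of available domain Z-scores,
requiring at least five non-missing baseline domains), and assemble the
complete-case baseline feature matrix (log10 CRP, composite) for clustering.

The HC-baseline reference is applied to all rows - both groups, both
visits - so follow-up scores are expressed on the same scale and
longitudinal change is interpretable.
"""

from __future__ import annotations

import numbers
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .config import COGNITIVE_DOMAINS

Z_PREFIX = "z_"
ACUTE_INFECTION_CRP = 10.0  # mg/L, strict inequality
MIN_BASELINE_DOMAINS = 5


class PreprocessError(ValueError):
    pass


def log10_crp(
    table: pd.DataFrame, detection_limit_rule: bool = False
) -> pd.DataFrame:
    """Add a ``crp_log10`` column; missing CRP propagates.

    With ``detection_limit_rule`` enabled, string values of the form ``"<L"``
    (below the assay detection limit) are mapped to L/2 before the transform,
    a common laboratory convention. Non-positive numeric CRP is an error.
    """
    out = table.copy()
    crp = out["crp"]
    if detection_limit_rule and crp.dtype == object:
        def _parse(v):
            if isinstance(v, str) and v.strip().startswith("<"):
                return float(v.strip()[1:]) / 2.0
            return v
        crp = crp.map(_parse)
    crp = pd.to_numeric(crp, errors="raise")
    bad = crp.notna() & (crp <= 0)
    if bad.any():
        raise PreprocessError(
            f"non-positive CRP for rows {list(out.index[bad][:5])}; "
            "enable the detection-limit rule for censored values"
        )
    out["crp"] = crp
    out["crp_log10"] = np.log10(crp)
    return out


def exclude_acute_infection(
    table: pd.DataFrame, threshold: float = ACUTE_INFECTION_CRP
) -> Tuple[pd.DataFrame, List[str]]:
    """Drop every row of any participant with CRP > threshold at either visit.

    Missing CRP at a visit never triggers exclusion. Returns the filtered
    table and the sorted excluded participant ids. Idempotent.
    """
    flagged = table.loc[table["crp"] > threshold, "participant_id"]
    excluded = sorted(flagged.unique())
    kept = table[~table["participant_id"].isin(excluded)].reset_index(drop=True)
    return kept, excluded


def standardize_cognition(
    table: pd.DataFrame,
) -> Tuple[pd.DataFrame, Dict[str, Tuple[float, float]]]:
    """Z-score every cognitive domain against the HC baseline mean and s.d.

    The reference is computed once from healthy-control baseline rows and
    applied to all rows; it is returned for audit. Uses the ddof=1 sample s.d.
    """
    out = table.copy()
    hc0 = out[(out["diagnosis"] == "HC") & (out["timepoint"] == 0)]
    reference: Dict[str, Tuple[float, float]] = {}
    for d in COGNITIVE_DOMAINS:
        vals = hc0[d].dropna()
        if len(vals) < 2:
            raise PreprocessError(f"need >=2 HC baseline observations for {d}")
        mu, sd = float(vals.mean()), float(vals.std(ddof=1))
        if sd == 0.0:
            raise PreprocessError(f"zero HC baseline s.d. for domain {d}")
        reference[d] = (mu, sd)
        out[Z_PREFIX + d] = (out[d] - mu) / sd
    return out, reference


def cognitive_composite(table: pd.DataFrame) -> pd.DataFrame:
    """Mean of available domain Z-scores per participant-visit.

    A participant needs at least five non-missing baseline domains for any
    composite; the same reliability floor is applied to the follow-up visit
    itself, so a sparse follow-up assessment yields a missing follow-up
    composite rather than an unreliable one.
    """
    zcols = [Z_PREFIX + d for d in COGNITIVE_DOMAINS]
    missing = [c for c in zcols if c not in table.columns]
    if missing:
        raise PreprocessError(f"Z-columns absent (run standardize_cognition): {missing}")
    out = table.copy()
    z = out[zcols]
    n_avail = z.notna().sum(axis=1)
    comp = z.mean(axis=1)  # mean of available
    comp[n_avail < MIN_BASELINE_DOMAINS] = np.nan

    base_ok = (
        out.loc[out["timepoint"] == 0]
        .set_index("participant_id")[zcols]
        .notna()
        .sum(axis=1)
        >= MIN_BASELINE_DOMAINS
    )
    ok = out["participant_id"].map(base_ok).fillna(False).astype(bool)
    comp[~ok] = np.nan
    out["composite"] = comp
    return out


@dataclass
class FeatureMatrix:
    """Complete-case baseline clustering features (log10 CRP, composite)."""

    participant_ids: np.ndarray
    X: np.ndarray  # (n, 2)
    columns: Tuple[str, str] = ("crp_log10", "composite")
    scaling: Optional[Dict[str, Dict[str, float]]] = field(default=None)

    @property
    def n(self) -> int:
        return self.X.shape[0]


def build_feature_matrix(
    table: pd.DataFrame, scale: bool = True, min_n: int = 10
) -> FeatureMatrix:
    """Baseline rows with both features present, ordered by participant id.

    With ``scale=True`` (default) each column is centered and scaled to unit
    variance before Euclidean distances are taken downstream; the applied
    centers/scales are recorded so the choice is auditable. Raw log10 CRP
    spans roughly one unit while the composite spans several s.d., so
    unscaled Euclidean distance would weight the two features unequally.
    """
    base = table[table["timepoint"] == 0]
    keep = base["crp_log10"].notna() & base["composite"].notna()
    base = base.loc[keep].sort_values("participant_id", kind="stable")
    if len(base) < min_n:
        raise PreprocessError(
            f"only {len(base)} complete-case participants; clustering not meaningful"
        )
    X = base[["crp_log10", "composite"]].to_numpy(dtype=float)
    scaling = None
    if scale:
        center = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise PreprocessError("zero variance in a clustering feature")
        X = (X - center) / sd
        scaling = {
            col: {"center": float(center[i]), "scale": float(sd[i])}
            for i, col in enumerate(("crp_log10", "composite"))
        }
    return FeatureMatrix(
        participant_ids=base["participant_id"].to_numpy(),
        X=X,
        scaling=scaling,
    )


def preprocess(
    table: pd.DataFrame,
    detection_limit_rule: bool = False,
    scale_features: bool = True,
):
    """Full preprocessing chain; returns (table, audit dict, FeatureMatrix)."""
    t = log10_crp(table, detection_limit_rule=detection_limit_rule)
    t, excluded = exclude_acute_infection(t)
    t, reference = standardize_cognition(t)
    t = cognitive_composite(t)
    fm = build_feature_matrix(t, scale=scale_features)
    audit = {
        "excluded_acute_infection": list(excluded),
        "hc_baseline_reference": {d: {"mean": m, "sd": s} for d, (m, s) in reference.items()},
        "n_feature_matrix": int(fm.n),
        "feature_scaling": fm.scaling,
    }
    return t, audit, fm
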