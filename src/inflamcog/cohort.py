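"""Synthetic longitudinal cohort generator.

Emulates a two-visit case-control cohort (schizophrenia-spectrum SZ,
bipolar-spectrum BD, healthy controls HC) carrying a latent transdiagnostic
two-subgroup mixture that jointly shifts systemic inflammation (CRP) and
cognition. Subgroup 2 is the higher-inflammation / lower-cognition phenotype
and is more prevalent in SZ than BD than HC.

Model for the cognitive score of participant i, domain d, visit j:

    Y_idj = offset(diag_i) + shift_cog * (z_i - pbar(diag_i))
            + b_i + practice * 1[j=1, d in P] + e_idj

where z_i in {0,1} indicates latent subgroup 2, b_i ~ N(0, sigma_b^2) is a
person intercept shared across domains and visits, and e_idj ~ N(0,
sigma_e^2). The subgroup shift is centered within diagnosis (pbar is the
configured subgroup-2 probability), so each diagnosis's marginal mean equals
its configured offset exactly: the subgroup structure redistributes
individuals around the group mean rather than moving it. This mirrors the
reported cohort, where SZ scores ~1 s.d. below HC while CRP shows no
case-control difference even though subgroup membership is strongly
diagnosis-dependent.

log10 CRP is generated per person (near-constant across visits, small visit
noise), with a BMI slope and the centered subgroup-2 shift; values are
back-transformed to mg/L and may exceed the 10 mg/L acute-infection bound so
that the downstream exclusion rule is exercised.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
import pandas as pd

from .config import (
    CLINICAL_SCALES,
    COGNITIVE_DOMAINS,
    DIAGNOSES,
    ConfigurationError,
    GeneratorConfig,
)
from .rng import stage_rng

CLINICAL_COLUMNS = tuple(CLINICAL_SCALES)

#: Columns of the long-format cohort table, in write order.
COHORT_COLUMNS = (
    ("participant_id", "stable identifier, P0001..."),
    ("diagnosis", "SZ | BD | HC"),
    ("timepoint", "0 = baseline, 1 = follow-up"),
    ("visit_day", "days since baseline"),
    ("sex", "F | M"),
    ("age", "years at baseline"),
    ("bmi", "kg/m^2"),
    ("crp", "C-reactive protein, mg/L"),
    *[(d, "cognitive domain score, s.d. units") for d in COGNITIVE_DOMAINS],
    *[(c, "clinical score (SMI rows only)") for c in CLINICAL_COLUMNS],
)

_SEX_FEMALE_PROB = {"SZ": 0.40, "BD": 0.58, "HC": 0.52}
_AGE_MEAN = {"SZ": 27.0, "BD": 30.0, "HC": 31.0}
_AGE_SD = {"SZ": 8.0, "BD": 9.0, "HC": 8.5}
_BMI_MEAN = {"SZ": 25.5, "BD": 25.5, "HC": 24.5}
_BMI_SD = {"SZ": 4.2, "BD": 4.2, "HC": 3.5}


@dataclass(frozen=True)
class LatentAssignment:
    """Ground-truth latent state for one generated participant."""

    participant_id: str
    true_subgroup: int  # 1 or 2
    person_intercept: float


def generate_cohort(
    config: GeneratorConfig,
) -> Tuple[pd.DataFrame, List[LatentAssignment]]:
    """Generate a complete (pre-missingness) long-format cohort.

    Returns one row per participant per timepoint plus the latent subgroup
    assignment of every participant. Deterministic under ``config.seed``.
    """
    config.validate()
    rng = stage_rng(config.seed, "cohort")

    diag_list, n_total = [], 0
    for g in DIAGNOSES:
        diag_list += [g] * config.n_by_group[g]
        n_total += config.n_by_group[g]
    diagnosis = np.array(diag_list)
    pid = np.array([f"P{i + 1:04d}" for i in range(n_total)])

    p_sg2 = np.array([config.subgroup2_prob_by_group[g] for g in diagnosis])
    z = (rng.random(n_total) < p_sg2).astype(float)  # 1 -> subgroup 2
    b = rng.normal(0.0, config.person_intercept_sd, n_total)
    u_crp = rng.normal(0.0, config.logcrp_person_sd, n_total)

    sex = np.where(
        rng.random(n_total) < np.array([_SEX_FEMALE_PROB[g] for g in diagnosis]),
        "F",
        "M",
    )
    age = np.clip(
        rng.normal(
            [_AGE_MEAN[g] for g in diagnosis], [_AGE_SD[g] for g in diagnosis]
        ),
        18.0,
        65.0,
    ).round(1)
    bmi = np.clip(
        rng.normal(
            [_BMI_MEAN[g] for g in diagnosis], [_BMI_SD[g] for g in diagnosis]
        ),
        16.0,
        45.0,
    ).round(1)
    # Uniform window centered on the configured mean gap, inside the
    # 6-month..1.5-year follow-up corridor.
    gap = rng.uniform(
        config.followup_gap_days_mean - 150.0,
        config.followup_gap_days_mean + 150.0,
        n_total,
    ).round(0)

    offsets = np.array([config.domain_offsets[g] for g in diagnosis])
    centered = z - p_sg2  # centered subgroup indicator
    cog_mean = offsets + config.subgroup2_cognition_shift * centered + b  # (n,)

    logcrp_person = (
        config.baseline_logcrp_mean
        + config.subgroup2_logcrp_shift * centered
        + config.bmi_logcrp_slope * (bmi - 25.0)
        + u_crp
    )

    is_smi = diagnosis != "HC"
    practice = np.array(
        [d in config.practice_effect_domains for d in COGNITIVE_DOMAINS], dtype=float
    )

    frames = []
    for j in (0, 1):
        scores = (
            cog_mean[:, None]
            + config.practice_effect_size * practice[None, :] * j
            + rng.normal(0.0, config.residual_sd, (n_total, len(COGNITIVE_DOMAINS)))
        )
        logcrp = logcrp_person + rng.normal(0.0, config.logcrp_visit_sd, n_total)
        row = {
            "participant_id": pid,
            "diagnosis": diagnosis,
            "timepoint": j,
            "visit_day": (gap * j).astype(float),
            "sex": sex,
            "age": age,
            "bmi": bmi,
            "crp": np.round(10.0 ** logcrp, 4),
        }
        for d_idx, d in enumerate(COGNITIVE_DOMAINS):
            row[d] = np.round(scores[:, d_idx], 4)
        for scale, (m1, m2, sd, dt, lo, hi) in CLINICAL_SCALES.items():
            sg_gap = (m2 - m1) * config.clinical_subgroup_effect
            mean = m1 + sg_gap * z + dt * j
            vals = np.clip(rng.normal(mean, sd), lo, hi).round(1)
            row[scale] = np.where(is_smi, vals, np.nan)
        frames.append(pd.DataFrame(row))

    table = (
        pd.concat(frames, ignore_index=True)
        .sort_values(["participant_id", "timepoint"], kind="stable")
        .reset_index(drop=True)
    )
    latent = [
        LatentAssignment(pid[i], int(z[i]) + 1, float(b[i])) for i in range(n_total)
    ]
    return table, latent


def inject_missingness(table: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    """Blank cognitive-domain cells and CRP values completely at random.

    Each domain cell is independently set missing with
    ``config.missing_domain_prob`` and each CRP value with
    ``config.missing_crp_prob``. Deterministic under ``config.seed`` and
    independent of the generation stream.
    """
    for name in ("missing_domain_prob", "missing_crp_prob"):
        p = getattr(config, name)
        if not 0.0 <= p <= 1.0:
            raise ConfigurationError(f"{name}={p} outside [0, 1]")
    rng = stage_rng(config.seed, "missingness")
    out = table.copy()
    n = len(out)
    mask = rng.random((n, len(COGNITIVE_DOMAINS))) < config.missing_domain_prob
    for d_idx, d in enumerate(COGNITIVE_DOMAINS):
        out.loc[mask[:, d_idx], d] = np.nan
    out.loc[rng.random(n) < config.missing_crp_prob, "crp"] = np.nan
    return out


def latent_frame(latent: List[LatentAssignment]) -> pd.DataFrame:
    """Latent assignments as a DataFrame (for CSV export and joins)."""
    return pd.DataFrame(
        {
            "participant_id": [a.participant_id for a in latent],
            "true_subgroup": [a.true_subgroup for a in latent],
            "person_intercept": [a.person_intercept for a in latent],
        }
    )
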