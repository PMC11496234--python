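"""Configuration objects for cohort generation and the analysis pipeline."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import yaml

DIAGNOSES = ("SZ", "BD", "HC")

COGNITIVE_DOMAINS = (
    "fine_motor_speed",
    "psychomotor_speed",
    "mental_speed",
    "attention",
    "verbal_learning",
    "verbal_memory",
    "semantic_fluency",
    "working_memory",
    "cognitive_control",
)

#: Clinical scales simulated for SMI participants only.
#: name -> (subgroup-1 mean, subgroup-2 mean, s.d., follow-up change, lower, upper)
#: The disorganized factor has zero change over time by design (it is the
#: scale reported to remain stable); GAF improves (positive change), symptom
#: scales improve (negative change).
CLINICAL_SCALES: Mapping[str, tuple] = {
    "panss_positive": (12.0, 14.0, 4.0, -3.0, 4.0, 28.0),
    "panss_negative": (13.0, 16.0, 5.0, -2.0, 6.0, 42.0),
    "panss_disorganized": (6.0, 7.5, 2.0, 0.0, 3.0, 21.0),
    "panss_excited": (7.0, 8.0, 2.5, -1.0, 4.0, 28.0),
    "panss_depressed": (7.0, 8.5, 3.0, -1.5, 3.0, 21.0),
    "ymrs": (5.0, 6.5, 4.0, -1.5, 0.0, 60.0),
    "gaf_s": (55.0, 48.0, 10.0, 7.0, 1.0, 100.0),
    "gaf_f": (52.0, 45.0, 10.0, 6.0, 1.0, 100.0),
}


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


def _freeze(mapping: Mapping) -> dict:
    return dict(mapping)


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic longitudinal cohort generator.

    The defaults encode the cohort structure of a two-visit first-treatment
    severe-mental-illness sample with healthy controls: group sizes
    SZ=133/BD=88/HC=220, a latent two-subgroup mixture whose subgroup 2
    (higher inflammation - lower cognition) has mixing probability 0.75 in
    SZ, 0.48 in BD and 0.38 in HC, diagnosis-level cognitive offsets of
    -1.0 s.d. (SZ) and -0.5 s.d. (BD) against HC, a -1.0 s.d. cognition /
    +0.35 log10 mg/L CRP subgroup-2 shift, practice effects on four domains
    at follow-up, and a follow-up visit ~400 days after baseline.
    """

    n_by_group: Mapping[str, int] = field(
        default_factory=lambda: {"SZ": 133, "BD": 88, "HC": 220}
    )
    subgroup2_prob_by_group: Mapping[str, float] = field(
        default_factory=lambda: {"SZ": 0.75, "BD": 0.48, "HC": 0.38}
    )
    domain_offsets: Mapping[str, float] = field(
        default_factory=lambda: {"SZ": -1.0, "BD": -0.5, "HC": 0.0}
    )
    subgroup2_cognition_shift: float = -1.0
    subgroup2_logcrp_shift: float = 0.35
    practice_effect_domains: frozenset = frozenset(
        {"fine_motor_speed", "psychomotor_speed", "verbal_learning", "cognitive_control"}
    )
    practice_effect_size: float = 0.2
    #: scales the subgroup-2 minus subgroup-1 gap of every clinical scale;
    #: 0 removes all latent-subgroup structure from the clinical scores
    clinical_subgroup_effect: float = 1.0
    person_intercept_sd: float = 0.3
    residual_sd: float = 0.8
    baseline_logcrp_mean: float = 0.18
    logcrp_person_sd: float = 0.12
    logcrp_visit_sd: float = 0.08
    bmi_logcrp_slope: float = 0.02
    missing_domain_prob: float = 0.02
    missing_crp_prob: float = 0.03
    followup_gap_days_mean: float = 400.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.n_by_group = _freeze(self.n_by_group)
        self.subgroup2_prob_by_group = _freeze(self.subgroup2_prob_by_group)
        self.domain_offsets = _freeze(self.domain_offsets)
        self.practice_effect_domains = frozenset(self.practice_effect_domains)
        self.validate()

    def validate(self) -> None:
        for g in DIAGNOSES:
            if g not in self.n_by_group:
                raise ConfigurationError(f"missing group count for {g}")
            if self.n_by_group[g] <= 0:
                raise ConfigurationError(f"non-positive count for group {g}")
            p = self.subgroup2_prob_by_group.get(g)
            if p is None or not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"subgroup-2 probability for {g} outside [0, 1]")
        for name in ("missing_domain_prob", "missing_crp_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name}={p} outside [0, 1]")
        for name in (
            "person_intercept_sd",
            "residual_sd",
            "logcrp_person_sd",
            "logcrp_visit_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        unknown = self.practice_effect_domains - set(COGNITIVE_DOMAINS)
        if unknown:
            raise ConfigurationError(f"unknown practice-effect domains: {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["practice_effect_domains"] = sorted(self.practice_effect_domains)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        return cls(**dict(d))


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings (input, clustering, validation, output)."""

    generator: Optional[GeneratorConfig] = None
    cohort_csv: Optional[str] = None
    scale_features: bool = True
    linkage: Optional[str] = None  # None -> select by agglomerative coefficient
    ward_dialect: str = "ward.D2"
    k_range: Sequence[int] = tuple(range(2, 9))
    n_null_sim: int = 999
    n_bootstrap: int = 100
    n_perm: int = 10_000
    alpha: float = 0.05
    null_covariance: str = "full"  # or "diagonal"
    reselect_k_in_null: bool = False
    detection_limit_rule: bool = False
    lmm_bonferroni_family: str = "outcomes"
    force_profile: bool = False
    seed: int = 0
    output_dir: str = "results"

    def __post_init__(self) -> None:
        self.k_range = tuple(int(k) for k in self.k_range)
        if self.generator is None and self.cohort_csv is None:
            self.generator = GeneratorConfig(seed=self.seed)
        if not self.k_range:
            raise ConfigurationError("k_range must be non-empty")
        if self.linkage is not None and self.linkage not in (
            "single",
            "complete",
            "average",
            "ward",
        ):
            raise ConfigurationError(f"unknown linkage {self.linkage!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.generator is not None:
            d["generator"] = self.generator.to_dict()
        d["k_range"] = list(self.k_range)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        gen = d.get("generator")
        if gen is not None and not isinstance(gen, GeneratorConfig):
            d["generator"] = GeneratorConfig.from_dict(gen)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), fh, sort_keys=True)
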