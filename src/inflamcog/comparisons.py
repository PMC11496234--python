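"""Group-comparison battery.

Covers the tests used for diagnosis contrasts (Kruskal-Wallis, pairwise
permutation t tests, chi-squared) and subgroup contrasts (Welch t with
Cohen's d, chi-squared for composition, Wilcoxon signed-rank time effects
with the r effect size, change scores, Bonferroni correction), plus the
subgroup profile driver that assembles the battery for a cluster solution.

Conventions: effect sizes are signed group1 - group2; Cohen's d uses the
(n-1)-weighted pooled s.d. by default (a Welch-style denominator is
available); chi-squared is Pearson without continuity correction; the
permutation test shuffles group labels jointly and uses the Welch t
statistic with the add-one Monte-Carlo p-value.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .config import CLINICAL_SCALES, COGNITIVE_DOMAINS
from .preprocess import Z_PREFIX


class ComparisonError(ValueError):
    pass


@dataclass
class ComparisonResult:
    variable: str
    grouping: str
    test: str
    statistic: float
    p_raw: float
    df: Optional[float] = None
    p_bonferroni: Optional[float] = None
    effect_size: Optional[float] = None
    effect_size_name: Optional[str] = None
    effect_ci: Optional[Tuple[float, float]] = None
    group_summaries: Optional[Dict[str, Dict[str, float]]] = None
    timepoint: Optional[int] = None
    family: Optional[str] = None

    def to_row(self) -> dict:
        row = {
            "variable": self.variable,
            "grouping": self.grouping,
            "timepoint": self.timepoint,
            "test": self.test,
            "statistic": self.statistic,
            "df": self.df,
            "p_raw": self.p_raw,
            "p_bonferroni": self.p_bonferroni,
            "effect_size": self.effect_size,
            "effect_size_name": self.effect_size_name,
            "family": self.family,
        }
        if self.effect_ci is not None:
            row["effect_ci_low"], row["effect_ci_high"] = self.effect_ci
        if self.group_summaries:
            for g, s in self.group_summaries.items():
                for stat_name, v in s.items():
                    row[f"{g}_{stat_name}"] = v
        return row


def cohens_d(
    x: np.ndarray, y: np.ndarray, denominator: str = "pooled"
) -> Tuple[float, Tuple[float, float]]:
    """Signed d = (mean_x - mean_y) / s with a 95% normal-approximation CI."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    if denominator == "pooled":
        s2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
        s = math.sqrt(s2)
    elif denominator == "welch":
        s = math.sqrt((x.var(ddof=1) + y.var(ddof=1)) / 2.0)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if s == 0:
        raise ComparisonError("zero variance in both samples")
    d = (x.mean() - y.mean()) / s
    se = math.sqrt((nx + ny) / (nx * ny) + d * d / (2.0 * (nx + ny - 2)))
    return d, (d - 1.96 * se, d + 1.96 * se)


def welch_t(
    x: Sequence[float],
    y: Sequence[float],
    variable: str = "",
    grouping: str = "",
    d_denominator: str = "pooled",
) -> ComparisonResult:
    """Welch two-sample t test with Cohen's d (sign: x - y)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ComparisonError("each sample needs n >= 2")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        raise ComparisonError("both samples have zero variance")
    res = stats.ttest_ind(x, y, equal_var=False)
    d, ci = cohens_d(x, y, d_denominator)
    return ComparisonResult(
        variable=variable,
        grouping=grouping,
        test="welch_t",
        statistic=float(res.statistic),
        df=float(res.df),
        p_raw=float(res.pvalue),
        effect_size=d,
        effect_size_name="cohens_d",
        effect_ci=ci,
        group_summaries={
            "group1": {"mean": float(x.mean()), "sd": float(x.std(ddof=1)), "n": len(x)},
            "group2": {"mean": float(y.mean()), "sd": float(y.std(ddof=1)), "n": len(y)},
        },
    )


def kruskal_wallis(
    groups: Sequence[Sequence[float]], variable: str = "", grouping: str = ""
) -> ComparisonResult:
    """Kruskal-Wallis H with midrank tie correction, chi-squared reference."""
    groups = [np.asarray(g, float) for g in groups]
    if any(len(g) == 0 for g in groups):
        raise ComparisonError("empty group")
    if sum(len(g) for g in groups) < 3:
        raise ComparisonError("need total n >= 3")
    res = stats.kruskal(*groups)
    return ComparisonResult(
        variable=variable,
        grouping=grouping,
        test="kruskal_wallis",
        statistic=float(res.statistic),
        df=float(len(groups) - 1),
        p_raw=float(res.pvalue),
    )


def _welch_stat(x: np.ndarray, y: np.ndarray) -> float:
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    denom = math.sqrt(vx / len(x) + vy / len(y))
    if denom == 0:
        return 0.0
    return (x.mean() - y.mean()) / denom


def pairwise_permutation_t(
    groups: Dict[str, Sequence[float]],
    n_perm: int = 10_000,
    seed: int = 0,
    rng: Optional[np.random.Generator] = None,
    bonferroni_adjust: bool = False,
    exhaustive: bool = False,
) -> pd.DataFrame:
    """Two-sided permutation p for the Welch t statistic, for each group pair.

    Monte-Carlo p uses the add-one rule p = (1 + #{|t*| >= |t|}) / (n_perm+1);
    with ``exhaustive=True`` all label assignments are enumerated instead and
    p is the exact proportion. A pair that is constant across both groups
    gets p = 1 with a warning.
    """
    if not exhaustive and n_perm < 99:
        raise ComparisonError("n_perm must be >= 99")
    if rng is None:
        rng = np.random.default_rng(seed)
    names = list(groups)
    rows = []
    for g1, g2 in itertools.combinations(names, 2):
        x = np.asarray(groups[g1], float)
        y = np.asarray(groups[g2], float)
        pooled = np.concatenate([x, y])
        n1 = len(x)
        if np.ptp(pooled) == 0:
            warnings.warn(f"degenerate pair ({g1}, {g2}): all values identical")
            rows.append({"group1": g1, "group2": g2, "t_obs": 0.0, "p": 1.0})
            continue
        t_obs = _welch_stat(x, y)
        if exhaustive:
            hits = total = 0
            for idx in itertools.combinations(range(len(pooled)), n1):
                mask = np.zeros(len(pooled), bool)
                mask[list(idx)] = True
                t_star = _welch_stat(pooled[mask], pooled[~mask])
                hits += abs(t_star) >= abs(t_obs) - 1e-12
                total += 1
            p = hits / total
        else:
            order = np.argsort(rng.random((n_perm, len(pooled))), axis=1)
            shuffled = pooled[order]
            xs, ys = shuffled[:, :n1], shuffled[:, n1:]
            vx, vy = xs.var(axis=1, ddof=1), ys.var(axis=1, ddof=1)
            denom = np.sqrt(vx / n1 + vy / (len(pooled) - n1))
            with np.errstate(divide="ignore", invalid="ignore"):
                t_star = np.where(
                    denom > 0, (xs.mean(axis=1) - ys.mean(axis=1)) / denom, 0.0
                )
            p = (1.0 + np.sum(np.abs(t_star) >= abs(t_obs) - 1e-12)) / (n_perm + 1.0)
        rows.append({"group1": g1, "group2": g2, "t_obs": t_obs, "p": p})
    out = pd.DataFrame(rows)
    if bonferroni_adjust and len(out):
        out["p_bonferroni"] = np.minimum(1.0, out["p"] * len(out))
    return out


def chi_squared(
    table: np.ndarray, variable: str = "", grouping: str = ""
) -> ComparisonResult:
    """Pearson chi-squared on an r x c count table, no continuity correction."""
    table = np.asarray(table, float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ComparisonError("zero marginal in contingency table")
    res = stats.chi2_contingency(table, correction=False)
    if (res.expected_freq <= 0).any():
        raise ComparisonError("expected count <= 0")
    return ComparisonResult(
        variable=variable,
        grouping=grouping,
        test="chi_squared",
        statistic=float(res.statistic),
        df=float(res.dof),
        p_raw=float(res.pvalue),
    )


def wilcoxon_signed_rank(
    y0: Sequence[float],
    y1: Sequence[float],
    variable: str = "",
    grouping: str = "",
) -> ComparisonResult:
    """Wilcoxon signed-rank test on paired differences y1 - y0.

    Exact p for n <= 25 without ties; otherwise the normal approximation
    with continuity correction. The effect size r = |Z| / sqrt(n_pairs) is
    always computed from the normal-approximation deviate over all pairs
    (including zero differences in n_pairs), matching the convention that
    reports r alongside exact p-values.
    """
    y0 = np.asarray(y0, float)
    y1 = np.asarray(y1, float)
    if y0.shape != y1.shape:
        raise ComparisonError("paired samples differ in length")
    diff = y1 - y0
    nz = diff[diff != 0]
    m = len(nz)
    if m == 0:
        raise ComparisonError("all paired differences are zero")
    ranks = stats.rankdata(np.abs(nz))
    w_plus = float(ranks[nz > 0].sum())
    has_ties = len(np.unique(np.abs(nz))) < m
    method = "exact" if (m <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(
        y1, y0, zero_method="wilcox", correction=True, method=method
    )
    mu = m * (m + 1) / 4.0
    tie_counts = np.unique(ranks, return_counts=True)[1]
    sigma2 = m * (m + 1) * (2 * m + 1) / 24.0 - np.sum(
        tie_counts ** 3 - tie_counts
    ) / 48.0
    if w_plus == mu or sigma2 <= 0:
        z = 0.0
    else:
        z = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / math.sqrt(sigma2)
    r = abs(z) / math.sqrt(len(diff))
    return ComparisonResult(
        variable=variable,
        grouping=grouping,
        test=f"wilcoxon_signed_rank[{method}]",
        statistic=w_plus,
        p_raw=float(res.pvalue),
        effect_size=r,
        effect_size_name="wilcoxon_r",
        group_summaries={
            "diff": {"mean": float(diff.mean()), "sd": float(diff.std(ddof=1)) if len(diff) > 1 else 0.0, "n": len(diff)}
        },
    )


def rank_sum(
    x: Sequence[float], y: Sequence[float], variable: str = "", grouping: str = ""
) -> ComparisonResult:
    """Wilcoxon rank-sum (Mann-Whitney) contrast with effect size r."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    n = len(x) + len(y)
    mu = len(x) * len(y) / 2.0
    ranks = stats.rankdata(np.concatenate([x, y]))
    tie_counts = np.unique(ranks, return_counts=True)[1]
    sigma2 = (
        len(x) * len(y) / 12.0 * (n + 1 - np.sum(tie_counts ** 3 - tie_counts) / (n * (n - 1)))
    )
    z = 0.0 if sigma2 <= 0 else (res.statistic - mu) / math.sqrt(sigma2)
    return ComparisonResult(
        variable=variable,
        grouping=grouping,
        test="wilcoxon_rank_sum",
        statistic=float(res.statistic),
        p_raw=float(res.pvalue),
        effect_size=abs(z) / math.sqrt(n),
        effect_size_name="wilcoxon_r",
    )


def change_scores(
    table: pd.DataFrame, variable: str
) -> Tuple[pd.Series, List[str]]:
    """Per-participant follow-up minus baseline; lists excluded participants."""
    wide = table.pivot_table(
        index="participant_id", columns="timepoint", values=variable, aggfunc="first",
        dropna=False,
    )
    for tp in (0, 1):
        if tp not in wide.columns:
            wide[tp] = np.nan
    delta = wide[1] - wide[0]
    excluded = sorted(delta.index[delta.isna()])
    return delta.dropna().rename(f"delta_{variable}"), excluded


def bonferroni(p_values: Sequence[float], m: Optional[int] = None) -> np.ndarray:
    """min(1, m * p) with m defaulting to the number of p-values."""
    p = np.asarray(p_values, float)
    if ((p < 0) | (p > 1)).any():
        raise ComparisonError("p-values outside [0, 1]")
    if m is None:
        m = len(p)
    return np.minimum(1.0, m * p)


def diagnosis_comparisons(
    table: pd.DataFrame,
    variables: Sequence[str] = ("age", "bmi", "crp_log10", "composite"),
    n_perm: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Baseline sample-characteristics battery across SZ/BD/HC.

    Continuous variables get a Kruskal-Wallis omnibus plus pairwise
    permutation t tests (Bonferroni over the three pairs); sex gets a
    chi-squared. Returns a tidy table mirroring a baseline-characteristics
    layout.
    """
    base = table[table["timepoint"] == 0]
    rows: List[dict] = []
    rng = np.random.default_rng(seed)
    for var in variables:
        if var not in base.columns:
            continue
        groups = {
            g: base.loc[base["diagnosis"] == g, var].dropna().to_numpy()
            for g in ("SZ", "BD", "HC")
        }
        groups = {g: v for g, v in groups.items() if len(v) >= 2}
        if len(groups) < 2:
            continue
        omni = kruskal_wallis(list(groups.values()), variable=var, grouping="diagnosis")
        row = omni.to_row()
        for g, v in groups.items():
            row[f"{g}_mean"], row[f"{g}_sd"], row[f"{g}_n"] = (
                float(np.mean(v)), float(np.std(v, ddof=1)), len(v),
            )
        rows.append(row)
        pw = pairwise_permutation_t(groups, n_perm=n_perm, rng=rng, bonferroni_adjust=True)
        for pr in pw.to_dict("records"):
            rows.append(
                {
                    "variable": var,
                    "grouping": f"{pr['group1']}_vs_{pr['group2']}",
                    "test": "permutation_t",
                    "statistic": pr["t_obs"],
                    "p_raw": pr["p"],
                    "p_bonferroni": pr.get("p_bonferroni"),
                }
            )
    counts = pd.crosstab(base["diagnosis"], base["sex"])
    if counts.shape[0] >= 2 and (counts.to_numpy().sum(axis=1) > 0).all():
        rows.append(chi_squared(counts.to_numpy(), variable="sex", grouping="diagnosis").to_row())
    out = pd.DataFrame(rows)
    omnibus = out["test"].isin(["kruskal_wallis", "chi_squared"])
    m = int(omnibus.sum())
    out.loc[omnibus, "p_bonferroni"] = bonferroni(out.loc[omnibus, "p_raw"], m)
    return out


# ---------------------------------------------------------------------------
# Subgroup profile battery
# ---------------------------------------------------------------------------

_PROFILE_CONTINUOUS = ("crp_log10", "composite") + tuple(
    Z_PREFIX + d for d in COGNITIVE_DOMAINS
)
_PROFILE_BASELINE_ONLY = ("age", "bmi")
_PROFILE_CLINICAL = tuple(CLINICAL_SCALES)


def subgroup_profile(
    table: pd.DataFrame,
    labels: pd.Series,
    alpha: float = 0.05,
    family_mode: str = "single",
) -> pd.DataFrame:
    """Compare the two clusters across the full characteristics battery.

    ``labels`` maps participant_id -> cluster (1 or 2). Continuous variables
    (inflammation, composite, the nine domains, clinical scales for SMI
    rows) are contrasted by Welch t / Cohen's d at each visit; demographics
    at baseline; sex and diagnosis composition by chi-squared. Variables
    with sustained subgroup differences (Bonferroni-significant at both
    visits) are followed up longitudinally: within-subgroup Wilcoxon
    signed-rank time effects and a between-subgroup rank-sum contrast on the
    change score. With ``family_mode="single"`` (default) the Bonferroni
    correction spans the whole cross-sectional battery; "per_timepoint"
    corrects each visit's family separately. The longitudinal follow-ups
    always form their own family.
    """
    df = table.copy()
    df["cluster"] = df["participant_id"].map(labels)
    df = df[df["cluster"].notna()]
    df["cluster"] = df["cluster"].astype(int)

    results: List[ComparisonResult] = []

    def _split(sub: pd.DataFrame, var: str):
        x = sub.loc[sub["cluster"] == 1, var].dropna().to_numpy()
        y = sub.loc[sub["cluster"] == 2, var].dropna().to_numpy()
        return x, y

    for tp in (0, 1):
        sub = df[df["timepoint"] == tp]
        vars_tp = list(_PROFILE_CONTINUOUS) + list(_PROFILE_CLINICAL)
        if tp == 0:
            vars_tp += list(_PROFILE_BASELINE_ONLY)
        for var in vars_tp:
            if var not in sub.columns:
                continue
            x, y = _split(sub, var)
            if len(x) < 2 or len(y) < 2:
                warnings.warn(f"skipping {var} at t={tp}: a cluster has n < 2")
                continue
            try:
                r = welch_t(x, y, variable=var, grouping="cluster")
            except ComparisonError as exc:
                warnings.warn(f"skipping {var} at t={tp}: {exc}")
                continue
            r.timepoint = tp
            r.family = "cross_sectional" if family_mode == "single" else f"t{tp}"
            results.append(r)

    base = df[df["timepoint"] == 0]
    for var in ("sex", "diagnosis"):
        counts = pd.crosstab(base["cluster"], base[var])
        if counts.shape[0] == 2 and (counts.to_numpy() > 0).all(axis=None):
            r = chi_squared(counts.to_numpy(), variable=var, grouping="cluster")
            r.timepoint = 0
            r.family = "cross_sectional" if family_mode == "single" else "t0"
            results.append(r)

    # Bonferroni within cross-sectional families
    fams: Dict[str, List[ComparisonResult]] = {}
    for r in results:
        fams.setdefault(r.family, []).append(r)
    for fam_results in fams.values():
        adj = bonferroni([r.p_raw for r in fam_results])
        for r, pa in zip(fam_results, adj):
            r.p_bonferroni = float(pa)

    # Sustained differences -> longitudinal follow-up battery
    sig: Dict[str, set] = {}
    for r in results:
        if r.test == "welch_t" and r.p_bonferroni is not None and r.p_bonferroni < alpha:
            sig.setdefault(r.variable, set()).add(r.timepoint)
    sustained = sorted(v for v, tps in sig.items() if tps >= {0, 1})

    longitudinal: List[ComparisonResult] = []
    for var in sustained:
        wide = df.pivot_table(
            index="participant_id", columns="timepoint", values=var, aggfunc="first"
        )
        wide["cluster"] = wide.index.map(labels)
        complete = wide.dropna(subset=[0, 1])
        for cl in (1, 2):
            part = complete[complete["cluster"] == cl]
            if len(part) < 2 or (part[1] - part[0]).abs().sum() == 0:
                continue
            r = wilcoxon_signed_rank(
                part[0].to_numpy(), part[1].to_numpy(),
                variable=var, grouping=f"time_within_cluster{cl}",
            )
            r.family = "longitudinal"
            longitudinal.append(r)
        d1 = (complete.loc[complete["cluster"] == 1, 1] - complete.loc[complete["cluster"] == 1, 0])
        d2 = (complete.loc[complete["cluster"] == 2, 1] - complete.loc[complete["cluster"] == 2, 0])
        if len(d1) >= 2 and len(d2) >= 2:
            r = rank_sum(
                d1.to_numpy(), d2.to_numpy(), variable=f"delta_{var}", grouping="cluster"
            )
            r.family = "longitudinal"
            longitudinal.append(r)
    if longitudinal:
        adj = bonferroni([r.p_raw for r in longitudinal])
        for r, pa in zip(longitudinal, adj):
            r.p_bonferroni = float(pa)
    results.extend(longitudinal)

    return pd.DataFrame([r.to_row() for r in results])
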