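"""Random-intercept linear mixed models fitted by REML.

The model for outcome Y of participant i at visit j is

    Y_ij = x_ij' beta + b_i + e_ij,   b_i ~ N(0, sigma_b^2),  e_ij ~ N(0, sigma_e^2)

with a single random intercept per participant (compound symmetry within
participant). Estimation profiles everything onto the variance ratio
lambda = sigma_b^2 / sigma_e^2: for fixed lambda the GLS estimate of beta
and the REML estimate of sigma_e^2 are closed-form, so the REML criterion is
maximized by a 1-D bounded search on log(lambda) in [-12, 12]. The
log-ratio parameterization keeps both variances positive by construction;
the lower boundary returns sigma_b^2 = 0 (the OLS limit).

Inference is by normal-approximation Wald tests (z = beta/se against the
standard normal); no Satterthwaite/Kenward-Roger degrees of freedom.
Time is a 0/1 factor and the diagnostic group enters as BD/SZ dummies with
HC the reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .config import COGNITIVE_DOMAINS
from .preprocess import Z_PREFIX

LOG_LAMBDA_BOUNDS = (-12.0, 12.0)
_XATOL = 1e-9


class LmmError(RuntimeError):
    pass


@dataclass
class LmmSpec:
    """Fixed-effect layout for one outcome."""

    outcome: str
    covariates: Tuple[str, ...] = ("age", "sex")
    group: str = "diagnosis"
    reference: str = "HC"
    time: str = "timepoint"
    grouping: str = "participant_id"


@dataclass
class DesignBundle:
    y: np.ndarray
    X: np.ndarray
    columns: List[str]
    participant_index: np.ndarray  # 0..g-1 codes aligned with rows
    participant_ids: np.ndarray
    n_obs: int
    n_participants: int
    outcome: str


def build_design(table: pd.DataFrame, spec: LmmSpec) -> DesignBundle:
    """Listwise-complete response vector and full-rank fixed-effect matrix.

    Participants contributing a single visit are retained. Group dummies use
    the configured reference level; each non-reference level also gets a
    time-interaction column.
    """
    cols = [spec.outcome, spec.time, spec.group, spec.grouping, *spec.covariates]
    df = table[cols].dropna().reset_index(drop=True)
    if df.empty:
        raise LmmError(f"no complete rows for outcome {spec.outcome}")

    time = df[spec.time].astype(float).to_numpy()
    if not set(np.unique(time)) <= {0.0, 1.0}:
        raise LmmError("time must be coded 0/1")

    parts: Dict[str, np.ndarray] = {"intercept": np.ones(len(df)), "time": time}
    levels = [l for l in sorted(df[spec.group].unique()) if l != spec.reference]
    for lev in levels:
        ind = (df[spec.group] == lev).astype(float).to_numpy()
        parts[f"group[{lev}]"] = ind
    for lev in levels:
        parts[f"time:group[{lev}]"] = time * parts[f"group[{lev}]"]
    for cov in spec.covariates:
        v = df[cov]
        if v.dtype == object or str(v.dtype) == "category":
            lv = sorted(v.unique())
            for l in lv[1:]:
                parts[f"{cov}[{l}]"] = (v == l).astype(float).to_numpy()
        else:
            parts[cov] = v.astype(float).to_numpy()

    X = np.column_stack(list(parts.values()))
    columns = list(parts)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # small |R| diagonal entries point at the collinear columns
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        bad = [columns[i] for i in np.argsort(diag)[: X.shape[1] - rank]]
        raise LmmError(f"rank-deficient design; collinear terms near {bad}")

    ids, codes = np.unique(df[spec.grouping].to_numpy(), return_inverse=True)
    return DesignBundle(
        y=df[spec.outcome].astype(float).to_numpy(),
        X=X,
        columns=columns,
        participant_index=codes,
        participant_ids=ids,
        n_obs=len(df),
        n_participants=len(ids),
        outcome=spec.outcome,
    )


@dataclass
class LmmFit:
    outcome: str
    columns: List[str]
    beta: np.ndarray
    se_beta: np.ndarray
    sigma2_b: float
    sigma2_e: float
    reml_loglik: float
    n_obs: int
    n_participants: int
    wald_z: np.ndarray = field(default=None)
    p: np.ndarray = field(default=None)
    boundary: bool = False
    log_lambda: float = float("nan")

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.columns,
                "estimate": self.beta,
                "se": self.se_beta,
                "z": self.wald_z,
                "p": self.p,
            }
        )


def _profiled_pieces(y, X, group_idx, group_sizes, lam):
    """GLS quantities for V = sigma_e^2 (I + lambda * J) per participant."""
    c = lam / (1.0 + group_sizes * lam)  # (g,)
    gy = np.bincount(group_idx, weights=y, minlength=len(group_sizes))
    Gx = np.empty((len(group_sizes), X.shape[1]))
    for j in range(X.shape[1]):
        Gx[:, j] = np.bincount(group_idx, weights=X[:, j], minlength=len(group_sizes))
    XtWX = X.T @ X - (Gx * c[:, None]).T @ Gx
    XtWy = X.T @ y - Gx.T @ (c * gy)
    yWy = y @ y - c @ (gy ** 2)
    beta = np.linalg.solve(XtWX, XtWy)
    rss = yWy - beta @ XtWy
    return beta, rss, XtWX


def fit_reml(design: DesignBundle) -> LmmFit:
    """Maximize the REML criterion over log(lambda) and return the fit."""
    y, X = design.y, design.X
    gi = design.participant_index
    sizes = np.bincount(gi).astype(float)
    if np.sum(sizes >= 2) < 2:
        raise LmmError(
            "variance ratio unidentifiable: need >=2 participants with 2 visits"
        )
    n, p = X.shape

    def neg2_restricted(loglam: float) -> float:
        lam = np.exp(loglam)
        _, rss, XtWX = _profiled_pieces(y, X, gi, sizes, lam)
        rss = max(rss, 1e-300)
        sign, logdet = np.linalg.slogdet(XtWX)
        if sign <= 0:
            return np.inf
        return (
            (n - p) * np.log(rss)
            + np.sum(np.log1p(sizes * lam))
            + logdet
        )

    res = optimize.minimize_scalar(
        neg2_restricted,
        bounds=LOG_LAMBDA_BOUNDS,
        method="bounded",
        options={"xatol": _XATOL},
    )
    if not res.success:
        raise LmmError(f"REML search failed: {res.message}; criterion {res.fun}")
    loglam = float(res.x)
    boundary = loglam <= LOG_LAMBDA_BOUNDS[0] + 1e-6 or loglam >= LOG_LAMBDA_BOUNDS[1] - 1e-6
    lam = 0.0 if loglam <= LOG_LAMBDA_BOUNDS[0] + 1e-6 else float(np.exp(loglam))

    beta, rss, XtWX = _profiled_pieces(y, X, gi, sizes, lam)
    sigma2_e = max(rss, 0.0) / (n - p)
    boundary = boundary or sigma2_e < 1e-12
    sigma2_b = lam * sigma2_e
    cov_beta = np.linalg.inv(XtWX) * sigma2_e if sigma2_e > 0 else np.zeros((p, p))
    se = np.sqrt(np.diag(cov_beta))

    sign, logdet = np.linalg.slogdet(XtWX)
    if sigma2_e > 0:
        reml_loglik = -0.5 * (
            (n - p) * (np.log(2 * np.pi) + np.log(sigma2_e) + 1.0)
            + np.sum(np.log1p(sizes * lam))
            + logdet
        )
    else:
        reml_loglik = np.inf

    fit = LmmFit(
        outcome=design.outcome,
        columns=design.columns,
        beta=beta,
        se_beta=se,
        sigma2_b=float(sigma2_b),
        sigma2_e=float(sigma2_e),
        reml_loglik=float(reml_loglik),
        n_obs=n,
        n_participants=design.n_participants,
        boundary=boundary,
        log_lambda=loglam if lam > 0 else -np.inf,
    )
    fit.wald_z, fit.p = wald_tests(fit)
    return fit


def wald_tests(fit: LmmFit) -> Tuple[np.ndarray, np.ndarray]:
    """Per-coefficient z = beta/se and two-sided standard-normal p."""
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(fit.se_beta > 0, fit.beta / fit.se_beta, np.inf * np.sign(fit.beta))
        z = np.where(fit.beta == 0, 0.0, z)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return z, p


def fit_all_outcomes(
    table: pd.DataFrame,
    outcomes: Optional[Sequence[str]] = None,
    bonferroni_family: str = "outcomes",
) -> Tuple[Dict[str, "LmmFit | Exception"], pd.DataFrame]:
    """One fit per outcome: the nine domain Z-scores plus log10 CRP.

    The CRP model adds BMI to the covariates. Per-outcome failures are
    captured, not raised, so one degenerate outcome cannot abort the batch.
    Returns the fits and a tidy results table with Bonferroni-adjusted
    p-values; with the default family ("outcomes") each coefficient's p is
    adjusted by the number of successfully fitted outcomes.
    """
    if outcomes is None:
        outcomes = [Z_PREFIX + d for d in COGNITIVE_DOMAINS] + ["crp_log10"]
    fits: Dict[str, LmmFit | Exception] = {}
    for out in outcomes:
        cov = ("age", "sex", "bmi") if out == "crp_log10" else ("age", "sex")
        try:
            fits[out] = fit_reml(build_design(table, LmmSpec(outcome=out, covariates=cov)))
        except Exception as exc:  # propagate per-outcome, keep the batch
            fits[out] = exc

    ok = {o: f for o, f in fits.items() if isinstance(f, LmmFit)}
    m = len(ok) if bonferroni_family == "outcomes" else None
    rows = []
    for out, f in ok.items():
        for i, term in enumerate(f.columns):
            m_eff = m if m is not None else len(f.columns)
            rows.append(
                {
                    "outcome": out,
                    "term": term,
                    "estimate": f.beta[i],
                    "se": f.se_beta[i],
                    "z": f.wald_z[i],
                    "p": f.p[i],
                    "p_bonferroni": min(1.0, m_eff * f.p[i]),
                    "sigma2_b": f.sigma2_b,
                    "sigma2_e": f.sigma2_e,
                    "n": f.n_obs,
                }
            )
    return fits, pd.DataFrame(rows)
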