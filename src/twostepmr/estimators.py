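"""Mendelian randomization estimators.

One-sample: two-stage least squares (2SLS) with a genetic risk score as the
instrument, and the Durbin score form of the Durbin-Wu-Hausman endogeneity
test.  Two-sample: per-SNP Wald ratios pooled by the inverse-variance
weighted (IVW) method with Cochran's Q heterogeneity.  Cross-cohort pooling:
fixed-effect and DerSimonian-Laird random-effects meta-analysis.  Power for
a continuous outcome follows the standard non-centrality approximation
``z = beta * sqrt(n * r2_gx)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "MrEstimate",
    "MetaResult",
    "tsls_estimate",
    "durbin_wu_hausman",
    "wald_ratio",
    "ivw_combine",
    "cochran_q",
    "meta_analyze",
    "mr_power",
    "detectable_effect",
]


@dataclass
class MrEstimate:
    """A causal effect estimate with its uncertainty and provenance.

    ``beta`` is in outcome units per exposure unit; ``exp(beta)`` is the
    odds ratio when the outcome side is a log-odds scale.  Heterogeneity
    fields (Q, Q_df, Q_p) are populated for multi-SNP pooled estimates.
    """

    beta: float
    se: float
    p: float
    method: str
    n: int | None = None
    n_snps: int | None = None
    first_stage_F: float | None = None
    Q: float | None = None
    Q_df: int | None = None
    Q_p: float | None = None

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError(f"se must be positive, got {self.se}")

    @property
    def ci(self) -> tuple[float, float]:
        """95% Wald confidence interval on the beta scale."""
        return (self.beta - 1.959963984540054 * self.se, self.beta + 1.959963984540054 * self.se)

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.beta)


@dataclass
class MetaResult:
    """Pooled cross-cohort (or cross-SNP) estimate.

    ``weights`` are normalized to sum to 1; for the fixed model the pooled
    beta is exactly their weighted average of the inputs.
    """

    beta: float
    se: float
    p: float
    model: str
    weights: np.ndarray = field(default_factory=lambda: np.array([]))
    Q: float | None = None
    Q_df: int | None = None
    Q_p: float | None = None
    tau2: float | None = None

    @property
    def ci(self) -> tuple[float, float]:
        return (self.beta - 1.959963984540054 * self.se, self.beta + 1.959963984540054 * self.se)


def _design(n: int, *cols) -> np.ndarray:
    parts = [np.ones(n)]
    for c in cols:
        if c is None:
            continue
        c = np.asarray(c, dtype=float)
        parts.append(c[:, None] if c.ndim == 1 else c)
    return np.column_stack(parts)


def _complete_rows(*arrays) -> np.ndarray:
    mask = None
    for a in arrays:
        if a is None:
            continue
        a = np.asarray(a, dtype=float)
        m = np.isfinite(a) if a.ndim == 1 else np.all(np.isfinite(a), axis=1)
        mask = m if mask is None else (mask & m)
    return mask


def _ols(X: np.ndarray, y: np.ndarray):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, resid


def tsls_estimate(outcome, exposure, instrument, covariates=None) -> MrEstimate:
    """Two-stage least squares with classical IV standard errors.

    Stage 1 regresses the exposure on the instrument(s) plus covariates;
    stage 2 regresses the outcome on the fitted exposure plus covariates.
    The residual variance for the SE uses stage-2 coefficients with the
    *observed* exposure (the classical IV variance), not the stage-2 OLS
    residuals.  The first-stage partial F-statistic for the instrument(s)
    is reported as the instrument-strength diagnostic.

    Parameters
    ----------
    outcome, exposure : array-like, length n
    instrument : array-like, length n or (n, k)
        One or more instruments (typically a weighted genetic risk score).
    covariates : array-like (n, c), optional
        Exogenous covariates included in both stages.

    Returns
    -------
    MrEstimate
        method ``"2SLS"``; beta in outcome units per exposure unit.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(exposure, dtype=float)
    z = np.asarray(instrument, dtype=float)
    if z.ndim == 1:
        z = z[:, None]
    cov = None if covariates is None else np.asarray(covariates, dtype=float)
    if cov is not None and cov.ndim == 1:
        cov = cov[:, None]
    mask = _complete_rows(y, x, z, cov)
    y, x, z = y[mask], x[mask], z[mask]
    cov = None if cov is None else cov[mask]
    n = len(y)
    if n < 30:
        raise ValueError(f"2SLS requires n >= 30, got {n}")
    if np.var(z, axis=0).min() <= 0:
        raise ValueError("instrument has zero variance")

    # stage 1: exposure on [1, Z, C]
    X1 = _design(n, z, cov)
    b1, v_hat = _ols(X1, x)
    x_hat = X1 @ b1
    # restricted stage-1 model without the instruments, for the partial F
    X1r = _design(n, cov)
    _, r_resid = _ols(X1r, x)
    k = z.shape[1]
    rss_full = float(v_hat @ v_hat)
    rss_restr = float(r_resid @ r_resid)
    df_resid1 = n - X1.shape[1]
    if rss_full <= 0:
        # exogenous limit: the instrument spans the exposure exactly
        F = float("inf")
    else:
        F = max((rss_restr - rss_full) / k, 0.0) / (rss_full / df_resid1)
    if F < 1e-6:
        raise ValueError(f"weak-instrument degenerate fit: first-stage F = {F:.3g}")

    # stage 2: outcome on [1, x_hat, C]
    X2 = _design(n, x_hat, cov)
    b2, _ = _ols(X2, y)
    # classical IV variance: residuals with the observed exposure
    W = _design(n, x, cov)
    iv_resid = y - W @ b2
    df2 = n - X2.shape[1]
    sigma2 = float(iv_resid @ iv_resid) / df2
    XtX_inv = np.linalg.inv(X2.T @ X2)
    se = math.sqrt(sigma2 * XtX_inv[1, 1])
    beta = float(b2[1])
    t = beta / se
    p = 2.0 * stats.t.sf(abs(t), df2)
    return MrEstimate(beta=beta, se=se, p=float(p), method="2SLS", n=n, first_stage_F=float(F))


def durbin_wu_hausman(outcome, exposure, instrument, covariates=None):
    """Durbin score form of the Durbin-Wu-Hausman endogeneity test.

    Control-function construction: the first-stage residuals ``v_hat`` are
    appended to the outcome-side regressors, and the statistic is ``n * R^2``
    from the auxiliary regression of the OLS residuals on
    ``[1, exposure, covariates, v_hat]``, referred to chi-square(1) for one
    endogenous regressor.  Asymptotically this agrees with the t-test on the
    ``v_hat`` coefficient.

    Returns
    -------
    (statistic, df, p)
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(exposure, dtype=float)
    z = np.asarray(instrument, dtype=float)
    if z.ndim == 1:
        z = z[:, None]
    cov = None if covariates is None else np.asarray(covariates, dtype=float)
    if cov is not None and cov.ndim == 1:
        cov = cov[:, None]
    mask = _complete_rows(y, x, z, cov)
    y, x, z = y[mask], x[mask], z[mask]
    cov = None if cov is None else cov[mask]
    n = len(y)
    n_params = 2 + (0 if cov is None else cov.shape[1]) + 1  # 1, x, C, v_hat
    if n < n_params + 2:
        raise ValueError(f"DWH requires n >= {n_params + 2}, got {n}")

    X1 = _design(n, z, cov)
    _, v_hat = _ols(X1, x)
    Xo = _design(n, x, cov)
    _, e = _ols(Xo, y)
    sst = float(e @ e)
    if sst <= 0 or float(v_hat @ v_hat) / n < 1e-12:
        # exogenous limit: instrument spans the exposure, v_hat ~ 0
        return 0.0, 1, 1.0
    Xa = np.column_stack([Xo, v_hat])
    _, ea = _ols(Xa, e)
    r2 = 1.0 - float(ea @ ea) / sst
    statistic = n * max(r2, 0.0)
    p = float(stats.chi2.sf(statistic, 1))
    return float(statistic), 1, p


def wald_ratio(beta_gx: float, se_gx: float, beta_gy: float, se_gy: float) -> MrEstimate:
    """Per-SNP Wald ratio causal estimate.

    ``beta = beta_gy / beta_gx`` with the first-order delta-method SE
    ``|se_gy / beta_gx|`` (the contribution of the SNP-exposure uncertainty
    is deliberately omitted; documented limitation).  p from the normal
    approximation.
    """
    if beta_gx == 0:
        raise ValueError("Wald ratio undefined: SNP-exposure beta is zero")
    if se_gy <= 0:
        raise ValueError("se_gy must be positive")
    beta = beta_gy / beta_gx
    se = abs(se_gy / beta_gx)
    z = beta / se
    p = 2.0 * stats.norm.sf(abs(z))
    return MrEstimate(beta=float(beta), se=float(se), p=float(p), method="wald_ratio", n_snps=1)


def _betas_ses(estimates) -> tuple[np.ndarray, np.ndarray]:
    betas = np.array([e.beta for e in estimates], dtype=float)
    ses = np.array([e.se for e in estimates], dtype=float)
    if np.any(ses <= 0):
        raise ValueError("all standard errors must be positive")
    return betas, ses


def cochran_q(estimates):
    """Cochran's Q heterogeneity statistic across estimates.

    ``Q = sum(w_i * (b_i - b_ivw)^2)`` with ``w_i = 1/se_i^2``; df = k-1;
    p from the upper tail of chi-square(df).
    """
    if len(estimates) < 2:
        raise ValueError("Cochran's Q requires at least 2 estimates")
    betas, ses = _betas_ses(estimates)
    w = 1.0 / ses**2
    pooled = float(np.sum(w * betas) / np.sum(w))
    Q = float(np.sum(w * (betas - pooled) ** 2))
    df = len(betas) - 1
    p = float(stats.chi2.sf(Q, df))
    return Q, df, p


def ivw_combine(estimates, scale: str = "fixed") -> MrEstimate:
    """Inverse-variance weighted pooling of per-SNP Wald ratios.

    Weights ``w_i = 1/se_i^2``; pooled beta is the weighted mean and
    ``se = (sum w_i)^(-1/2)`` (pure fixed-effect, residual scale fixed at 1).
    ``scale="multiplicative"`` inflates the SE by ``sqrt(max(1, Q/df))``,
    the multiplicative random-effects variant.  Cochran's Q is attached
    whenever two or more estimates are pooled.
    """
    if len(estimates) == 0:
        raise ValueError("ivw_combine requires at least one estimate")
    if scale not in ("fixed", "multiplicative"):
        raise ValueError(f"unknown scale {scale!r}")
    betas, ses = _betas_ses(estimates)
    w = 1.0 / ses**2
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    Q = Q_df = Q_p = None
    if len(betas) >= 2:
        Q, Q_df, Q_p = cochran_q(estimates)
        if scale == "multiplicative":
            se *= math.sqrt(max(1.0, Q / Q_df))
    z = beta / se
    p = 2.0 * stats.norm.sf(abs(z))
    return MrEstimate(
        beta=beta, se=se, p=float(p), method="IVW", n_snps=len(betas), Q=Q, Q_df=Q_df, Q_p=Q_p
    )


def meta_analyze(estimates, model: str = "fixed") -> MetaResult:
    """Pool per-cohort estimates by fixed-effect or DerSimonian-Laird
    random-effects inverse-variance meta-analysis.

    DL: ``tau2 = max(0, (Q - df) / (sum w - sum w^2 / sum w))`` with
    fixed-effect weights ``w = 1/se^2``, then re-weight by
    ``1/(se^2 + tau2)``.  Homogeneous inputs (Q <= df) truncate tau2 to 0
    and the result equals the fixed model exactly.
    """
    if len(estimates) == 0:
        raise ValueError("meta_analyze requires at least one estimate")
    if model not in ("fixed", "random-DL"):
        raise ValueError(f"unknown model {model!r}")
    betas, ses = _betas_ses(estimates)
    w = 1.0 / ses**2
    Q = Q_df = Q_p = None
    tau2 = 0.0
    if len(betas) >= 2:
        Q, Q_df, Q_p = cochran_q(estimates)
        if model == "random-DL":
            denom = np.sum(w) - np.sum(w**2) / np.sum(w)
            tau2 = max(0.0, (Q - Q_df) / denom) if denom > 0 else 0.0
    w_used = 1.0 / (ses**2 + tau2) if model == "random-DL" else w
    beta = float(np.sum(w_used * betas) / np.sum(w_used))
    se = float(np.sum(w_used) ** -0.5)
    z = beta / se
    p = 2.0 * stats.norm.sf(abs(z))
    return MetaResult(
        beta=beta,
        se=se,
        p=float(p),
        model=model,
        weights=w_used / np.sum(w_used),
        Q=Q,
        Q_df=Q_df,
        Q_p=Q_p,
        tau2=tau2 if model == "random-DL" else None,
    )


def mr_power(n: int, r2_gx: float, beta_xy: float, alpha: float = 0.05) -> float:
    """Power of an MR test of a continuous outcome effect ``beta_xy`` (SD/SD).

    Two-sided test at level ``alpha`` with non-centrality
    ``lambda = beta_xy * sqrt(n * r2_gx)``, where ``r2_gx`` is the exposure
    variance explained by the instrument:
    ``power = Phi(lambda - z_{1-a/2}) + Phi(-lambda - z_{1-a/2})``.
    """
    if not 0 < r2_gx < 1:
        raise ValueError(f"r2_gx must be in (0,1), got {r2_gx}")
    if n < 10:
        raise ValueError(f"n must be >= 10, got {n}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    zc = stats.norm.ppf(1.0 - alpha / 2.0)
    lam = beta_xy * math.sqrt(n * r2_gx)
    return float(stats.norm.cdf(lam - zc) + stats.norm.cdf(-lam - zc))


def detectable_effect(n: int, r2_gx: float, power: float = 0.8, alpha: float = 0.05) -> float:
    """Smallest effect size (SD per SD) detectable with the given power.

    Numerically inverts :func:`mr_power` in the positive-effect direction.
    Requests with ``power <= alpha`` or ``power >= 1`` are unattainable by a
    two-sided level-``alpha`` test and raise.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    if not alpha < power < 1:
        raise ValueError(f"requested power {power} unattainable at alpha={alpha}")
    f = lambda b: mr_power(n, r2_gx, b, alpha) - power
    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e6:
            raise ValueError("requested power unattainable")
    return float(optimize.brentq(f, 0.0, hi, xtol=1e-12))
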