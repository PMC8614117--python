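"""Phenotype transformations for the observational and one-sample MR analyses.

Cytokine-type mediators are right-skewed and zero-inflated, so the analysis
variables are built by rank-based inverse normal transformation (RNT),
residualization on age, sex and genetic principal components, and a second
RNT of the residuals.  A natural-log rerun (``log1_shift``) supports
reporting effects as ratios of geometric means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "TraitVector",
    "rank_inverse_normal",
    "prepare_trait",
    "log1_shift",
    "zscore",
    "BLOM_OFFSET",
]

#: Blom's rank offset, the conventional default for inverse normal scores.
BLOM_OFFSET = 3.0 / 8.0


@dataclass
class TraitVector:
    """A trait column with an append-only log of applied transforms.

    Attributes
    ----------
    values : numpy.ndarray
        Float vector, NaN marks missing. Empty when ``excluded`` is True.
    label : str
        Trait name.
    transform_log : list of str
        Transforms applied so far, in order.
    excluded : bool
        True when the trait failed a preparation gate (e.g. too much
        missingness) and carries no values.
    exclusion_reason : str or None
    """

    values: np.ndarray
    label: str = ""
    transform_log: list[str] = field(default_factory=list)
    excluded: bool = False
    exclusion_reason: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)


def _as_float_array(values) -> np.ndarray:
    if isinstance(values, TraitVector):
        return np.asarray(values.values, dtype=float).copy()
    return np.asarray(values, dtype=float).copy()


def rank_inverse_normal(values, offset: float = BLOM_OFFSET, label: str = "") -> TraitVector:
    """Rank-based inverse normal transformation.

    A non-missing value with rank ``r`` among ``n`` non-missing values maps to
    ``Phi^-1((r - offset) / (n - 2*offset + 1))``.  Ties receive average
    ranks, which keeps the transform deterministic on heavily tied
    (zero-inflated) inputs.  Missing values stay missing.

    Parameters
    ----------
    values : array-like or TraitVector
        Input trait; NaN marks missing.
    offset : float
        Rank offset in [0, 0.5]; default Blom's 3/8.

    Returns
    -------
    TraitVector
        Transformed values, order-preserving on the non-missing entries.
    """
    if not 0.0 <= offset <= 0.5:
        raise ValueError(f"offset must be in [0, 0.5], got {offset}")
    x = _as_float_array(values)
    mask = np.isfinite(x)
    n = int(mask.sum())
    if n < 2:
        raise ValueError("rank_inverse_normal requires at least 2 non-missing values")
    obs = x[mask]
    if np.all(obs == obs[0]):
        raise ValueError("all non-missing values identical; transform undefined")
    ranks = stats.rankdata(obs, method="average")
    quantiles = (ranks - offset) / (n - 2.0 * offset + 1.0)
    out = np.full_like(x, np.nan)
    out[mask] = stats.norm.ppf(quantiles)
    prior = values.transform_log if isinstance(values, TraitVector) else []
    lab = label or (values.label if isinstance(values, TraitVector) else "")
    return TraitVector(out, label=lab, transform_log=prior + [f"rnt(offset={offset})"])


def _residualize(y: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """OLS residuals of y on covariates (with intercept), complete cases only.

    Rows with missing y or any missing covariate are left missing in the
    output.  Raises on rank-deficient covariates, naming the offending
    columns.
    """
    n = len(y)
    cov = np.asarray(covariates, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]
    if cov.shape[0] != n:
        raise ValueError("covariate rows must match trait length")
    fit_mask = np.isfinite(y) & np.all(np.isfinite(cov), axis=1)
    design = np.column_stack([np.ones(fit_mask.sum()), cov[fit_mask]])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify collinear columns by incremental rank
        bad = []
        kept = np.ones((fit_mask.sum(), 1))
        for j in range(cov.shape[1]):
            cand = np.column_stack([kept, cov[fit_mask, j]])
            if np.linalg.matrix_rank(cand) == kept.shape[1]:
                bad.append(j)
            else:
                kept = cand
        raise ValueError(f"rank-deficient covariate matrix; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(design, y[fit_mask], rcond=None)
    out = np.full(n, np.nan)
    out[fit_mask] = y[fit_mask] - design @ beta
    return out


def prepare_trait(
    trait,
    covariates,
    missing_threshold: float = 0.9,
    offset: float = BLOM_OFFSET,
    label: str = "",
) -> TraitVector:
    """RNT -> residualize on covariates -> second RNT.

    This is the standard preparation for each mediator before the
    observational regression and the two-stage least squares: the raw trait
    is rank-inverse-normalized, regressed on the covariates (age, sex,
    principal components) with residuals extracted, and the residuals are
    rank-inverse-normalized again.

    Traits with a missing fraction above ``missing_threshold`` are flagged
    excluded and return no values (mirrors the >90 % missingness exclusion
    rule).  Rows with missing trait or covariates are dropped from fitting
    and stay missing in the output.
    """
    x = _as_float_array(trait)
    lab = label or (trait.label if isinstance(trait, TraitVector) else "")
    missing_frac = float(np.mean(~np.isfinite(x)))
    if missing_frac > missing_threshold:
        return TraitVector(
            np.array([]),
            label=lab,
            transform_log=[f"excluded(missing={missing_frac:.3f}>{missing_threshold})"],
            excluded=True,
            exclusion_reason="missingness_above_threshold",
        )
    first = rank_inverse_normal(x, offset=offset, label=lab)
    resid = _residualize(first.values, covariates)
    second = rank_inverse_normal(resid, offset=offset, label=lab)
    return TraitVector(
        second.values,
        label=lab,
        transform_log=first.transform_log + ["residualize(covariates)", f"rnt(offset={offset})"],
    )


def log1_shift(values, label: str = "") -> TraitVector:
    """Natural log of (value + 1), for traits with exact zeros.

    The +1 shift accommodates zero measurements.  A downstream regression
    coefficient ``b`` on this scale exponentiates to ``exp(b)``, the ratio of
    geometric means of (value + 1) per unit of exposure — the documented
    reporting convention for the log-scale rerun.
    """
    x = _as_float_array(values)
    if np.nanmin(x) < 0:
        raise ValueError("log1_shift requires non-negative values")
    out = np.where(np.isfinite(x), np.log(x + 1.0), np.nan)
    prior = values.transform_log if isinstance(values, TraitVector) else []
    lab = label or (values.label if isinstance(values, TraitVector) else "")
    return TraitVector(out, label=lab, transform_log=prior + ["log1_shift"])


def zscore(values) -> np.ndarray:
    """(x - mean) / SD over non-missing rows; missing stays missing."""
    x = _as_float_array(values)
    mask = np.isfinite(x)
    mu = x[mask].mean()
    sd = x[mask].std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance; z-score undefined")
    out = np.full_like(x, np.nan)
    out[mask] = (x[mask] - mu) / sd
    return out
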