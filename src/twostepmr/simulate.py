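"""Synthetic study generator for the two-step MR design.

Everything downstream of real cohort data is emulated here: LD-blocked
genotype panels, three population cohorts with a BMI-like exposure and a
panel of right-skewed, zero-inflated inflammatory mediators causally
downstream of the exposure, split-sample GWAS summary statistics for the
mediators, and case-control disease GWAS driven by a mediator (with optional
pleiotropic direct SNP effects).

The generative model
--------------------
Exposure (standardized):  ``X = sqrt(h2) * Gstd + c_U * U + e``
with ``Gstd`` the standardized weighted allele score over the instrument
SNPs, ``U`` a standard-normal confounder shared with the mediators, and the
residual scaled so var(X) = 1.  BMI is reported as ``27 + 4.5 * X`` kg/m^2.

Mediator core (standardized):  ``M_k = theta_k * X + d_U * U + g_k + e_k``
where ``g_k`` is an optional direct SNP contribution with variance share
``mediator_h2``.  The observed mediator is ``exp(M_k)`` (right-skewed),
left-censored to exact zeros at the ``zero_inflation`` quantile (emulating
assay detection limits), and masked missing at ``missing_fraction``.

Disease:  ``logit P(D=1) = b0 + log_or_per_sd * z(M) [+ direct SNP effects]``.

All randomness flows from a single integer seed; sub-streams are derived by
fixed spawn keys, so identical parameters give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .instruments import GWAS_COLUMNS

__all__ = [
    "SimParams",
    "GenotypePanel",
    "CohortData",
    "StudyData",
    "simulate_genotypes",
    "simulate_cohort",
    "simulate_two_sample_gwas",
    "simulate_disease_gwas",
    "simulate_study",
    "mediator_gwas_from_study",
    "disease_gwas_from_study",
]

_NON_PALINDROMIC = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "A")]


@dataclass(frozen=True)
class SimParams:
    """Parameters of the synthetic two-step MR study.

    Defaults mirror the study conditions: three cohorts of 1,980 / 4,608 /
    1,705 individuals, a BMI-like exposure (mean 27, SD 4.5 kg/m^2), a
    97-SNP instrument set explaining ~2.7 % of exposure variance, and a
    panel of 41 mediators.
    """

    n_individuals: tuple[int, ...] = (1980, 4608, 1705)
    n_instrument_snps: int = 97
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 1
    ld_within_block_r2: float = 0.0
    exposure_h2: float = 0.027
    confounder_effect_on_exposure: float = 0.3
    confounder_effect_on_mediator: float = 0.5
    theta: float | tuple[float, ...] = 0.2
    n_mediators: int = 41
    n_mediator_snps: int = 30
    mediator_h2: float = 0.05
    pleiotropy_fraction: float = 0.0
    pleiotropy_log_or: float = 0.1
    log_or_per_sd: float = 0.0
    case_fraction: float = 1.0 / 3.0
    n_outcome_individuals: int = 0
    zero_inflation: float = 0.10
    missing_fraction: float = 0.02
    bmi_mean: float = 27.0
    bmi_sd: float = 4.5
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.n_individuals):
            raise ValueError("every cohort needs n_individuals >= 2")
        if self.n_instrument_snps <= 0 or self.n_mediator_snps < 0:
            raise ValueError("SNP counts must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        if not 0 <= self.ld_within_block_r2 < 1:
            raise ValueError("ld_within_block_r2 must be in [0, 1)")
        if not 0 <= self.exposure_h2 < 1:
            raise ValueError("exposure_h2 must be in [0, 1)")
        for name in ("pleiotropy_fraction", "zero_inflation", "missing_fraction"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if not 0 < self.case_fraction < 1:
            raise ValueError("case_fraction must be in (0, 1)")
        if self.exposure_h2 + self.confounder_effect_on_exposure**2 >= 1:
            raise ValueError("exposure_h2 + confounder^2 must be < 1")

    def thetas(self) -> np.ndarray:
        t = np.asarray(self.theta, dtype=float)
        if t.ndim == 0:
            t = np.full(self.n_mediators, float(t))
        if len(t) != self.n_mediators:
            raise ValueError("theta length must equal n_mediators")
        return t

    @property
    def n_total(self) -> int:
        return int(sum(self.n_individuals))


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


@dataclass
class GenotypePanel:
    """SNP dosages with block LD structure.

    ``dosages`` are hard-call allele counts in {0, 1, 2}; ``ld_r2`` is the
    empirical within-block pairwise r^2 map (cross-block pairs are generated
    independent and omitted); ``target_r2`` records the generative target.
    """

    snp_ids: list[str]
    effect_alleles: list[str]
    other_alleles: list[str]
    mafs: np.ndarray
    dosages: np.ndarray
    ld_r2: dict
    target_r2: float = 0.0
    positions: np.ndarray | None = None

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def dosage_frame(self, sample_ids: Sequence[str] | None = None) -> pd.DataFrame:
        idx = sample_ids if sample_ids is not None else pd.RangeIndex(self.n_individuals)
        return pd.DataFrame(self.dosages, columns=self.snp_ids, index=idx)

    def alleles(self) -> dict:
        return {
            s: (ea, oa)
            for s, ea, oa in zip(self.snp_ids, self.effect_alleles, self.other_alleles)
        }


def _latent_rho_for_allele_r(maf: float, target_r: float) -> float:
    """Latent Gaussian correlation giving binary allele correlation target_r.

    Alleles are thresholded latents (allele = 1 iff Z < Phi^-1(maf)); the
    product-moment correlation of the two binaries is
    ``(P11(rho) - maf^2) / (maf (1 - maf))`` with P11 the bivariate normal
    orthant probability.  Solved by bisection.
    """
    if target_r <= 0:
        return 0.0
    t = stats.norm.ppf(maf)

    def binary_r(rho: float) -> float:
        p11 = stats.multivariate_normal.cdf(
            [t, t], mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]
        )
        return (p11 - maf**2) / (maf * (1.0 - maf))

    return float(optimize.brentq(lambda r: binary_r(r) - target_r, 0.0, 0.999999, xtol=1e-10))


def simulate_genotypes(
    params: SimParams,
    n_individuals: int | None = None,
    n_snps: int | None = None,
    id_prefix: str = "rs",
    stream: int = 0,
) -> GenotypePanel:
    """Draw Hardy-Weinberg hard-call genotypes with block LD.

    Each individual's dosage at a SNP is the sum of two allele draws.
    Within an LD block, the latent Gaussians behind the allele draws are
    equicorrelated so the realized pairwise dosage r^2 approximates
    ``params.ld_within_block_r2``; blocks are mutually independent.  Blocks
    share a single MAF (drawn from ``maf_range``) so the latent correlation
    is solved once per panel.
    """
    n = int(n_individuals if n_individuals is not None else params.n_total)
    m = int(n_snps if n_snps is not None else params.n_instrument_snps)
    if n <= 0 or m <= 0:
        raise ValueError("individual and SNP counts must be positive")
    rng = _rng(params.seed, 1, stream)
    lo, hi = params.maf_range
    bs = params.ld_block_size
    r2 = params.ld_within_block_r2
    blocks = [list(range(i, min(i + bs, m))) for i in range(0, m, bs)]

    mafs = np.empty(m)
    dosages = np.empty((n, m), dtype=np.int8)
    for block in blocks:
        if r2 > 0 and len(block) > 1:
            maf = float(rng.uniform(lo, hi))
            mafs[block] = maf
            rho = _latent_rho_for_allele_r(maf, np.sqrt(r2))
            t = stats.norm.ppf(maf)
            g = np.zeros((n, len(block)), dtype=np.int8)
            for _draw in range(2):
                common = rng.standard_normal((n, 1))
                idio = rng.standard_normal((n, len(block)))
                z = np.sqrt(rho) * common + np.sqrt(1.0 - rho) * idio
                g += (z < t).astype(np.int8)
            dosages[:, block] = g
        else:
            maf = rng.uniform(lo, hi, size=len(block))
            mafs[block] = maf
            dosages[:, block] = rng.binomial(2, maf, size=(n, len(block))).astype(np.int8)

    snp_ids = [f"{id_prefix}{i + 1:05d}" for i in range(m)]
    allele_pairs = [_NON_PALINDROMIC[i % len(_NON_PALINDROMIC)] for i in range(m)]
    effect_alleles = [a for a, _ in allele_pairs]
    other_alleles = [b for _, b in allele_pairs]

    ld_map: dict = {}
    if r2 > 0 and bs > 1:
        for block in blocks:
            sub = dosages[:, block].astype(float)
            if len(block) > 1 and sub.std(axis=0).min() > 0:
                corr = np.corrcoef(sub, rowvar=False)
                for i in range(len(block)):
                    for j in range(i + 1, len(block)):
                        ld_map[(snp_ids[block[i]], snp_ids[block[j]])] = float(corr[i, j] ** 2)
    positions = np.arange(1, m + 1) * 10_000
    return GenotypePanel(
        snp_ids=snp_ids,
        effect_alleles=effect_alleles,
        other_alleles=other_alleles,
        mafs=mafs,
        dosages=dosages,
        ld_r2=ld_map,
        target_r2=r2,
        positions=positions,
    )


@dataclass
class CohortData:
    """Individual-level cohort table: dosages, exposure, mediators, covariates.

    ``truth`` records the generative values (per-mediator theta, confounder
    loadings, mediator SNP effects) for calibration tests.
    """

    cohort_id: str
    sample_ids: list[str]
    dosages: pd.DataFrame
    dosage_alleles: dict
    exposure: pd.Series
    mediators: pd.DataFrame
    covariates: pd.DataFrame
    truth: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def to_table(self) -> pd.DataFrame:
        """Tab-delimited cohort layout: sample_id, bmi, mediators, covariates."""
        df = pd.concat(
            [self.exposure.rename("bmi"), self.mediators, self.covariates], axis=1
        )
        df.insert(0, "sample_id", self.sample_ids)
        return df


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant vector")
    return (v - v.mean()) / sd


# fixed small loadings of the auxiliary covariates on exposure and mediators
_COVARIATE_LOADING_X = 0.05
_COVARIATE_LOADING_M = 0.03


def _covariate_table(rng: np.random.Generator, n: int) -> pd.DataFrame:
    cov = {
        "age": rng.normal(48.0, 13.0, n),
        "sex": rng.integers(0, 2, n).astype(float),
    }
    for k in range(1, 11):
        cov[f"pc{k}"] = rng.standard_normal(n)
    return pd.DataFrame(cov)


def simulate_cohort(
    params: SimParams,
    panel: GenotypePanel,
    cohort_id: str = "cohort1",
    stream: int = 0,
    mediator_panel: GenotypePanel | None = None,
    mediator_alphas: np.ndarray | None = None,
    instrument_weights: np.ndarray | None = None,
) -> CohortData:
    """Generate exposure, mediator panel, and covariates for one cohort.

    ``panel`` supplies the exposure-instrument dosages for exactly the
    cohort's individuals.  When ``mediator_panel``/``mediator_alphas`` are
    given, mediator k receives a direct SNP contribution
    ``mediator_panel.dosages @ mediator_alphas[:, k]`` standardized to
    variance share ``params.mediator_h2``.  ``instrument_weights`` fixes the
    generative per-SNP exposure weights (shared across cohorts in a study);
    when absent they are drawn from the cohort's stream.
    """
    n = panel.n_individuals
    rng = _rng(params.seed, 2, stream)
    h2 = params.exposure_h2
    c_ux = params.confounder_effect_on_exposure
    d_um = params.confounder_effect_on_mediator
    thetas = params.thetas()

    # per-SNP exposure weights; the score is standardized so its variance
    # share is exactly exposure_h2
    if instrument_weights is not None:
        b_raw = np.asarray(instrument_weights, dtype=float)
        if len(b_raw) != panel.n_snps:
            raise ValueError("instrument_weights length must equal panel SNPs")
    else:
        b_raw = np.abs(rng.normal(0.0, 1.0, panel.n_snps)) + 0.1  # all informative
    g_score = panel.dosages.astype(float) @ b_raw
    g_std = _standardize(g_score)

    U = rng.standard_normal(n)
    eps_x = rng.standard_normal(n)
    resid_sd_x = np.sqrt(max(1.0 - h2 - c_ux**2, 0.0))
    x = np.sqrt(h2) * g_std + c_ux * U + resid_sd_x * eps_x

    covariates = _covariate_table(rng, n)
    cov_z = np.column_stack(
        [_standardize(covariates[c].to_numpy()) for c in covariates.columns]
    )
    x = x + _COVARIATE_LOADING_X * cov_z.sum(axis=1)
    bmi = params.bmi_mean + params.bmi_sd * x

    med_core_var = thetas**2 + d_um**2 + 2.0 * thetas * c_ux * d_um + params.mediator_h2 * (
        mediator_panel is not None
    )
    if np.any(med_core_var >= 1.0):
        raise ValueError("mediator structural variance exceeds 1; reduce theta/confounder/h2")

    med_cols = {}
    truth_alphas = {}
    for k in range(params.n_mediators):
        gm = 0.0
        if mediator_panel is not None and mediator_alphas is not None:
            contrib = mediator_panel.dosages.astype(float) @ mediator_alphas[:, k]
            if contrib.std() > 0:
                gm = np.sqrt(params.mediator_h2) * _standardize(contrib)
        eps = rng.standard_normal(n)
        resid_sd = np.sqrt(1.0 - med_core_var[k])
        core = thetas[k] * x + d_um * U + gm + resid_sd * eps
        core = core + _COVARIATE_LOADING_M * cov_z.sum(axis=1)
        raw = np.exp(core)
        if params.zero_inflation > 0:
            cut = np.quantile(raw, params.zero_inflation)
            raw = np.where(raw <= cut, 0.0, raw)
        if params.missing_fraction > 0:
            miss = rng.random(n) < params.missing_fraction
            raw = np.where(miss, np.nan, raw)
        med_cols[f"cyt_{k + 1:03d}"] = raw
        truth_alphas[f"cyt_{k + 1:03d}"] = thetas[k]

    sample_ids = [f"{cohort_id}_{i + 1:06d}" for i in range(n)]
    mediators = pd.DataFrame(med_cols, index=pd.RangeIndex(n))
    dosages = panel.dosage_frame()
    dosages.index = pd.RangeIndex(n)
    exposure = pd.Series(bmi, name="bmi")
    return CohortData(
        cohort_id=cohort_id,
        sample_ids=sample_ids,
        dosages=dosages,
        dosage_alleles=panel.alleles(),
        exposure=exposure,
        mediators=mediators,
        covariates=covariates,
        truth={
            "theta": truth_alphas,
            "confounder_effect_on_exposure": c_ux,
            "confounder_effect_on_mediator": d_um,
            "exposure_h2": h2,
            "U": U,
            "x_standardized": x,
            "instrument_weights": b_raw,
        },
    )


def _linear_gwas(dosages: np.ndarray, trait: np.ndarray) -> tuple[np.ndarray, ...]:
    """Vectorized per-SNP simple linear regression (intercept + dosage).

    Returns (beta, se, p) arrays.  Closed form: beta = cov(g, y) / var(g);
    residual df = n - 2.
    """
    mask = np.isfinite(trait)
    g = dosages[mask].astype(float)
    y = trait[mask]
    n = len(y)
    if n < 3:
        raise ValueError("too few complete observations for a GWAS")
    gc = g - g.mean(axis=0)
    yc = y - y.mean()
    ssg = np.sum(gc**2, axis=0)
    if np.any(ssg == 0):
        raise ValueError("monomorphic SNP in GWAS input")
    beta = (gc.T @ yc) / ssg
    resid_ss = np.sum(yc**2) - beta**2 * ssg
    sigma2 = resid_ss / (n - 2)
    se = np.sqrt(sigma2 / ssg)
    tstat = beta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), n - 2)
    return beta, se, p


def _gwas_frame(panel: GenotypePanel, idx: np.ndarray, beta, se, p) -> pd.DataFrame:
    g = panel.dosages[idx].astype(float)
    eaf = g.mean(axis=0) / 2.0
    return pd.DataFrame(
        {
            "SNP": panel.snp_ids,
            "EA": panel.effect_alleles,
            "OA": panel.other_alleles,
            "EAF": eaf,
            "BETA": beta,
            "SE": se,
            "P": p,
            "N": len(idx),
        },
        columns=GWAS_COLUMNS,
    )


def simulate_two_sample_gwas(
    panel: GenotypePanel,
    trait: np.ndarray,
    n_split: tuple[int, int],
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summary statistics for one trait in two disjoint subsamples.

    The individuals are partitioned (no overlap, honoring the two-sample
    assumption) and per-SNP simple-regression beta/SE/p/EAF/N are computed
    independently in each half.
    """
    n1, n2 = n_split
    if n1 <= 0 or n2 <= 0:
        raise ValueError("both split sizes must be positive")
    if n1 + n2 > panel.n_individuals:
        raise ValueError(
            f"splits overlap: {n1}+{n2} exceeds {panel.n_individuals} individuals"
        )
    trait = np.asarray(trait, dtype=float)
    if len(trait) != panel.n_individuals:
        raise ValueError("trait length must match panel individuals")
    rng = _rng(seed, 3)
    perm = rng.permutation(panel.n_individuals)
    idx1, idx2 = np.sort(perm[:n1]), np.sort(perm[n1 : n1 + n2])
    tables = []
    for idx in (idx1, idx2):
        beta, se, p = _linear_gwas(panel.dosages[idx], trait[idx])
        tables.append(_gwas_frame(panel, idx, beta, se, p))
    return tables[0], tables[1]


def _logistic_gwas(dosages: np.ndarray, y: np.ndarray, max_iter: int = 50) -> tuple[np.ndarray, ...]:
    """Vectorized Newton-Raphson single-SNP logistic regressions.

    Fits ``logit P(y=1) = b0 + b1 g`` for every SNP column simultaneously.
    Returns (beta, se, p) for the dosage coefficient.
    """
    g = dosages.astype(float)
    n, m = g.shape
    b0 = np.full(m, np.log(y.mean() / (1.0 - y.mean())))
    b1 = np.zeros(m)
    for _ in range(max_iter):
        eta = b0[None, :] + g * b1[None, :]
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        r = y[:, None] - mu
        s0 = r.sum(axis=0)
        s1 = (g * r).sum(axis=0)
        i00 = w.sum(axis=0)
        i01 = (w * g).sum(axis=0)
        i11 = (w * g**2).sum(axis=0)
        det = i00 * i11 - i01**2
        d0 = (i11 * s0 - i01 * s1) / det
        d1 = (-i01 * s0 + i00 * s1) / det
        b0 += d0
        b1 += d1
        if max(np.abs(d0).max(), np.abs(d1).max()) < 1e-10:
            break
    eta = b0[None, :] + g * b1[None, :]
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    i00 = w.sum(axis=0)
    i01 = (w * g).sum(axis=0)
    i11 = (w * g**2).sum(axis=0)
    det = i00 * i11 - i01**2
    se = np.sqrt(i00 / det)
    z = b1 / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return b1, se, p


def simulate_disease_gwas(
    panel: GenotypePanel,
    mediator: np.ndarray,
    log_or_per_sd: float,
    case_fraction: float,
    n: int | None = None,
    seed: int = 0,
    direct_snp_log_or: np.ndarray | None = None,
) -> pd.DataFrame:
    """Case-control summary statistics for a disease downstream of a mediator.

    Disease status is drawn from ``logit P = b0 + log_or_per_sd * z(M)``
    (plus optional direct per-SNP log-ORs for pleiotropic variants); the
    intercept targets the requested case fraction.  Per-SNP log-OR/SE/p come
    from single-SNP logistic regressions.
    """
    if not 0 < case_fraction < 1:
        raise ValueError("case_fraction must be in (0, 1)")
    total = panel.n_individuals
    n = total if n is None else int(n)
    if n < 100:
        raise ValueError(f"disease GWAS requires n >= 100, got {n}")
    if n > total:
        raise ValueError("n exceeds panel individuals")
    mediator = np.asarray(mediator, dtype=float)
    if len(mediator) != total:
        raise ValueError("mediator length must match panel individuals")
    rng = _rng(seed, 4)
    idx = np.sort(rng.permutation(total)[:n])
    m_std = _standardize(mediator[idx])
    eta = np.log(case_fraction / (1.0 - case_fraction)) + log_or_per_sd * m_std
    if direct_snp_log_or is not None:
        direct = np.asarray(direct_snp_log_or, dtype=float)
        if len(direct) != panel.n_snps:
            raise ValueError("direct_snp_log_or length must equal panel SNPs")
        g = panel.dosages[idx].astype(float)
        eta = eta + (g - g.mean(axis=0)) @ direct
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
    if y.sum() == 0 or y.sum() == n:
        raise ValueError(
            f"degenerate outcome draw: {int(y.sum())} cases of {n}; "
            "adjust case_fraction or effect sizes"
        )
    beta, se, p = _logistic_gwas(panel.dosages[idx], y)
    return _gwas_frame(panel, idx, beta, se, p)


@dataclass
class StudyData:
    """A complete synthetic study: panels, cohorts, and external GWAS tables.

    ``outcome_cohort`` (present when ``params.n_outcome_individuals > 0``)
    holds a disjoint sample drawn on the same SNP panels, honoring the
    no-sample-overlap requirement of two-sample MR; ``outcome_mediator_panel``
    is the mediator-SNP genotype slice for those individuals.
    """

    params: SimParams
    panel: GenotypePanel
    mediator_panel: GenotypePanel | None
    cohorts: list[CohortData]
    grs_weights: pd.DataFrame
    mediator_ld: dict = field(default_factory=dict)
    mediator_alphas: np.ndarray | None = None
    pleiotropic_snps: np.ndarray | None = None
    outcome_cohort: CohortData | None = None
    outcome_mediator_panel: GenotypePanel | None = None


def _external_grs_weights(params: SimParams, panel: GenotypePanel, weights: np.ndarray,
                          rng: np.random.Generator) -> pd.DataFrame:
    """Emulate published GRS weights from a large external exposure GWAS.

    The true per-allele effects (on the BMI scale) receive sampling noise at
    an external-consortium sample size, so the score is a noisy but strong
    proxy for the genetic component of the exposure.
    """
    n_ext = 339_224
    g = panel.dosages.astype(float)
    var_g = g.var(axis=0)
    var_g[var_g == 0] = np.nan
    # translate internal score weights to per-allele BMI effects
    score = g @ weights
    scale = np.sqrt(params.exposure_h2) / score.std() * params.bmi_sd
    beta_true = weights * scale
    se = params.bmi_sd / np.sqrt(n_ext * var_g)
    beta_pub = beta_true + rng.normal(0.0, se)
    z = beta_pub / se
    return pd.DataFrame(
        {
            "SNP": panel.snp_ids,
            "EA": panel.effect_alleles,
            "OA": panel.other_alleles,
            "EAF": g.mean(axis=0) / 2.0,
            "BETA": beta_pub,
            "SE": se,
            "P": 2.0 * stats.norm.sf(np.abs(z)),
            "N": n_ext,
        },
        columns=GWAS_COLUMNS,
    )


def _panel_slice(panel: GenotypePanel, rows: slice) -> GenotypePanel:
    return GenotypePanel(
        snp_ids=panel.snp_ids,
        effect_alleles=panel.effect_alleles,
        other_alleles=panel.other_alleles,
        mafs=panel.mafs,
        dosages=panel.dosages[rows],
        ld_r2=panel.ld_r2,
        target_r2=panel.target_r2,
        positions=panel.positions,
    )


def simulate_study(params: SimParams) -> StudyData:
    """Generate the full synthetic study.

    One instrument panel covers all individuals (cohorts plus the optional
    disjoint outcome sample), split at the configured sizes; an optional
    mediator SNP panel (with LD blocks and a pleiotropic subset) drives the
    mediators' direct genetic component.  GRS weights emulate an external
    consortium exposure GWAS.
    """
    total = params.n_total + params.n_outcome_individuals
    panel = simulate_genotypes(params, n_individuals=total)
    rng = _rng(params.seed, 5)

    mediator_panel = None
    mediator_alphas = None
    pleio = None
    if params.n_mediator_snps > 0 and params.mediator_h2 > 0:
        mediator_panel = simulate_genotypes(
            params,
            n_individuals=total,
            n_snps=params.n_mediator_snps,
            id_prefix="rsM",
            stream=1,
        )
        mediator_alphas = rng.normal(
            0.0, 1.0, (params.n_mediator_snps, params.n_mediators)
        )
        pleio = rng.random(params.n_mediator_snps) < params.pleiotropy_fraction

    # one generative weight vector shared by all cohorts (one published GWAS)
    weights_vec = np.abs(rng.normal(0.0, 1.0, panel.n_snps)) + 0.1

    cohorts = []
    offset = 0
    sizes = list(params.n_individuals)
    if params.n_outcome_individuals > 0:
        sizes.append(params.n_outcome_individuals)
    generated = []
    for i, n in enumerate(sizes):
        rows = slice(offset, offset + n)
        sub_panel = _panel_slice(panel, rows)
        sub_med = _panel_slice(mediator_panel, rows) if mediator_panel is not None else None
        is_outcome = params.n_outcome_individuals > 0 and i == len(sizes) - 1
        generated.append(
            (
                simulate_cohort(
                    params,
                    sub_panel,
                    cohort_id="outcome_sample" if is_outcome else f"cohort{i + 1}",
                    stream=i,
                    mediator_panel=sub_med,
                    mediator_alphas=mediator_alphas,
                    instrument_weights=weights_vec,
                ),
                sub_med,
                is_outcome,
            )
        )
        offset += n
    outcome_cohort = None
    outcome_med_panel = None
    for c, sub_med, is_outcome in generated:
        if is_outcome:
            outcome_cohort, outcome_med_panel = c, sub_med
        else:
            cohorts.append(c)

    grs_weights = _external_grs_weights(params, _panel_slice(panel, slice(0, params.n_total)),
                                        weights_vec, rng)

    return StudyData(
        params=params,
        panel=panel,
        mediator_panel=mediator_panel,
        cohorts=cohorts,
        grs_weights=grs_weights,
        mediator_ld=dict(mediator_panel.ld_r2) if mediator_panel is not None else {},
        mediator_alphas=mediator_alphas,
        pleiotropic_snps=pleio,
        outcome_cohort=outcome_cohort,
        outcome_mediator_panel=outcome_med_panel,
    )


def mediator_gwas_from_study(study: StudyData, trait: str) -> pd.DataFrame:
    """Per-SNP mediator associations across the study cohorts.

    Emulates the exposure-side summary statistics of the two-sample step:
    the mediator is rank-inverse-normalized within each cohort (so effects
    are in normalized SD units per effect allele) and regressed on each
    mediator-panel SNP over all cohort individuals.
    """
    from .phenotypes import rank_inverse_normal

    if study.mediator_panel is None:
        raise ValueError("study has no mediator SNP panel")
    pieces = []
    for c in study.cohorts:
        raw = c.mediators[trait].to_numpy(dtype=float)
        pieces.append(rank_inverse_normal(raw).values)
    values = np.concatenate(pieces)
    rows = slice(0, study.params.n_total)
    dosages = study.mediator_panel.dosages[rows]
    beta, se, p = _linear_gwas(dosages, values)
    sub = _panel_slice(study.mediator_panel, rows)
    tab = _gwas_frame(sub, np.arange(sub.n_individuals), beta, se, p)
    tab["N"] = int(np.isfinite(values).sum())
    return tab


def disease_gwas_from_study(
    study: StudyData,
    trait: str,
    log_or_per_sd: float | None = None,
    case_fraction: float | None = None,
    seed_offset: int = 0,
) -> pd.DataFrame:
    """Case-control GWAS of a disease in the study's disjoint outcome sample.

    The disease is driven by the *normalized* (rank-inverse-normal) mediator
    at ``log_or_per_sd`` per SD (default from params), so the log-odds scale
    matches the normalized-SD units of the exposure-side summary statistics
    and the two-sample estimand equals ``log_or_per_sd`` by construction.
    Pleiotropic mediator SNPs flagged at generation receive direct outcome
    effects of ``params.pleiotropy_log_or``.
    """
    from .phenotypes import rank_inverse_normal

    if study.outcome_cohort is None or study.outcome_mediator_panel is None:
        raise ValueError("study was generated without an outcome sample")
    params = study.params
    lam = params.log_or_per_sd if log_or_per_sd is None else log_or_per_sd
    cf = params.case_fraction if case_fraction is None else case_fraction
    direct = None
    if study.pleiotropic_snps is not None and study.pleiotropic_snps.any():
        direct = np.where(study.pleiotropic_snps, params.pleiotropy_log_or, 0.0)
    raw = study.outcome_cohort.mediators[trait].to_numpy(dtype=float)
    mediator = rank_inverse_normal(raw).values
    # the latent draw needs a complete vector; mean-impute the missing few
    med = np.where(np.isfinite(mediator), mediator, 0.0)
    return simulate_disease_gwas(
        study.outcome_mediator_panel,
        med,
        log_or_per_sd=lam,
        case_fraction=cf,
        seed=params.seed + 7_000 + seed_offset,
        direct_snp_log_or=direct,
    )
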