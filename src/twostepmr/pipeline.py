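"""End-to-end orchestration of the two-step MR design.

Step 1 (individual-level, per cohort, meta-analyzed): observational
association of each prepared mediator with the z-scored exposure, one-sample
MR via a weighted genetic risk score and 2SLS, the Durbin-Wu-Hausman
endogeneity check, and a natural-log rerun for suggestive traits.  Mediators
whose meta-analyzed MR p-value passes the step-1 gate (default P < 0.001,
a Bonferroni-style penalty for 41 tests) go forward.

Step 2 (summary-level): for each gated mediator and each disease outcome
with at least ``min_outcome_n`` subjects, instruments are selected
(P < 5e-8, proxy r^2 > 0.8, clump r^2 = 0.01), harmonized, and combined by
per-SNP Wald ratios and IVW with Cochran's Q.  No multiplicity penalty is
applied in step 2.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml

from . import __version__
from .estimators import (
    MrEstimate,
    durbin_wu_hausman,
    ivw_combine,
    meta_analyze,
    tsls_estimate,
    wald_ratio,
)
from .instruments import build_grs, select_instruments
from .phenotypes import log1_shift, prepare_trait, zscore
from .simulate import CohortData

__all__ = ["StudyConfig", "Step1Result", "Step2Result", "run_step1", "run_step2", "write_report"]


@dataclass
class StudyConfig:
    """Thresholds and paths governing a study run.

    Defaults are the design's canonical values: step-1 gate P < 0.001
    (penalized for 41 tests), step-2 evidence threshold P < 0.05,
    genome-wide selection P < 5e-8, clumping r^2 = 0.01, proxy r^2 > 0.8,
    >90 % missingness exclusion, and outcome GWAS of at least 50,000
    subjects.
    """

    step1_alpha: float = 1e-3
    step2_alpha: float = 0.05
    suggestive_alpha: float = 0.05
    gwas_p: float = 5e-8
    clump_r2: float = 0.01
    proxy_r2: float = 0.8
    missing_threshold: float = 0.9
    min_outcome_n: int = 50_000
    rnt_offset: float = 0.375
    palindrome_window: tuple[float, float] = (0.42, 0.58)
    meta_model: str = "random-DL"
    seed: int = 0
    output_dir: str | None = None
    cohort_files: list[str] = field(default_factory=list)
    dosage_files: list[str] = field(default_factory=list)
    grs_weights_file: str | None = None
    exposure_gwas_files: dict = field(default_factory=dict)
    outcome_gwas_files: dict = field(default_factory=dict)
    ld_file: str | None = None

    def __post_init__(self) -> None:
        for name in (
            "step1_alpha", "step2_alpha", "suggestive_alpha", "gwas_p",
            "clump_r2", "proxy_r2", "missing_threshold",
        ):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0,1), got {v}")
        if self.min_outcome_n < 0:
            raise ValueError("min_outcome_n must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "palindrome_window" in raw:
            raw["palindrome_window"] = tuple(raw["palindrome_window"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["palindrome_window"] = list(self.palindrome_window)
        return d


_PER_COHORT_COLS = [
    "trait", "cohort", "analysis", "beta", "se", "p", "n",
    "first_stage_F", "dwh_stat", "dwh_df", "dwh_p",
]
_META_COLS = ["trait", "analysis", "model", "beta", "se", "p", "n_cohorts", "Q", "Q_df", "Q_p"]


@dataclass
class Step1Result:
    per_cohort: pd.DataFrame
    meta: pd.DataFrame
    gated: list[str]
    exclusions: pd.DataFrame
    counts: dict

    def meta_row(self, trait: str, analysis: str, model: str) -> pd.Series:
        m = self.meta
        sel = m[(m["trait"] == trait) & (m["analysis"] == analysis) & (m["model"] == model)]
        return sel.iloc[0]


def _ols_slope(y: np.ndarray, x: np.ndarray) -> tuple[float, float, float, int]:
    mask = np.isfinite(y) & np.isfinite(x)
    yy, xx = y[mask], x[mask]
    res = sm.OLS(yy, sm.add_constant(xx)).fit()
    return float(res.params[1]), float(res.bse[1]), float(res.pvalues[1]), int(mask.sum())


def run_step1(cohorts: list[CohortData], grs_weights: pd.DataFrame, config: StudyConfig) -> Step1Result:
    """Observational and one-sample MR analyses, meta-analyzed across cohorts.

    Returns per-cohort and meta tables plus the gating list (traits with
    meta MR p below ``config.step1_alpha`` under ``config.meta_model``).
    Traits excluded for missingness, or absent from every cohort, never
    reach the gate.
    """
    if not cohorts:
        raise ValueError("run_step1 requires at least one cohort")
    all_traits = sorted({t for c in cohorts for t in c.mediators.columns})
    rows, exclusions = [], []
    per_trait_obs: dict[str, list[MrEstimate]] = {t: [] for t in all_traits}
    per_trait_mr: dict[str, list[MrEstimate]] = {t: [] for t in all_traits}
    per_trait_log: dict[str, list[MrEstimate]] = {t: [] for t in all_traits}

    cohort_ctx = []
    for c in cohorts:
        z_x = zscore(c.exposure.to_numpy())
        grs = build_grs(c.dosages, grs_weights, c.dosage_alleles)
        cohort_ctx.append((c, z_x, grs.score))

    for trait in all_traits:
        for c, z_x, score in cohort_ctx:
            if trait not in c.mediators.columns:
                exclusions.append(
                    {"trait": trait, "cohort": c.cohort_id, "reason": "not_measured"}
                )
                continue
            raw = c.mediators[trait].to_numpy(dtype=float)
            prepared = prepare_trait(
                raw,
                c.covariates.to_numpy(dtype=float),
                missing_threshold=config.missing_threshold,
                offset=config.rnt_offset,
                label=trait,
            )
            if prepared.excluded:
                exclusions.append(
                    {"trait": trait, "cohort": c.cohort_id, "reason": prepared.exclusion_reason}
                )
                continue
            ob, ose, op_, on = _ols_slope(prepared.values, z_x)
            rows.append(
                dict(
                    trait=trait, cohort=c.cohort_id, analysis="observational",
                    beta=ob, se=ose, p=op_, n=on,
                    first_stage_F=np.nan, dwh_stat=np.nan, dwh_df=np.nan, dwh_p=np.nan,
                )
            )
            per_trait_obs[trait].append(MrEstimate(ob, ose, op_, "OLS", n=on))
            mr = tsls_estimate(prepared.values, z_x, score)
            dwh_stat, dwh_df, dwh_p = durbin_wu_hausman(prepared.values, z_x, score)
            rows.append(
                dict(
                    trait=trait, cohort=c.cohort_id, analysis="mr_2sls",
                    beta=mr.beta, se=mr.se, p=mr.p, n=mr.n,
                    first_stage_F=mr.first_stage_F,
                    dwh_stat=dwh_stat, dwh_df=dwh_df, dwh_p=dwh_p,
                )
            )
            per_trait_mr[trait].append(mr)

    per_cohort = pd.DataFrame(rows, columns=_PER_COHORT_COLS)
    meta_rows = []
    gated: list[str] = []
    log_candidates: list[str] = []
    for trait in all_traits:
        if not per_trait_mr[trait]:
            continue
        mo = meta_analyze(per_trait_obs[trait], model="fixed")
        meta_rows.append(
            dict(
                trait=trait, analysis="observational", model="fixed",
                beta=mo.beta, se=mo.se, p=mo.p, n_cohorts=len(per_trait_obs[trait]),
                Q=mo.Q, Q_df=mo.Q_df, Q_p=mo.Q_p,
            )
        )
        gate_p = None
        for model in ("random-DL", "fixed"):
            mm = meta_analyze(per_trait_mr[trait], model=model)
            meta_rows.append(
                dict(
                    trait=trait, analysis="mr_2sls", model=model,
                    beta=mm.beta, se=mm.se, p=mm.p, n_cohorts=len(per_trait_mr[trait]),
                    Q=mm.Q, Q_df=mm.Q_df, Q_p=mm.Q_p,
                )
            )
            if model == config.meta_model:
                gate_p = mm.p
        if gate_p < config.step1_alpha:
            gated.append(trait)
        if gate_p < config.suggestive_alpha:
            log_candidates.append(trait)

    # natural-log rerun for suggestive traits, adjusting for age and sex only
    log_rows = []
    for trait in log_candidates:
        for c, z_x, score in cohort_ctx:
            if trait not in c.mediators.columns:
                continue
            raw = c.mediators[trait].to_numpy(dtype=float)
            if np.mean(~np.isfinite(raw)) > config.missing_threshold:
                continue
            logged = log1_shift(raw, label=trait)
            age_sex = c.covariates[["age", "sex"]].to_numpy(dtype=float)
            mr = tsls_estimate(logged.values, z_x, score, covariates=age_sex)
            log_rows.append(
                dict(
                    trait=trait, cohort=c.cohort_id, analysis="mr_2sls_log",
                    beta=mr.beta, se=mr.se, p=mr.p, n=mr.n,
                    first_stage_F=mr.first_stage_F,
                    dwh_stat=np.nan, dwh_df=np.nan, dwh_p=np.nan,
                )
            )
            per_trait_log[trait].append(mr)
        if per_trait_log[trait]:
            ml = meta_analyze(per_trait_log[trait], model=config.meta_model)
            meta_rows.append(
                dict(
                    trait=trait, analysis="mr_2sls_log", model=config.meta_model,
                    beta=ml.beta, se=ml.se, p=ml.p, n_cohorts=len(per_trait_log[trait]),
                    Q=ml.Q, Q_df=ml.Q_df, Q_p=ml.Q_p,
                )
            )
    if log_rows:
        per_cohort = pd.concat(
            [per_cohort, pd.DataFrame(log_rows, columns=_PER_COHORT_COLS)], ignore_index=True
        )

    meta = pd.DataFrame(meta_rows, columns=_META_COLS)
    exclusions_df = pd.DataFrame(exclusions, columns=["trait", "cohort", "reason"])
    analyzed = sorted(meta.loc[meta["analysis"] == "mr_2sls", "trait"].unique())
    counts = {
        "n_traits": len(all_traits),
        "n_analyzed": len(analyzed),
        "n_trait_cohort_excluded": len(exclusions_df),
        "n_gated": len(gated),
        "n_log_rerun": len(log_candidates),
    }
    return Step1Result(
        per_cohort=per_cohort, meta=meta, gated=sorted(gated),
        exclusions=exclusions_df, counts=counts,
    )


_STEP2_COLS = [
    "trait", "outcome", "status", "reason", "method", "n_snps",
    "beta", "se", "p", "odds_ratio", "or_lci", "or_uci", "Q", "Q_df", "Q_p",
]
_PER_SNP_COLS = [
    "trait", "outcome", "SNP", "source", "beta_exp", "se_exp",
    "beta_out", "se_out", "action", "wald_beta", "wald_se", "wald_p",
]


@dataclass
class Step2Result:
    results: pd.DataFrame
    per_snp: pd.DataFrame
    counts: dict


def run_step2(
    exposure_gwas: dict,
    outcome_gwas: dict,
    ld_r2: dict,
    config: StudyConfig,
    gated: list[str],
    preselected: dict | None = None,
) -> Step2Result:
    """Two-sample MR of each gated mediator on each disease outcome.

    ``exposure_gwas`` maps trait -> summary-statistic table; ``outcome_gwas``
    maps outcome name -> table.  ``preselected`` optionally maps a trait to a
    fixed instrument list that bypasses the p-value gate (cis instruments).
    Gate consistency is enforced: only gated traits are analyzed.
    """
    preselected = preselected or {}
    rows, snp_rows = [], []
    filter_counts: dict = {}
    for trait in sorted(exposure_gwas):
        if trait not in gated:
            raise ValueError(
                f"gate violation: trait {trait!r} supplied to step 2 without passing step 1"
            )
    for trait in sorted(gated):
        if trait not in exposure_gwas:
            rows.append(
                dict(trait=trait, outcome=None, status="skipped",
                     reason="no_exposure_gwas", method=None, n_snps=0)
            )
            continue
        for outcome in sorted(outcome_gwas):
            out_tab = outcome_gwas[outcome]
            n_outcome = int(out_tab["N"].max())
            base = dict(trait=trait, outcome=outcome)
            if n_outcome < config.min_outcome_n:
                rows.append(
                    dict(**base, status="excluded", reason="outcome_n_below_minimum",
                         method=None, n_snps=0)
                )
                continue
            sel = select_instruments(
                exposure_gwas[trait],
                out_tab,
                ld_r2,
                p_threshold=config.gwas_p,
                proxy_r2=config.proxy_r2,
                clump_r2=config.clump_r2,
                palindrome_window=config.palindrome_window,
                preselected=preselected.get(trait),
            )
            filter_counts[f"{trait}|{outcome}"] = sel.counts
            if sel.empty:
                reason = "; ".join(
                    f"{k}={v}" for k, v in sel.counts.items() if k != "n_final" and v
                )
                rows.append(
                    dict(**base, status="no_instruments", reason=reason, method=None, n_snps=0)
                )
                continue
            prov = sel.provenance.set_index("SNP")
            walds = []
            for rec in sel.pair.table.itertuples(index=False):
                w = wald_ratio(rec.beta_exp, rec.se_exp, rec.beta_out, rec.se_out)
                walds.append(w)
                snp_rows.append(
                    dict(
                        trait=trait, outcome=outcome, SNP=rec.SNP,
                        source=prov.loc[rec.SNP, "source"],
                        beta_exp=rec.beta_exp, se_exp=rec.se_exp,
                        beta_out=rec.beta_out, se_out=rec.se_out,
                        action=rec.action, wald_beta=w.beta, wald_se=w.se, wald_p=w.p,
                    )
                )
            est = walds[0] if len(walds) == 1 else ivw_combine(walds)
            lci, uci = est.ci
            rows.append(
                dict(
                    **base, status="ok", reason=None, method=est.method,
                    n_snps=len(walds), beta=est.beta, se=est.se, p=est.p,
                    odds_ratio=float(np.exp(est.beta)),
                    or_lci=float(np.exp(lci)), or_uci=float(np.exp(uci)),
                    Q=est.Q, Q_df=est.Q_df, Q_p=est.Q_p,
                )
            )
    results = pd.DataFrame(rows, columns=_STEP2_COLS)
    per_snp = pd.DataFrame(snp_rows, columns=_PER_SNP_COLS)
    return Step2Result(results=results, per_snp=per_snp, counts=filter_counts)


def write_report(
    step1: Step1Result,
    step2: Step2Result | None,
    config: StudyConfig,
    outdir,
) -> dict:
    """Write tab-delimited result tables and a deterministic run manifest.

    Returns the manifest dict.  Reruns with identical inputs produce
    byte-identical files; the manifest records SHA-256 digests of every
    table, the config echo, the seed, and counts at every filter.
    """
    import os

    from .io import ensure_dir, sha256_of

    outdir = ensure_dir(outdir)
    fmt = "%.10g"
    files = {
        "step1_per_cohort.tsv": step1.per_cohort,
        "step1_meta.tsv": step1.meta,
        "step1_exclusions.tsv": step1.exclusions,
    }
    if step2 is not None:
        files["step2_results.tsv"] = step2.results
        files["step2_per_snp.tsv"] = step2.per_snp
    digests = {}
    for name, df in files.items():
        path = os.path.join(outdir, name)
        df.to_csv(path, sep="\t", index=False, float_format=fmt)
        digests[name] = sha256_of(path)
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "step1_counts": step1.counts,
        "gated_traits": list(step1.gated),
        "step2_filter_counts": step2.counts if step2 is not None else {},
        "sha256": digests,
    }
    with open(os.path.join(outdir, "manifest.yaml"), "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest
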