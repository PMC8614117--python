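"""Genetic instrument construction: weighted risk scores, LD clumping,
proxy lookup, and allele harmonization of exposure/outcome summary statistics.

GWAS summary statistics travel as pandas DataFrames with the columns
``SNP, EA, OA, EAF, BETA, SE, P, N`` (effect allele, other allele,
effect-allele frequency, per-allele beta).  LD is a sparse pairwise r^2 map
``{(id1, id2): r2}``; absent pairs are treated as independent (r^2 = 0) and
counted in the provenance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GWAS_COLUMNS",
    "GrsResult",
    "InstrumentSet",
    "HarmonizedPair",
    "SelectionResult",
    "validate_gwas_table",
    "ld_lookup",
    "build_grs",
    "ld_clump",
    "find_proxies",
    "harmonize_pair",
    "select_instruments",
]

GWAS_COLUMNS = ["SNP", "EA", "OA", "EAF", "BETA", "SE", "P", "N"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMES = ({"A", "T"}, {"C", "G"})

#: EAF window in which a palindromic SNP cannot be strand-oriented.
DEFAULT_PALINDROME_WINDOW = (0.42, 0.58)


def validate_gwas_table(df: pd.DataFrame, name: str = "gwas table") -> pd.DataFrame:
    """Check schema and basic invariants of a summary-statistics table."""
    missing = [c for c in GWAS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{name} missing columns: {missing}")
    bad_alleles = ~(df["EA"].isin(_COMPLEMENT) & df["OA"].isin(_COMPLEMENT))
    if bad_alleles.any():
        raise ValueError(f"{name}: non-ACGT alleles for SNPs {df.loc[bad_alleles, 'SNP'].tolist()}")
    eaf = df["EAF"]
    if ((eaf <= 0) | (eaf >= 1)).fillna(False).any():
        raise ValueError(f"{name}: EAF outside (0,1)")
    if (df["SE"] <= 0).any():
        raise ValueError(f"{name}: non-positive SE")
    if df["SNP"].duplicated().any():
        raise ValueError(f"{name}: duplicated SNP ids")
    return df


def ld_lookup(ld_r2: dict, a: str, b: str) -> float | None:
    """Symmetric lookup; returns None for absent pairs (caller decides)."""
    if a == b:
        return 1.0
    return ld_r2.get((a, b), ld_r2.get((b, a)))


@dataclass
class GrsResult:
    """A weighted genetic risk score per individual.

    ``score`` is the raw weighted sum of effect-allele dosages.  ``scaled``
    rescales by ``n_snps / sum(weights)`` so a one-unit increase corresponds
    to one additional average-effect allele (the conventional reporting unit
    for a risk-score effect on the exposure scale).
    """

    score: np.ndarray
    scaled: np.ndarray | None
    n_snps: int
    n_imputed: int


def _flip_dosage_orientation(counted: str, other: str, ea: str, oa: str) -> bool | None:
    """True if the dosage counts the weight's OA (so g -> 2-g); None if
    irreconcilable."""
    if counted == ea and other == oa:
        return False
    if counted == oa and other == ea:
        return True
    cc, co = _COMPLEMENT[counted], _COMPLEMENT[other]
    if cc == ea and co == oa:
        return False
    if cc == oa and co == ea:
        return True
    return None


def build_grs(dosages: pd.DataFrame, weights: pd.DataFrame, dosage_alleles: dict) -> GrsResult:
    """Weighted genetic risk score from effect-allele dosages.

    Parameters
    ----------
    dosages : DataFrame, individuals x SNPs
        Values in [0, 2]; NaN marks a missing call, imputed as 2 x EAF of
        the weight table.
    weights : GwasTable DataFrame
        Published per-allele betas; every weight SNP must be present in the
        dosage matrix with alleles resolvable by swap or strand complement.
    dosage_alleles : dict
        SNP id -> (counted_allele, other_allele) describing the dosage
        orientation.
    """
    validate_gwas_table(weights, "GRS weights")
    absent = [s for s in weights["SNP"] if s not in dosages.columns]
    if absent:
        raise ValueError(f"weight SNPs absent from dosage matrix: {absent}")
    mismatched = []
    n = len(dosages)
    score = np.zeros(n)
    n_imputed = 0
    for rec in weights.itertuples(index=False):
        counted, other = dosage_alleles[rec.SNP]
        flip = _flip_dosage_orientation(counted, other, rec.EA, rec.OA)
        if flip is None:
            mismatched.append(rec.SNP)
            continue
        g = dosages[rec.SNP].to_numpy(dtype=float)
        if flip:
            g = 2.0 - g
        miss = ~np.isfinite(g)
        if miss.any():
            g = np.where(miss, 2.0 * rec.EAF, g)
            n_imputed += int(miss.sum())
        score += rec.BETA * g
    if mismatched:
        raise ValueError(f"allele mismatch irresolvable by strand/flip rules: {mismatched}")
    wsum = float(weights["BETA"].sum())
    scaled = score * len(weights) / wsum if wsum != 0 else None
    return GrsResult(score=score, scaled=scaled, n_snps=len(weights), n_imputed=n_imputed)


@dataclass
class InstrumentSet:
    """Independent SNPs chosen to proxy one trait.

    ``snps`` holds the (possibly proxy-substituted) summary-statistic rows;
    ``provenance`` has one row per retained SNP with columns
    ``SNP, source (direct|proxy), original_id, proxy_r2``.
    """

    snps: pd.DataFrame
    provenance: pd.DataFrame
    p_threshold: float
    n_missing_ld_pairs: int = 0


def ld_clump(
    stats: pd.DataFrame, ld_r2: dict, p_threshold: float = 5e-8, r2_threshold: float = 0.01
) -> InstrumentSet:
    """Greedy LD clumping.

    SNPs passing ``P < p_threshold`` are visited in ascending p (ties broken
    by SNP id); a SNP is accepted iff its r^2 with every previously accepted
    SNP is below ``r2_threshold``.  Absent LD pairs are treated as r^2 = 0
    and counted.  An empty result is valid.
    """
    validate_gwas_table(stats, "clump input")
    passing = stats[stats["P"] < p_threshold].sort_values(["P", "SNP"], kind="mergesort")
    accepted: list[str] = []
    missing_pairs = 0
    for rec in passing.itertuples(index=False):
        independent = True
        for kept in accepted:
            r2 = ld_lookup(ld_r2, rec.SNP, kept)
            if r2 is None:
                missing_pairs += 1
                logger.debug("LD pair (%s, %s) absent from map; assuming r2=0", rec.SNP, kept)
                r2 = 0.0
            if r2 >= r2_threshold:
                independent = False
                break
        if independent:
            accepted.append(rec.SNP)
    kept_df = stats[stats["SNP"].isin(accepted)].sort_values("SNP", kind="mergesort")
    kept_df = kept_df.reset_index(drop=True)
    prov = pd.DataFrame(
        {
            "SNP": kept_df["SNP"],
            "source": "direct",
            "original_id": kept_df["SNP"],
            "proxy_r2": np.nan,
        }
    )
    return InstrumentSet(
        snps=kept_df,
        provenance=prov,
        p_threshold=p_threshold,
        n_missing_ld_pairs=missing_pairs,
    )


def find_proxies(needed, available, ld_r2: dict, r2_min: float = 0.8) -> dict:
    """Best-proxy lookup for instruments absent from an outcome dataset.

    For each needed SNP, returns ``(proxy_id, r2)`` for the available SNP
    with maximal r^2 above ``r2_min`` (ties broken by lexicographically
    smaller id), or ``None`` when no candidate qualifies.
    """
    if not 0 < r2_min <= 1:
        raise ValueError(f"r2_min must be in (0,1], got {r2_min}")
    available = sorted(set(available))
    out: dict = {}
    for snp in needed:
        best = None
        for cand in available:
            if cand == snp:
                continue
            r2 = ld_lookup(ld_r2, snp, cand)
            if r2 is None or r2 <= r2_min:
                continue
            # ties: candidates are visited in id order, so strict > keeps the
            # lexicographically smaller id
            if best is None or r2 > best[1]:
                best = (cand, r2)
        out[snp] = best
    return out


@dataclass
class HarmonizedPair:
    """Exposure and outcome effects aligned to a shared effect allele.

    ``table`` columns: SNP, EA, OA, beta_exp, se_exp, eaf_exp, beta_out,
    se_out, eaf_out, action (none|flipped).  ``dropped`` records SNPs removed
    during harmonization with a reason.
    """

    table: pd.DataFrame
    dropped: pd.DataFrame

    def __len__(self) -> int:
        return len(self.table)


def _is_palindromic(a1: str, a2: str) -> bool:
    return {a1, a2} in _PALINDROMES


def harmonize_pair(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    palindrome_window: tuple[float, float] = DEFAULT_PALINDROME_WINDOW,
) -> HarmonizedPair:
    """Align outcome records to the exposure table's effect alleles.

    Swapped alleles flip the outcome beta sign and complement its EAF;
    strand flips (A<->T, C<->G) are resolved by complementing.  Palindromic
    SNPs are oriented by EAF concordance and dropped when either EAF is
    missing or falls inside ``palindrome_window``.  Irreconcilable allele
    sets drop the SNP with a reason rather than failing.
    """
    validate_gwas_table(exposure, "exposure")
    validate_gwas_table(outcome, "outcome")
    out_idx = outcome.set_index("SNP")
    rows, dropped = [], []
    lo, hi = palindrome_window
    for e in exposure.itertuples(index=False):
        if e.SNP not in out_idx.index:
            dropped.append({"SNP": e.SNP, "reason": "absent_from_outcome"})
            continue
        o = out_idx.loc[e.SNP]
        b_out, eaf_out = float(o["BETA"]), o["EAF"]
        if _is_palindromic(e.EA, e.OA):
            if {o["EA"], o["OA"]} != {e.EA, e.OA}:
                dropped.append({"SNP": e.SNP, "reason": "allele_mismatch"})
                continue
            eaf_e, eaf_o = e.EAF, eaf_out
            ambiguous = (
                not np.isfinite(eaf_e)
                or not np.isfinite(eaf_o)
                or lo <= eaf_e <= hi
                or lo <= eaf_o <= hi
            )
            if ambiguous:
                dropped.append({"SNP": e.SNP, "reason": "palindromic_ambiguous"})
                continue
            # same labelled effect allele on a palindrome may sit on either
            # strand; frequencies orient it
            same_side = (eaf_e < 0.5) == (eaf_o < 0.5)
            label_match = o["EA"] == e.EA
            aligned = same_side if label_match else not same_side
            action = "none" if aligned else "flipped"
            if not aligned:
                b_out, eaf_out = -b_out, 1.0 - eaf_out
        else:
            flip = _flip_dosage_orientation(o["EA"], o["OA"], e.EA, e.OA)
            if flip is None:
                dropped.append({"SNP": e.SNP, "reason": "allele_mismatch"})
                continue
            action = "flipped" if flip else "none"
            if flip:
                b_out = -b_out
                eaf_out = 1.0 - eaf_out if np.isfinite(eaf_out) else eaf_out
        rows.append(
            {
                "SNP": e.SNP,
                "EA": e.EA,
                "OA": e.OA,
                "beta_exp": float(e.BETA),
                "se_exp": float(e.SE),
                "eaf_exp": e.EAF,
                "beta_out": b_out,
                "se_out": float(o["SE"]),
                "eaf_out": eaf_out,
                "action": action,
            }
        )
    cols = [
        "SNP", "EA", "OA", "beta_exp", "se_exp", "eaf_exp",
        "beta_out", "se_out", "eaf_out", "action",
    ]
    table = pd.DataFrame(rows, columns=cols)
    dropped_df = pd.DataFrame(dropped, columns=["SNP", "reason"])
    return HarmonizedPair(table=table, dropped=dropped_df)


@dataclass
class SelectionResult:
    """Analysis-ready harmonized pair plus a filter-count provenance report.

    ``counts`` conserves candidates at every stage:
    ``n_candidates = n_below_p + n_no_proxy + n_clumped_out + n_dropped_harmonization + n_final``.
    """

    pair: HarmonizedPair
    provenance: pd.DataFrame
    counts: dict = field(default_factory=dict)

    @property
    def empty(self) -> bool:
        return len(self.pair.table) == 0


def select_instruments(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    ld_r2: dict,
    p_threshold: float = 5e-8,
    proxy_r2: float = 0.8,
    clump_r2: float = 0.01,
    palindrome_window: tuple[float, float] = DEFAULT_PALINDROME_WINDOW,
    preselected: list[str] | None = None,
) -> SelectionResult:
    """Full instrument-selection pipeline for one exposure/outcome pair.

    Order of operations: p-value threshold -> cross-match to the outcome
    table with proxy substitution (r^2 > ``proxy_r2``) -> greedy LD clumping
    at ``clump_r2`` -> allele harmonization.  A proxy substitutes the
    original SNP's record with the proxy's own exposure-table record and is
    logged in the provenance.

    ``preselected`` bypasses the p-value gate with a fixed instrument list
    (e.g. a cis instrument set for an acute-phase protein); the listed SNPs
    must exist in the exposure table.
    """
    validate_gwas_table(exposure, "exposure")
    validate_gwas_table(outcome, "outcome")
    n_candidates = len(exposure)
    if preselected is not None:
        missing = [s for s in preselected if s not in set(exposure["SNP"])]
        if missing:
            raise ValueError(f"preselected SNPs absent from exposure table: {missing}")
        passing = exposure[exposure["SNP"].isin(preselected)].copy()
        n_below_p = 0
        n_candidates = len(passing)
    else:
        passing = exposure[exposure["P"] < p_threshold].copy()
        n_below_p = n_candidates - len(passing)

    # cross-match with proxy substitution
    outcome_ids = set(outcome["SNP"])
    exposure_by_id = exposure.set_index("SNP", drop=False)
    present = passing[passing["SNP"].isin(outcome_ids)]
    absent = [s for s in passing["SNP"] if s not in outcome_ids]
    # a proxy must carry exposure stats and appear in the outcome table
    proxy_pool = sorted((outcome_ids & set(exposure["SNP"])) - set(present["SNP"]))
    proxies = find_proxies(absent, proxy_pool, ld_r2, r2_min=proxy_r2)
    prov_records = {s: ("direct", s, np.nan) for s in present["SNP"]}
    rows = [present]
    used_proxies = set()
    n_no_proxy = 0
    for snp in absent:
        hit = proxies.get(snp)
        if hit is None or hit[0] in used_proxies:
            n_no_proxy += 1
            continue
        proxy_id, r2 = hit
        used_proxies.add(proxy_id)
        rows.append(exposure_by_id.loc[[proxy_id]])
        prov_records[proxy_id] = ("proxy", snp, r2)
    matched = pd.concat(rows, ignore_index=True).drop_duplicates(subset="SNP")

    clumped = ld_clump(matched, ld_r2, p_threshold=np.inf, r2_threshold=clump_r2)
    n_clumped_out = len(matched) - len(clumped.snps)

    pair = harmonize_pair(clumped.snps, outcome, palindrome_window=palindrome_window)
    n_dropped_harm = len(pair.dropped)

    prov = pd.DataFrame(
        [
            {"SNP": s, "source": src, "original_id": orig, "proxy_r2": r2}
            for s, (src, orig, r2) in prov_records.items()
            if s in set(pair.table["SNP"])
        ],
        columns=["SNP", "source", "original_id", "proxy_r2"],
    ).sort_values("SNP", kind="mergesort").reset_index(drop=True)
    counts = {
        "n_candidates": n_candidates,
        "n_below_p": n_below_p,
        "n_no_proxy": n_no_proxy,
        "n_proxied": int((prov["source"] == "proxy").sum()),
        "n_clumped_out": n_clumped_out,
        "n_dropped_harmonization": n_dropped_harm,
        "n_missing_ld_pairs": clumped.n_missing_ld_pairs,
        "n_final": len(pair.table),
    }
    return SelectionResult(pair=pair, provenance=prov, counts=counts)
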