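"""Tab-delimited and VCF input/output for cohorts, dosages, GWAS tables, LD.

All tabular formats are plain text with headers:

* cohort table: ``sample_id, bmi, cyt_001..., age, sex, pc1..pc10``
* dosage matrix: ``sample_id`` plus one column per SNP id
* GWAS table: ``SNP, EA, OA, EAF, BETA, SE, P, N``
* LD map: three columns ``id1, id2, r2``

Genotypes may optionally round-trip as uncompressed VCF with GT hard calls.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import pysam

from .instruments import GWAS_COLUMNS, validate_gwas_table
from .simulate import GenotypePanel

__all__ = [
    "read_gwas_table",
    "write_gwas_table",
    "read_cohort_table",
    "write_cohort_table",
    "read_dosages",
    "write_dosages",
    "read_ld_map",
    "write_ld_map",
    "write_vcf",
    "read_vcf_dosages",
]


def read_gwas_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return validate_gwas_table(df, name=str(path))


def write_gwas_table(df: pd.DataFrame, path) -> None:
    validate_gwas_table(df)
    df.to_csv(path, sep="\t", index=False, columns=GWAS_COLUMNS, float_format="%.10g")


def read_cohort_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns or "bmi" not in df.columns:
        raise ValueError(f"{path}: cohort table needs sample_id and bmi columns")
    return df


def write_cohort_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_dosages(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: dosage matrix needs a sample_id column")
    return df.set_index("sample_id")


def write_dosages(dosages: pd.DataFrame, sample_ids, path) -> None:
    out = dosages.copy()
    out.insert(0, "sample_id", list(sample_ids))
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_ld_map(path) -> dict:
    df = pd.read_csv(path, sep="\t")
    expected = ["id1", "id2", "r2"]
    if list(df.columns[:3]) != expected:
        raise ValueError(f"{path}: LD map needs columns {expected}")
    return {(a, b): float(r) for a, b, r in df.itertuples(index=False)}


def write_ld_map(ld_r2: dict, path) -> None:
    rows = sorted((a, b, r) for (a, b), r in ld_r2.items())
    pd.DataFrame(rows, columns=["id1", "id2", "r2"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def write_vcf(panel: GenotypePanel, sample_ids, path) -> None:
    """Write hard-called genotypes as an uncompressed VCF (GT field only)."""
    header = pysam.VariantHeader()
    header.add_line("##contig=<ID=1>")
    header.formats.add("GT", 1, "String", "Genotype")
    for s in sample_ids:
        header.add_sample(str(s))
    positions = (
        panel.positions
        if panel.positions is not None
        else np.arange(1, panel.n_snps + 1) * 10_000
    )
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for j, snp in enumerate(panel.snp_ids):
            rec = vcf.new_record(
                contig="1",
                start=int(positions[j]) - 1,
                stop=int(positions[j]),
                alleles=(panel.other_alleles[j], panel.effect_alleles[j]),
                id=snp,
            )
            col = panel.dosages[:, j]
            for i, s in enumerate(sample_ids):
                d = int(col[i])
                rec.samples[str(s)]["GT"] = [(0, 0), (0, 1), (1, 1)][d]
            vcf.write(rec)


def read_vcf_dosages(path) -> tuple[pd.DataFrame, dict]:
    """Read GT hard calls into an effect-allele (ALT) dosage matrix.

    Returns the dosage DataFrame (samples x SNPs) and a SNP -> (counted,
    other) allele map, with the ALT allele counted.
    """
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        cols: dict[str, np.ndarray] = {}
        alleles: dict[str, tuple[str, str]] = {}
        for rec in vcf:
            dos = np.array(
                [
                    sum(1 for a in rec.samples[s]["GT"] if a == 1)
                    if None not in rec.samples[s]["GT"]
                    else np.nan
                    for s in samples
                ],
                dtype=float,
            )
            cols[rec.id] = dos
            alleles[rec.id] = (rec.alts[0], rec.ref)
    df = pd.DataFrame(cols, index=samples)
    df.index.name = "sample_id"
    return df, alleles


def sha256_of(path) -> str:
    import hashlib

    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def ensure_dir(path) -> str:
    os.makedirs(path, exist_ok=True)
    return str(path)
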