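"""Readers and writers for the formats the pipeline touches.

Genotypes go out both as an uncompressed VCF (hard-call GT derived from
dosages, ALT = counted effect allele) and as a plain TSV dosage matrix,
which is also the round-trip format the other stages read.  Result
tables are TSV/CSV with a leading ``# config_digest=...`` comment line
so every output is traceable to the configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CohortGenotypes
from .errors import DataError

__all__ = ["config_digest", "write_table", "read_table",
           "write_dosage_tsv", "read_dosage_tsv",
           "write_covariates_csv", "write_vcf", "read_vcf",
           "read_genotypes"]


def config_digest(config_obj) -> str:
    """Stable 12-hex digest of a configuration mapping/dataclass."""
    try:
        payload = json.dumps(config_obj, sort_keys=True, default=str)
    except TypeError:
        payload = repr(config_obj)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, digest: str | None = None,
                sep: str = "\t") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if digest is not None:
            fh.write(f"# config_digest={digest}\n")
        df.to_csv(fh, sep=sep, index=False)


def read_table(path, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#")


def write_dosage_tsv(genotypes: CohortGenotypes, path,
                     digest: str | None = None) -> None:
    """Subjects x SNPs dosage matrix plus a SNP metadata header block."""
    meta = pd.DataFrame({
        "snp_id": genotypes.snp_ids,
        "chrom": genotypes.chrom if genotypes.chrom is not None
        else np.repeat("NA", genotypes.n_snps),
        "pos": genotypes.pos if genotypes.pos is not None
        else np.repeat(-1, genotypes.n_snps),
        "effect_allele": genotypes.effect_alleles,
        "other_allele": genotypes.other_alleles,
    })
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if digest is not None:
            fh.write(f"# config_digest={digest}\n")
        for rec in meta.itertuples(index=False):
            fh.write(f"## SNP {rec.snp_id} {rec.chrom} {rec.pos} "
                     f"{rec.effect_allele} {rec.other_allele}\n")
        genotypes.dosage_frame().to_csv(fh, sep="\t", index=False,
                                        na_rep="NA")


def read_dosage_tsv(path, covariates_path=None) -> CohortGenotypes:
    """Rebuild :class:`CohortGenotypes` from the TSV pair written by
    :func:`write_dosage_tsv` / :func:`write_covariates_csv`."""
    meta_rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("## SNP "):
                _, _, sid, chrom, pos, ea, oa = line.split()
                meta_rows.append((sid, chrom, int(pos), ea, oa))
            elif not line.startswith("#"):
                break
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
    snp_ids = [c for c in df.columns if c != "subject_id"]
    meta = {r[0]: r for r in meta_rows}
    missing = [s for s in snp_ids if s not in meta]
    if missing:
        raise DataError(f"dosage TSV lacks metadata lines for {missing}")
    if covariates_path is not None:
        cov = pd.read_csv(covariates_path, comment="#")
        cov = cov.set_index("subject_id").reindex(df["subject_id"])
        sex = cov["sex"].to_numpy(float)
        pc1 = cov["pc1"].to_numpy(float)
        status = cov["status"].to_numpy() if "status" in cov else None
        if status is not None:
            status = status.astype(int)
    else:
        n = len(df)
        sex = np.zeros(n)
        pc1 = np.zeros(n)
        status = None
    return CohortGenotypes(
        subject_ids=df["subject_id"].to_numpy(str),
        snp_ids=np.array(snp_ids),
        effect_alleles=np.array([meta[s][3] for s in snp_ids]),
        other_alleles=np.array([meta[s][4] for s in snp_ids]),
        dosages=df[snp_ids].to_numpy(float),
        sex=sex, pc1=pc1, status=status,
        chrom=np.array([meta[s][1] for s in snp_ids]),
        pos=np.array([meta[s][2] for s in snp_ids]),
    )


def write_covariates_csv(genotypes: CohortGenotypes, path,
                         digest: str | None = None) -> None:
    write_table(genotypes.covariate_frame(), path, digest=digest, sep=",")


def read_vcf(path, covariates_path=None) -> CohortGenotypes:
    """Rebuild a cohort from an (uncompressed) VCF with GT calls.

    The ALT allele is taken as the counted effect allele, so dosages are
    ALT-allele counts; ``./.`` becomes a missing dosage.
    """
    samples = None
    snp_rows = []
    gt_cols = []
    allele_count = {"0/0": 0.0, "0/1": 1.0, "1/0": 1.0, "1/1": 2.0,
                    "0|0": 0.0, "0|1": 1.0, "1|0": 1.0, "1|1": 2.0}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                samples = line.split("\t")[9:]
                continue
            fields = line.split("\t")
            chrom, pos, sid, ref, alt = fields[:5]
            fmt = fields[8].split(":")
            gt_idx = fmt.index("GT")
            calls = [f.split(":")[gt_idx] for f in fields[9:]]
            gt_cols.append([allele_count.get(c, np.nan) for c in calls])
            snp_rows.append((sid, chrom, int(pos), alt, ref))
    if samples is None or not snp_rows:
        raise DataError(f"{path}: no VCF header/records found")
    dosages = np.asarray(gt_cols, float).T  # subjects x SNPs
    n = len(samples)
    if covariates_path is not None:
        cov = pd.read_csv(covariates_path, comment="#")
        cov = cov.set_index("subject_id").reindex(samples)
        sex = cov["sex"].to_numpy(float)
        pc1 = cov["pc1"].to_numpy(float)
        status = cov["status"].to_numpy().astype(int) \
            if "status" in cov else None
    else:
        sex, pc1, status = np.zeros(n), np.zeros(n), None
    return CohortGenotypes(
        subject_ids=np.array(samples),
        snp_ids=np.array([r[0] for r in snp_rows]),
        effect_alleles=np.array([r[3] for r in snp_rows]),
        other_alleles=np.array([r[4] for r in snp_rows]),
        dosages=dosages,
        sex=sex, pc1=pc1, status=status,
        chrom=np.array([r[1] for r in snp_rows]),
        pos=np.array([r[2] for r in snp_rows]),
    )


def read_genotypes(path, covariates_path=None) -> CohortGenotypes:
    """Dispatch on extension: ``.vcf`` or the dosage-TSV format."""
    if str(path).endswith(".vcf"):
        return read_vcf(path, covariates_path)
    return read_dosage_tsv(path, covariates_path)


def write_vcf(genotypes: CohortGenotypes, path) -> None:
    """Uncompressed VCF 4.2 with hard-call GTs rounded from dosages.

    REF is the non-counted (other) allele and ALT the counted effect
    allele, so the ALT allele count equals the rounded dosage; missing
    dosages become ``./.``.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    chrom = genotypes.chrom if genotypes.chrom is not None \
        else np.repeat("1", genotypes.n_snps)
    pos = genotypes.pos if genotypes.pos is not None \
        else np.arange(1, genotypes.n_snps + 1)
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                 'Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.subject_ids) + "\n")
        for j in range(genotypes.n_snps):
            calls = []
            for d in genotypes.dosages[:, j]:
                if np.isnan(d):
                    calls.append("./.")
                else:
                    calls.append(gt_map[int(round(d))])
            fh.write("\t".join([
                str(chrom[j]), str(int(pos[j])), genotypes.snp_ids[j],
                genotypes.other_alleles[j], genotypes.effect_alleles[j],
                ".", "PASS", ".", "GT", *calls]) + "\n")
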