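"""Readers and writers for the pipeline's file formats.

Genotypes travel as PLINK bed/bim/fam triples (SNP-major 2-bit codec) or as
plain VCF (read through cyvcf2, biallelic SNPs only); phenotypes as
long-format CSV ``id,trait,value,year,herd,sex,age``; kinship matrices as a
dense lower-triangle text layout with an id header.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .grm import KinshipMatrix

log = logging.getLogger(__name__)

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "read_kinship",
    "write_kinship",
]

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major
# 2-bit PLINK codes -> dosage of the bim A1 allele (01 = missing)
_BED_DECODE = np.array([2.0, np.nan, 1.0, 0.0])

PHENO_COLUMNS = ["id", "trait", "value", "year", "herd", "sex", "age"]


# ---------------------------------------------------------------- PLINK bed

def _read_plink(prefix: str | Path) -> GenotypeMatrix:
    prefix = str(prefix)
    fam = pd.read_csv(
        prefix + ".fam", sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"], dtype={"iid": str},
    )
    bim = pd.read_csv(
        prefix + ".bim", sep=r"\s+", header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
    )
    n, m = len(fam), len(bim)
    raw = Path(prefix + ".bed").read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise ValueError(f"{prefix}.bed: bad magic bytes (not SNP-major PLINK bed)")
    bytes_per_snp = math.ceil(n / 4)
    expected = 3 + bytes_per_snp * m
    if len(raw) != expected:
        raise ValueError(
            f"{prefix}.bed: {len(raw)} bytes but fam/bim imply {expected} "
            f"({n} individuals x {m} SNPs)"
        )
    data = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, bytes_per_snp)
    shifts = np.arange(4) * 2
    codes = (data[:, :, None] >> shifts[None, None, :]) & 0b11  # m x bytes x 4
    codes = codes.reshape(m, bytes_per_snp * 4)[:, :n]
    dosages = _BED_DECODE[codes].T.copy()  # n x m
    snps = bim[["id", "chrom", "pos", "a1", "a2"]].copy()
    return GenotypeMatrix(dosages, fam["iid"].to_numpy(dtype=object), snps)


def _write_plink(geno: GenotypeMatrix, prefix: str | Path) -> None:
    prefix = str(prefix)
    n, m = geno.n_individuals, geno.n_snps
    fam = pd.DataFrame(
        {"fid": geno.ids, "iid": geno.ids, "father": 0, "mother": 0, "sex": 0, "pheno": -9}
    )
    fam.to_csv(prefix + ".fam", sep="\t", header=False, index=False)
    bim = geno.snps.assign(cm=0)[["chrom", "id", "cm", "pos", "a1", "a2"]]
    bim.to_csv(prefix + ".bim", sep="\t", header=False, index=False)

    code = np.full(geno.dosages.shape, 1, dtype=np.uint8)  # missing
    ok = ~np.isnan(geno.dosages)
    rounded = np.zeros_like(geno.dosages)
    rounded[ok] = np.rint(geno.dosages[ok])
    code[ok & (rounded == 2)] = 0
    code[ok & (rounded == 1)] = 2
    code[ok & (rounded == 0)] = 3
    bytes_per_snp = math.ceil(n / 4)
    padded = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)
    padded[:, :n] = code.T
    packed = (
        padded[:, 0::4] | (padded[:, 1::4] << 2) | (padded[:, 2::4] << 4) | (padded[:, 3::4] << 6)
    )
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


# --------------------------------------------------------------------- VCF

def _read_vcf(path: str | Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = np.array(vcf.samples, dtype=object)
    rows, meta = [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        # dosage of ALT; gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        g = var.gt_types.astype(float)
        dos = np.select([g == 0, g == 1, g == 3], [0.0, 1.0, 2.0], default=np.nan)
        rows.append(dos)
        meta.append((var.ID or f"{var.CHROM}:{var.POS}", var.CHROM, var.POS, var.ALT[0], var.REF))
    vcf.close()
    if n_multi:
        log.warning("skipped %d multiallelic VCF records", n_multi)
    if not rows:
        raise ValueError(f"{path}: no biallelic SNP records")
    snps = pd.DataFrame(meta, columns=["id", "chrom", "pos", "a1", "a2"])
    try:
        snps["chrom"] = snps["chrom"].astype(int)
    except (TypeError, ValueError):
        pass
    return GenotypeMatrix(np.array(rows).T, ids, snps)


def _write_vcf(geno: GenotypeMatrix, path: str | Path) -> None:
    gt_of = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = pd.unique(geno.snps["chrom"])
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(map(str, geno.ids)) + "\n")
        for j in range(geno.n_snps):
            row = geno.snps.iloc[j]
            gts = [
                "./." if np.isnan(d) else gt_of[float(np.rint(d))]
                for d in geno.dosages[:, j]
            ]
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['id']}\t{row['a2']}\t{row['a1']}"
                f"\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    """Load a PLINK bed/bim/fam prefix or a VCF into a GenotypeMatrix."""
    s = str(path)
    if s.endswith((".vcf", ".vcf.gz")):
        return _read_vcf(s)
    if s.endswith(".bed"):
        s = s[:-4]
    return _read_plink(s)


def write_genotypes(geno: GenotypeMatrix, path: str | Path) -> None:
    """Write a GenotypeMatrix to a PLINK prefix or a VCF (.vcf suffix)."""
    s = str(path)
    if s.endswith(".vcf"):
        _write_vcf(geno, s)
    else:
        _write_plink(geno, s)


# -------------------------------------------------------------- phenotypes

def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", dtype={"id": str})
    missing = [c for c in PHENO_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: phenotype file lacks columns {missing}")
    return df[PHENO_COLUMNS]


def write_phenotypes(records: pd.DataFrame, path: str | Path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        records.to_csv(fh, index=False)


# ----------------------------------------------------------------- kinship

def write_kinship(K: KinshipMatrix, path: str | Path, header: str | None = None) -> None:
    """Dense lower-triangle text layout: id header then one row per individual."""
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write(f"# kind={K.kind} n_markers={K.n_markers_used} blend_beta={K.blend_beta}\n")
        fh.write(",".join(map(str, K.ids)) + "\n")
        for i in range(K.n):
            fh.write(",".join(f"{v:.10g}" for v in K.values[i, : i + 1]) + "\n")


def read_kinship(path: str | Path) -> KinshipMatrix:
    kind, n_markers, beta = "all", 0, 0.0
    with open(path) as fh:
        lines = fh.read().splitlines()
    body = []
    for ln in lines:
        if ln.startswith("#"):
            if "kind=" in ln:
                parts = dict(p.split("=") for p in ln.lstrip("# ").split())
                kind = parts.get("kind", "all")
                n_markers = int(parts.get("n_markers", 0))
                beta = float(parts.get("blend_beta", 0.0))
            continue
        body.append(ln)
    ids = np.array(body[0].split(","), dtype=object)
    n = len(ids)
    vals = np.zeros((n, n))
    for i in range(n):
        row = np.array(body[1 + i].split(","), dtype=float)
        vals[i, : i + 1] = row
        vals[: i + 1, i] = row
    return KinshipMatrix(ids, vals, kind=kind, n_markers_used=n_markers, blend_beta=beta)
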