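"""Diploid dosage matrices and VCF input/output.

Genotypes are held as a samples x SNPs dosage matrix (count of alternate
alleles, ``nan`` for missing calls) together with per-call sequencing depth
(DP), 1-based positions and biallelic ref/alt alleles — the representation
every population-genetics stage of the package operates on.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix", "read_vcf", "write_vcf"]


@dataclasses.dataclass
class GenotypeMatrix:
    """Biallelic SNP dosages for a panel of (inbred) lines.

    Attributes
    ----------
    samples : list of sample ids
    chrom, pos, ref, alt : per-SNP arrays; ``pos`` is 1-based and strictly
        increasing within a chromosome
    dosage : float array (n_samples, n_snps) in {0, 1, 2, nan}
    dp : int array (n_samples, n_snps), read depth per call
    metadata : optional per-sample table (e.g. collection of origin)
    """

    samples: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    dosage: np.ndarray
    dp: np.ndarray
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        n, m = self.dosage.shape
        if n != len(self.samples):
            raise ValueError("dosage rows must match samples")
        if m != len(self.pos):
            raise ValueError("dosage columns must match SNP records")
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if len(p) > 1 and not (np.diff(p) > 0).all():
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.pos)

    def take_snps(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            samples=list(self.samples),
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            dosage=self.dosage[:, idx],
            dp=self.dp[:, idx],
            metadata=self.metadata,
        )

    def take_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        meta = self.metadata.iloc[idx] if self.metadata is not None else None
        return GenotypeMatrix(
            samples=[self.samples[i] for i in np.atleast_1d(idx)],
            chrom=self.chrom,
            pos=self.pos,
            ref=self.ref,
            alt=self.alt,
            dosage=self.dosage[idx],
            dp=self.dp[idx],
            metadata=meta,
        )


_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(geno: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCFv4.2 with GT:DP fields."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for c in pd.unique(geno.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.samples)
            + "\n"
        )
        for j in range(geno.n_snps):
            calls = []
            for i in range(geno.n_samples):
                d = geno.dosage[i, j]
                gt = "./." if np.isnan(d) else _GT_STRING[int(d)]
                calls.append(f"{gt}:{int(geno.dp[i, j])}")
            fh.write(
                f"{geno.chrom[j]}\t{int(geno.pos[j])}\tsnp{j}\t{geno.ref[j]}\t"
                f"{geno.alt[j]}\t.\tPASS\t.\tGT:DP\t" + "\t".join(calls) + "\n"
            )


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read biallelic SNPs with GT and DP from a VCF via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chrom, pos, ref, alt, dos, dp = [], [], [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            continue  # biallelic SNPs only
        chrom.append(var.CHROM)
        pos.append(var.POS)
        ref.append(var.REF)
        alt.append(var.ALT[0])
        # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        gt = var.gt_types.astype(float)
        d = np.where(gt == 3, 2.0, gt)
        d[gt == 2] = np.nan
        dos.append(d)
        depth = var.format("DP")
        dp.append(
            np.zeros(len(samples), dtype=int)
            if depth is None
            else np.nan_to_num(depth[:, 0].astype(float)).astype(int)
        )
    vcf.close()
    return GenotypeMatrix(
        samples=samples,
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        dosage=np.array(dos).T if dos else np.empty((len(samples), 0)),
        dp=np.array(dp).T if dp else np.empty((len(samples), 0), dtype=int),
    )
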