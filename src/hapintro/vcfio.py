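"""Phased-VCF I/O, the haplotype container, and variant QC.

``HaplotypeMatrix`` is the substrate of every statistic in the package: one
row per haplotype (two per diploid sample, sample-major order), one column
per biallelic SNV, entries in {0, 1}.  Missing genotypes are not supported
downstream; the QC filter removes them (the analyses assume imputed, phased
input).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .intervals import GenomicInterval

logger = logging.getLogger("hapintro")

_SNV_ALLELES = {"A", "C", "G", "T"}


@dataclass
class VariantTable:
    """Biallelic SNV coordinates: chrom, 1-based pos, id, ref, alt."""

    frame: pd.DataFrame  # columns: chrom, pos, id, ref, alt

    def __post_init__(self) -> None:
        req = {"chrom", "pos", "id", "ref", "alt"}
        if not req.issubset(self.frame.columns):
            raise ValueError(f"VariantTable needs columns {sorted(req)}")
        for chrom, sub in self.frame.groupby("chrom", sort=False):
            p = sub["pos"].to_numpy()
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def chrom(self) -> np.ndarray:
        return self.frame["chrom"].to_numpy()

    @property
    def pos(self) -> np.ndarray:
        return self.frame["pos"].to_numpy()

    def subset(self, idx) -> "VariantTable":
        return VariantTable(self.frame.iloc[idx].reset_index(drop=True))


@dataclass
class HaplotypeMatrix:
    """Phased 0/1 alleles, (2 x n_samples) haplotypes x m variants."""

    variants: VariantTable
    alleles: np.ndarray  # int8, shape (2*n_samples, m)
    sample_ids: list[str]
    haplotype_phase: np.ndarray = field(default=None)  # 0/1 per row

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.shape[0] != 2 * len(self.sample_ids):
            raise ValueError("row count != 2 x sample count")
        if self.alleles.shape[1] != len(self.variants):
            raise ValueError("column count != variant count")
        if self.haplotype_phase is None:
            self.haplotype_phase = np.tile([0, 1], len(self.sample_ids))

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_variants(self) -> int:
        return self.alleles.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per site (missing entries excluded)."""
        a = self.alleles
        valid = a >= 0
        with np.errstate(invalid="ignore"):
            return np.where(valid, a, 0).sum(0) / valid.sum(0)

    def dosages(self) -> np.ndarray:
        """Per-sample alt-allele dosage (n_samples x m, values 0/1/2)."""
        return self.alleles.reshape(self.n_samples, 2, -1).sum(1)

    def subset_variants(self, idx) -> "HaplotypeMatrix":
        return HaplotypeMatrix(
            self.variants.subset(idx),
            self.alleles[:, idx],
            list(self.sample_ids),
            self.haplotype_phase.copy(),
        )

    def subset_samples(self, sample_ids: list[str]) -> "HaplotypeMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = []
        for s in sample_ids:
            if s not in index:
                raise KeyError(f"unknown sample id: {s}")
            rows.extend([2 * index[s], 2 * index[s] + 1])
        return HaplotypeMatrix(
            self.variants,
            self.alleles[rows],
            list(sample_ids),
            self.haplotype_phase[rows],
        )


class UnphasedGenotypeError(ValueError):
    pass


def read_phased_vcf(
    path: str, region: Optional[GenomicInterval] = None
) -> tuple[VariantTable, HaplotypeMatrix]:
    """Read a phased VCF into a (VariantTable, HaplotypeMatrix) pair.

    Only biallelic SNVs are kept; multiallelic or indel records are skipped
    with a logged count.  Any unphased genotype raises
    ``UnphasedGenotypeError`` naming the offending record.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    rows = []
    haps = []
    n_skipped = 0
    for v in vcf:
        if len(v.ALT) != 1 or v.REF not in _SNV_ALLELES or v.ALT[0] not in _SNV_ALLELES:
            n_skipped += 1
            continue
        if region is not None and not (
            v.CHROM == region.chrom and region.start <= v.POS - 1 < region.end
        ):
            continue
        col = np.empty(2 * len(samples), dtype=np.int8)
        for si, gt in enumerate(v.genotypes):
            a, b, phased = gt[0], gt[1], gt[-1]
            if not phased:
                raise UnphasedGenotypeError(
                    f"unphased genotype for sample {samples[si]} at {v.CHROM}:{v.POS}"
                )
            col[2 * si] = a
            col[2 * si + 1] = b
        rows.append((v.CHROM, v.POS, v.ID or f"{v.CHROM}:{v.POS}", v.REF, v.ALT[0]))
        haps.append(col)
    if n_skipped:
        logger.info("read_phased_vcf: skipped %d non-biallelic-SNV records", n_skipped)
    vt = VariantTable(pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt"]))
    hm = HaplotypeMatrix(
        vt, np.array(haps, dtype=np.int8).T if haps else np.empty((2 * len(samples), 0), np.int8), samples
    )
    logger.info(
        "read_phased_vcf: %d samples, %d variants from %s", len(samples), len(vt), path
    )
    return vt, hm


def write_phased_vcf(path: str, hm: HaplotypeMatrix) -> None:
    """Write a HaplotypeMatrix as an uncompressed phased VCF (via pysam)."""
    import pysam

    header = pysam.VariantHeader()
    header.add_meta("source", "hapintro")
    for chrom, sub in hm.variants.frame.groupby("chrom", sort=False):
        header.contigs.add(str(chrom), length=int(sub["pos"].max()) + 1)
    header.formats.add("GT", 1, "String", "Genotype")
    for s in hm.sample_ids:
        header.add_sample(s)
    with pysam.VariantFile(path, "w", header=header) as out:
        for j, row in hm.variants.frame.iterrows():
            rec = out.new_record(
                contig=str(row["chrom"]),
                start=int(row["pos"]) - 1,
                stop=int(row["pos"]),
                alleles=(row["ref"], row["alt"]),
                id=str(row["id"]),
            )
            for si in range(hm.n_samples):
                rec.samples[si]["GT"] = (
                    int(hm.alleles[2 * si, j]),
                    int(hm.alleles[2 * si + 1, j]),
                )
                rec.samples[si].phased = True
            out.write(rec)


def hwe_exact_midp(n_het: int, n_hom_ref: int, n_hom_alt: int) -> float:
    """Mid-p exact Hardy-Weinberg test on diploid genotype counts.

    Conditional on the observed allele counts, heterozygote counts follow
    the Levene-Haldane distribution; the two-sided mid-p value sums the
    probabilities of configurations less probable than the observed one
    plus half the observed configuration's probability.
    """
    n = n_het + n_hom_ref + n_hom_alt
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    if n == 0:
        return 1.0
    # possible het counts share parity with n_rare
    hets = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    logp = np.zeros(len(hets))
    from scipy.special import gammaln

    n_common = 2 * n - n_rare
    for i, h in enumerate(hets):
        rr = (n_rare - h) // 2
        cc = (n_common - h) // 2
        logp[i] = (
            h * np.log(2)
            + gammaln(n + 1)
            - gammaln(h + 1)
            - gammaln(rr + 1)
            - gammaln(cc + 1)
        )
    logp -= np.logaddexp.reduce(logp)
    p = np.exp(logp)
    p_obs = p[hets == n_het][0]
    return float(min(1.0, p[p < p_obs].sum() + 0.5 * p[np.isclose(p, p_obs)].sum()))


def filter_variants(
    vt: VariantTable,
    hm: HaplotypeMatrix,
    maf_min: float = 0.05,
    max_missing: float = 0.0,
    hwe_p_min: Optional[float] = None,
    drop_indels: bool = True,
) -> tuple[VariantTable, HaplotypeMatrix]:
    """Site-level QC: MAF, missingness, and optional exact-HWE filtering.

    MAF is computed over all haplotypes; HWE uses the mid-p exact test on
    diploid genotype counts.  Original site order is preserved and the
    filter is idempotent.
    """
    if not (0.0 <= maf_min < 0.5):
        raise ValueError("maf_min must lie in [0, 0.5)")
    a = hm.alleles
    miss_frac = (a < 0).mean(0)
    freq = hm.allele_freq()
    maf = np.minimum(freq, 1 - freq)
    keep = (maf >= maf_min) & (miss_frac <= max_missing)
    if drop_indels:
        ok = vt.frame["ref"].isin(_SNV_ALLELES) & vt.frame["alt"].isin(_SNV_ALLELES)
        keep &= ok.to_numpy()
    if hwe_p_min is not None:
        geno = hm.dosages()
        for j in np.flatnonzero(keep):
            g = geno[:, j]
            g = g[g >= 0]
            p = hwe_exact_midp(
                int((g == 1).sum()), int((g == 0).sum()), int((g == 2).sum())
            )
            if p < hwe_p_min:
                keep[j] = False
    idx = np.flatnonzero(keep)
    logger.info("filter_variants: %d -> %d sites", len(vt), len(idx))
    return vt.subset(idx), hm.subset_variants(idx)


def read_phenotypes(path: str) -> pd.DataFrame:
    """Read a phenotype TSV (sample_id, trait columns, covariates)."""
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ValueError("phenotype table needs a 'sample_id' column")
    return df


def read_expression(path: str) -> pd.DataFrame:
    """Read a genes x samples TPM TSV; first column is gene_id."""
    return pd.read_csv(path, sep="\t", index_col=0)
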