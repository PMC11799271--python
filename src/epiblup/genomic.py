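"""Genotype QC, genomic relationship matrix, blending, and H⁻¹ assembly.

The single-step relationship matrix H combines pedigree and genomic
information; its inverse is formed directly as

    H⁻¹ = A⁻¹ + [0 0; 0 τ(αG + βA22)⁻¹ − ω A22⁻¹]

on the genotyped block, with default scaling τ = ω = 1 and blending
α = 0.95, β = 0.05.  G follows VanRaden's method 1: centred marker codes
scaled by 2Σp(1−p) at observed allele frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sparsesym import SparseSymTriplets

MISSING = -9


@dataclass
class GenotypeMatrix:
    """0/1/2 marker codes (MISSING = -9) with a SNP map.

    ``individuals`` are pedigree ids (renumbered).  ``snp_map`` carries
    columns snp, chrom, pos; chrom 0 or pos 0 marks an unmapped SNP.
    """

    individuals: np.ndarray
    codes: np.ndarray
    snp_map: pd.DataFrame

    def __post_init__(self):
        self.individuals = np.asarray(self.individuals, dtype=np.int64)
        self.codes = np.asarray(self.codes, dtype=np.int16)
        if self.codes.shape != (len(self.individuals), len(self.snp_map)):
            raise ValueError("codes shape does not match ids / SNP map")
        valid = np.isin(self.codes, (0, 1, 2, MISSING))
        if not valid.all():
            raise ValueError("genotype codes must be 0/1/2 or missing")

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """Observed alternate-allele frequency per SNP, ignoring missing."""
        obs = self.codes != MISSING
        counts = np.where(obs, self.codes, 0).sum(axis=0)
        denom = 2.0 * obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(denom > 0, counts / denom, np.nan)

    def write(self, matrix_path, map_path) -> None:
        with open(matrix_path, "w") as fh:
            for i, row in zip(self.individuals, self.codes):
                fh.write(f"{i} " + " ".join(str(int(c)) for c in row) + "\n")
        self.snp_map.to_csv(map_path, sep=" ", index=False)

    @classmethod
    def read(cls, matrix_path, map_path) -> "GenotypeMatrix":
        ids, rows = [], []
        with open(matrix_path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                ids.append(int(parts[0]))
                rows.append([int(x) for x in parts[1:]])
        snp_map = pd.read_csv(map_path, sep=r"\s+")
        return cls(np.asarray(ids), np.asarray(rows), snp_map)


@dataclass
class QCThresholds:
    min_sample_call_rate: float = 0.90
    min_snp_call_rate: float = 0.90
    min_maf: float = 0.05
    max_het_deviation: float = 0.15
    autosomes: tuple[int, int] = (1, 18)  # porcine autosome range


@dataclass
class QCReport:
    samples_in: int
    snps_in: int
    samples_call_rate: int = 0
    snps_call_rate: int = 0
    snps_maf: int = 0
    snps_het_deviation: int = 0
    snps_map: int = 0

    @property
    def samples_out(self) -> int:
        return self.samples_in - self.samples_call_rate

    @property
    def snps_out(self) -> int:
        return (self.snps_in - self.snps_call_rate - self.snps_maf
                - self.snps_het_deviation - self.snps_map)


def qc_genotypes(geno: GenotypeMatrix,
                 thresholds: QCThresholds | None = None
                 ) -> tuple[GenotypeMatrix, QCReport]:
    """Filter samples and SNPs; returns surviving genotypes plus counts.

    Order: sample call rate first, then (on recomputed frequencies) SNP call
    rate, MAF, heterozygosity deviation from the HWE expectation 2p(1−p), and
    map filters (non-autosomal or unmapped).  A SNP is charged to the first
    filter it fails.
    """
    th = thresholds or QCThresholds()
    rep = QCReport(samples_in=geno.n_individuals, snps_in=geno.n_snps)

    obs = geno.codes != MISSING
    sample_cr = obs.mean(axis=1)
    keep_s = sample_cr >= th.min_sample_call_rate
    rep.samples_call_rate = int((~keep_s).sum())

    codes = geno.codes[keep_s]
    obs = codes != MISSING
    n_kept = codes.shape[0]
    if n_kept == 0:
        raise ValueError("no samples survive the call-rate filter")

    snp_cr = obs.mean(axis=0)
    counts = np.where(obs, codes, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(obs.sum(axis=0) > 0, counts / (2.0 * obs.sum(axis=0)),
                     np.nan)
        maf = np.minimum(p, 1.0 - p)
        het_obs = np.where(obs.sum(axis=0) > 0,
                           (codes == 1).sum(axis=0) / obs.sum(axis=0), np.nan)
    het_exp = 2.0 * p * (1.0 - p)

    fail_cr = snp_cr < th.min_snp_call_rate
    fail_maf = ~fail_cr & (np.isnan(maf) | (maf < th.min_maf))
    fail_het = (~fail_cr & ~fail_maf
                & (np.abs(het_obs - het_exp) > th.max_het_deviation))
    chrom = geno.snp_map["chrom"].to_numpy()
    pos = geno.snp_map["pos"].to_numpy()
    lo, hi = th.autosomes
    fail_map = (~fail_cr & ~fail_maf & ~fail_het
                & ((chrom < lo) | (chrom > hi) | (pos <= 0)))

    rep.snps_call_rate = int(fail_cr.sum())
    rep.snps_maf = int(fail_maf.sum())
    rep.snps_het_deviation = int(fail_het.sum())
    rep.snps_map = int(fail_map.sum())

    keep_m = ~(fail_cr | fail_maf | fail_het | fail_map)
    if not keep_m.any():
        raise ValueError("all SNPs removed by QC")
    out = GenotypeMatrix(
        individuals=geno.individuals[keep_s],
        codes=codes[:, keep_m],
        snp_map=geno.snp_map.loc[keep_m].reset_index(drop=True),
    )
    return out, rep


def build_grm(geno: GenotypeMatrix) -> np.ndarray:
    """VanRaden method-1 genomic relationship matrix.

    Z = M − 2p with missing codes imputed to 2p; G = ZZ′ / (2Σ pⱼ(1−pⱼ)).
    """
    p = geno.allele_frequencies()
    denom = 2.0 * np.nansum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("all SNPs monomorphic: G denominator is zero")
    m = geno.codes.astype(float)
    m[geno.codes == MISSING] = np.nan
    z = np.where(np.isnan(m), 0.0, m - 2.0 * p)  # missing → 2p, i.e. Z = 0
    return (z @ z.T) / denom


def blend_grm(g: np.ndarray, a22: np.ndarray, alpha: float = 0.95,
              beta: float = 0.05) -> np.ndarray:
    """G_blended = αG + βA22; α + β must equal 1."""
    if abs(alpha + beta - 1.0) > 1e-12:
        raise ValueError("alpha + beta must equal 1")
    g = np.asarray(g, dtype=float)
    a22 = np.asarray(a22, dtype=float)
    if g.shape != a22.shape:
        raise ValueError("G and A22 are not conformable")
    return alpha * g + beta * a22


def build_h_inverse(a_inv: SparseSymTriplets, a22: np.ndarray,
                    g_blended: np.ndarray, genotyped_ids,
                    tau: float = 1.0, omega: float = 1.0
                    ) -> SparseSymTriplets:
    """H⁻¹ = A⁻¹ + [0 0; 0 τG_b⁻¹ − ωA22⁻¹] on the genotyped block."""
    genotyped_ids = np.asarray(list(genotyped_ids), dtype=np.int64)
    out = SparseSymTriplets(n=a_inv.n)
    out.rows = list(a_inv.rows)
    out.cols = list(a_inv.cols)
    out.vals = list(a_inv.vals)
    if genotyped_ids.size == 0:
        return out.accumulate()

    try:
        g_inv = np.linalg.inv(g_blended)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "G is singular; blend with A22 (e.g. alpha=0.95) before "
            "building H inverse"
        ) from exc
    a22_inv = np.linalg.inv(a22)
    block = tau * g_inv - omega * a22_inv
    for i, gi in enumerate(genotyped_ids):
        for j, gj in enumerate(genotyped_ids[:i + 1]):
            out.add(int(gi), int(gj), block[i, j])
    return out.accumulate()
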