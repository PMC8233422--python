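"""Genotype quality control for array-style SNP panels.

Filters are applied in a fixed, reported order — animal call rate,
sex-chromosome SNPs, SNP call rate, minor allele frequency, Hardy–Weinberg
equilibrium — and every removal is accounted for in a :class:`QCReport`.
Missing dosages in the surviving panel are mean-imputed (2p per SNP) so the
matrix is ready for genomic relationship construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "GenotypeMatrix",
    "SNPMap",
    "QCThresholds",
    "QCReport",
    "hwe_test",
    "qc_filter",
    "impute_missing",
]


@dataclass
class GenotypeMatrix:
    """Dosage matrix (animals x SNPs), values in {0, 1, 2} with NaN = missing."""

    animal_ids: np.ndarray
    snp_ids: np.ndarray
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.animal_ids = np.asarray(self.animal_ids)
        self.snp_ids = np.asarray(self.snp_ids)
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        if self.dosages.shape != (self.animal_ids.size, self.snp_ids.size):
            raise ValueError("dosage matrix shape inconsistent with id vectors")
        if pd.unique(self.animal_ids).size != self.animal_ids.size:
            raise ValueError("duplicate animal ids")
        if pd.unique(self.snp_ids).size != self.snp_ids.size:
            raise ValueError("duplicate SNP ids")

    @property
    def n_animals(self) -> int:
        return int(self.animal_ids.size)

    @property
    def n_snps(self) -> int:
        return int(self.snp_ids.size)

    def subset(self, animal_mask=None, snp_mask=None) -> "GenotypeMatrix":
        am = np.ones(self.n_animals, bool) if animal_mask is None else animal_mask
        sm = np.ones(self.n_snps, bool) if snp_mask is None else snp_mask
        return GenotypeMatrix(
            self.animal_ids[am], self.snp_ids[sm], self.dosages[np.ix_(am, sm)]
        )


def snp_map_frame(snp_id, chromosome, position_bp) -> pd.DataFrame:
    """Build a SNP map table: one row per SNP, (chromosome, bp) sortable."""
    df = pd.DataFrame(
        {
            "snp_id": np.asarray(snp_id),
            "chromosome": np.asarray(chromosome).astype(str),
            "position_bp": np.asarray(position_bp, dtype=np.int64),
        }
    )
    if (df["position_bp"] < 0).any():
        raise ValueError("positions must be >= 0")
    return df


# Backwards-friendly alias used in type hints: a SNP map is a DataFrame with
# columns snp_id / chromosome / position_bp, one row per panel SNP.
SNPMap = pd.DataFrame


@dataclass
class QCThresholds:
    """Default cut-offs: call rates 95%, MAF 1%, HWE P < 1e-6 (conventional)."""

    animal_call_rate: float = 0.95
    snp_call_rate: float = 0.95
    maf: float = 0.01
    hwe_p: float = 1e-6
    sex_chromosomes: tuple[str, ...] = ("X", "Y")


@dataclass
class QCReport:
    n_animals_in: int = 0
    n_animals_out: int = 0
    n_snps_in: int = 0
    n_snps_out: int = 0
    removed_animals_call_rate: int = 0
    removed_snps_sex_chromosome: int = 0
    removed_snps_call_rate: int = 0
    removed_snps_maf: int = 0
    removed_snps_hwe: int = 0
    thresholds: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_animals_in - self.removed_animals_call_rate != self.n_animals_out:
            raise AssertionError("animal accounting inconsistent")
        removed = (
            self.removed_snps_sex_chromosome
            + self.removed_snps_call_rate
            + self.removed_snps_maf
            + self.removed_snps_hwe
        )
        if self.n_snps_in - removed != self.n_snps_out:
            raise AssertionError("SNP accounting inconsistent")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def hwe_test(genotype_counts: tuple[int, int, int]) -> float:
    """1-df chi-square Hardy–Weinberg goodness-of-fit P-value.

    Observed (n_AA, n_Aa, n_aa) are compared with expectations from the
    observed allele frequency. A monomorphic SNP returns P = 1: no departure
    from equilibrium is definable.
    """
    n_aa_, n_ab, n_bb = (int(c) for c in genotype_counts)
    if min(n_aa_, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa_ + n_ab + n_bb
    if n == 0:
        raise ValueError("no genotype observations")
    p = (2 * n_aa_ + n_ab) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 1.0
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([n_aa_, n_ab, n_bb], dtype=float)
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    return float(scipy.stats.chi2.sf(chi2, df=1))


def _hwe_pvalues(dosages: np.ndarray) -> np.ndarray:
    """Vectorised HWE P per SNP column, missing ignored."""
    with np.errstate(invalid="ignore"):
        n_bb = np.nansum(dosages == 2, axis=0).astype(float)
        n_ab = np.nansum(dosages == 1, axis=0).astype(float)
        n_aa = np.nansum(dosages == 0, axis=0).astype(float)
    n = n_aa + n_ab + n_bb
    p = np.where(n > 0, (2 * n_aa + n_ab) / np.maximum(2 * n, 1), 0.5)
    q = 1.0 - p
    poly = (p > 0) & (q > 0) & (n > 0)
    exp_aa = n * p * p
    exp_ab = 2 * n * p * q
    exp_bb = n * q * q
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = (
            (n_aa - exp_aa) ** 2 / exp_aa
            + (n_ab - exp_ab) ** 2 / exp_ab
            + (n_bb - exp_bb) ** 2 / exp_bb
        )
    pvals = np.ones(dosages.shape[1])
    pvals[poly] = scipy.stats.chi2.sf(chi2[poly], df=1)
    return pvals


def qc_filter(
    genotypes: GenotypeMatrix,
    snp_map: pd.DataFrame,
    thresholds: QCThresholds | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame, QCReport]:
    """Apply animal- and SNP-level filters; returns (matrix, map, report).

    Order: animals by call rate, then SNPs on sex chromosomes, SNP call
    rate, MAF and HWE. MAF and HWE are computed on non-missing calls of the
    animals surviving the first step.
    """
    thr = thresholds or QCThresholds()
    if snp_map.shape[0] != genotypes.n_snps:
        raise ValueError("SNP map and genotype matrix disagree on SNP count")
    if not np.array_equal(np.asarray(snp_map["snp_id"]), genotypes.snp_ids):
        raise ValueError("SNP map order must match genotype columns")
    report = QCReport(
        n_animals_in=genotypes.n_animals,
        n_snps_in=genotypes.n_snps,
        thresholds={
            "animal_call_rate": thr.animal_call_rate,
            "snp_call_rate": thr.snp_call_rate,
            "maf": thr.maf,
            "hwe_p": thr.hwe_p,
            "sex_chromosomes": list(thr.sex_chromosomes),
        },
    )
    dos = genotypes.dosages
    # 1) animal call rate
    animal_cr = 1.0 - np.isnan(dos).mean(axis=1)
    keep_animals = animal_cr >= thr.animal_call_rate
    report.removed_animals_call_rate = int((~keep_animals).sum())
    dos = dos[keep_animals]

    snp_keep = np.ones(genotypes.n_snps, dtype=bool)
    # 2) sex chromosomes
    sex = snp_map["chromosome"].astype(str).str.upper().isin(
        [c.upper() for c in thr.sex_chromosomes]
    ).to_numpy()
    report.removed_snps_sex_chromosome = int((snp_keep & sex).sum())
    snp_keep &= ~sex
    # 3) SNP call rate
    snp_cr = 1.0 - np.isnan(dos).mean(axis=0)
    low_cr = snp_cr < thr.snp_call_rate
    report.removed_snps_call_rate = int((snp_keep & low_cr).sum())
    snp_keep &= ~low_cr
    # 4) MAF on non-missing calls of retained animals
    with np.errstate(invalid="ignore"):
        p = np.nanmean(dos, axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    low_maf = ~(maf >= thr.maf)  # NaN-frequency columns also fail
    report.removed_snps_maf = int((snp_keep & low_maf).sum())
    snp_keep &= ~low_maf
    # 5) HWE
    hwe_p = _hwe_pvalues(dos)
    hwe_fail = hwe_p < thr.hwe_p
    report.removed_snps_hwe = int((snp_keep & hwe_fail).sum())
    snp_keep &= ~hwe_fail

    if not snp_keep.any():
        raise ValueError("quality control removed every SNP: empty panel")

    out = GenotypeMatrix(
        genotypes.animal_ids[keep_animals], genotypes.snp_ids[snp_keep], dos[:, snp_keep]
    )
    out_map = snp_map.loc[snp_keep].reset_index(drop=True)
    report.n_animals_out = out.n_animals
    report.n_snps_out = out.n_snps
    report.validate()
    return out, out_map, report


def impute_missing(genotypes: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing dosages by the SNP's mean dosage among observed calls.

    Mean imputation (2p) leaves per-SNP allele-frequency estimates exactly
    unchanged, which is what VanRaden centering requires.
    """
    dos = genotypes.dosages.copy()
    missing = np.isnan(dos)
    if not missing.any():
        return GenotypeMatrix(genotypes.animal_ids, genotypes.snp_ids, dos)
    if missing.all(axis=0).any():
        raise ValueError("SNP with 100% missing calls cannot be imputed")
    means = np.nanmean(dos, axis=0)
    idx = np.where(missing)
    dos[idx] = means[idx[1]]
    return GenotypeMatrix(genotypes.animal_ids, genotypes.snp_ids, dos)
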