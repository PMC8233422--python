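"""Genome scans from back-solved SNP effects.

Marker effects are recovered from genomic breeding values through

    s_hat = D M' [M D M']^-1 a_hat_g

with M the centered dosage matrix (same observed-frequency centering used
for G) and D diagonal SNP weights (equal weights by default). Candidate
regions are ranked by the percentage of additive genetic variance explained
by 2.0-Mb windows of adjacent SNPs: for window i,

    pct_i = var(u_i) / sigma2_a * 100,   u_i = sum_j M_j s_j over window SNPs,

the variance taken empirically across genotyped animals. Cross-parity
genetic correlations are computed as Pearson correlations between
back-solved SNP-effect vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

__all__ = [
    "SNPEffectVector",
    "center_dosages",
    "backsolve_snp_effects",
    "window_partition",
    "window_variance_percent",
    "cross_parity_correlation",
]


@dataclass
class SNPEffectVector:
    """Back-solved marker effects aligned with the post-QC SNP panel."""

    snp_ids: np.ndarray
    effects: np.ndarray
    weights: np.ndarray | None = None
    parity: str = ""

    def __post_init__(self) -> None:
        self.snp_ids = np.asarray(self.snp_ids)
        self.effects = np.asarray(self.effects, dtype=np.float64)
        if self.effects.shape != self.snp_ids.shape:
            raise ValueError("effects and snp_ids must align")
        if not np.isfinite(self.effects).all():
            raise ValueError("SNP effects must be finite")


def center_dosages(
    dosages: np.ndarray, freqs: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Center dosages by twice the observed allele frequency (as for G)."""
    dos = np.asarray(dosages, dtype=np.float64)
    if np.isnan(dos).any():
        raise ValueError("dosages must be complete (impute missing first)")
    p = dos.mean(axis=0) / 2.0 if freqs is None else np.asarray(freqs, dtype=np.float64)
    return dos - 2.0 * p, p


def backsolve_snp_effects(
    a_g: np.ndarray,
    dosages: np.ndarray,
    snp_ids: np.ndarray | None = None,
    weights: np.ndarray | None = None,
    blend: float = 1.0,
    A22: np.ndarray | None = None,
    freqs: np.ndarray | None = None,
    parity: str = "",
) -> SNPEffectVector:
    """s_hat = D M' (M D M')^-1 a_hat_g.

    The GEBV vector is centered first: its base is arbitrary, and with M
    centered by the observed allele frequencies of the same animals each
    column of M is zero-mean, so M D M' annihilates the 1-vector and only
    the centered part of a_hat_g is recoverable. The (structurally singular)
    system is solved by minimum-norm least squares; the reconstruction
    identity M s_hat = a_hat_g - mean(a_hat_g) then holds exactly whenever
    rank(M D M') = n - 1 (panel larger than the genotyped set).

    When ``blend`` < 1 and ``A22`` is supplied, M D M' is regularised the
    same way G is blended for inversion: K = blend*MDM' + (1-blend)*c*A22
    with c = 2 sum p(1-p) (the VanRaden denominator), keeping K and A22 on
    the same scale.
    """
    a_g = np.asarray(a_g, dtype=np.float64)
    dos = np.asarray(dosages, dtype=np.float64)
    if a_g.shape[0] != dos.shape[0]:
        raise ValueError("a_g length does not match genotype rows")
    a_g = a_g - a_g.mean()
    M, p = center_dosages(dos, freqs)
    n_snps = M.shape[1]
    d = np.ones(n_snps) if weights is None else np.asarray(weights, dtype=np.float64)
    if d.shape != (n_snps,):
        raise ValueError("weights must be one value per SNP")
    MD = M * d
    K = MD @ M.T
    if blend < 1.0:
        if A22 is None:
            raise ValueError("blending requires A22")
        c = 2.0 * np.sum(p * (1.0 - p))
        K = blend * K + (1.0 - blend) * c * np.asarray(A22, dtype=np.float64)
    sol = scipy.linalg.lstsq(K, a_g, lapack_driver="gelsd")[0]
    effects = MD.T @ sol
    if snp_ids is None:
        snp_ids = np.arange(n_snps)
    return SNPEffectVector(snp_ids=snp_ids, effects=effects, weights=d, parity=parity)


def window_partition(
    snp_map: pd.DataFrame, span_bp: int = 2_000_000, mode: str = "sliding"
) -> pd.DataFrame:
    """Index sets of SNP windows that never span chromosomes.

    ``sliding`` (default): one window per index SNP, containing every SNP of
    the same chromosome with position in [pos, pos + span) — half-open,
    stepping one SNP at a time. ``tiled``: non-overlapping [k*span,
    (k+1)*span) bins, one window per occupied bin. Returns a table with
    chromosome, start/end bp, index SNP and the member SNP row indices.
    """
    if mode not in ("sliding", "tiled"):
        raise ValueError("mode must be 'sliding' or 'tiled'")
    chrom = snp_map["chromosome"].to_numpy()
    pos = snp_map["position_bp"].to_numpy()
    codes = pd.factorize(chrom)[0]
    order_ok = not np.any(np.diff(codes) < 0)  # each chromosome one contiguous block
    for c in pd.unique(chrom):
        if np.any(np.diff(pos[chrom == c]) < 0):
            order_ok = False
    if not order_ok:
        raise ValueError("SNP map must be sorted by (chromosome, position)")
    rows = []
    idx_all = np.arange(snp_map.shape[0])
    for c in pd.unique(chrom):
        on_c = idx_all[chrom == c]
        pc = pos[on_c]
        if mode == "sliding":
            for k, i in enumerate(on_c):
                start = pc[k]
                hi = np.searchsorted(pc, start + span_bp, side="left")
                members = on_c[k:hi]
                rows.append(
                    (c, int(start), int(start + span_bp), snp_map["snp_id"].iloc[i], members)
                )
        else:
            bins = pc // span_bp
            for b in np.unique(bins):
                members = on_c[bins == b]
                rows.append(
                    (
                        c,
                        int(b * span_bp),
                        int((b + 1) * span_bp),
                        snp_map["snp_id"].iloc[members[0]],
                        members,
                    )
                )
    return pd.DataFrame(
        rows, columns=["chromosome", "start_bp", "end_bp", "index_snp", "snp_rows"]
    )


def window_variance_percent(
    windows: pd.DataFrame,
    dosages: np.ndarray,
    effects: SNPEffectVector,
    sigma2_a: float,
    freqs: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-window percentage of additive genetic variance.

    ``var_u`` is the empirical variance, across genotyped animals, of the
    window's summed marker contributions; ``pct_var`` expresses it against
    the posterior-mean additive variance of the matching analysis.
    """
    if sigma2_a <= 0:
        raise ValueError("sigma2_a must be > 0")
    M, _ = center_dosages(dosages, freqs)
    s = effects.effects
    if M.shape[1] != s.shape[0]:
        raise ValueError("effect vector does not match SNP columns")
    out = windows.copy()
    var_u = np.empty(len(windows))
    for k, members in enumerate(windows["snp_rows"]):
        u = M[:, members] @ s[members]
        var_u[k] = u.var()
    out["B"] = [len(m) for m in windows["snp_rows"]]
    out["var_u"] = var_u
    out["pct_var"] = var_u / sigma2_a * 100.0
    return out.drop(columns=["snp_rows"]).assign(snp_rows=windows["snp_rows"])


def cross_parity_correlation(s1: SNPEffectVector, s2: SNPEffectVector) -> float:
    """Pearson correlation between two parities' SNP-effect vectors."""
    if not np.array_equal(s1.snp_ids, s2.snp_ids):
        raise ValueError("SNP panels differ between effect vectors")
    e1, e2 = s1.effects, s2.effects
    if e1.std() == 0.0 or e2.std() == 0.0:
        warnings.warn("zero-variance SNP-effect vector: correlation undefined")
        return float("nan")
    return float(np.corrcoef(e1, e2)[0, 1])
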