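"""Pedigree and genomic relationship matrices for single-step evaluation.

Builds the classical numerator relationship matrix machinery (inbreeding
coefficients by the Meuwissen–Luo recursion, the sparse inverse ``A``:sup:`-1`
by Henderson's rules, tabular relationships for arbitrary subsets) and the
genomic side (VanRaden method-1 ``G``), then combines them into the inverse
of the single-step matrix

    H^-1 = A^-1 + [0 0; 0 G*^-1 - A22^-1]

where the correction block acts on the genotyped animals and ``G*`` is ``G``
blended with ``A22`` for guaranteed invertibility.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse as sp

__all__ = [
    "Pedigree",
    "RelationshipMatrices",
    "inbreeding",
    "a_inverse",
    "inbreeding_and_a_inverse",
    "tabular_a",
    "a22",
    "g_matrix",
    "h_inverse",
]


@dataclass
class Pedigree:
    """Renumbered pedigree: animals 1..n, parents precede offspring, 0 = unknown.

    ``sire`` and ``dam`` are arrays aligned with animal ids 1..n (index i-1
    holds the parents of animal i). ``generation`` and ``sex`` are optional
    simulation metadata (sex: 0 = male, 1 = female).
    """

    sire: np.ndarray
    dam: np.ndarray
    generation: np.ndarray | None = None
    sex: np.ndarray | None = None
    inbreeding_: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        n = self.n_animals
        if self.dam.shape != self.sire.shape:
            raise ValueError("sire and dam arrays must have equal length")
        ids = np.arange(1, n + 1)
        for name, par in (("sire", self.sire), ("dam", self.dam)):
            if np.any(par < 0) or np.any(par > n):
                raise ValueError(f"{name} ids must be 0 (unknown) or in 1..{n}")
            if np.any(par >= ids):
                bad = int(np.argmax(par >= ids)) + 1
                raise ValueError(
                    f"pedigree not topologically ordered: animal {bad} has "
                    f"{name} {int(par[bad - 1])} >= its own id"
                )

    @property
    def n_animals(self) -> int:
        return int(self.sire.shape[0])

    @property
    def inbreeding(self) -> np.ndarray:
        if self.inbreeding_ is None:
            self.inbreeding_ = inbreeding(self)
        return self.inbreeding_

    def ancestors(self, animals: np.ndarray) -> np.ndarray:
        """All ancestors of ``animals`` (1-based ids), including themselves, sorted."""
        keep = np.zeros(self.n_animals + 1, dtype=bool)
        keep[np.asarray(animals, dtype=np.int64)] = True
        for i in range(self.n_animals, 0, -1):
            if keep[i]:
                keep[self.sire[i - 1]] = True
                keep[self.dam[i - 1]] = True
        keep[0] = False
        return np.nonzero(keep)[0]


@dataclass
class RelationshipMatrices:
    """Bundle of the matrices entering a single-step evaluation."""

    A_inv: sp.csr_matrix
    A22: np.ndarray
    G: np.ndarray
    G_star: np.ndarray
    H_inv: sp.csr_matrix
    genotyped_index: np.ndarray


def inbreeding(ped: Pedigree) -> np.ndarray:
    """Per-animal inbreeding coefficients F by the Meuwissen–Luo recursion.

    Uses the convention F = -1 for an unknown parent so that the
    Mendelian-sampling variance d_i = 0.5 - 0.25 (F_s + F_d) covers the
    one- and zero-known-parent cases without special-casing.
    """
    n = ped.n_animals
    F = np.empty(n + 1)
    F[0] = -1.0
    sire, dam = ped.sire, ped.dam
    d = np.empty(n + 1)  # Mendelian sampling variance, 1-based
    for i in range(1, n + 1):
        s, dm = sire[i - 1], dam[i - 1]
        if s == 0 or dm == 0:
            F[i] = 0.0
            d[i] = 0.5 - 0.25 * (F[s] + F[dm])
            continue
        # accumulate A_ii = sum_j L_ij^2 d_j over ancestors j of i
        coef: dict[int, float] = {}
        heap: list[int] = []
        coef[i] = 1.0
        heapq.heappush(heap, -i)
        aii = 0.0
        while heap:
            j = -heapq.heappop(heap)
            cj = coef.pop(j, 0.0)
            if cj == 0.0:
                continue
            aii += cj * cj * d[j] if j != i else cj * cj * (0.5 - 0.25 * (F[s] + F[dm]))
            js, jd = (s, dm) if j == i else (sire[j - 1], dam[j - 1])
            for p in (js, jd):
                if p != 0:
                    if p in coef:
                        coef[p] += 0.5 * cj
                    else:
                        coef[p] = 0.5 * cj
                        heapq.heappush(heap, -p)
        F[i] = aii - 1.0
        d[i] = 0.5 - 0.25 * (F[s] + F[dm])
    return F[1:]


def a_inverse(ped: Pedigree, F: np.ndarray | None = None) -> sp.csr_matrix:
    """Sparse A^-1 assembled by Henderson's rules accounting for inbreeding.

    Each animal contributes 1/d_i times the {1, -1/2, 1/4} pattern on
    (itself, its known parents), with d_i the Mendelian-sampling variance
    computed from parental inbreeding.
    """
    n = ped.n_animals
    if F is None:
        F = ped.inbreeding
    Fx = np.concatenate(([-1.0], F))  # unknown-parent convention
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(r: int, c: int, v: float) -> None:
        rows.append(r - 1)
        cols.append(c - 1)
        vals.append(v)

    for i in range(1, n + 1):
        s, dm = int(ped.sire[i - 1]), int(ped.dam[i - 1])
        d = 0.5 - 0.25 * (Fx[s] + Fx[dm])
        alpha = 1.0 / d
        add(i, i, alpha)
        for p in (s, dm):
            if p != 0:
                add(i, p, -alpha / 2.0)
                add(p, i, -alpha / 2.0)
                add(p, p, alpha / 4.0)
        if s != 0 and dm != 0:
            add(s, dm, alpha / 4.0)
            add(dm, s, alpha / 4.0)
    return sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


def inbreeding_and_a_inverse(ped: Pedigree) -> tuple[np.ndarray, sp.csr_matrix]:
    """Convenience: (F, A^-1) in one call."""
    F = ped.inbreeding
    return F, a_inverse(ped, F)


def tabular_a(ped: Pedigree, subset: np.ndarray | None = None) -> np.ndarray:
    """Dense relationships by the tabular method, optionally restricted.

    When ``subset`` (1-based ids) is given, the recursion runs on the pruned
    ancestor set only and the returned matrix is ordered as ``subset`` —
    ancestral paths through excluded animals are still fully accounted for.
    """
    if subset is None:
        subset = np.arange(1, ped.n_animals + 1)
    subset = np.asarray(subset, dtype=np.int64)
    if subset.size and (subset.min() < 1 or subset.max() > ped.n_animals):
        raise ValueError("subset contains ids outside the pedigree")
    anc = ped.ancestors(subset)
    pos = {int(a): k for k, a in enumerate(anc)}
    m = anc.size
    A = np.zeros((m, m))
    for k, i in enumerate(anc):
        s, dm = int(ped.sire[i - 1]), int(ped.dam[i - 1])
        ks = pos.get(s, -1)
        kd = pos.get(dm, -1)
        row = np.zeros(k)
        if ks >= 0:
            row += 0.5 * A[ks, :k]
        if kd >= 0:
            row += 0.5 * A[kd, :k]
        A[k, :k] = row
        A[:k, k] = row
        A[k, k] = 1.0 + (0.5 * A[ks, kd] if ks >= 0 and kd >= 0 else 0.0)
    idx = np.array([pos[int(i)] for i in subset])
    return A[np.ix_(idx, idx)]


def a22(ped: Pedigree, genotyped: np.ndarray) -> np.ndarray:
    """Pedigree relationships among the genotyped animals (tabular, pruned)."""
    genotyped = np.asarray(genotyped, dtype=np.int64)
    if genotyped.size and (genotyped.min() < 1 or genotyped.max() > ped.n_animals):
        raise ValueError("genotyped ids absent from pedigree")
    return tabular_a(ped, genotyped)


def g_matrix(dosages: np.ndarray) -> np.ndarray:
    """VanRaden method-1 genomic relationship matrix from complete dosages.

    G = WW' / (2 Σ p_j (1 - p_j)) with W the dosage matrix centered by twice
    the observed allele frequency of each SNP.
    """
    dos = np.asarray(dosages, dtype=np.float64)
    if dos.ndim != 2 or dos.shape[0] < 2:
        raise ValueError("need a 2-D dosage matrix with >= 2 animals")
    if np.isnan(dos).any():
        raise ValueError("dosages must be complete (impute missing first)")
    p = dos.mean(axis=0) / 2.0
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0.0:
        raise ValueError("all SNPs monomorphic: zero VanRaden denominator")
    W = dos - 2.0 * p
    return (W @ W.T) / denom


def h_inverse(
    A_inv: sp.spmatrix,
    A22: np.ndarray,
    G: np.ndarray,
    genotyped: np.ndarray,
    blend: float = 0.95,
) -> tuple[sp.csr_matrix, np.ndarray]:
    """Single-step H^-1 with a blended, invertible G*.

    G* = blend·G + (1-blend)·A22; H^-1 adds (G*^-1 - A22^-1) on the
    genotyped coordinates of A^-1. Returns (H^-1, G*).
    """
    if not 0.0 < blend <= 1.0:
        raise ValueError("blend must be in (0, 1]")
    genotyped = np.asarray(genotyped, dtype=np.int64)
    A_inv = sp.csr_matrix(A_inv)
    if genotyped.size == 0:
        return A_inv.copy(), np.asarray(G, dtype=np.float64).copy()
    G = np.asarray(G, dtype=np.float64)
    A22 = np.asarray(A22, dtype=np.float64)
    if G.shape != (genotyped.size, genotyped.size) or A22.shape != G.shape:
        raise ValueError("G / A22 dimensions inconsistent with genotyped set")
    G_star = blend * G + (1.0 - blend) * A22
    cond = np.linalg.cond(G_star)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"blended G* numerically singular (condition number {cond:.3e}); "
            "increase the A22 blending weight"
        )
    G_star_inv = scipy.linalg.inv(G_star)
    A22_inv = scipy.linalg.inv(A22)
    corr = G_star_inv - A22_inv
    gi = genotyped - 1
    rows = np.repeat(gi, genotyped.size)
    cols = np.tile(gi, genotyped.size)
    block = sp.coo_matrix((corr.ravel(), (rows, cols)), shape=A_inv.shape)
    H_inv = (A_inv + block.tocsr()).tocsr()
    return H_inv, G_star


def build_relationships(
    ped: Pedigree,
    dosages: np.ndarray,
    genotyped: np.ndarray,
    blend: float = 0.95,
) -> RelationshipMatrices:
    """One-stop construction of A^-1, A22, G, G* and H^-1."""
    F, A_inv = inbreeding_and_a_inverse(ped)
    A22_ = a22(ped, genotyped)
    G = g_matrix(dosages)
    H_inv, G_star = h_inverse(A_inv, A22_, G, genotyped, blend=blend)
    return RelationshipMatrices(
        A_inv=A_inv,
        A22=A22_,
        G=G,
        G_star=G_star,
        H_inv=H_inv,
        genotyped_index=np.asarray(genotyped, dtype=np.int64),
    )
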