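"""SNP-based gene-set enrichment with the cumulative hypergeometric test.

SNPs are mapped to genes when they fall within the gene body or within a
flanking distance (15 kb by default, boundary inclusive) on either side; a
SNP near several genes counts for all of them. Genes carrying at least one
SNP whose back-solved effect lies in the top 5% of the |effect| distribution
are flagged, and each functional term (GO / MeSH / Reactome / InterPro /
MSigDB supplied as GMT) with at least 10 universe genes is tested for
overrepresentation of flagged genes by the upper-tail hypergeometric
probability P(X >= g) — Fisher's exact test of proportions. Raw P-values are
reported; a Benjamini–Hochberg column is added for convenience but never
used for filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import false_discovery_control, hypergeom

__all__ = [
    "SNPGeneMap",
    "FlaggedGenes",
    "EnrichmentInput",
    "map_snps_to_genes",
    "flag_significant_genes",
    "hypergeometric_pvalue",
    "enrich_terms",
]


@dataclass
class SNPGeneMap:
    """Bidirectional SNP <-> gene assignment."""

    snp_to_genes: dict[str, frozenset]
    gene_to_snps: dict[str, frozenset]
    unmapped_snps: frozenset

    @property
    def universe(self) -> frozenset:
        """Genes with at least one mapped SNP."""
        return frozenset(self.gene_to_snps)


@dataclass
class FlaggedGenes:
    """Outcome of the top-fraction flagging step."""

    universe: frozenset  # genes with >= 1 mapped SNP
    flagged: frozenset  # the S significant genes
    relevant_snps: frozenset
    threshold: float
    top_fraction: float

    @property
    def n_universe(self) -> int:
        return len(self.universe)

    @property
    def n_flagged(self) -> int:
        return len(self.flagged)


@dataclass
class EnrichmentInput:
    """Hypergeometric counts for one term: draws of K from N with S successes."""

    N: int
    S: int
    K: int
    g: int

    def __post_init__(self) -> None:
        if not (0 <= self.S <= self.N and 0 <= self.K <= self.N):
            raise ValueError("require 0 <= S, K <= N")
        if not 0 <= self.g <= min(self.S, self.K):
            raise ValueError("require 0 <= g <= min(S, K)")


def map_snps_to_genes(
    snp_map: pd.DataFrame,
    genes: pd.DataFrame,
    flank_bp: int = 15_000,
) -> SNPGeneMap:
    """Assign each SNP to every gene within ``flank_bp`` of its body.

    Gene coordinates are 1-based closed [start_bp, end_bp]; a SNP is
    assigned iff position in [start - flank, end + flank], bounds inclusive.
    Deterministic: outputs are plain sorted-key dicts of frozensets.
    """
    trees: dict[str, IntervalTree] = {}
    for row in genes.itertuples(index=False):
        lo = int(row.start_bp) - flank_bp
        hi = int(row.end_bp) + flank_bp + 1  # half-open tree interval, closed rule
        trees.setdefault(str(row.chromosome), IntervalTree()).addi(lo, hi, row.gene_id)
    snp_to_genes: dict[str, frozenset] = {}
    gene_to_snps: dict[str, set] = {}
    unmapped = []
    for row in snp_map.itertuples(index=False):
        tree = trees.get(str(row.chromosome))
        hits = tree[int(row.position_bp)] if tree is not None else set()
        if not hits:
            unmapped.append(row.snp_id)
            continue
        gids = frozenset(h.data for h in hits)
        snp_to_genes[row.snp_id] = gids
        for gid in gids:
            gene_to_snps.setdefault(gid, set()).add(row.snp_id)
    return SNPGeneMap(
        snp_to_genes={k: snp_to_genes[k] for k in sorted(snp_to_genes)},
        gene_to_snps={k: frozenset(v) for k, v in sorted(gene_to_snps.items())},
        unmapped_snps=frozenset(unmapped),
    )


def flag_significant_genes(
    effects,  # SNPEffectVector or (snp_ids, effects) pair
    snp_gene_map: SNPGeneMap,
    top_fraction: float = 0.05,
    signed: bool = False,
) -> FlaggedGenes:
    """Flag genes carrying at least one top-``top_fraction`` SNP effect.

    Relevance is two-sided by default: |effect| at or above the empirical
    (1 - top_fraction) quantile of |effects| (sign is arbitrary under allele
    recoding). Ties at the threshold are all included. ``signed=True``
    ranks the raw effects instead.
    """
    if hasattr(effects, "snp_ids"):
        snp_ids = np.asarray(effects.snp_ids)
        vals = np.asarray(effects.effects, dtype=float)
    else:
        snp_ids, vals = np.asarray(effects[0]), np.asarray(effects[1], dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("SNP effects must be finite")
    if not 0.0 < top_fraction < 1.0:
        raise ValueError("top_fraction must be in (0, 1)")
    if not snp_gene_map.gene_to_snps:
        raise ValueError("empty gene universe: no SNP mapped to any gene")
    ranked = vals if signed else np.abs(vals)
    threshold = float(np.quantile(ranked, 1.0 - top_fraction, method="higher"))
    relevant = frozenset(snp_ids[ranked >= threshold])
    flagged = frozenset(
        g for g, snps in snp_gene_map.gene_to_snps.items() if snps & relevant
    )
    return FlaggedGenes(
        universe=frozenset(snp_gene_map.gene_to_snps),
        flagged=flagged,
        relevant_snps=relevant,
        threshold=threshold,
        top_fraction=top_fraction,
    )


def hypergeometric_pvalue(N, S, K, g):
    """Upper-tail P(X >= g), X ~ Hypergeometric(N, S, K).

    Probability of observing at least ``g`` flagged genes among ``K`` term
    genes drawn from a universe of ``N`` genes containing ``S`` flagged
    ones; computed as the numerically stable survival function (log-gamma
    based). Accepts scalars or aligned arrays.
    """
    N = np.asarray(N, dtype=np.int64)
    S = np.asarray(S, dtype=np.int64)
    K = np.asarray(K, dtype=np.int64)
    g = np.asarray(g, dtype=np.int64)
    if np.any(S > N) or np.any(K > N) or np.any(S < 0) or np.any(K < 0):
        raise ValueError("require 0 <= S, K <= N")
    if np.any(g < 0) or np.any(g > np.minimum(S, K)):
        raise ValueError("require 0 <= g <= min(S, K)")
    p = hypergeom.sf(g - 1, N, S, K)
    out = np.clip(p, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def enrich_terms(
    flags: FlaggedGenes,
    collection: dict[str, tuple[str, frozenset]],
    min_term_size: int = 10,
    database: str = "",
) -> pd.DataFrame:
    """Test every term of one collection; returns a table sorted by P.

    Term membership is intersected with the analysis universe before the
    ``min_term_size`` (>= 10 genes) filter and before counting. Columns
    mirror the conventional report: term id, name, N, S, K, g, p_value and
    an auxiliary BH-FDR column.
    """
    if not collection:
        import warnings

        warnings.warn("empty gene-set collection: no terms to test")
        return pd.DataFrame(
            columns=["term_id", "term_name", "database", "N", "S", "K", "g", "p_value", "fdr_bh"]
        )
    N = flags.n_universe
    S = flags.n_flagged
    out = []
    for term_id in sorted(collection):
        name, members = collection[term_id]
        in_universe = set(members) & flags.universe
        K = len(in_universe)
        if K < min_term_size:
            continue
        g = len(in_universe & flags.flagged)
        p = hypergeometric_pvalue(N, S, K, g)
        out.append((term_id, name, database, N, S, K, g, p))
    df = pd.DataFrame(
        out, columns=["term_id", "term_name", "database", "N", "S", "K", "g", "p_value"]
    )
    if len(df):
        df["fdr_bh"] = false_discovery_control(df["p_value"].to_numpy(), method="bh")
        df = df.sort_values(["p_value", "term_id"], kind="stable").reset_index(drop=True)
    else:
        df["fdr_bh"] = pd.Series(dtype=float)
    return df
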