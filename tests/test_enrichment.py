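"""SNP-to-gene mapping, gene flagging and the hypergeometric enrichment test."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from liabscan.enrichment import (
    EnrichmentInput,
    enrich_terms,
    flag_significant_genes,
    hypergeometric_pvalue,
    map_snps_to_genes,
)
from liabscan.scan import SNPEffectVector


def enumeration_tail(N: int, S: int, K: int) -> np.ndarray:
    """Brute-force oracle: enumerate all C(N, K) draws of the universe and
    return P(|draw & flagged| >= g) for g = 0..min(S, K)."""
    flagged = set(range(S))
    gmax = min(S, K)
    counts = np.zeros(gmax + 1)
    total = 0
    for draw in itertools.combinations(range(N), K):
        counts[len(flagged.intersection(draw))] += 1
        total += 1
    return counts[::-1].cumsum()[::-1] / total


def enumeration_pvalue(N: int, S: int, K: int, g: int) -> float:
    return float(enumeration_tail(N, S, K)[g])


def _genes(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chromosome", "start_bp", "end_bp", "strand"])


def _map(rows):
    return pd.DataFrame(rows, columns=["snp_id", "chromosome", "position_bp"])


class TestSNPGeneMapping:
    def test_snp_inside_gene_body_assigned(self):
        genes = _genes([("g1", "1", 50_000, 60_000, "+")])
        snp_map = _map([("s1", "1", 55_000)])
        m = map_snps_to_genes(snp_map, genes)
        assert m.snp_to_genes["s1"] == frozenset({"g1"})

    def test_flank_boundary_inclusive(self):
        genes = _genes([("g1", "1", 50_000, 60_000, "+")])
        snp_map = _map([("in", "1", 75_000), ("out", "1", 75_001), ("up", "1", 35_000)])
        m = map_snps_to_genes(snp_map, genes, flank_bp=15_000)
        assert "g1" in m.snp_to_genes["in"]
        assert "out" in m.unmapped_snps
        assert "g1" in m.snp_to_genes["up"]

    def test_snp_near_two_genes_assigned_to_both(self):
        genes = _genes([("g1", "1", 10_000, 20_000, "+"), ("g2", "1", 40_000, 50_000, "-")])
        snp_map = _map([("s1", "1", 30_000)])  # within 15 kb of both
        m = map_snps_to_genes(snp_map, genes)
        assert m.snp_to_genes["s1"] == frozenset({"g1", "g2"})

    def test_chromosome_mismatch_unmapped(self):
        genes = _genes([("g1", "2", 10_000, 20_000, "+")])
        m = map_snps_to_genes(_map([("s1", "1", 15_000)]), genes)
        assert "s1" in m.unmapped_snps

    def test_mapping_deterministic(self):
        rng = np.random.default_rng(0)
        genes = _genes(
            [(f"g{i}", "1", int(p), int(p) + 8000, "+") for i, p in
             enumerate(rng.integers(0, 5_000_000, 60))]
        )
        snp_map = _map([(f"s{i}", "1", int(p)) for i, p in
                        enumerate(rng.integers(0, 5_000_000, 200))])
        m1 = map_snps_to_genes(snp_map, genes)
        m2 = map_snps_to_genes(snp_map, genes)
        assert m1.snp_to_genes == m2.snp_to_genes
        assert m1.gene_to_snps == m2.gene_to_snps


class TestFlagging:
    def _map_all(self, n):
        """Each SNP i maps to its own gene i."""
        genes = _genes([(f"g{i}", "1", 1000 * i + 1, 1000 * i + 10, "+") for i in range(n)])
        snp_map = _map([(f"s{i}", "1", 1000 * i + 5) for i in range(n)])
        return map_snps_to_genes(snp_map, genes, flank_bp=0)

    def test_exactly_top_five_percent(self):
        sg = self._map_all(100)
        vals = np.arange(1, 101, dtype=float)  # strictly distinct magnitudes
        effects = SNPEffectVector(np.array([f"s{i}" for i in range(100)]), vals)
        flags = flag_significant_genes(effects, sg, top_fraction=0.05)
        assert len(flags.relevant_snps) == 5
        assert flags.relevant_snps == frozenset({"s95", "s96", "s97", "s98", "s99"})
        assert flags.n_flagged == 5

    def test_rank_six_gene_not_flagged(self):
        sg = self._map_all(100)
        vals = np.arange(1, 101, dtype=float)
        effects = SNPEffectVector(np.array([f"s{i}" for i in range(100)]), vals)
        flags = flag_significant_genes(effects, sg, top_fraction=0.05)
        assert "g94" not in flags.flagged  # rank 6 from the top

    def test_threshold_ties_all_included(self):
        sg = self._map_all(100)
        vals = np.concatenate([np.full(10, 5.0), np.arange(90, dtype=float) / 100])
        effects = SNPEffectVector(np.array([f"s{i}" for i in range(100)]), vals)
        flags = flag_significant_genes(effects, sg, top_fraction=0.05)
        # all ten tied SNPs at the threshold magnitude are relevant
        assert len(flags.relevant_snps) == 10

    def test_absolute_value_ranking_default(self):
        sg = self._map_all(4)
        effects = SNPEffectVector(np.array(["s0", "s1", "s2", "s3"]),
                                  np.array([-10.0, 0.1, 0.2, 0.3]))
        flags = flag_significant_genes(effects, sg, top_fraction=0.25)
        assert flags.relevant_snps == frozenset({"s0"})

    def test_empty_universe_rejected(self):
        genes = _genes([("g1", "2", 1, 10, "+")])
        sg = map_snps_to_genes(_map([("s1", "1", 5)]), genes)
        effects = SNPEffectVector(np.array(["s1"]), np.array([1.0]))
        with pytest.raises(ValueError, match="universe"):
            flag_significant_genes(effects, sg)


class TestHypergeometricPvalue:
    def test_zero_count_is_one(self):
        assert hypergeometric_pvalue(50, 10, 5, 0) == 1.0

    def test_worked_value_11_over_42(self):
        assert hypergeometric_pvalue(10, 4, 5, 3) == pytest.approx(11 / 42, abs=1e-12)

    def test_exhaustive_enumeration_small_universes(self):
        for N in range(1, 13):
            for S in range(N + 1):
                for K in range(N + 1):
                    expected = enumeration_tail(N, S, K)
                    gs = np.arange(min(S, K) + 1)
                    got = np.atleast_1d(
                        hypergeometric_pvalue(
                            np.full_like(gs, N), np.full_like(gs, S), np.full_like(gs, K), gs
                        )
                    )
                    np.testing.assert_allclose(got, expected, atol=1e-10,
                                               err_msg=f"(N,S,K)=({N},{S},{K})")

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(2, 200), st.data())
    def test_monotone_in_g_and_pmf_sums_to_one(self, N, data):
        S = data.draw(st.integers(0, N))
        K = data.draw(st.integers(1, N))
        gmax = min(S, K)
        ps = hypergeometric_pvalue(
            np.full(gmax + 1, N), np.full(gmax + 1, S), np.full(gmax + 1, K),
            np.arange(gmax + 1),
        )
        ps = np.atleast_1d(ps)
        assert ps[0] == pytest.approx(1.0)
        assert np.all(np.diff(ps) <= 1e-12)
        # tail differences are the pmf; total mass 1
        pmf = np.diff(np.append(ps, 0.0)) * -1
        assert pmf.sum() == pytest.approx(1.0, abs=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_pvalue(10, 12, 5, 3)
        with pytest.raises(ValueError):
            hypergeometric_pvalue(10, 4, 5, 5)
        with pytest.raises(ValueError):
            EnrichmentInput(N=10, S=4, K=5, g=5)


class TestEnrichTerms:
    def test_small_terms_excluded(self):
        from liabscan.enrichment import FlaggedGenes

        flags = FlaggedGenes(
            universe=frozenset(f"g{i}" for i in range(40)),
            flagged=frozenset(f"g{i}" for i in range(8)),
            relevant_snps=frozenset(), threshold=0.0, top_fraction=0.05,
        )
        collection = {
            "small": ("nine universe genes", frozenset(f"g{i}" for i in range(9))),
            "big": ("eleven universe genes", frozenset(f"g{i}" for i in range(11))),
            "padded": ("9 in universe + 5 outside",
                       frozenset(f"g{i}" for i in range(9)) | frozenset(f"x{i}" for i in range(5))),
        }
        res = enrich_terms(flags, collection, min_term_size=10)
        assert set(res["term_id"]) == {"big"}

    def test_whole_universe_term_p_one(self):
        from liabscan.enrichment import FlaggedGenes

        universe = frozenset(f"g{i}" for i in range(20))
        flags = FlaggedGenes(universe=universe,
                             flagged=frozenset(f"g{i}" for i in range(6)),
                             relevant_snps=frozenset(), threshold=0.0, top_fraction=0.05)
        res = enrich_terms(flags, {"all": ("everything", universe)}, min_term_size=10)
        assert res.loc[0, "g"] == 6
        assert res.loc[0, "p_value"] == pytest.approx(1.0)

    def test_empty_collection_warns(self):
        from liabscan.enrichment import FlaggedGenes

        flags = FlaggedGenes(universe=frozenset({"g1"}), flagged=frozenset(),
                             relevant_snps=frozenset(), threshold=0.0, top_fraction=0.05)
        with pytest.warns(UserWarning, match="empty"):
            res = enrich_terms(flags, {})
        assert res.empty

    def test_results_sorted_by_p(self):
        from liabscan.enrichment import FlaggedGenes

        rng = np.random.default_rng(1)
        universe = frozenset(f"g{i}" for i in range(200))
        flags = FlaggedGenes(universe=universe,
                             flagged=frozenset(f"g{i}" for i in range(20)),
                             relevant_snps=frozenset(), threshold=0.0, top_fraction=0.05)
        collection = {
            f"T{t}": ("t", frozenset(rng.choice(sorted(universe), 30, replace=False)))
            for t in range(8)
        }
        res = enrich_terms(flags, collection)
        assert (res["p_value"].diff().dropna() >= 0).all()
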