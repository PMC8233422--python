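"""Synthetic study generator for the liability-threshold pipeline.

Produces a multi-generation pedigree with a small sire pool, gene-drop SNP
genotypes (independent loci), liability-scale breeding values composed of a
few designated QTL plus a pedigree-sampled polygenic remainder, binary
phenotypes from a probit model with fixed effects and an iid service-sire
effect, and gene/gene-set annotations for enrichment testing. Every stage is
driven by a single :class:`~liabscan.config.SimConfig` and a seed, and is
byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .config import ParitySpec, SimConfig
from .qc import GenotypeMatrix, snp_map_frame
from .relationships import Pedigree

__all__ = [
    "SimulatedStudy",
    "simulate_pedigree",
    "simulate_snp_map",
    "gene_drop_genotypes",
    "simulate_breeding_values",
    "simulate_phenotypes",
    "simulate_annotation",
    "simulate_study",
]


@dataclass
class SimulatedStudy:
    """A complete synthetic dataset plus its generating truth."""

    config: SimConfig
    pedigree: Pedigree
    genotypes: GenotypeMatrix  # genotyped subset, with missingness
    snp_map: pd.DataFrame
    phenotypes: pd.DataFrame
    true_breeding_values: np.ndarray  # per pedigree animal, liability scale
    true_qtl: list[tuple[int, float]]  # (panel SNP index, allele substitution effect)
    true_params: dict = field(default_factory=dict)
    full_dosages: np.ndarray | None = None  # all pedigree animals, no missing

    @property
    def genotyped_ids(self) -> np.ndarray:
        return np.asarray(self.genotypes.animal_ids, dtype=np.int64)


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    """Independent, reproducible stream per generator stage."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), stage]))


def simulate_pedigree(config: SimConfig) -> Pedigree:
    """Discrete-generation pedigree with a limited sire pool per generation.

    Founders (generation 0) have unknown parents (0). Each later generation
    draws each offspring's sire from that generation's selected sire pool and
    its dam from the previous generation's females, so parents always precede
    offspring and ids are already topologically ordered.
    """
    rng = _stage_rng(config.seed, 1)
    n0 = config.n_founders
    sire = [0] * n0
    dam = [0] * n0
    gen = [0] * n0
    sex = list((rng.random(n0) < 0.5).astype(np.int8))  # 0 male, 1 female
    prev = np.arange(1, n0 + 1)
    for g in range(1, config.n_generations + 1):
        prev_sex = np.array([sex[i - 1] for i in prev])
        males = prev[prev_sex == 0]
        females = prev[prev_sex == 1]
        if males.size == 0 or females.size == 0:
            raise ValueError("a generation lacks one sex; increase n_founders")
        pool = rng.choice(males, size=min(config.n_sires_per_generation, males.size), replace=False)
        cur: list[int] = []
        for _ in range(config.matings_per_generation):
            s = int(rng.choice(pool))
            d = int(rng.choice(females))
            for _ in range(config.offspring_per_mating):
                sire.append(s)
                dam.append(d)
                gen.append(g)
                sex.append(int(rng.random() < 0.5))
                cur.append(len(sire))
        prev = np.array(cur)
    return Pedigree(
        sire=np.array(sire),
        dam=np.array(dam),
        generation=np.array(gen),
        sex=np.array(sex, dtype=np.int8),
    )


def simulate_snp_map(config: SimConfig) -> pd.DataFrame:
    """Evenly indexed random positions per chromosome, sorted by (chrom, bp)."""
    rng = _stage_rng(config.seed, 2)
    rows = []
    for c in range(1, config.n_chromosomes + 1):
        pos = np.sort(
            rng.choice(config.chrom_length_bp, size=config.snps_per_chromosome, replace=False)
        )
        for k, p in enumerate(pos):
            rows.append((f"snp{c}_{k + 1}", str(c), int(p)))
    ids, chroms, bps = zip(*rows)
    return snp_map_frame(ids, chroms, bps)


def gene_drop_genotypes(
    pedigree: Pedigree,
    snp_map: pd.DataFrame,
    founder_maf_range: tuple[float, float],
    config: SimConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Drop founder alleles through the pedigree, locus by locus.

    Founder dosages are Binomial(2, p_j) with p_j drawn uniformly from
    ``founder_maf_range``; each descendant receives one gamete from each
    parent, sampled Binomial(1, dosage/2) independently per locus (no
    within-chromosome linkage). Returns (dosages for all pedigree animals,
    founder allele frequencies). No missingness here — masking to the
    genotyped subset happens downstream.
    """
    lo, hi = founder_maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("founder_maf_range must lie within (0, 0.5]")
    n_snps = snp_map.shape[0]
    n = pedigree.n_animals
    rng = _stage_rng(config.seed, 3)
    freqs = rng.uniform(lo, hi, size=n_snps)
    dos = np.zeros((n, n_snps), dtype=np.float64)
    founders = np.nonzero((pedigree.sire == 0) & (pedigree.dam == 0))[0]
    dos[founders] = rng.binomial(2, freqs, size=(founders.size, n_snps))
    nonf = np.nonzero((pedigree.sire != 0) | (pedigree.dam != 0))[0]
    # parents precede offspring, so a single ordered pass is enough
    for i in nonf:
        s = pedigree.sire[i] - 1
        d = pedigree.dam[i] - 1
        gam_s = rng.binomial(1, dos[s] / 2.0)
        gam_d = rng.binomial(1, dos[d] / 2.0)
        dos[i] = gam_s + gam_d
    return dos, freqs


def simulate_breeding_values(
    pedigree: Pedigree,
    dosages: np.ndarray,
    config: SimConfig,
) -> tuple[np.ndarray, list[tuple[int, float]]]:
    """Liability-scale additive values: designated QTL plus polygenic remainder.

    QTL effects are scaled so their founder-generation variance equals
    ``qtl_var_fraction * sigma2_a``. The polygenic remainder follows the
    standard pedigree model: founders N(0, s2_poly), non-founders midparent
    average plus a Mendelian-sampling deviation with variance
    0.5 * (1 - (F_s + F_d)/2) * s2_poly.
    """
    rng = _stage_rng(config.seed, 4)
    n, n_snps = dosages.shape
    founders = (pedigree.sire == 0) & (pedigree.dam == 0)

    qtl: list[tuple[int, float]] = []
    qtl_contrib = np.zeros(n)
    if config.n_qtl > 0 and config.sigma2_a > 0 and config.qtl_var_fraction > 0:
        idx = np.sort(rng.choice(n_snps, size=config.n_qtl, replace=False))
        raw = rng.standard_normal(config.n_qtl)
        c_f = dosages[founders][:, idx] @ raw
        v = c_f.var()
        if v <= 0:
            raise ValueError("QTL genotypes monomorphic among founders")
        scale = np.sqrt(config.qtl_var_fraction * config.sigma2_a / v)
        effects = raw * scale
        centered = dosages[:, idx] - dosages[founders][:, idx].mean(axis=0)
        qtl_contrib = centered @ effects
        qtl = [(int(j), float(e)) for j, e in zip(idx, effects)]
        s2_poly = (1.0 - config.qtl_var_fraction) * config.sigma2_a
    else:
        s2_poly = config.sigma2_a

    poly = np.zeros(n)
    if s2_poly > 0:
        F = pedigree.inbreeding
        sd0 = np.sqrt(s2_poly)
        for i in range(n):
            s = pedigree.sire[i]
            d = pedigree.dam[i]
            if s == 0 and d == 0:
                poly[i] = rng.normal(0.0, sd0)
            else:
                mid = 0.0
                fs = fd = 0.0
                if s != 0:
                    mid += 0.5 * poly[s - 1]
                    fs = F[s - 1]
                if d != 0:
                    mid += 0.5 * poly[d - 1]
                    fd = F[d - 1]
                ms_var = 0.5 * (1.0 - 0.5 * (fs + fd)) * s2_poly
                poly[i] = mid + rng.normal(0.0, np.sqrt(ms_var))
    return qtl_contrib + poly, qtl


def _factor_values(levels: int, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Per-level fixed-effect values, drawn once and centered to zero mean."""
    v = rng.normal(0.0, sd, size=levels)
    return v - v.mean()


def _calibrate_intercept(g: np.ndarray, incidence: float) -> float:
    """mu with mean(Phi(mu + g)) = incidence over the realised components g."""
    from scipy.optimize import brentq
    from scipy.special import ndtr

    if g.size == 0 or np.allclose(g, 0.0):
        return float(ndtri(incidence))
    lo = float(ndtri(incidence)) - float(np.abs(g).max()) - 1.0
    hi = float(ndtri(incidence)) + float(np.abs(g).max()) + 1.0
    return float(brentq(lambda m: ndtr(m + g).mean() - incidence, lo, hi, xtol=1e-12))


def simulate_phenotypes(
    pedigree: Pedigree,
    breeding_values: np.ndarray,
    config: SimConfig,
    parities: tuple[ParitySpec, ...] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Binary pregnancy-loss style records from the liability model.

    For each record, z = mu + fixed effects + a_animal + ss_sire + e with
    e ~ N(0,1), and Y = 1 iff z > 0. The intercept mu is calibrated by root
    finding so that the expected incidence over the realised non-residual
    liability components equals the target: mean_i Phi(mu + g_i) = target.
    When every other term is zero this reduces to mu = Phi^-1(target), and
    in general it keeps the realised incidence on target despite the
    variance contributed by random and fixed effects and the pedigree drift
    of the breeding-value mean. Eligible record animals are those of the
    last ``pheno_generations`` generations.
    """
    rng = _stage_rng(config.seed, 5)
    if parities is None:
        parities = (
            ParitySpec(
                "all",
                config.incidence_target,
                config.n_records,
                tuple(config.fixed_effect_levels),
            ),
        )
    gen = (
        pedigree.generation
        if pedigree.generation is not None
        else np.zeros(pedigree.n_animals, dtype=int)
    )
    min_gen = max(gen.max() - config.pheno_generations + 1, 0)
    eligible = np.nonzero(gen >= min_gen)[0] + 1  # 1-based animal ids

    ss_effects = rng.normal(0.0, np.sqrt(config.sigma2_ss), size=config.n_service_sires)
    level_values = {
        f: _factor_values(nlev, config.fixed_effect_sd, rng)
        for f, nlev in config.fixed_effect_levels.items()
    }

    frames = []
    truth: dict = {
        "sigma2_a": config.sigma2_a,
        "sigma2_ss": config.sigma2_ss,
        "service_sire_effects": ss_effects,
        "factor_values": {k: v.copy() for k, v in level_values.items()},
        "intercepts": {},
    }
    for spec in parities:
        n_rec = min(spec.n_records, eligible.size)
        animals = rng.choice(eligible, size=n_rec, replace=False)
        rec = pd.DataFrame({"animal_id": animals, "parity": spec.name})
        fixed_part = np.zeros(n_rec)
        for f in config.fixed_effect_levels:
            if f in spec.factors:
                lev = rng.integers(0, config.fixed_effect_levels[f], size=n_rec)
                rec[f] = lev + 1
                fixed_part += level_values[f][lev]
            else:
                rec[f] = pd.array([pd.NA] * n_rec, dtype="Int64")
        ss = rng.integers(0, config.n_service_sires, size=n_rec)
        rec["service_sire"] = ss + 1
        g = fixed_part + breeding_values[animals - 1] + ss_effects[ss]
        mu = _calibrate_intercept(g, spec.incidence)
        z = mu + g + rng.standard_normal(n_rec)
        rec["y"] = (z > 0).astype(np.int8)
        frames.append(rec)
        truth["intercepts"][spec.name] = float(mu)
    pheno = pd.concat(frames, ignore_index=True)
    cols = ["animal_id", "parity"] + list(config.fixed_effect_levels) + ["service_sire", "y"]
    return pheno[cols], truth


def simulate_annotation(
    snp_map: pd.DataFrame,
    n_genes: int,
    n_terms: int,
    genes_per_term: tuple[int, int],
    seed: int,
    qtl_positions: list[tuple[str, int]] | None = None,
    span_bp: int = 2_000_000,
) -> tuple[pd.DataFrame, dict[str, tuple[str, frozenset]]]:
    """Random gene models plus gene-set terms; optional QTL-seeded terms.

    Genes are placed uniformly on the simulated chromosomes (overlap
    allowed) with lengths 5–50 kb. Terms sample gene ids with sizes in
    ``genes_per_term`` (all emitted terms therefore satisfy the >= 10-gene
    convention when the lower bound does). When ``qtl_positions`` is given,
    one extra term per QTL is seeded with every gene within ``span_bp`` of
    it, to give downstream enrichment something to find.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    lo, hi = genes_per_term
    if not 1 <= lo <= hi:
        raise ValueError("genes_per_term bounds must satisfy 1 <= lo <= hi")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 6]))
    chroms = snp_map["chromosome"].unique()
    max_bp = int(snp_map["position_bp"].max()) + 1_000_000
    gene_rows = []
    for k in range(n_genes):
        c = str(rng.choice(chroms))
        start = int(rng.integers(1, max_bp))
        length = int(rng.integers(5_000, 50_000))
        strand = "+" if rng.random() < 0.5 else "-"
        gene_rows.append((f"gene{k + 1}", c, start, start + length, strand))
    genes = pd.DataFrame(
        gene_rows, columns=["gene_id", "chromosome", "start_bp", "end_bp", "strand"]
    )

    terms: dict[str, tuple[str, frozenset]] = {}
    all_ids = genes["gene_id"].to_numpy()
    for t in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        size = min(size, n_genes)
        members = rng.choice(all_ids, size=size, replace=False)
        terms[f"T{t + 1:04d}"] = (f"random term {t + 1}", frozenset(members))
    if qtl_positions:
        for q, (chrom, pos) in enumerate(qtl_positions):
            near = genes[
                (genes["chromosome"] == str(chrom))
                & (genes["end_bp"] >= pos - span_bp)
                & (genes["start_bp"] <= pos + span_bp)
            ]["gene_id"]
            members = set(near)
            if len(members) < lo:  # pad with random genes to satisfy the size rule
                pad = rng.choice(
                    np.setdiff1d(all_ids, list(members)), size=lo - len(members), replace=False
                )
                members |= set(pad)
            terms[f"QTLT{q + 1:02d}"] = (f"genes near QTL {q + 1}", frozenset(members))
    return genes, terms


def simulate_study(
    config: SimConfig,
    parities: tuple[ParitySpec, ...] | None = None,
    keep_full_dosages: bool = True,
) -> SimulatedStudy:
    """Run the whole generator: pedigree, genotypes, truth, phenotypes."""
    ped = simulate_pedigree(config)
    snp_map = simulate_snp_map(config)
    full_dos, founder_freqs = gene_drop_genotypes(
        ped, snp_map, config.founder_maf_range, config
    )
    bv, qtl = simulate_breeding_values(ped, full_dos, config)
    pheno, truth = simulate_phenotypes(ped, bv, config, parities)
    truth["founder_freqs"] = founder_freqs

    rng = _stage_rng(config.seed, 7)
    rec_animals = np.unique(pheno["animal_id"].to_numpy())
    n_gt = max(2, int(round(config.prop_genotyped * rec_animals.size)))
    genotyped = rng.choice(rec_animals, size=min(n_gt, rec_animals.size), replace=False)
    sires = np.unique(ped.sire[rec_animals - 1])
    sires = sires[sires > 0]
    genotyped = np.unique(np.concatenate([genotyped, sires]))
    sub = full_dos[genotyped - 1].copy()
    if config.missing_rate > 0:
        mask = rng.random(sub.shape) < config.missing_rate
        sub[mask] = np.nan
    gmat = GenotypeMatrix(genotyped, snp_map["snp_id"].to_numpy(), sub)
    return SimulatedStudy(
        config=config,
        pedigree=ped,
        genotypes=gmat,
        snp_map=snp_map,
        phenotypes=pheno,
        true_breeding_values=bv,
        true_qtl=qtl,
        true_params=truth,
        full_dosages=full_dos if keep_full_dosages else None,
    )
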