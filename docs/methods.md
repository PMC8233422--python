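# Methods

`liabscan` implements a single-step genomic evaluation of a binary trait on
the liability scale, together with the post-evaluation genome scan and
SNP-based gene-set enrichment that turn the fitted model into biological
candidates. This note records the model, the algorithmic and numerical
choices, what the synthetic-data generator does and does not emulate, and
the problem sizes the default tests and scripts run at.

## The threshold animal model

The observed outcome per breeding record is binary (e.g., pregnancy loss
after confirmed pregnancy). The model places a latent liability

    z = Xβ + Z₁a + Z₂ss + ε,      ε ~ N(0, I)

behind each record, with Y = 1 exactly when z > 0, so
P(Y = 1 | η) = Φ(η). Identification fixes the residual variance at 1 and
the threshold at 0; the overall mean is absorbed by the first fixed factor
(year-season), and every later factor carries a corner constraint (first
observed level pinned to 0), since X with several full factors is rank
deficient.

Fixed effects β cover year-season of breeding, breeding type, and — for
lactating parities only — days-in-milk class and uterine-disease status.
`a` is the additive genetic effect with Var(a) = H σ²_a, and `ss` is an iid
service-sire effect, Var(ss) = I σ²_ss, capturing the bull of the
insemination. Each parity (nulliparous, primiparous, multiparous) is fitted
as its own independent model on its own records.

### Single-step relationship matrix

H merges pedigree and genomic information:

    H⁻¹ = A⁻¹ + [0 0; 0 G*⁻¹ − A₂₂⁻¹]

* `A⁻¹` is assembled sparsely by Henderson's rules with inbreeding
  (Mendelian-sampling variances dᵢ = ½ − ¼(F_s + F_d), F by the
  Meuwissen–Luo recursion; an unknown parent contributes F = −1 so the one-
  and zero-parent cases need no special-casing).
* `A₂₂` is computed by the tabular method on the pruned ancestor set of the
  genotyped animals — exactness over speed at desk scale.
* `G` is VanRaden method 1 from mean-imputed dosages, centered by observed
  allele frequencies: G = WW′ / (2Σp(1−p)).
* `G* = 0.95·G + 0.05·A₂₂` before inversion. VanRaden G is frequently
  singular (it always annihilates the 1-vector when centered by observed
  frequencies); blending is the standard remedy, and the weight is
  configurable. No further scaling or tuning of G to A₂₂ is applied.

### Gibbs sampler

One iteration draws, in order:

1. **Liabilities** from their truncated-normal full conditionals. The draw
   inverts the CDF/survival function on the side nearest the truncation
   point (`z = η − Φ⁻¹(u·Φ(η))` for Y = 1), which stays well-conditioned
   for |η| far beyond 6; a record with a missing outcome gets an
   untruncated draw, which also yields the prior-recovery property used in
   testing.
2. **Location effects** by a single-site sweep over (β, a, ss): each
   coefficient from its exact conjugate normal conditional given all
   others. The sweep runs over precomputed CSR structures (W′W and H⁻¹) in
   a numba kernel; β has a flat prior, a is penalised by H⁻¹/σ²_a, ss by
   I/σ²_ss. A fixed-effect level with no observations is constrained to 0
   with a warning.
3. **Variances** from scaled inverse chi-square conditionals,
   σ² ~ (q + ν₀S₀)/χ²_{n+ν₀} with q = a′H⁻¹a (resp. ss′ss). The residual
   variance is never sampled.

Default priors are scaled inverse chi-square with ν₀ = 4 and scale set so
the prior mode equals the start value (start σ²_a = 0.1 → scale 0.15);
ν₀ = 0 gives the flat limit. Draws are floored at 1e-8; a variance above
1e6 aborts the chain as divergent. Chains are deterministic given the seed.

Heritability is reported per retained sample as
h² = σ²_a / (σ²_a + σ²_ss + 1); the denominator includes the service-sire
variance by default (a flag removes it) and the choice is echoed in the run
metadata. Posterior intervals are 95% equal-tail. The full-scale protocol
(600,000 iterations, 100,000 burn-in, thinning 100) is the `GibbsConfig`
default; analyses in the test-suite and acceptance script run 20,000
iterations with 4,000 burn-in and thinning 10, which the convergence
diagnostics (effective sample size via arviz, Geweke z implemented here,
trace plots) show is adequate at those problem sizes.

### Sampler validation

The location sweep is an exact fixed point of the mixed-model equations at
zero injected noise; its stationary marginal SDs match the dense Gaussian
posterior; the truncated draws match scipy's `truncnorm` moments; and on a
250-animal fixture the full chain's variance posterior agrees with an
independently written dense block-Gibbs sampler (joint Cholesky location
draws). These checks live in the test suite.

## Genome scan

SNP effects are back-solved from the genomic breeding values of the
genotyped animals, ŝ = DM′[MDM′]⁻¹â_g, with D = I (equal weights) and M
centered exactly as for G. Because centering by observed frequencies makes
every column of M sum to zero, MDM′ is structurally singular (null vector
1): the GEBV vector is therefore centered — its base is arbitrary anyway —
and the system solved by minimum-norm least squares; the reconstruction
Mŝ = â_g − mean(â_g) is exact whenever rank(MDM′) = n−1. When the pipeline
back-solves from a blended G*, MDM′ is regularised with the same 0.95/0.05
blend against c·A₂₂ (c the VanRaden denominator) so both matrices share a
scale.

Windows are 2.0 Mb of adjacent SNPs, by default sliding one SNP at a time
(one window per index SNP, half-open [pos, pos+2 Mb), truncated at
chromosome ends); a non-overlapping tiled mode exists and is what the
variance-decomposition property uses. A window's genetic value per animal
is u = Σ M_j ŝ_j over its SNPs; `pct_var` = var(u)/σ²_a × 100 with the
variance taken empirically across genotyped animals and σ²_a the posterior
mean from the same parity's fit. Cross-parity genetic correlations are
Pearson correlations between effect vectors on the identical panel.

## Gene-set enrichment

SNPs map to every gene whose body ±15 kb (boundary inclusive) contains
them; the analysis universe is the set of genes with ≥1 mapped SNP. A SNP
is *relevant* when |ŝ| reaches the empirical 95th percentile of |ŝ| (the
sign of a back-solved effect is arbitrary under allele recoding; a signed
option exists); ties at the threshold are all included, so slightly more
than 5% of SNPs can be relevant. A gene is flagged when it carries ≥1
relevant SNP. Terms (GMT collections; GO, MeSH, Reactome, InterPro, MSigDB
are all consumed this way) are intersected with the universe, dropped below
10 universe genes, and tested by the upper-tail hypergeometric probability
P(X ≥ g) computed with scipy's log-gamma-based survival function — exact
agreement with full enumeration is asserted for every universe of size
≤ 12. Raw P-values are reported; a Benjamini–Hochberg column is included
for convenience and never used to filter.

Because the test is discrete, its attainable size is below the nominal 5%;
with realistic term sizes (hundreds of genes in a universe of thousands)
the permutation-null type-I rate sits near 0.04, which is what the
calibration check verifies.

## The synthetic study

The generator exists because the motivating data (commercial Holstein herd
records) are proprietary. It emulates the *statistical structure* the
method assumes, at roughly 1/4 scale:

* **Pedigree** — discrete generations; 500 founders, then 3 generations of
  2,500 offspring each; per generation 25 sires (drawn from the previous
  generation's males) are mated to randomly drawn females. The small sire
  pool mirrors AI usage — each bull leaves on the order of 100–200
  offspring — and is what makes σ²_a estimable with useful precision from
  5,000 binary records: with the pool at 50 sires the h² posterior SD
  roughly doubles. Inbreeding accumulates naturally.
* **Genotypes** — gene drop: founder dosages Binomial(2, p) with p uniform
  on the configured MAF range; each descendant receives one Bernoulli
  gamete per parent per locus. Loci are independent — no within-chromosome
  LD — so QTL detection rests on co-location within windows, and window
  variances are additive in expectation. ~12% of phenotyped animals plus
  all their sires are genotyped; 1% of calls are set missing.
* **Breeding values** — by default 5 designated panel SNPs carry 30% of
  σ²_a (scaled against realized founder variance); the remainder is
  polygenic: founders N(0, σ²_poly), descendants midparent plus a
  Mendelian-sampling deviation of variance ½(1 − (F_s+F_d)/2)σ²_poly. The
  parameter-recovery analyses use the purely polygenic (`n_qtl = 0`)
  variant: with few large QTL, a replicate's realized genetic covariance
  deviates from A·σ²_a, so the animal-model "truth" is blurred by
  finite-locus sampling rather than by the estimator; the QTL variant is
  the one the window-scan power analyses need.
* **Phenotypes** — z = μ + fixed + a + ss + ε per record, Y = 1 iff z > 0.
  Fixed-effect level values are drawn once per level from N(0, 0.2²) and
  centered; the intercept is calibrated by root finding so that
  mean Φ(μ + g) over the realized non-residual components g equals the
  target incidence (8.3/13.5/13.7% across parities, per-parity record
  counts in proportion) — this keeps the realized incidence on target
  despite variance inflation and pedigree drift of the mean breeding
  value. Records go to animals of the last two generations, one record per
  animal per parity.
* **Annotation** — random gene models (5–50 kb, overlap allowed) and GMT
  terms drawn from them, with optional terms seeded by the genes within
  2 Mb of each QTL so enrichment has signal to find.

What it does *not* emulate — and what passing tests therefore do not
establish about real data: linkage disequilibrium and realistic MAF
spectra, selection and non-random mating, genotyping error, cohort/herd
confounding beyond the drawn fixed effects, and repeated records within
parity.

Everything is reproducible byte-for-byte from (`SimConfig`, seed); each
generator stage draws from its own `SeedSequence([seed, stage])` stream so
changing one stage's parameters leaves the others' draws untouched.

## Problem sizes used by the default checks

The test suite and `scripts/acceptance.py` run the study at n = 5,000
records (pedigree ≈ 8,000; ≈ 650 genotyped; 2,000 SNPs on 5 chromosomes of
100 Mb), chains of 20,000 iterations; window-scan power uses 20 replicates
of 800 founder-genotyped animals on the same panel; enrichment calibration
uses 1,000 permutations over 80 terms in a 3,000-gene universe; the
end-to-end demo (`liabscan pipeline`, `demo_config()`) is a three-parity
run on a ~1,150-animal pedigree with a 600-SNP panel and 2,000-iteration
chains. The demo is for orchestration and reproducibility demonstration,
not inference.

## Known limitations

* Single-site Gibbs mixes slowly along directions where factor blocks are
  mutually confounded with the intercept; variance-component traces at
  desk scale show effective sample sizes in the tens-to-hundreds per
  20,000 iterations. The diagnostics report ESS and Geweke z so users can
  lengthen chains when needed.
* Posterior means of variance components are right-skewed under weak
  identification; at n = 5,000 binary records the h² posterior SD is
  ≈ 0.03–0.06 and single-replicate posterior means scatter accordingly.
* A₂₂ by the tabular method is O(m²) in the pruned ancestor count; Colleau's
  indirect method would be the optimization for large genotyped sets.
* Fixed effects carry flat priors, so a factor level whose records are all
  non-cases (or all cases) is quasi-separated and its effect drifts;
  liability-scale variances inflate with it. Keep enough records per level
  that each cell is expected to contain cases — at 13.5% incidence, a few
  dozen records per level suffice; the demo configuration reduces the
  year-season factor to 6 levels for exactly this reason.
* No metafounders, unknown-parent groups, APY, multi-trait models, or SNP
  reweighting.
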