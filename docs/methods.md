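# Methods

## Model

The evaluation is a multivariate linear animal model. For trait vector
**y** (stacked trait-major over a pedigree of *n* animals),

    y = Xβ + Zu + e,    u ~ N(0, G₀ ⊗ H),    e ~ N(0, R-structured)

* **β** — one fixed effect per contemporary group (CG) per trait. CG cells
  are farm × birth year × birth season (dry: March–August, rainy:
  September–February) × management group × sex; the intake trait (DMI)
  additionally keys on the feed-efficiency test id. CG levels are formed
  from observed records only, so the fixed-effect design is always full
  column rank.
* **u** — additive genetic effects for *every* pedigree animal and every
  trait of the scheme, covariance G₀ ⊗ H.
* **e** — residuals. Each animal contributes at most one record per trait;
  a record's residual covariance is the submatrix of R₀ for its observed
  trait pattern. Missing trait values therefore contribute nothing for
  that trait instead of forcing record deletion.

Henderson's mixed-model equations are assembled sparsely with the penalty
term G₀⁻¹ ⊗ H⁻¹ and solved by Jacobi-preconditioned conjugate gradients to
a 1e−12 relative residual (`method="direct"` switches to a sparse LU
solve). Equation ordering is fixed and no stochastic preconditioning is
used, so solutions are bit-reproducible.

Variance components (G₀, R₀) are **inputs**, not estimated. On simulated
data the generator's true components are used, which is what makes the
calibration checks meaningful.

## Relationship structures

* **A** by the tabular method in pedigree (ancestors-first) order;
  inbreeding F = diag(A) − 1. **A⁻¹** by Henderson's rules with the
  inbreeding-adjusted Mendelian-sampling variances.
* **G** = ZZ′ / (2Σⱼpⱼ(1−pⱼ)) with Z the genotype matrix centred by 2p and
  allele frequencies observed in the current genotyped set. Missing
  genotypes (possible after QC on real-format input) are mean-imputed
  (2p) for matrix construction. Monomorphic columns carry no signal and
  are excluded from Z.
* **G\*** = Z D Z′ λ with per-SNP weights D and λ = 1/Σ2pᵢ(1−pᵢ), the
  constant that also converts SNP-effect variance to animal additive
  variance.
* **Compatibility adjustment**: G's mean diagonal and mean off-diagonal
  are first matched to A₂₂ (solving a + bG for the two moments), then
  G_adj = (1−α)G + αA₂₂ with α = 0.05. Neither step is dictated by the
  model itself; they are standard single-step practice to put G on the
  pedigree base and guarantee invertibility, and both are config-exposed
  (`tune`, `alpha`). The correction block of H⁻¹ uses plain unit τ/ω
  scaling.
* **H⁻¹** = A⁻¹ plus the dense correction G_adj⁻¹ − A₂₂⁻¹ scattered on the
  genotyped block; verified blockwise against the dense inverse of the
  joined H matrix in the tests.

## SNP weighting (WssGBLUP)

Round 0 solves with D = I (plain ssGBLUP). Each weighting round then
back-solves SNP effects from the genotyped animals' GEBVs through the
identity û = λDZ′G\*⁻¹â_g, updates weights — linear dᵢ = ûᵢ²·2pᵢ(1−pᵢ) or
nonlinear dᵢ = 1.125^(|ûᵢ|/sd(û) − 2) — renormalises them so Σdᵢ·2pᵢ(1−pᵢ)
keeps its D = I value (total genetic variance constant), rebuilds G\*/H⁻¹
and re-solves. Scheme names: `ST_sswl1`/`ST_sswnl1` use the weights from
one round, `ST_sswl2`/`ST_sswnl2` from two; two rounds is the default
protocol. The nonlinear exponent caps |û|/sd at 5 so one extreme SNP
cannot dominate (cap config-exposed); with sd(û) = 0 all weights fall back
to 1 with a warning. Weighting applies to single-trait schemes only; in
multi-trait runs D stays I.

Window summaries report, for each non-overlapping window of 10 adjacent
SNPs (never spanning chromosomes; short chromosome tails form flagged
truncated windows), 100 × Var(Z_w û_w)/σ²_a over genotyped animals. σ²_a
defaults to the variance of the total genomic value so that window shares
sum to ≈100% (covariances between windows make the sum approximate); a
fixed σ²_a can be supplied instead.

## LR validation

The validation cohort (youngest fraction by birth year, an explicit id
list, or a year cut-off) has its **target-trait** records blanked to form
the partial dataset; helper-trait records are retained so correlated
information still flows, as it would for real selection candidates. Over
the cohort: acc²_p = cov(û_w,û_p)/[(1−F̄)σ²_a] with F̄ the mean pedigree
inbreeding of the cohort and σ²_a the (true/config) additive variance;
bias μ_wp = mean(û_p)−mean(û_w); dispersion b_w,p = cov(û_w,û_p)/var(û_p);
predictive ability r(û_p, y − Xβ̂)/√h² with β̂ from the whole-data solve
and h² = G₀ᵢᵢ/(G₀ᵢᵢ+R₀ᵢᵢ). Standard errors are computed across simulation
replicates (seeds), and are labelled as such in reports.

## Synthetic data generator

The generator produces the structure the model assumes, at desk scale:

* **Pedigree** — generation 0 founders; each later generation mates the
  previous generation's females (``n_offspring_per_dam`` each, default 2)
  to its males, either randomly or in sire harems. With half the animals
  female, each generation roughly replaces itself, so a default run
  (400 founders × 4 generations) holds ~2,000 animals. Birth dates spread
  over months (driving the season factor), farms are assigned so the
  farm × year × season × sex cells come out near the configured
  ``cg_count``.
* **Genotypes** — gene dropping: founder haplotypes Bernoulli(p) with
  per-locus p ~ U(0.05, 0.95), offspring inherit one random parental
  allele per locus. The genotyped subset is the youngest
  ``genotyped_fraction`` of the herd (default 0.4), emulating genotyped
  selection candidates.
* **Breeding values** — a random ``qtl_fraction`` of SNPs carries
  correlated normal effects, rescaled so the founder BV covariance equals
  G₀ *exactly*; descendants inherit BVs through their QTL genotypes, so
  Mendelian sampling arises mechanically and genomic models can genuinely
  beat pedigree BLUP. This is a deliberate design choice over sampling
  BVs down the pedigree.
* **Phenotypes** — y = CG effect + BV + residual, residuals drawn from
  R₀; per-trait missingness emulates sparsely recorded novel traits
  (3,969-record profit traits next to 55,052-record growth in the
  motivating data).
* **Feedlot series** — daily weight on a linear track whose slope loads
  on the growth BV (0.25 proportional load per genetic SD), intake level
  loading 0.35 on the intake BV, Gaussian measurement noise (4 kg weight,
  0.4 kg intake), 80 days. This is deliberately simpler than commercial
  growth-curve optimisation tools: a linear-plus-noise track suffices to
  exercise the profit accounting and keeps every parameter transparent.

Default trait set: PFT, APF, W450, DMI, REA, RFT with phenotypic SDs on
the scales reported for Nelore feedlot data (9.54 $/arroba, 67.18 $,
63.23 kg, 2.06 kg/d, 12.85 cm², 2.74 mm), heritabilities 0.17–0.35 and
moderate positive genetic correlations (PFT–APF 0.85, profit–growth
0.45–0.60); residual correlations are set at half the genetic ones. The
matrices are verified positive definite at construction.

What the generator does **not** emulate: linkage disequilibrium between
markers and realistic haplotype structure (founder loci are independent),
selection across generations, genotyping error, heterogeneous residual
variances, or maternal effects. Passing calibration tests therefore show
the estimators are correct under a correctly specified model — not that
real-data evaluations are unbiased.

The end-to-end pipeline computes APF/PFT from the simulated feedlot
series through the profit module (exercising the accounting chain), but
evaluates the generator's own trait phenotypes, whose variance components
are known by construction; the series-derived profits are driven by the
growth/intake BVs and would not match any pre-stated G₀.

## Numerical choices and problem sizes

* PCG tolerance 1e−12 (relative), Jacobi preconditioner, iteration cap
  20 × n_equations with a warning on non-convergence.
* Blending α = 0.05, tuning on, by default; `blend_and_tune_G` raises if
  the blended matrix still fails a Cholesky factorisation.
* Phenotype outlier screen: per-CG mean and SD (switchable to a trait-wide
  SD), one pass, then a single CG-size re-check — no iteration to
  convergence. Note a per-group 3.5-SD screen cannot remove anything from
  groups smaller than ~14 records, since the deviating record inflates
  its own group SD.
* Genotype QC order: non-autosomal → SNP call rate → animal call rate →
  MAF → monomorphic → duplicate position → Hardy–Weinberg (|observed −
  expected| heterozygote frequency > 0.15) → Mendelian conflicts (> 1% of
  checkable opposite-homozygote parent–offspring comparisons; SNPs, then
  animals). Each rule sees the survivors of the previous one, so report
  counts sum exactly to the removals. With the default MAF ≥ 0.05 screen,
  the monomorphic rule only fires when MAF filtering is disabled.
* Calibration experiments use ten replicates of ~2,000 pedigree animals
  with 2,000 SNPs (single trait, h² = 0.3, youngest ~15% of phenotyped
  animals as validation); the multi-trait comparison uses ~1,200 animals,
  1,000 SNPs, a 10%-recorded target and an r_g = 0.7 dense helper. These
  sizes give stable means across seeds while each replicate solves in
  about a second.

## Known limitations

REML/Gibbs variance-component estimation, metafounders/unknown-parent
groups, APY-type sparse G approximations, dominance/epistasis, genotype
imputation and candidate-gene annotation of GWAS windows are out of
scope. Repeated records per animal-trait are not supported by the MME
assembler (adjusted phenotypes average repeats if present in input
tables). The LR statistics are computed over the validation cohort only,
as in the motivating design; the config can widen the cohort rule but not
to arbitrary record subsets.
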