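"""Synthetic herd generator.

Produces a multi-generation pedigree, gene-dropped SNP genotypes for a
genotyped subset, correlated multi-trait breeding values driven by QTL,
contemporary-group fixed effects, phenotypes, and daily feedlot
weight/intake trajectories — the statistical structure that single-step
evaluation assumes, at desk scale.

Breeding values are built from QTL genotypes (not sampled down the
pedigree), so genomic models can genuinely outperform pedigree BLUP on the
simulated data. All draws flow from one seeded generator with per-stage
sub-streams.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimConfig
from .containers import UNKNOWN_PARENT, GenotypeMatrix, PedigreeTable
from .errors import ConfigError

# dry season: March-August; rainy: September-February
DRY_MONTHS = frozenset(range(3, 9))


def season_of_month(month: int) -> str:
    return "dry" if month in DRY_MONTHS else "rainy"


@dataclass
class TrueValues:
    """Simulation ground truth: per-animal BVs, QTL effects, CG effects."""

    breeding_values: np.ndarray  # animals x traits, pedigree order
    qtl_effects: np.ndarray  # SNPs x traits (zero rows for non-QTL)
    fixed_effects: pd.DataFrame  # one row per CG cell, effect columns per trait
    cg_of_animal: np.ndarray  # CG row index per animal


def _streams(cfg: SimConfig, name: str) -> np.random.Generator:
    # stable named sub-streams independent of call order
    offsets = {"pedigree": 1, "genotypes": 2, "bv": 3, "phen": 4, "feedlot": 5}
    return np.random.default_rng([cfg.seed, offsets[name]])


def simulate_pedigree(cfg: SimConfig) -> PedigreeTable:
    """Multi-generation pedigree with sexes, birth dates and farms.

    Generation 0 holds ``n_founders`` animals with unknown parents. Each
    later generation mates the previous generation's females (each dam
    leaves ``n_offspring_per_dam`` offspring) to its males — every offspring
    a random sire under ``random`` mating, block-assigned harems under
    ``hierarchical-sires``.
    """
    rng = _streams(cfg, "pedigree")
    n_farms = max(1, round(cfg.cg_count / ((cfg.n_generations + 1) * 4)))

    ids, sires, dams, sexes, years, months, farms = [], [], [], [], [], [], []
    next_id = 1

    def add(n, gen, sire_ids, dam_ids):
        nonlocal next_id
        new = np.arange(next_id, next_id + n)
        next_id += n
        ids.append(new)
        sires.append(sire_ids)
        dams.append(dam_ids)
        # enforce both sexes in every generation that has >= 2 animals
        sx = rng.integers(0, 2, size=n)
        if n >= 2 and len(np.unique(sx)) == 1:
            sx[rng.integers(n)] ^= 1
        sexes.append(np.where(sx == 0, "F", "M"))
        years.append(np.full(n, cfg.founder_year + 2 * gen))
        months.append(rng.integers(1, 13, size=n))
        farms.append(rng.integers(1, n_farms + 1, size=n))
        return new

    gen_ids = add(cfg.n_founders, 0,
                  np.full(cfg.n_founders, UNKNOWN_PARENT),
                  np.full(cfg.n_founders, UNKNOWN_PARENT))
    for gen in range(1, cfg.n_generations + 1):
        sex_prev = sexes[-1]
        dams_prev = gen_ids[sex_prev == "F"]
        sires_prev = gen_ids[sex_prev == "M"]
        if len(dams_prev) == 0 or len(sires_prev) == 0:
            break
        dam_ids = np.repeat(dams_prev, cfg.n_offspring_per_dam)
        n_off = len(dam_ids)
        if cfg.mating_scheme == "random":
            sire_ids = rng.choice(sires_prev, size=n_off)
        else:  # hierarchical-sires: contiguous harems of dams per sire
            harem = np.array_split(np.arange(len(dams_prev)), len(sires_prev))
            sire_of_dam = np.empty(len(dams_prev), dtype=np.int64)
            for s_idx, dam_block in enumerate(harem):
                sire_of_dam[dam_block] = sires_prev[s_idx]
            sire_ids = np.repeat(sire_of_dam, cfg.n_offspring_per_dam)
        gen_ids = add(n_off, gen, sire_ids, dam_ids)

    df = pd.DataFrame({
        "id": np.concatenate(ids),
        "sire": np.concatenate(sires),
        "dam": np.concatenate(dams),
        "sex": np.concatenate(sexes),
        "farm": np.concatenate(farms),
    })
    yr = np.concatenate(years)
    mo = np.concatenate(months)
    df["birth_date"] = pd.to_datetime(
        {"year": yr, "month": mo, "day": np.ones(len(yr), dtype=int)}
    )
    return PedigreeTable(df)


def drop_genotypes(ped: PedigreeTable, cfg: SimConfig,
                   return_haplotypes: bool = False):
    """Gene-drop SNP alleles through the pedigree.

    Founder haplotype alleles are Bernoulli draws at per-locus frequencies
    sampled uniformly in (0.05, 0.95); each offspring inherits one random
    allele per locus from each parent. Returns genotypes for the genotyped
    subset (the youngest ``genotyped_fraction`` of the pedigree, emulating
    genotyping of recent selection candidates).
    """
    rng = _streams(cfg, "genotypes")
    n, m = len(ped), cfg.n_snps
    p0 = rng.uniform(0.05, 0.95, size=m)
    sire_ix, dam_ix = ped.parent_indices()
    h = np.zeros((2, n, m), dtype=np.int8)
    for i in range(n):
        for k, par in enumerate((sire_ix[i], dam_ix[i])):
            if par < 0:
                h[k, i] = rng.random(m) < p0
            else:
                pick = rng.integers(0, 2, size=m)
                h[k, i] = h[pick, par, np.arange(m)]
    geno_all = (h[0] + h[1]).astype(float)

    n_geno = int(np.ceil(cfg.genotyped_fraction * n))
    # youngest animals (pedigree is ancestor-sorted; birth order breaks ties)
    order = np.argsort(ped.df["birth_date"].to_numpy(), kind="stable")
    chosen = np.sort(order[n - n_geno:]) if n_geno else np.array([], dtype=int)

    per_chrom = np.array_split(np.arange(m), cfg.n_chromosomes)
    chrom = np.empty(m, dtype=int)
    pos = np.empty(m, dtype=int)
    for c, idx in enumerate(per_chrom, start=1):
        chrom[idx] = c
        pos[idx] = np.arange(1, len(idx) + 1) * 1000
    snp_map = pd.DataFrame({
        "snp": [f"snp{j+1}" for j in range(m)], "chrom": chrom, "pos": pos,
    })
    gm = GenotypeMatrix(ids=ped.ids[chosen], matrix=geno_all[chosen], snp_map=snp_map)
    if return_haplotypes:
        return gm, geno_all
    return gm


def simulate_breeding_values(ped: PedigreeTable, geno_all: np.ndarray,
                             cfg: SimConfig) -> TrueValues:
    """Multi-trait breeding values from QTL effects.

    A random ``qtl_fraction`` of SNPs carry correlated normal effects,
    rescaled so the *founder* BV covariance equals G0 exactly. Offspring
    BVs then decompose into parent average plus Mendelian sampling by the
    gene-dropping construction itself.
    """
    rng = _streams(cfg, "bv")
    n, m = geno_all.shape
    t = cfg.n_traits
    n_qtl = max(t + 1, int(round(cfg.qtl_fraction * m)))
    qtl = np.sort(rng.choice(m, size=min(n_qtl, m), replace=False))

    corr = cfg.G0 / np.sqrt(np.outer(np.diag(cfg.G0), np.diag(cfg.G0)))
    alpha = rng.standard_normal((len(qtl), t)) @ np.linalg.cholesky(corr).T

    n_founders = int(np.sum(ped.parent_indices()[0] < 0))  # founders come first
    centered = geno_all[:, qtl] - geno_all[:n_founders, qtl].mean(axis=0)
    bv_raw = centered @ alpha
    S = np.cov(bv_raw[:n_founders].T).reshape(t, t)
    try:
        Ls = np.linalg.cholesky(S)
    except np.linalg.LinAlgError:
        raise ConfigError(
            "founder BV covariance is singular; increase n_founders or qtl_fraction"
        ) from None
    Lg = np.linalg.cholesky(cfg.G0)
    T = np.linalg.solve(Ls.T, Lg.T)  # bv_raw @ T has founder covariance G0
    bv = bv_raw @ T

    effects = np.zeros((m, t))
    effects[qtl] = alpha @ T

    # contemporary-group cells from the pedigree's own factor columns
    months = ped.df["birth_date"].dt.month.to_numpy()
    cg_key = pd.DataFrame({
        "farm": ped.df["farm"].to_numpy(),
        "year": ped.df["birth_date"].dt.year.to_numpy(),
        "season": [season_of_month(mo) for mo in months],
        "sex": ped.df["sex"].to_numpy(),
    })
    cells, cg_of_animal = np.unique(
        cg_key.apply(tuple, axis=1).to_numpy(), return_inverse=True
    )
    fx = pd.DataFrame(list(cells), columns=["farm", "year", "season", "sex"])
    for j, trait in enumerate(cfg.trait_names):
        fx[trait] = rng.normal(0.0, cfg.cg_effect_sd[j], size=len(fx))
    return TrueValues(breeding_values=bv, qtl_effects=effects,
                      fixed_effects=fx, cg_of_animal=cg_of_animal)


def simulate_phenotypes(ped: PedigreeTable, truth: TrueValues,
                        cfg: SimConfig) -> pd.DataFrame:
    """Phenotypes y = CG effect + BV + residual, one row per animal.

    Residuals are multi-trait draws from R0; per-trait missingness (the
    ``missingness`` config map, fraction of records blanked at random)
    emulates sparsely recorded novel traits next to densely recorded
    helper traits.
    """
    rng = _streams(cfg, "phen")
    n, t = truth.breeding_values.shape
    e = rng.standard_normal((n, t)) @ np.linalg.cholesky(cfg.R0).T
    cg_fx = truth.fixed_effects[list(cfg.trait_names)].to_numpy()[truth.cg_of_animal]
    y = cg_fx + truth.breeding_values + e

    out = pd.DataFrame({
        "animal": ped.ids,
        "farm": ped.df["farm"].to_numpy(),
        "year": ped.df["birth_date"].dt.year.to_numpy(),
        "season": [season_of_month(mo) for mo in ped.df["birth_date"].dt.month],
        "sex": ped.df["sex"].to_numpy(),
        "mg": np.ones(n, dtype=int),
    })
    for j, trait in enumerate(cfg.trait_names):
        col = y[:, j].copy()
        frac = cfg.missingness.get(trait, 0.0)
        if frac > 0:
            col[rng.random(n) < frac] = np.nan
        out[trait] = col
    return out


def simulate_feedlot_series(ped: PedigreeTable, truth: TrueValues,
                            cfg: SimConfig, *,
                            base_weight: float = 350.0,
                            base_gain: float = 1.2,
                            base_dmi: float = 8.2,
                            growth_load: float = 0.25,
                            intake_load: float = 0.35,
                            weight_noise_sd: float = 4.0,
                            intake_noise_sd: float = 0.4) -> pd.DataFrame:
    """Daily feedlot weight/intake trajectories over ``feedlot_days`` days.

    Weight follows a linear track whose slope loads on the animal's growth
    BV (trait ``W450`` when present, standardised by its genetic SD);
    intake level loads on the ``DMI`` BV. Gaussian measurement noise on
    both; values clipped positive. Long format: one row per animal-day with
    ``batch`` = farm.
    """
    if cfg.feedlot_days < 2:
        raise ConfigError("feedlot_days must be >= 2")
    rng = _streams(cfg, "feedlot")
    n = len(ped)
    d = cfg.feedlot_days
    traits = list(cfg.trait_names)
    sd_a = np.sqrt(np.diag(cfg.G0))

    def loading(trait):
        if trait in traits:
            j = traits.index(trait)
            return truth.breeding_values[:, j] / sd_a[j]
        return np.zeros(n)

    slope = base_gain * (1.0 + growth_load * loading("W450"))
    dmi_level = base_dmi * (1.0 + intake_load * loading("DMI"))

    days = np.arange(1, d + 1)
    w = base_weight + slope[:, None] * days[None, :]
    if weight_noise_sd > 0:
        w = w + rng.normal(0.0, weight_noise_sd, size=(n, d))
    dmi = np.broadcast_to(dmi_level[:, None], (n, d)).copy()
    if intake_noise_sd > 0:
        dmi = dmi + rng.normal(0.0, intake_noise_sd, size=(n, d))
    w = np.clip(w, 1.0, None)
    dmi = np.clip(dmi, 0.1, None)

    return pd.DataFrame({
        "animal": np.repeat(ped.ids, d),
        "day": np.tile(days, n),
        "weight_kg": w.ravel(),
        "dmi_kg": dmi.ravel(),
        "sex": np.repeat(ped.df["sex"].to_numpy(), d),
        "batch": np.repeat(ped.df["farm"].to_numpy(), d),
    })


@dataclass
class SimulatedDataset:
    """Everything one simulation run produces."""

    config: SimConfig
    pedigree: PedigreeTable
    genotypes: GenotypeMatrix
    genotypes_all: np.ndarray  # full-pedigree genotypes (truth-side only)
    truth: TrueValues
    phenotypes: pd.DataFrame
    feedlot: pd.DataFrame | None = None


def simulate_dataset(cfg: SimConfig, with_feedlot: bool = False) -> SimulatedDataset:
    """Run the full generator: pedigree -> genotypes -> BVs -> phenotypes."""
    ped = simulate_pedigree(cfg)
    geno, geno_all = drop_genotypes(ped, cfg, return_haplotypes=True)
    truth = simulate_breeding_values(ped, geno_all, cfg)
    phen = simulate_phenotypes(ped, truth, cfg)
    feedlot = simulate_feedlot_series(ped, truth, cfg) if with_feedlot else None
    return SimulatedDataset(cfg, ped, geno, geno_all, truth, phen, feedlot)
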