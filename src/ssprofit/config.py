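"""Configuration objects shared across the pipeline.

The variance components (``G0``, ``R0``) are *inputs* throughout: this package
evaluates genomic prediction models given known (co)variances, it does not
estimate them.  The bundled defaults describe six feedlot traits on their
phenotypic scales:

========  ==========================================  =========
trait     meaning                                      unit
========  ==========================================  =========
PFT       profit per arroba (15 kg) gained             $/arroba
APF       accumulated feedlot profit over the period   $
W450      weight adjusted to 450 days of age           kg
DMI       daily dry-matter intake                      kg/day
REA       ribeye area                                  cm^2
RFT       rump fat thickness                           mm
========  ==========================================  =========
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigError

DEFAULT_TRAITS = ("PFT", "APF", "W450", "DMI", "REA", "RFT")

# Phenotypic SDs on the traits' own scales, and plausible heritabilities for
# feedlot profitability, growth, intake and ultrasound carcass traits in zebu
# cattle. These drive the default G0/R0.
_PHEN_SD = {"PFT": 9.54, "APF": 67.18, "W450": 63.23, "DMI": 2.06, "REA": 12.85, "RFT": 2.74}
_H2 = {"PFT": 0.17, "APF": 0.20, "W450": 0.35, "DMI": 0.30, "REA": 0.30, "RFT": 0.25}

# Genetic correlations (symmetric, PFT/APF strongly related by construction;
# growth and carcass moderately correlated with profit).
_GEN_CORR = {
    ("PFT", "APF"): 0.85,
    ("PFT", "W450"): 0.45,
    ("PFT", "DMI"): 0.15,
    ("PFT", "REA"): 0.40,
    ("PFT", "RFT"): 0.30,
    ("APF", "W450"): 0.60,
    ("APF", "DMI"): 0.30,
    ("APF", "REA"): 0.45,
    ("APF", "RFT"): 0.30,
    ("W450", "DMI"): 0.45,
    ("W450", "REA"): 0.50,
    ("W450", "RFT"): 0.25,
    ("DMI", "REA"): 0.30,
    ("DMI", "RFT"): 0.20,
    ("REA", "RFT"): 0.20,
}


def _corr_matrix(traits: Sequence[str], table: Mapping, scale: float = 1.0) -> np.ndarray:
    t = len(traits)
    c = np.eye(t)
    for i in range(t):
        for j in range(i + 1, t):
            r = table.get((traits[i], traits[j]), table.get((traits[j], traits[i]), 0.0))
            c[i, j] = c[j, i] = r * scale
    return c


def check_spd(m: np.ndarray, name: str) -> np.ndarray:
    """Validate that ``m`` is a symmetric positive-definite covariance matrix."""
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ConfigError(f"{name} must be square, got shape {m.shape}")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ConfigError(f"{name} must be symmetric")
    if np.linalg.eigvalsh(m).min() <= 0:
        raise ConfigError(f"{name} must be positive definite")
    return m


def default_covariances(traits: Sequence[str] = DEFAULT_TRAITS) -> tuple[np.ndarray, np.ndarray]:
    """Default genetic (G0) and residual (R0) covariance matrices.

    Built from per-trait phenotypic SDs and heritabilities; residual
    correlations are set at half the genetic ones, a common rough pattern
    when no estimate is available.
    """
    unknown = [t for t in traits if t not in _PHEN_SD]
    if unknown:
        raise ConfigError(f"no default covariances for traits {unknown}")
    sd_a = np.array([_PHEN_SD[t] * np.sqrt(_H2[t]) for t in traits])
    sd_e = np.array([_PHEN_SD[t] * np.sqrt(1.0 - _H2[t]) for t in traits])
    G0 = _corr_matrix(traits, _GEN_CORR) * np.outer(sd_a, sd_a)
    R0 = _corr_matrix(traits, _GEN_CORR, scale=0.5) * np.outer(sd_e, sd_e)
    check_spd(G0, "G0")
    check_spd(R0, "R0")
    return G0, R0


@dataclass
class SimConfig:
    """Parameters of the synthetic herd generator.

    The defaults emulate the study conditions: a multi-generation pedigree
    with a genotyped subset, six correlated traits led by two profit
    phenotypes, contemporary-group fixed effects, and an 80-day feedlot
    period.
    """

    n_founders: int = 200
    n_generations: int = 4
    n_offspring_per_dam: int = 2
    mating_scheme: str = "random"  # or "hierarchical-sires"
    n_snps: int = 2000
    n_chromosomes: int = 10
    qtl_fraction: float = 0.10
    trait_names: tuple = DEFAULT_TRAITS
    G0: np.ndarray | None = None
    R0: np.ndarray | None = None
    cg_count: int = 40
    cg_effect_sd: np.ndarray | None = None  # per trait; default 0.5 x phenotypic SD
    genotyped_fraction: float = 0.4
    missingness: dict = field(default_factory=dict)  # trait -> fraction of records blanked
    feedlot_days: int = 80
    founder_year: int = 1998
    seed: int = 0

    def __post_init__(self):
        if self.n_founders < 2:
            raise ConfigError("n_founders must be >= 2")
        if self.n_generations < 0:
            raise ConfigError("n_generations must be >= 0")
        if self.mating_scheme not in ("random", "hierarchical-sires"):
            raise ConfigError(f"unknown mating scheme {self.mating_scheme!r}")
        if not 0 < self.qtl_fraction <= 1:
            raise ConfigError("qtl_fraction must be in (0, 1]")
        if self.n_snps < 100:
            raise ConfigError("n_snps must be >= 100 (10 x the 10-SNP window size)")
        if not 0 <= self.genotyped_fraction <= 1:
            raise ConfigError("genotyped_fraction must be in [0, 1]")
        self.trait_names = tuple(self.trait_names)
        if self.G0 is None or self.R0 is None:
            g, r = default_covariances(self.trait_names)
            if self.G0 is None:
                self.G0 = g
            if self.R0 is None:
                self.R0 = r
        self.G0 = check_spd(self.G0, "G0")
        self.R0 = check_spd(self.R0, "R0")
        t = len(self.trait_names)
        if self.G0.shape != (t, t) or self.R0.shape != (t, t):
            raise ConfigError("G0/R0 dimensions must match trait_names")
        if self.cg_effect_sd is None:
            self.cg_effect_sd = 0.5 * np.sqrt(np.diag(self.G0) + np.diag(self.R0))
        else:
            self.cg_effect_sd = np.broadcast_to(
                np.asarray(self.cg_effect_sd, dtype=float), (t,)
            ).copy()
        for tr in self.missingness:
            if tr not in self.trait_names:
                raise ConfigError(f"missingness refers to unknown trait {tr!r}")

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)

    def heritabilities(self) -> np.ndarray:
        g, r = np.diag(self.G0), np.diag(self.R0)
        return g / (g + r)


@dataclass
class EconomicParams:
    """Economic inputs of the profit phenotypes.

    Prices are in a single currency; the arroba is the Brazilian 15-kg
    carcass unit. Dressing percentages are sex-specific.
    """

    diet_price_kg: float = 1.20  # $/kg dry matter
    feedlot_daily_overhead: float = 2.50  # $/day non-feed cost
    arroba_price: float = 300.0  # $ per 15 kg carcass
    carcass_dressing_female: float = 55.34  # %
    carcass_dressing_male: float = 58.55  # %
    arroba_kg: float = 15.0
    shrink_factor: float = 0.96  # shrunk body weight as fraction of live weight
    period_days: int = 80

    def __post_init__(self):
        for name in ("diet_price_kg", "feedlot_daily_overhead", "arroba_price"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("carcass_dressing_female", "carcass_dressing_male"):
            if not 0 < getattr(self, name) < 100:
                raise ConfigError(f"{name} must be in (0, 100)")
        if self.period_days < 2:
            raise ConfigError("period_days must be >= 2")

    def dressing_for(self, sex: str) -> float:
        if sex in ("F", "female"):
            return self.carcass_dressing_female
        if sex in ("M", "male", "entire-male"):
            return self.carcass_dressing_male
        raise ConfigError(f"unknown sex code {sex!r}")


@dataclass
class QCThresholds:
    """Phenotype and genotype quality-control thresholds."""

    phen_sd_limit: float = 3.5
    min_cg_size: int = 4
    snp_call_rate: float = 0.90
    animal_call_rate: float = 0.90
    maf_min: float = 0.05
    mendel_conflict_max: float = 0.01
    hwe_limit: float = 0.15  # |observed - expected| heterozygote frequency
    autosomes_only: bool = True
    cg_sd_scope: str = "per-cg"  # or "overall": scope of the outlier SD

    def __post_init__(self):
        for name in ("snp_call_rate", "animal_call_rate", "maf_min",
                     "mendel_conflict_max", "hwe_limit"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.cg_sd_scope not in ("per-cg", "overall"):
            raise ConfigError("cg_sd_scope must be 'per-cg' or 'overall'")
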