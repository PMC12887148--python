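"""Contemporary groups and phenotype/genotype quality control.

Contemporary groups (CGs) are cells of animals sharing farm, birth year,
birth season (dry: March-August, rainy: September-February), management
group and sex; for the intake trait the feed-efficiency test id joins the
key. Phenotype QC removes records deviating more than 3.5 SD from their CG
mean and CGs with fewer than four records. Genotype QC applies, in order:
non-autosomal removal, SNP and animal call-rate screens, MAF, monomorphic
and duplicate-position removal, a Hardy-Weinberg heterozygote-frequency
screen, and a Mendelian-conflict screen on genotyped parent-offspring
pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import QCThresholds
from .containers import GenotypeMatrix, PedigreeTable
from .errors import DataError, PipelineError
from .simdata import season_of_month

__all__ = [
    "ContemporaryGroup", "season_of_month", "build_contemporary_groups",
    "filter_phenotypes", "filter_genotypes",
]

INTAKE_TRAITS = ("DMI",)

_CG_COLS = ("farm", "year", "season", "mg", "sex")


@dataclass
class ContemporaryGroup:
    key: tuple
    members: np.ndarray  # animal ids with a record for the trait
    mean: float
    sd: float


def _cg_key_frame(phen: pd.DataFrame, trait: str) -> pd.DataFrame:
    cols = list(_CG_COLS)
    if trait in INTAKE_TRAITS and "test_id" in phen.columns:
        cols.append("test_id")
    missing = [c for c in cols if c not in phen.columns]
    if missing:
        raise DataError(f"phenotype table missing CG factor column(s) {missing}")
    return phen[cols]


def build_contemporary_groups(phen: pd.DataFrame, trait: str) -> list[ContemporaryGroup]:
    """Partition the records carrying ``trait`` into contemporary groups."""
    if trait not in phen.columns:
        raise DataError(f"trait column {trait!r} not in phenotype table")
    has = phen[trait].notna()
    keys = _cg_key_frame(phen, trait)[has]
    vals = phen.loc[has, trait]
    animals = phen.loc[has, "animal"]
    groups = []
    for key, idx in keys.groupby(list(keys.columns), sort=True).groups.items():
        v = vals.loc[idx]
        groups.append(ContemporaryGroup(
            key=key if isinstance(key, tuple) else (key,),
            members=animals.loc[idx].to_numpy(),
            mean=float(v.mean()),
            sd=float(v.std(ddof=1)) if len(v) > 1 else 0.0,
        ))
    return groups


def cg_labels(phen: pd.DataFrame, trait: str) -> pd.Series:
    """One CG label (string) per record with the trait observed; NaN otherwise."""
    keys = _cg_key_frame(phen, trait)
    lab = keys.astype(str).agg("/".join, axis=1)
    return lab.where(phen[trait].notna())


def filter_phenotypes(phen: pd.DataFrame, trait: str, th: QCThresholds,
                      return_report: bool = False):
    """Apply the 3.5-SD outlier screen then the minimum-CG-size screen.

    Filtering blanks the trait value (sets NaN) so other traits' records
    survive. Outliers are judged against their own CG's mean and SD
    (``th.cg_sd_scope='overall'`` switches the SD to the trait-wide SD of
    CG-deviations). After outlier removal CG sizes are re-checked once and
    groups below ``min_cg_size`` are dropped.
    """
    out = phen.copy()
    report = {"outliers_removed": 0, "small_cg_removed": 0}

    lab = cg_labels(out, trait)
    obs = out[trait].notna()
    grp = out.loc[obs, trait].groupby(lab[obs])
    mean = grp.transform("mean")
    if th.cg_sd_scope == "per-cg":
        sd = grp.transform(lambda v: v.std(ddof=1) if len(v) > 1 else 0.0)
    else:
        dev_sd = (out.loc[obs, trait] - mean).std(ddof=1)
        sd = pd.Series(dev_sd, index=mean.index)
    outlier = (out.loc[obs, trait] - mean).abs() > th.phen_sd_limit * sd
    out.loc[outlier[outlier].index, trait] = np.nan
    report["outliers_removed"] = int(outlier.sum())

    lab = cg_labels(out, trait)
    obs = out[trait].notna()
    sizes = lab[obs].value_counts()
    small = set(sizes[sizes < th.min_cg_size].index)
    in_small = obs & lab.isin(small)
    out.loc[in_small, trait] = np.nan
    report["small_cg_removed"] = int(in_small.sum())

    if not out[trait].notna().any():
        import warnings
        warnings.warn(f"no records of {trait} survive phenotype QC")
    return (out, report) if return_report else out


def _is_autosome(label) -> bool:
    s = str(label).lower().removeprefix("chr")
    return s.isdigit() and int(s) > 0


def filter_genotypes(geno: GenotypeMatrix, ped: PedigreeTable | None,
                     th: QCThresholds) -> tuple[GenotypeMatrix, dict]:
    """Genotype QC; returns the filtered matrix and a rule -> count report.

    Rules apply in the documented order, each to the survivors of the
    previous one; the report counts SNPs (and animals) removed by each rule
    with no double counting.
    """
    g = geno
    report: dict[str, int] = {}

    if th.autosomes_only:
        keep = np.array([_is_autosome(c) for c in g.snp_map["chrom"]])
        report["non_autosomal_snps"] = int((~keep).sum())
        g = g.subset(snp_mask=keep)

    call = 1.0 - np.isnan(g.matrix).mean(axis=0)
    keep = call >= th.snp_call_rate
    report["snp_call_rate"] = int((~keep).sum())
    g = g.subset(snp_mask=keep)

    call_a = 1.0 - np.isnan(g.matrix).mean(axis=1)
    keep_a = call_a >= th.animal_call_rate
    report["animal_call_rate"] = int((~keep_a).sum())
    g = g.subset(animal_mask=keep_a)

    p = g.allele_freqs()
    maf = np.minimum(p, 1.0 - p)
    keep = maf >= th.maf_min
    report["maf"] = int((~keep).sum())
    g = g.subset(snp_mask=keep)

    p = g.allele_freqs()
    keep = (p > 0) & (p < 1)
    report["monomorphic"] = int((~keep).sum())
    g = g.subset(snp_mask=keep)

    dup = g.snp_map.duplicated(subset=["chrom", "pos"], keep="first").to_numpy()
    report["duplicate_position"] = int(dup.sum())
    g = g.subset(snp_mask=~dup)

    p = g.allele_freqs()
    with np.errstate(invalid="ignore"):
        obs_het = np.nanmean(g.matrix == 1.0, axis=0)
    exp_het = 2.0 * p * (1.0 - p)
    keep = np.abs(obs_het - exp_het) <= th.hwe_limit
    report["hwe"] = int((~keep).sum())
    g = g.subset(snp_mask=keep)

    if ped is not None:
        g, rep = _mendel_filter(g, ped, th)
        report.update(rep)

    if g.n_snps == 0:
        raise PipelineError("genotype QC removed every SNP")
    return g, report


def _mendel_filter(g: GenotypeMatrix, ped: PedigreeTable,
                   th: QCThresholds) -> tuple[GenotypeMatrix, dict]:
    """Drop SNPs, then animals, whose parent-offspring conflict rate > threshold.

    A conflict is an opposite-homozygote pair (parent 0 / offspring 2 or
    vice versa) among genotyped parent-offspring pairs with both calls
    present.
    """
    row_of = {a: i for i, a in enumerate(g.ids)}
    pairs = []  # (parent_row, child_row)
    for _, rec in ped.df.iterrows():
        c = row_of.get(rec["id"])
        if c is None:
            continue
        for par in (rec["sire"], rec["dam"]):
            pr = row_of.get(par)
            if pr is not None:
                pairs.append((pr, c))
    if not pairs:
        return g, {"mendel_snps": 0, "mendel_animals": 0}

    m = g.matrix
    n_snps = g.n_snps
    snp_conf = np.zeros(n_snps)
    snp_chk = np.zeros(n_snps)
    anim_conf = np.zeros(g.n_animals)
    anim_chk = np.zeros(g.n_animals)
    for pr, c in pairs:
        a, b = m[pr], m[c]
        ok = ~np.isnan(a) & ~np.isnan(b)
        conf = ok & (((a == 0) & (b == 2)) | ((a == 2) & (b == 0)))
        snp_conf += conf
        snp_chk += ok
        nc, nk = conf.sum(), ok.sum()
        for r in (pr, c):
            anim_conf[r] += nc
            anim_chk[r] += nk

    with np.errstate(invalid="ignore", divide="ignore"):
        snp_rate = np.where(snp_chk > 0, snp_conf / np.maximum(snp_chk, 1), 0.0)
        anim_rate = np.where(anim_chk > 0, anim_conf / np.maximum(anim_chk, 1), 0.0)
    keep_snp = snp_rate <= th.mendel_conflict_max
    keep_anim = anim_rate <= th.mendel_conflict_max
    rep = {"mendel_snps": int((~keep_snp).sum()),
           "mendel_animals": int((~keep_anim).sum())}
    return g.subset(animal_mask=keep_anim, snp_mask=keep_snp), rep
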