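"""Canned simulation experiments at the study's conditions.

Both the test suite and the reproduction script run these; they define the
experimental conditions once so results are comparable everywhere.

* :func:`lr_calibration_replicate` — correctly specified single-trait
  ssGBLUP (h² = 0.3 by default) with the youngest cohort as validation;
  returns the LR statistics plus truth-based measures.
* :func:`multitrait_gain_replicate` — sparse target trait (10% recorded)
  with a genetically correlated dense helper; returns single- vs
  multi-trait validation accuracy against the simulated true breeding
  values.
"""

from __future__ import annotations

import numpy as np

from .config import SimConfig
from .kinship import build_relationships
from .lrval import evaluate_split, make_split
from .simdata import simulate_dataset
from .ssgblup import SingleStepModel

# single-trait genetic/residual variance giving h2 = 0.3 on an SD-10 scale
_VAR_A, _VAR_E = 30.0, 70.0


def lr_calibration_replicate(seed: int, n_founders: int = 400,
                             n_generations: int = 4, n_snps: int = 2000,
                             genotyped_fraction: float = 0.4,
                             youngest_fraction: float = 0.15,
                             scheme: str = "ST_ss") -> dict:
    """One LR whole/partial replicate under a correctly specified model.

    The pedigree holds roughly ``n_founders × (n_generations + 1)`` animals
    (each generation replaces itself). Returns acc², bias, dispersion,
    predictive ability, the truth-based correlation of the partial GEBVs,
    and the scales needed to standardise them.
    """
    cfg = SimConfig(
        n_founders=n_founders, n_generations=n_generations, n_snps=n_snps,
        seed=seed, trait_names=("PFT",),
        G0=np.array([[_VAR_A]]), R0=np.array([[_VAR_E]]),
        genotyped_fraction=genotyped_fraction,
    )
    ds = simulate_dataset(cfg)
    rel = build_relationships(ds.pedigree, ds.genotypes)
    split = make_split(ds.phenotypes, "PFT", youngest_fraction=youngest_fraction)
    f_bar = float(np.mean(rel.F[ds.pedigree.index_of(split.validation_ids)]))

    results = {}

    def fit_fn(tab, tag):
        m = SingleStepModel.from_scheme(
            scheme, "PFT", tab, ds.pedigree, ds.genotypes,
            cfg.G0, cfg.R0, cfg.trait_names, relationships=rel,
        )
        res = m.fit(dataset_tag=tag)
        results[tag] = res
        return res

    h2 = _VAR_A / (_VAR_A + _VAR_E)
    stats = evaluate_split(split, fit_fn, f_bar, _VAR_A, h2)
    ids = split.validation_ids
    u_true = ds.truth.breeding_values[ds.pedigree.index_of(ids), 0]
    u_p = results["partial"].gebv.loc[ids, "PFT"].to_numpy()
    stats.update({
        "truth_corr": float(np.corrcoef(u_p, u_true)[0, 1]),
        "sigma_a": float(np.sqrt(_VAR_A)),
        "f_bar": f_bar,
        "h2": h2,
        "n_animals": len(ds.pedigree),
    })
    return stats


def multitrait_gain_replicate(seed: int, n_founders: int = 240,
                              n_generations: int = 4, n_snps: int = 1000,
                              genotyped_fraction: float = 0.4,
                              target_missing: float = 0.9,
                              r_g: float = 0.7) -> dict:
    """Single- vs multi-trait validation accuracy on a sparse target trait.

    The target trait is recorded on ~10% of animals; a dense helper trait
    shares genetic correlation ``r_g`` with it. Validation animals are the
    genotyped members of the youngest generation, their target records
    blanked; accuracy is the correlation of partial-data GEBVs with the
    true breeding values.
    """
    sd_a = np.array([np.sqrt(_VAR_A), np.sqrt(40.0)])
    G0 = np.array([[1.0, r_g], [r_g, 1.0]]) * np.outer(sd_a, sd_a)
    R0 = np.diag([_VAR_E, 60.0])
    cfg = SimConfig(
        n_founders=n_founders, n_generations=n_generations, n_snps=n_snps,
        seed=seed, trait_names=("PFT", "W450"), G0=G0, R0=R0,
        genotyped_fraction=genotyped_fraction,
        missingness={"PFT": target_missing},
    )
    ds = simulate_dataset(cfg)
    rel = build_relationships(ds.pedigree, ds.genotypes)

    year_max = ds.phenotypes["year"].max()
    young = ds.phenotypes.loc[ds.phenotypes["year"] == year_max, "animal"].to_numpy()
    candidates = np.intersect1d(young, ds.genotypes.ids)
    partial = ds.phenotypes.copy()
    partial.loc[partial["animal"].isin(candidates), "PFT"] = np.nan

    u_true = ds.truth.breeding_values[ds.pedigree.index_of(candidates), 0]
    out = {"n_candidates": len(candidates), "n_animals": len(ds.pedigree)}
    for scheme, key in (("ST_ss", "acc_st"), ("MT_ss", "acc_mt")):
        m = SingleStepModel.from_scheme(
            scheme, "PFT", partial, ds.pedigree, ds.genotypes,
            cfg.G0, cfg.R0, cfg.trait_names, relationships=rel,
        )
        res = m.fit(dataset_tag="partial")
        u_p = res.gebv.loc[candidates, "PFT"].to_numpy()
        out[key] = float(np.corrcoef(u_p, u_true)[0, 1])
    return out
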