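"""LR-method validation of genomic predictions.

The LR ("linear regression") method compares breeding values predicted
from a *partial* dataset — the validation animals' target-trait phenotypes
removed — with those from the *whole* dataset:

* squared accuracy   acc²_p = cov(û_w, û_p) / [(1 − F̄) σ²_a]
* bias               μ_wp  = mean(û_p) − mean(û_w)   (expectation 0)
* dispersion         b_w,p = cov(û_w, û_p) / var(û_p) (expectation 1)

all over the validation animals, with F̄ their mean pedigree inbreeding and
σ²_a the additive genetic variance of the target trait. Predictive ability
is the Pearson correlation of û_p with the phenotype adjusted for fixed
effects, divided by √h².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError


@dataclass
class ValidationSplit:
    """Whole/partial phenotype tables for one validation cohort."""

    validation_ids: np.ndarray
    whole: pd.DataFrame
    partial: pd.DataFrame
    target: str


def make_split(phen: pd.DataFrame, target: str,
               validation_ids=None, youngest_fraction: float | None = None,
               year_min: int | None = None) -> ValidationSplit:
    """Blank the validation animals' target-trait records.

    The cohort is given explicitly (``validation_ids``), as the youngest
    fraction of phenotyped animals (``youngest_fraction``, by birth year),
    or as every animal born in/after ``year_min`` — emulating the youngest
    selection candidates. Helper-trait records are retained in the partial
    table so correlated information still flows.
    """
    if target not in phen.columns:
        raise DataError(f"target trait {target!r} not in phenotype table")
    has_target = phen[target].notna()
    if validation_ids is not None:
        ids = np.asarray(validation_ids)
    elif year_min is not None:
        ids = phen.loc[has_target & (phen["year"] >= year_min), "animal"].to_numpy()
    elif youngest_fraction is not None:
        cand = phen[has_target].sort_values(["year", "animal"])
        k = int(np.ceil(youngest_fraction * len(cand)))
        ids = cand["animal"].to_numpy()[-k:] if k else np.array([])
    else:
        raise ConfigError("give validation_ids, youngest_fraction or year_min")
    ids = np.intersect1d(ids, phen.loc[has_target, "animal"].to_numpy())
    if len(ids) < 2:
        raise ConfigError("validation cohort selects fewer than 2 phenotyped animals")
    partial = phen.copy()
    partial.loc[partial["animal"].isin(ids), target] = np.nan
    return ValidationSplit(validation_ids=ids, whole=phen, partial=partial,
                           target=target)


def _paired(gebv_w, gebv_p) -> tuple[np.ndarray, np.ndarray]:
    w = np.asarray(gebv_w, dtype=float)
    p = np.asarray(gebv_p, dtype=float)
    if w.shape != p.shape:
        raise DataError("whole/partial GEBV vectors must match")
    return w, p


def lr_accuracy(gebv_w, gebv_p, f_bar: float, sigma2_a: float) -> float:
    """acc²_p = cov(û_w, û_p) / [(1 − F̄) σ²_a] over validation animals."""
    w, p = _paired(gebv_w, gebv_p)
    if len(w) < 2:
        raise DataError("need at least 2 validation animals")
    if sigma2_a <= 0:
        raise ConfigError("sigma2_a must be positive")
    return float(np.cov(w, p)[0, 1] / ((1.0 - f_bar) * sigma2_a))


def lr_bias(gebv_w, gebv_p) -> float:
    """μ_wp = mean(û_p) − mean(û_w); 0 under an unbiased evaluation."""
    w, p = _paired(gebv_w, gebv_p)
    return float(np.mean(p) - np.mean(w))


def lr_dispersion(gebv_w, gebv_p) -> float:
    """b_w,p = cov(û_w, û_p) / var(û_p); 1 without over/under-dispersion."""
    w, p = _paired(gebv_w, gebv_p)
    v = np.var(p, ddof=1)
    if v <= 0:
        raise DataError("partial GEBVs have zero variance")
    return float(np.cov(w, p)[0, 1] / v)


def adjust_phenotypes(phen: pd.DataFrame, fixed_effects: pd.DataFrame,
                      trait: str) -> pd.Series:
    """y* = y − Xβ̂: records corrected for their CG solution.

    ``fixed_effects`` is the whole-data solve's (trait, cg, estimate)
    table. Returns one adjusted value per animal with a record (indexed by
    animal id); repeated records would be averaged per animal.
    """
    from .prep import cg_labels

    lab = cg_labels(phen, trait)
    obs = lab.notna()
    fx = fixed_effects[fixed_effects["trait"] == trait]
    sol = dict(zip(fx["cg"], fx["estimate"]))
    missing = set(lab[obs]) - set(sol)
    if missing:
        raise DataError(f"no fixed-effect solution for CG(s) {sorted(missing)[:3]}")
    adj = phen.loc[obs, trait] - lab[obs].map(sol)
    out = pd.DataFrame({"animal": phen.loc[obs, "animal"], "ystar": adj})
    return out.groupby("animal")["ystar"].mean()


def predictive_ability(gebv_p, y_star, h2: float) -> float:
    """r(û_p, y*) / √h² over validation animals with phenotypes."""
    if not 0 < h2 <= 1:
        raise ConfigError("h2 must be in (0, 1]")
    u = np.asarray(gebv_p, dtype=float)
    y = np.asarray(y_star, dtype=float)
    if len(u) != len(y) or len(u) < 3:
        raise DataError("need >= 3 matched validation records")
    return float(np.corrcoef(u, y)[0, 1] / np.sqrt(h2))


@dataclass
class LRReport:
    """Per-replicate LR statistics and their across-replicate summary."""

    rows: pd.DataFrame  # scheme, trait, replicate, acc2, bias, dispersion, ...

    def summary(self) -> pd.DataFrame:
        stats = ["acc2", "bias", "dispersion", "pred_ability"]
        cols = [c for c in stats if c in self.rows.columns]
        g = self.rows.groupby(["scheme", "trait"])[cols]
        mean = g.mean()
        se = g.sem(ddof=1)
        out = mean.join(se, lsuffix="", rsuffix="_se").reset_index()
        return out

    def to_csv(self, path):
        self.rows.to_csv(path, index=False)

    def to_json(self, path):
        self.rows.to_json(path, orient="records", indent=1)


def evaluate_split(split: ValidationSplit, fit_fn, f_bar: float,
                   sigma2_a: float, h2: float) -> dict:
    """Run one whole/partial pair through ``fit_fn`` and compute the four
    LR statistics.

    ``fit_fn(phen, tag)`` must return an object with ``.gebv`` (DataFrame
    indexed by animal) and ``.fixed_effects``; it is called once with the
    whole and once with the partial table.
    """
    res_w = fit_fn(split.whole, "whole")
    res_p = fit_fn(split.partial, "partial")
    ids = split.validation_ids
    uw = res_w.gebv.loc[ids, split.target].to_numpy()
    up = res_p.gebv.loc[ids, split.target].to_numpy()
    ystar = adjust_phenotypes(split.whole, res_w.fixed_effects, split.target)
    common = [a for a in ids if a in ystar.index]
    return {
        "acc2": lr_accuracy(uw, up, f_bar, sigma2_a),
        "bias": lr_bias(uw, up),
        "dispersion": lr_dispersion(uw, up),
        "pred_ability": predictive_ability(
            res_p.gebv.loc[common, split.target].to_numpy(),
            ystar.loc[common].to_numpy(), h2),
        "n_validation": len(ids),
    }
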