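"""End-to-end orchestration: simulate → profit → prep → solve → validate.

A single YAML mapping configures the run; every stage persists its outputs
under the configured directory and the manifest records per-file checksums
so a re-run with identical config and seeds is bit-reproducible.

The evaluation stage fits each requested scheme on the whole and partial
datasets and emits one LR-statistics row per scheme, shaped like a model
comparison table (Accuracy, Bias, Dispersion, predictive ability).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .config import EconomicParams, QCThresholds, SimConfig
from .errors import ConfigError, PipelineError
from .kinship import build_relationships
from .lrval import ValidationSplit, evaluate_split, make_split
from .prep import filter_genotypes, filter_phenotypes
from .profit import profit_series, standardize_prices
from .simdata import simulate_dataset
from .ssgblup import SCHEMES, SingleStepModel

log = logging.getLogger("ssprofit")


@dataclass
class PipelineConfig:
    """Parsed pipeline configuration."""

    sim: SimConfig
    economics: EconomicParams
    qc: QCThresholds
    target: str = "PFT"
    models: tuple = ("ST_ss",)
    validation: dict = field(default_factory=lambda: {"youngest_fraction": 0.15})
    out_dir: Path = Path("ssprofit_out")
    solver: str = "pcg"
    alpha: float = 0.05
    tune: bool = True
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        models = tuple(raw.get("models", ["ST_ss"]))
        bad = [m for m in models if m not in SCHEMES]
        if bad:
            raise ConfigError(f"unknown scheme name(s) {bad}; valid: {sorted(SCHEMES)}")
        sim = SimConfig(**raw.get("simulate", {}))
        return cls(
            sim=sim,
            economics=EconomicParams(**raw.get("economics", {})),
            qc=QCThresholds(**raw.get("qc", {})),
            target=raw.get("target", "PFT"),
            models=models,
            validation=raw.get("validation", {"youngest_fraction": 0.15}),
            out_dir=Path(raw.get("out_dir", "ssprofit_out")),
            solver=raw.get("solver", "pcg"),
            alpha=raw.get("alpha", 0.05),
            tune=raw.get("tune", True),
            raw=raw,
        )


@dataclass
class RunManifest:
    config_hash: str
    version: str
    checksums: dict
    timestamps: dict
    log_path: str

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, sort_keys=True)


def _sha(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> RunManifest:
    """Execute all stages in order; any stage error aborts with its stage tag."""
    from . import __version__

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    checks: dict[str, str] = {}
    stamps: dict[str, float] = {}

    def stage(name):
        stamps[name] = time.time()
        log.info("stage %s", name)

    def persist(path: Path):
        checks[path.name] = _sha(path)

    try:
        stage("simulate")
        ds = simulate_dataset(cfg.sim, with_feedlot=True)
        sio.write_pedigree(ds.pedigree, out / "pedigree.csv")
        sio.write_genotypes(ds.genotypes, out / "genotypes.txt")
        sio.write_snp_map(ds.genotypes, out / "snp_map.csv")
        sio.write_phenotypes(ds.phenotypes, out / "phenotypes.csv")
        ds.feedlot.to_csv(out / "feedlot_series.csv", index=False)
        log.info("simulated %d animals (%d genotyped), %d SNPs",
                 len(ds.pedigree), ds.genotypes.n_animals, ds.genotypes.n_snps)
    except Exception as e:
        raise PipelineError(f"[simulate] {e}") from e

    try:
        stage("profit")
        series = standardize_prices(ds.feedlot, cfg.economics)
        prof = profit_series(series, cfg.economics)
        prof.to_csv(out / "profit.csv", index=False)
        log.info("profit phenotypes for %d animals (mean APF %.2f)",
                 len(prof), prof["APF"].mean())
    except Exception as e:
        raise PipelineError(f"[profit] {e}") from e

    try:
        stage("prep")
        phen = ds.phenotypes
        for tr in cfg.sim.trait_names:
            phen, rep = filter_phenotypes(phen, tr, cfg.qc, return_report=True)
            log.info("phenotype QC %s: %s", tr, rep)
        geno, qc_report = filter_genotypes(ds.genotypes, ds.pedigree, cfg.qc)
        with open(out / "qc_report.json", "w") as fh:
            json.dump(qc_report, fh, indent=1)
        sio.write_phenotypes(phen, out / "phenotypes_qc.csv")
        log.info("genotype QC: %s -> %d SNPs, %d animals",
                 qc_report, geno.n_snps, geno.n_animals)
    except Exception as e:
        raise PipelineError(f"[prep] {e}") from e

    try:
        stage("solve")
        rel = build_relationships(ds.pedigree, geno, alpha=cfg.alpha, tune=cfg.tune)
        sio.save_matrix(rel.H_inv, ds.pedigree.ids, out / "H_inv.mtx")

        split = make_split(phen, cfg.target, **cfg.validation)
        f_bar = float(np.mean(rel.F[ds.pedigree.index_of(split.validation_ids)]))
        ti = list(cfg.sim.trait_names).index(cfg.target)
        sigma2_a = float(cfg.sim.G0[ti, ti])
        h2 = sigma2_a / (sigma2_a + float(cfg.sim.R0[ti, ti]))

        rows = []
        gebv_frames = []
        for scheme in cfg.models:
            def fit_fn(table, tag, _scheme=scheme):
                m = SingleStepModel.from_scheme(
                    _scheme, cfg.target, table, ds.pedigree, geno,
                    cfg.sim.G0, cfg.sim.R0, cfg.sim.trait_names,
                    alpha=cfg.alpha, tune=cfg.tune,
                    relationships=rel if SCHEMES[_scheme][1] == "identity" else None,
                )
                res = m.fit(method=cfg.solver, dataset_tag=tag)
                gf = res.gebv[[cfg.target]].rename(columns={cfg.target: "gebv"})
                gf = gf.assign(scheme=_scheme, dataset=tag, trait=cfg.target)
                gebv_frames.append(gf.reset_index())
                return res

            stats = evaluate_split(split, fit_fn, f_bar, sigma2_a, h2)
            stats.update({"scheme": scheme, "trait": cfg.target})
            rows.append(stats)
            log.info("scheme %-9s acc2 %.3f bias %+.3f disp %.3f predAb %.3f",
                     scheme, stats["acc2"], stats["bias"], stats["dispersion"],
                     stats["pred_ability"])

        report = pd.DataFrame(rows)[
            ["scheme", "trait", "acc2", "bias", "dispersion", "pred_ability",
             "n_validation"]
        ].rename(columns={"acc2": "Accuracy2", "bias": "Bias",
                          "dispersion": "Dispersion"})
        report.to_csv(out / "lr_report.csv", index=False)
        report.to_json(out / "lr_report.json", orient="records", indent=1)
        pd.concat(gebv_frames).to_csv(out / "gebv.csv", index=False)
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(f"[solve/validate] {e}") from e

    for f in sorted(out.iterdir()):
        if f.is_file() and f.suffix != ".log" and f.name != "manifest.json":
            persist(f)
    cfg_hash = hashlib.sha256(
        json.dumps(cfg.raw, sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest = RunManifest(config_hash=cfg_hash, version=__version__,
                           checksums=checks, timestamps=stamps,
                           log_path=str(out / "run.log"))
    manifest.to_json(out / "manifest.json")
    return manifest
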