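"""End-to-end workflow orchestration with seeded reproducibility.

The pipeline runs the full modelling chain on one output directory:

    simulate -> filter predictors -> tune -> fit -> bootstrap ensemble
    -> surfaces -> thresholds (independent test set only) -> nine maps
    -> zonal report

Every stage reads its inputs from, and writes its artifacts to, the
output directory in plain formats (ASCII grid, GeoJSON, CSV, JSON), so
stages are independently re-runnable.  A single global seed fans out to
per-stage seeds through ``numpy.random.SeedSequence([global_seed,
stage_index])``; the manifest records every artifact with a SHA-256
content hash plus a site-id audit showing the test set never enters
tuning or bootstrap fitting.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import brt, ensemble, thresholds, zoning
from .grids import (
    read_ascii_grid,
    read_sites_csv,
    read_zones_geojson,
    write_ascii_grid,
    write_sites_csv,
)
from .predictors import PredictorStack, filter_correlated
from .synthetic import SeascapeConfig, generate_seascape, sample_sites

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all", "STAGES", "stage_seed", "threshold_triple"]

STAGES = [
    "simulate",
    "predictors",
    "tune",
    "fit",
    "ensemble",
    "thresholds",
    "maps",
    "zones",
    "report",
]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    idx = STAGES.index(stage)
    ss = np.random.SeedSequence([int(global_seed), idx])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Everything one pipeline run needs; defaults mirror the published
    workflow shape (36-combination tuning grid, 100 bootstraps, four
    threshold rules)."""

    seascape: SeascapeConfig = field(default_factory=SeascapeConfig)
    lr_values: tuple = brt.DEFAULT_LR_VALUES
    tc_values: tuple = brt.DEFAULT_TC_VALUES
    bf_values: tuple = brt.DEFAULT_BF_VALUES
    fold_count: int = 10
    step_size: int = 50
    max_trees: int = 10_000
    n_boot: int = 100
    rho_threshold: float = 0.9
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        sea = SeascapeConfig(**doc.pop("seascape", {}))
        for key in ("lr_values", "tc_values", "bf_values"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(seascape=sea, **doc)

    def with_seed(self, seed: int) -> "RunConfig":
        sea = dataclasses.replace(self.seascape, seed=stage_seed(seed, "simulate"))
        return dataclasses.replace(self, seed=seed, seascape=sea)


def threshold_triple(ts: thresholds.ThresholdSet) -> tuple[float, float, float]:
    """(low, moderate, high) probability thresholds from the four rules.

    SES and MSS typically coincide for well-performing models, leaving
    three distinct values: the MSS, PPOP and max-Kappa thresholds, sorted
    ascending.
    """
    vals = sorted([ts.mss.threshold, ts.ppop.threshold, ts.max_kappa.threshold])
    return (vals[0], vals[1], vals[2])


# ---------------------------------------------------------------------------
# Stage functions (each reads/writes the output directory)
# ---------------------------------------------------------------------------

def _path(outdir, name):
    return os.path.join(outdir, name)


def stage_simulate(config: RunConfig, outdir) -> None:
    os.makedirs(outdir, exist_ok=True)
    sea_cfg = dataclasses.replace(config.seascape, seed=stage_seed(config.seed, "simulate"))
    sea = generate_seascape(sea_cfg)
    train, test = sample_sites(sea, sea_cfg)
    sea.save(outdir)
    with open(_path(outdir, "stack.json"), "w") as fh:
        json.dump(
            {"names": sea.predictors.names, "family": sea.predictors.family,
             "truth": sea.truth_description}, fh, indent=1,
        )
    write_sites_csv(train, _path(outdir, "sites_train.csv"))
    write_sites_csv(test, _path(outdir, "sites_test.csv"))


def load_stack(outdir) -> PredictorStack:
    with open(_path(outdir, "stack.json")) as fh:
        meta = json.load(fh)
    grids = {n: read_ascii_grid(_path(outdir, f"predictor_{n}.asc")) for n in meta["names"]}
    return PredictorStack(names=meta["names"], grids=grids, family=meta["family"])


def stage_predictors(config: RunConfig, outdir) -> None:
    train = read_sites_csv(_path(outdir, "sites_train.csv"))
    result = filter_correlated(train, rho_threshold=config.rho_threshold)
    with open(_path(outdir, "filter.json"), "w") as fh:
        json.dump(
            {"retained": result.retained,
             "dropped": [[n, p, r] for n, p, r in result.dropped]},
            fh, indent=1,
        )


def _retained(outdir) -> list[str]:
    with open(_path(outdir, "filter.json")) as fh:
        return json.load(fh)["retained"]


def stage_tune(config: RunConfig, outdir) -> None:
    train = read_sites_csv(_path(outdir, "sites_train.csv"))
    tuning = brt.tune_grid(
        train,
        lr_values=config.lr_values,
        tc_values=config.tc_values,
        bf_values=config.bf_values,
        fold_count=config.fold_count,
        step_size=config.step_size,
        max_trees=config.max_trees,
        seed=stage_seed(config.seed, "tune"),
        predictor_names=_retained(outdir),
    )
    tuning.rows.to_csv(_path(outdir, "tuning.csv"), index=False)
    lr, tc, bf = tuning.best
    with open(_path(outdir, "best_params.json"), "w") as fh:
        json.dump({"lr": lr, "tc": tc, "bf": bf}, fh)


def _best_params(config: RunConfig, outdir, seed_stage: str) -> brt.BRTParams:
    with open(_path(outdir, "best_params.json")) as fh:
        best = json.load(fh)
    return brt.BRTParams(
        lr=best["lr"], tc=int(best["tc"]), bf=best["bf"],
        step_size=config.step_size, max_trees=config.max_trees,
        fold_count=config.fold_count, seed=stage_seed(config.seed, seed_stage),
    )


def stage_fit(config: RunConfig, outdir) -> None:
    train = read_sites_csv(_path(outdir, "sites_train.csv"))
    params = _best_params(config, outdir, "fit")
    model, cv_pde = brt.fit_brt_step(train, params, predictor_names=_retained(outdir))
    with open(_path(outdir, "model.json"), "w") as fh:
        fh.write(model.to_json())


def stage_ensemble(config: RunConfig, outdir) -> None:
    train = read_sites_csv(_path(outdir, "sites_train.csv"))
    model = brt.BRTModel.from_json(open(_path(outdir, "model.json")).read())
    params = _best_params(config, outdir, "ensemble")
    stack = load_stack(outdir)
    models = ensemble.bootstrap_ensemble(
        train, params,
        n_boot=config.n_boot,
        seed=stage_seed(config.seed, "ensemble"),
        n_trees=model.n_trees_selected,
        predictor_names=model.predictor_names,
    )
    preds = [brt.predict_surface(m, stack) for m in models]
    surfaces = ensemble.ensemble_surfaces(preds)
    write_ascii_grid(surfaces.mean, _path(outdir, "prob_mean.asc"))
    write_ascii_grid(surfaces.sd, _path(outdir, "prob_sd.asc"))
    write_ascii_grid(surfaces.cov, _path(outdir, "prob_cov.asc"))


def stage_thresholds(config: RunConfig, outdir) -> None:
    test = read_sites_csv(_path(outdir, "sites_test.csv"))
    mean = read_ascii_grid(_path(outdir, "prob_mean.asc"))
    pred = mean.value_at(test["x"].to_numpy(), test["y"].to_numpy())
    ok = ~np.isnan(pred)
    obs = test["presence"].to_numpy()[ok]
    pred = pred[ok]
    ts = thresholds.optimize_thresholds(obs, pred)
    roc = thresholds.roc_curve(obs, pred)
    pd.DataFrame(
        {"threshold": roc.thresholds, "sensitivity": roc.sens, "specificity": roc.spec}
    ).to_csv(_path(outdir, "roc.csv"), index=False)
    doc = {
        "auc": thresholds.auc(obs, pred),
        "test_pde": brt.percent_deviance_explained(obs, pred),
        "observed_prevalence": float(np.mean(obs)),
        "n_test_used": int(len(obs)),
    }
    for name, m in ts.as_dict().items():
        doc[name] = dataclasses.asdict(m)
    with open(_path(outdir, "thresholds.json"), "w") as fh:
        json.dump(doc, fh, indent=1)


def _threshold_set(outdir) -> thresholds.ThresholdSet:
    with open(_path(outdir, "thresholds.json")) as fh:
        doc = json.load(fh)
    return thresholds.ThresholdSet(
        **{k: thresholds.ThresholdMetrics(**doc[k]) for k in ("ses", "mss", "ppop", "max_kappa")}
    )


def stage_maps(config: RunConfig, outdir) -> None:
    mean = read_ascii_grid(_path(outdir, "prob_mean.asc"))
    cov = read_ascii_grid(_path(outdir, "prob_cov.asc"))
    triple = threshold_triple(_threshold_set(outdir))
    combos = zoning.combo_maps(mean, cov, triple)
    meta = []
    for c in combos:
        write_ascii_grid(c.mask, _path(outdir, f"combo_{c.name}.asc"))
        meta.append(
            {"name": c.name, "probability_level": c.probability_level,
             "precision_level": c.precision_level,
             "probability_threshold": c.probability_threshold,
             "cov_cutoff": None if np.isnan(c.cov_cutoff) else c.cov_cutoff,
             "area_m2": c.area_m2}
        )
    with open(_path(outdir, "combos.json"), "w") as fh:
        json.dump(meta, fh, indent=1)


def _load_combos(outdir) -> list[zoning.ComboMap]:
    with open(_path(outdir, "combos.json")) as fh:
        meta = json.load(fh)
    out = []
    for m in meta:
        mask = read_ascii_grid(_path(outdir, f"combo_{m['name']}.asc"))
        out.append(
            zoning.ComboMap(
                probability_level=m["probability_level"],
                precision_level=m["precision_level"],
                probability_threshold=m["probability_threshold"],
                cov_cutoff=np.nan if m["cov_cutoff"] is None else m["cov_cutoff"],
                mask=mask,
                area_m2=m["area_m2"],
            )
        )
    return out


def stage_zones(config: RunConfig, outdir) -> None:
    zones = read_zones_geojson(_path(outdir, "zones.geojson"))
    combos = _load_combos(outdir)
    frames = [zoning.zonal_area(c, zones) for c in combos]
    pd.concat(frames, ignore_index=True).to_csv(_path(outdir, "zonal.csv"), index=False)


def stage_report(config: RunConfig, outdir) -> None:
    combos = _load_combos(outdir)
    zonal = pd.read_csv(_path(outdir, "zonal.csv"))
    frames = [zonal[zonal.combo == c.name].reset_index(drop=True) for c in combos]
    report = zoning.sensitivity_report(frames, combos)
    with open(_path(outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=1)


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "predictors": stage_predictors,
    "tune": stage_tune,
    "fit": stage_fit,
    "ensemble": stage_ensemble,
    "thresholds": stage_thresholds,
    "maps": stage_maps,
    "zones": stage_zones,
    "report": stage_report,
}


def run_stage(name: str, config: RunConfig, outdir) -> None:
    logger.info("stage %s (seed %d)", name, stage_seed(config.seed, name))
    _STAGE_FUNCS[name](config, outdir)


def run_all(config: RunConfig, outdir) -> dict:
    """Run every stage in order and write the artifact manifest.

    Any stage error aborts with the stage name; artifacts written by
    earlier stages persist.
    """
    os.makedirs(outdir, exist_ok=True)
    for name in STAGES:
        try:
            run_stage(name, config, outdir)
        except Exception as exc:
            raise RuntimeError(f"pipeline aborted at stage {name!r}: {exc}") from exc
    manifest = build_manifest(config, outdir)
    with open(_path(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def build_manifest(config: RunConfig, outdir) -> dict:
    files = {}
    for fname in sorted(os.listdir(outdir)):
        if fname == "manifest.json":
            continue
        fpath = _path(outdir, fname)
        if os.path.isfile(fpath):
            with open(fpath, "rb") as fh:
                files[fname] = hashlib.sha256(fh.read()).hexdigest()
    train = read_sites_csv(_path(outdir, "sites_train.csv"))
    test = read_sites_csv(_path(outdir, "sites_test.csv"))
    shared = sorted(set(zip(train.x, train.y)) & set(zip(test.x, test.y)))
    audit = {
        "n_train": int(len(train)),
        "n_test": int(len(test)),
        "shared_cells": len(shared),
        "test_used_only_for": ["thresholds"],
    }
    return {
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in STAGES},
        "files": files,
        "site_audit": audit,
    }
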