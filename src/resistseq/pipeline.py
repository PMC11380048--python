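"""End-to-end orchestration: simulate/load -> preprocess -> select -> train -> evaluate.

One YAML config drives the whole run. A single master seed derives
per-stage seeds by fixed offsets, so one integer reproduces everything;
every stage output is digested into a run manifest for provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__
from .containers import MultiCohortDataset, SplitDataset, write_dataset
from .ensemble import (
    default_grid,
    grid_from_axes,
    small_grid,
    subsample_grid,
    tiny_grid,
    train_ensemble,
)
from .errors import ConfigurationError, ResistSeqError
from .evaluation import evaluate_ensemble, random_panel_null, roc_auc
from .preprocess import (
    filter_low_expression,
    load_expression,
    merge_cohorts,
    stratified_split,
)
from .selection import select_panel
from .simulate import config_from_dict, simulate_multicohort

log = logging.getLogger(__name__)

# per-stage seed offsets from the master seed
_STAGE_OFFSETS = {"simulate": 1, "split": 2, "select": 3, "train": 4, "null": 5}

_SCHEMA: dict[str, Any] = {
    "seed": int,
    "simulate": {
        "cohorts": list,
        "n_genes": int,
        "shared_de_genes": int,
        "specific_de_genes_per_cohort": int,
        "effect_size": (int, float),
        "base_mean": (int, float),
        "noise_sd": (int, float),
    },
    "data": {"matrices": list, "annotation": str},
    "preprocess": {
        "min_tpm": (int, float),
        "min_fraction": (int, float),
        "test_fraction": (int, float),
    },
    "select": {"alpha": (int, float), "n_trials": int, "min_trials": int},
    "train": {
        "primary_cohort": str,
        "selection_cohort": str,
        "k": int,
        "grid": str,
        "grid_axes": dict,
        "grid_subsample": int,
    },
    "evaluate": {"sens_floor": (int, float), "threshold_cohort": str},
    "null": {"n_draws": int, "grid": str},
}

_GRIDS = {"default": default_grid, "small": small_grid, "tiny": tiny_grid}


def validate_config(config: Mapping[str, Any]) -> None:
    """Reject unknown keys and wrongly typed values, naming the field path."""

    def walk(node: Mapping[str, Any], schema: Mapping[str, Any], path: str) -> None:
        for key, value in node.items():
            here = f"{path}.{key}" if path else key
            if key not in schema:
                raise ConfigurationError(f"unknown config key: {here}")
            expected = schema[key]
            if isinstance(expected, dict):
                if not isinstance(value, dict):
                    raise ConfigurationError(f"{here}: expected a mapping")
                walk(value, expected, here)
            elif not isinstance(value, expected) or isinstance(value, bool):
                raise ConfigurationError(f"{here}: wrong type")

    walk(config, _SCHEMA, "")
    if "simulate" in config and "data" in config:
        raise ConfigurationError("config sets both 'simulate' and 'data'")
    if "simulate" not in config and "data" not in config:
        raise ConfigurationError("config needs one of 'simulate' or 'data'")


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    config_hash: str
    package_version: str
    stage_seeds: dict[str, int]
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    timestamps: dict[str, str] = field(default_factory=dict)
    metrics: dict[str, Any] = field(default_factory=dict)

    def record(self, name: str, path: Path) -> None:
        self.outputs[name] = hashlib.sha256(path.read_bytes()).hexdigest()
        self.timestamps[name] = time.strftime("%Y-%m-%dT%H:%M:%S")

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=2))


def _resolve_grid(train_cfg: Mapping[str, Any], seed: int):
    if "grid_axes" in train_cfg:
        grid = grid_from_axes(train_cfg["grid_axes"])
    else:
        name = train_cfg.get("grid", "small")
        if name not in _GRIDS:
            raise ConfigurationError(f"train.grid: unknown grid {name!r}")
        grid = _GRIDS[name]()
    if "grid_subsample" in train_cfg:
        grid = subsample_grid(grid, train_cfg["grid_subsample"], seed=seed)
    return grid


def run_pipeline(config: Mapping[str, Any] | str | Path, outdir: str | Path) -> RunManifest:
    """Execute every stage and persist panel, model, report and manifest."""
    if isinstance(config, (str, Path)):
        raw = Path(config).read_text()
        config = yaml.safe_load(raw)
    if not isinstance(config, dict):
        raise ConfigurationError("config root must be a mapping")
    validate_config(config)

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    master_seed = int(config.get("seed", 0))
    seeds = {s: master_seed + off for s, off in _STAGE_OFFSETS.items()}
    config_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest = RunManifest(
        config_hash=config_hash,
        package_version=__version__,
        stage_seeds=seeds,
    )

    # -- stage 1: obtain data -------------------------------------------
    if "simulate" in config:
        sim_cfg = config_from_dict({**config["simulate"], "seed": seeds["simulate"]})
        ds, truth = simulate_multicohort(sim_cfg)
        write_dataset(ds, outdir / "data")
        truth.to_json(outdir / "data" / "ground_truth.json")
        manifest.record("ground_truth", outdir / "data" / "ground_truth.json")
        log.info("simulated %d cohorts, %d genes", len(ds.cohorts), len(ds.gene_ids))
    else:
        data_cfg = config["data"]
        matrices = [
            load_expression(p, data_cfg["annotation"]) for p in data_cfg["matrices"]
        ]
        ds = merge_cohorts(matrices)
        log.info("loaded %d cohorts, %d common genes", len(ds.cohorts), len(ds.gene_ids))

    # -- stage 2: preprocess --------------------------------------------
    pp = config.get("preprocess", {})
    ds = filter_low_expression(
        ds, min_tpm=pp.get("min_tpm", 1.0), min_fraction=pp.get("min_fraction", 0.2)
    )
    split = stratified_split(
        ds, test_fraction=pp.get("test_fraction", 1.0 / 3.0), seed=seeds["split"]
    )
    log.info(
        "filtered to %d genes; train/test = %d/%d samples",
        len(ds.gene_ids),
        split.train.n_samples(),
        split.test.n_samples(),
    )

    # -- stage 3: gene selection ----------------------------------------
    sel = config.get("select", {})
    panel, records = select_panel(
        split.train,
        alpha=sel.get("alpha", 0.05),
        n_trials=sel.get("n_trials", 100),
        min_trials=sel.get("min_trials", 80),
        seed=seeds["select"],
    )
    panel_path = outdir / "panel.json"
    panel.to_json(panel_path, records=records)
    manifest.record("panel", panel_path)
    log.info(
        "panel: %d tier1 + %s tier2 -> %d combined",
        len(panel.tier1),
        {c: len(g) for c, g in panel.tier2.items()},
        len(panel.combined),
    )
    if not panel.combined:
        raise ResistSeqError("selection produced an empty panel")

    # -- stage 4: train ensemble ----------------------------------------
    tr = config.get("train", {})
    names = split.train.cohort_names
    primary = tr.get("primary_cohort", names[0])
    selection = tr.get("selection_cohort", names[1 if len(names) > 1 else 0])
    grid = _resolve_grid(tr, seeds["train"])
    ens = train_ensemble(
        split.train.cohort(primary),
        split.train.cohort(selection),
        panel,
        grid=grid,
        k=tr.get("k", 5),
        seed=seeds["train"],
    )
    ens.save(outdir / "model")
    manifest.record("model", outdir / "model" / "manifest.json")

    # -- stage 5: evaluate ----------------------------------------------
    ev = config.get("evaluate", {})
    reports = evaluate_ensemble(
        ens,
        split.test,
        sens_floor=ev.get("sens_floor", 1.0),
        threshold_cohort=ev.get("threshold_cohort", selection),
    )
    report_payload = {r.cohort: r.to_dict() for r in reports}

    # -- stage 6 (optional): random-panel null --------------------------
    if "null" in config:
        nl = config["null"]
        sel_test = split.test.cohort(selection)
        observed = roc_auc(ens.predict_proba(sel_test), sel_test.labels())
        null_grid = _GRIDS[nl.get("grid", "tiny")]()
        comparison = random_panel_null(
            split,
            observed_auc=observed,
            panel_size=len(panel.combined),
            n_draws=nl.get("n_draws", 10),
            grid=null_grid,
            k=tr.get("k", 5),
            seed=seeds["null"],
            primary_cohort=primary,
            selection_cohort=selection,
        )
        report_payload["random_panel_null"] = {
            "observed_auc": comparison.observed_auc,
            "null_aucs": comparison.null_aucs,
            "empirical_p": comparison.empirical_p,
            "panel_size": comparison.panel_size,
            "n_draws": comparison.n_draws,
        }

    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report_payload, indent=2))
    manifest.record("report", report_path)
    manifest.metrics = {
        c: {k: v for k, v in r.items() if k in ("auc", "sensitivity", "specificity")}
        for c, r in report_payload.items()
        if c != "random_panel_null"
    }
    manifest.save(outdir / "manifest.json")
    return manifest
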