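"""Multi-cohort synthetic TPM generator with planted differential genes.

The generator emulates the study design this pipeline targets: several
patient cohorts of bulk RNA-seq TPM profiles, each sample labelled
chemo-resistant or chemo-sensitive, with

* a small set of *shared* genes differentially expressed between classes
  in every cohort (ground truth for the cross-cohort t-test intersection),
* per-cohort *specific* differential genes (ground truth for the bagging
  Mann-Whitney filter), and
* an additive cohort-constant batch shift on the log scale, standing in
  for cohort composition differences (ancestry, center effects).

Expression is drawn on the log2(TPM+1) scale as
``Normal(base_mean + batch_shift_c + delta_g * 1[resistant], noise_sd)``,
truncated below at 0, then back-transformed to TPM = 2^value - 1, so TPM
is always non-negative. ``delta_g = effect_size`` for shared genes in all
cohorts and for cohort-specific genes in their own cohort only; 0
otherwise. A single seeded RNG stream, consumed in (cohort, sample, gene)
order, makes output bit-identical for identical configs.

Default cohort sizes mirror the three study cohorts: 149/59 (TCGA-like),
24/16 (Patch-like) and 14/72 (SNUH-like) resistant/sensitive patients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import (
    RESISTANT,
    SENSITIVE,
    ExpressionMatrix,
    MultiCohortDataset,
    write_dataset,
)
from .errors import ConfigurationError


@dataclass(frozen=True)
class CohortSpec:
    """One simulated cohort: class sizes and its log2-scale batch shift."""

    name: str
    n_resistant: int
    n_sensitive: int
    batch_shift: float = 0.0


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for :func:`simulate_multicohort`.

    ``effect_size`` is the log2 fold-change of resistant over sensitive
    samples for planted genes; ``base_mean`` and ``noise_sd`` are the
    location and spread of log2(TPM+1); ``batch_shift`` (per cohort) is an
    additive log2-scale constant applied to every gene.
    """

    cohorts: tuple[CohortSpec, ...]
    n_genes: int = 2000
    shared_de_genes: int = 5
    specific_de_genes_per_cohort: int = 5
    effect_size: float = 2.0
    base_mean: float = 5.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.cohorts:
            raise ConfigurationError("cohorts: at least one cohort required")
        names = [c.name for c in self.cohorts]
        if len(set(names)) != len(names):
            raise ConfigurationError("cohorts: duplicate cohort name")
        for c in self.cohorts:
            if c.n_resistant < 0 or c.n_sensitive < 0:
                raise ConfigurationError(
                    f"cohorts[{c.name}]: class counts must be >= 0"
                )
        for fname in ("n_genes", "shared_de_genes", "specific_de_genes_per_cohort"):
            if getattr(self, fname) < 0:
                raise ConfigurationError(f"{fname}: must be >= 0")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd: must be > 0")
        n_planted = (
            self.shared_de_genes
            + self.specific_de_genes_per_cohort * len(self.cohorts)
        )
        if n_planted > self.n_genes:
            raise ConfigurationError(
                "n_genes: fewer genes than planted differential genes "
                f"({self.n_genes} < {n_planted})"
            )


@dataclass(frozen=True)
class GroundTruth:
    """Planted differential genes: the recovery oracle for gene selection."""

    shared_genes: tuple[str, ...]
    specific_genes: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def all_planted(self) -> set[str]:
        out = set(self.shared_genes)
        for genes in self.specific_genes.values():
            out.update(genes)
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "shared_genes": list(self.shared_genes),
            "specific_genes": {k: list(v) for k, v in self.specific_genes.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            shared_genes=tuple(payload["shared_genes"]),
            specific_genes={
                k: tuple(v) for k, v in payload["specific_genes"].items()
            },
        )


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Three cohorts at the study's printed class counts."""
    cohorts = overrides.pop(
        "cohorts",
        (
            CohortSpec("TCGA-like", 149, 59, batch_shift=0.0),
            CohortSpec("Patch-like", 24, 16, batch_shift=0.5),
            CohortSpec("SNUH-like", 14, 72, batch_shift=-0.5),
        ),
    )
    return SimulationConfig(cohorts=tuple(cohorts), seed=seed, **overrides)


def _gene_ids(n: int) -> list[str]:
    return [f"ENSG{i:011d}" for i in range(1, n + 1)]


def simulate_multicohort(
    config: SimulationConfig,
) -> tuple[MultiCohortDataset, GroundTruth]:
    """Draw a multi-cohort TPM dataset and its planted-gene ground truth.

    Planted gene roles (shared vs each cohort-specific set) are disjoint;
    assignments and expression are drawn from one RNG seeded with
    ``config.seed``, so identical configs give bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)

    n_specific_total = config.specific_de_genes_per_cohort * len(config.cohorts)
    planted_idx = rng.choice(
        config.n_genes,
        size=config.shared_de_genes + n_specific_total,
        replace=False,
    )
    shared_idx = planted_idx[: config.shared_de_genes]
    shared = tuple(genes[i] for i in sorted(shared_idx))
    specific: dict[str, tuple[str, ...]] = {}
    specific_idx: dict[str, np.ndarray] = {}
    offset = config.shared_de_genes
    for c in config.cohorts:
        idx = planted_idx[offset : offset + config.specific_de_genes_per_cohort]
        offset += config.specific_de_genes_per_cohort
        specific_idx[c.name] = idx
        specific[c.name] = tuple(genes[i] for i in sorted(idx))

    matrices = []
    for c in config.cohorts:
        n = c.n_resistant + c.n_sensitive
        delta = np.zeros(config.n_genes)
        delta[shared_idx] = config.effect_size
        delta[specific_idx[c.name]] = config.effect_size

        resistant = np.zeros(n, dtype=bool)
        resistant[: c.n_resistant] = True
        mean = (
            config.base_mean
            + c.batch_shift
            + np.outer(resistant, delta)  # samples x genes
        )
        log2_vals = rng.normal(mean, config.noise_sd, size=(n, config.n_genes))
        log2_vals = np.clip(log2_vals, 0.0, None)
        tpm = np.exp2(log2_vals) - 1.0

        sample_ids = [
            f"{c.name}-R{i + 1:03d}" for i in range(c.n_resistant)
        ] + [f"{c.name}-S{i + 1:03d}" for i in range(c.n_sensitive)]
        frame = pd.DataFrame(tpm.T, index=genes, columns=sample_ids)
        annot = pd.DataFrame(
            {
                "cohort": c.name,
                "response": [RESISTANT] * c.n_resistant
                + [SENSITIVE] * c.n_sensitive,
            },
            index=sample_ids,
        )
        matrices.append(ExpressionMatrix(frame, annot))

    truth = GroundTruth(shared_genes=shared, specific_genes=specific)
    return MultiCohortDataset(matrices), truth


def simulate_to_dir(config: SimulationConfig, outdir: str | Path) -> None:
    """Simulate and persist matrices, annotation and ground-truth JSON."""
    ds, truth = simulate_multicohort(config)
    outdir = Path(outdir)
    write_dataset(ds, outdir)
    truth.to_json(outdir / "ground_truth.json")


def config_from_dict(payload: dict) -> SimulationConfig:
    """Build a SimulationConfig from a parsed YAML/JSON mapping."""
    payload = dict(payload)
    cohorts_raw = payload.pop("cohorts", None)
    if not cohorts_raw:
        raise ConfigurationError("cohorts: missing or empty")
    cohorts = tuple(
        CohortSpec(
            name=str(c["name"]),
            n_resistant=int(c["n_resistant"]),
            n_sensitive=int(c["n_sensitive"]),
            batch_shift=float(c.get("batch_shift", 0.0)),
        )
        for c in cohorts_raw
    )
    known = {
        "n_genes",
        "shared_de_genes",
        "specific_de_genes_per_cohort",
        "effect_size",
        "base_mean",
        "noise_sd",
        "seed",
    }
    unknown = set(payload) - known
    if unknown:
        raise ConfigurationError(f"unknown simulation field: {sorted(unknown)[0]}")
    return SimulationConfig(cohorts=cohorts, **payload)
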