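"""ROC metrics, sensitivity-prioritized thresholding, random-panel null.

The positive class is chemo-resistant throughout: the clinical cost of
missing a resistant patient (treating with a regimen that will fail)
motivates thresholds that maximize specificity subject to a sensitivity
floor — 100% by default. The random-panel null asks whether the
discovered panel beats ensembles trained on uniformly drawn gene panels
of the same size, with an add-one empirical p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .containers import MultiCohortDataset, SplitDataset
from .ensemble import Ensemble, HyperParams, train_ensemble
from .errors import DataError
from .selection import GenePanel

log = logging.getLogger(__name__)


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) != {0, 1}:
        raise DataError("labels must contain both classes")
    return labels


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Probability a random positive outscores a random negative, ties = 1/2."""
    labels = _check_binary(np.asarray(labels))
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def sens_spec_at(
    scores: Sequence[float], labels: Sequence[int], threshold: float
) -> tuple[float, float]:
    """(sensitivity, specificity) predicting positive iff score >= threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(np.asarray(labels))
    pred = scores >= threshold
    pos = labels == 1
    sensitivity = float(pred[pos].mean())
    specificity = float((~pred[~pos]).mean())
    return sensitivity, specificity


def threshold_max_spec_at_sens(
    scores: Sequence[float],
    labels: Sequence[int],
    sens_floor: float = 1.0,
) -> float:
    """Threshold maximizing specificity subject to sensitivity >= floor.

    Candidates are the observed scores plus -inf (predict-all-positive,
    which always attains sensitivity 1 under the >= rule); ties in
    specificity resolve to the higher threshold.
    """
    if not 0.0 < sens_floor <= 1.0:
        raise DataError("sens_floor must be in (0, 1]")
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(np.asarray(labels))
    best_threshold: float | None = None
    best_key: tuple | None = None
    for t in sorted(set(scores.tolist()) | {-np.inf}):
        sens, spec = sens_spec_at(scores, labels, t)
        if sens >= sens_floor:
            key = (spec, t)
            if best_key is None or key > best_key:
                best_key, best_threshold = key, t
    if best_threshold is None:  # unreachable: -inf always satisfies the floor
        raise DataError("no threshold attains the sensitivity floor")
    return float(best_threshold)


@dataclass
class MetricsReport:
    """Per-cohort performance at a stated decision threshold."""

    cohort: str
    auc: float
    sensitivity: float
    specificity: float
    threshold: float
    n_resistant: int
    n_sensitive: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def evaluate_ensemble(
    ens: Ensemble,
    test: MultiCohortDataset,
    sens_floor: float | None = None,
    threshold_cohort: str | None = None,
) -> list[MetricsReport]:
    """Score each test cohort; optionally retune the threshold first.

    When ``sens_floor`` is given, the threshold is set by
    :func:`threshold_max_spec_at_sens` on the cohort named by
    ``threshold_cohort`` (default: first test cohort), then applied to
    every cohort.
    """
    threshold = ens.threshold
    if sens_floor is not None:
        ref = test.cohort(threshold_cohort) if threshold_cohort else test.cohorts[0]
        threshold = threshold_max_spec_at_sens(
            ens.predict_proba(ref), ref.labels(), sens_floor
        )
    reports = []
    for matrix in test.cohorts:
        scores = ens.predict_proba(matrix)
        y = matrix.labels()
        sens, spec = sens_spec_at(scores, y, threshold)
        n_res, n_sen = matrix.class_counts()
        reports.append(
            MetricsReport(
                cohort=matrix.cohort_name,
                auc=roc_auc(scores, y),
                sensitivity=sens,
                specificity=spec,
                threshold=float(threshold),
                n_resistant=n_res,
                n_sensitive=n_sen,
            )
        )
    return reports


@dataclass
class NullComparison:
    """Observed AUC against the random-panel AUC distribution."""

    observed_auc: float
    null_aucs: list[float]
    panel_size: int
    n_draws: int
    seed: int
    empirical_p: float = field(init=False)

    def __post_init__(self) -> None:
        n = len(self.null_aucs)
        exceed = sum(a >= self.observed_auc for a in self.null_aucs)
        self.empirical_p = (1 + exceed) / (1 + n)


def random_panel_null(
    split: SplitDataset,
    observed_auc: float,
    panel_size: int,
    n_draws: int,
    grid: Sequence[HyperParams],
    k: int = 5,
    seed: int = 0,
    primary_cohort: str | None = None,
    selection_cohort: str | None = None,
) -> NullComparison:
    """AUC distribution of ensembles trained on random same-size panels.

    Each draw samples ``panel_size`` genes uniformly without replacement
    from the filtered gene pool (the observed panel's genes are not
    excluded), trains the fold-wise ensemble, and scores the selection
    cohort's test split. A draw whose training fails is dropped; fewer
    than half completing is an error.
    """
    genes = split.train.gene_ids
    if panel_size > len(genes):
        raise DataError("panel_size exceeds the filtered gene pool")
    if n_draws < 1:
        raise DataError("n_draws must be >= 1")
    names = split.train.cohort_names
    primary = primary_cohort or names[0]
    selection = selection_cohort or names[1 if len(names) > 1 else 0]

    rng = np.random.default_rng(seed)
    null_aucs: list[float] = []
    for draw in range(n_draws):
        chosen = sorted(rng.choice(len(genes), size=panel_size, replace=False))
        panel = GenePanel(tier1=[genes[i] for i in chosen], tier2={})
        try:
            ens = train_ensemble(
                split.train.cohort(primary),
                split.train.cohort(selection),
                panel,
                grid=grid,
                k=k,
                seed=int(rng.integers(2**31)),
            )
            test_matrix = split.test.cohort(selection)
            null_aucs.append(roc_auc(ens.predict_proba(test_matrix), test_matrix.labels()))
        except DataError as err:
            log.warning("null draw %d failed: %s", draw, err)
    if len(null_aucs) < n_draws / 2:
        raise DataError(
            f"only {len(null_aucs)} of {n_draws} null draws completed"
        )
    return NullComparison(
        observed_auc=float(observed_auc),
        null_aucs=null_aucs,
        panel_size=panel_size,
        n_draws=n_draws,
        seed=seed,
    )
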