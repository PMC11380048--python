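"""Fold-wise deep ensemble with cross-cohort model selection.

One cohort's training samples are split into k class-stratified folds
(k = 5 by default). For each fold, every hyperparameter combination in a
grid is trained on the fold's fit split (Adam, binary cross-entropy) and
the candidate with the best ROC AUC on a *second* cohort's training data
is kept. The ensemble predicts by averaging the k selected members'
sigmoid outputs; selecting on an independent cohort favours members
whose decision rule transfers across cohorts rather than fitting one
cohort's batch structure.

Inputs are log2(TPM+1), z-scored per gene with each member's own
fit-split statistics, so no information flows from the selection or test
samples into standardization.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .containers import ExpressionMatrix
from .errors import DataError, SelectionError, TrainingError
from .nnet import MLP, binary_cross_entropy
from .selection import GenePanel

#: default grid axes; their Cartesian product has 4*3*5*3*3*4 = 2160 entries
DEFAULT_AXES: dict[str, tuple] = {
    "learning_rate": (0.01, 0.003, 0.001, 0.0003),
    "n_hidden_layers": (1, 2, 3),
    "hidden_units": (8, 16, 32, 64, 128),
    "dropout": (0.0, 0.25, 0.5),
    "batch_size": (8, 16, 32),
    "epochs": (25, 50, 100, 200),
}


@dataclass(frozen=True)
class HyperParams:
    """One hyperparameter combination for a member network."""

    learning_rate: float
    n_hidden_layers: int
    hidden_units: int
    dropout: float
    batch_size: int
    epochs: int

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise DataError("learning_rate must be > 0")
        if self.n_hidden_layers < 1 or self.hidden_units < 1:
            raise DataError("network must have >= 1 hidden layer and unit")
        if not 0.0 <= self.dropout < 1.0:
            raise DataError("dropout must be in [0, 1)")
        if self.batch_size < 1 or self.epochs < 1:
            raise DataError("batch_size and epochs must be >= 1")


def grid_from_axes(axes: Mapping[str, Sequence]) -> list[HyperParams]:
    """Cartesian product of hyperparameter axes, in axis-major order."""
    names = list(DEFAULT_AXES)
    missing = set(names) - set(axes)
    if missing:
        raise DataError(f"grid axes missing field: {sorted(missing)[0]}")
    return [
        HyperParams(**dict(zip(names, combo)))
        for combo in itertools.product(*(axes[n] for n in names))
    ]


def default_grid() -> list[HyperParams]:
    """The full 2160-combination search grid."""
    return grid_from_axes(DEFAULT_AXES)


def small_grid() -> list[HyperParams]:
    """A 12-entry grid for desk-scale runs and pipeline demos."""
    return grid_from_axes(
        {
            "learning_rate": (0.01, 0.003, 0.001),
            "n_hidden_layers": (1, 2),
            "hidden_units": (16, 32),
            "dropout": (0.25,),
            "batch_size": (16,),
            "epochs": (50,),
        }
    )


def tiny_grid() -> list[HyperParams]:
    """A 2-entry grid for the random-panel null, where many ensembles train."""
    return grid_from_axes(
        {
            "learning_rate": (0.01, 0.003),
            "n_hidden_layers": (1,),
            "hidden_units": (16,),
            "dropout": (0.25,),
            "batch_size": (8,),
            "epochs": (50,),
        }
    )


def subsample_grid(
    grid: Sequence[HyperParams], n: int, seed: int = 0
) -> list[HyperParams]:
    """Seeded uniform subsample of a grid (order-preserving)."""
    if n >= len(grid):
        return list(grid)
    idx = np.sort(np.random.default_rng(seed).choice(len(grid), n, replace=False))
    return [grid[i] for i in idx]


def make_folds(
    train: ExpressionMatrix, k: int = 5, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """k disjoint, exhaustive, class-stratified folds.

    Returns (fit_indices, holdout_indices) per fold, positional into the
    matrix's sample order; fold i's holdout is fold i. Deterministic
    given the seed.
    """
    y = train.labels()
    for cls in (0, 1):
        if (y == cls).sum() < k:
            raise DataError(
                f"class {'resistant' if cls else 'sensitive'} has fewer than "
                f"{k} samples"
            )
    rng = np.random.default_rng(seed)
    assignment = np.empty(len(y), dtype=int)
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        idx = idx[rng.permutation(len(idx))]
        assignment[idx] = np.arange(len(idx)) % k
    folds = []
    for i in range(k):
        holdout = np.flatnonzero(assignment == i)
        fit = np.flatnonzero(assignment != i)
        folds.append((fit, holdout))
    return folds


@dataclass
class TrainedModel:
    """A member network plus everything needed to apply it to raw TPM."""

    net: MLP
    hyperparams: HyperParams
    feature_order: list[str]
    mean: np.ndarray  # per-gene mean of log2(TPM+1) on the fit split
    sd: np.ndarray  # per-gene sd, > 0 (constant features clamped to 1)
    fold_index: int = 0
    grid_index: int = 0
    selection_score: float = float("nan")

    def _standardize(self, matrix: ExpressionMatrix) -> np.ndarray:
        X = matrix.subset_genes(self.feature_order).log2_tpm().to_numpy().T
        return (X - self.mean) / self.sd

    def predict_proba(self, matrix: ExpressionMatrix) -> np.ndarray:
        return self.net.predict_proba(self._standardize(matrix))

    def embedding(self, matrix: ExpressionMatrix) -> np.ndarray:
        return self.net.hidden_embedding(self._standardize(matrix))


def _member_seed(base_seed: int, fold: int, grid_index: int) -> int:
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(fold, grid_index))
    return int(ss.generate_state(1)[0] % (2**31))


def train_member(
    X: np.ndarray,
    y: np.ndarray,
    hp: HyperParams,
    seed: int = 0,
) -> MLP:
    """Train one network on standardized features.

    ``X`` is samples x features, already z-scored. Deterministic given
    the seed (single-threaded numpy).
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise DataError("training labels contain a single class")
    if len(y) < hp.batch_size:
        raise DataError("fewer samples than batch_size")
    rng = np.random.default_rng(seed)
    net = MLP.init(X.shape[1], hp.n_hidden_layers, hp.hidden_units, hp.dropout, rng)
    try:
        net.fit(
            X,
            y,
            learning_rate=hp.learning_rate,
            batch_size=hp.batch_size,
            epochs=hp.epochs,
            rng=rng,
        )
    except TrainingError as err:
        raise TrainingError(f"{err} (hyperparams: {hp})") from None
    return net


def select_member(
    candidates: Sequence[TrainedModel],
    selection_matrix: ExpressionMatrix,
) -> TrainedModel:
    """Pick the candidate with the best ROC AUC on the selection cohort.

    Ties break by lower selection-set cross-entropy, then lower grid
    index. Each candidate standardizes the selection data with its own
    fit-split statistics.
    """
    from .evaluation import roc_auc  # local import avoids a cycle

    if not candidates:
        raise SelectionError("no candidate models to select from")
    y_sel = selection_matrix.labels()
    if len(np.unique(y_sel)) < 2:
        raise SelectionError("selection cohort has a single class")
    best: TrainedModel | None = None
    best_key: tuple | None = None
    for cand in candidates:
        prob = cand.predict_proba(selection_matrix)
        auc = roc_auc(prob, y_sel)
        xent = binary_cross_entropy(y_sel.astype(float), prob)
        key = (-auc, xent, cand.grid_index)
        if best_key is None or key < best_key:
            best, best_key = cand, key
            cand.selection_score = auc
    assert best is not None
    return best


@dataclass
class Ensemble:
    """k fold-wise members; the score is the mean of member outputs."""

    members: list[TrainedModel]
    panel: GenePanel
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if not self.members:
            raise DataError("ensemble has no members")
        ref = self.members[0].feature_order
        for m in self.members[1:]:
            if m.feature_order != ref:
                raise DataError("ensemble members disagree on feature order")

    @property
    def feature_order(self) -> list[str]:
        return self.members[0].feature_order

    def predict_proba(self, matrix: ExpressionMatrix) -> np.ndarray:
        """Mean of member sigmoid outputs; one score in [0,1] per sample."""
        missing = [g for g in self.feature_order if g not in matrix.tpm.index]
        if missing:
            raise DataError(f"matrix lacks panel gene {missing[0]!r}")
        scores = np.stack([m.predict_proba(matrix) for m in self.members])
        return scores.mean(axis=0)

    def predict(self, matrix: ExpressionMatrix) -> np.ndarray:
        """Binary calls at the stored threshold (resistant = 1, >= rule)."""
        return (self.predict_proba(matrix) >= self.threshold).astype(int)

    def last_layer_embedding(self, matrix: ExpressionMatrix) -> np.ndarray:
        """Concatenated final-hidden-layer activations of every member."""
        missing = [g for g in self.feature_order if g not in matrix.tpm.index]
        if missing:
            raise DataError(f"matrix lacks panel gene {missing[0]!r}")
        return np.hstack([m.embedding(matrix) for m in self.members])

    # -- serialization ---------------------------------------------------
    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest = {
            "threshold": self.threshold,
            "panel": {
                "tier1": self.panel.tier1,
                "tier2": self.panel.tier2,
                "combined": self.panel.combined,
            },
            "members": [],
        }
        for i, m in enumerate(self.members):
            fname = f"member_{i}.json"
            payload = {
                "hyperparams": m.hyperparams.__dict__,
                "feature_order": m.feature_order,
                "mean": m.mean.tolist(),
                "sd": m.sd.tolist(),
                "fold_index": m.fold_index,
                "grid_index": m.grid_index,
                "selection_score": m.selection_score,
                "dropout": m.net.dropout,
                "weights": [w.tolist() for w in m.net.weights],
                "biases": [b.tolist() for b in m.net.biases],
            }
            (outdir / fname).write_text(json.dumps(payload))
            manifest["members"].append(fname)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, indir: str | Path) -> "Ensemble":
        indir = Path(indir)
        manifest = json.loads((indir / "manifest.json").read_text())
        panel = GenePanel(
            tier1=manifest["panel"]["tier1"],
            tier2=manifest["panel"]["tier2"],
            combined=manifest["panel"]["combined"],
        )
        members = []
        for fname in manifest["members"]:
            payload = json.loads((indir / fname).read_text())
            net = MLP(
                weights=[np.array(w) for w in payload["weights"]],
                biases=[np.array(b) for b in payload["biases"]],
                dropout=payload["dropout"],
            )
            members.append(
                TrainedModel(
                    net=net,
                    hyperparams=HyperParams(**payload["hyperparams"]),
                    feature_order=payload["feature_order"],
                    mean=np.array(payload["mean"]),
                    sd=np.array(payload["sd"]),
                    fold_index=payload["fold_index"],
                    grid_index=payload["grid_index"],
                    selection_score=payload["selection_score"],
                )
            )
        return cls(members=members, panel=panel, threshold=manifest["threshold"])


def train_ensemble(
    train_primary: ExpressionMatrix,
    train_selection: ExpressionMatrix,
    panel: GenePanel,
    grid: Sequence[HyperParams] | None = None,
    k: int = 5,
    seed: int = 0,
) -> Ensemble:
    """Train the fold-wise ensemble with cross-cohort model selection.

    For each of ``k`` stratified folds of the primary cohort's training
    samples, one network per grid entry is trained on the fold's fit
    split and the best performer on the selection cohort's training data
    is kept. The decision threshold is initialized to 0.5; tune it
    afterwards with the evaluation module's sensitivity-floor rule.
    """
    if grid is None:
        grid = default_grid()
    if not panel.combined:
        raise DataError("panel is empty")
    for name, matrix in (("primary", train_primary), ("selection", train_selection)):
        missing = [g for g in panel.combined if g not in matrix.tpm.index]
        if missing:
            raise DataError(
                f"{name} cohort lacks panel gene {missing[0]!r}"
            )

    primary = train_primary.subset_genes(panel.combined)
    log_primary = primary.log2_tpm().to_numpy().T  # samples x genes
    y = primary.labels()

    # features constant across the whole primary training set carry no
    # trainable signal and would break per-fold z-scoring
    overall_sd = log_primary.std(axis=0, ddof=0)
    features = list(panel.combined)
    if (overall_sd == 0).any():
        dropped = [g for g, s in zip(features, overall_sd) if s == 0]
        warnings.warn(
            f"dropping {len(dropped)} zero-variance panel genes "
            f"(first: {dropped[0]!r})",
            stacklevel=2,
        )
        keep = overall_sd > 0
        features = [g for g, k_ in zip(features, keep) if k_]
        log_primary = log_primary[:, keep]
        if not features:
            raise DataError("all panel genes have zero variance")

    folds = make_folds(primary, k=k, seed=seed)
    members: list[TrainedModel] = []
    for fold_index, (fit_idx, _holdout) in enumerate(folds):
        X_fit = log_primary[fit_idx]
        y_fit = y[fit_idx]
        mean = X_fit.mean(axis=0)
        sd = X_fit.std(axis=0, ddof=0)
        sd = np.where(sd > 0, sd, 1.0)  # fold-constant features carry z=const
        X_std = (X_fit - mean) / sd
        candidates = []
        for grid_index, hp in enumerate(grid):
            net = train_member(
                X_std, y_fit, hp, seed=_member_seed(seed, fold_index, grid_index)
            )
            candidates.append(
                TrainedModel(
                    net=net,
                    hyperparams=hp,
                    feature_order=features,
                    mean=mean,
                    sd=sd,
                    fold_index=fold_index,
                    grid_index=grid_index,
                )
            )
        members.append(select_member(candidates, train_selection))
    return Ensemble(members=members, panel=panel)
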