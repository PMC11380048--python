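"""Two-tier gene selection for cross-cohort chemoresistance panels.

Tier 1 captures genes concordant across every cohort: a pooled-variance
Student's t-test per gene per cohort on log2(TPM+1), intersecting the
per-cohort significant sets (p < alpha).

Tier 2 captures genes differential within a single cohort but robust to
class imbalance: 100 balanced bagging trials, each drawing an equal
number of resistant and sensitive samples (with replacement, m = size of
the minority class per class), testing each gene with a two-sided
Mann-Whitney U-test, and keeping genes significant (p < alpha) in
*strictly more than* ``min_trials`` of the trials.

The final panel is the deduplicated union of tier 1 and the per-cohort
tier-2 lists. No multiple-testing correction is applied anywhere: the
cross-cohort intersection and the trial-frequency filter are the guards
against false positives, not FDR control.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .containers import ExpressionMatrix, MultiCohortDataset
from .errors import DataError

log = logging.getLogger(__name__)

#: largest total sample size for which the exact Mann-Whitney null is used
_EXACT_MAX_N = 12


def student_t_pvalue(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided pooled-variance Student's t-test p-value.

    Returns NaN (caller skips the gene) when the pooled variance is zero,
    where the statistic is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise DataError("student_t_pvalue requires >= 2 values per group")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        return float("nan")
    return float(stats.ttest_ind(x, y, equal_var=True).pvalue)


def mann_whitney_pvalue(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Mann-Whitney U p-value.

    Uses the exact null distribution when the pooled sample is small
    (n <= 12) and tie-free; otherwise the normal approximation with tie
    and continuity corrections. Always defined for non-empty inputs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise DataError("mann_whitney_pvalue requires non-empty groups")
    pooled = np.concatenate([x, y])
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= _EXACT_MAX_N and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def _cohort_t_pvalues(matrix: ExpressionMatrix) -> np.ndarray:
    """Vectorized per-gene pooled t-test on log2(TPM+1); NaN where degenerate."""
    res, sen = matrix.split_by_response()
    if res.shape[1] < 2 or sen.shape[1] < 2:
        raise DataError(
            f"cohort {matrix.cohort_name!r} needs >= 2 samples per class"
        )
    log_res = np.log2(res.to_numpy() + 1.0)
    log_sen = np.log2(sen.to_numpy() + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pvals = stats.ttest_ind(log_res, log_sen, axis=1, equal_var=True).pvalue
    degenerate = (np.var(log_res, axis=1) == 0) & (np.var(log_sen, axis=1) == 0)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance genes skipped in t-tests",
            stacklevel=2,
        )
        pvals = np.where(degenerate, np.nan, pvals)
    return np.asarray(pvals, dtype=float)


def tier1_select(train: MultiCohortDataset, alpha: float = 0.05) -> list[str]:
    """Genes significant (Student's t, p < alpha) in every cohort.

    Runs on training samples only; returns the lexicographically sorted
    intersection. An empty intersection is a valid (logged) outcome.
    """
    selected: set[str] | None = None
    for matrix in train.cohorts:
        pvals = _cohort_t_pvalues(matrix)
        sig = {
            g
            for g, p in zip(matrix.gene_ids, pvals)
            if np.isfinite(p) and p < alpha
        }
        selected = sig if selected is None else (selected & sig)
    assert selected is not None
    if not selected:
        log.info("tier1: empty cross-cohort intersection")
    return sorted(selected)


@dataclass
class BaggingRecord:
    """Per-gene count of bagging trials with a significant Mann-Whitney test."""

    counts: dict[str, int]
    n_trials: int
    alpha: float
    seed: int

    def __post_init__(self) -> None:
        bad = [g for g, c in self.counts.items() if not 0 <= c <= self.n_trials]
        if bad:
            raise DataError(f"bagging count out of range for gene {bad[0]!r}")


def tier2_select(
    cohort_train: ExpressionMatrix,
    n_trials: int = 100,
    alpha: float = 0.05,
    min_trials: int = 80,
    seed: int = 0,
    replace: bool = True,
) -> tuple[list[str], BaggingRecord]:
    """Balanced-bagging Mann-Whitney frequency filter within one cohort.

    Per trial, m samples are drawn from each class (m = minority-class
    size; with replacement by default, ``replace=False`` subsamples
    instead), every gene is tested on the drawn log2(TPM+1) values, and
    trials with p < alpha are counted. Genes significant in strictly more
    than ``min_trials`` trials are selected. Deterministic given ``seed``.
    """
    if n_trials < 1:
        raise DataError("n_trials must be >= 1")
    if not 0 <= min_trials <= n_trials:
        raise DataError("min_trials must be in [0, n_trials]")
    res, sen = cohort_train.split_by_response()
    n_res, n_sen = res.shape[1], sen.shape[1]
    if n_res == 0 or n_sen == 0:
        raise DataError(
            f"cohort {cohort_train.samples['cohort'].iloc[0]!r} lacks one class"
        )
    m = min(n_res, n_sen)
    log_res = np.log2(res.to_numpy() + 1.0)
    log_sen = np.log2(sen.to_numpy() + 1.0)

    rng = np.random.default_rng(seed)
    counts = np.zeros(cohort_train.n_genes, dtype=int)
    for _ in range(n_trials):
        if replace:
            ri = rng.integers(0, n_res, size=m)
            si = rng.integers(0, n_sen, size=m)
        else:
            ri = rng.permutation(n_res)[:m]
            si = rng.permutation(n_sen)[:m]
        xs = log_res[:, ri]
        ys = log_sen[:, si]
        if 2 * m <= _EXACT_MAX_N:
            pvals = np.array(
                [mann_whitney_pvalue(xs[g], ys[g]) for g in range(xs.shape[0])]
            )
        else:
            pvals = stats.mannwhitneyu(
                xs, ys, alternative="two-sided", method="asymptotic", axis=1
            ).pvalue
        counts += pvals < alpha

    record = BaggingRecord(
        counts=dict(zip(cohort_train.gene_ids, (int(c) for c in counts))),
        n_trials=n_trials,
        alpha=alpha,
        seed=seed,
    )
    selected = sorted(
        g for g, c in record.counts.items() if c > min_trials
    )
    return selected, record


@dataclass
class GenePanel:
    """Tier-1, per-cohort tier-2 lists, and their union (the panel).

    ``combined`` is the deduplicated union in stable order: tier-1 genes
    first, then each cohort's tier-2 genes in cohort order, sorted
    lexicographically within each group.
    """

    tier1: list[str]
    tier2: dict[str, list[str]]
    combined: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.combined:
            self.combined = _stable_union(self.tier1, self.tier2)
        elif self.combined != _stable_union(self.tier1, self.tier2):
            raise DataError("combined list is not the stable union of the tiers")

    def to_json(
        self, path: str | Path, records: Mapping[str, BaggingRecord] | None = None
    ) -> None:
        payload: dict = {
            "tier1": self.tier1,
            "tier2": self.tier2,
            "combined": self.combined,
        }
        if records is not None:
            payload["bagging_records"] = {
                name: {
                    "counts": rec.counts,
                    "n_trials": rec.n_trials,
                    "alpha": rec.alpha,
                    "seed": rec.seed,
                }
                for name, rec in records.items()
            }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GenePanel":
        payload = json.loads(Path(path).read_text())
        return cls(
            tier1=list(payload["tier1"]),
            tier2={k: list(v) for k, v in payload["tier2"].items()},
            combined=list(payload["combined"]),
        )


def _stable_union(tier1: Sequence[str], tier2: Mapping[str, Sequence[str]]) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    for group in [sorted(tier1)] + [sorted(tier2[c]) for c in tier2]:
        for g in group:
            if g not in seen:
                seen.add(g)
                out.append(g)
    return out


def combine_panel(
    tier1: Sequence[str], tier2: Mapping[str, Sequence[str]]
) -> GenePanel:
    """Assemble the predictive panel from the two selection tiers."""
    return GenePanel(tier1=list(tier1), tier2={k: list(v) for k, v in tier2.items()})


def select_panel(
    train: MultiCohortDataset,
    alpha: float = 0.05,
    n_trials: int = 100,
    min_trials: int = 80,
    seed: int = 0,
) -> tuple[GenePanel, dict[str, BaggingRecord]]:
    """Run both tiers on the training split and combine the panel.

    Per-cohort tier-2 seeds are derived from ``seed`` via a spawned seed
    sequence, so cohorts are independent but the whole selection is
    reproducible from one integer.
    """
    tier1 = tier1_select(train, alpha=alpha)
    tier2: dict[str, list[str]] = {}
    records: dict[str, BaggingRecord] = {}
    children = np.random.SeedSequence(seed).spawn(len(train.cohorts))
    for matrix, child in zip(train.cohorts, children):
        name = matrix.cohort_name
        cohort_seed = int(child.generate_state(1)[0] % (2**31))
        genes, record = tier2_select(
            matrix,
            n_trials=n_trials,
            alpha=alpha,
            min_trials=min_trials,
            seed=cohort_seed,
        )
        tier2[name] = genes
        records[name] = record
    return combine_panel(tier1, tier2), records
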