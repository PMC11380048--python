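"""Loading, merging, low-expression filtering and stratified splitting.

Mirrors the preprocessing phase of the workflow: per-cohort TPM matrices
keyed by Ensembl gene IDs are merged on the intersection of their gene
sets, lowly expressed genes are removed, and each cohort is split for
training and testing with class balance preserved (2:1 by default).
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, MultiCohortDataset, SplitDataset
from .errors import DataError

log = logging.getLogger(__name__)


def _read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, **kwargs)


def load_expression(
    path: str | Path,
    annotation_path: str | Path,
    strip_gene_versions: bool = False,
) -> ExpressionMatrix:
    """Load a genes x samples TPM table and its sample annotation.

    The matrix file is TSV (or CSV by extension) with gene IDs in the
    first column and a header row of sample IDs. The annotation file has
    columns ``sample_id``, ``cohort``, ``response`` and must cover every
    sample in the matrix. Set ``strip_gene_versions`` to drop Ensembl
    ``.N`` version suffixes; IDs are otherwise treated as opaque strings.
    """
    frame = _read_table(path, index_col=0)
    frame.index = frame.index.astype(str)
    if strip_gene_versions:
        frame.index = frame.index.str.replace(r"\.\d+$", "", regex=True)
        if frame.index.has_duplicates:
            dup = frame.index[frame.index.duplicated()][0]
            raise DataError(
                f"stripping versions collapsed gene IDs: {dup!r} duplicated"
            )
    non_numeric = frame.columns[
        [not np.issubdtype(dt, np.number) for dt in frame.dtypes]
    ]
    if len(non_numeric):
        col = non_numeric[0]
        bad = frame[col][pd.to_numeric(frame[col], errors="coerce").isna()]
        gene = bad.index[0] if len(bad) else frame.index[0]
        raise DataError(
            f"non-numeric TPM for gene {gene!r} sample {col!r}"
        )

    annot = _read_table(annotation_path)
    required = {"sample_id", "cohort", "response"}
    missing_cols = required - set(annot.columns)
    if missing_cols:
        raise DataError(f"annotation missing column: {sorted(missing_cols)[0]}")
    annot = annot.set_index("sample_id")[["cohort", "response"]]
    annot.index = annot.index.astype(str)
    present = frame.columns.intersection(annot.index)
    annot = annot.loc[present]
    return ExpressionMatrix(frame, annot)


def merge_cohorts(matrices: Sequence[ExpressionMatrix]) -> MultiCohortDataset:
    """Merge cohorts on the intersection of their gene sets.

    Retained genes are sorted lexicographically; each cohort matrix is
    row-subset and reordered accordingly. Union-with-imputation is
    deliberately not offered — only genes quantified in every cohort are
    comparable across them.
    """
    if len(matrices) < 2:
        raise DataError("merge_cohorts requires at least two matrices")
    common = set(matrices[0].gene_ids)
    for m in matrices[1:]:
        common &= set(m.gene_ids)
    if not common:
        raise DataError("no common genes across cohorts")
    order = sorted(common)
    return MultiCohortDataset([m.subset_genes(order) for m in matrices])


def filter_low_expression(
    ds: MultiCohortDataset,
    min_tpm: float = 1.0,
    min_fraction: float = 0.2,
) -> MultiCohortDataset:
    """Keep genes with TPM >= ``min_tpm`` in >= ``min_fraction`` of samples.

    The fraction is computed over all samples pooled across cohorts, and
    both bounds are inclusive. Gene order is preserved.
    """
    if not 0.0 <= min_fraction <= 1.0:
        raise DataError("min_fraction must be in [0, 1]")
    pooled = pd.concat([m.tpm for m in ds.cohorts], axis=1)
    frac = (pooled >= min_tpm).mean(axis=1)
    keep = [g for g, f in zip(pooled.index, frac) if f >= min_fraction]
    if not keep:
        raise DataError("low-expression filter removed all genes")
    log.info("low-expression filter: %d of %d genes kept", len(keep), len(frac))
    return ds.subset_genes(keep)


def stratified_split(
    ds: MultiCohortDataset,
    test_fraction: float = 1.0 / 3.0,
    seed: int = 0,
) -> SplitDataset:
    """Split each (cohort, class) stratum into train and test.

    Each stratum contributes ``floor(n * test_fraction)`` test samples —
    at least 1 when the stratum has >= 2 samples, so evaluation strata
    are never empty — chosen by a seeded shuffle. Singleton strata go to
    train with a warning. Deterministic given the seed.
    """
    if not 0.0 < test_fraction < 1.0:
        raise DataError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_parts, test_parts = [], []
    for m in ds.cohorts:
        train_ids: list[str] = []
        test_ids: list[str] = []
        for response in sorted(m.samples["response"].unique()):
            ids = [
                s
                for s, r in m.samples["response"].items()
                if r == response
            ]
            n = len(ids)
            if n == 1:
                warnings.warn(
                    f"stratum ({m.cohort_name}, {response}) has a single "
                    "sample; assigned to train",
                    stacklevel=2,
                )
                train_ids.extend(ids)
                continue
            n_test = max(1, int(np.floor(n * test_fraction)))
            perm = rng.permutation(n)
            test_ids.extend(ids[i] for i in perm[:n_test])
            train_ids.extend(ids[i] for i in perm[n_test:])
        # keep original sample order within each part
        order = {s: i for i, s in enumerate(m.sample_ids)}
        train_parts.append(m.subset_samples(sorted(train_ids, key=order.get)))
        test_parts.append(m.subset_samples(sorted(test_ids, key=order.get)))
    return SplitDataset(
        train=MultiCohortDataset(train_parts),
        test=MultiCohortDataset(test_parts),
        test_fraction=test_fraction,
        seed=seed,
    )
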