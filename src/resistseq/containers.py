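"""Core data containers: expression matrices with sample labels.

TPM matrices are stored as pandas DataFrames (rows = gene IDs, columns =
sample IDs) next to a sample-annotation frame with ``cohort`` and
``response`` columns. ``response`` is binary: ``"resistant"`` (recurrence
within 6 months of initial platinum-based chemotherapy — the positive
class throughout) or ``"sensitive"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError

RESISTANT = "resistant"
SENSITIVE = "sensitive"
VALID_RESPONSES = frozenset({RESISTANT, SENSITIVE})


@dataclass
class ExpressionMatrix:
    """A genes x samples TPM matrix with per-sample cohort and response labels.

    Parameters
    ----------
    tpm
        Non-negative TPM values; index = gene IDs, columns = sample IDs.
    samples
        Annotation frame indexed by sample ID with columns ``cohort`` and
        ``response``; must cover exactly the columns of ``tpm``.
    """

    tpm: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.tpm.index.has_duplicates:
            dup = self.tpm.index[self.tpm.index.duplicated()][0]
            raise DataError(f"duplicated gene ID: {dup!r}")
        if self.tpm.columns.has_duplicates:
            dup = self.tpm.columns[self.tpm.columns.duplicated()][0]
            raise DataError(f"duplicated sample ID: {dup!r}")
        values = self.tpm.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise DataError("non-numeric TPM values")
        if values.size and not np.all(np.isfinite(values)):
            g, s = np.argwhere(~np.isfinite(values))[0]
            raise DataError(
                f"non-finite TPM for gene {self.tpm.index[g]!r} "
                f"sample {self.tpm.columns[s]!r}"
            )
        if values.size and (values < 0).any():
            g, s = np.argwhere(values < 0)[0]
            raise DataError(
                f"negative TPM for gene {self.tpm.index[g]!r} "
                f"sample {self.tpm.columns[s]!r}"
            )
        missing = self.tpm.columns.difference(self.samples.index)
        if len(missing):
            raise DataError(f"sample missing annotation: {missing[0]!r}")
        self.samples = self.samples.loc[self.tpm.columns]
        bad = set(self.samples["response"]) - VALID_RESPONSES
        if bad:
            raise DataError(
                f"invalid response label {sorted(bad)[0]!r}; "
                f"expected one of {sorted(VALID_RESPONSES)}"
            )

    # -- basic accessors -------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.tpm.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.tpm.columns)

    @property
    def n_genes(self) -> int:
        return self.tpm.shape[0]

    @property
    def n_samples(self) -> int:
        return self.tpm.shape[1]

    @property
    def cohort_name(self) -> str:
        """Cohort of the samples; raises if the matrix mixes cohorts."""
        names = self.samples["cohort"].unique()
        if len(names) != 1:
            raise DataError(f"matrix spans multiple cohorts: {sorted(names)}")
        return str(names[0])

    @property
    def response(self) -> pd.Series:
        return self.samples["response"]

    def labels(self) -> np.ndarray:
        """Binary label vector; resistant = 1."""
        return (self.samples["response"] == RESISTANT).to_numpy(dtype=int)

    def log2_tpm(self) -> pd.DataFrame:
        """log2(TPM + 1), the working scale for tests and models."""
        return np.log2(self.tpm + 1.0)

    def class_counts(self) -> tuple[int, int]:
        """(n_resistant, n_sensitive)."""
        y = self.labels()
        return int(y.sum()), int(len(y) - y.sum())

    # -- subsetting ------------------------------------------------------
    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        ids = list(sample_ids)
        return ExpressionMatrix(self.tpm[ids], self.samples.loc[ids].copy())

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        ids = list(gene_ids)
        missing = [g for g in ids if g not in self.tpm.index]
        if missing:
            raise DataError(f"gene not present in matrix: {missing[0]!r}")
        return ExpressionMatrix(self.tpm.loc[ids], self.samples.copy())

    def split_by_response(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(resistant TPM frame, sensitive TPM frame)."""
        is_res = (self.samples["response"] == RESISTANT).to_numpy()
        return self.tpm.loc[:, is_res], self.tpm.loc[:, ~is_res]


@dataclass
class MultiCohortDataset:
    """An ordered collection of cohort matrices sharing one gene-ID vector."""

    cohorts: list[ExpressionMatrix] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.cohorts:
            raise DataError("dataset has no cohorts")
        ref = self.cohorts[0].gene_ids
        for m in self.cohorts[1:]:
            if m.gene_ids != ref:
                raise DataError("cohort matrices disagree on gene IDs or order")

    @property
    def gene_ids(self) -> list[str]:
        return self.cohorts[0].gene_ids

    @property
    def cohort_names(self) -> list[str]:
        return [m.cohort_name for m in self.cohorts]

    def cohort(self, name: str) -> ExpressionMatrix:
        for m in self.cohorts:
            if m.cohort_name == name:
                return m
        raise DataError(f"unknown cohort: {name!r}")

    def subset_genes(self, gene_ids: Sequence[str]) -> "MultiCohortDataset":
        return MultiCohortDataset([m.subset_genes(gene_ids) for m in self.cohorts])

    def n_samples(self) -> int:
        return sum(m.n_samples for m in self.cohorts)


@dataclass
class SplitDataset:
    """Disjoint train/test partition of a multi-cohort dataset."""

    train: MultiCohortDataset
    test: MultiCohortDataset
    test_fraction: float
    seed: int


def write_dataset(ds: MultiCohortDataset, outdir: str | Path) -> None:
    """Write one TSV per cohort plus a sample-annotation TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    annot = []
    for m in ds.cohorts:
        name = m.cohort_name
        frame = m.tpm.copy()
        frame.index.name = "gene_id"
        frame.to_csv(outdir / f"{name}.tsv", sep="\t")
        a = m.samples.copy()
        a.index.name = "sample_id"
        annot.append(a.reset_index())
    pd.concat(annot, ignore_index=True).to_csv(
        outdir / "annotation.tsv", sep="\t", index=False
    )
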