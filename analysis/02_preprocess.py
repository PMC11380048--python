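"""Merge the cohort matrices, drop lowly expressed genes, split 2:1.

Reads results/data/ (written by 01_simulate.py), keeps genes with
TPM >= 1 in >= 20% of pooled samples, splits each (cohort, class)
stratum 2:1 into train and test, and writes both halves under
results/split/.
"""

from pathlib import Path

from resistseq.containers import write_dataset
from resistseq.preprocess import (
    filter_low_expression,
    load_expression,
    merge_cohorts,
    stratified_split,
)

DATA = Path("scratch/analysis/data")
OUT = Path("scratch/analysis/split")
SEED = 12


def main() -> None:
    annot = DATA / "annotation.tsv"
    matrices = [
        load_expression(p, annot)
        for p in sorted(DATA.glob("*.tsv"))
        if p.name != "annotation.tsv"
    ]
    ds = merge_cohorts(matrices)
    n_before = len(ds.gene_ids)
    ds = filter_low_expression(ds, min_tpm=1.0, min_fraction=0.2)
    print(f"low-expression filter kept {len(ds.gene_ids)} of {n_before} genes")

    split = stratified_split(ds, test_fraction=1 / 3, seed=SEED)
    write_dataset(split.train, OUT / "train")
    write_dataset(split.test, OUT / "test")
    for part, name in ((split.train, "train"), (split.test, "test")):
        counts = {m.cohort_name: m.class_counts() for m in part.cohorts}
        print(f"{name}: {counts}")


if __name__ == "__main__":
    main()
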