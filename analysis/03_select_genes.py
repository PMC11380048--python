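"""Discover the gene panel on the training split and check it against
the planted ground truth.

Tier 1: per-gene pooled t-tests in each cohort, intersected across
cohorts. Tier 2: 100 balanced bagging trials per cohort with per-gene
Mann-Whitney tests, keeping genes significant in more than 80 trials.
Writes the full panel (with bagging records) to scratch/analysis/
and a compact per-gene summary table to results/panel_summary.tsv.
"""

import json
from pathlib import Path

from resistseq.preprocess import load_expression, merge_cohorts
from resistseq.selection import select_panel
from resistseq.simulate import GroundTruth

SPLIT = Path("scratch/analysis/split")
OUT = Path("scratch/analysis/panel.json")
SEED = 13


def load_train():
    annot = SPLIT / "train" / "annotation.tsv"
    return merge_cohorts(
        [
            load_expression(p, annot)
            for p in sorted((SPLIT / "train").glob("*.tsv"))
            if p.name != "annotation.tsv"
        ]
    )


def main() -> None:
    train = load_train()
    panel, records = select_panel(train, seed=SEED)
    OUT.parent.mkdir(parents=True, exist_ok=True)
    panel.to_json(OUT, records=records)

    summary = Path("results/panel_summary.tsv")
    summary.parent.mkdir(exist_ok=True)
    with summary.open("w") as fh:
        fh.write("gene_id\ttier\tcohort\tbagging_count\n")
        for g in panel.tier1:
            fh.write(f"{g}\ttier1\tall\t\n")
        for cohort, genes in panel.tier2.items():
            for g in genes:
                fh.write(f"{g}\ttier2\t{cohort}\t{records[cohort].counts[g]}\n")

    truth = GroundTruth.from_json(Path("scratch/analysis/data/ground_truth.json"))
    shared = set(truth.shared_genes)
    t1 = set(panel.tier1)
    print(f"tier1: {len(panel.tier1)} genes; "
          f"recovered {len(t1 & shared)}/{len(shared)} planted shared genes, "
          f"{len(t1 - shared)} others")
    for cohort, genes in panel.tier2.items():
        planted = set(truth.specific_genes[cohort])
        got = set(genes)
        print(f"tier2[{cohort}]: {len(genes)} genes; "
              f"recovered {len(got & planted)}/{len(planted)} planted")
    print(f"combined panel: {len(panel.combined)} genes -> {OUT}")


if __name__ == "__main__":
    main()
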