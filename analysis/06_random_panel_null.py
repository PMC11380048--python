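"""Compare the discovered panel against random panels of the same size.

Draws 10 random gene panels from the filtered pool, trains a reduced
ensemble on each, and scores the SNUH-like test split. The add-one
empirical p-value says how often a random panel matches the discovered
panel's AUC. Appends the comparison to results/report.json.
"""

import importlib
import json
from pathlib import Path

from resistseq.containers import SplitDataset
from resistseq.ensemble import Ensemble, tiny_grid
from resistseq.evaluation import random_panel_null, roc_auc

REPORT = Path("results/report.json")
SEED = 15

mod03 = importlib.import_module("03_select_genes")
mod05 = importlib.import_module("05_evaluate")


def main() -> None:
    train, test = mod03.load_train(), mod05.load_test()
    split = SplitDataset(train=train, test=test, test_fraction=1 / 3, seed=0)
    ens = Ensemble.load("scratch/analysis/model")

    sel_test = test.cohort("SNUH-like")
    observed = roc_auc(ens.predict_proba(sel_test), sel_test.labels())
    comparison = random_panel_null(
        split,
        observed_auc=observed,
        panel_size=len(ens.panel.combined),
        n_draws=10,
        grid=tiny_grid(),
        k=5,
        seed=SEED,
        primary_cohort="TCGA-like",
        selection_cohort="SNUH-like",
    )

    report = json.loads(REPORT.read_text())
    report["random_panel_null"] = {
        "observed_auc": comparison.observed_auc,
        "null_aucs": comparison.null_aucs,
        "empirical_p": comparison.empirical_p,
        "panel_size": comparison.panel_size,
        "n_draws": comparison.n_draws,
    }
    REPORT.write_text(json.dumps(report, indent=2))
    print(f"observed AUC {comparison.observed_auc:.3f} vs "
          f"null mean {sum(comparison.null_aucs)/len(comparison.null_aucs):.3f} "
          f"(max {max(comparison.null_aucs):.3f}); "
          f"empirical p = {comparison.empirical_p:.3f}")


if __name__ == "__main__":
    main()
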