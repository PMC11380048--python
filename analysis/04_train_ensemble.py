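"""Train the fold-wise deep ensemble with cross-cohort model selection.

The TCGA-like training samples are split into five class-stratified
folds; per fold, each hyperparameter combination of the 12-entry grid is
trained (Adam, binary cross-entropy) and the model with the best ROC AUC
on the SNUH-like training data is kept. The five winners' averaged
output is the ensemble score. Writes the model bundle to
scratch/analysis/model/ and a member summary to results/model_summary.json.
"""

from pathlib import Path

from resistseq.ensemble import small_grid, train_ensemble
from resistseq.selection import GenePanel

import importlib

load_train = importlib.import_module("03_select_genes").load_train

OUT = Path("scratch/analysis/model")
SEED = 14


def main() -> None:
    train = load_train()
    panel = GenePanel.from_json("scratch/analysis/panel.json")
    ens = train_ensemble(
        train.cohort("TCGA-like"),
        train.cohort("SNUH-like"),
        panel,
        grid=small_grid(),
        k=5,
        seed=SEED,
    )
    ens.save(OUT)
    import json

    summary = [
        {
            "fold": m.fold_index,
            "grid_index": m.grid_index,
            "learning_rate": m.hyperparams.learning_rate,
            "n_hidden_layers": m.hyperparams.n_hidden_layers,
            "hidden_units": m.hyperparams.hidden_units,
            "selection_auc": m.selection_score,
        }
        for m in ens.members
    ]
    Path("results").mkdir(exist_ok=True)
    Path("results/model_summary.json").write_text(json.dumps(summary, indent=2))
    print(f"trained {len(ens.members)} members on a {len(panel.combined)}-gene panel")
    for m in ens.members:
        print(
            f"  fold {m.fold_index}: grid entry {m.grid_index} "
            f"(lr={m.hyperparams.learning_rate}, layers={m.hyperparams.n_hidden_layers}, "
            f"units={m.hyperparams.hidden_units}), selection AUC {m.selection_score:.3f}"
        )


if __name__ == "__main__":
    main()
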