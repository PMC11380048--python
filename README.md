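# resistseq

Cross-cohort gene-panel discovery and deep-ensemble prediction of
platinum chemoresistance in high-grade serous ovarian carcinoma (HGSOC),
from bulk RNA-seq TPM matrices.

Platinum-based chemotherapy fails early (recurrence within 6 months) in
a substantial fraction of HGSOC patients, and no single cohort is large
enough to train a reliable transcriptomic predictor. The workflow
implemented here compensates by combining several cohorts with different
ancestry and batch structure:

1. **Preprocessing** — per-cohort TPM matrices (Ensembl gene IDs) are
   merged on the intersection of their gene sets, lowly expressed genes
   are removed (TPM ≥ 1 in ≥ 20% of pooled samples), and every
   (cohort, class) stratum is split 2:1 into training and testing.
2. **Two-tier gene selection** (training data only)
   - *Tier 1*: per gene and cohort, a pooled-variance Student's t-test on
     log2(TPM+1) between chemo-resistant and chemo-sensitive samples;
     genes with p < .05 in **every** cohort form the cross-cohort set.
   - *Tier 2*: per cohort, 100 balanced bagging trials; each trial draws
     m samples per class with replacement (m = minority-class size) and
     applies a two-sided Mann–Whitney U-test per gene. Genes significant
     (p < .05) in more than 80 of the 100 trials are kept.
   - The panel is the deduplicated union of tier 1 and the per-cohort
     tier-2 lists.
3. **Fold-wise deep ensemble** — the primary cohort's training samples
   are split into k = 5 class-stratified folds. For every fold, one
   fully connected network (ReLU, dropout, sigmoid output) per
   hyperparameter combination of a 2160-entry grid is trained with Adam
   on binary cross-entropy; the member with the best ROC AUC on a
   *second* cohort's training data is kept. The ensemble score is the
   mean of the k selected members' outputs, each standardizing
   log2(TPM+1) inputs with its own fold statistics.
4. **Sensitivity-prioritized evaluation** — with chemo-resistant as the
   positive class, the decision threshold maximizes specificity subject
   to a sensitivity floor (100% by default). A random-panel null —
   ensembles trained on uniformly drawn gene panels of the same size —
   yields an add-one empirical p-value for the discovered panel's AUC.

Real cohorts of this design are controlled-access, so the package ships
a synthetic-data generator that emulates the study geometry: three
cohorts with class counts 149/59, 24/16 and 14/72, cohort-level batch
shifts on the log2 scale, and planted shared plus cohort-specific
differential genes that serve as recovery ground truth for every stage.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (intermediate matrices go to `scratch/`, small tables to
`results/`):

```bash
python analysis/01_simulate.py       # three cohorts, 2000 genes, 5+5 planted
python analysis/02_preprocess.py
python analysis/03_select_genes.py
python analysis/04_train_ensemble.py
python analysis/05_evaluate.py
python analysis/06_random_panel_null.py
```

Output of the selection and evaluation stages on the shipped seeds:

```
tier1: 5 genes; recovered 5/5 planted shared genes, 0 others
tier2[Patch-like]: 25 genes; recovered 5/5 planted
tier2[SNUH-like]: 11 genes; recovered 5/5 planted
tier2[TCGA-like]: 13 genes; recovered 5/5 planted
combined panel: 40 genes

Patch-like: AUC=1.000 sensitivity=1.000 specificity=0.400 (threshold 0.019, 8R/5S)
SNUH-like:  AUC=1.000 sensitivity=1.000 specificity=1.000 (threshold 0.019, 4R/24S)
TCGA-like:  AUC=0.999 sensitivity=1.000 specificity=0.895 (threshold 0.019, 49R/19S)

observed AUC 1.000 vs null mean 0.467 (max 0.854); empirical p = 0.091
```

Tier 1 recovers exactly the five genes planted as differential in all
cohorts; each cohort's tier 2 recovers its five cohort-specific genes
plus a handful of sample-specific extremes. The ensemble separates the
held-out test samples essentially perfectly at this effect size
(2 log2-fold), and the threshold tuned to 100% sensitivity on the
selection cohort keeps specificity high. Random panels of the same size
average chance-level AUC; with 10 draws the smallest attainable add-one
p is 1/11 ≈ 0.09, which the discovered panel reaches.

The same pipeline runs on real data by replacing the `simulate` block of
the YAML config with a `data` block (per-cohort TSV matrices plus a
sample annotation of cohort and response labels), or via the CLI:

```bash
resistseq run --config pipeline.yaml --out rundir/
resistseq simulate|preprocess|select|train|evaluate --help
```

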