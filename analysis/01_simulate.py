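"""Simulate the three-cohort study design with planted resistance genes.

Generates TPM matrices for cohorts sized like the study's (149/59, 24/16,
14/72 resistant/sensitive), with 5 shared and 5 per-cohort differential
genes at a 2-fold log2 effect, and writes them with the ground truth to
scratch/analysis/data/ (large intermediates stay out of results/).
"""

from pathlib import Path

from resistseq.simulate import default_config, simulate_to_dir

OUT = Path("scratch/analysis/data")
SEED = 11


def main() -> None:
    cfg = default_config(
        seed=SEED,
        n_genes=2000,
        shared_de_genes=5,
        specific_de_genes_per_cohort=5,
        effect_size=2.0,
        noise_sd=1.0,
    )
    simulate_to_dir(cfg, OUT)
    print(f"wrote {len(cfg.cohorts)} cohort matrices ({cfg.n_genes} genes) to {OUT}/")
    for c in cfg.cohorts:
        print(f"  {c.name}: {c.n_resistant} resistant / {c.n_sensitive} sensitive")


if __name__ == "__main__":
    main()
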