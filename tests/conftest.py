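import numpy as np
import pandas as pd
import pytest

from resistseq.containers import RESISTANT, SENSITIVE, ExpressionMatrix


def make_matrix(values, gene_ids=None, cohort="c1", responses=None, sample_ids=None):
    """Build an ExpressionMatrix from a genes x samples array."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    sample_ids = sample_ids or [f"{cohort}-s{i}" for i in range(n_samples)]
    responses = responses or [RESISTANT] * (n_samples // 2) + [SENSITIVE] * (
        n_samples - n_samples // 2
    )
    frame = pd.DataFrame(values, index=gene_ids, columns=sample_ids)
    annot = pd.DataFrame(
        {"cohort": cohort, "response": responses}, index=sample_ids
    )
    return ExpressionMatrix(frame, annot)


def separable_cohort(
    n_per_class=30, n_genes=5, signal_gene=0, gap=6.0, noise=0.3,
    cohort="c1", seed=0,
):
    """A cohort whose classes separate cleanly on one gene (log2 scale)."""
    rng = np.random.default_rng(seed)
    log2 = rng.normal(4.0, noise, size=(n_genes, 2 * n_per_class))
    log2[signal_gene, :n_per_class] += gap
    tpm = np.exp2(np.clip(log2, 0, None)) - 1.0
    responses = [RESISTANT] * n_per_class + [SENSITIVE] * n_per_class
    return make_matrix(tpm, cohort=cohort, responses=responses)


@pytest.fixture
def toy_matrix():
    return make_matrix([[1.0, 2.0, 3.0, 4.0], [5.0, 5.0, 5.0, 5.0]])
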