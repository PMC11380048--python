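"""Statistical tests and the two-tier gene-selection procedure."""

import itertools
from math import comb

import numpy as np
import pytest

from resistseq.containers import MultiCohortDataset
from resistseq.errors import DataError
from resistseq.selection import (
    combine_panel,
    mann_whitney_pvalue,
    student_t_pvalue,
    tier1_select,
    tier2_select,
)
from resistseq.simulate import CohortSpec, SimulationConfig, simulate_multicohort

from conftest import make_matrix, separable_cohort


def exact_mw_pvalue(x, y):
    """Brute-force two-sided Mann-Whitney p by enumerating rank assignments.

    Two-sided p = P(|U - n1*n2/2| >= |u_obs - n1*n2/2|) under the exact
    tie-free null (all C(n1+n2, n1) splits equally likely).
    """
    x, y = list(x), list(y)
    n1, n2 = len(x), len(y)
    u_obs = sum(xi > yj for xi in x for yj in y)
    center = n1 * n2 / 2.0
    pooled = sorted(x + y)
    count = 0
    for combo in itertools.combinations(range(n1 + n2), n1):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(n1 + n2) if i not in combo]
        u = sum(xi > yj for xi in xs for yj in ys)
        if abs(u - center) >= abs(u_obs - center):
            count += 1
    return count / comb(n1 + n2, n1)


class TestStudentT:
    def test_closed_form_df2(self):
        # t = -2.8284, df = 2; F(t) = (1 + t/sqrt(2 + t^2))/2
        assert student_t_pvalue([1, 2], [3, 4]) == pytest.approx(0.10557, abs=1e-4)

    def test_identical_lists_give_p_one(self):
        assert student_t_pvalue([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_zero_variance_is_undefined(self):
        assert np.isnan(student_t_pvalue([0.0, 0.0], [0.0, 0.0]))

    def test_too_few_samples_rejected(self):
        with pytest.raises(DataError):
            student_t_pvalue([1.0], [2.0, 3.0])


class TestMannWhitney:
    def test_full_separation_exact(self):
        # U = 0; 2 of the C(6,3) = 20 splits are at least as extreme
        assert mann_whitney_pvalue([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_no_separation(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert mann_whitney_pvalue(x, x) >= 0.99

    def test_symmetry_in_arguments(self):
        x, y = [1.0, 5.0, 2.5], [3.0, 0.5, 4.0, 6.0]
        assert mann_whitney_pvalue(x, y) == pytest.approx(mann_whitney_pvalue(y, x))

    @pytest.mark.parametrize("n1,n2", [(1, 1), (2, 2), (3, 2), (3, 3), (4, 3), (4, 4)])
    def test_matches_enumeration_oracle(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(25):
            pooled = rng.permutation(np.arange(1.0, n1 + n2 + 1))
            x, y = pooled[:n1], pooled[n1:]
            assert mann_whitney_pvalue(x, y) == pytest.approx(
                exact_mw_pvalue(x, y), abs=1e-12
            )

    def test_asymptotic_branch_reasonable(self):
        # 20+20 values: large-sample approximation, still a valid p-value
        rng = np.random.default_rng(0)
        p = mann_whitney_pvalue(rng.normal(size=20), rng.normal(size=20))
        assert 0.0 < p <= 1.0


def two_cohort_signal(seed=0, effect=4.0, n_genes=30):
    cfg = SimulationConfig(
        cohorts=(CohortSpec("a", 20, 20), CohortSpec("b", 20, 20)),
        n_genes=n_genes,
        shared_de_genes=1,
        specific_de_genes_per_cohort=0,
        effect_size=effect,
        noise_sd=1.0,
        seed=seed,
    )
    return simulate_multicohort(cfg)


class TestTier1:
    def test_recovers_single_strong_shared_gene(self):
        ds, truth = two_cohort_signal(seed=5)
        assert tier1_select(ds, alpha=1e-4) == list(truth.shared_genes)

    def test_alpha_zero_selects_nothing(self):
        ds, _ = two_cohort_signal(seed=1)
        assert tier1_select(ds, alpha=0.0) == []

    def test_single_cohort_equals_its_significant_set(self):
        ds, _ = two_cohort_signal(seed=2)
        single = MultiCohortDataset([ds.cohorts[0]])
        both = tier1_select(ds, alpha=0.05)
        alone = tier1_select(single, alpha=0.05)
        assert set(both) <= set(alone)

    def test_result_subset_of_each_cohort(self):
        ds, _ = two_cohort_signal(seed=3)
        joint = set(tier1_select(ds, alpha=0.05))
        for m in ds.cohorts:
            solo = set(tier1_select(MultiCohortDataset([m]), alpha=0.05))
            assert joint <= solo


class TestTier2:
    def test_constant_gene_never_selected(self):
        m = separable_cohort(n_per_class=15, n_genes=3, seed=0)
        m.tpm.iloc[2] = 7.0  # constant gene
        selected, record = tier2_select(m, seed=1)
        gene = m.gene_ids[2]
        assert record.counts[gene] == 0
        assert gene not in selected

    def test_strict_threshold_at_n_trials(self):
        m = separable_cohort(n_per_class=15, seed=0)
        selected, _ = tier2_select(m, n_trials=50, min_trials=50, seed=1)
        assert selected == []

    def test_strong_gene_selected_across_seeds(self):
        """effect 3, 30/30: the planted gene passes >= 95 trials, 10 seeds."""
        for seed in range(10):
            cfg = SimulationConfig(
                cohorts=(CohortSpec("c", 30, 30),),
                n_genes=40,
                shared_de_genes=1,
                specific_de_genes_per_cohort=0,
                effect_size=3.0,
                noise_sd=1.0,
                seed=seed,
            )
            ds, truth = simulate_multicohort(cfg)
            selected, record = tier2_select(ds.cohorts[0], seed=seed + 100)
            gene = truth.shared_genes[0]
            assert record.counts[gene] >= 95
            assert gene in selected

    def test_same_seed_reproducible(self):
        m = separable_cohort(seed=4)
        s1, r1 = tier2_select(m, seed=9)
        s2, r2 = tier2_select(m, seed=9)
        assert s1 == s2
        assert r1.counts == r2.counts

    def test_seed_robustness_on_strong_signal(self):
        """Selected sets from different bagging seeds overlap >= 90%."""
        cfg = SimulationConfig(
            cohorts=(CohortSpec("c", 30, 30),),
            n_genes=300,
            shared_de_genes=20,
            specific_de_genes_per_cohort=0,
            effect_size=3.0,
            noise_sd=1.0,
            seed=0,
        )
        ds, _ = simulate_multicohort(cfg)
        for pair in range(10):
            s1, _ = tier2_select(ds.cohorts[0], seed=2 * pair)
            s2, _ = tier2_select(ds.cohorts[0], seed=2 * pair + 1)
            union = set(s1) | set(s2)
            inter = set(s1) & set(s2)
            assert union and len(inter) / len(union) >= 0.9

    def test_monotone_recovery_in_effect_size(self):
        """A planted gene's mean bagging count never drops as effect grows."""

        def mean_count(effect):
            counts = []
            for seed in range(10):
                cfg = SimulationConfig(
                    cohorts=(CohortSpec("c", 20, 20),),
                    n_genes=30,
                    shared_de_genes=1,
                    specific_de_genes_per_cohort=0,
                    effect_size=effect,
                    noise_sd=1.0,
                    seed=seed,
                )
                ds, truth = simulate_multicohort(cfg)
                _, record = tier2_select(ds.cohorts[0], seed=seed)
                counts.append(record.counts[truth.shared_genes[0]])
            return np.mean(counts)

        means = [mean_count(e) for e in (0.5, 1.0, 2.0)]
        assert means[0] <= means[1] <= means[2]

    def test_noise_false_positives_are_sample_extremes(self):
        """On pure noise the filter passes only genes extreme in the
        realized sample, and only a small fraction of them."""
        cfg = SimulationConfig(
            cohorts=(CohortSpec("c", 30, 30),),
            n_genes=2000,
            shared_de_genes=0,
            specific_de_genes_per_cohort=0,
            seed=17,
        )
        ds, _ = simulate_multicohort(cfg)
        m = ds.cohorts[0]
        selected, _ = tier2_select(m, seed=23)
        assert len(selected) <= 0.015 * m.n_genes
        res, sen = m.split_by_response()
        for g in selected:
            p_full = mann_whitney_pvalue(
                np.log2(res.loc[g] + 1), np.log2(sen.loc[g] + 1)
            )
            # a selected null gene must at least be significant in the
            # full realized sample at the per-trial alpha
            assert p_full < 0.05

    def test_single_class_cohort_rejected(self):
        m = separable_cohort(n_per_class=10, seed=0)
        only_res = m.subset_samples(
            [s for s, r in m.samples["response"].items() if r == "resistant"]
        )
        with pytest.raises(DataError, match="lacks one class"):
            tier2_select(only_res, seed=0)


class TestCombinePanel:
    def test_union_with_overlap(self):
        panel = combine_panel(["A", "B"], {"c1": ["B", "C"], "c2": ["D"]})
        assert len(panel.combined) == 4

    def test_study_sized_panel(self):
        # 4 tier1 + 4 + 7 + 16 disjoint tier2 genes -> 31-gene panel
        tier1 = [f"t{i}" for i in range(4)]
        tier2 = {
            "TCGA": [f"a{i}" for i in range(4)],
            "SNUH": [f"b{i}" for i in range(7)],
            "Patch": [f"c{i}" for i in range(16)],
        }
        assert len(combine_panel(tier1, tier2).combined) == 31

    def test_all_empty(self):
        assert combine_panel([], {"c1": []}).combined == []

    def test_stable_order_tier1_first(self):
        panel = combine_panel(["z", "a"], {"c1": ["m", "b"], "c2": ["a", "k"]})
        assert panel.combined == ["a", "z", "b", "m", "k"]
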