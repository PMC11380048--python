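"""Fold construction, grid, member training and the averaged ensemble."""

import numpy as np
import pytest

from resistseq.containers import MultiCohortDataset
from resistseq.ensemble import (
    Ensemble,
    HyperParams,
    TrainedModel,
    default_grid,
    grid_from_axes,
    make_folds,
    select_member,
    small_grid,
    train_ensemble,
    train_member,
)
from resistseq.errors import DataError, SelectionError
from resistseq.evaluation import roc_auc
from resistseq.preprocess import stratified_split
from resistseq.simulate import CohortSpec, SimulationConfig, simulate_multicohort

from conftest import separable_cohort

HP = HyperParams(
    learning_rate=0.01,
    n_hidden_layers=1,
    hidden_units=8,
    dropout=0.0,
    batch_size=8,
    epochs=50,
)


class TestGrid:
    def test_default_grid_has_2160_unique_entries(self):
        grid = default_grid()
        assert len(grid) == 2160
        assert len(set(grid)) == 2160

    def test_singleton_axes_give_one_entry(self):
        axes = {
            "learning_rate": (0.01,),
            "n_hidden_layers": (1,),
            "hidden_units": (8,),
            "dropout": (0.0,),
            "batch_size": (8,),
            "epochs": (10,),
        }
        assert len(grid_from_axes(axes)) == 1

    def test_invalid_hyperparams_rejected(self):
        with pytest.raises(DataError):
            HyperParams(0.01, 1, 8, dropout=1.0, batch_size=8, epochs=10)
        with pytest.raises(DataError):
            HyperParams(-0.01, 1, 8, dropout=0.0, batch_size=8, epochs=10)


class TestMakeFolds:
    def test_balanced_exact_division(self):
        m = separable_cohort(n_per_class=10, seed=0)
        y = m.labels()
        for fit, holdout in make_folds(m, k=5, seed=1):
            assert y[holdout].sum() == 2
            assert len(holdout) == 4

    def test_folds_partition_samples(self):
        m = separable_cohort(n_per_class=13, seed=0)
        folds = make_folds(m, k=5, seed=2)
        all_holdout = np.concatenate([h for _, h in folds])
        assert sorted(all_holdout) == list(range(m.n_samples))
        for fit, holdout in folds:
            assert not set(fit) & set(holdout)
            assert len(fit) + len(holdout) == m.n_samples

    def test_determinism(self):
        m = separable_cohort(n_per_class=10, seed=0)
        f1 = make_folds(m, k=5, seed=7)
        f2 = make_folds(m, k=5, seed=7)
        for (a, b), (c, d) in zip(f1, f2):
            assert (a == c).all() and (b == d).all()

    def test_class_smaller_than_k_rejected(self):
        m = separable_cohort(n_per_class=3, seed=0)
        with pytest.raises(DataError, match="fewer than"):
            make_folds(m, k=5, seed=0)


def separable_xy(n=20, seed=0):
    rng = np.random.default_rng(seed)
    y = np.array([1] * (n // 2) + [0] * (n // 2))
    X = rng.normal(0.0, 1.0, size=(n, 2))
    X[:, 0] += 3.0 * (2 * y - 1)  # 3-sd margin on the first feature
    return X, y


class TestTrainMember:
    def test_fits_linearly_separable_toy_set(self):
        X, y = separable_xy()
        net = train_member(X, y, HP, seed=0)
        assert ((net.predict_proba(X) >= 0.5).astype(int) == y).all()

    def test_single_class_rejected(self):
        X, _ = separable_xy()
        with pytest.raises(DataError, match="single class"):
            train_member(X, np.ones(len(X)), HP, seed=0)

    def test_training_is_deterministic(self):
        X, y = separable_xy(seed=3)
        n1 = train_member(X, y, HP, seed=5)
        n2 = train_member(X, y, HP, seed=5)
        assert abs(n1.final_loss - n2.final_loss) < 1e-6


def toy_split(seed=0, n_per_class=30):
    # one strong signal gene plus a single noise gene: cleanly separable
    primary = separable_cohort(
        n_per_class=n_per_class, n_genes=2, cohort="primary", seed=seed
    )
    selection = separable_cohort(
        n_per_class=n_per_class, n_genes=2, cohort="selection", seed=seed + 1
    )
    return primary, selection


def toy_panel(matrix):
    from resistseq.selection import combine_panel

    return combine_panel(matrix.gene_ids, {})


def make_candidate(net_like, grid_index, feature_order, mean, sd):
    return TrainedModel(
        net=net_like,
        hyperparams=HP,
        feature_order=feature_order,
        mean=mean,
        sd=sd,
        grid_index=grid_index,
    )


class TestSelectMember:
    def _candidates(self, primary, n):
        log2 = primary.log2_tpm().to_numpy().T
        mean, sd = log2.mean(axis=0), np.maximum(log2.std(axis=0), 1e-9)
        X = (log2 - mean) / sd
        out = []
        for i in range(n):
            net = train_member(X, primary.labels(), HP, seed=i)
            out.append(make_candidate(net, i, primary.gene_ids, mean, sd))
        return out

    def test_single_candidate_returned(self):
        primary, selection = toy_split()
        cand = self._candidates(primary, 1)
        assert select_member(cand, selection) is cand[0]

    def test_dominant_candidate_wins(self):
        primary, selection = toy_split()
        good = self._candidates(primary, 1)[0]

        class Inverter:
            def predict_proba(self, X):
                return 1.0 - good.net.predict_proba(X)

        bad = make_candidate(
            Inverter(), 1, good.feature_order, good.mean, good.sd
        )
        assert select_member([bad, good], selection) is good

    def test_identical_predictions_break_to_lower_grid_index(self):
        primary, selection = toy_split()
        a = self._candidates(primary, 1)[0]
        twin = make_candidate(a.net, 5, a.feature_order, a.mean, a.sd)
        a.grid_index = 9
        assert select_member([a, twin], selection) is twin

    def test_single_class_selection_labels_rejected(self):
        primary, selection = toy_split()
        cand = self._candidates(primary, 1)
        res_only = selection.subset_samples(
            [s for s, r in selection.samples["response"].items() if r == "resistant"]
        )
        with pytest.raises(SelectionError):
            select_member(cand, res_only)


@pytest.fixture(scope="module")
def trained():
    primary, selection = toy_split(seed=2)
    panel = toy_panel(primary)
    ens = train_ensemble(primary, selection, panel, grid=[HP], k=2, seed=0)
    return ens, primary, selection


class TestEnsemble:
    def test_two_members_with_perfect_selection_auc(self, trained):
        ens, _, _ = trained
        assert len(ens.members) == 2
        for m in ens.members:
            assert m.selection_score == pytest.approx(1.0)

    def test_score_is_member_mean(self, trained):
        ens, primary, _ = trained
        scores = ens.predict_proba(primary)
        member_scores = np.stack([m.predict_proba(primary) for m in ens.members])
        assert np.abs(scores - member_scores.mean(axis=0)).max() < 1e-9

    def test_member_order_permutation_invariance(self, trained):
        ens, primary, _ = trained
        permuted = Ensemble(
            members=list(reversed(ens.members)), panel=ens.panel,
            threshold=ens.threshold,
        )
        assert np.allclose(
            ens.predict_proba(primary), permuted.predict_proba(primary), atol=1e-12
        )

    def test_duplicated_sample_gets_identical_score(self, trained):
        from conftest import make_matrix

        ens, primary, _ = trained
        scores = ens.predict_proba(primary)
        col = primary.tpm.iloc[:, 0].to_numpy()
        dup = make_matrix(
            np.column_stack([col, col]),
            gene_ids=primary.gene_ids,
            responses=["resistant", "sensitive"],
        )
        dup_scores = ens.predict_proba(dup)
        assert dup_scores[0] == pytest.approx(dup_scores[1], abs=1e-12)
        assert dup_scores[0] == pytest.approx(scores[0], abs=1e-12)

    def test_missing_panel_gene_named(self, trained):
        ens, primary, _ = trained
        reduced = primary.subset_genes(primary.gene_ids[1:])
        with pytest.raises(DataError, match=primary.gene_ids[0]):
            ens.predict_proba(reduced)

    def test_embedding_shape_and_identical_rows(self, trained):
        ens, primary, _ = trained
        emb = ens.last_layer_embedding(primary)
        expected_d = sum(m.hyperparams.hidden_units for m in ens.members)
        assert emb.shape == (primary.n_samples, expected_d)
        dup = primary.subset_samples([primary.sample_ids[0]] * 1)
        # two copies of one sample embed identically
        row = ens.last_layer_embedding(dup)
        assert np.allclose(row, emb[0])

    def test_serialization_round_trip(self, trained, tmp_path):
        ens, primary, _ = trained
        ens.save(tmp_path / "model")
        loaded = Ensemble.load(tmp_path / "model")
        assert np.allclose(
            ens.predict_proba(primary), loaded.predict_proba(primary), atol=1e-12
        )
        assert loaded.panel.combined == ens.panel.combined

    def test_full_retrain_reproducibility(self):
        primary, selection = toy_split(seed=6)
        panel = toy_panel(primary)
        e1 = train_ensemble(primary, selection, panel, grid=[HP], k=2, seed=4)
        e2 = train_ensemble(primary, selection, panel, grid=[HP], k=2, seed=4)
        assert np.abs(
            e1.predict_proba(selection) - e2.predict_proba(selection)
        ).max() < 1e-6


class TestLearningSanity:
    def test_signal_gives_high_heldout_auc(self):
        """effect >= 2, 60/60 per cohort: held-out AUC >= 0.9 (5 seeds)."""
        for seed in range(5):
            cfg = SimulationConfig(
                cohorts=(CohortSpec("p", 60, 60), CohortSpec("s", 60, 60)),
                n_genes=50,
                shared_de_genes=5,
                specific_de_genes_per_cohort=0,
                effect_size=2.0,
                noise_sd=1.0,
                seed=seed,
            )
            ds, truth = simulate_multicohort(cfg)
            split = stratified_split(ds, seed=seed)
            from resistseq.selection import combine_panel

            panel = combine_panel(list(truth.shared_genes), {})
            ens = train_ensemble(
                split.train.cohort("p"),
                split.train.cohort("s"),
                panel,
                grid=small_grid(),
                k=5,
                seed=seed,
            )
            test = split.test.cohort("s")
            auc = roc_auc(ens.predict_proba(test), test.labels())
            assert auc >= 0.9, f"seed {seed}: AUC {auc:.3f}"
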