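"""Losses, metrics, splits, cross-validation, grid search, transfer fitting."""

import numpy as np
import pytest

from biodrop import (TrainConfig, auc_score, aux_loss, balanced_accuracy,
                     cross_validate, evaluate, fit_transfer, grid_search,
                     primary_loss, simulate_linear_transfer_latents,
                     split_train_test, summarize_cv, total_loss, train_model)
from biodrop.simulate import SimConfig


class TestLosses:
    def test_primary_loss_perfect_is_zero(self):
        y = np.array([0, 1, 1])
        P = np.eye(2)[y]
        assert primary_loss(y, P) == pytest.approx(0.0, abs=1e-9)

    def test_primary_loss_uniform_is_log2(self):
        y = np.array([0, 1])
        P = np.full((2, 2), 0.5)
        assert primary_loss(y, P) == pytest.approx(np.log(2))

    def test_primary_loss_single_sample(self):
        assert primary_loss(np.array([0]), np.array([[0.8, 0.2]]),
                            classes=[0, 1]) == pytest.approx(-np.log(0.8))

    def test_primary_loss_rejects_unknown_label(self):
        with pytest.raises(ValueError, match="outside"):
            primary_loss(np.array([2]), np.array([[0.5, 0.5]]), classes=[0, 1])

    def test_aux_loss_entrywise_mean(self):
        assert aux_loss([[1.0, 1.0]], [[0.0, 0.0]]) == 1.0
        with pytest.raises(ValueError):
            aux_loss(np.ones((2, 2)), np.ones((2, 3)))

    def test_total_loss(self):
        assert total_loss(0.5, 0.25, 1.0) == 0.75
        assert total_loss(0.0, 0.3, 2.0) == pytest.approx(0.6)
        assert total_loss(0.5, 0.25, 0.0) == 0.5
        with pytest.raises(ValueError):
            total_loss(0.1, 0.1, -1.0)


class TestSplit:
    def test_stratified_counts(self):
        ids = [f"s{i}" for i in range(100)]
        y = np.array([0] * 50 + [1] * 50)
        tr, te = split_train_test(ids, y, ratio=0.8, seed=0)
        assert len(tr) == 80 and len(te) == 20
        lab = dict(zip(ids, y))
        assert sum(lab[s] for s in tr) == 40
        assert sum(lab[s] for s in te) == 10

    def test_deterministic(self):
        ids = [f"s{i}" for i in range(40)]
        y = np.array([0, 1] * 20)
        assert split_train_test(ids, y, seed=5) == split_train_test(ids, y, seed=5)

    def test_guards(self):
        ids = [f"s{i}" for i in range(20)]
        y = np.array([0, 1] * 10)
        with pytest.raises(ValueError):
            split_train_test(ids, y, ratio=1.0)
        with pytest.raises(ValueError, match="fewer than 2"):
            split_train_test(ids, np.array([0] * 19 + [1]))


class TestBalancedAccuracy:
    def test_confusion_arithmetic_example(self):
        # TP=3, FN=1, TN=2, FP=2 with class 1 positive
        y_true = [1, 1, 1, 1, 0, 0, 0, 0]
        y_pred = [1, 1, 1, 0, 0, 0, 1, 1]
        assert balanced_accuracy(y_true, y_pred) == pytest.approx(0.625)

    def test_perfect_and_constant(self):
        y = np.array([0, 1, 0, 1])
        assert balanced_accuracy(y, y) == 1.0
        assert balanced_accuracy(y, np.zeros(4)) == 0.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            balanced_accuracy([], [])

    def test_matches_confusion_matrix_oracle_on_random_vectors(self):
        """Mean per-class recall computed by hand on random multiclass labels."""
        rng = np.random.default_rng(0)
        for _ in range(300):
            n_classes = rng.integers(2, 5)
            n = rng.integers(n_classes * 2, 60)
            y_true = rng.integers(0, n_classes, n)
            while len(np.unique(y_true)) < n_classes:
                y_true = rng.integers(0, n_classes, n)
            y_pred = rng.integers(0, n_classes, n)
            recalls = [np.mean(y_pred[y_true == c] == c)
                       for c in range(n_classes)]
            assert balanced_accuracy(y_true, y_pred) == pytest.approx(
                np.mean(recalls), abs=1e-12)


class TestAucScore:
    def test_perfect_separation(self):
        assert auc_score([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_constant_scores_are_half(self):
        assert auc_score([0, 1, 0, 1], [0.3, 0.3, 0.3, 0.3]) == 0.5

    def test_four_point_rank_counting(self):
        # one of four positive-negative pairs is discordant (0.35 < 0.4)
        assert auc_score([0, 0, 1, 1], [0.1, 0.4, 0.35, 0.8]) == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_score([1, 1], [0.2, 0.4])

    def test_matches_pair_counting_oracle(self):
        """O(n^2) concordant-pair oracle with half credit for ties."""
        rng = np.random.default_rng(1)
        for _ in range(100):
            n = rng.integers(4, 30)
            y = rng.integers(0, 2, n)
            while len(np.unique(y)) < 2:
                y = rng.integers(0, 2, n)
            s = np.round(rng.random(n), 2)  # induce ties
            pos, neg = s[y == 1], s[y == 0]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            want = wins / (len(pos) * len(neg))
            assert auc_score(y, s) == pytest.approx(want, abs=1e-9)

    def test_macro_ovr_for_multiclass(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 3, 30)
        P = rng.dirichlet(np.ones(3), size=30)
        from sklearn.metrics import roc_auc_score
        assert auc_score(y, P) == pytest.approx(
            roc_auc_score(y, P, multi_class="ovr", average="macro"))


class TestEvaluate:
    def test_confusion_sums_and_fields(self):
        y_true = [0, 0, 1, 1, 1]
        y_pred = [0, 1, 1, 1, 0]
        P = np.eye(2)[y_pred]
        rep = evaluate(y_true, y_pred, P, classes=[0, 1], fold=2)
        assert rep.confusion.sum() == 5
        assert rep.fold == 2
        assert rep.sensitivity[1] == pytest.approx(2 / 3)
        assert rep.specificity[1] == pytest.approx(1 / 2)
        assert 0.0 <= rep.bacc <= 1.0


@pytest.fixture(scope="module")
def data(small_scaled):
    d = small_scaled
    tr = d["train"]
    return (d["Xa"][tr], d["Xb"][tr], d["y"][tr], (d["mask_a"], d["mask_b"]))


class TestCrossValidateAndGrid:
    def test_fold_counts(self, data, quick_config):
        Xa, Xb, y, masks = data
        reports = cross_validate(Xa, Xb, y, masks, quick_config, k=4)
        assert len(reports) == 4
        assert sum(r.confusion.sum() for r in reports) == len(y)

    def test_k_exceeding_class_count_rejected(self, data, quick_config):
        Xa, Xb, y, masks = data
        with pytest.raises(ValueError, match="smallest class"):
            cross_validate(Xa[:8], Xb[:8], y[:8], masks, quick_config, k=7)

    def test_summary_of_identical_folds(self):
        from biodrop.training import EvalReport
        reps = [EvalReport(bacc=0.7, auc=0.8, sensitivity={}, specificity={},
                           confusion=np.zeros((2, 2)), fold=i)
                for i in range(3)]
        s = summarize_cv(reps)
        assert s["bacc_mean"] == pytest.approx(0.7)
        assert s["bacc_sd"] == pytest.approx(0.0)

    def test_grid_enumerates_all_candidates(self, data, quick_config):
        Xa, Xb, y, masks = data
        best, table = grid_search(
            {"lambda_aux": [0.5, 1.0], "dropout_rate": [0.0, 0.2]},
            Xa, Xb, y, masks, base_config=quick_config, k=3)
        assert len(table) == 4
        assert isinstance(best, TrainConfig)

    def test_grid_tie_break_prefers_smaller_latent_dim(self, data, quick_config):
        # latent_dim is ignored when masks are supplied, so both candidates
        # produce identical CV results and the tie-break decides
        Xa, Xb, y, masks = data
        best, table = grid_search({"latent_dim": [128, 64]}, Xa, Xb, y, masks,
                                  base_config=quick_config, k=3)
        assert best.latent_dim == 64

    def test_empty_grid_rejected(self, data, quick_config):
        with pytest.raises(ValueError, match="empty"):
            grid_search({}, *data[:3], data[3], base_config=quick_config)


class TestTrainModel:
    def test_separable_data_reaches_perfect_train_bacc(self):
        rng = np.random.default_rng(0)
        K = 200
        Xa = rng.normal(size=(K, 6))
        Xb = rng.normal(size=(K, 4))
        y = (Xa[:, 0] + Xa[:, 1] > 0).astype(int)
        masks = (np.ones((6, 5)), np.ones((4, 5)))
        cfg = TrainConfig(seed=0, max_epochs=200, patience=199,
                          val_fraction=0.0, dropout_rate=0.0,
                          learning_rate=3e-3)
        est, log = train_model(Xa, Xb, y, masks, cfg)
        X = np.concatenate([Xa, Xb], axis=1)
        assert balanced_accuracy(y, est.predict(X)) == 1.0
        assert {"epoch", "train_total"} <= set(log.columns)

    def test_higher_lambda_does_not_increase_final_aux_loss(self, small_scaled):
        d = small_scaled
        tr = d["train"]
        masks = (d["mask_a"], d["mask_b"])
        finals = {}
        for lam in (1.0, 10.0):
            vals = []
            for seed in (0, 1, 2):
                cfg = TrainConfig(seed=seed, lambda_aux=lam, max_epochs=25,
                                  patience=6)
                _, log = train_model(d["Xa"][tr], d["Xb"][tr], d["y"][tr],
                                     masks, cfg)
                vals.append(log["train_aux"].iloc[-1])
            finals[lam] = np.mean(vals)
        assert finals[10.0] <= finals[1.0] + 1e-9


class TestFitTransfer:
    def test_recovers_exact_linear_relation(self):
        cfg = SimConfig(seed=11, n_samples=300, n_snps=40, n_tfs=10,
                        n_genes=15, transfer_alpha=2.0, transfer_beta=0.5)
        Ca, Cb, truth = simulate_linear_transfer_latents(cfg)
        a, b = fit_transfer(Ca, Cb, method="adam")
        assert a == pytest.approx(truth["alpha"], rel=0.01)
        assert b == pytest.approx(truth["beta"], abs=0.01)
        a2, b2 = fit_transfer(Ca, Cb, method="lstsq")
        assert a2 == pytest.approx(truth["alpha"], rel=1e-6)
        assert b2 == pytest.approx(truth["beta"], abs=1e-6)

    def test_shape_guard(self):
        with pytest.raises(ValueError):
            fit_transfer(np.ones((2, 2)), np.ones((3, 2)))


class TestTrainConfig:
    def test_guards(self):
        with pytest.raises(ValueError):
            TrainConfig(lambda_aux=-1.0)
        with pytest.raises(ValueError):
            TrainConfig(max_epochs=0)
        with pytest.raises(ValueError):
            TrainConfig(patience=100, max_epochs=100)
        with pytest.raises(ValueError):
            TrainConfig(normalization="robust")
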