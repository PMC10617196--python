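"""Integrated gradients: exactness, completeness, node and edge importance."""

import math

import numpy as np
import pytest

from biodrop import (integrated_gradients, link_importance, node_importance,
                     top_link_genes)
from biodrop.attribution import completeness_gap, edge_score
from biodrop.masks import BipartiteMask
from biodrop.model import BioDropClassifier
from biodrop.nn import MaskedDualNet

from conftest import make_tiny_net


def linear_grad_fn(w):
    def fn(X):
        return X @ w, np.tile(w, (X.shape[0], 1))
    return fn


class TestIntegratedGradients:
    def test_linear_model_exact_for_any_step_count(self):
        rng = np.random.default_rng(0)
        w = rng.normal(size=4)
        x = rng.normal(size=(3, 4))
        for n_steps in (1, 3, 50):
            attr = integrated_gradients(linear_grad_fn(w), x, n_steps=n_steps)
            assert np.allclose(attr, x * w, atol=1e-12)

    def test_input_equal_to_baseline_gives_zero(self):
        w = np.array([1.0, -2.0])
        x = np.array([[0.3, 0.7]])
        attr = integrated_gradients(linear_grad_fn(w), x, baseline=x[0],
                                    n_steps=10)
        assert np.allclose(attr, 0.0)

    def test_step_count_guard(self):
        with pytest.raises(ValueError):
            integrated_gradients(linear_grad_fn(np.ones(2)), np.ones((1, 2)),
                                 n_steps=0)

    def test_completeness_on_small_network(self):
        """Sum of attributions approximates F(x) - F(baseline) at 200 steps."""
        net = make_tiny_net(seed=9, la=5, nb=4, p=4, hidden=(6,))
        rng = np.random.default_rng(1)
        Xa, Xb = rng.normal(size=(6, 5)), rng.normal(size=(6, 4))
        X = np.concatenate([Xa, Xb], axis=1)

        def grad_fn(batch):
            F, dXa, dXb = net.logit_input_gradients(batch[:, :5], batch[:, 5:], 1)
            return F, np.concatenate([dXa, dXb], axis=1)

        total, delta = completeness_gap(grad_fn, X, n_steps=200)
        assert np.all(np.abs(total - delta) <= 1e-3 * np.abs(delta) + 1e-6)


@pytest.fixture(scope="module")
def attribution_model():
    """A small fitted model with identifier-carrying masks."""
    rng = np.random.default_rng(0)
    la, nb, p = 6, 4, 5
    ma = (rng.random((la, p)) < 0.6).astype(float)
    mb = (rng.random((nb, p)) < 0.6).astype(float)
    ma[0], mb[0] = 1.0, 1.0
    mask_a = BipartiteMask(ma, [f"rs{i}" for i in range(la)],
                           [f"G{j}" for j in range(p)])
    mask_b = BipartiteMask(mb, [f"TF{i}" for i in range(nb)],
                           [f"G{j}" for j in range(p)])
    K = 80
    Xa = rng.normal(size=(K, la))
    Xb = rng.normal(size=(K, nb))
    y = (Xa[:, 0] > 0).astype(int)
    est = BioDropClassifier(mask_a=mask_a, mask_b=mask_b, max_epochs=30,
                            patience=5, random_state=1)
    est.fit(np.concatenate([Xa, Xb], axis=1), y)
    return est, Xa, Xb


class TestNodeImportance:
    def test_table_schema_and_ranks(self, attribution_model):
        est, Xa, Xb = attribution_model
        df = node_importance(est, Xa, Xb, 1, n_steps=20)
        assert set(df["layer"]) == {"input_a", "input_b", "latent"}
        for layer, n in (("input_a", 6), ("input_b", 4), ("latent", 5)):
            sub = df[df["layer"] == layer]
            assert sorted(sub["rank"]) == list(range(1, n + 1))
            # ranks ordered by descending score
            assert (sub.sort_values("rank")["score"].diff().dropna() <= 1e-12).all()

    def test_disconnected_feature_scores_zero(self):
        rng = np.random.default_rng(3)
        ma = np.ones((3, 2))
        ma[2, :] = 0.0  # SNP 2 reaches nothing
        net_est = BioDropClassifier(mask_a=ma, mask_b=np.ones((2, 2)),
                                    max_epochs=10, patience=3, random_state=0)
        Xa = rng.normal(size=(40, 3))
        Xb = rng.normal(size=(40, 2))
        y = (Xa[:, 0] > 0).astype(int)
        net_est.fit(np.concatenate([Xa, Xb], axis=1), y)
        df = node_importance(net_est, Xa, Xb, 1, n_steps=10)
        score = df[(df["layer"] == "input_a") & (df["feature_id"] == "a2")]
        assert float(score["score"].iloc[0]) == 0.0

    def test_duplicate_sample_averaging(self, attribution_model):
        est, Xa, Xb = attribution_model
        one = node_importance(est, Xa[:1], Xb[:1], 1, n_steps=10)
        two = node_importance(est, np.vstack([Xa[0], Xa[0]]),
                              np.vstack([Xb[0], Xb[0]]), 1, n_steps=10)
        assert np.allclose(one["score"], two["score"])

    def test_symmetric_features_get_identical_attributions(self):
        """Two inputs with identical wiring and identical values."""
        net = MaskedDualNet(np.ones((2, 2)), np.ones((2, 2)),
                            hidden_sizes=(3,), n_classes=2, dropout_rate=0.0,
                            rng=np.random.default_rng(0))
        net.params["W1"][1] = net.params["W1"][0]
        x = np.array([[0.7, 0.7]])
        xb = np.array([[0.1, -0.2]])
        F, dXa, _ = net.logit_input_gradients(x, xb, 1)
        assert dXa[0, 0] == pytest.approx(dXa[0, 1], abs=1e-12)


class TestLinkImportance:
    def test_only_permitted_edges_scored(self, attribution_model):
        est, Xa, Xb = attribution_model
        df = link_importance(est, Xa, Xb, 1, n_steps=10)
        n_edges = est.net_.mask_a.sum() + est.net_.mask_b.sum()
        assert len(df) == n_edges
        assert list(df["rank"]) == list(range(1, len(df) + 1))

    def test_zero_weight_edge_scores_zero(self, attribution_model):
        est, Xa, Xb = attribution_model
        i, j = map(int, np.argwhere(est.net_.mask_a == 1)[0])
        old = est.net_.params["W1"][i, j]
        est.net_.params["W1"][i, j] = 0.0
        try:
            s = edge_score(est, Xa[:5], Xb[:5], 1,
                           est.mask_a.input_ids[i], est.mask_a.latent_ids[j],
                           n_steps=10)
            assert s == 0.0
        finally:
            est.net_.params["W1"][i, j] = old

    def test_masked_out_edge_rejected(self, attribution_model):
        est, Xa, Xb = attribution_model
        zeros = np.argwhere(est.net_.mask_a == 0)
        if len(zeros) == 0:
            pytest.skip("mask has no zero entries")
        i, j = map(int, zeros[0])
        with pytest.raises(ValueError, match="not a permitted"):
            edge_score(est, Xa[:5], Xb[:5], 1,
                       est.mask_a.input_ids[i], est.mask_a.latent_ids[j],
                       n_steps=5)

    def test_single_edge_linear_chain_closed_form(self):
        """x -> (w) -> logit with identity activations: gate attribution
        equals the exact path value."""
        ma = np.ones((1, 1))
        mb = np.ones((1, 1))
        net = MaskedDualNet(ma, mb, hidden_sizes=(), n_classes=2,
                            dropout_rate=0.0, activation="identity",
                            rng=np.random.default_rng(0))
        net.params["W1"] = np.array([[1.5]])
        net.params["b1"] = np.array([0.0])
        net.params["W2"] = np.array([[0.0]])
        net.params["b2"] = np.array([0.0])
        net.params["V0"] = np.array([[0.0, 2.0], [0.0, 0.0]])
        net.params["c0"] = np.array([0.0, 0.0])
        x = np.array([[0.8]])
        xb = np.array([[0.4]])
        acc = np.zeros((1, 1, 1))
        n_steps = 7
        for s in range(n_steps):
            t = (s + 0.5) / n_steps
            _, Ga, _ = net.logit_gate_gradients(x, xb, 1, gate=t)
            acc += Ga
        attr = float((acc / n_steps)[0, 0, 0])
        # F(g) = x * w * g * V -> attribution over g in [0,1] is x*w*V
        assert attr == pytest.approx(0.8 * 1.5 * 2.0, abs=1e-12)


class TestTopLinkGenes:
    def _table(self, scores):
        import pandas as pd
        rows = [{"source": f"s{i}", "target": g, "network": "A",
                 "class": 1, "score": s}
                for i, (g, s) in enumerate(scores)]
        return pd.DataFrame(rows)

    def test_ceil_fraction_of_edges(self):
        df = self._table([(f"G{i}", float(10 - i)) for i in range(10)])
        top = top_link_genes(df, fraction=0.1)
        assert list(top["gene"]) == ["G0"]

    def test_tie_break_lexicographic(self):
        df = self._table([("Gb", 1.0), ("Ga", 1.0), ("Gc", 1.0)])
        top = top_link_genes(df, fraction=1 / 3)
        # equal scores: the (source, target) lexicographically smallest edge
        assert list(top["gene"]) == ["Gb"]  # s0 -> Gb is the smallest source

    def test_matches_exhaustive_sort_oracle(self):
        rng = np.random.default_rng(0)
        genes = [f"G{i}" for i in range(5)]
        entries = [(genes[rng.integers(0, 5)], float(np.round(rng.random(), 3)))
                   for _ in range(20)]
        df = self._table(entries)
        frac = 0.25
        top = top_link_genes(df, fraction=frac)
        n_top = math.ceil(frac * len(df))
        ranked = sorted(df.itertuples(), key=lambda r: (-r.score, r.source, r.target))
        want = {}
        for r in ranked[:n_top]:
            want[r.target] = want.get(r.target, 0) + 1
        got = dict(zip(top["gene"], top["n_prioritized_links"]))
        assert got == want

    def test_fraction_guard(self):
        df = self._table([("G0", 1.0)])
        with pytest.raises(ValueError):
            top_link_genes(df, fraction=0.0)
        with pytest.raises(ValueError):
            top_link_genes(df, fraction=1.5)
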