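"""Losses, contrastive views, episodic meta-learning, and the training loop."""

import numpy as np
import pytest

from spectradti.calibration import PredictionHead
from spectradti.model import DTIModel, ModelConfig
from spectradti.nn import Tensor
from spectradti.objectives import (
    ContrastiveBatch,
    LossWeights,
    TrainConfig,
    bce_with_logits,
    composite_loss,
    infonce_loss,
    meta_episode_loss,
    sample_contrastive_views,
    spectral_loss,
    train,
)
from spectradti.spectral import build_distance_cache, build_operator, compute_spectral_basis


def normalized(rng, n, d):
    z = rng.normal(size=(n, d)).astype(np.float32)
    return z / np.linalg.norm(z, axis=1, keepdims=True)


def infonce_reference(A, P, tau, extras=None):
    """Naive double-loop InfoNCE (mean per anchor)."""
    n = len(A)
    total = 0.0
    for i in range(n):
        pos = np.exp(A[i] @ P[i] / tau)
        denom = pos
        for j in range(n):
            if j != i:
                denom += np.exp(A[i] @ A[j] / tau)
        if extras is not None:
            denom += np.exp(A[i] @ extras.T / tau).sum()
        total += -np.log(pos / denom)
    return total / n


class TestInfoNCE:
    def test_uniform_similarities_give_log_n(self):
        # all projections identical: every similarity is 1, N-1 in-batch
        # negatives -> per-anchor loss log(N)
        n, d = 6, 8
        z = np.tile(normalized(np.random.default_rng(0), 1, d), (n, 1))
        batch = ContrastiveBatch(anchors=Tensor(z), positives=Tensor(z), temperature=0.07)
        assert float(infonce_loss(batch).data) == pytest.approx(np.log(n), rel=1e-5)

    def test_hand_value_single_negative(self):
        # pos sim 1, one negative sim 0, tau = 1 -> -log(e / (e + 1))
        A = np.array([[1.0, 0.0], [0.0, 1.0]], dtype=np.float32)
        batch = ContrastiveBatch(anchors=Tensor(A), positives=Tensor(A), temperature=1.0)
        expected = -np.log(np.e / (np.e + 1.0))
        assert float(infonce_loss(batch).data) == pytest.approx(expected, rel=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_double_loop_reference(self, seed):
        rng = np.random.default_rng(seed)
        A = normalized(rng, 7, 16)
        P = normalized(rng, 7, 16)
        E = normalized(rng, 3, 16)
        batch = ContrastiveBatch(
            anchors=Tensor(A), positives=Tensor(P), temperature=0.07,
            extra_negatives=Tensor(E),
        )
        ref = infonce_reference(A.astype(np.float64), P.astype(np.float64), 0.07,
                                E.astype(np.float64))
        assert float(infonce_loss(batch).data) == pytest.approx(ref, rel=1e-5)

    def test_gradient_flows_to_anchors(self):
        rng = np.random.default_rng(3)
        A = Tensor(normalized(rng, 4, 8), requires_grad=True)
        P = Tensor(normalized(rng, 4, 8))
        infonce_loss(ContrastiveBatch(anchors=A, positives=P)).backward()
        assert A.grad is not None and np.abs(A.grad).sum() > 0


class TestCompositeLoss:
    def test_reduces_to_dti_at_zero_weights(self):
        w = LossWeights(beta=0.0, gamma=0.0, eta=0.0)
        out = composite_loss(Tensor(1.7), Tensor(9.0), Tensor(9.0), Tensor(9.0), w)
        assert float(out.data) == pytest.approx(1.7)

    def test_arithmetic_with_default_weights(self):
        w = LossWeights(beta=0.5, gamma=0.3, eta=1e-3)
        out = composite_loss(Tensor(1.0), Tensor(2.0), Tensor(3.0), Tensor(4.0), w)
        assert float(out.data) == pytest.approx(1 + 1 + 0.9 + 0.004)

    def test_eta_scales_only_the_spectral_term(self):
        a = composite_loss(Tensor(1.0), Tensor(0.0), Tensor(0.0), Tensor(4.0),
                           LossWeights(eta=1e-3))
        b = composite_loss(Tensor(1.0), Tensor(0.0), Tensor(0.0), Tensor(4.0),
                           LossWeights(eta=2e-3))
        assert float(b.data) - float(a.data) == pytest.approx(0.004, abs=1e-6)

    def test_non_finite_component_is_named(self):
        with pytest.raises(FloatingPointError, match="meta"):
            composite_loss(Tensor(1.0), Tensor(1.0), Tensor(np.nan), Tensor(1.0), LossWeights())


def test_bce_with_logits_matches_closed_form():
    rng = np.random.default_rng(1)
    x = rng.normal(size=20).astype(np.float32) * 4
    y = (rng.random(20) < 0.5).astype(np.float32)
    got = float(bce_with_logits(Tensor(x), y).data)
    p = 1 / (1 + np.exp(-x.astype(np.float64)))
    ref = -(y * np.log(p) + (1 - y) * np.log(1 - p)).mean()
    assert got == pytest.approx(ref, rel=1e-5)
    assert got >= 0


def test_spectral_loss_matches_dirichlet_energy(small_kg):
    from spectradti.spectral import dirichlet_energy

    _, graph, _, _ = small_kg
    op = build_operator(graph)
    rng = np.random.default_rng(2)
    H = rng.normal(size=(graph.n_nodes, 5)).astype(np.float32)
    got = float(spectral_loss(Tensor(H), op.dense_laplacian(), normalize=False).data)
    assert got == pytest.approx(dirichlet_energy(H, op), rel=1e-4)
    assert got >= 0


@pytest.fixture(scope="module")
def tiny_model():
    from spectradti.synthetic import SyntheticConfig, generate_kg
    from spectradti.kg import sample_negatives

    cfg = SyntheticConfig(n_drugs=24, n_proteins=8, n_pathways=3, n_families=2, seed=5)
    graph, positives, truth = generate_kg(cfg)
    negs = sample_negatives(graph, positives, ratio=1.0, seed=0)
    pairs = positives + negs
    tasks = np.array([truth.family_of[p.protein] % 2 for p in pairs])
    op = build_operator(graph)
    basis = compute_spectral_basis(op, d_eig=8)
    cache = build_distance_cache(graph, basis)
    mc = ModelConfig.desk(d=16, layers=1)
    model = DTIModel(graph, basis, cache, mc, seed=0, operator=op)
    return graph, pairs, tasks, model, cache


class TestContrastiveViews:
    def test_views_are_seeded_and_anchored(self, tiny_model):
        graph, pairs, _, model, cache = tiny_model
        ea = (model.aggregator.src, model.aggregator.dst, model.aggregator.rel)
        pair = (pairs[0].drug, pairs[0].protein)
        v1 = sample_contrastive_views(pair, graph, cache, ea, seed=3)
        v2 = sample_contrastive_views(pair, graph, cache, ea, seed=3)
        np.testing.assert_array_equal(v1.anchor_nodes, v2.anchor_nodes)
        np.testing.assert_array_equal(v1.positive_nodes, v2.positive_nodes)
        np.testing.assert_array_equal(v1.negative_edges, v2.negative_edges)
        # both endpoints always present in both views
        for nodes in (v1.anchor_nodes, v1.positive_nodes):
            assert pair[0] in nodes and pair[1] in nodes

    def test_keep_probability_nonincreasing_in_diffusion_distance(self, tiny_model):
        graph, pairs, _, model, cache = tiny_model
        ea = (model.aggregator.src, model.aggregator.dst, model.aggregator.rel)
        checked = 0
        for p in pairs[:100]:
            v = sample_contrastive_views((p.drug, p.protein), graph, cache, ea, seed=1)
            others = [n for n in v.keep_prob if n not in (p.drug, p.protein)]
            if len(others) < 2:
                continue
            dd = np.minimum(cache.d_diff[others, p.drug], cache.d_diff[others, p.protein])
            kp = np.array([v.keep_prob[n] for n in others])
            order = np.argsort(dd)
            assert (np.diff(kp[order]) <= 1e-9).all()
            checked += 1
        assert checked >= 20

    def test_negative_view_drops_edges(self, tiny_model):
        graph, pairs, _, model, cache = tiny_model
        ea = (model.aggregator.src, model.aggregator.dst, model.aggregator.rel)
        v = sample_contrastive_views((pairs[0].drug, pairs[0].protein), graph, cache, ea, seed=2)
        assert len(v.negative_edges) <= len(v.anchor_edges)
        assert set(v.negative_edges) <= set(v.anchor_edges)


class TestMetaEpisodes:
    def _head_and_data(self, seed=0, n=16, d=12):
        rng = np.random.default_rng(seed)
        head = PredictionHead(d, np.random.default_rng(1), hidden=8).eval()
        X = rng.normal(size=(n, d)).astype(np.float32)
        w = rng.normal(size=d)
        y = (X @ w > 0).astype(np.float32)
        return head, Tensor(X), y

    def test_zero_inner_steps_equals_plain_query_bce(self):
        head, X, y = self._head_and_data()
        q, clone = meta_episode_loss(head, X, y, X, y, inner_steps=0)
        plain = bce_with_logits(head.logits(X).reshape(len(y)), y)
        assert float(q.data) == pytest.approx(float(plain.data), rel=1e-6)

    def test_adaptation_usually_reduces_loss_on_support_equals_query(self):
        wins = 0
        for seed in range(50):
            head, X, y = self._head_and_data(seed=seed)
            before = float(bce_with_logits(head.logits(X).reshape(len(y)), y).data)
            q, _ = meta_episode_loss(head, X, y, X, y, inner_steps=1, alpha_inner=0.01)
            if float(q.data) <= before + 1e-9:
                wins += 1
        assert wins >= 45  # >= 90% of seeded trials

    def test_identical_episodes_identical_losses(self):
        head, X, y = self._head_and_data(seed=3)
        q1, _ = meta_episode_loss(head, X, y, X, y, inner_steps=2)
        q2, _ = meta_episode_loss(head, X, y, X, y, inner_steps=2)
        assert float(q1.data) == float(q2.data)

    def test_outer_head_parameters_untouched(self):
        head, X, y = self._head_and_data(seed=4)
        before = {k: v.copy() for k, v in head.state_dict().items()}
        meta_episode_loss(head, X, y, X, y, inner_steps=3)
        for k, v in head.state_dict().items():
            np.testing.assert_array_equal(v, before[k])

    def test_empty_support_warns_and_returns_unadapted(self, caplog):
        head, X, y = self._head_and_data(seed=5)
        q, _ = meta_episode_loss(head, None, np.array([]), X, y)
        plain = bce_with_logits(head.logits(X).reshape(len(y)), y)
        assert float(q.data) == pytest.approx(float(plain.data), rel=1e-6)


class TestTrainLoop:
    def _run(self, model_seed=0, train_seed=0, epochs=2):
        from spectradti.synthetic import SyntheticConfig, generate_kg
        from spectradti.kg import make_splits, sample_negatives

        cfg = SyntheticConfig(n_drugs=24, n_proteins=8, n_pathways=3, n_families=2, seed=5)
        graph, positives, truth = generate_kg(cfg)
        negs = sample_negatives(graph, positives, ratio=1.0, seed=0)
        pairs = positives + negs
        tasks = np.array([truth.family_of[p.protein] % 2 for p in pairs])
        splits = make_splits(pairs, mode="random", k=3, seed=0)
        tr, val, te = splits.train_test(0)
        op = build_operator(graph)
        basis = compute_spectral_basis(op, d_eig=8)
        cache = build_distance_cache(graph, basis)
        model = DTIModel(graph, basis, cache, ModelConfig.desk(d=16, layers=1),
                         seed=model_seed, operator=op)
        tc = TrainConfig(base_lr=1e-3, max_epochs=epochs, batch_size=16,
                         steps_per_epoch=2, seed=train_seed, contrastive_pairs=2,
                         support_size=4, query_size=4)
        return train(model, pairs, tasks, tr, val, tc)

    def test_smoke_history_and_loss_components_nonnegative(self):
        res = self._run(epochs=2)
        assert len(res.history) == 2
        for h in res.history:
            for k in ("dti", "contrastive", "meta", "spectral"):
                assert h[k] >= -1e-9

    def test_same_seed_reproduces_loss_trajectory(self):
        a = self._run(epochs=2)
        b = self._run(epochs=2)
        assert [h["total"] for h in a.history] == [h["total"] for h in b.history]

    def test_empty_validation_rejected(self, tiny_model):
        graph, pairs, tasks, model, _ = tiny_model
        with pytest.raises(ValueError):
            train(model, pairs, tasks, np.arange(10), np.array([], dtype=int),
                  TrainConfig(max_epochs=1))
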