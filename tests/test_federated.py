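"""FedAvg aggregation, federated rounds and the single-node baseline."""

import inspect

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from col6fl import (
    FedAvgConfig,
    ModelParams,
    Node,
    fedavg_aggregate,
    local_update,
    run_federated,
    run_single_node,
)
from col6fl.features import head_gradient

g = np.random.default_rng(11)


def _node(site_id="S", n=20, d=5, k=3, seed=0):
    r = np.random.default_rng(seed)
    return Node(site_id, r.normal(size=(n, d)), r.integers(0, k, n))


def _params(d=5, k=3, seed=1):
    r = np.random.default_rng(seed)
    return ModelParams(r.normal(size=(d, k)) * 0.1, r.normal(size=k) * 0.1)


class TestLocalUpdate:
    def test_zero_learning_rate_returns_broadcast_params(self):
        node = _node()
        p0 = _params()
        cfg = FedAvgConfig(rounds=1, local_epochs=3, learning_rate=0.0)
        p1, n_k = local_update(node, p0, cfg)
        assert n_k == node.n_k
        assert np.array_equal(p1.weights, p0.weights)
        assert np.array_equal(p1.bias, p0.bias)

    def test_seeded_updates_are_reproducible(self):
        node = _node()
        cfg = FedAvgConfig(learning_rate=0.1, local_epochs=2, batch_size=8, seed=3)
        a, _ = local_update(node, _params(), cfg)
        b, _ = local_update(node, _params(), cfg)
        assert np.array_equal(a.weights, b.weights)

    def test_one_full_batch_epoch_equals_analytic_gradient_step(self):
        node = _node(n=30)
        p0 = _params()
        cfg = FedAvgConfig(learning_rate=0.2, local_epochs=1, l2=1e-3)
        p1, _ = local_update(node, p0, cfg)
        gw, gb = head_gradient(p0, node.features, node.labels, cfg.l2)
        assert np.abs(p1.weights - (p0.weights - 0.2 * gw)).max() < 1e-6
        assert np.abs(p1.bias - (p0.bias - 0.2 * gb)).max() < 1e-6

    def test_empty_node_rejected(self):
        empty = Node("E", np.empty((0, 5)), np.empty(0, dtype=int))
        with pytest.raises(ValueError, match="E"):
            local_update(empty, _params(), FedAvgConfig())


class TestFedAvgAggregate:
    def test_single_update_is_identity(self):
        p = _params()
        out = fedavg_aggregate([(p, 10)])
        assert np.array_equal(out.weights, p.weights)

    def test_identical_updates_average_to_themselves(self):
        p = _params()
        out = fedavg_aggregate([(p, 3), (p.copy(), 7)])
        assert np.allclose(out.weights, p.weights, atol=1e-15)

    def test_sample_count_weighting_forced_example(self):
        a = ModelParams(np.array([[0.0]]), np.array([0.0]))
        b = ModelParams(np.array([[4.0]]), np.array([4.0]))
        out = fedavg_aggregate([(a, 1), (b, 3)], "sample_count")
        assert out.weights[0, 0] == pytest.approx(3.0)
        uni = fedavg_aggregate([(a, 1), (b, 3)], "uniform")
        assert uni.weights[0, 0] == pytest.approx(2.0)

    def test_shape_mismatch_and_zero_total_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            fedavg_aggregate([(_params(d=5), 1), (_params(d=6), 1)])
        with pytest.raises(ValueError, match="zero"):
            fedavg_aggregate([(_params(), 0), (_params(), 0)])

    @given(st.floats(-3, 3), st.floats(-3, 3), st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_aggregation_is_affine_equivariant(self, a, b, seed):
        r = np.random.default_rng(seed)
        ps = [_params(seed=s) for s in r.integers(0, 1000, 3)]
        ns = [int(n) for n in r.integers(1, 50, 3)]
        direct = fedavg_aggregate([(p, n) for p, n in zip(ps, ns)])
        scaled = fedavg_aggregate(
            [
                (ModelParams(a * p.weights + b, a * p.bias + b), n)
                for p, n in zip(ps, ns)
            ]
        )
        assert np.allclose(scaled.weights, a * direct.weights + b, atol=1e-9)
        assert np.allclose(scaled.bias, a * direct.bias + b, atol=1e-9)


class TestRunFederated:
    def test_zero_rounds_returns_initial_params(self):
        p0 = _params()
        out, hist = run_federated([_node()], FedAvgConfig(rounds=0), p0)
        assert np.array_equal(out.weights, p0.weights)
        assert hist.global_loss == []

    def test_singleton_federation_equals_single_node_baseline(self):
        node = _node(n=40)
        cfg = FedAvgConfig(rounds=12, local_epochs=2, learning_rate=0.05, seed=2)
        fed, _ = run_federated([node], cfg, _params())
        solo, _ = run_single_node(node, cfg, _params())
        assert np.array_equal(fed.weights, solo.weights)
        assert np.array_equal(fed.bias, solo.bias)

    def test_each_round_equals_pooled_centralized_gradient_step(self):
        """With E=1, full batch and sample-count weighting, 20 federated
        rounds coincide with 20 full-batch steps on the pooled objective."""
        n1, n2 = _node("A", n=30, seed=1), _node("B", n=50, seed=2)
        cfg = FedAvgConfig(rounds=20, local_epochs=1, learning_rate=0.1, l2=1e-3)
        fed, _ = run_federated([n1, n2], cfg, ModelParams.zeros(5, 3))

        X = np.vstack([n1.features, n2.features])
        y = np.concatenate([n1.labels, n2.labels])
        p = ModelParams.zeros(5, 3)
        for _ in range(20):
            gw, gb = head_gradient(p, X, y, cfg.l2)
            p = ModelParams(p.weights - 0.1 * gw, p.bias - 0.1 * gb)
        assert np.abs(fed.weights - p.weights).max() < 1e-6
        assert np.abs(fed.bias - p.bias).max() < 1e-6

    def test_history_lengths_match_rounds(self):
        _, hist = run_federated(
            [_node("A"), _node("B", seed=4)],
            FedAvgConfig(rounds=7, learning_rate=0.05),
            _params(),
        )
        assert len(hist.global_loss) == 7
        assert len(hist.local_losses) == 7
        assert len(hist.param_delta_norm) == 7
        assert set(hist.local_losses[0]) == {"A", "B"}

    def test_negative_round_count_rejected(self):
        with pytest.raises(ValueError, match="rounds"):
            FedAvgConfig(rounds=-1)


def test_privacy_boundary_aggregator_accepts_only_params_and_counts():
    """Structural contract: no public training operation in the federated
    module takes raw data from more than one node; the aggregator's
    signature admits only (ModelParams, count) pairs."""
    sig = inspect.signature(fedavg_aggregate)
    assert list(sig.parameters) == ["updates", "weighting"]
    for fn in (local_update, run_single_node):
        params = inspect.signature(fn).parameters
        node_like = [p for p in params if "node" in p]
        assert len(node_like) == 1  # exactly one node's data enters
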