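"""Network construction, forward pass, parameter counting, gene splitting."""

import numpy as np
import pytest

from taafgex.activations import init_taaf
from taafgex.model import (
    ArchitectureSpec,
    Layer,
    NetworkParameters,
    build_network,
    capacity_matched_width,
    forward,
    load_checkpoint,
    parameter_count,
    save_checkpoint,
    split_target_genes,
)


def spec(**kw):
    base = dict(input_dim=5, output_dim=3, n_hidden_layers=1, width=4)
    base.update(kw)
    return ArchitectureSpec(**base)


class TestArchitectureSpec:
    @pytest.mark.parametrize(
        "kw",
        [
            {"n_hidden_layers": 4},
            {"width": 0},
            {"dropout_rate": 1.0},
            {"hidden_mode": "relu"},
            {"inner_kind": "swish"},
        ],
    )
    def test_invalid_fields_rejected(self, kw):
        with pytest.raises(ValueError):
            spec(**kw)


class TestBuildNetwork:
    def test_deterministic_given_spec_and_seed(self):
        a = build_network(spec(), seed=7)
        b = build_network(spec(), seed=7)
        for la, lb in zip(a.layers, b.layers):
            np.testing.assert_array_equal(la.weights, lb.weights)

    def test_shape_chaining(self):
        net = build_network(spec(), seed=0)
        assert net.layers[0].weights.shape == (5, 4)
        assert net.layers[1].weights.shape == (4, 3)

    def test_normalized_initialization_bound(self):
        # normalized init: |w| <= sqrt(6 / (fan_in + fan_out)), every layer
        for seed in range(20):
            net = build_network(spec(width=16), seed=seed)
            for layer in net.layers:
                fan_in, fan_out = layer.weights.shape
                limit = np.sqrt(6.0 / (fan_in + fan_out))
                assert np.all(np.abs(layer.weights) <= limit)

    def test_taaf_layers_have_no_bias(self):
        net = build_network(spec(hidden_mode="taaf", output_mode="taaf"), seed=0)
        for layer in net.layers:
            assert layer.bias is None and layer.taaf is not None
            np.testing.assert_array_equal(layer.taaf.alpha, 1.0)
            np.testing.assert_array_equal(layer.taaf.delta, 0.0)


class TestForward:
    def test_evaluation_is_deterministic_despite_dropout_rate(self):
        net = build_network(spec(dropout_rate=0.25), seed=1)
        x = np.random.default_rng(0).normal(size=(10, 5))
        np.testing.assert_array_equal(forward(net, x), forward(net, x))

    def test_training_dropout_changes_activations(self):
        net = build_network(spec(dropout_rate=0.5, width=64), seed=1)
        x = np.random.default_rng(0).normal(size=(10, 5))
        a = forward(net, x, training=True, seed=1)
        b = forward(net, x, training=True, seed=2)
        assert not np.array_equal(a, b)

    def test_taaf_at_init_equals_fixed_activation_network(self):
        # same weights, gamma == bias == 0: outputs agree to double precision
        fixed = build_network(spec(hidden_mode="fixed"), seed=3)
        taaf = build_network(spec(hidden_mode="taaf"), seed=3)
        for lf, lt in zip(fixed.layers, taaf.layers):
            lt.weights = lf.weights.copy()
        x = np.random.default_rng(1).normal(size=(8, 5))
        np.testing.assert_allclose(forward(fixed, x), forward(taaf, x), rtol=1e-15)

    def test_hand_computed_single_unit(self):
        # one tanh-TAAF hidden unit (2, 1, 0.5, -1), linear output weight 1:
        # landmarks [1, 2], weights [0.5, -0.25] -> 2*tanh(0.5) - 1
        s = ArchitectureSpec(
            input_dim=2, output_dim=1, n_hidden_layers=1, width=1,
            inner_kind="tanh", hidden_mode="taaf", dropout_rate=0.0,
        )
        taaf = init_taaf(1)
        taaf.alpha[:] = 2.0
        taaf.gamma[:] = 0.5
        taaf.delta[:] = -1.0
        net = NetworkParameters(
            architecture=s,
            layers=[
                Layer(weights=np.array([[0.5], [-0.25]]), taaf=taaf),
                Layer(weights=np.array([[1.0]]), bias=np.zeros(1)),
            ],
            rng_seed=0,
        )
        out = forward(net, np.array([[1.0, 2.0]]))
        np.testing.assert_allclose(out, [[2 * np.tanh(0.5) - 1]], atol=1e-12)
        assert abs(out[0, 0] - (-0.0758)) < 5e-4

    def test_dimension_mismatch_raises(self):
        net = build_network(spec(), seed=0)
        with pytest.raises(ValueError, match="columns"):
            forward(net, np.zeros((3, 4)))


def _brute_force_count(s: ArchitectureSpec, trainable_only: bool) -> int:
    """Oracle: enumerate the stored arrays of a built network."""
    net = build_network(s, seed=0)
    total = 0
    for layer in net.layers:
        total += layer.weights.size
        if layer.bias is not None:
            total += layer.bias.size
        else:
            n_taaf = 4 if not trainable_only else len(layer.taaf.adaptivity_mask)
            total += n_taaf * layer.taaf.n_units
    return total


class TestParameterCount:
    def test_fixed_example(self):
        s = ArchitectureSpec(input_dim=3, output_dim=1, n_hidden_layers=1, width=2)
        assert parameter_count(s) == 11  # (3+1)*2 + (2+1)*1

    def test_taaf_hidden_example(self):
        s = ArchitectureSpec(
            input_dim=3, output_dim=1, n_hidden_layers=1, width=2, hidden_mode="taaf"
        )
        assert parameter_count(s) == 17  # 2*(3+4) + (2+1)

    def test_taaf_output_example(self):
        s = ArchitectureSpec(
            input_dim=3, output_dim=1, n_hidden_layers=1, width=2,
            hidden_mode="taaf", output_mode="taaf",
        )
        assert parameter_count(s) == 20  # 14 + (2+4)

    def test_agrees_with_brute_force_on_random_specs(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            s = ArchitectureSpec(
                input_dim=int(rng.integers(1, 8)),
                output_dim=int(rng.integers(1, 6)),
                n_hidden_layers=int(rng.integers(1, 4)),
                width=int(rng.integers(1, 9)),
                hidden_mode=rng.choice(["fixed", "taaf"]),
                output_mode=rng.choice(["linear", "taaf"]),
                adaptivity_mask=frozenset(
                    np.random.default_rng(int(rng.integers(1000))).choice(
                        ["alpha", "beta", "gamma", "delta"],
                        size=int(rng.integers(0, 5)),
                        replace=False,
                    )
                ),
            )
            for trainable_only in (False, True):
                assert parameter_count(s, trainable_only) == _brute_force_count(
                    s, trainable_only
                )


class TestCapacityMatchedWidth:
    def test_identical_cost_template_returns_reference_width(self):
        ref = spec(width=10)
        assert capacity_matched_width(ref, ref) == 10

    def test_taaf_template_example(self):
        # reference: 1 hidden layer width 10, 5 -> 3, plain = 93 parameters;
        # TAAF hidden costs 12w + 3 -> largest w with 12w + 3 <= 93 is 7
        ref = spec(width=10)
        template = spec(width=1, hidden_mode="taaf")
        assert parameter_count(ref) == 93
        assert capacity_matched_width(ref, template) == 7

    def test_sandwich_inequality_on_random_specs(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            depth = int(rng.integers(1, 4))
            ref = ArchitectureSpec(
                input_dim=int(rng.integers(2, 20)),
                output_dim=int(rng.integers(1, 15)),
                n_hidden_layers=depth,
                width=int(rng.integers(4, 40)),
            )
            template = ArchitectureSpec(
                input_dim=ref.input_dim, output_dim=ref.output_dim,
                n_hidden_layers=depth, width=1,
                hidden_mode="taaf", output_mode=rng.choice(["linear", "taaf"]),
            )
            w = capacity_matched_width(ref, template)
            budget = parameter_count(ref)
            at = lambda width: parameter_count(
                ArchitectureSpec(
                    input_dim=ref.input_dim, output_dim=ref.output_dim,
                    n_hidden_layers=depth, width=width,
                    hidden_mode="taaf", output_mode=template.output_mode,
                )
            )
            assert at(w) <= budget < at(w + 1)

    def test_mismatched_depth_rejected(self):
        with pytest.raises(ValueError, match="share"):
            capacity_matched_width(spec(), spec(n_hidden_layers=2))


class TestSplitTargetGenes:
    def test_halves_partition_and_sizes(self):
        ids = [f"g{i}" for i in range(9518)]
        a, b = split_target_genes(ids, seed=0)
        assert len(a) == len(b) == 4759
        assert set(a) | set(b) == set(ids) and not set(a) & set(b)

    def test_odd_split(self):
        a, b = split_target_genes(list("abcde"), seed=1)
        assert sorted((len(a), len(b))) == [2, 3]

    def test_deterministic_and_order_independent(self):
        ids = [f"g{i}" for i in range(11)]
        assert split_target_genes(ids, 3) == split_target_genes(ids[::-1], 3)

    def test_too_few_genes(self):
        with pytest.raises(ValueError):
            split_target_genes(["only"], seed=0)


class TestCheckpoint:
    def test_round_trip(self, tmp_path):
        net = build_network(
            spec(hidden_mode="taaf", output_mode="taaf",
                 adaptivity_mask=frozenset({"alpha", "gamma"})),
            seed=11,
        )
        net.target_ids = ["T0", "T1", "T2"]
        path = tmp_path / "model.npz"
        save_checkpoint(net, path)
        loaded = load_checkpoint(path)
        assert loaded.architecture == net.architecture
        assert loaded.target_ids == net.target_ids
        assert loaded.rng_seed == 11
        x = np.random.default_rng(0).normal(size=(4, 5))
        np.testing.assert_array_equal(forward(net, x), forward(loaded, x))
        assert loaded.layers[0].taaf.adaptivity_mask == {"alpha", "gamma"}
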