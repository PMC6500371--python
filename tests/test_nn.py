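"""Numpy network engine: shapes, determinism, gradients, dropout/eval modes."""

import numpy as np
import pytest

from sargnet.nn import build, predict_proba, softmax
from sargnet.specs import (
    ArchitectureSpec,
    ConvBlockSpec,
    DenseBlockSpec,
    RecurrentBlockSpec,
    erisnet_spec,
    fcn_spec,
    mlp_spec,
    parameter_count,
)

ALL_SPECS = [mlp_spec, fcn_spec, erisnet_spec]


def _batch(n=5, seed=0, width=14):
    return np.random.default_rng(seed).normal(0.15, 0.05, (n, width))


@pytest.mark.parametrize("spec_factory", ALL_SPECS)
class TestContracts:
    def test_probability_rows(self, spec_factory):
        model = build(spec_factory(), seed=7)
        proba = predict_proba(model, _batch())
        assert proba.shape == (5, 2)
        assert np.all(proba >= 0) and np.all(proba <= 1)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    def test_parameter_count_matches_closed_form(self, spec_factory):
        spec = spec_factory()
        assert build(spec, seed=1).n_parameters == parameter_count(spec)

    def test_same_seed_same_network_different_seed_not(self, spec_factory):
        x = _batch()
        a = predict_proba(build(spec_factory(), seed=3), x)
        b = predict_proba(build(spec_factory(), seed=3), x)
        c = predict_proba(build(spec_factory(), seed=4), x)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_eval_mode_is_deterministic(self, spec_factory):
        model = build(spec_factory(), seed=5)
        x = _batch()
        np.testing.assert_array_equal(model.predict_proba(x), model.predict_proba(x))

    def test_identical_inputs_identical_outputs(self, spec_factory):
        model = build(spec_factory(), seed=5)
        x = np.tile(_batch(1), (2, 1))
        proba = model.predict_proba(x)
        np.testing.assert_array_equal(proba[0], proba[1])

    def test_feature_width_mismatch_raises(self, spec_factory):
        with pytest.raises(ValueError, match="feature"):
            build(spec_factory(), seed=1).forward(_batch(width=13))


def test_dropout_active_in_training_inactive_in_eval():
    model = build(mlp_spec(), seed=2)
    x = _batch(8)
    train_a = model.forward(x, training=True)
    train_b = model.forward(x, training=True)
    assert not np.array_equal(train_a, train_b)  # stochastic masks
    eval_a = model.forward(x, training=False)
    eval_b = model.forward(x, training=False)
    np.testing.assert_array_equal(eval_a, eval_b)


def test_hard_call_is_argmax_and_half_probability_goes_to_class_zero():
    model = build(mlp_spec(), seed=2)
    x = _batch(20)
    proba = model.predict_proba(x)
    predictions = model.predict(x)
    ties = np.isclose(proba[:, 1], 0.5)
    np.testing.assert_array_equal(predictions[~ties], proba[~ties].argmax(axis=1))
    # force an exact tie: zero the classification head
    head = [layer for layer in model.layers if layer.params()][-1]
    for param in head.params():
        param.value[...] = 0.0
    proba = model.predict_proba(x)
    np.testing.assert_allclose(proba[:, 1], 0.5, atol=0)
    assert np.all(model.predict(x) == 0)


def test_gradients_match_central_differences():
    """Backprop through every layer type agrees with finite differences.

    Conv biases that feed directly into batch norm have an exactly zero
    gradient (the normalization removes per-channel shifts), so errors
    are compared absolutely as well as relatively.
    """
    spec = ArchitectureSpec(
        name="tiny", input_layout=(14, 1),
        conv_blocks=(
            ConvBlockSpec(3, 4, l2_coefficient=1e-3),
            ConvBlockSpec(2, 3, order="conv_bn_relu"),
        ),
        recurrent_blocks=(
            RecurrentBlockSpec(3, emits_sequence=True),
            RecurrentBlockSpec(3, emits_sequence=False),
        ),
        dense_blocks=(DenseBlockSpec(2, activation="softmax"),),
    )
    net = build(spec, seed=3)
    rng = np.random.default_rng(0)
    x = rng.normal(0.15, 0.05, (6, 14))
    y = rng.integers(0, 2, 6)
    net.loss_and_grad(x, y)
    grads = [p.grad.copy() for p in net.params()]
    eps = 1e-6
    for pi, p in enumerate(net.params()):
        flat = p.value.reshape(-1)
        for j in range(0, flat.size, max(1, flat.size // 6)):
            orig = flat[j]
            flat[j] = orig + eps
            lp = net.loss_and_grad(x, y)
            flat[j] = orig - eps
            lm = net.loss_and_grad(x, y)
            flat[j] = orig
            numeric = (lp - lm) / (2 * eps)
            analytic = grads[pi].reshape(-1)[j]
            assert numeric == pytest.approx(analytic, rel=1e-4, abs=1e-7)


def test_softmax_is_shift_invariant_and_normalized():
    z = np.array([[1.0, 3.0], [-2.0, -2.0], [500.0, 499.0]])
    p = softmax(z)
    np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)
    np.testing.assert_allclose(softmax(z + 100.0), p, atol=1e-12)


def test_state_round_trip_preserves_predictions():
    model = build(fcn_spec(), seed=6)
    x = _batch(4)
    # a training pass moves batch-norm running statistics too
    model.loss_and_grad(x, np.array([0, 1, 0, 1]))
    state = model.get_state()
    reference = model.predict_proba(x)
    clone = build(fcn_spec(), seed=99)
    clone.set_state(state)
    np.testing.assert_array_equal(clone.predict_proba(x), reference)


def test_state_shape_mismatch_rejected():
    model = build(mlp_spec(), seed=1)
    with pytest.raises(ValueError):
        model.set_state(model.get_state()[:-1])


def test_two_channel_layout_consumes_family_split_features():
    spec = erisnet_spec((7, 2))
    model = build(spec, seed=1)
    proba = model.predict_proba(_batch(3))
    assert proba.shape == (3, 2)
    np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)
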