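import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stackcvae import stack_cell as scell
from stackcvae.autodiff import parameter, tsum
from stackcvae.stack_cell import (NOOP, POP, PUSH, action_distribution,
                                  cell_step, pushdown_oracle, update_hidden,
                                  update_stack)


def one_hot(op):
    a = np.zeros(3)
    a[op] = 1.0
    return a


def make_params(rng, in_dim=4, m=6, k=3):
    return scell.init_params(in_dim, m, k, rng)


class TestActionDistribution:
    def test_softmax_of_zeros_is_uniform(self, rng):
        p = make_params(rng)
        p.A = np.zeros_like(p.A)
        a = action_distribution(np.zeros(6), p)
        np.testing.assert_allclose(a, np.full(3, 1 / 3))

    def test_closed_form_log2(self, rng):
        p = make_params(rng, m=1)
        p.A = np.array([[np.log(2.0)], [0.0], [0.0]])
        a = action_distribution(np.ones(1), p)
        np.testing.assert_allclose(a, [0.5, 0.25, 0.25])

    def test_sums_to_one(self, rng):
        p = make_params(rng)
        a = action_distribution(rng.normal(size=6), p)
        assert a.sum() == pytest.approx(1.0)

    def test_shape_mismatch_errors(self, rng):
        with pytest.raises(ValueError):
            action_distribution(np.zeros(5), make_params(rng))


class TestUpdateStack:
    def test_noop_identity(self, rng):
        prev = rng.random((4, 2))
        out = update_stack(prev, one_hot(NOOP), rng.random(2))
        np.testing.assert_array_equal(out, prev)

    def test_push_shifts_down(self):
        prev = np.array([[0.2], [0.5], [0.0]])
        out = update_stack(prev, one_hot(PUSH), np.array([0.9]))
        np.testing.assert_array_equal(out[:, 0], [0.9, 0.2, 0.5])

    def test_pop_shifts_up_zero_fills(self):
        prev = np.array([[0.2], [0.5], [0.0]])
        out = update_stack(prev, one_hot(POP), np.array([0.0]))
        np.testing.assert_array_equal(out[:, 0], [0.5, 0.0, 0.0])

    def test_soft_blend_top(self):
        prev = np.array([[0.2], [0.5], [0.0]])
        out = update_stack(prev, np.array([0.5, 0.5, 0.0]), np.array([1.0]))
        assert out[0, 0] == pytest.approx(0.75)

    def test_non_probability_action_rejected(self):
        with pytest.raises(ValueError):
            update_stack(np.zeros((3, 1)), np.array([0.5, 0.5, 0.5]), np.zeros(1))

    def test_entries_stay_in_unit_interval(self, rng):
        prev, value = rng.random((5, 3)), rng.random(3)
        logits = rng.normal(size=3)
        a = np.exp(logits) / np.exp(logits).sum()
        out = update_stack(prev, a, value)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_linear_in_action_probabilities(self, rng):
        """Blending one-hot results with (alpha, 1-alpha) equals running the
        blended action directly."""
        prev, value = rng.random((6, 2)), rng.random(2)
        alpha = 0.3
        blended_action = alpha * one_hot(PUSH) + (1 - alpha) * one_hot(POP)
        direct = update_stack(prev, blended_action, value)
        mixture = alpha * update_stack(prev, one_hot(PUSH), value) \
            + (1 - alpha) * update_stack(prev, one_hot(POP), value)
        np.testing.assert_allclose(direct, mixture, atol=1e-12)


class TestUpdateHidden:
    def test_zero_everything_gives_half(self, rng):
        p = make_params(rng)
        for f in ("A", "D", "U", "R", "P"):
            setattr(p, f, np.zeros_like(getattr(p, f)))
        h = update_hidden(np.zeros(4), np.zeros(6), np.zeros((5, 3)), p)
        np.testing.assert_allclose(h, np.full(6, 0.5))

    def test_sigmoid_of_ln3_is_three_quarters(self, rng):
        p = make_params(rng)
        p.U = np.zeros_like(p.U)
        p.R = np.zeros_like(p.R)
        p.P = np.full_like(p.P, np.log(3.0))
        stack = np.zeros((5, 3))
        stack[0] = 1.0 / 3.0  # P @ top = ln 3 per entry
        h = update_hidden(np.zeros(4), np.zeros(6), stack, p)
        np.testing.assert_allclose(h, np.full(6, 0.75))

    def test_reads_top_row_only(self, rng):
        p = make_params(rng)
        s1 = rng.random((5, 3))
        s2 = s1.copy()
        s2[1:] = rng.random((4, 3))  # perturb everything below the top
        x, h0 = rng.normal(size=4), rng.random(6)
        np.testing.assert_array_equal(update_hidden(x, h0, s1, p),
                                      update_hidden(x, h0, s2, p))

    def test_output_in_open_unit_interval(self, rng):
        p = make_params(rng)
        h = update_hidden(rng.normal(size=4), rng.random(6), rng.random((5, 3)), p)
        assert np.all(h > 0) and np.all(h < 1)


class TestPushdownOracle:
    def test_noop_trace_is_identity(self, rng):
        init = rng.random((4, 2))
        out = pushdown_oracle(init, [(NOOP, None)] * 10)
        np.testing.assert_array_equal(out, init)

    def test_push_then_pop_restores_when_bottom_zero(self):
        init = np.array([[0.4], [0.1], [0.0]])
        out = pushdown_oracle(init, [(PUSH, [0.9]), (POP, None)])
        np.testing.assert_array_equal(out, init)

    def test_two_pushes(self):
        out = pushdown_oracle(np.zeros((3, 1)), [(PUSH, [0.3]), (PUSH, [0.7])])
        np.testing.assert_array_equal(out[:, 0], [0.7, 0.3, 0.0])

    def test_unknown_op_rejected(self):
        with pytest.raises(ValueError):
            pushdown_oracle(np.zeros((2, 1)), [(7, None)])


class TestContinuousDiscreteEquivalence:
    @pytest.mark.parametrize("depth,width", [(1, 1), (3, 2), (5, 1), (10, 4)])
    def test_one_hot_trace_bit_exact(self, depth, width, rng):
        for _ in range(20):
            init = rng.random((depth, width))
            trace = [(int(rng.integers(0, 3)), rng.random(width)) for _ in range(30)]
            cur = init.copy()
            for op, v in trace:
                cur = update_stack(cur, one_hot(op), v)
            np.testing.assert_array_equal(cur, pushdown_oracle(init, trace))


class TestCellStep:
    def test_zero_params_closed_form(self, rng):
        p = make_params(rng)
        for f in ("A", "D", "U", "R", "P"):
            setattr(p, f, np.zeros_like(getattr(p, f)))
        h, s = cell_step(np.zeros(4), np.zeros(6), np.zeros((5, 3)), p)
        np.testing.assert_allclose(h, np.full(6, 0.5))
        # uniform action: top row = (1/3)*sigma(0) + (1/3)*0 + (1/3)*0
        np.testing.assert_allclose(s[0], np.full(3, 0.5 / 3))
        np.testing.assert_allclose(s[1:], np.zeros((4, 3)))

    def test_hidden_uses_previous_stack(self, rng):
        """Ordering: the new hidden state is computed from the *previous*
        stack, then the stack update uses the *new* hidden state."""
        p = make_params(rng)
        x, h0 = rng.normal(size=4), rng.random(6)
        s0 = rng.random((5, 3))
        h1, s1 = cell_step(x, h0, s0, p)
        np.testing.assert_array_equal(h1, update_hidden(x, h0, s0, p))
        a = action_distribution(h1, p)
        from stackcvae.autodiff import sigmoid
        v = sigmoid(h1 @ p.D.T)
        np.testing.assert_array_equal(s1, update_stack(s0, a, v))

    def test_gradient_check(self, rng):
        p = scell.init_params(3, 4, 2, rng, make=parameter)
        x = parameter(rng.normal(size=3))
        h0 = parameter(rng.random(4))
        s0 = parameter(rng.random((4, 2)))

        def forward():
            h, s = cell_step(x, h0, s0, p)
            return tsum(h) + tsum(s * s)

        out = forward()
        out.backward()
        eps = 1e-6
        for t in (x, h0, s0, p.A, p.D, p.U, p.R, p.P):
            analytic = t.grad.copy()
            numeric = np.zeros_like(t.data)
            it = np.nditer(t.data, flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                t.data[i] += eps
                f1 = float(forward().data)
                t.data[i] -= 2 * eps
                f2 = float(forward().data)
                t.data[i] += eps
                numeric[i] = (f1 - f2) / (2 * eps)
            scale = max(np.abs(numeric).max(), 1e-8)
            assert np.abs(analytic - numeric).max() / scale < 1e-4


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(1, 10), st.integers(1, 4), st.integers(0, 2 ** 31 - 1))
def test_convex_combination_bound_property(depth, width, seed):
    """Every output cell is a convex combination of push value and shifted
    neighbours, so entries never leave [0, 1]."""
    r = np.random.default_rng(seed)
    prev, value = r.random((depth, width)), r.random(width)
    logits = r.normal(size=3)
    a = np.exp(logits) / np.exp(logits).sum()
    out = update_stack(prev, a, value)
    assert out.min() >= -1e-12 and out.max() <= 1.0 + 1e-12
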