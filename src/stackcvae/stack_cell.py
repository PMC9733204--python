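"""Stack-augmented recurrent cell with a differentiable pushdown memory.

The cell maintains an external stack ``s`` of fixed depth ``p`` whose
elements are width-``k`` vectors.  At each step a soft 3-way action
(PUSH, POP, NO-OP) is computed from the hidden state and the stack is
updated as a convex combination of the three discrete outcomes:

    a_t    = softmax(A h_t)                       (action probabilities)
    s_t[0] = a[PUSH] * sigmoid(D h_t) + a[POP] * s_{t-1}[1] + a[NOOP] * s_{t-1}[0]
    s_t[i] = a[PUSH] * s_{t-1}[i-1]   + a[POP] * s_{t-1}[i+1] + a[NOOP] * s_{t-1}[i]
    h_t    = sigmoid(U x_t + R h_{t-1} + P s_{t-1}[0])

With one-hot actions this reduces exactly to discrete pushdown-automaton
semantics (PUSH shifts every element down one row and discards the bottom;
POP shifts up and zero-fills the bottom), which :func:`pushdown_oracle`
implements literally and the tests compare against bit-for-bit.

All operations accept either plain float64 ndarrays or autodiff
:class:`~stackcvae.autodiff.Tensor` objects, and allow an arbitrary number
of leading batch axes: hidden states are ``(..., m)``, stacks ``(..., p, k)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

from .autodiff import Tensor, concatenate, sigmoid, softmax

PUSH, POP, NOOP = 0, 1, 2

__all__ = [
    "PUSH",
    "POP",
    "NOOP",
    "StackCellParams",
    "action_distribution",
    "update_stack",
    "update_hidden",
    "cell_step",
    "pushdown_oracle",
    "init_params",
]


@dataclass
class StackCellParams:
    """Weights of one stack-augmented recurrent layer.

    Shapes follow the column-vector convention: ``A`` is (3, m), ``D`` is
    (k, m), ``U`` is (m, input_dim), ``R`` is (m, m), ``P`` is (m, k).
    The push value is a width-``k`` vector so that the stack read ``P s[0]``
    is well-defined.
    """

    A: object
    D: object
    U: object
    R: object
    P: object

    @property
    def hidden_size(self) -> int:
        return _shape(self.R)[0]

    @property
    def stack_width(self) -> int:
        return _shape(self.P)[1]


def _shape(x):
    return x.shape if hasattr(x, "shape") else np.asarray(x).shape


def _check_action(action) -> None:
    a = action.data if isinstance(action, Tensor) else np.asarray(action, dtype=float)
    if a.shape[-1] != 3:
        raise ValueError(f"action must have 3 components, got shape {a.shape}")
    if np.any(a < -1e-9) or np.any(np.abs(a.sum(axis=-1) - 1.0) > 1e-6):
        raise ValueError("action is not a probability vector (entries >= 0 summing to 1)")


def action_distribution(h, params: StackCellParams):
    """Soft PUSH/POP/NOOP probabilities ``softmax(A h)`` for hidden state h."""
    m = params.hidden_size
    if _shape(h)[-1] != m:
        raise ValueError(f"hidden state has size {_shape(h)[-1]}, expected {m}")
    return softmax(h @ params.A.T, axis=-1)


def update_stack(prev, action, push_value):
    """Blend the three discrete stack outcomes by the action probabilities.

    ``prev`` is ``(..., p, k)``, ``action`` ``(..., 3)``, ``push_value``
    ``(..., k)``.  On PUSH the bottom row is discarded; on POP a zero row
    enters at the bottom.
    """
    _check_action(action)
    p = _shape(prev)[-2]
    top_in = push_value[..., None, :]
    if p > 1:
        pushed = concatenate([top_in, prev[..., :-1, :]], axis=-2)
        zero_row = np.zeros(_shape(prev)[:-2] + (1, _shape(prev)[-1]))
        popped = concatenate([prev[..., 1:, :], zero_row], axis=-2)
    else:
        pushed = top_in
        popped = prev * 0.0
    a_push = action[..., PUSH : PUSH + 1, None]
    a_pop = action[..., POP : POP + 1, None]
    a_noop = action[..., NOOP : NOOP + 1, None]
    return a_push * pushed + a_pop * popped + a_noop * prev


def update_hidden(x, h_prev, stack_prev, params: StackCellParams):
    """``h = sigmoid(U x + R h_prev + P s_prev[0])`` — reads the stack top."""
    top = stack_prev[..., 0, :]
    return sigmoid(x @ params.U.T + h_prev @ params.R.T + top @ params.P.T)


def cell_step(x, h_prev, stack_prev, params: StackCellParams):
    """One full step: new hidden from the previous stack, then stack update.

    Returns ``(h_t, stack_t)`` where the push value is ``sigmoid(D h_t)``
    and the action distribution is computed from the *new* hidden state.
    """
    h = update_hidden(x, h_prev, stack_prev, params)
    a = action_distribution(h, params)
    v = sigmoid(h @ params.D.T)
    return h, update_stack(stack_prev, a, v)


def pushdown_oracle(initial: np.ndarray, trace: Sequence[Tuple[int, object]]) -> np.ndarray:
    """Discrete fixed-depth pushdown automaton used to verify the soft cell.

    ``trace`` is a list of ``(op, push_value)`` pairs with
    ``op in {PUSH, POP, NOOP}``; ``push_value`` is ignored except on PUSH.
    """
    stack = np.array(initial, dtype=np.float64)
    p = stack.shape[0]
    for op, value in trace:
        if op == PUSH:
            if p > 1:
                stack[1:] = stack[:-1]
            stack[0] = np.asarray(value, dtype=np.float64)
        elif op == POP:
            if p > 1:
                stack[:-1] = stack[1:]
            stack[-1] = 0.0
        elif op == NOOP:
            pass
        else:
            raise ValueError(f"unknown stack operation {op!r}")
    return stack


def init_params(input_dim: int, hidden: int, width: int, rng: np.random.Generator,
                scale: float = 0.1, make=np.asarray) -> StackCellParams:
    """Random small-weight initialization; `make` wraps arrays (e.g. parameter)."""
    def w(*shape):
        return make(rng.normal(0.0, scale, size=shape))

    return StackCellParams(
        A=w(3, hidden),
        D=w(width, hidden),
        U=w(hidden, input_dim),
        R=w(hidden, hidden),
        P=w(hidden, width),
    )
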