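"""Adam optimizer with bias-corrected moment estimates.

Per parameter tensor the update keeps an exponential moving average of
the gradient (first moment m) and of its elementwise square (second
moment v), corrects both for initialization bias, and steps

    m_t = b1 m_{t-1} + (1 - b1) g_t
    v_t = b2 v_{t-1} + (1 - b2) g_t^2
    m̂_t = m_t / (1 - b1^t),   v̂_t = v_t / (1 - b2^t)
    θ_t = θ_{t-1} - a m̂_t / (sqrt(v̂_t) + eps)

Defaults follow the training recipe this package targets: learning rate
a = 2e-5 and b1 = 0.7; b2 = 0.999 and eps = 1e-8 are the conventional
values.  At t = 1 the bias corrections cancel, so the first step has
magnitude ≈ a regardless of the gradient scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AdamState", "adam_step"]


@dataclass
class AdamState:
    """Per-parameter first/second moment estimates and the step counter."""

    m: dict[str, np.ndarray]
    v: dict[str, np.ndarray]
    t: int = 0
    lr: float = 2e-5
    beta1: float = 0.7
    beta2: float = 0.999
    eps: float = 1e-8

    @classmethod
    def for_params(cls, params: dict[str, np.ndarray], lr: float = 2e-5,
                   beta1: float = 0.7, beta2: float = 0.999, eps: float = 1e-8) -> "AdamState":
        return cls(
            m={k: np.zeros_like(np.asarray(p, dtype=np.float64)) for k, p in params.items()},
            v={k: np.zeros_like(np.asarray(p, dtype=np.float64)) for k, p in params.items()},
            t=0, lr=lr, beta1=beta1, beta2=beta2, eps=eps,
        )


def adam_step(params: dict[str, np.ndarray], grads: dict[str, np.ndarray],
              state: AdamState) -> tuple[dict[str, np.ndarray], AdamState]:
    """Apply one Adam update in place; returns the same (params, state).

    ``grads`` must hold one array per parameter with matching shape; a
    mismatch is rejected before any parameter is touched.
    """
    if set(grads) != set(params):
        missing = set(params) ^ set(grads)
        raise ValueError(f"gradient keys do not match parameters: {sorted(missing)}")
    for k in params:
        if np.shape(grads[k]) != np.shape(params[k]):
            raise ValueError(
                f"shape mismatch for {k!r}: param {np.shape(params[k])}, "
                f"grad {np.shape(grads[k])}"
            )
    state.t += 1
    t = state.t
    b1, b2 = state.beta1, state.beta2
    bias1 = 1.0 - b1 ** t
    bias2 = 1.0 - b2 ** t
    for k, p in params.items():
        g = np.asarray(grads[k], dtype=np.float64)
        state.m[k] = b1 * state.m[k] + (1.0 - b1) * g
        state.v[k] = b2 * state.v[k] + (1.0 - b2) * g * g
        m_hat = state.m[k] / bias1
        v_hat = state.v[k] / bias2
        p -= state.lr * m_hat / (np.sqrt(v_hat) + state.eps)
    return params, state
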