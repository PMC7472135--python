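"""Adam optimiser, written out explicitly.

Adaptive moment estimation keeps exponential moving averages of the
gradient (first moment ``m``) and of its elementwise square (second moment
``v``), corrects both for their zero initialisation, and scales each
coordinate's step by the corrected root second moment:

    m_t = b1 * m_{t-1} + (1 - b1) * g_t
    v_t = b2 * v_{t-1} + (1 - b2) * g_t**2
    m_hat = m_t / (1 - b1**t),  v_hat = v_t / (1 - b2**t)
    theta_t = theta_{t-1} - lr * m_hat / (sqrt(v_hat) + eps)

With a constant gradient g the corrected moments telescope to exactly
``m_hat = g`` and ``v_hat = g**2`` at every step, so each update is about
``-lr * sign(g)``; per-coordinate steps are always bounded by roughly the
learning rate.  All gradient-trained layers in this package use this
implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

Params = list[np.ndarray]


def _as_list(x) -> Params:
    if isinstance(x, np.ndarray):
        return [x]
    return list(x)


@dataclass
class AdamState:
    """Moment estimates and hyperparameters for one parameter set.

    ``m``/``v`` mirror the parameter shapes and start at zero with ``t = 0``;
    ``t`` increases by one per step.  ``beta_1``/``beta_2`` are the moment
    attenuation coefficients, ``lr`` the learning rate and ``eps`` the
    numerical-stability constant in the denominator.
    """

    m: Params
    v: Params
    t: int = 0
    beta_1: float = 0.9
    beta_2: float = 0.999
    lr: float = 1e-3
    eps: float = 1e-8
    shapes: list[tuple] = field(default_factory=list)

    @classmethod
    def init(cls, params, lr: float = 1e-3, beta_1: float = 0.9,
             beta_2: float = 0.999, eps: float = 1e-8) -> "AdamState":
        if not 0 <= beta_1 < 1 or not 0 <= beta_2 < 1:
            raise ValueError("attenuation coefficients must lie in [0, 1)")
        if lr <= 0 or eps <= 0:
            raise ValueError("lr and eps must be > 0")
        plist = _as_list(params)
        return cls(
            m=[np.zeros_like(np.asarray(p, dtype=float)) for p in plist],
            v=[np.zeros_like(np.asarray(p, dtype=float)) for p in plist],
            t=0,
            beta_1=beta_1, beta_2=beta_2, lr=lr, eps=eps,
            shapes=[np.shape(p) for p in plist],
        )


def adam_step(state: AdamState, params, grads,
              names: list[str] | None = None) -> tuple[Params, AdamState]:
    """Advance one Adam step; returns new parameter arrays and the state.

    ``names`` (optional) labels parameters in error messages, e.g. layer
    names, so a non-finite gradient can be pinned to its layer.
    """
    plist, glist = _as_list(params), _as_list(grads)
    if len(plist) != len(state.m) or len(glist) != len(plist):
        raise ValueError(
            f"parameter/gradient count mismatch: {len(plist)} params, "
            f"{len(glist)} grads, state holds {len(state.m)}"
        )
    out: Params = []
    state.t += 1
    bc1 = 1.0 - state.beta_1 ** state.t
    bc2 = 1.0 - state.beta_2 ** state.t
    for i, (p, g) in enumerate(zip(plist, glist)):
        p = np.asarray(p, dtype=float)
        g = np.asarray(g, dtype=float)
        if p.shape != g.shape or p.shape != state.shapes[i]:
            raise ValueError(
                f"shape mismatch at parameter {i}: param {p.shape}, "
                f"grad {g.shape}, state {state.shapes[i]}"
            )
        if not np.all(np.isfinite(g)):
            label = names[i] if names else f"parameter {i}"
            raise FloatingPointError(f"non-finite gradient in {label}")
        state.m[i] = state.beta_1 * state.m[i] + (1.0 - state.beta_1) * g
        state.v[i] = state.beta_2 * state.v[i] + (1.0 - state.beta_2) * g * g
        m_hat = state.m[i] / bc1
        v_hat = state.v[i] / bc2
        out.append(p - state.lr * m_hat / (np.sqrt(v_hat) + state.eps))
    return out, state


class AdamOptimizer:
    """Thin stateful wrapper: ``opt.step(params, grads) -> new params``."""

    def __init__(self, params, lr: float = 1e-3, beta_1: float = 0.9,
                 beta_2: float = 0.999, eps: float = 1e-8):
        self.state = AdamState.init(params, lr=lr, beta_1=beta_1,
                                    beta_2=beta_2, eps=eps)

    def step(self, params, grads, names=None) -> Params:
        new_params, self.state = adam_step(self.state, params, grads, names)
        return new_params
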