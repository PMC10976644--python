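"""SchNet-style short-range message passing.

One *interaction* is a message step followed by an update step:

    m_i = Σ_{j ∈ N(i)}  W(e_ij) ⊙ (W_h h_j + b_h)          (continuous-filter
    h_i ← h_i + U(m_i)                                       convolution)

where ``e_ij`` is a Gaussian radial-basis expansion of the interatomic
distance, smoothly damped to zero at the cutoff by a cosine switching
function, ``W(·)`` a filter-generating network (two linear layers with
softplus) and ``U`` an atomwise MLP whose output layer is zero-initialized so
a fresh model starts as a pure readout of x⁰.  Messages depend on distances
only, which makes every interaction exactly invariant to proper rigid
motions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, segment_sum, softplus
from .errors import InvalidInputError
from .molecular import NeighborList


@dataclass
class EdgeFeatures:
    """Radial-basis activations and smooth cutoff weights per directed pair."""

    rbf: np.ndarray  # (m, n_rbf)
    cutoff_weight: np.ndarray  # (m,), in [0, 1], exactly 0 at d == cutoff

    @property
    def weighted(self) -> np.ndarray:
        return self.rbf * self.cutoff_weight[:, None]


@dataclass
class HiddenState:
    h: Tensor  # (n, F)
    step: int = 0


def rbf_expand(distances, n_rbf: int, cutoff: float) -> EdgeFeatures:
    """Gaussian basis with centers uniform on (0, cutoff], width = spacing."""
    d = np.asarray(distances, dtype=float)
    if np.any(d <= 0) or np.any(d > cutoff + 1e-12):
        raise InvalidInputError("distances must satisfy 0 < d <= cutoff")
    spacing = cutoff / n_rbf
    centers = np.linspace(spacing, cutoff, n_rbf)
    rbf = np.exp(-0.5 * ((d[:, None] - centers[None, :]) / spacing) ** 2)
    cw = 0.5 * (np.cos(np.pi * np.minimum(d, cutoff) / cutoff) + 1.0)
    return EdgeFeatures(rbf=rbf, cutoff_weight=cw)


def init_interaction_params(rng: np.random.Generator, F: int, n_rbf: int) -> dict[str, Tensor]:
    p: dict[str, Tensor] = {}

    def lin(name, fan_in, fan_out, zero=False):
        w = np.zeros((fan_in, fan_out)) if zero else rng.normal(0, 1 / np.sqrt(fan_in), (fan_in, fan_out))
        p[f"{name}.W"] = Tensor.param(w)
        p[f"{name}.b"] = Tensor.param(np.zeros(fan_out))

    lin("filter.0", n_rbf, F)
    lin("filter.1", F, F)
    lin("in2f", F, F)
    lin("update.0", F, F)
    lin("update.1", F, F, zero=True)  # fresh interactions are identity maps
    return p


def _linear(x: Tensor, p: dict, name: str) -> Tensor:
    return x @ p[f"{name}.W"] + p[f"{name}.b"]


def message_step(state: HiddenState, nl: NeighborList, ef: EdgeFeatures,
                 params: dict) -> Tensor:
    """Aggregate filtered neighbor features; isolated atoms receive zero."""
    n = state.h.shape[0]
    if len(nl.pairs) == 0:
        return Tensor(np.zeros(state.h.shape))
    if nl.pairs.max() >= n:
        raise InvalidInputError("neighbor list indexes beyond the atom count")
    if len(nl.pairs) != len(ef.rbf):
        raise InvalidInputError("edge features inconsistent with neighbor list")
    filt = _linear(softplus(_linear(Tensor(ef.weighted), params, "filter.0")),
                   params, "filter.1")
    filt = filt * Tensor(ef.cutoff_weight[:, None])
    hj = _linear(state.h, params, "in2f").take_rows(nl.pairs[:, 1])
    return segment_sum(filt * hj, nl.pairs[:, 0], n)


def update_step(state: HiddenState, m: Tensor, params: dict) -> HiddenState:
    """Residual atomwise update h ← h + U(m)."""
    if m.shape != state.h.shape:
        raise InvalidInputError(f"message shape {m.shape} != state shape {state.h.shape}")
    u = _linear(softplus(_linear(m, params, "update.0")), params, "update.1")
    return HiddenState(h=state.h + u, step=state.step + 1)
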