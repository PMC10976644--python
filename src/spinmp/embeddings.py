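"""Initial per-atom representations from nuclear identity, charge and spin.

The representation of atom *i* is

    x⁰_i = ResidualBlock( x_N,i + x_Q,i + x_S,i ),     x_N = x_z + x_ez

where ``x_z`` is a learned per-element lookup, ``x_ez`` a learned linear map
of the ground-state electron-configuration descriptor, and ``x_Q`` / ``x_S``
are *electronic* embeddings built from the global total charge Q and spin
state S (number of unpaired electrons).  Three variants are provided:

``nuclear_only``
    x_Q = x_S = 0; the model is blind to Q and S by construction.
``scaled``
    The total charge is first shared equally over atoms (Q/N each), the
    shares are re-weighted by a learned positive per-atom importance
    softplus(MLP(x_N)), renormalized so they sum exactly to Q, and each atom's
    scaled partial charge multiplies a learned per-atom feature vector.  Spin
    follows the same pipeline with its own parameters.
``attention``
    A scaled dot-product attention over atoms: queries from x_N, keys and
    values from two independent linear maps of the scalar (Q or S).

All operations are purely pre-geometric (no coordinates) and permutation
equivariant.  They run on :class:`~spinmp.autodiff.Tensor` so the same code
path serves both inference and training.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .autodiff import Tensor, softplus
from .errors import InvalidInputError, UnknownElementError

VARIANTS = ("nuclear_only", "scaled", "attention")

_N_SUBSHELLS = 8  # 1s 2s 2p 3s 3p 3d 4s 4p


@dataclass
class ScaledPartialCharges:
    """Diagnostic trace of the scaled-embedding pipeline (plain numpy)."""

    raw: np.ndarray  # s/N each
    weighted: np.ndarray  # raw · importance
    scaled: np.ndarray  # renormalized, sums to s


@dataclass
class EmbeddingSet:
    """All embedding components for one molecule (plain numpy views)."""

    x_z: np.ndarray
    x_ez: np.ndarray
    x_N: np.ndarray
    x_Q: np.ndarray
    x_S: np.ndarray
    x0: np.ndarray


def load_electron_configs() -> np.ndarray:
    """(Z_max+1, 8) table of subshell occupancies; row 0 unused."""
    text = (resources.files("spinmp") / "data" / "electron_configs.txt").read_text()
    rows = [ln.split() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    z_max = max(int(r[0]) for r in rows)
    table = np.zeros((z_max + 1, _N_SUBSHELLS))
    for r in rows:
        table[int(r[0])] = [float(x) for x in r[1:]]
    return table


_ECONF = load_electron_configs()
SUPPORTED_Z_MAX = _ECONF.shape[0] - 1


def _linear(x: Tensor, p: dict, name: str) -> Tensor:
    return x @ p[f"{name}.W"] + p[f"{name}.b"]


def _mlp(x: Tensor, p: dict, name: str) -> Tensor:
    """One hidden layer of width F with softplus."""
    return _linear(softplus(_linear(x, p, f"{name}.0")), p, f"{name}.1")


def residual_block(x: Tensor, p: dict, name: str = "res") -> Tensor:
    return x + _mlp(x, p, name)


def init_embedding_params(rng: np.random.Generator, F: int,
                          variant: str = "scaled") -> dict[str, Tensor]:
    """Seeded parameter initialization for one embedding variant."""
    if variant not in VARIANTS:
        raise InvalidInputError(f"unknown embedding variant {variant!r}")
    p: dict[str, Tensor] = {}

    def lin(name, fan_in, fan_out, scale=1.0):
        p[f"{name}.W"] = Tensor.param(rng.normal(0, scale / np.sqrt(fan_in), (fan_in, fan_out)))
        p[f"{name}.b"] = Tensor.param(np.zeros(fan_out))

    p["element_table"] = Tensor.param(rng.normal(0, 1.0, (SUPPORTED_Z_MAX + 1, F)))
    lin("econf", _N_SUBSHELLS, F, scale=0.3)
    if variant == "scaled":
        for comp in ("Q", "S"):
            lin(f"{comp}.imp.0", F, F)
            lin(f"{comp}.imp.1", F, 1)
            lin(f"{comp}.val.0", F, F)
            lin(f"{comp}.val.1", F, F)
    elif variant == "attention":
        for comp in ("Q", "S"):
            lin(f"{comp}.query", F, F)
            p[f"{comp}.key.w"] = Tensor.param(rng.normal(0, 1 / np.sqrt(F), F))
            p[f"{comp}.key.b"] = Tensor.param(np.zeros(F))
            p[f"{comp}.value.w"] = Tensor.param(rng.normal(0, 1 / np.sqrt(F), F))
            p[f"{comp}.value.b"] = Tensor.param(np.zeros(F))
    lin("res.0", F, F)
    lin("res.1", F, F)
    return p


def nuclear_embedding(atomic_numbers, params: dict) -> Tensor:
    """x_N = x_z + x_ez: per-element lookup plus electron-configuration map."""
    z = np.asarray(atomic_numbers, dtype=int)
    bad = z[(z < 1) | (z > SUPPORTED_Z_MAX)]
    if bad.size:
        raise UnknownElementError(f"unsupported atomic number(s) {sorted(set(bad.tolist()))}")
    x_z = params["element_table"].take_rows(z)
    x_ez = _linear(Tensor(_ECONF[z]), params, "econf")
    return x_z + x_ez


def scaled_electronic_embedding(x_N: Tensor, s: int, params: dict,
                                component: str) -> tuple[Tensor, ScaledPartialCharges]:
    """Scaled electronic embedding for one global scalar s (Q or S).

    Pipeline: equal shares s/N → learned positive importances → renormalize so
    the shares sum exactly to s → per-atom feature = share · MLP_v(x_N).
    When s = 0 the renormalization target is 0 and every share is exactly 0.
    """
    n = x_N.shape[0]
    if n == 0:
        raise InvalidInputError("empty system")
    raw = np.full((n, 1), s / n, dtype=float)
    importance = softplus(_mlp(x_N, params, f"{component}.imp"))  # (n,1), > 0
    weighted = importance * Tensor(raw)
    if s == 0:
        scaled = Tensor(np.zeros((n, 1)))
    else:
        scaled = weighted * float(s) / weighted.sum()
    x_comp = scaled * _mlp(x_N, params, f"{component}.val")
    trace = ScaledPartialCharges(
        raw=raw[:, 0].copy(),
        weighted=weighted.data[:, 0].copy(),
        scaled=scaled.data[:, 0].copy(),
    )
    return x_comp, trace


def attention_electronic_embedding(x_N: Tensor, s: int, params: dict,
                                   component: str) -> Tensor:
    """Attention-style electronic embedding (queries from x_N, keys/values
    from two independent linear maps of the scalar s); softplus weights are
    normalized over atoms, and the output scales with s."""
    n, F = x_N.shape
    if n == 0:
        raise InvalidInputError("empty system")
    q = _linear(x_N, params, f"{component}.query")  # (n, F)
    key = params[f"{component}.key.w"] * float(s) + params[f"{component}.key.b"]  # (F,)
    value = params[f"{component}.value.w"] * float(s) + params[f"{component}.value.b"]
    logits = (q * key).sum(axis=1, keepdims=True) * (1.0 / np.sqrt(F))
    w = softplus(logits)
    w = w / w.sum()
    return w * (value * float(s))


def compose_initial(x_N: Tensor, x_Q: Tensor, x_S: Tensor, params: dict) -> Tensor:
    """x⁰ = ResidualBlock(x_N + x_Q + x_S)."""
    if x_N.shape != x_Q.shape or x_N.shape != x_S.shape:
        raise InvalidInputError(
            f"feature widths differ: {x_N.shape}, {x_Q.shape}, {x_S.shape}"
        )
    return residual_block(x_N + x_Q + x_S, params, "res")


def build_embeddings(atomic_numbers, total_charge: int, spin_state: int,
                     params: dict, variant: str) -> tuple[Tensor, EmbeddingSet]:
    """Full embedding pass for one molecule; returns x⁰ and the component set."""
    if variant not in VARIANTS:
        raise InvalidInputError(f"unknown embedding variant {variant!r}")
    x_N = nuclear_embedding(atomic_numbers, params)
    n, F = x_N.shape
    zero = Tensor(np.zeros((n, F)))
    if variant == "nuclear_only":
        x_Q, x_S = zero, Tensor(np.zeros((n, F)))
    elif variant == "scaled":
        x_Q, _ = scaled_electronic_embedding(x_N, total_charge, params, "Q")
        x_S, _ = scaled_electronic_embedding(x_N, spin_state, params, "S")
    else:
        x_Q = attention_electronic_embedding(x_N, total_charge, params, "Q")
        x_S = attention_electronic_embedding(x_N, spin_state, params, "S")
    x0 = compose_initial(x_N, x_Q, x_S, params)
    x_z = params["element_table"].data[np.asarray(atomic_numbers, dtype=int)]
    es = EmbeddingSet(x_z=x_z, x_ez=x_N.data - x_z, x_N=x_N.data.copy(),
                      x_Q=x_Q.data.copy(), x_S=x_S.data.copy(), x0=x0.data.copy())
    return x0, es
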