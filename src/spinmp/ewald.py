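"""Aperiodic Ewald-style long-range message passing.

Per-atom features are projected onto a truncated frequency grid through
structure factors

    s(k) = Σ_j h_j · exp(i k·r_j),

multiplied by learned per-frequency filters w(k) (tied across ±k so every
output stays real), and projected back:

    m_i = (1/|K|) Σ_k Re[ exp(−i k·r_i) · s(k) ] ⊙ w(k).

The wave-vector set contains every nonzero integer multiple of 2π/L inside
|k| ≤ k_cut, where L is a bounding-box edge derived from the molecular
extent.  Because phases enter only through k·(r_j − r_i), the messages are
exactly translation invariant; rotational invariance is obtained by
canonicalizing coordinates to a principal-axes frame before phase evaluation
(see :func:`spinmp.molecular.canonical_frame`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .errors import ConfigurationError, EmptyGridError, InvalidInputError

TWO_PI = 2.0 * np.pi


@dataclass
class KGrid:
    """Truncated frequency lattice, closed under negation, sorted lexically."""

    k_vectors: np.ndarray  # (n_k, 3), Å⁻¹
    L: float  # bounding-box edge, Å
    k_cut: float  # Å⁻¹
    neg_index: np.ndarray = field(default=None)  # index of −k for each k
    half_index: np.ndarray = field(default=None)  # map k → its ±k pair id

    @property
    def n_k(self) -> int:
        return len(self.k_vectors)

    @property
    def n_half(self) -> int:
        return self.n_k // 2


def build_kgrid(L: float, k_cut: float) -> KGrid:
    """Enumerate nonzero integer multiples of 2π/L with |k| ≤ k_cut."""
    if L <= 0 or k_cut <= 0:
        raise InvalidInputError("L and k_cut must be positive")
    base = TWO_PI / L
    n_max = int(np.floor(k_cut / base))
    if n_max < 1:
        raise EmptyGridError(f"k_cut {k_cut:g} admits no vector for L {L:g}")
    rng_ = np.arange(-n_max, n_max + 1)
    grid = np.stack(np.meshgrid(rng_, rng_, rng_, indexing="ij"), axis=-1).reshape(-1, 3)
    grid = grid[np.any(grid != 0, axis=1)]
    grid = grid[np.linalg.norm(grid, axis=1) * base <= k_cut + 1e-12]
    if len(grid) == 0:
        raise EmptyGridError(f"k_cut {k_cut:g} admits no vector for L {L:g}")
    order = np.lexsort((grid[:, 2], grid[:, 1], grid[:, 0]))
    grid = grid[order]
    # pair each k with its negation; representative = lexicographically larger
    key = {tuple(v): i for i, v in enumerate(grid)}
    neg = np.array([key[tuple(-v)] for v in grid], dtype=int)
    half_id = np.full(len(grid), -1, dtype=int)
    nxt = 0
    for i in range(len(grid)):
        if half_id[i] < 0:
            half_id[i] = half_id[neg[i]] = nxt
            nxt += 1
    return KGrid(k_vectors=grid * base, L=float(L), k_cut=float(k_cut),
                 neg_index=neg, half_index=half_id)


def init_ewald_params(rng: np.random.Generator, F: int, kgrid: KGrid) -> dict[str, Tensor]:
    """Free learned filter vectors per ±k pair plus the atomwise output map."""
    p = {"filters.half": Tensor.param(rng.normal(0, 0.5, (kgrid.n_half, F)))}
    p["out.W"] = Tensor.param(rng.normal(0, 1 / np.sqrt(F), (F, F)))
    p["out.b"] = Tensor.param(np.zeros(F))
    p["update.W"] = Tensor.param(np.zeros((F, F)))  # residual starts as identity
    p["update.b"] = Tensor.param(np.zeros(F))
    return p


def expand_filters(params: dict, kgrid: KGrid) -> Tensor:
    """(n_k, F) filter matrix, tied across ±k by construction."""
    return params["filters.half"].take_rows(kgrid.half_index)


def structure_factors(h, positions, kgrid: KGrid) -> np.ndarray:
    """s(k) = Σ_j h_j exp(i k·r_j) as a complex (n_k, F) array."""
    h_arr = h.data if isinstance(h, Tensor) else np.asarray(h, dtype=float)
    pos = np.asarray(positions, dtype=float)
    if len(h_arr) != len(pos):
        raise InvalidInputError("feature rows and positions disagree")
    phase = np.exp(1j * pos @ kgrid.k_vectors.T)  # (n, n_k)
    return phase.T @ h_arr.astype(complex)


def ewald_message(h, positions, kgrid: KGrid, filters) -> Tensor:
    """Per-atom long-range messages; real whenever filters are ±k-tied.

    ``filters`` is either the Tensor returned by :func:`expand_filters`
    (tied by construction) or a raw (n_k, F) array, in which case tying is
    verified and untied filters are rejected.
    """
    if not isinstance(filters, Tensor):
        filters = np.asarray(filters, dtype=float)
        if not np.allclose(filters, filters[kgrid.neg_index], atol=1e-12):
            raise ConfigurationError("frequency filters must be tied across ±k")
        filters = Tensor(filters)
    h_t = h if isinstance(h, Tensor) else Tensor(np.asarray(h, dtype=float))
    pos = np.asarray(positions, dtype=float)
    kr = pos @ kgrid.k_vectors.T  # (n, n_k)
    c, s = Tensor(np.cos(kr)), Tensor(np.sin(kr))
    re_s = Tensor(c.data.T) @ h_t  # Re s(k), (n_k, F)
    im_s = Tensor(s.data.T) @ h_t  # Im s(k)
    return (c @ (filters * re_s) + s @ (filters * im_s)) * (1.0 / kgrid.n_k)
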