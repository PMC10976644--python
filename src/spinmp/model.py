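"""Assembly of embeddings, short-range interactions and the optional
frequency-space long-range block into a single energy model.

Three coupling modes mirror the model families compared in the package:

``base``
    x⁰ feeds a stack of T short-range interactions only.
``shared_plus``
    One hidden stream; every iteration applies a short-range interaction and
    then a long-range (Ewald) update to the same state, so both interaction
    families share the same embeddings throughout.
``split_comma``
    Two independent streams: the nuclear embeddings x_N⁰ are updated only by
    short-range interactions while the electronic embeddings x_E⁰ = x_Q⁰+x_S⁰
    are updated only by Ewald blocks; the streams are summed before readout.

Energies are reported in eV as a sum of atomwise contributions plus fitted
per-element reference energies (subtracted before training, re-added at
prediction).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .autodiff import Tensor, softplus
from .embeddings import (
    SUPPORTED_Z_MAX,
    VARIANTS,
    attention_electronic_embedding,
    compose_initial,
    init_embedding_params,
    nuclear_embedding,
    residual_block,
    scaled_electronic_embedding,
)
from .errors import ConfigurationError, PairingError
from .ewald import TWO_PI, build_kgrid, expand_filters, ewald_message, init_ewald_params
from .molecular import Molecule, SpinLabel, build_neighbor_list, canonical_frame
from .short_range import (
    EdgeFeatures,
    HiddenState,
    init_interaction_params,
    message_step,
    rbf_expand,
    update_step,
)

COUPLINGS = ("base", "shared_plus", "split_comma")


@dataclass
class ModelConfig:
    embedding_variant: str = "scaled"
    coupling: str = "base"
    F: int = 32
    T: int = 3
    n_rbf: int = 20
    cutoff: float = 5.0  # Å
    k_max: float = 3.6  # frequency radius in units of 2π/L (|K| ≈ 180)
    box_margin: float = 2.0  # L = extent + box_margin · cutoff
    ewald_order: str = "interleave"  # shared_plus: interleave | append
    seed: int = 0

    def validate(self) -> None:
        if self.embedding_variant not in VARIANTS:
            raise ConfigurationError(f"unknown embedding variant {self.embedding_variant!r}")
        if self.coupling not in COUPLINGS:
            raise ConfigurationError(f"unknown coupling {self.coupling!r}")
        if self.coupling == "split_comma" and self.embedding_variant == "nuclear_only":
            raise ConfigurationError(
                "split_comma feeds the electronic embeddings to the Ewald stream; "
                "nuclear_only has none"
            )
        if self.ewald_order not in ("interleave", "append"):
            raise ConfigurationError(f"unknown ewald_order {self.ewald_order!r}")


@dataclass
class EnergyPrediction:
    total_energy: float  # eV
    per_atom_contributions: np.ndarray  # eV


def _lin(x: Tensor, p: dict, name: str) -> Tensor:
    return x @ p[f"{name}.W"] + p[f"{name}.b"]


class SpinPotential:
    """A charge/spin-aware message-passing potential."""

    def __init__(self, cfg: ModelConfig):
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.emb = init_embedding_params(rng, cfg.F, cfg.embedding_variant)
        self.interactions = [init_interaction_params(rng, cfg.F, cfg.n_rbf)
                             for _ in range(cfg.T)]
        self.ewald_blocks: list[dict] = []
        if cfg.coupling != "base":
            # integer-unit template fixes the ±k pairing shared by all grids
            self._kgrid_template = build_kgrid(TWO_PI, cfg.k_max)
            self.ewald_blocks = [init_ewald_params(rng, cfg.F, self._kgrid_template)
                                 for _ in range(cfg.T)]
        self.readout = {}
        for name, (fi, fo) in (("ro.0", (cfg.F, cfg.F)), ("ro.1", (cfg.F, 1))):
            self.readout[f"{name}.W"] = Tensor.param(rng.normal(0, 1 / np.sqrt(fi), (fi, fo)))
            self.readout[f"{name}.b"] = Tensor.param(np.zeros(fo))
        self.element_baseline = np.zeros(SUPPORTED_Z_MAX + 1)

    # -- parameters --------------------------------------------------------
    def parameters(self) -> list[Tensor]:
        out = list(self.emb.values()) + list(self.readout.values())
        for p in self.interactions + self.ewald_blocks:
            out.extend(p.values())
        return out

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    # -- forward -----------------------------------------------------------
    def _embed(self, mol: Molecule) -> tuple[Tensor, Tensor]:
        """Return (x_N, x_E) for one molecule."""
        x_N = nuclear_embedding(mol.atomic_numbers, self.emb)
        variant = self.cfg.embedding_variant
        if variant == "nuclear_only":
            zeros = Tensor(np.zeros(x_N.shape))
            return x_N, zeros
        if variant == "scaled":
            x_Q, _ = scaled_electronic_embedding(x_N, mol.total_charge, self.emb, "Q")
            x_S, _ = scaled_electronic_embedding(x_N, mol.spin_state, self.emb, "S")
        else:
            x_Q = attention_electronic_embedding(x_N, mol.total_charge, self.emb, "Q")
            x_S = attention_electronic_embedding(x_N, mol.spin_state, self.emb, "S")
        return x_N, x_Q + x_S

    def _kgrid(self, positions: np.ndarray):
        if len(positions) > 1:
            diff = positions[:, None, :] - positions[None, :, :]
            extent = float(np.sqrt((diff**2).sum(-1)).max())
        else:
            extent = 0.0
        L = extent + self.cfg.box_margin * self.cfg.cutoff
        return build_kgrid(L, self.cfg.k_max * TWO_PI / L)

    def _ewald_update(self, state: HiddenState, canon_pos, kgrid, block) -> HiddenState:
        m = ewald_message(state.h, canon_pos, kgrid, expand_filters(block, kgrid))
        u = softplus(m @ block["out.W"] + block["out.b"]) @ block["update.W"] + block["update.b"]
        return HiddenState(h=state.h + u, step=state.step)

    def forward_residual(self, mol: Molecule) -> Tensor:
        """Atomwise readout sum (eV) *before* the per-element baseline."""
        cfg = self.cfg
        x_N, x_E = self._embed(mol)
        nl = build_neighbor_list(mol, cfg.cutoff)
        if len(nl.pairs):
            ef = rbf_expand(nl.distances, cfg.n_rbf, cfg.cutoff)
        else:
            ef = EdgeFeatures(rbf=np.zeros((0, cfg.n_rbf)), cutoff_weight=np.zeros(0))
        canon_pos = kgrid = None
        if cfg.coupling != "base":
            canon_pos = canonical_frame(mol.positions)
            kgrid = self._kgrid(mol.positions)

        if cfg.coupling == "split_comma":
            sa = HiddenState(residual_block(x_N, self.emb, "res"))
            sb = HiddenState(residual_block(x_E, self.emb, "res"))
            for t in range(cfg.T):
                sa = update_step(sa, message_step(sa, nl, ef, self.interactions[t]),
                                 self.interactions[t])
                sb = self._ewald_update(sb, canon_pos, kgrid, self.ewald_blocks[t])
            h = sa.h + sb.h
        else:
            state = HiddenState(compose_initial(x_N, x_E, Tensor(np.zeros(x_N.shape)),
                                                self.emb))
            if cfg.coupling == "shared_plus" and cfg.ewald_order == "append":
                for t in range(cfg.T):
                    state = update_step(state, message_step(state, nl, ef,
                                                            self.interactions[t]),
                                        self.interactions[t])
                for t in range(cfg.T):
                    state = self._ewald_update(state, canon_pos, kgrid,
                                               self.ewald_blocks[t])
            else:
                for t in range(cfg.T):
                    state = update_step(state, message_step(state, nl, ef,
                                                            self.interactions[t]),
                                        self.interactions[t])
                    if cfg.coupling == "shared_plus":
                        state = self._ewald_update(state, canon_pos, kgrid,
                                                   self.ewald_blocks[t])
            h = state.h
        per_atom = _lin(softplus(_lin(h, self.readout, "ro.0")), self.readout, "ro.1")
        return per_atom  # (n, 1) Tensor

    def forward_energy(self, mol: Molecule) -> EnergyPrediction:
        per_atom = self.forward_residual(mol).data[:, 0]
        contrib = per_atom + self.element_baseline[mol.atomic_numbers]
        return EnergyPrediction(total_energy=float(contrib.sum()),
                                per_atom_contributions=contrib)

    def predict_splitting(self, hs: Molecule, ls: Molecule) -> float:
        """ΔE_HS−LS in eV; positive means the LS state is the ground state."""
        if hs.spin_label != SpinLabel.HS or ls.spin_label != SpinLabel.LS:
            raise PairingError("arguments must be (HS, LS) labelled molecules")
        if hs.config_id != ls.config_id:
            raise PairingError(
                f"config mismatch: {hs.config_id!r} vs {ls.config_id!r}"
            )
        return self.forward_energy(hs).total_energy - self.forward_energy(ls).total_energy

    # -- persistence --------------------------------------------------------
    def state_dict(self) -> dict:
        def grp(d):
            return {k: v.data.tolist() for k, v in d.items()}

        return {
            "config": asdict(self.cfg),
            "element_baseline": self.element_baseline.tolist(),
            "embeddings": grp(self.emb),
            "interactions": [grp(p) for p in self.interactions],
            "ewald_blocks": [grp(p) for p in self.ewald_blocks],
            "readout": grp(self.readout),
        }

    def load_state_dict(self, state: dict) -> None:
        def setgrp(dst, src):
            for k, v in src.items():
                dst[k].data = np.asarray(v, dtype=float)

        self.element_baseline = np.asarray(state["element_baseline"], dtype=float)
        setgrp(self.emb, state["embeddings"])
        for p, s in zip(self.interactions, state["interactions"]):
            setgrp(p, s)
        for p, s in zip(self.ewald_blocks, state["ewald_blocks"]):
            setgrp(p, s)
        setgrp(self.readout, state["readout"])

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.state_dict(), fh)

    @classmethod
    def load(cls, path) -> "SpinPotential":
        with open(path) as fh:
            state = json.load(fh)
        model = cls(ModelConfig(**state["config"]))
        model.load_state_dict(state)
        return model


def build_model(cfg: ModelConfig) -> SpinPotential:
    """Construct a model; same seed + config ⇒ bit-identical predictions."""
    return SpinPotential(cfg)
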