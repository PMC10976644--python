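"""Deterministic training of the potential models.

Energies are reduced to residuals of a least-squares per-element baseline
(E ≈ Σ_Z count_Z·μ_Z) before optimization, which removes the large
composition-dependent offset and conditions the regression; the baseline is
re-added at prediction.  Optimization is AdamW with either a
milestone-with-warmup or a plateau learning-rate schedule.  All randomness
flows from the config seed, so two runs with identical seeds produce
identical logs and parameters.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field

import numpy as np

from .autodiff import AdamW, concat_rows
from .errors import DataError
from .model import SpinPotential
from .molecular import DatasetRecord, SplitTag

logger = logging.getLogger(__name__)

#: step count of the full-scale schedule the milestone defaults refer to;
#: warmup and milestones are rescaled proportionally for shorter runs.
SCHEDULE_REFERENCE_STEPS = 400_000


@dataclass
class TrainConfig:
    batch_size: int = 16
    lr0: float = 5e-4
    scheduler: str = "milestone_warmup"  # or "plateau"
    warmup_steps: int = 50_000
    warmup_factor: float = 0.2
    milestones: tuple = (150_000, 25_000, 350_000)  # normalized (sorted) on use
    decay: float = 0.1
    plateau_decay: float = 0.5
    plateau_patience: int = 10
    max_steps: int = 2500
    seed: int = 0
    loss: str = "mse"  # training loss; MAE is always reported
    weight_decay: float = 0.01
    scale_schedule: bool = True  # shrink warmup/milestones to max_steps

    def normalized_milestones(self) -> list[int]:
        return sorted(int(m) for m in self.milestones)

    def effective_schedule(self) -> tuple[int, list[int]]:
        """(warmup_steps, milestones) actually used for this run length."""
        ms = self.normalized_milestones()
        if not self.scale_schedule:
            return self.warmup_steps, ms
        scale = self.max_steps / SCHEDULE_REFERENCE_STEPS
        return max(1, round(self.warmup_steps * scale)), [
            max(1, round(m * scale)) for m in ms
        ]


@dataclass
class TrainLog:
    seed: int
    config_hash: str
    notes: list = field(default_factory=list)
    epochs: list = field(default_factory=list)  # dicts: train_loss, val_mae, lr
    lr_trace: list = field(default_factory=list)  # per-step lr factor
    wall_time_s: float = 0.0


def lr_factor_milestone_warmup(step: int, cfg: TrainConfig) -> float:
    """Linear ramp warmup_factor → 1 over the warmup, ×decay at milestones."""
    warmup, milestones = cfg.effective_schedule()
    if step < warmup:
        ramp = cfg.warmup_factor + (1.0 - cfg.warmup_factor) * step / warmup
    else:
        ramp = 1.0
    n_passed = sum(1 for m in milestones if step >= m)
    return ramp * cfg.decay**n_passed


def lr_plateau(val_history, cfg: TrainConfig) -> float:
    """Multiplicative factor after replaying a validation-loss history."""
    if len(val_history) == 0:
        raise DataError("empty validation history")
    factor, best, bad = 1.0, np.inf, 0
    for v in val_history:
        if v < best:
            best, bad = v, 0
        else:
            bad += 1
            if bad >= cfg.plateau_patience:
                factor *= cfg.plateau_decay
                bad = 0
    return factor


def fit_element_baseline(records) -> dict[int, float]:
    """Least-squares per-element reference energies E ≈ Σ_Z count_Z·μ_Z."""
    elems = sorted({int(z) for r in records for z in r.molecule.atomic_numbers})
    a = np.zeros((len(records), len(elems)))
    y = np.zeros(len(records))
    for i, rec in enumerate(records):
        if rec.molecule.ref_energy is None:
            raise DataError(f"record {i} has no reference energy")
        y[i] = rec.molecule.ref_energy
        zs, counts = np.unique(rec.molecule.atomic_numbers, return_counts=True)
        for z, c in zip(zs, counts):
            a[i, elems.index(int(z))] = c
    if np.linalg.matrix_rank(a) < len(elems):
        logger.warning("rank-deficient composition matrix; using pseudo-inverse")
    mu, *_ = np.linalg.lstsq(a, y, rcond=None)
    return {z: float(m) for z, m in zip(elems, mu)}


def _baseline_sum(mol, baseline: np.ndarray) -> float:
    return float(baseline[mol.atomic_numbers].sum())


def _mae(model: SpinPotential, records) -> float:
    errs = [abs(model.forward_energy(r.molecule).total_energy - r.molecule.ref_energy)
            for r in records]
    return float(np.mean(errs))


def train(model: SpinPotential, records: list[DatasetRecord],
          cfg: TrainConfig) -> tuple[SpinPotential, TrainLog]:
    """Train on records tagged ``train``, select on records tagged ``val``.

    Returns the model restored to its best-validation parameters, together
    with the per-epoch log.  With ``max_steps == 0`` the model is returned
    unchanged.
    """
    train_recs = [r for r in records if r.split_tag == SplitTag.TRAIN]
    val_recs = [r for r in records if r.split_tag == SplitTag.VAL]
    if not train_recs:
        raise DataError("no records tagged 'train'")
    missing = [i for i, r in enumerate(train_recs + val_recs)
               if r.molecule.ref_energy is None]
    if missing:
        raise DataError(f"records without reference energy: {missing[:10]}")

    cfg_hash = hashlib.sha256(
        json.dumps(asdict(cfg), sort_keys=True, default=list).encode()
    ).hexdigest()[:16]
    log = TrainLog(seed=cfg.seed, config_hash=cfg_hash)
    if cfg.normalized_milestones() != [int(m) for m in cfg.milestones]:
        log.notes.append(
            f"milestones normalized (sorted) to {cfg.normalized_milestones()}"
        )
    if cfg.max_steps == 0:
        return model, log

    mu = fit_element_baseline(train_recs)
    model.element_baseline = np.zeros_like(model.element_baseline)
    for z, m in mu.items():
        model.element_baseline[z] = m
    targets = np.array(
        [r.molecule.ref_energy - _baseline_sum(r.molecule, model.element_baseline)
         for r in train_recs]
    )

    params = model.parameters()
    opt = AdamW(params, lr=cfg.lr0, weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed)
    t0 = time.time()
    step = 0
    best_val = np.inf
    best_state = [p.data.copy() for p in params]
    val_history: list[float] = []
    plateau_factor = 1.0

    while step < cfg.max_steps:
        order = rng.permutation(len(train_recs))
        epoch_losses = []
        for b0 in range(0, len(order), cfg.batch_size):
            if step >= cfg.max_steps:
                break
            idx = order[b0 : b0 + cfg.batch_size]
            if cfg.scheduler == "milestone_warmup":
                factor = lr_factor_milestone_warmup(step, cfg)
            else:
                factor = plateau_factor
            preds = concat_rows([model.forward_residual(train_recs[i].molecule).sum(
                keepdims=True).reshape(1, 1) for i in idx])
            err = preds - targets[idx][:, None]
            loss = (err * err).mean() if cfg.loss == "mse" else None
            if loss is None:
                raise DataError(f"unknown loss {cfg.loss!r}")
            opt.zero_grad()
            loss.backward()
            opt.step(lr_factor=factor)
            log.lr_trace.append(cfg.lr0 * factor)
            epoch_losses.append(float(loss.data))
            step += 1

        val_mae = _mae(model, val_recs) if val_recs else float(np.mean(epoch_losses))
        val_history.append(val_mae)
        if cfg.scheduler == "plateau":
            plateau_factor = lr_plateau(val_history, cfg)
        if val_mae < best_val:
            best_val = val_mae
            best_state = [p.data.copy() for p in params]
        log.epochs.append({
            "train_loss": float(np.mean(epoch_losses)),
            "val_mae": val_mae,
            "lr": log.lr_trace[-1],
            "step": step,
        })

    for p, d in zip(params, best_state):
        p.data = d
    log.wall_time_s = time.time() - t0
    return model, log
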