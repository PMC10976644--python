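"""HS/LS splitting-energy evaluation protocol.

For every configuration present in a record set with conformers in *both*
spin states, the full cross product of HS × LS conformers is enumerated; each
pair carries a reference and a predicted splitting energy

    ΔE_HS−LS = E(HS conformer) − E(LS conformer)   [eV],

whose sign identifies the ground spin state (positive ⇒ low spin).  Reported
metrics are the splitting-energy MAE and the number of pairs whose predicted
sign matches the reference.  A global constant shift of all total energies
cancels in ΔE, so the splitting metrics probe relative energetics only.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .errors import DataError
from .molecular import DatasetRecord, SpinLabel

logger = logging.getLogger(__name__)

EV_PER_KCALMOL = 1.0 / 23.0605  # used only at I/O boundaries


@dataclass
class SpinPair:
    hs_record: DatasetRecord
    ls_record: DatasetRecord
    ref_dE: float | None = None  # eV, E_HS − E_LS
    pred_dE: float | None = None  # eV


@dataclass
class EvalReport:
    energy_mae: float  # eV
    splitting_mae: float  # eV
    n_pairs: int
    n_correct_spin: int
    per_config: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "energy_mae_ev": self.energy_mae,
            "splitting_mae_ev": self.splitting_mae,
            "n_pairs": self.n_pairs,
            "n_correct_spin": self.n_correct_spin,
            "per_config": self.per_config,
        }


def enumerate_spin_pairs(records) -> list[SpinPair]:
    """Cross product of HS × LS conformers per configuration.

    Total pair count is Σ_c n_HS(c)·n_LS(c); ordering is deterministic by
    (config_id, HS input index, LS input index).  Records with spin label
    NONE are excluded with a warning.
    """
    by_config: dict[str, dict[SpinLabel, list]] = defaultdict(
        lambda: {SpinLabel.HS: [], SpinLabel.LS: []}
    )
    for rec in records:
        lbl = rec.molecule.spin_label
        if lbl == SpinLabel.NONE:
            logger.warning("record with config_id=%r has no spin label; skipped",
                           rec.molecule.config_id)
            continue
        by_config[rec.molecule.config_id][lbl].append(rec)
    pairs = []
    for cid in sorted(by_config):
        groups = by_config[cid]
        for hs in groups[SpinLabel.HS]:
            for ls in groups[SpinLabel.LS]:
                ref = None
                if hs.molecule.ref_energy is not None and ls.molecule.ref_energy is not None:
                    ref = hs.molecule.ref_energy - ls.molecule.ref_energy
                pairs.append(SpinPair(hs_record=hs, ls_record=ls, ref_dE=ref))
    return pairs


def splitting_mae(pairs) -> float:
    """Mean |pred_dE − ref_dE| in eV."""
    if len(pairs) == 0:
        raise DataError("splitting MAE undefined on an empty pair list")
    for p in pairs:
        if p.pred_dE is None or p.ref_dE is None:
            raise DataError("pairs must carry both reference and predicted ΔE")
    return float(np.mean([abs(p.pred_dE - p.ref_dE) for p in pairs]))


def spin_state_accuracy(pairs) -> tuple[int, int]:
    """(n_correct, n_total): correct iff sign(pred_dE) == sign(ref_dE).

    A predicted ΔE of exactly 0 counts as correct only when the reference is
    also exactly 0.
    """
    n_correct = 0
    for p in pairs:
        if p.pred_dE is None or p.ref_dE is None:
            raise DataError("pairs must carry both reference and predicted ΔE")
        if np.sign(p.pred_dE) == np.sign(p.ref_dE):
            n_correct += 1
    return n_correct, len(pairs)


def evaluate_model(model, records) -> EvalReport:
    """Full protocol: total-energy MAE plus splitting metrics on a record set."""
    labelled = [r for r in records if r.molecule.ref_energy is not None]
    if not labelled:
        raise DataError("no records with reference energies")
    cache = {id(r): model.forward_energy(r.molecule).total_energy for r in labelled}
    energy_mae = float(np.mean([abs(cache[id(r)] - r.molecule.ref_energy)
                                for r in labelled]))
    pairs = enumerate_spin_pairs(labelled)
    per_config: dict[str, dict] = {}
    for p in pairs:
        p.pred_dE = cache[id(p.hs_record)] - cache[id(p.ls_record)]
    if pairs:
        s_mae = splitting_mae(pairs)
        n_correct, n_total = spin_state_accuracy(pairs)
        for p in pairs:
            cid = p.hs_record.molecule.config_id
            d = per_config.setdefault(cid, {"n_pairs": 0, "abs_err_sum": 0.0,
                                            "n_correct": 0})
            d["n_pairs"] += 1
            d["abs_err_sum"] += abs(p.pred_dE - p.ref_dE)
            d["n_correct"] += int(np.sign(p.pred_dE) == np.sign(p.ref_dE))
        for d in per_config.values():
            d["splitting_mae"] = d.pop("abs_err_sum") / d["n_pairs"]
    else:
        s_mae, n_correct, n_total = float("nan"), 0, 0
    return EvalReport(energy_mae=energy_mae, splitting_mae=s_mae,
                      n_pairs=n_total, n_correct_spin=n_correct,
                      per_config=per_config)
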