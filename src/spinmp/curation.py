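"""Conformer-ensemble curation: RMSD deduplication, quality filters, splits.

The filters act on *supplied* records and annotations; no quantum chemistry
is run here.  Deduplication removes near-duplicate conformers (optimal-
alignment RMSD ≤ 0.1 Å by default) in a greedy first-seen-kept pass.  The
quality filter drops structures whose reference calculation did not converge,
shows an imaginary frequency, or is spin-contaminated: the ⟨Ŝ²⟩ expectation
deviates from the ideal s(s+1) (s = unpaired electrons / 2) by more than a
dimensionless tolerance (default 1.0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, InvalidInputError, PairingError
from .molecular import DatasetRecord, SplitTag, optimal_rmsd


@dataclass
class QCAnnotation:
    converged: bool
    has_imaginary_freq: bool
    s2_actual: float
    s2_expected: float | None = None  # filled from the record's spin if None


@dataclass
class CurationReport:
    n_input: int = 0
    removed: dict = field(default_factory=dict)  # cause -> count
    n_retained: int = 0

    def telescopes(self) -> bool:
        return self.n_input == self.n_retained + sum(self.removed.values())


def expected_s2(spin_unpaired: int) -> float:
    """Ideal ⟨Ŝ²⟩ = s(s+1) with s = unpaired electrons / 2."""
    if spin_unpaired < 0:
        raise InvalidInputError("unpaired electron count must be non-negative")
    s = spin_unpaired / 2.0
    return s * (s + 1.0)


def dedup_conformers(ensemble, threshold: float = 0.1):
    """Greedy in input order: drop a conformer whose optimal RMSD to any
    already-retained conformer is ≤ threshold (Å).  Idempotent."""
    mols = [e.molecule if isinstance(e, DatasetRecord) else e for e in ensemble]
    if len({m.config_id for m in mols}) > 1:
        raise PairingError("dedup requires a single configuration")
    retained_idx: list[int] = []
    for i, mol in enumerate(mols):
        if all(optimal_rmsd(mol, mols[j]) > threshold for j in retained_idx):
            retained_idx.append(i)
    return [ensemble[i] for i in retained_idx]


def filter_qc(records, annotations, s2_tolerance: float = 1.0):
    """Drop non-converged / imaginary-frequency / spin-contaminated records.

    ``annotations`` is a parallel sequence of :class:`QCAnnotation` (None
    entries raise).  Returns (retained, CurationReport).
    """
    if len(records) != len(annotations):
        raise DataError("records and annotations differ in length")
    report = CurationReport(n_input=len(records),
                            removed={"not_converged": 0, "imaginary_freq": 0,
                                     "spin_contaminated": 0})
    retained = []
    for i, (rec, ann) in enumerate(zip(records, annotations)):
        if ann is None:
            raise DataError(f"record {i} has no QC annotation")
        exp = ann.s2_expected
        if exp is None:
            exp = expected_s2(rec.molecule.spin_state)
        if not ann.converged:
            report.removed["not_converged"] += 1
        elif ann.has_imaginary_freq:
            report.removed["imaginary_freq"] += 1
        elif abs(ann.s2_actual - exp) > s2_tolerance:
            report.removed["spin_contaminated"] += 1
        else:
            retained.append(rec)
    report.n_retained = len(retained)
    return retained, report


def split_dataset(records, sizes=None, fractions=None, seed: int = 0):
    """Random disjoint train/val/test assignment, deterministic per seed.

    Exactly one of ``sizes`` (train, val, test counts summing to the record
    count) or ``fractions`` (summing to 1; sizes are floored with the
    remainder assigned to train) must be given.  Tags are written in place
    and the records are returned.
    """
    n = len(records)
    if (sizes is None) == (fractions is None):
        raise InvalidInputError("give exactly one of sizes or fractions")
    if fractions is not None:
        if not np.isclose(sum(fractions), 1.0):
            raise InvalidInputError("fractions must sum to 1")
        sizes = [int(np.floor(f * n)) for f in fractions]
        sizes[0] += n - sum(sizes)
    sizes = [int(s) for s in sizes]
    if len(sizes) != 3 or any(s < 0 for s in sizes) or sum(sizes) != n:
        raise InvalidInputError(f"sizes {sizes} incompatible with {n} records")
    perm = np.random.default_rng(seed).permutation(n)
    tags = ([SplitTag.TRAIN] * sizes[0] + [SplitTag.VAL] * sizes[1]
            + [SplitTag.TEST] * sizes[2])
    for pos, tag in zip(perm, tags):
        records[pos].split_tag = tag
    return records
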