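"""Domain types, geometry utilities and extended-XYZ I/O.

A :class:`Molecule` is a single metal-complex structure: atomic numbers,
Cartesian coordinates in Å, the total charge ``Q`` (elementary charges) and
the spin state ``S`` (number of unpaired electrons; Fe(II) low spin → 0,
high spin → 4), plus bookkeeping metadata.  Conformers of the same ligand
configuration share a ``config_id`` and an atom ordering, which is what makes
index-wise RMSD superposition and HS/LS pairing well defined downstream.
"""

from __future__ import annotations

import logging
import shlex
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import (
    ExtXYZParseError,
    IncompatibleStructuresError,
    InvalidInputError,
)

logger = logging.getLogger(__name__)

# fmt: off
ELEMENT_SYMBOLS = (
    "X", "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar", "K", "Ca",
    "Sc", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn",
    "Ga", "Ge", "As", "Se", "Br", "Kr",
)
# fmt: on
SYMBOL_TO_Z = {s: z for z, s in enumerate(ELEMENT_SYMBOLS) if z > 0}


class SpinLabel(str, Enum):
    HS = "HS"
    LS = "LS"
    NONE = "NONE"


class SplitTag(str, Enum):
    TRAIN = "train"
    VAL = "val"
    TEST = "test"
    NONE = "none"


@dataclass
class Molecule:
    """One structure with per-structure electronic metadata."""

    atomic_numbers: np.ndarray  # (n,) int
    positions: np.ndarray  # (n, 3) float, Å
    total_charge: int = 0
    spin_state: int = 0
    config_id: str = ""
    spin_label: SpinLabel = SpinLabel.NONE
    ref_energy: float | None = None  # eV

    def __post_init__(self):
        self.atomic_numbers = np.asarray(self.atomic_numbers, dtype=int)
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if isinstance(self.spin_label, str):
            self.spin_label = SpinLabel(self.spin_label)
        if len(self.atomic_numbers) != len(self.positions) or len(self.positions) < 1:
            raise InvalidInputError("atomic_numbers and positions must match and be non-empty")
        if np.any(self.atomic_numbers < 1):
            raise InvalidInputError("atomic numbers must be >= 1")

    @property
    def n_atoms(self) -> int:
        return len(self.atomic_numbers)

    def validate_spin_parity(self) -> None:
        """Check N_electrons − S is even (unpaired electrons come in excess)."""
        n_el = int(self.atomic_numbers.sum()) - self.total_charge
        if (n_el - self.spin_state) % 2 != 0:
            raise InvalidInputError(
                f"spin state {self.spin_state} inconsistent with {n_el} electrons"
            )

    def copy(self, **updates) -> "Molecule":
        mol = replace(self, **updates)
        mol.positions = np.array(mol.positions, dtype=float)
        mol.atomic_numbers = np.array(mol.atomic_numbers, dtype=int)
        return mol


@dataclass
class NeighborList:
    """Directed within-cutoff pairs with displacements r_j − r_i."""

    pairs: np.ndarray  # (m, 2) int, directed (i, j)
    distances: np.ndarray  # (m,) float, Å
    displacement_vectors: np.ndarray  # (m, 3) float, Å
    cutoff: float


@dataclass
class DatasetRecord:
    molecule: Molecule
    split_tag: SplitTag = SplitTag.NONE
    provenance: dict = field(default_factory=dict)


def build_neighbor_list(mol: Molecule, cutoff: float) -> NeighborList:
    """All directed atom pairs with 0 < d_ij ≤ cutoff.

    Uses a KD-tree for the candidate search; the returned distances are exact
    recomputations from the coordinates.
    """
    if cutoff <= 0:
        raise InvalidInputError("cutoff must be positive")
    pos = mol.positions
    if not np.all(np.isfinite(pos)):
        raise InvalidInputError("non-finite coordinates")
    from scipy.spatial import cKDTree

    tree = cKDTree(pos)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")  # undirected i<j
    if len(pairs) == 0:
        return NeighborList(
            pairs=np.zeros((0, 2), dtype=int),
            distances=np.zeros(0),
            displacement_vectors=np.zeros((0, 3)),
            cutoff=float(cutoff),
        )
    directed = np.concatenate([pairs, pairs[:, ::-1]], axis=0)
    order = np.lexsort((directed[:, 1], directed[:, 0]))
    directed = directed[order]
    disp = pos[directed[:, 1]] - pos[directed[:, 0]]
    dist = np.linalg.norm(disp, axis=1)
    return NeighborList(pairs=directed, distances=dist,
                        displacement_vectors=disp, cutoff=float(cutoff))


def optimal_rmsd(a: Molecule, b: Molecule) -> float:
    """Minimum RMSD over proper rotations + translations (Kabsch).

    Atom correspondence is by index; conformers from the same ensemble share
    atom order.  Reflections are excluded — mirror images are distinct
    conformers.
    """
    if a.n_atoms != b.n_atoms:
        raise IncompatibleStructuresError(
            f"atom counts differ: {a.n_atoms} vs {b.n_atoms}"
        )
    if sorted(a.atomic_numbers.tolist()) != sorted(b.atomic_numbers.tolist()):
        raise IncompatibleStructuresError("element multisets differ")
    pa = a.positions - a.positions.mean(axis=0)
    pb = b.positions - b.positions.mean(axis=0)
    if a.n_atoms == 1:
        return 0.0
    rot, _ = Rotation.align_vectors(pa, pb)
    # recompute from the aligned coordinates: scipy's rssd loses precision
    # near zero, and exact zeros matter for duplicate detection
    return float(np.sqrt(((rot.apply(pb) - pa) ** 2).sum(axis=1).mean()))


def canonical_frame(positions: np.ndarray) -> np.ndarray:
    """Rotate/translate coordinates into a deterministic principal-axes frame.

    The frame diagonalizes the gyration tensor; each axis sign is fixed so the
    third central moment along it is non-negative (falling back to +1 when the
    moment vanishes), and handedness is enforced with a cross product so the
    map is a proper rigid motion.  Two structures related by a proper rigid
    motion map to identical canonical coordinates, which is what makes the
    frequency-space block exactly E(3) invariant.
    """
    pos = np.asarray(positions, dtype=float)
    centered = pos - pos.mean(axis=0)
    if len(pos) == 1:
        return centered
    gyr = centered.T @ centered
    _, vecs = np.linalg.eigh(gyr)
    vecs = vecs[:, ::-1]  # descending variance
    proj = centered @ vecs
    for ax in range(3):
        m3 = np.sum(proj[:, ax] ** 3)
        if m3 < -1e-10:
            vecs[:, ax] = -vecs[:, ax]
    vecs[:, 2] = np.cross(vecs[:, 0], vecs[:, 1])
    return centered @ vecs


# ---------------------------------------------------------------------------
# Extended-XYZ I/O
# ---------------------------------------------------------------------------

_FRAME_KEYS = ("energy", "charge", "spin", "config_id", "spin_label", "split")


def _format_value(v) -> str:
    s = str(v)
    if " " in s or "=" in s or s == "":
        return f'"{s}"'
    return s


def write_extxyz(records: Iterable[DatasetRecord], path) -> None:
    """Write records as ase-compatible extended XYZ (energies eV, coords Å)."""
    with open(path, "w") as fh:
        for rec in records:
            mol = rec.molecule
            fields = {
                "Properties": "species:S:1:pos:R:3",
                "charge": mol.total_charge,
                "spin": mol.spin_state,
                "config_id": mol.config_id or "none",
                "spin_label": mol.spin_label.value,
                "split": rec.split_tag.value,
            }
            if mol.ref_energy is not None:
                fields["energy"] = f"{mol.ref_energy:.12f}"
            comment = " ".join(f"{k}={_format_value(v)}" for k, v in fields.items())
            fh.write(f"{mol.n_atoms}\n{comment}\n")
            for z, (x, y, zz) in zip(mol.atomic_numbers, mol.positions):
                fh.write(f"{ELEMENT_SYMBOLS[z]} {x:.10f} {y:.10f} {zz:.10f}\n")


def _parse_comment(line: str, frame: int) -> dict:
    out = {}
    try:
        tokens = shlex.split(line)
    except ValueError as exc:
        raise ExtXYZParseError(f"unparseable comment line: {exc}", frame)
    for tok in tokens:
        if "=" in tok:
            k, v = tok.split("=", 1)
            out[k] = v
    return out


def read_extxyz(path) -> list[DatasetRecord]:
    """Read an extended-XYZ file into dataset records.

    Missing ``charge``/``spin`` keys default to 0 with a logged warning;
    missing ``energy`` leaves ``ref_energy`` unset.
    """
    records: list[DatasetRecord] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i, frame = 0, 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise ExtXYZParseError(f"expected atom count, got {lines[i]!r}", frame)
        if i + 1 >= len(lines):
            raise ExtXYZParseError("truncated frame", frame)
        meta = _parse_comment(lines[i + 1], frame)
        body = lines[i + 2 : i + 2 + n]
        if len(body) < n:
            raise ExtXYZParseError(f"declared {n} atoms but file ends early", frame)
        zs, pos = [], []
        for ln in body:
            parts = ln.split()
            if len(parts) < 4:
                raise ExtXYZParseError(f"bad atom line {ln!r}", frame)
            sym = parts[0]
            if sym not in SYMBOL_TO_Z:
                try:
                    zs.append(int(sym))
                except ValueError:
                    raise ExtXYZParseError(f"unknown element {sym!r}", frame)
            else:
                zs.append(SYMBOL_TO_Z[sym])
            try:
                pos.append([float(parts[1]), float(parts[2]), float(parts[3])])
            except ValueError:
                raise ExtXYZParseError(f"bad coordinates in {ln!r}", frame)
        for key, default in (("charge", 0), ("spin", 0)):
            if key not in meta:
                logger.warning("frame %d: missing %s key, defaulting to %d", frame, key, default)
        mol = Molecule(
            atomic_numbers=np.array(zs),
            positions=np.array(pos),
            total_charge=int(float(meta.get("charge", 0))),
            spin_state=int(float(meta.get("spin", 0))),
            config_id=meta.get("config_id", ""),
            spin_label=SpinLabel(meta.get("spin_label", "NONE")),
            ref_energy=float(meta["energy"]) if "energy" in meta else None,
        )
        if mol.config_id == "none":
            mol.config_id = ""
        records.append(
            DatasetRecord(molecule=mol, split_tag=SplitTag(meta.get("split", "none")))
        )
        i += 2 + n
        frame += 1
    return records
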