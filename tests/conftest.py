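import numpy as np
import pytest

from spinmp.molecular import Molecule, SpinLabel


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_molecule(rng, n_atoms=None, box=8.0, elements=(1, 6, 7, 8, 16, 26),
                    charge=None, spin=None, min_sep=0.8):
    """Random well-separated molecule inside a cubic box."""
    if n_atoms is None:
        n_atoms = int(rng.integers(2, 9))
    pos = []
    while len(pos) < n_atoms:
        cand = rng.uniform(0, box, 3)
        if all(np.linalg.norm(cand - p) > min_sep for p in pos):
            pos.append(cand)
    return Molecule(
        atomic_numbers=rng.choice(elements, size=n_atoms),
        positions=np.array(pos),
        total_charge=int(rng.integers(-1, 3)) if charge is None else charge,
        spin_state=int(rng.choice([0, 4])) if spin is None else spin,
        config_id="rand",
        spin_label=SpinLabel.NONE,
    )
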