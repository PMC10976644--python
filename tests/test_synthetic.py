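"""Toy complex generator and its closed-form reference energy."""

import numpy as np
import pytest
from scipy import stats
from scipy.spatial.transform import Rotation

from spinmp.errors import SingularGeometryError
from spinmp.molecular import Molecule, SpinLabel
from spinmp.synthetic import (
    ToyParams,
    generate_complex,
    irreducible_error_bound,
    make_spin_dataset,
    toy_energy,
)

P = ToyParams()


def _loop_energy(mol, params=P):
    z, pos = mol.atomic_numbers, mol.positions
    n = len(z)
    e = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            d = np.linalg.norm(pos[i] - pos[j])
            eps = params.epsilon(z[i], z[j])
            sig = params.sigma(z[i], z[j])
            e += 4 * eps * ((sig / d) ** 12 - (sig / d) ** 6)
            e += mol.total_charge * params.alpha * (z[i] / 10) * (z[j] / 10) / d
    r_mean = np.mean([np.linalg.norm(pos[k] - pos[0]) for k in range(1, n)])
    return e + mol.spin_state * (params.beta0 + params.beta1 * r_mean)


class TestToyEnergy:
    def test_neutral_singlet_is_pure_short_range(self, rng):
        mol = generate_complex(6, [6] * 6, Q=0, S=0, seed=1).molecule
        charged = mol.copy(total_charge=2)
        lj_only = toy_energy(mol)
        assert toy_energy(charged) != lj_only
        # with Q = 0 and S = 0 both extra terms vanish exactly
        assert lj_only == pytest.approx(
            _loop_energy(mol.copy(total_charge=0, spin_state=0)), abs=1e-12)

    def test_spin_term_is_exactly_linear(self):
        mol = generate_complex(6, [7] * 6, Q=1, S=0, seed=2).molecule
        hs = mol.copy(spin_state=4)
        r_mean = np.mean(np.linalg.norm(mol.positions[1:] - mol.positions[0], axis=1))
        assert toy_energy(hs) - toy_energy(mol) == pytest.approx(
            4 * (P.beta0 + P.beta1 * r_mean), abs=1e-12)

    def test_matches_term_by_term_loop(self, rng):
        mol = Molecule(rng.choice([1, 6, 7, 8, 26], 5),
                       rng.uniform(0, 4, (5, 3)), total_charge=2, spin_state=4)
        assert toy_energy(mol) == pytest.approx(_loop_energy(mol), abs=1e-10)

    def test_euclidean_and_ligand_permutation_invariance(self, rng):
        mol = generate_complex(6, [6, 7, 8, 6, 7, 8], Q=1, S=4, seed=5).molecule
        e0 = toy_energy(mol)
        rot = Rotation.random(random_state=2).as_matrix()
        moved = mol.copy(positions=mol.positions @ rot.T + [5.0, 1.0, -2.0])
        assert toy_energy(moved) == pytest.approx(e0, abs=1e-10)
        perm = np.concatenate([[0], 1 + rng.permutation(6)])  # metal stays first
        permuted = mol.copy(positions=mol.positions[perm],
                            atomic_numbers=mol.atomic_numbers[perm])
        assert toy_energy(permuted) == pytest.approx(e0, abs=1e-10)

    def test_coincident_atoms_rejected(self):
        mol = Molecule([6, 6], np.zeros((2, 3)))
        with pytest.raises(SingularGeometryError):
            toy_energy(mol)


class TestGenerator:
    def test_deterministic_per_seed(self):
        a = generate_complex(6, [6] * 6, Q=0, S=0, seed=9).molecule
        b = generate_complex(6, [6] * 6, Q=0, S=0, seed=9).molecule
        assert np.array_equal(a.positions, b.positions)

    def test_high_spin_stretches_bonds_by_factor(self):
        ls = generate_complex(6, [8] * 6, Q=0, S=0, seed=4).molecule
        hs = generate_complex(6, [8] * 6, Q=0, S=4, seed=4).molecule
        r_ls = np.linalg.norm(ls.positions[1:], axis=1).mean()
        r_hs = np.linalg.norm(hs.positions[1:], axis=1).mean()
        assert r_hs / r_ls == pytest.approx(P.hs_stretch, abs=1e-12)

    def test_radial_sampling_statistics(self):
        radii = []
        for seed in range(200):
            mol = generate_complex(6, [6] * 6, Q=0, S=0, seed=seed).molecule
            radii.extend(np.linalg.norm(mol.positions[1:], axis=1))
        se = P.bond_sigma / np.sqrt(len(radii))
        assert abs(np.mean(radii) - P.bond_length) < 3 * se

    def test_hs_ensembles_have_longer_bonds(self):
        records, _ = make_spin_dataset(20, 5, seed=13)
        r_hs, r_ls = [], []
        for rec in records:
            mol = rec.molecule
            r = np.linalg.norm(mol.positions[1:] - mol.positions[0], axis=1).mean()
            (r_hs if mol.spin_label == SpinLabel.HS else r_ls).append(r)
        assert len(r_hs) >= 100 and len(r_ls) >= 100
        t = stats.ttest_ind(r_hs, r_ls, alternative="greater")
        assert t.pvalue < 1e-6


class TestSpinDataset:
    def test_counts_and_truth_table(self):
        records, truth = make_spin_dataset(3, 2, seed=1)
        assert len(records) == 12
        assert len(truth) == 12  # 3 configs × 2 HS × 2 LS

    def test_labels_equal_closed_form_energy(self):
        records, _ = make_spin_dataset(4, 2, seed=2)
        for rec in records:
            assert rec.molecule.ref_energy == pytest.approx(
                toy_energy(rec.molecule), abs=1e-12)

    def test_truth_table_matches_recomputation(self):
        records, truth = make_spin_dataset(3, 3, seed=6)
        by_cfg = {}
        for rec in records:
            m = rec.molecule
            by_cfg.setdefault(m.config_id, {SpinLabel.HS: [], SpinLabel.LS: []})[
                m.spin_label].append(m)
        for row in truth.itertuples():
            hs = by_cfg[row.config_id][SpinLabel.HS][row.hs_index]
            ls = by_cfg[row.config_id][SpinLabel.LS][row.ls_index]
            assert row.ref_dE_ev == pytest.approx(
                toy_energy(hs) - toy_energy(ls), abs=1e-12)


class TestIrreducibleBound:
    def _rec(self, pos, energy, q=0, s=0):
        from spinmp.molecular import DatasetRecord

        return DatasetRecord(molecule=Molecule([26, 8], pos, total_charge=q,
                                               spin_state=s, ref_energy=energy))

    def test_singleton_groups_give_zero_with_warning(self, rng, caplog):
        recs = [self._rec(rng.uniform(0, 4, (2, 3)), 1.0) for _ in range(4)]
        with caplog.at_level("WARNING"):
            assert irreducible_error_bound(recs) == 0.0
        assert any("degenerate" in m for m in caplog.messages)

    def test_two_point_group_gives_half_gap(self, rng):
        pos = rng.uniform(0, 4, (2, 3))
        recs = [self._rec(pos, 0.0, s=0), self._rec(pos.copy(), 2.0, s=4)]
        assert irreducible_error_bound(recs) == pytest.approx(1.0)

    def test_matches_exhaustive_constant_per_group_minimization(self, rng):
        recs = []
        group_energies = []
        for g in range(5):
            pos = rng.uniform(0, 4, (2, 3))
            energies = rng.normal(size=rng.integers(1, 5))
            group_energies.append(list(energies))
            for k, e in enumerate(energies):
                recs.append(self._rec(pos.copy(), float(e), s=int(k)))
        bound = irreducible_error_bound(recs)
        # oracle: scan a fine grid of constants per group for the minimal MAE
        total = 0.0
        n = sum(len(g) for g in group_energies)
        for energies in group_energies:
            grid = np.linspace(min(energies) - 1, max(energies) + 1, 20001)
            costs = np.abs(np.array(energies)[:, None] - grid[None, :]).sum(axis=0)
            total += costs.min()
        assert bound == pytest.approx(total / n, abs=1e-3)

    def test_default_dataset_has_positive_bound(self):
        records, _ = make_spin_dataset(30, 5, seed=7)
        assert irreducible_error_bound(records) > 0.0
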