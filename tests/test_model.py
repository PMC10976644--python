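"""Model assembly: coupling modes, invariances, blindness, persistence."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from spinmp.autodiff import AdamW
from spinmp.errors import ConfigurationError, PairingError, UnknownElementError
from spinmp.model import ModelConfig, SpinPotential, build_model
from spinmp.molecular import Molecule, SpinLabel

from conftest import random_molecule

SMALL = dict(F=8, T=2, n_rbf=6, seed=3)


def _perturb(model, rng, scale=0.2):
    """Randomize weights so zero-initialized blocks participate."""
    for p in model.parameters():
        p.data = p.data + rng.normal(0, scale, p.data.shape)
    return model


class TestConfig:
    def test_split_comma_requires_electronic_embeddings(self):
        with pytest.raises(ConfigurationError):
            build_model(ModelConfig(embedding_variant="nuclear_only",
                                    coupling="split_comma"))

    def test_unknown_names_rejected(self):
        with pytest.raises(ConfigurationError):
            ModelConfig(embedding_variant="magic").validate()
        with pytest.raises(ConfigurationError):
            ModelConfig(coupling="mixed").validate()

    def test_base_coupling_builds_no_kgrid(self):
        m = build_model(ModelConfig(coupling="base", **SMALL))
        assert m.ewald_blocks == []

    def test_parameter_counts_reflect_structure(self):
        base_nuc = build_model(ModelConfig(embedding_variant="nuclear_only",
                                           coupling="base", **SMALL))
        base_scaled = build_model(ModelConfig(embedding_variant="scaled",
                                              coupling="base", **SMALL))
        plus_scaled = build_model(ModelConfig(embedding_variant="scaled",
                                              coupling="shared_plus", **SMALL))
        assert base_nuc.n_parameters() < base_scaled.n_parameters()
        assert base_scaled.n_parameters() < plus_scaled.n_parameters()

    def test_split_comma_streams_use_disjoint_parameter_groups(self):
        m = build_model(ModelConfig(embedding_variant="scaled",
                                    coupling="split_comma", **SMALL))
        short_ids = {id(p) for grp in m.interactions for p in grp.values()}
        ewald_ids = {id(p) for grp in m.ewald_blocks for p in grp.values()}
        assert short_ids.isdisjoint(ewald_ids)


class TestForward:
    def test_same_seed_gives_bit_identical_predictions(self, rng):
        mol = random_molecule(rng, n_atoms=6)
        cfg = ModelConfig(embedding_variant="scaled", coupling="shared_plus", **SMALL)
        e1 = build_model(cfg).forward_energy(mol).total_energy
        e2 = build_model(cfg).forward_energy(mol).total_energy
        assert e1 == e2

    def test_total_equals_sum_of_contributions(self, rng):
        m = build_model(ModelConfig(**SMALL))
        pred = m.forward_energy(random_molecule(rng, n_atoms=5))
        assert pred.total_energy == pytest.approx(
            pred.per_atom_contributions.sum(), abs=1e-8)

    @pytest.mark.parametrize("coupling", ["base", "shared_plus", "split_comma"])
    def test_rigid_motion_and_permutation_invariance(self, coupling, rng):
        m = _perturb(build_model(ModelConfig(embedding_variant="scaled",
                                             coupling=coupling, **SMALL)), rng)
        mol = random_molecule(rng, n_atoms=7)
        e0 = m.forward_energy(mol).total_energy
        rot = Rotation.random(random_state=11).as_matrix()
        if np.linalg.det(rot) < 0:
            rot = -rot
        moved = mol.copy(positions=mol.positions @ rot.T + [3.0, -1.0, 2.0])
        assert abs(m.forward_energy(moved).total_energy - e0) <= 1e-6
        perm = rng.permutation(mol.n_atoms)
        permuted = mol.copy(positions=mol.positions[perm],
                            atomic_numbers=mol.atomic_numbers[perm])
        assert abs(m.forward_energy(permuted).total_energy - e0) <= 1e-8

    def test_nuclear_only_is_charge_spin_blind(self, rng):
        m = build_model(ModelConfig(embedding_variant="nuclear_only", **SMALL))
        mol = random_molecule(rng, n_atoms=6, charge=0, spin=0)
        varied = mol.copy(total_charge=2, spin_state=4)
        assert (m.forward_energy(mol).total_energy
                == m.forward_energy(varied).total_energy)

    @pytest.mark.parametrize("variant", ["scaled", "attention"])
    def test_electronic_variants_are_not_blind(self, variant, rng):
        m = build_model(ModelConfig(embedding_variant=variant, **SMALL))
        mol = random_molecule(rng, n_atoms=6, charge=0, spin=0)
        varied = mol.copy(total_charge=2, spin_state=4)
        # one gradient step ensures the sensitivity survives training
        mol.ref_energy = 1.0
        opt = AdamW(m.parameters(), lr=1e-3)
        loss = (m.forward_residual(mol).sum() - 1.0).square()
        loss.backward()
        opt.step()
        assert (m.forward_energy(mol).total_energy
                != m.forward_energy(varied).total_energy)

    def test_unsupported_element_rejected(self):
        m = build_model(ModelConfig(**SMALL))
        with pytest.raises(UnknownElementError):
            m.forward_energy(Molecule([92], [[0, 0, 0]]))

    def test_zero_interactions_reduce_to_readout_of_x0(self, rng):
        from spinmp.autodiff import softplus

        cfg = ModelConfig(embedding_variant="scaled", coupling="base",
                          F=8, T=0, n_rbf=6, seed=3)
        m = build_model(cfg)
        mol = random_molecule(rng, n_atoms=5)
        x_N, x_E = m._embed(mol)
        from spinmp.embeddings import residual_block

        x0 = residual_block(x_N + x_E, m.emb, "res")
        manual = ((softplus(x0 @ m.readout["ro.0.W"] + m.readout["ro.0.b"])
                   @ m.readout["ro.1.W"]) + m.readout["ro.1.b"]).data.sum()
        assert m.forward_residual(mol).data.sum() == pytest.approx(manual, abs=1e-10)

    def test_size_extensive_for_separated_copies(self, rng):
        m = _perturb(build_model(ModelConfig(embedding_variant="scaled",
                                             coupling="base", **SMALL)), rng)
        mol = random_molecule(rng, n_atoms=5, charge=0, spin=0)
        double = Molecule(
            np.concatenate([mol.atomic_numbers] * 2),
            np.concatenate([mol.positions, mol.positions + 100.0]),
            total_charge=0, spin_state=0,
        )
        e1 = m.forward_energy(mol).total_energy
        e2 = m.forward_energy(double).total_energy
        assert e2 == pytest.approx(2 * e1, abs=1e-8)


class TestSplitting:
    def _pair(self, rng):
        hs = random_molecule(rng, n_atoms=6, charge=1, spin=4)
        hs.spin_label, hs.config_id = SpinLabel.HS, "c0"
        ls = hs.copy(spin_state=0, spin_label=SpinLabel.LS,
                     positions=hs.positions + rng.normal(0, 0.05, hs.positions.shape))
        return hs, ls

    def test_identical_inputs_give_zero_splitting(self, rng):
        m = build_model(ModelConfig(embedding_variant="scaled", **SMALL))
        hs, _ = self._pair(rng)
        twin = hs.copy(spin_label=SpinLabel.LS)  # same geometry, charge, spin
        assert m.predict_splitting(hs, twin) == pytest.approx(0.0, abs=1e-12)

    def test_antisymmetric_under_swap(self, rng):
        m = build_model(ModelConfig(embedding_variant="scaled", **SMALL))
        hs, ls = self._pair(rng)
        d = m.predict_splitting(hs, ls)
        swapped = m.predict_splitting(ls.copy(spin_label=SpinLabel.HS),
                                      hs.copy(spin_label=SpinLabel.LS))
        assert swapped == pytest.approx(-d, abs=1e-10)

    def test_config_mismatch_rejected(self, rng):
        m = build_model(ModelConfig(**SMALL))
        hs, ls = self._pair(rng)
        ls.config_id = "other"
        with pytest.raises(PairingError):
            m.predict_splitting(hs, ls)
        with pytest.raises(PairingError):
            m.predict_splitting(ls, hs)  # wrong labels


class TestPersistence:
    def test_save_load_round_trip(self, rng, tmp_path):
        m = _perturb(build_model(ModelConfig(embedding_variant="attention",
                                             coupling="shared_plus", **SMALL)), rng)
        m.element_baseline[26] = -3.5
        mol = random_molecule(rng, n_atoms=6)
        path = tmp_path / "ckpt.json"
        m.save(path)
        m2 = SpinPotential.load(path)
        assert (m2.forward_energy(mol).total_energy
                == m.forward_energy(mol).total_energy)
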