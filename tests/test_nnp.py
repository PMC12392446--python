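import numpy as np
import pytest

from mlmmfe import (AtomicSystem, EnsembleModel, HDNNPModel, featurize,
                    partition_regions, predict_energy, predict_forces)
from mlmmfe.nnp import (Frame, NetworkSpec, TrainingDataset, _loss_and_grad,
                        _Packed, train_hdnnp)

from conftest import rigid_transform


def _make_frames(rng, config, n_frames=4, n_atoms=8):
    frames = []
    elements = ["C", "O", "H", "H", "S", "H", "O", "H"]
    regions = ["QM"] * 3 + ["MM"] * 5
    for fid in range(n_frames):
        pos = rng.normal(scale=1.8, size=(n_atoms, 3))
        charges = rng.uniform(-0.4, 0.4, n_atoms)
        s = AtomicSystem(elements, pos, regions, charges)
        p = partition_regions(s, config.r_cut)
        G, jacs = featurize(s, p, config, gradients=True)
        mask = np.zeros(n_atoms, bool)
        mask[np.concatenate([p.Q, p.E_prime]).astype(int)] = True
        f_t = rng.normal(scale=5.0, size=(n_atoms, 3)) * mask[:, None]
        frames.append(Frame(G, jacs, [elements[i] for i in p.Q], n_atoms,
                            float(rng.normal(scale=3.0)), f_t, mask, fid))
    return frames


@pytest.fixture()
def tiny_dataset(small_config):
    rng = np.random.default_rng(3)
    return TrainingDataset(_make_frames(rng, small_config), small_config,
                           test_fraction=0.25, split_seed=0)


_ALL_ELEMENTS = ["C", "Cl", "H", "O", "S"]


@pytest.fixture()
def tiny_model(tiny_dataset, small_config):
    m = HDNNPModel(_ALL_ELEMENTS, (6, 6), small_config, init_seed=1)
    m.set_standardization(tiny_dataset.subset(tiny_dataset.train_idx))
    return m


class TestArchitecture:
    def test_two_hidden_layers_enforced(self):
        with pytest.raises(ValueError):
            NetworkSpec(10, (4, 4, 4))

    def test_zeroed_output_layer_gives_offset_energy(self, tiny_model,
                                                     random_system,
                                                     small_config):
        for p in tiny_model.nets.values():
            p["w3"][:] = 0.0
            p["b3"][:] = 0.0
        part = partition_regions(random_system, small_config.r_cut)
        e = predict_energy(tiny_model, random_system, part)
        assert e == pytest.approx(tiny_model.y_mean * len(part.Q))

    def test_unknown_element_raises(self, tiny_model, small_config):
        s = AtomicSystem(["Ru"], [[0, 0, 0]], ["QM"], [0.1])
        with pytest.raises(ValueError):
            predict_energy(tiny_model, s)


class TestPredictionInvariances:
    def test_energy_invariant_under_rigid_motion(self, tiny_model,
                                                 random_system, small_config):
        e0 = predict_energy(tiny_model, random_system)
        moved = random_system.with_positions(
            rigid_transform(random_system.positions, seed=5))
        assert predict_energy(tiny_model, moved) == pytest.approx(e0,
                                                                  rel=1e-10)

    def test_energy_invariant_under_identical_atom_swap(self, tiny_model,
                                                        small_config):
        base = AtomicSystem(["C", "H", "H", "O"],
                            [[0, 0, 0], [1.1, 0, 0], [0, 1.1, 0],
                             [0, 0, 1.4]],
                            ["QM", "QM", "QM", "MM"], [0.2, 0.05, 0.05, -0.3])
        perm = AtomicSystem(["C", "H", "H", "O"],
                            [[0, 0, 0], [0, 1.1, 0], [1.1, 0, 0],
                             [0, 0, 1.4]],
                            ["QM", "QM", "QM", "MM"], [0.2, 0.05, 0.05, -0.3])
        assert predict_energy(tiny_model, perm) == pytest.approx(
            predict_energy(tiny_model, base), rel=1e-12)

    def test_forces_match_finite_difference_of_energy(self, tiny_model,
                                                      random_system,
                                                      small_config):
        f = predict_forces(tiny_model, random_system)
        h = 1e-5
        scale = max(1.0, np.abs(f).max())
        for a in (0, 2, 5):
            for x in range(3):
                p1 = random_system.positions.copy()
                p2 = random_system.positions.copy()
                p1[a, x] += h
                p2[a, x] -= h
                fd = -(predict_energy(tiny_model,
                                      random_system.with_positions(p1))
                       - predict_energy(tiny_model,
                                        random_system.with_positions(p2))) \
                    / (2 * h)
                assert abs(fd - f[a, x]) / scale < 1e-5

    def test_atoms_beyond_cutoff_get_zero_force(self, tiny_model,
                                                small_config):
        s = AtomicSystem(["C", "O", "O"],
                         [[0, 0, 0], [1.5, 0, 0], [30.0, 0, 0]],
                         ["QM", "QM", "MM"], [0.2, -0.1, -0.3])
        f = predict_forces(tiny_model, s)
        np.testing.assert_array_equal(f[2], 0.0)

    def test_total_force_sums_to_zero(self, tiny_model, random_system):
        f = predict_forces(tiny_model, random_system)
        np.testing.assert_allclose(f.sum(axis=0), 0.0, atol=1e-9)


class TestTraining:
    def test_loss_gradient_matches_finite_differences(self, tiny_dataset,
                                                      tiny_model):
        pk = _Packed(tiny_dataset.subset(tiny_dataset.train_idx),
                     tiny_model.elements, jac_dtype=np.float64)
        _, _, _, grads, _, _ = _loss_and_grad(tiny_model, pk, 1.0, 0.3, True)
        h = 1e-6
        rng = np.random.default_rng(0)
        for e in tiny_model.elements:
            for key in ("W1", "b1", "W2", "b2", "w3", "b3"):
                p = tiny_model.nets[e][key]
                flat = p.reshape(-1)
                for idx in rng.choice(flat.size, min(3, flat.size),
                                      replace=False):
                    orig = flat[idx]
                    flat[idx] = orig + h
                    l1 = _loss_and_grad(tiny_model, pk, 1.0, 0.3, True)[0]
                    flat[idx] = orig - h
                    l2 = _loss_and_grad(tiny_model, pk, 1.0, 0.3, True)[0]
                    flat[idx] = orig
                    fd = (l1 - l2) / (2 * h)
                    an = grads[e][key].reshape(-1)[idx]
                    assert abs(fd - an) / max(abs(fd), 1e-6) < 1e-4

    def test_same_seed_reproduces_loss_trace(self, tiny_dataset, small_config):
        def run():
            m = HDNNPModel(tiny_dataset.elements, (6, 6), small_config, 2)
            return train_hdnnp(m, tiny_dataset, epochs=20, seed=5).loss_trace

        np.testing.assert_array_equal(run(), run())

    def test_self_generated_targets_are_realizable(self, tiny_dataset,
                                                   small_config):
        """Training on a model's own outputs drives the loss to ~zero."""
        teacher = HDNNPModel(tiny_dataset.elements, (6, 6), small_config, 9)
        teacher.set_standardization(tiny_dataset.frames)
        relabelled = []
        for f in tiny_dataset.frames:
            e = float(teacher.predict_from_features(
                f.features, f.qm_elements)[0])
            relabelled.append(Frame(f.features, f.jacobians, f.qm_elements,
                                    f.n_atoms, e,
                                    np.zeros_like(f.f_target),
                                    f.force_mask, f.frame_id))
        ds = TrainingDataset(relabelled, small_config, test_fraction=0.25,
                             split_seed=0)
        student = HDNNPModel(ds.elements, (6, 6), small_config, 9)
        res = train_hdnnp(student, ds, epochs=400, loss_weights=(1.0, 0.0),
                          seed=0, lr=2e-2)
        assert res.loss_trace[-1, 0] < 1e-4

    def test_divergence_raises_with_trace(self, tiny_dataset, small_config):
        m = HDNNPModel(tiny_dataset.elements, (6, 6), small_config, 3)
        for p in m.nets.values():
            p["W1"][:] = 1e200
            p["w3"][:] = 1e200
        with pytest.raises(FloatingPointError):
            train_hdnnp(m, tiny_dataset, epochs=5, seed=0)


class TestEnsemble:
    def test_minimum_two_members(self, tiny_model):
        with pytest.raises(ValueError):
            EnsembleModel([tiny_model])

    def test_identical_members_hit_the_floor_exactly(self, tiny_model,
                                                     random_system):
        ens = EnsembleModel([tiny_model, tiny_model], rmse_floor_energy=0.7,
                            rmse_floor_force=0.3, c=1.0)
        _, de, _, df = ens.predict(random_system)
        assert de == 0.7
        assert np.all(df == 0.3)

    def test_two_member_spread_matches_sample_std(self, tiny_dataset,
                                                  tiny_model, random_system,
                                                  small_config):
        other = HDNNPModel(_ALL_ELEMENTS, (6, 6), small_config, 42)
        other.set_standardization(tiny_dataset.frames)
        ens = EnsembleModel([tiny_model, other], rmse_floor_energy=0.0,
                            rmse_floor_force=0.0, c=1.0)
        e_mean, de, _, _ = ens.predict(random_system)
        e1 = predict_energy(tiny_model, random_system)
        e2 = predict_energy(other, random_system)
        assert e_mean == pytest.approx(0.5 * (e1 + e2))
        assert de == pytest.approx(np.std([e1, e2], ddof=1))

    def test_uncertainty_monotone_in_calibration_factor(self, tiny_dataset,
                                                        tiny_model,
                                                        random_system,
                                                        small_config):
        other = HDNNPModel(_ALL_ELEMENTS, (6, 6), small_config, 43)
        other.set_standardization(tiny_dataset.frames)
        uncs = []
        for c in (0.5, 1.0, 2.0):
            ens = EnsembleModel([tiny_model, other], 0.0, 0.0, c=c)
            uncs.append(ens.predict(random_system)[1])
        assert uncs[0] < uncs[1] < uncs[2]
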