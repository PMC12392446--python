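import numpy as np
import pytest

from mlmmfe import (AtomicSystem, DescriptorConfig, descriptor_size,
                    featurize, partition_regions)
from mlmmfe.descriptors import (angular_charge_weight, angular_element_weight,
                                angular_mixed_weight, angular_structure,
                                compute_descriptors, compute_jacobian,
                                interaction_mask, radial_charge_weight,
                                radial_element_weight, radial_structure,
                                radial_structure_derivative)
from mlmmfe.elements import element_properties

from conftest import rigid_transform


class TestBuildingBlocks:
    def test_radial_structure_values(self):
        assert radial_structure(0.0, 2.0, 5.0) == pytest.approx(1.0)
        assert radial_structure(5.0, 2.0, 5.0) == 0.0
        assert radial_structure(7.0, 2.0, 5.0) == 0.0
        # r=3, eta=2, r_cut=5: exponent 2*(1 - 1/(1-9/25)) = -9/8
        assert radial_structure(3.0, 2.0, 5.0) == pytest.approx(np.exp(-9 / 8))

    def test_radial_structure_smooth_at_cutoff(self):
        eps = 1e-5
        assert radial_structure(5.0 - eps, 2.0, 5.0) < 1e-12
        assert abs(radial_structure_derivative(5.0 - eps, 2.0, 5.0)) < 1e-8

    def test_angular_structure_limits(self):
        assert angular_structure(0.0, 1, 4.0) == pytest.approx(1.0)
        assert angular_structure(np.pi, 1, 4.0) == pytest.approx(0.0)
        assert angular_structure(np.pi, -1, 1.0) == pytest.approx(1.0)
        theta = np.linspace(0, np.pi, 20)
        vals = angular_structure(theta, -1, 3.0)
        assert np.all((vals >= 0) & (vals <= 1))

    def test_radial_element_weight(self):
        assert radial_element_weight(1.0, 1.0) == 1.0
        c = element_properties("C")
        assert radial_element_weight(c.n, 5.0) == pytest.approx(2 / 5)
        ru = element_properties("Ru")
        assert radial_element_weight(ru.d, 10.0) == pytest.approx(6 / 10)

    def test_angular_element_weight(self):
        # equal maximal properties, sum channel
        assert angular_element_weight(5.0, 5.0, +1, 5.0) == pytest.approx(1.0)
        # equal nonzero properties, difference channel: shift / h_max
        assert angular_element_weight(3.0, 3.0, -1, 5.0) == pytest.approx(1 / 5)
        # both zero: no shift applied
        assert angular_element_weight(0.0, 0.0, -1, 5.0) == 0.0
        # symmetry under neighbor exchange
        assert angular_element_weight(2.0, 7.0, -1, 8.0) == \
            angular_element_weight(7.0, 2.0, -1, 8.0)

    def test_charge_weights(self):
        assert radial_charge_weight(1.0, 1.0) == 0.5
        assert radial_charge_weight(0.0, 1.0) == 0.0
        assert radial_charge_weight(-1.0, 1.0) == -0.5
        assert angular_mixed_weight(5.0, 1.0, 5.0, 1.0) == 0.5
        assert angular_mixed_weight(5.0, 0.0, 5.0, 1.0) == 0.0
        assert angular_mixed_weight(5.0, -0.3, 5.0, 1.0) < 0
        assert angular_charge_weight(1.0, 1.0, 1.0) == 0.5
        assert angular_charge_weight(1.0, -1.0, 1.0) == -0.5
        assert angular_charge_weight(0.0, 1.0, 1.0) == 0.0

    def test_interaction_masks(self):
        assert interaction_mask("radial_Q", "MM") == 0.0
        assert interaction_mask("radial_Q", "QM") == 1.0
        assert interaction_mask("radial_E", "MM") == 1.0
        assert interaction_mask("angular_QE", ("QM", "MM")) == 1.0
        assert interaction_mask("angular_QE", ("MM", "QM")) == 1.0
        assert interaction_mask("angular_QQ", ("QM", "MM")) == 0.0
        assert interaction_mask("angular_EE", ("MM", "MM")) == 1.0


class TestDescriptorSize:
    def test_reference_counts_five_elements(self):
        cfg = DescriptorConfig()  # 5 eta_rad, 2 eta_ang, 2 lambda, 3 zeta
        assert descriptor_size(cfg, 5, "acsf") == (25, 180, 205)
        assert descriptor_size(cfg, 5, "eeacsf") == (35, 132, 167)

    def test_minimal_acsf_count(self):
        cfg = DescriptorConfig(eta_rad=(1.0,), eta_ang=(1.0,),
                               lambda_vals=(1,), zeta_vals=(1.0,))
        assert descriptor_size(cfg, 1, "acsf") == (1, 1, 2)

    def test_element_embracing_size_is_element_count_independent(self):
        cfg = DescriptorConfig()
        assert descriptor_size(cfg, 5, "eeacsf") == \
            descriptor_size(cfg, 10, "eeacsf")
        assert descriptor_size(cfg, 10, "acsf")[2] > \
            descriptor_size(cfg, 5, "acsf")[2]

    def test_qmmm_mode_matches_feature_vector_length(self, random_system,
                                                     small_config):
        p = partition_regions(random_system, small_config.r_cut)
        g = featurize(random_system, p, small_config)
        assert g.shape[1] == descriptor_size(small_config,
                                             mode="eeacsf_qmmm")[2]
        assert g.shape[1] == len(small_config.feature_names())


class TestInvariances:
    def test_isolated_atom_all_zero(self, small_config):
        s = AtomicSystem(["C"], [[0, 0, 0]], ["QM"], [0.1])
        vecs = compute_descriptors(s, partition_regions(s, 4.0), small_config)
        assert np.all(vecs[0].values == 0.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_rigid_motion_invariance(self, random_system, small_config, seed):
        p = partition_regions(random_system, small_config.r_cut)
        g0 = featurize(random_system, p, small_config)
        moved = random_system.with_positions(
            rigid_transform(random_system.positions, seed=seed))
        g1 = featurize(moved, partition_regions(moved, small_config.r_cut),
                       small_config)
        np.testing.assert_allclose(g1, g0, atol=1e-10)

    def test_permutation_invariance(self, small_config):
        # two identical O/charge MM neighbors swapped
        base = AtomicSystem(["C", "O", "O"],
                            [[0, 0, 0], [1.5, 0, 0], [0, 1.5, 0]],
                            ["QM", "MM", "MM"], [0.2, -0.1, -0.1])
        swap = AtomicSystem(["C", "O", "O"],
                            [[0, 0, 0], [0, 1.5, 0], [1.5, 0, 0]],
                            ["QM", "MM", "MM"], [0.2, -0.1, -0.1])
        g0 = featurize(base, partition_regions(base, 4.0), small_config)
        g1 = featurize(swap, partition_regions(swap, 4.0), small_config)
        np.testing.assert_allclose(g1, g0, atol=1e-12)

    def test_continuity_as_neighbor_crosses_cutoff(self, small_config):
        """A neighbor's contribution and gradient vanish smoothly at r_cut."""
        rc = small_config.r_cut

        def state(r):
            s = AtomicSystem(["C", "O"], [[0, 0, 0], [r, 0, 0]],
                             ["QM", "MM"], [0.2, -0.3])
            p = partition_regions(s, rc)
            return featurize(s, p, small_config, gradients=True)

        g_in, jac_in = state(rc - 1e-5)
        g_out, _ = state(rc + 1e-5)
        assert np.all(g_out == 0.0)
        assert np.max(np.abs(g_in)) < 1e-10
        assert np.max(np.abs(jac_in[0].values)) < 1e-8

    def test_charge_channels_linear_in_neighbor_charge(self, small_config):
        def vec(q):
            s = AtomicSystem(["C", "O", "F"],
                             [[0, 0, 0], [1.4, 0, 0], [0, 2.0, 0.5]],
                             ["QM", "QM", "MM"], [0.2, -0.1, q])
            return featurize(s, partition_regions(s, 4.0), small_config)[0]

        g1, g2, g0 = vec(0.2), vec(0.4), vec(0.0)
        np.testing.assert_allclose(g2 - g0, 2.0 * (g1 - g0), atol=1e-12)


class TestJacobian:
    def test_matches_finite_differences(self, random_system, small_config):
        p = partition_regions(random_system, small_config.r_cut)
        jacs = compute_jacobian(random_system, p, small_config)
        h = 1e-5
        q_list = list(p.Q)
        for jac in jacs[:2]:
            ci = q_list.index(jac.center)
            scale = max(1.0, np.abs(jac.values).max())
            for a in jac.atom_indices[:4]:
                loc = list(jac.atom_indices).index(a)
                for x in range(3):
                    p1 = random_system.positions.copy()
                    p2 = random_system.positions.copy()
                    p1[a, x] += h
                    p2[a, x] -= h
                    s1 = random_system.with_positions(p1)
                    s2 = random_system.with_positions(p2)
                    fd = (featurize(s1, partition_regions(s1, small_config.r_cut),
                                    small_config)[ci]
                          - featurize(s2, partition_regions(s2, small_config.r_cut),
                                      small_config)[ci]) / (2 * h)
                    err = np.abs(fd - jac.values[:, loc, x]).max() / scale
                    assert err < 1e-6

    def test_translation_invariance_gradient_sum(self, random_system,
                                                 small_config):
        p = partition_regions(random_system, small_config.r_cut)
        for jac in compute_jacobian(random_system, p, small_config):
            np.testing.assert_allclose(jac.values.sum(axis=1), 0.0, atol=1e-10)

    def test_out_of_cutoff_atom_has_no_entry(self, small_config):
        s = AtomicSystem(["C", "O", "O"],
                         [[0, 0, 0], [1.5, 0, 0], [20.0, 0, 0]],
                         ["QM", "QM", "MM"], [0.2, -0.1, -0.3])
        p = partition_regions(s, small_config.r_cut)
        for jac in compute_jacobian(s, p, small_config):
            assert 2 not in jac.atom_indices
            assert np.all(jac.entry(0, 2) == 0.0)
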