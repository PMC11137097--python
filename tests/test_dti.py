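"""Tensor-fit correctness: exactness on noiseless data, axis conventions,
shell handling and noise robustness."""

import numpy as np
import pytest

from conftest import random_spd_tensor
from glymph.dti import (COMPONENT_ORDER, TensorFit, TensorModel, design_matrix,
                        split_shells)
from glymph.io import GradientTable, Volume
from glymph.phantom import (PhantomSpec, alps_protocol, make_tensor_phantom,
                            simulate_dwi)


def _single_shell_table(b=1000.0, n_dirs=30):
    t = alps_protocol(n_dirs=n_dirs, shells=(b,))
    return t


def _signals(tensors, table, s0=1.0):
    """Noiseless monoexponential signals for an array of (v, 3, 3) tensors."""
    comps = np.stack([tensors[:, 0, 0], tensors[:, 1, 1], tensors[:, 2, 2],
                      tensors[:, 0, 1], tensors[:, 0, 2], tensors[:, 1, 2]], axis=-1)
    X = design_matrix(table)[:, 1:]
    return s0 * np.exp(comps @ X.T)


class TestFitExactness:
    def test_noiseless_recovery_of_random_spd_tensors(self, rng):
        table = _single_shell_table()
        tensors = np.stack([random_spd_tensor(rng) for _ in range(10)])
        data = _signals(tensors, table).reshape(10, 1, 1, len(table))
        fit = TensorModel(table).fit(data)
        for v in range(10):
            got = fit.tensor()[v, 0, 0]
            scale = np.linalg.norm(tensors[v])
            assert np.linalg.norm(got - tensors[v]) / scale < 1e-10

    def test_diagonal_tensor_recovered_componentwise(self):
        table = _single_shell_table()
        d = np.diag([1.2e-3, 0.6e-3, 1.8e-3])
        data = _signals(d[None], table).reshape(1, 1, 1, -1)
        fit = TensorModel(table).fit(data)
        np.testing.assert_allclose(
            fit.components[0, 0, 0, :3], [1.2e-3, 0.6e-3, 1.8e-3], rtol=1e-10)
        np.testing.assert_allclose(fit.components[0, 0, 0, 3:], 0.0, atol=1e-15)

    def test_isotropic_tensor_has_zero_off_diagonals(self):
        table = _single_shell_table()
        d = np.eye(3) * 1.0e-3
        data = _signals(d[None], table).reshape(1, 1, 1, -1)
        fit = TensorModel(table).fit(data)
        np.testing.assert_allclose(fit.components[0, 0, 0, 3:], 0.0, atol=1e-15)
        np.testing.assert_allclose(fit.components[0, 0, 0, :3], 1.0e-3, rtol=1e-10)

    def test_s0_recovered_in_noiseless_mode(self):
        table = _single_shell_table()
        d = np.diag([0.8e-3, 0.8e-3, 0.8e-3])
        data = 250.0 * _signals(d[None], table).reshape(1, 1, 1, -1)
        fit = TensorModel(table).fit(data)
        np.testing.assert_allclose(fit.s0[0, 0, 0], 250.0, rtol=1e-10)


class TestAxisConvention:
    def test_axis_maps_are_diagonals_not_eigenvalues(self):
        # with Dxy != 0 the diagonal differs from the eigenvalues
        table = _single_shell_table()
        d = np.array([[1.0e-3, 0.3e-3, 0.0],
                      [0.3e-3, 1.0e-3, 0.0],
                      [0.0, 0.0, 0.5e-3]])
        data = _signals(d[None], table).reshape(1, 1, 1, -1)
        fit = TensorModel(table).fit(data)
        dxx, dyy, dzz = (m.data[0, 0, 0] for m in fit.axis_diffusivities())
        np.testing.assert_allclose([dxx, dyy, dzz], np.diag(d), rtol=1e-9)
        eigs = np.linalg.eigvalsh(d)
        assert not np.any(np.isclose(dxx, eigs, rtol=1e-3))

    def test_rotation_about_z_swaps_dxx_and_dyy(self):
        table = _single_shell_table()
        d = np.diag([1.2e-3, 0.6e-3, 1.8e-3])
        rot = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        d_rot = rot @ d @ rot.T
        data = _signals(np.stack([d, d_rot]), table).reshape(2, 1, 1, -1)
        fit = TensorModel(table).fit(data)
        np.testing.assert_allclose(fit.dxx[1], fit.dyy[0], rtol=1e-10)
        np.testing.assert_allclose(fit.dyy[1], fit.dxx[0], rtol=1e-10)
        np.testing.assert_allclose(fit.dzz[1], fit.dzz[0], rtol=1e-10)


class TestShellSplitting:
    def test_study_protocol_splits_into_two_31_frame_sets(self, small_phantom_spec):
        phantom = make_tensor_phantom(small_phantom_spec)
        table = alps_protocol()
        dwi = simulate_dwi(phantom.field, table)
        shells = split_shells(dwi, table)
        assert sorted(shells) == [1000.0, 2000.0]
        for _, (sdwi, stab) in shells.items():
            assert sdwi.n_frames == 31
            assert len(stab) == 31
            assert int(stab.b0_mask.sum()) == 1

    def test_single_shell_passthrough(self, small_phantom_spec):
        phantom = make_tensor_phantom(small_phantom_spec)
        table = alps_protocol(shells=(1000.0,))
        dwi = simulate_dwi(phantom.field, table)
        shells = split_shells(dwi, table)
        assert list(shells) == [1000.0]
        np.testing.assert_array_equal(shells[1000.0][0].data, dwi.data)

    def test_all_b0_input_rejected(self):
        table = GradientTable([0.0, 0.0], np.zeros((2, 3)))
        dwi = Volume(np.ones((4, 4, 4, 2)))
        with pytest.raises(ValueError, match="all b=0"):
            split_shells(dwi, table)

    def test_too_few_directions_rejected(self):
        table = alps_protocol(n_dirs=4, shells=(1000.0,))
        dwi = Volume(np.ones((4, 4, 4, len(table))))
        with pytest.raises(ValueError, match="only 4 directions"):
            split_shells(dwi, table)

    def test_frame_count_mismatch_rejected(self):
        table = alps_protocol()
        dwi = Volume(np.ones((4, 4, 4, 10)))
        with pytest.raises(ValueError, match="frames"):
            split_shells(dwi, table)

    def test_multi_shell_table_refused_by_model(self):
        with pytest.raises(ValueError, match="split_shells"):
            TensorModel(alps_protocol())


class TestNoiseBehaviour:
    def test_invalid_voxels_flagged_not_fatal(self):
        table = _single_shell_table()
        data = np.ones((2, 1, 1, len(table)))
        data[1] = 0.0  # zero signal everywhere -> unusable voxel
        fit = TensorModel(table).fit(data)
        assert fit.valid[0, 0, 0]
        assert not fit.valid[1, 0, 0]
        assert np.isnan(fit.components[1, 0, 0]).all()

    def test_negative_diagonals_clamped_and_flagged(self, rng):
        # craft signals that grow with b along x -> negative Dxx estimate
        table = _single_shell_table(n_dirs=15)
        d = np.diag([-0.2e-3, 0.5e-3, 0.5e-3])
        comps = np.array([d[0, 0], d[1, 1], d[2, 2], 0, 0, 0])
        X = design_matrix(table)[:, 1:]
        data = np.exp(comps @ X.T).reshape(1, 1, 1, -1)
        fit = TensorModel(table).fit(data)
        assert fit.clamped[0, 0, 0]
        assert fit.components[0, 0, 0, 0] == 0.0

    def test_median_dxx_error_under_noise(self, rng):
        """At SNR 30 the projection-zone Dxx error stays under 5% (median,
        20 noise realisations)."""
        spec = PhantomSpec(shape=(24, 24, 8), snr=30.0)
        phantom = make_tensor_phantom(spec)
        table = alps_protocol(shells=(1000.0,))
        sel = phantom.mask.boolean("proj_L") | phantom.mask.boolean("proj_R")
        truth = spec.effective_zone("proj").dxx
        medians = []
        for _ in range(20):
            dwi = simulate_dwi(phantom.field, table, s0=1.0, snr=30.0, rng=rng)
            fit = TensorModel(table).fit(dwi)
            err = np.abs(fit.dxx[sel] - truth) / truth
            medians.append(np.median(err))
        assert np.mean(medians) < 0.05

    def test_projection_dxx_increases_with_perivascular_gain(self, rng):
        """Estimated Dxx in the projection zone rises with the gain knob
        (expectation over 20 seeds, 3-point grid)."""
        table = alps_protocol(shells=(1000.0,))
        means = []
        for g in (0.0, 0.15e-3, 0.3e-3):
            spec = PhantomSpec(shape=(24, 24, 8), snr=30.0, perivascular_gain=g)
            phantom = make_tensor_phantom(spec)
            sel = phantom.mask.boolean("proj_L") | phantom.mask.boolean("proj_R")
            vals = []
            for _ in range(20):
                dwi = simulate_dwi(phantom.field, table, snr=30.0, rng=rng)
                fit = TensorModel(table).fit(dwi)
                vals.append(fit.dxx[sel].mean())
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]


def test_component_order_is_documented_contract():
    assert COMPONENT_ORDER == ("Dxx", "Dyy", "Dzz", "Dxy", "Dxz", "Dyz")
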