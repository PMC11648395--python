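"""Gridding reconstruction against explicit adjoint-DFT oracles."""

import math

import numpy as np
import pytest
from scipy import ndimage

from conftest import adjoint_dft_image
from ztesim.acquisition import simulate_acquisition
from ztesim.phantom import disk_phantom
from ztesim.physics import ExcitationScheme, PulseParams
from ztesim.reconstruction import (
    ReconParams,
    density_compensation,
    grid,
    hamming_filter,
    offcenter_shift,
    offcenter_shift_samples,
    reconstruct,
)
from ztesim.trajectory import make_trajectory


def acquire(n=32, fov=0.2, radius=0.05, center=(0.01, 0.0), dead_time=20e-6,
            scheme=None, antialias=False):
    ph = disk_phantom((n, n), fov, radius, center, antialias=antialias)
    traj = make_trajectory(int(math.pi * n) + 1, 0.020, fov, n,
                           dead_time=dead_time, dim=2, full_circle=True)
    data = simulate_acquisition(ph, traj, scheme or ExcitationScheme.ideal(), PulseParams())
    return ph, data


class TestDensityCompensation:
    def test_uniform_cartesian_weights_equal(self):
        k = np.stack(np.meshgrid(np.arange(-4, 5.0), np.arange(-4, 5.0),
                                 indexing="ij"), -1).reshape(-1, 2)
        w = density_compensation(k, 2, k_gap=100.0, delta_k=1.0,
                                 is_spi=np.ones(len(k), bool))
        assert np.allclose(w, w[0])

    def test_2d_radial_weight_proportional_to_radius(self):
        pos = np.array([[10.0, 0.0], [0.0, 20.0]])
        w = density_compensation(pos, 2, k_gap=0.0, delta_k=1.0,
                                 is_spi=np.zeros(2, bool), dk_radial=1.0, n_spokes=8)
        assert w[1] / w[0] == pytest.approx(2.0)

    def test_3d_radial_weight_proportional_to_radius_squared(self):
        pos = np.array([[10.0, 0.0, 0.0], [0.0, 20.0, 0.0]])
        w = density_compensation(pos, 3, k_gap=0.0, delta_k=1.0,
                                 is_spi=np.zeros(2, bool), dk_radial=1.0, n_spokes=8)
        assert w[1] / w[0] == pytest.approx(4.0)

    def test_dcf_improves_3d_radial_reconstruction(self):
        # 3D radial acquisition of a uniform ball, reconstructed through the
        # gridding pipeline with and without density compensation, judged
        # against the density-compensated adjoint-DFT reference: dropping
        # the DCF lets the oversampled k-space center swamp the image
        n, fov = 16, 0.2
        ph = disk_phantom((n, n, n), fov, 0.055, (0, 0, 0), antialias=True)
        traj = make_trajectory(700, 0.020, fov, n, dead_time=0.0, dim=3)
        data = simulate_acquisition(ph, traj, ExcitationScheme.ideal(), PulseParams())
        w = density_compensation(data.positions, 3, k_gap=data.k_gap,
                                 delta_k=data.delta_k, is_spi=data.is_spi,
                                 dk_radial=data.dk_radial, n_spokes=data.n_radial_spokes)
        oracle = adjoint_dft_image(data.positions, data.values, w, n, fov, 3)

        def best_scale_nrmse(img):
            a, ref = np.abs(img).ravel(), np.abs(oracle).ravel()
            alpha = (a @ ref) / (a @ a)
            return np.linalg.norm(alpha * a - ref) / np.linalg.norm(ref)

        with_dcf = reconstruct(
            data, ReconParams(grid_shape=(n, n, n), hamming=False)
        ).image
        without = reconstruct(
            data, ReconParams(grid_shape=(n, n, n), hamming=False, dcf_mode="uniform")
        ).image
        assert best_scale_nrmse(with_dcf) * 5 <= best_scale_nrmse(without)

    def test_voronoi_uniform_grid_interior_weights_equal(self):
        ax = np.arange(-5, 6.0)
        k = np.stack(np.meshgrid(ax, ax, indexing="ij"), -1).reshape(-1, 2)
        w = density_compensation(k, 2, mode="voronoi", delta_k=1.0)
        interior = np.all(np.abs(k) < 5, axis=1)
        assert np.allclose(w[interior], 1.0, rtol=1e-9)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="dcf_mode"):
            density_compensation(np.zeros((3, 2)), 2, mode="magic", delta_k=1.0)


class TestGrid:
    def test_impulse_response_peaks_at_node(self):
        params = ReconParams(grid_shape=(16, 16))
        ng = 24  # 16 * 1.5
        dk_grid = 1.0 / (1.5 * 0.2)
        pos = np.array([[3 * dk_grid, -2 * dk_grid]])
        out = grid(pos, np.array([1.0 + 0j]), params, 0.2)
        assert out.shape == (ng, ng)
        peak = np.unravel_index(np.argmax(np.abs(out)), out.shape)
        assert peak == (ng // 2 + 3, ng // 2 - 2)
        # footprint limited to the kernel width
        assert np.count_nonzero(np.abs(out) > 0) <= 4 * 4

    def test_linearity(self):
        rng = np.random.default_rng(0)
        pos = rng.uniform(-30, 30, (50, 2))
        vals = rng.standard_normal(50) + 1j * rng.standard_normal(50)
        params = ReconParams(grid_shape=(16, 16))
        a = grid(pos, vals, params, 0.2)
        b = grid(pos, 2 * vals, params, 0.2)
        assert np.allclose(b, 2 * a, rtol=1e-12)

    def test_gridding_matches_adjoint_dft(self):
        n, fov = 32, 0.2
        ph, data = acquire(n=n, fov=fov)
        w = density_compensation(data.positions, 2, k_gap=data.k_gap,
                                 delta_k=data.delta_k, is_spi=data.is_spi,
                                 dk_radial=data.dk_radial, n_spokes=data.n_radial_spokes)
        img = reconstruct(data, ReconParams(grid_shape=(n, n), hamming=False)).image
        oracle = adjoint_dft_image(data.positions, data.values, w, n, fov, 2)
        nrmse = np.linalg.norm(img - oracle) / np.linalg.norm(oracle)
        assert nrmse < 1e-2


class TestHammingFilter:
    def test_window_endpoint_values(self):
        arr = np.ones((8, 8), dtype=complex)
        out = hamming_filter(arr, k_max=4.0, dk_grid=1.0)
        assert out[4, 4] == pytest.approx(1.0)  # 0.54 + 0.46 at |k| = 0
        assert out[0, 4] == pytest.approx(0.08, abs=1e-12)  # 0.54 - 0.46 at k_max

    def test_never_increases_spectral_energy(self):
        rng = np.random.default_rng(1)
        arr = rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))
        out = hamming_filter(arr, k_max=8.0, dk_grid=1.0)
        assert np.linalg.norm(out) <= np.linalg.norm(arr)

    def test_reduces_gibbs_overshoot_of_step_edge(self):
        # 1D partial-Fourier reconstruction of a step: truncation rings,
        # the Hamming window damps the overshoot
        n = 256
        step = np.zeros(n)
        step[n // 4 : 3 * n // 4] = 1.0
        spec = np.fft.fftshift(np.fft.fft(np.fft.ifftshift(step)))
        k = np.arange(n) - n // 2
        k_cut = 32.0
        box = spec * (np.abs(k) <= k_cut)
        ham = hamming_filter(box, k_max=k_cut, dk_grid=1.0)
        rec_box = np.fft.fftshift(np.fft.ifft(np.fft.ifftshift(box))).real
        rec_ham = np.fft.fftshift(np.fft.ifft(np.fft.ifftshift(ham))).real
        assert rec_ham.max() - 1.0 < rec_box.max() - 1.0

    def test_invalid_k_max_rejected(self):
        with pytest.raises(ValueError):
            hamming_filter(np.ones((4, 4)), k_max=0.0)


class TestOffcenterShift:
    def test_zero_shift_is_identity(self):
        rng = np.random.default_rng(2)
        arr = rng.standard_normal((16, 16)) + 0j
        assert np.array_equal(offcenter_shift(arr, (0.0, 0.0), 1.0), arr)

    def test_integer_voxel_shift_equals_circular_shift(self):
        n, fov = 32, 0.2
        vox = fov / n
        rng = np.random.default_rng(3)
        img = rng.standard_normal((n, n))
        spec = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(img)))
        shifted_spec = offcenter_shift(spec, (5 * vox, -3 * vox), dk_grid=1.0 / fov)
        shifted = np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(shifted_spec))).real
        # object at +r0 moves to the center: the image shifts by -r0
        oracle = np.roll(img, (-5, 3), axis=(0, 1))
        assert np.allclose(shifted, oracle, atol=1e-10)

    def test_shift_and_unshift_compose_to_identity(self):
        rng = np.random.default_rng(4)
        arr = rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))
        out = offcenter_shift(offcenter_shift(arr, (0.013, -0.007), 2.5),
                              (-0.013, 0.007), 2.5)
        assert np.allclose(out, arr, atol=1e-12)

    def test_sample_domain_matches_grid_domain(self):
        rng = np.random.default_rng(5)
        pos = rng.uniform(-10, 10, (20, 2))
        vals = rng.standard_normal(20) + 1j * rng.standard_normal(20)
        r0 = (0.01, 0.02)
        direct = offcenter_shift_samples(vals, pos, r0)
        expected = vals * np.exp(2j * np.pi * (pos @ np.array(r0)))
        assert np.allclose(direct, expected, rtol=1e-14)


class TestReconstruct:
    def test_fully_sampled_disk_fidelity(self):
        n = 64
        ph, data = acquire(n=n, fov=0.2, radius=0.05, center=(0.0, 0.0),
                           dead_time=50e-6, antialias=True)
        img = reconstruct(data, ReconParams(grid_shape=(n, n), hamming=False))
        nrmse = np.linalg.norm(img.magnitude - ph.values) / np.linalg.norm(ph.values)
        assert nrmse < 0.05

    def test_empty_input_gives_zero_image(self):
        _, data = acquire(n=16)
        data.values[:] = 0.0
        img = reconstruct(data, ReconParams(grid_shape=(16, 16)))
        assert np.all(img.image == 0.0)

    def test_offex_with_shift_centers_the_object(self):
        n, fov = 48, 0.3
        center = (0.09, -0.03)
        ph, data = acquire(n=n, fov=fov, radius=0.035, center=center,
                           scheme=ExcitationScheme.offcenter(np.array(center)))
        img = reconstruct(
            data, ReconParams(grid_shape=(n, n), shift_r0=(center[0], center[1], 0.0))
        )
        mag = img.magnitude
        com = ndimage.center_of_mass(mag > 0.5 * mag.max())
        assert abs(com[0] - n / 2) <= 1.0 and abs(com[1] - n / 2) <= 1.0

    def test_mismatched_grid_shape_rejected(self):
        _, data = acquire(n=16)
        with pytest.raises(ValueError, match="dim"):
            reconstruct(data, ReconParams(grid_shape=(16, 16, 16)))
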