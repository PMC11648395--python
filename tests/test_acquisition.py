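"""Forward model: analytic transforms, scheme equivalences, sinograms."""

import math

import numpy as np
import pytest
from scipy.special import j1

from conftest import rotate_and_sum
from ztesim.acquisition import simulate_acquisition, simulate_shot, simulate_spi, sinogram
from ztesim.phantom import disk_phantom
from ztesim.physics import ExcitationScheme, PointOfInterest, PulseParams, first_zero_crossing
from ztesim.trajectory import make_trajectory, spi_grid


def jinc_disk_transform(k, radius, amplitude=1.0):
    """Closed-form 2D Fourier transform of a uniform disk (Airy pattern)."""
    k = np.asarray(k, dtype=float)
    out = np.full(k.shape, amplitude * math.pi * radius**2)
    nz = k != 0
    arg = 2 * math.pi * k[nz] * radius
    out[nz] = amplitude * math.pi * radius**2 * 2 * j1(arg) / arg
    return out


@pytest.fixture
def small_traj():
    return make_trajectory(80, 0.020, 0.2, 24, dead_time=20e-6, dim=2, full_circle=True)


class TestSimulateShot:
    def test_ideal_disk_matches_airy_transform(self, pulse):
        n, fov, R = 128, 0.4, 0.08
        ph = disk_phantom((n, n), fov, R, (0.0, 0.0), antialias=True)
        k = np.linspace(1.0, n / (4 * fov), 40)  # up to half-Nyquist
        s = simulate_shot(ph, np.array([0.02, 0.0]), k, ExcitationScheme.ideal(), pulse)
        expected = jinc_disk_transform(k, R)
        err = np.linalg.norm(np.abs(s) - np.abs(expected)) / np.linalg.norm(expected)
        assert err < 0.01

    def test_isocenter_near_ideal_for_central_object(self, pulse):
        # object well inside the first zero crossing: sinc ~ 1 over it
        n, fov = 64, 0.1
        ph = disk_phantom((n, n), fov, 0.02, (0.0, 0.0))
        k = np.linspace(0.0, n / (2 * fov), 30)
        g = np.array([0.02, 0.0])
        s_ideal = simulate_shot(ph, g, k, ExcitationScheme.ideal(), pulse)
        s_iso = simulate_shot(ph, g, k, ExcitationScheme.isocenter(), pulse)
        assert np.linalg.norm(s_iso - s_ideal) / np.linalg.norm(s_ideal) < 0.02

    def test_offcenter_point_object_equals_ideal(self, pulse):
        # single-voxel object exactly at the POI: OffEx weight there is 1
        n, fov = 32, 0.2
        vox = fov / n
        ix, iy = 24, 10
        values = np.zeros((n, n))
        values[ix, iy] = 1.0
        from ztesim.phantom import Phantom, axis_coords

        ph = Phantom(values=values, fov=fov)
        poi = np.array([axis_coords(n, fov)[ix], axis_coords(n, fov)[iy]])
        k = np.linspace(10.0, 60.0, 11)
        rng = np.random.default_rng(5)
        for _ in range(5):
            th = rng.uniform(0, 2 * math.pi)
            g = 0.02 * np.array([math.cos(th), math.sin(th)])
            s_off = simulate_shot(ph, g, k, ExcitationScheme.offcenter(poi), pulse)
            s_ideal = simulate_shot(ph, g, k, ExcitationScheme.ideal(), pulse)
            assert np.allclose(s_off, s_ideal, rtol=1e-9, atol=1e-12)

    def test_zero_gradient_radial_shot_rejected(self, pulse):
        ph = disk_phantom((16, 16), 0.1, 0.02)
        with pytest.raises(ValueError, match="nonzero gradient"):
            simulate_shot(ph, np.zeros(2), np.array([1.0]), ExcitationScheme.ideal(), pulse)


class TestSimulateSpi:
    def test_dc_point_is_total_mass(self, pulse):
        ph = disk_phantom((32, 32), 0.2, 0.05, (0.02, 0.0))
        grid = spi_grid(0.0, 5.0, 50e-6, dim=2)
        s = simulate_spi(ph, grid, ExcitationScheme.isocenter(), pulse)
        assert s[0] == pytest.approx(ph.mass() * ph.voxel_volume, rel=1e-12)

    def test_spi_nearly_ideal_under_weak_gradients(self, pulse):
        # SPI gradients scale as k/k_gap times the radial gradient, so the
        # near-flat-profile regime holds for objects compact relative to the
        # first zero crossing (here r = 0.015 m ~ rzc/10)
        ph = disk_phantom((48, 48), 0.2, 0.015, (0.0, 0.0))
        grid = spi_grid(42.58, 5.0, 50e-6, dim=2)
        s_iso = simulate_spi(ph, grid, ExcitationScheme.isocenter(), pulse)
        s_ideal = simulate_spi(ph, grid, ExcitationScheme.ideal(), pulse)
        assert np.linalg.norm(s_iso - s_ideal) / np.linalg.norm(s_ideal) < 0.005

    def test_hermitian_symmetry_for_real_phantom(self, pulse):
        ph = disk_phantom((32, 32), 0.2, 0.04, (0.03, -0.02))
        grid = spi_grid(20.0, 5.0, 50e-6, dim=2)
        s = simulate_spi(ph, grid, ExcitationScheme.ideal(), pulse)
        pts = grid.points
        for i in range(len(grid)):
            (j,) = np.nonzero(np.all(pts == -pts[i], axis=1))
            assert s[j[0]] == pytest.approx(np.conj(s[i]), rel=1e-12)


class TestSimulateAcquisition:
    def test_deterministic_without_noise(self, pulse, small_traj):
        ph = disk_phantom((24, 24), 0.2, 0.04)
        a = simulate_acquisition(ph, small_traj, ExcitationScheme.isocenter(), pulse)
        b = simulate_acquisition(ph, small_traj, ExcitationScheme.isocenter(), pulse)
        assert np.array_equal(a.values, b.values)

    def test_noise_reproducible_from_seed(self, pulse, small_traj):
        ph = disk_phantom((24, 24), 0.2, 0.04)
        a = simulate_acquisition(ph, small_traj, ExcitationScheme.ideal(), pulse,
                                 noise_sigma=0.01, seed=11)
        b = simulate_acquisition(ph, small_traj, ExcitationScheme.ideal(), pulse,
                                 noise_sigma=0.01, seed=11)
        c = simulate_acquisition(ph, small_traj, ExcitationScheme.ideal(), pulse,
                                 noise_sigma=0.01, seed=12)
        assert np.array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)

    def test_sample_count_bookkeeping(self, pulse, small_traj):
        ph = disk_phantom((24, 24), 0.2, 0.04)
        data = simulate_acquisition(ph, small_traj, ExcitationScheme.ideal(), pulse)
        expected = sum(s.sample_k.size for s in small_traj.spokes) + len(small_traj.spi)
        assert len(data) == expected
        assert data.n_radial_spokes == len(small_traj.spokes)

    def test_dim_mismatch_rejected(self, pulse, small_traj):
        ph3 = disk_phantom((8, 8, 8), 0.1, 0.02, (0, 0, 0))
        with pytest.raises(ValueError, match="dim"):
            simulate_acquisition(ph3, small_traj, ExcitationScheme.ideal(), pulse)

    def test_linearity_in_the_phantom(self, pulse, small_traj):
        from ztesim.phantom import Phantom

        a = disk_phantom((24, 24), 0.2, 0.03, (0.03, 0.0))
        b = disk_phantom((24, 24), 0.2, 0.03, (-0.04, 0.02))
        ab = Phantom(values=a.values + b.values, fov=0.2)
        sch = ExcitationScheme.isocenter()
        sa = simulate_acquisition(a, small_traj, sch, pulse).values
        sb = simulate_acquisition(b, small_traj, sch, pulse).values
        sab = simulate_acquisition(ab, small_traj, sch, pulse).values
        assert np.allclose(sab, sa + sb, rtol=1e-12, atol=1e-15)

    def test_offex_at_origin_identical_to_isoex(self, pulse, small_traj):
        ph = disk_phantom((24, 24), 0.2, 0.05, (0.02, 0.01))
        iso = simulate_acquisition(ph, small_traj, ExcitationScheme.isocenter(), pulse)
        off = simulate_acquisition(
            ph, small_traj, ExcitationScheme.offcenter(PointOfInterest(0, 0, 0)), pulse
        )
        assert np.array_equal(iso.values, off.values)

    def test_vanishing_pulse_duration_approaches_ideal(self, small_traj):
        ph = disk_phantom((24, 24), 0.2, 0.05, (0.05, 0.0))
        short = PulseParams(duration_tau=0.1e-6)
        ideal = simulate_acquisition(ph, small_traj, ExcitationScheme.ideal(), short)
        iso = simulate_acquisition(ph, small_traj, ExcitationScheme.isocenter(), short)
        rel = np.linalg.norm(iso.values - ideal.values) / np.linalg.norm(ideal.values)
        assert rel < 1e-3


class TestSinogram:
    def test_ideal_matches_rotate_and_sum(self, pulse):
        n, fov = 128, 0.4
        ph = disk_phantom((n, n), fov, 0.06, (0.05, 0.02), antialias=True)
        angles = math.pi * np.arange(24) / 24
        s = sinogram(ph, angles, ExcitationScheme.ideal(), pulse, 0.02)
        oracle = np.array(
            [rotate_and_sum(ph.values, th, fov / n) for th in angles]
        )
        assert np.linalg.norm(s - oracle) / np.linalg.norm(oracle) < 0.01

    def test_offex_projection_correct_at_poi_detector_position(self, pulse):
        n, fov, g = 128, 0.4, 0.02
        r0 = first_zero_crossing(g, pulse) * 0.9
        center = np.array([r0, 0.0])
        ph = disk_phantom((n, n), fov, 0.03, center, antialias=True)
        angles = math.pi * np.arange(12) / 12
        s_off = sinogram(ph, angles, ExcitationScheme.offcenter(center), pulse, g)
        s_ideal = sinogram(ph, angles, ExcitationScheme.ideal(), pulse, g)
        vox = fov / n
        for row, th in enumerate(angles):
            t = center @ np.array([math.cos(th), math.sin(th)])
            det = int(round(t / vox)) + n // 2
            assert s_off[row, det] == pytest.approx(s_ideal[row, det], rel=0.01)

    def test_isoex_near_ideal_for_small_central_object(self, pulse):
        n, fov = 96, 0.1  # radius << rzc = 14.7 cm
        ph = disk_phantom((n, n), fov, 0.02, (0.0, 0.0))
        angles = math.pi * np.arange(8) / 8
        s_iso = sinogram(ph, angles, ExcitationScheme.isocenter(), pulse, 0.02)
        s_ideal = sinogram(ph, angles, ExcitationScheme.ideal(), pulse, 0.02)
        assert np.linalg.norm(s_iso - s_ideal) / np.linalg.norm(s_ideal) < 0.02

    def test_requires_2d_phantom(self, pulse):
        ph3 = disk_phantom((8, 8, 8), 0.1, 0.02, (0, 0, 0))
        with pytest.raises(ValueError, match="2D"):
            sinogram(ph3, [0.0], ExcitationScheme.ideal(), pulse, 0.02)
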