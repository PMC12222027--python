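"""Phantom generators: integrals, symmetry, determinism."""

import numpy as np
import pytest

import rotasym as rs
from rotasym.disk import DiskLatticeModel
from rotasym.phantoms import (
    RingPhantomSpec,
    make_concentric_disk_phantom,
    make_cylinder_phantom,
    make_half_maps,
    make_ring_phantom,
)


def single_blob_integral(sigma: float, amplitude: float = 1.0) -> float:
    """Closed-form integral of one isotropic 3D Gaussian."""
    return amplitude * (sigma * np.sqrt(2.0 * np.pi)) ** 3


class TestRingPhantom:
    def test_single_blob_total_density(self):
        spec = RingPhantomSpec(n_subunits=1, ring_radius=50.0, subunit_sigma=10.0)
        phantom = make_ring_phantom(spec, (64, 64, 64), 4.0)
        assert phantom.total_density() == pytest.approx(
            single_blob_integral(10.0), rel=0.01
        )

    @pytest.mark.parametrize("n", [3, 17])
    def test_total_density_scales_with_subunits(self, n):
        spec = RingPhantomSpec(n_subunits=n, ring_radius=80.0, subunit_sigma=8.0)
        phantom = make_ring_phantom(spec, (64, 64, 64), 4.0)
        assert phantom.total_density() == pytest.approx(
            n * single_blob_integral(8.0), rel=0.01
        )

    def test_phase_shift_by_symmetry_angle_is_identity(self):
        base = RingPhantomSpec(n_subunits=17, ring_radius=90.0, subunit_sigma=8.0)
        shifted = RingPhantomSpec(
            n_subunits=17, ring_radius=90.0, subunit_sigma=8.0,
            phase0=2.0 * np.pi / 17,
        )
        a = make_ring_phantom(base, (64, 64, 64), 4.0)
        b = make_ring_phantom(shifted, (64, 64, 64), 4.0)
        assert np.abs(a.grid - b.grid).max() < 1e-9 * a.grid.max()

    def test_rotational_symmetry_under_map_rotation(self, small_c17_map):
        rotated = rs.impose_cyclic_symmetry(small_c17_map, 17)
        dev = np.abs(rotated.grid - small_c17_map.grid).max()
        assert dev < 0.01 * small_c17_map.grid.max()

    def test_ring_must_fit_in_grid(self):
        spec = RingPhantomSpec(n_subunits=17, ring_radius=150.0, subunit_sigma=12.0)
        with pytest.raises(ValueError, match="does not fit"):
            make_ring_phantom(spec, (64, 64, 64), 4.0)

    def test_round_trip_symmetry_detection(self):
        spec = RingPhantomSpec(n_subunits=17, ring_radius=150.0, subunit_sigma=12.0)
        phantom = make_ring_phantom(spec, (128, 128, 128), 4.0)
        call = rs.detect_cyclic_symmetry(phantom, (110, 190), (-30, 30))
        assert call.n_fold == 17


class TestConcentricDiskPhantom:
    def test_reduces_to_ring_phantom_for_one_ring(self):
        model = DiskLatticeModel(R1=90.0, n1=17, n_rings=1)
        disk = make_concentric_disk_phantom(model, 8.0, (64, 64, 64), 4.0)
        ring = make_ring_phantom(
            RingPhantomSpec(n_subunits=17, ring_radius=90.0, subunit_sigma=8.0),
            (64, 64, 64), 4.0,
        )
        assert np.array_equal(disk.grid, ring.grid)

    def test_blob_count_from_total_density(self):
        # 5 rings at the inner-disk stoichiometry: 51+62+73+84+95 = 365 blobs
        model = DiskLatticeModel(R1=180.0, n1=51, spacing_ratio=0.216, n_rings=5)
        disk = make_concentric_disk_phantom(model, 6.0, (192, 192, 192), 4.0)
        n_blobs = disk.total_density() / single_blob_integral(6.0)
        assert n_blobs == pytest.approx(365, rel=0.01)

    def test_radial_profile_peaks_at_each_ring(self):
        model = DiskLatticeModel(R1=100.0, n1=40, spacing_ratio=0.4, n_rings=3)
        disk = make_concentric_disk_phantom(model, 5.0, (160, 160, 160), 4.0)
        profile = rs.radial_density_profile(disk, (-12.0, 12.0))
        for expected in (100.0, 140.0, 180.0):
            peak = rs.peak_radius(profile, (expected - 15.0, expected + 15.0))
            assert peak == pytest.approx(expected, abs=2.0)


class TestCylinderPhantom:
    @pytest.mark.parametrize("radius", [62.0, 51.0])
    def test_peak_radius_matches_construction(self, radius):
        phantom = make_cylinder_phantom(radius, 60.0, 6.0, (128, 128, 128), 2.0)
        profile = rs.radial_density_profile(phantom, (-25.0, 25.0))
        assert rs.peak_radius(profile, (30.0, 90.0)) == pytest.approx(radius, abs=1.0)

    def test_azimuthally_featureless(self, beta_collar_map):
        call = rs.detect_cyclic_symmetry(beta_collar_map, (40.0, 90.0), (-25.0, 25.0))
        assert call.n_fold is None

    def test_invariant_under_lathing(self):
        phantom = make_cylinder_phantom(40.0, 40.0, 5.0, (64, 64, 64), 2.0)
        lathed = rs.cylindrical_average(phantom)
        assert np.abs(lathed.grid - phantom.grid).max() < 0.02 * phantom.grid.max()


class TestHalfMaps:
    def test_infinite_snr_limit_fsc_one(self, small_c17_map):
        a, b = make_half_maps(small_c17_map, snr=np.inf, seed=3)
        curve = rs.fsc_curve(a, b)
        assert np.all(curve.correlation > 1.0 - 1e-9)

    def test_noise_variance_matches_snr(self, small_c17_map):
        snr = 2.0
        a, _ = make_half_maps(small_c17_map, snr=snr, seed=3)
        noise_var = np.var(a.grid - small_c17_map.grid)
        assert noise_var == pytest.approx(np.var(small_c17_map.grid) / snr, rel=0.05)

    def test_fixed_seed_bit_identical(self, small_c17_map):
        a1, b1 = make_half_maps(small_c17_map, snr=2.0, seed=11)
        a2, b2 = make_half_maps(small_c17_map, snr=2.0, seed=11)
        assert np.array_equal(a1.grid, a2.grid) and np.array_equal(b1.grid, b2.grid)
        a3, _ = make_half_maps(small_c17_map, snr=2.0, seed=12)
        assert not np.array_equal(a1.grid, a3.grid)


class TestDensityMapInvariants:
    def test_rejects_tiny_and_non_finite_grids(self):
        with pytest.raises(ValueError):
            rs.DensityMap(np.zeros((4, 4, 4)), 1.0)
        bad = np.zeros((8, 8, 8))
        bad[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            rs.DensityMap(bad, 1.0)
        with pytest.raises(ValueError):
            rs.DensityMap(np.zeros((8, 8, 8)), 0.0)
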