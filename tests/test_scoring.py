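"""Track-length deposition exactness and the derived stimulation metrics."""

import math

import numpy as np
import pytest

from optomc import (
    NO_DEPTH,
    FluenceGrid,
    activation_report,
    activation_volume,
    deposit_track,
    fluence_map,
    interface_profile,
    penetration_depth,
)
from optomc.scoring import _deposit_uniform


def small_grid(**kw):
    return FluenceGrid.uniform(dr=0.01, dz=0.01, r_max=0.1, z_lo=0.0, z_hi=0.1, **kw)


class TestDepositTrack:
    def test_segment_within_one_voxel(self):
        g = small_grid()
        deposit_track(g, (0.001, 0.0, 0.002), (0.001, 0.0, 0.022), 1.0)
        # 0.02 mm split across z-bins [0,0.01) and [0.01,0.02) and [0.02,0.03)
        assert g.values.sum() == pytest.approx(0.02, abs=1e-15)

    def test_equal_split_across_two_voxels(self):
        g = small_grid()
        deposit_track(g, (0.001, 0.0, 0.0), (0.001, 0.0, 0.02), 1.0)
        assert g.values[0, 0] == pytest.approx(0.01, abs=1e-15)
        assert g.values[1, 0] == pytest.approx(0.01, abs=1e-15)

    def test_zero_length_is_noop(self):
        g = small_grid()
        clipped = deposit_track(g, (0.01, 0.0, 0.01), (0.01, 0.0, 0.01), 1.0)
        assert clipped == 0.0
        assert g.values.sum() == 0.0

    def test_conservation_over_random_segments(self):
        """Total deposited + clipped equals sum of weight x length to 1e-10."""
        g = small_grid()
        rng = np.random.default_rng(3)
        total = 0.0
        clipped = 0.0
        for _ in range(10_000):
            p0 = rng.uniform([-0.05, -0.05, -0.02], [0.15, 0.05, 0.12])
            p1 = p0 + rng.uniform(-0.05, 0.05, 3)
            w = rng.uniform(0.1, 1.0)
            clipped += deposit_track(g, tuple(p0), tuple(p1), w)
            total += w * math.sqrt(((p1 - p0) ** 2).sum())
        assert g.values.sum() + clipped == pytest.approx(total, rel=1e-10)

    def test_uniform_fast_path_matches_general(self):
        """The uniform-grid engine path and the general scorer agree bitwise."""
        ga = small_grid()
        gb = small_grid()
        rng = np.random.default_rng(4)
        for _ in range(2_000):
            p0 = rng.uniform([-0.05, -0.05, -0.02], [0.15, 0.05, 0.12])
            p1 = p0 + rng.uniform(-0.05, 0.05, 3)
            w = rng.uniform(0.1, 1.0)
            ca = deposit_track(ga, tuple(p0), tuple(p1), w)
            cb = _deposit_uniform(gb.values, 0.01, 10, 0.0, 0.01, 10, *p0, *p1, w)
            assert ca == pytest.approx(cb, rel=1e-9, abs=1e-15)
        np.testing.assert_allclose(ga.values, gb.values, rtol=1e-9, atol=1e-15)


class TestFluenceMap:
    def test_zero_grid_is_zero_map(self):
        g = small_grid(n_photons=10)
        assert fluence_map(g).sum() == 0.0

    def test_normalisation_identity(self):
        """value = V*N/P in one voxel gives exactly 1 mW/mm^2."""
        g = small_grid(n_photons=50, source_power=2.5)
        V = g.voxel_volumes[3, 2]
        g.values[3, 2] = V * 50 / 2.5
        fl = fluence_map(g)
        assert fl[3, 2] == pytest.approx(1.0, rel=1e-12)

    def test_requires_photons(self):
        with pytest.raises(ValueError):
            fluence_map(small_grid())


class TestActivationMetrics:
    def make_map(self):
        g = FluenceGrid.uniform(dr=0.1, dz=0.01, r_max=0.1, z_lo=0.0, z_hi=0.5, n_photons=1)
        fl = np.zeros(g.values.shape)
        return g, fl

    def test_threshold_above_maximum(self):
        g, fl = self.make_map()
        fl[:, 0] = 0.5
        assert activation_volume(fl, g, 1.0) == 0.0
        assert penetration_depth(fl, g, 1.0) == NO_DEPTH

    def test_constructed_voxel_counting(self):
        g, fl = self.make_map()
        fl[:7, 0] = 2.0  # 7 voxels of volume pi*0.1^2*0.01
        vol = activation_volume(fl, g, 1.0)
        assert vol == pytest.approx(7 * math.pi * 0.01 * 0.01, rel=1e-12)
        rep = activation_report(fl, g, 1.0)
        assert rep.above_voxel_count == 7

    def test_depth_is_last_bin_centre(self):
        g, fl = self.make_map()
        fl[:50, 0] = 2.0
        fl[50:, 0] = 0.0
        assert penetration_depth(fl, g, 1.0) == pytest.approx(0.495)

    def test_monotone_in_threshold(self):
        g, fl = self.make_map()
        rng = np.random.default_rng(5)
        fl[:] = rng.exponential(1.0, fl.shape)
        thresholds = np.linspace(0.2, 3.0, 10)
        vols = [activation_volume(fl, g, t) for t in thresholds]
        depths = [penetration_depth(fl, g, t) for t in thresholds]
        assert all(a >= b for a, b in zip(vols, vols[1:]))
        assert all(a >= b for a, b in zip(depths, depths[1:]))

    def test_tissue_mask_restricts_counting(self):
        g, fl = self.make_map()
        fl[:, 0] = 2.0
        mask = np.zeros(fl.shape, dtype=bool)
        mask[:10] = True
        vol_masked = activation_volume(fl, g, 1.0, mask)
        assert vol_masked == pytest.approx(10 * math.pi * 0.01 * 0.01, rel=1e-12)


class TestInterfaceProfile:
    def test_uniform_row_spans_full_width(self):
        g = FluenceGrid.uniform(dr=0.01, dz=0.01, r_max=0.1, z_lo=-0.05, z_hi=0.05, n_photons=1)
        fl = np.ones(g.values.shape)
        r, prof, d = interface_profile(fl, g)
        assert d == pytest.approx(2 * g.r_centers[-1])
        assert prof.tolist() == [1.0] * len(r)

    def test_half_max_interpolation(self):
        g = FluenceGrid.uniform(dr=0.01, dz=0.01, r_max=0.1, z_lo=-0.05, z_hi=0.05, n_photons=1)
        fl = np.zeros(g.values.shape)
        iz = np.searchsorted(g.z_centers, 0.0, side="right")
        fl[iz, :] = [4.0, 4.0, 2.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0]
        _, _, d = interface_profile(fl, g)
        # half-max = 2.0, crossing exactly at the third bin centre r=0.025
        assert d == pytest.approx(0.05, rel=1e-12)


def test_grid_validation():
    with pytest.raises(ValueError, match="r_edges"):
        FluenceGrid(r_edges=[0.01, 0.02], z_edges=[0.0, 0.1])
    with pytest.raises(ValueError, match="z_edges"):
        FluenceGrid(r_edges=[0.0, 0.01], z_edges=[0.1, 0.0])
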