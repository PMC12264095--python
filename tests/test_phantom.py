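"""Synthetic 4D phantom: traces, binning, anatomy, motion, sequences."""

import numpy as np
import pytest
from scipy.spatial import Delaunay

from voxmotion.fields import Grid3, Mask3D, jacobian_determinant, negative_jacobian_fraction, warp_volume
from voxmotion.phantom import (
    AnatomyConfig,
    bin_trace,
    build_phantom,
    generate_trace,
    load_phantom,
    make_thoraco_mask,
    save_phantom,
    simulate_intrafraction,
)


class TestBreathingTrace:
    def test_jitter_free_trace_is_periodic_unit_range(self):
        tr = generate_trace(20.0, rate_hz=10.0, period_s=4.0, seed=0)
        assert tr.samples.min() == pytest.approx(0.0, abs=1e-9)
        assert tr.samples.max() == pytest.approx(1.0, abs=1e-3)
        np.testing.assert_allclose(tr.samples[:40], tr.samples[40:80], atol=1e-9)

    def test_one_minute_at_acquisition_rate_gives_630_samples(self):
        tr = generate_trace(60.0, rate_hz=10.5)
        assert len(tr.samples) == 630

    def test_deterministic_under_seed(self):
        a = generate_trace(30.0, amplitude_jitter=0.1, period_jitter=0.1, seed=4)
        b = generate_trace(30.0, amplitude_jitter=0.1, period_jitter=0.1, seed=4)
        c = generate_trace(30.0, amplitude_jitter=0.1, period_jitter=0.1, seed=5)
        np.testing.assert_array_equal(a.samples, b.samples)
        assert not np.array_equal(a.samples, c.samples)

    def test_cardiac_component_adds_high_frequency(self):
        base = generate_trace(20.0, seed=0)
        card = generate_trace(20.0, cardiac_fraction=0.1, seed=0)
        assert not np.array_equal(base.samples, card.samples)


class TestBinning:
    def test_constant_trace_all_in_bin_one(self):
        tr = generate_trace(10.0, seed=0)
        tr.samples = np.zeros_like(tr.samples)
        assert set(bin_trace(tr)) == {1}

    def test_linear_ramp_fills_bins_evenly(self):
        tr = generate_trace(10.0, rate_hz=10.0, seed=0)
        tr.samples = np.linspace(0, 1, 100)
        labels = bin_trace(tr, 10)
        counts = np.bincount(labels)[1:]
        assert counts.sum() == 100
        assert counts.min() >= 9 and counts.max() <= 11

    def test_labels_within_requested_range(self):
        tr = generate_trace(30.0, amplitude_jitter=0.1, seed=2)
        labels = bin_trace(tr, 10)
        assert labels.min() >= 1 and labels.max() <= 10

    def test_requires_at_least_two_bins(self):
        tr = generate_trace(10.0, seed=0)
        with pytest.raises(ValueError):
            bin_trace(tr, 1)


class TestBuildPhantom:
    def test_zero_amplitude_collapses_to_reference(self):
        grid = Grid3((16, 16, 16), (6.0, 6.0, 6.0))
        tr = generate_trace(30.0, amplitude_mm=0.0, seed=3)
        ph = build_phantom(AnatomyConfig(grid=grid), tr)
        for b in range(10):
            assert ph.dvfs[b].max_magnitude_mm() == 0.0
            np.testing.assert_array_equal(ph.bins[b].values, ph.reference.values)

    def test_amplitude_doubles_deep_inhale_excursion(self):
        """Doubling the programmed amplitude doubles the target centroid
        displacement.  Thresholded-mask centroids quantise to whole voxels
        under quasi-rigid motion, so the ratio is taken on the displacement
        summed over the deep-inhale bins, which dithers the quantisation."""
        grid = Grid3((64, 64, 64), (2.0, 2.0, 2.0))
        shifts = {}
        for amp in (5.0, 10.0):
            tr = generate_trace(60.0, amplitude_mm=amp, amplitude_jitter=0.05, period_jitter=0.05, seed=11)
            ph = build_phantom(AnatomyConfig(grid=grid), tr)
            c0 = ph.reference_structures["target"].centroid_mm()
            shifts[amp] = sum(
                ph.structures[b]["target"].centroid_mm()[2] - c0[2] for b in range(5, 10)
            )
        assert shifts[10.0] / shifts[5.0] == pytest.approx(2.0, rel=0.10)

    def test_ground_truth_fields_are_diffeomorphic(self, phantom32):
        for phi in phantom32.dvfs:
            assert negative_jacobian_fraction(jacobian_determinant(phi)) == 0.0

    def test_bins_round_trip_through_warp(self, phantom32):
        for b in (1, 5, 9):
            rewarped = warp_volume(phantom32.reference, phantom32.dvfs[b])
            np.testing.assert_allclose(rewarped.values, phantom32.bins[b].values, atol=1e-12)

    def test_target_excursion_monotone_in_amplitude(self, phantom32):
        c0 = phantom32.reference_structures["target"].centroid_mm()
        si = [phantom32.structures[b]["target"].centroid_mm()[2] - c0[2] for b in range(10)]
        halfvox = 0.5 * phantom32.grid.spacing[2]
        assert all(si[b + 1] <= si[b] + halfvox for b in range(9))

    def test_excessive_amplitude_rejected(self):
        grid = Grid3((16, 16, 16), (2.0, 2.0, 2.0))
        tr = generate_trace(30.0, amplitude_mm=150.0, seed=3)
        with pytest.raises(ValueError, match="amplitude"):
            build_phantom(AnatomyConfig(grid=grid), tr)

    def test_reference_bin_dvf_is_identity(self, phantom32):
        assert phantom32.dvfs[0].max_magnitude_mm() == 0.0


class TestThoracoMask:
    def test_contains_both_lungs(self, phantom32):
        m = phantom32.thoraco_mask.values
        for lung in ("left_lung", "right_lung"):
            assert (m >= phantom32.reference_structures[lung].values).all()

    def test_extends_to_inferior_boundary(self, phantom32):
        m = phantom32.thoraco_mask.values
        footprint = m.any(axis=2)
        assert (m[:, :, 0][footprint]).all()

    def test_hull_matches_brute_force_rasterization(self):
        grid = Grid3((14, 14, 14), (1.0, 1.0, 1.0))
        a = np.zeros(grid.shape, dtype=np.uint8)
        a[2:5, 2:5, 2:5] = 1
        b = np.zeros_like(a)
        b[9:12, 9:12, 6:9] = 1
        got = make_thoraco_mask(Mask3D(grid, a), Mask3D(grid, b), dilation_mm=0.0)
        pts = np.argwhere((a | b) > 0)
        tri = Delaunay(pts)
        coords = np.argwhere(np.ones(grid.shape, dtype=bool))
        hull = np.zeros(grid.shape, dtype=np.uint8)
        hull[tuple(coords[tri.find_simplex(coords) >= 0].T)] = 1
        # hull plus inferior fill below its footprint
        footprint = hull.any(axis=2)
        lowest = np.where(hull, np.arange(grid.shape[2])[None, None, :], grid.shape[2]).min(axis=2)
        si = np.arange(grid.shape[2])[None, None, :]
        hull |= (footprint[:, :, None] & (si <= lowest[:, :, None])).astype(np.uint8)
        np.testing.assert_array_equal(got.values, hull)

    def test_empty_lungs_rejected(self):
        grid = Grid3((8, 8, 8))
        empty = Mask3D(grid, np.zeros(grid.shape, dtype=np.uint8))
        with pytest.raises(ValueError):
            make_thoraco_mask(empty, empty)


class TestIntrafraction:
    def test_angles_span_arc_linearly(self, phantom16):
        tr = generate_trace(60.0, rate_hz=10.5, amplitude_mm=10.0, seed=6)
        seq = simulate_intrafraction(phantom16, tr)
        assert len(seq) == 630
        np.testing.assert_allclose(np.diff(seq.angles_deg[:100]), 360.0 / 630, atol=1e-9)

    def test_zero_amplitude_yields_reference_volumes(self, phantom16):
        tr = generate_trace(5.0, amplitude_mm=0.0, seed=6)
        ph = build_phantom(AnatomyConfig(grid=phantom16.grid), tr)
        seq = simulate_intrafraction(ph, tr)
        np.testing.assert_array_equal(seq.volume_at(3).values, ph.reference.values)

    def test_bin_snapped_volumes_match_phantom_bins(self, phantom16):
        tr = generate_trace(5.0, amplitude_mm=10.0, amplitude_jitter=0.05, seed=8)
        seq = simulate_intrafraction(phantom16, tr, bin_snapped=True)
        for i in (0, 10, 25, 40):
            vol = seq.volume_at(i).values
            assert any(np.array_equal(vol, b.values) for b in phantom16.bins)

    def test_requires_two_samples(self, phantom16):
        tr = generate_trace(60.0, amplitude_mm=10.0, seed=6)
        tr.samples = tr.samples[:1]
        with pytest.raises(ValueError):
            simulate_intrafraction(phantom16, tr)


def test_hdf5_round_trip(tmp_path, phantom16):
    path = str(tmp_path / "phantom.h5")
    save_phantom(path, phantom16)
    back = load_phantom(path)
    np.testing.assert_allclose(back.reference.values, phantom16.reference.values)
    np.testing.assert_allclose(back.dvfs[5].components, phantom16.dvfs[5].components)
    np.testing.assert_array_equal(
        back.structures[3]["target"].values, phantom16.structures[3]["target"].values
    )
    assert back.amplitude_mm == phantom16.amplitude_mm
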