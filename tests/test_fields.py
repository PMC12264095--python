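"""Geometry core: integration, composition, warping, Jacobian diagnostics."""

import numpy as np
import pytest
from scipy.ndimage import map_coordinates

from voxmotion.fields import (
    DisplacementField,
    Grid3,
    Mask3D,
    VelocityField,
    Volume3D,
    compose,
    integrate_velocity,
    invert,
    jacobian_determinant,
    negative_jacobian_fraction,
    read_displacement_field,
    read_volume,
    warp_mask,
    warp_volume,
    write_displacement_field,
    write_volume,
)

from conftest import smooth_velocity

INTERIOR = (slice(4, -4),) * 3


def euler_integrate(u: VelocityField, steps: int = 1024) -> np.ndarray:
    """Independent oracle: forward-Euler integration of the flow ODE."""
    grid = u.grid
    disp = np.zeros_like(u.components)
    coords = np.stack(grid.voxel_coords())
    spacing = np.asarray(grid.spacing).reshape(3, 1, 1, 1)
    for _ in range(steps):
        cur = coords + disp / spacing
        vel = np.stack([map_coordinates(c, cur, order=1, mode="nearest") for c in u.components])
        disp = disp + vel / steps
    return disp


class TestIntegrateVelocity:
    def test_zero_velocity_is_identity(self, grid24):
        u = VelocityField(grid24, np.zeros((3,) + grid24.shape))
        phi = integrate_velocity(u, 10)
        assert phi.max_magnitude_mm() == 0.0
        assert phi.provenance.startswith("integrated")

    def test_uniform_velocity_is_pure_translation(self, grid24):
        c = np.array([1.5, -2.0, 3.0])
        u = VelocityField(grid24, np.broadcast_to(c.reshape(3, 1, 1, 1), (3,) + grid24.shape).copy())
        phi = integrate_velocity(u, 10)
        # interior voxels never sample beyond the (constant) field
        inner = phi.components[(slice(None),) + INTERIOR]
        assert np.abs(inner - c.reshape(3, 1, 1, 1)).max() < 1e-9

    def test_matches_euler_oracle_on_smooth_field(self, grid24):
        u = smooth_velocity(grid24, seed=0, max_voxels=3.0)
        phi = integrate_velocity(u, 10)
        oracle = euler_integrate(u, 1024)
        err_vox = np.abs(phi.components - oracle) / np.asarray(grid24.spacing).reshape(3, 1, 1, 1)
        assert err_vox[(slice(None),) + INTERIOR].max() < 0.05

    def test_rejects_bad_inputs(self, grid24):
        comps = np.zeros((3,) + grid24.shape)
        comps[0, 0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            VelocityField(grid24, comps)
        u = VelocityField(grid24, np.zeros((3,) + grid24.shape))
        with pytest.raises(ValueError):
            integrate_velocity(u, 0)

    def test_doubling_T_converges_monotonically(self, grid24):
        u = smooth_velocity(grid24, seed=3, max_voxels=3.0)
        phis = {T: integrate_velocity(u, T).components for T in (5, 6, 12)}
        step_small = np.abs(phis[12] - phis[6]).max()
        step_prev = np.abs(phis[6] - phis[5]).max()
        assert step_small < step_prev

    def test_inverse_velocity_composes_to_identity(self, grid24):
        u = smooth_velocity(grid24, seed=5, max_voxels=3.0)
        fwd = integrate_velocity(u, 10)
        bwd = integrate_velocity(VelocityField(grid24, -u.components), 10)
        resid = compose(fwd, bwd).components
        resid_vox = np.abs(resid) / np.asarray(grid24.spacing).reshape(3, 1, 1, 1)
        assert resid_vox[(slice(None),) + INTERIOR].max() < 0.1


class TestComposeInvert:
    def test_compose_with_identity(self, grid24):
        phi = integrate_velocity(smooth_velocity(grid24, seed=1), 8)
        ident = DisplacementField.identity(grid24)
        np.testing.assert_allclose(compose(ident, phi).components, phi.components, atol=1e-9)

    def test_uniform_translations_add(self, grid24):
        a = np.array([2.0, 0.0, -1.0]).reshape(3, 1, 1, 1)
        b = np.array([-0.5, 1.0, 2.0]).reshape(3, 1, 1, 1)
        fa = DisplacementField(grid24, np.broadcast_to(a, (3,) + grid24.shape).copy())
        fb = DisplacementField(grid24, np.broadcast_to(b, (3,) + grid24.shape).copy())
        out = compose(fa, fb).components[(slice(None),) + INTERIOR]
        assert np.abs(out - (a + b)).max() < 1e-9

    def test_grid_mismatch_rejected(self, grid24):
        other = Grid3((16, 16, 16), (2.0, 2.0, 2.0))
        with pytest.raises(ValueError):
            compose(DisplacementField.identity(grid24), DisplacementField.identity(other))

    def test_invert_trivial_cases(self, grid24):
        ident = DisplacementField.identity(grid24)
        assert invert(ident).max_magnitude_mm() < 1e-12
        c = np.array([3.0, -1.0, 2.0]).reshape(3, 1, 1, 1)
        shift = DisplacementField(grid24, np.broadcast_to(c, (3,) + grid24.shape).copy())
        inv = invert(shift)
        assert np.abs(inv.components[(slice(None),) + INTERIOR] + c).max() < 1e-6

    def test_invert_then_compose_is_identity(self, grid24):
        phi = integrate_velocity(smooth_velocity(grid24, seed=2, max_voxels=3.0), 10)
        resid = compose(phi, invert(phi)).components
        resid_vox = np.abs(resid) / np.asarray(grid24.spacing).reshape(3, 1, 1, 1)
        assert resid_vox[(slice(None),) + INTERIOR].max() < 0.1

    def test_invert_warns_on_folded_field(self, grid24):
        comps = np.zeros((3,) + grid24.shape)
        comps[0] = -4.0 * np.sin(np.arange(grid24.shape[0]))[:, None, None]  # rough, folding
        folded = DisplacementField(grid24, comps)
        with pytest.warns(RuntimeWarning):
            invert(folded, iterations=2)


class TestWarping:
    def test_identity_warp_is_exact(self, grid24):
        rng = np.random.default_rng(0)
        vol = Volume3D(grid24, rng.random(grid24.shape))
        out = warp_volume(vol, DisplacementField.identity(grid24))
        np.testing.assert_array_equal(out.values, vol.values)

    def test_integer_shift_matches_rolled_array(self, grid24):
        rng = np.random.default_rng(1)
        vol = Volume3D(grid24, rng.random(grid24.shape))
        shift_vox = np.array([2, 0, -1])
        comps = (shift_vox * np.asarray(grid24.spacing)).reshape(3, 1, 1, 1)
        phi = DisplacementField(grid24, np.broadcast_to(comps, (3,) + grid24.shape).copy())
        out = warp_volume(vol, phi).values
        expected = vol.values[4:-4, 4:-4, 4:-4]
        got = out[2:-6, 4:-4, 5:-3]  # interior window shifted by (2, 0, -1)
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_matches_per_voxel_interpolation_oracle(self):
        grid = Grid3((16, 16, 16), (2.0, 1.0, 2.0))
        rng = np.random.default_rng(7)
        vol = Volume3D(grid, rng.random(grid.shape))
        phi = integrate_velocity(smooth_velocity(grid, seed=8, max_voxels=2.0, sigma=3.0), 8)
        out = warp_volume(vol, phi).values
        spacing = np.asarray(grid.spacing)
        oracle = np.empty(grid.shape)
        for i in range(16):
            for j in range(16):
                for k in range(16):
                    p = np.array([i, j, k]) + phi.components[:, i, j, k] / spacing
                    p = np.clip(p, 0.0, 15.0)
                    i0 = np.minimum(p.astype(int), 14)
                    f = p - i0
                    acc = 0.0
                    for ci in (0, 1):
                        for cj in (0, 1):
                            for ck in (0, 1):
                                w = (f[0] if ci else 1 - f[0]) * (f[1] if cj else 1 - f[1]) * (f[2] if ck else 1 - f[2])
                                acc += w * vol.values[i0[0] + ci, i0[1] + cj, i0[2] + ck]
                    oracle[i, j, k] = acc
        np.testing.assert_allclose(out, oracle, rtol=1e-6, atol=1e-9)

    def test_mask_warp_identity_and_shift(self, grid24):
        lr, ap, si = grid24.voxel_coords()
        sphere = (((lr - 12) ** 2 + (ap - 12) ** 2 + (si - 12) ** 2) <= 36).astype(np.uint8)
        mask = Mask3D(grid24, sphere)
        assert np.array_equal(warp_mask(mask, DisplacementField.identity(grid24)).values, sphere)
        comps = np.zeros((3,) + grid24.shape)
        comps[2] = 2.0 * grid24.spacing[2]
        shifted = warp_mask(mask, DisplacementField(grid24, comps)).values
        np.testing.assert_array_equal(shifted[:, :, 4:-4], sphere[:, :, 6:-2])

    def test_sphere_under_uniform_scaling_has_analytic_volume(self):
        grid = Grid3((40, 40, 40), (1.0, 1.0, 1.0))
        lr, ap, si = grid.voxel_coords()
        r = 10.0
        sphere = (((lr - 20) ** 2 + (ap - 20) ** 2 + (si - 20) ** 2) <= r**2).astype(np.uint8)
        mask = Mask3D(grid, sphere)
        # backward warp samples at v + s*(v - c): shrinks content by (1+s)^-1
        s = 0.2
        comps = np.stack([s * (lr - 20), s * (ap - 20), s * (si - 20)])
        warped = warp_mask(mask, DisplacementField(grid, comps))
        expected = sphere.sum() / (1 + s) ** 3
        assert abs(warped.values.sum() - expected) / expected < 0.05


class TestJacobian:
    def test_identity_has_unit_determinant(self, grid24):
        detj = jacobian_determinant(DisplacementField.identity(grid24))
        np.testing.assert_allclose(detj.values, 1.0, atol=1e-12)

    def test_linear_expansion_is_analytic(self, grid24):
        lr, ap, si = grid24.voxel_coords()
        sp = np.asarray(grid24.spacing)
        comps = np.stack([0.1 * lr * sp[0], 0.1 * ap * sp[1], 0.1 * si * sp[2]])
        detj = jacobian_determinant(DisplacementField(grid24, comps))
        np.testing.assert_allclose(detj.values[INTERIOR], 1.1**3, rtol=1e-9)

    def test_negative_fraction_cases(self, grid24):
        ident = jacobian_determinant(DisplacementField.identity(grid24))
        assert negative_jacobian_fraction(ident) == 0.0
        flipped = Volume3D(grid24, -np.ones(grid24.shape))
        assert negative_jacobian_fraction(flipped) == 1.0
        toy = np.ones((3, 3, 3))
        toy.flat[:3] = -1.0
        assert negative_jacobian_fraction(Volume3D(Grid3((3, 3, 3)), toy)) == pytest.approx(3 / 27)

    def test_integrated_fields_preserve_topology(self, grid24):
        # 50 random smoothed fields with up to 5-voxel velocities
        for seed in range(50):
            u = smooth_velocity(grid24, seed=seed, max_voxels=5.0)
            detj = jacobian_determinant(integrate_velocity(u, 10))
            assert negative_jacobian_fraction(detj) == 0.0


class TestIO:
    @pytest.mark.parametrize("ext", ["nii.gz", "mha"])
    def test_volume_round_trip(self, tmp_path, ext):
        grid = Grid3((8, 10, 12), (1.0, 2.0, 3.0), (5.0, -4.0, 0.0))
        vol = Volume3D(grid, np.random.default_rng(0).random(grid.shape))
        path = str(tmp_path / f"vol.{ext}")
        write_volume(path, vol)
        back = read_volume(path)
        assert back.grid.shape == grid.shape
        np.testing.assert_allclose(back.grid.spacing, grid.spacing)
        np.testing.assert_allclose(back.values, vol.values, atol=1e-6)

    @pytest.mark.parametrize("ext", ["nii.gz", "mha"])
    def test_displacement_round_trip(self, tmp_path, ext):
        grid = Grid3((8, 8, 8), (2.0, 2.0, 2.0))
        phi = DisplacementField(grid, np.random.default_rng(1).standard_normal((3,) + grid.shape))
        path = str(tmp_path / f"dvf.{ext}")
        write_displacement_field(path, phi)
        back = read_displacement_field(path)
        np.testing.assert_allclose(back.components, phi.components, atol=1e-5)
        np.testing.assert_allclose(back.grid.spacing, grid.spacing)
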