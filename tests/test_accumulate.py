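import numpy as np
import pytest
from scipy import ndimage

from dose4d import (
    DeformationField,
    GridGeometry,
    VoxelGrid,
    build_transfer,
    ddm_map,
    emt_dose,
    emt_map,
    precompute_deformed_mass,
    voxel_mass,
)

from conftest import random_grid


def smooth_dvf(rng, geom, amp=3.0):
    v = ndimage.gaussian_filter(rng.normal(0, amp, geom.shape + (3,)),
                                sigma=(3, 3, 3, 0))
    return DeformationField(v, "push", geom.spacing, geom.origin)


def zero_dvf(geom):
    return DeformationField(np.zeros(geom.shape + (3,)), "push",
                            geom.spacing, geom.origin)


class TestVoxelMass:
    def test_unit_density_2mm_voxel(self):
        g = VoxelGrid(np.ones((2, 2, 2)), (2.0, 2.0, 2.0), (0, 0, 0))
        np.testing.assert_allclose(voxel_mass(g).data, 0.008)
        z = VoxelGrid(np.zeros((2, 2, 2)), (2.0, 2.0, 2.0), (0, 0, 0))
        assert voxel_mass(z).data.sum() == 0.0
        with pytest.raises(ValueError):
            voxel_mass(VoxelGrid(np.full((2, 2, 2), -1.0), (1, 1, 1), (0, 0, 0)))

    def test_unit_sphere_total_mass(self):
        geom = GridGeometry.centered((32, 32, 32), (0.5, 0.5, 0.5))
        cx, cy, cz = geom.voxel_centers()
        xx, yy, zz = np.meshgrid(cx, cy, cz, indexing="ij")
        r = (3.0 / (4.0 * np.pi) * 1000.0) ** (1.0 / 3.0)  # 1 cm^3 sphere
        dens = (xx**2 + yy**2 + zz**2 <= r**2).astype(float)
        total = voxel_mass(VoxelGrid(dens, geom.spacing, geom.origin)).data.sum()
        assert total == pytest.approx(1.0, rel=0.02)


class TestTransfer:
    def test_identity_dvf_is_identity_operator(self, rng):
        geom = GridGeometry.centered((10, 10, 8), (1.0, 1.0, 2.0))
        assert build_transfer(zero_dvf(geom), 4) is None

    def test_uniform_one_voxel_translation(self, rng):
        g = random_grid(rng, (10, 10, 10), (2.0, 2.0, 2.0))
        m = voxel_mass(g)
        v = np.zeros(g.data.shape + (3,))
        v[..., 0] = 2.0
        S = build_transfer(DeformationField(v, "push", g.spacing, g.origin), 3)
        dep = (S @ m.data.ravel()).reshape(g.data.shape)
        expected = np.zeros_like(m.data)
        expected[1:] = m.data[:-1]
        np.testing.assert_allclose(dep, expected, rtol=1e-12, atol=1e-15)
        lost = m.data.sum() - dep.sum()
        assert lost == pytest.approx(m.data[-1].sum(), rel=1e-12)

    def test_mass_conservation_random_smooth(self, rng):
        geom = GridGeometry.centered((12, 12, 12), (2.0, 2.0, 2.0))
        for _ in range(10):
            m = voxel_mass(random_grid(rng, (12, 12, 12)))
            S = build_transfer(smooth_dvf(rng, geom), 4)
            dep = S @ m.data.ravel()
            lost = m.data.sum() - dep.sum()
            assert abs(dep.sum() + lost - m.data.sum()) <= 1e-9 * m.data.sum()
            assert lost >= -1e-12

    def test_subvoxel_count_validated(self, rng):
        geom = GridGeometry.centered((4, 4, 4), (2.0, 2.0, 2.0))
        with pytest.raises(ValueError):
            build_transfer(smooth_dvf(rng, geom), 0)


class TestEMT:
    def test_identity_energy_product_exact(self, rng):
        g = random_grid(rng, (8, 8, 8))
        m = voxel_mass(g)
        dose = random_grid(rng, (8, 8, 8))
        e, lost = emt_map(dose, m, zero_dvf(g.geometry), 4)
        np.testing.assert_array_equal(e.data, dose.data * m.data)
        assert lost == 0.0

    def test_energy_conservation_any_dvf(self, rng):
        geom = GridGeometry.centered((10, 10, 10), (2.0, 2.0, 2.0))
        dose = random_grid(rng, (10, 10, 10))
        m = voxel_mass(random_grid(rng, (10, 10, 10)))
        e, lost = emt_map(dose, m, smooth_dvf(rng, geom, 4.0), 4)
        total_src = float((dose.data * m.data).sum())
        assert e.data.sum() + lost == pytest.approx(total_src, rel=1e-9)

    def test_uniform_dose_invariance(self, rng):
        geom = GridGeometry.centered((10, 10, 10), (2.0, 2.0, 2.0))
        m = voxel_mass(random_grid(rng, (10, 10, 10)))
        push = smooth_dvf(rng, geom)
        S = build_transfer(push, 4)
        u = VoxelGrid(np.full(geom.shape, 2.5), geom.spacing, geom.origin)
        e, _ = emt_map(u, m, push, transfer=S)
        dm = m.like((S @ m.data.ravel()).reshape(geom.shape))
        d = emt_dose(e, dm)
        ok = dm.data > 1e-6
        np.testing.assert_allclose(d.data[ok], 2.5, rtol=1e-9)
        np.testing.assert_array_equal(d.data[~ok], 0.0)

    def test_rigid_translation_dose_preserved(self, rng):
        g = random_grid(rng, (10, 10, 10), (2.0, 2.0, 2.0))
        m = voxel_mass(g.like(np.full(g.data.shape, 0.8)))
        dose = random_grid(rng, (10, 10, 10), (2.0, 2.0, 2.0))
        v = np.zeros(g.data.shape + (3,))
        v[..., 2] = 2.0
        push = DeformationField(v, "push", g.spacing, g.origin)
        e, _ = emt_map(dose, m, push, 4)
        dm = m.like((build_transfer(push, 4) @ m.data.ravel()).reshape(g.data.shape))
        d = emt_dose(e, dm)
        expected = np.zeros_like(dose.data)
        expected[:, :, 1:] = dose.data[:, :, :-1]
        np.testing.assert_allclose(d.data[:, :, 1:], expected[:, :, 1:], rtol=1e-9)

    def test_zero_energy_zero_dose(self):
        geom = GridGeometry.centered((6, 6, 6), (2.0, 2.0, 2.0))
        z = VoxelGrid(np.zeros(geom.shape), geom.spacing, geom.origin)
        m = VoxelGrid(np.full(geom.shape, 0.01), geom.spacing, geom.origin)
        assert emt_dose(z, m).data.sum() == 0.0

    def test_subvoxel_refinement_convergence(self, rng):
        geom = GridGeometry.centered((14, 14, 14), (2.0, 2.0, 2.0))
        m = voxel_mass(VoxelGrid(np.full(geom.shape, 1.0), geom.spacing, geom.origin))
        cx, cy, cz = geom.voxel_centers()
        xx, yy, zz = np.meshgrid(cx, cy, cz, indexing="ij")
        blob = np.exp(-(xx**2 + yy**2 + zz**2) / (2 * 6.0**2))
        dose = VoxelGrid(blob, geom.spacing, geom.origin)
        push = smooth_dvf(rng, geom, 3.0)
        doses = {}
        for s in (2, 4, 8):
            S = build_transfer(push, s)
            e, _ = emt_map(dose, m, push, transfer=S)
            dm = m.like((S @ m.data.ravel()).reshape(geom.shape))
            doses[s] = emt_dose(e, dm).data
        err48 = np.abs(doses[4] - doses[8]).max() / doses[8].max()
        err24 = np.abs(doses[2] - doses[4]).max() / doses[4].max()
        assert err48 < 0.01
        assert err48 <= err24 + 1e-12


class TestDDM:
    def test_identity_and_uniform(self, rng):
        g = random_grid(rng, (8, 8, 8), (2.0, 2.0, 2.0))
        pull0 = DeformationField(np.zeros(g.data.shape + (3,)), "pull",
                                 g.spacing, g.origin)
        np.testing.assert_allclose(ddm_map(g, pull0).data, g.data, atol=1e-12)
        u = g.like(np.full(g.data.shape, 3.3))
        v = ndimage.gaussian_filter(
            np.random.default_rng(0).normal(0, 2, g.data.shape + (3,)), (2, 2, 2, 0))
        pull = DeformationField(v, "pull", g.spacing, g.origin)
        np.testing.assert_allclose(ddm_map(u, pull).data, 3.3, atol=1e-12)

    def test_push_field_rejected(self, rng):
        g = random_grid(rng, (6, 6, 6))
        push = DeformationField(np.zeros(g.data.shape + (3,)), "push",
                                g.spacing, g.origin)
        with pytest.raises(ValueError):
            ddm_map(g, push)

    def test_emt_ddm_agree_on_means_differ_locally(self, rng):
        """Under a compressive field EMT and DDM differ at a sharp dose edge
        while region means over uniform areas agree closely."""
        geom = GridGeometry.centered((16, 16, 16), (2.0, 2.0, 2.0))
        m = voxel_mass(VoxelGrid(np.ones(geom.shape), geom.spacing, geom.origin))
        dose_arr = np.zeros(geom.shape)
        dose_arr[:8] = 10.0  # sharp edge at the grid center
        dose = VoxelGrid(dose_arr, geom.spacing, geom.origin)
        # compressive push toward the center along x
        cx = geom.voxel_centers()[0]
        vx = -0.25 * cx
        v = np.zeros(geom.shape + (3,))
        v[..., 0] = vx[:, None, None]
        push = DeformationField(v, "push", geom.spacing, geom.origin)
        pull_v = np.zeros(geom.shape + (3,))
        pull_v[..., 0] = (cx / 0.75 - cx)[:, None, None]  # exact inverse of x -> 0.75 x
        pull = DeformationField(pull_v, "pull", geom.spacing, geom.origin)
        S = build_transfer(push, 4)
        e, _ = emt_map(dose, m, push, transfer=S)
        dm = m.like((S @ m.data.ravel()).reshape(geom.shape))
        d_emt = emt_dose(e, dm).data
        d_ddm = ddm_map(dose, pull).data
        interior = np.s_[3:5, 4:12, 4:12]  # uniform high-dose region
        assert abs(d_emt[interior].mean() - d_ddm[interior].mean()) < 0.1
        assert np.abs(d_emt - d_ddm).max() > 0.5  # local disagreement at the edge


class TestDeformedMass:
    def test_precompute_identity_phase(self, static_phases):
        dm = precompute_deformed_mass(static_phases.densities[:2],
                                      static_phases.push[:2], 2)
        for d in dm:
            assert d.transfer is None
            assert d.lost_mass == 0.0
            np.testing.assert_array_equal(d.mass.data, d.source_mass.data)

    def test_conservation_on_phantom(self, small_phases):
        dm = precompute_deformed_mass(small_phases.densities,
                                      small_phases.push, 2)
        for p, d in enumerate(dm):
            total = d.source_mass.data.sum()
            assert d.mass.data.sum() + d.lost_mass == pytest.approx(total, rel=1e-9)
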