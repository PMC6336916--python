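"""Feature operators against analytic phantoms and brute-force oracles."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from fcdsurf.features import (cortical_thickness, doughnut_map,
                              flair_profile, gwc,
                              interhemispheric_asymmetry,
                              local_cortical_deformation, pet_hypointensity,
                              sulcal_depth)
from fcdsurf.surface import (CorticalSurfacePair, HomotopicCorrespondence,
                             ScalarVolume, SurfaceScalarMap, TriangleMesh)
from fcdsurf.synthetic import CohortSpec, SyntheticSubject, flat_grid, icosphere

from conftest import dijkstra_oracle, make_volume


class TestThickness:
    def test_identical_surfaces_zero(self, planar_pair):
        pair = CorticalSurfacePair(white=planar_pair.white,
                                   pial=planar_pair.white)
        assert np.all(cortical_thickness(pair).values == 0)

    def test_parallel_planes(self, planar_pair):
        np.testing.assert_allclose(cortical_thickness(planar_pair).values,
                                   3.0, atol=1e-12)

    def test_concentric_spheres_radial(self):
        white = icosphere(2, 50.0)
        pial = TriangleMesh(white.vertices * (53.0 / 50.0), white.faces)
        pair = CorticalSurfacePair(white=white, pial=pial)
        got = cortical_thickness(pair).values
        expected = np.linalg.norm(pial.vertices - white.vertices, axis=1)
        np.testing.assert_allclose(got, expected, atol=1e-12)
        np.testing.assert_allclose(got, 3.0, atol=1e-6)


class TestGWC:
    def test_uniform_volume_unity(self, planar_pair):
        vol = make_volume(lambda x, y, z: np.full_like(x, 90.0))
        np.testing.assert_allclose(gwc(vol, planar_pair).values, 1.0,
                                   atol=1e-12)

    def test_sharp_phantom_ratio(self, planar_pair):
        vol = make_volume(lambda x, y, z: np.where(z < 0, 120.0, 80.0))
        got = gwc(vol, planar_pair).values
        np.testing.assert_allclose(got, 80.0 / 120.0, atol=1e-9)

    def test_blur_moves_ratio_toward_one(self, planar_pair):
        sharp = make_volume(lambda x, y, z: np.where(z < 0, 120.0, 80.0))
        blurred = ScalarVolume(gaussian_filter(sharp.data, 1.5),
                               sharp.affine)
        g_sharp = gwc(sharp, planar_pair).values
        g_blur = gwc(blurred, planar_pair).values
        assert np.all(g_blur > g_sharp)
        assert np.all(g_blur < 1.0)


class TestFlairProfile:
    def test_uniform_volume_all_depths_equal(self, planar_pair):
        vol = make_volume(lambda x, y, z: np.full_like(x, 55.0))
        maps = flair_profile(vol, planar_pair)
        assert set(maps) == {"flair_00", "flair_25", "flair_50", "flair_75",
                             "flair_m05", "flair_m10"}
        for smap in maps.values():
            np.testing.assert_allclose(smap.values, 55.0, atol=1e-12)

    def test_ramp_affine_in_depth(self, planar_pair):
        vol = make_volume(lambda x, y, z: z)
        maps = flair_profile(vol, planar_pair)
        # white z=0, pial z=3: depths 0, .75, 1.5, 2.25, -0.5, -1.0
        for name, expect in [("flair_00", 0.0), ("flair_25", 0.75),
                             ("flair_50", 1.5), ("flair_75", 2.25),
                             ("flair_m05", -0.5), ("flair_m10", -1.0)]:
            np.testing.assert_allclose(maps[name].values, expect, atol=1e-9)

    def test_blur_reduces_vertical_gradient(self, planar_pair):
        sharp = make_volume(lambda x, y, z: np.where(z < 0, 70.0, 100.0))
        blurred = ScalarVolume(gaussian_filter(sharp.data, 1.5),
                               sharp.affine)
        g_sharp = flair_profile(sharp, planar_pair)
        g_blur = flair_profile(blurred, planar_pair)
        grad_sharp = g_sharp["flair_00"].values - g_sharp["flair_m10"].values
        grad_blur = g_blur["flair_00"].values - g_blur["flair_m10"].values
        assert np.mean(np.abs(grad_blur)) < np.mean(np.abs(grad_sharp))


class TestSulcalDepth:
    def test_plane_all_crowns_zero_depth(self, plane):
        depth = sulcal_depth(plane, smoothing_iterations=50).values
        np.testing.assert_allclose(depth, 0.0, atol=1e-9)

    def test_nonnegative_and_zero_on_crowns(self):
        mesh = _folded_strip()
        depth = sulcal_depth(mesh).values
        assert (depth >= 0).all()
        assert np.any(depth == 0)

    def test_trough_depth_matches_multisource_oracle(self):
        mesh = _folded_strip()
        depth = sulcal_depth(mesh).values
        crowns = np.flatnonzero(depth == 0)
        oracle = dijkstra_oracle(mesh, crowns)
        np.testing.assert_allclose(depth, oracle, atol=1e-9)


def _folded_strip() -> TriangleMesh:
    """A single sinusoidal fold on a rectangular sheet."""
    base = flat_grid(25, 25, 1.5)
    v = base.vertices.copy()
    v[:, 2] = 3.0 * np.cos(2 * np.pi * v[:, 0] / 18.0)
    return TriangleMesh(v, base.faces)


class TestLCD:
    def test_plane_zero(self, plane):
        lcd = local_cortical_deformation(plane, radius=10.0).values
        assert np.nanmax(np.abs(lcd)) < 1e-9

    def test_sphere_inverse_radius_squared(self, sphere50):
        lcd = local_cortical_deformation(sphere50, radius=25.0).values
        np.testing.assert_allclose(np.nanmean(lcd), 1 / 2500.0, rtol=0.10)
        assert np.nanstd(lcd) / np.nanmean(lcd) < 0.1

    def test_bump_concentrates_lcd(self):
        base = flat_grid(31, 31, 2.0)
        v = base.vertices.copy()
        center = v[:, :2].mean(axis=0)
        d2 = np.sum((v[:, :2] - center) ** 2, axis=1)
        v[:, 2] = 6.0 * np.exp(-d2 / (2 * 6.0 ** 2))
        mesh = TriangleMesh(v, base.faces)
        lcd = local_cortical_deformation(mesh, radius=10.0).values
        peak = np.nanargmax(lcd)
        assert np.sqrt(d2[peak]) < 12.0  # peak disc covers the bump


class TestPET:
    def test_uniform_unity(self, planar_pair):
        vol = make_volume(lambda x, y, z: np.full_like(x, 123.0))
        (smap,) = pet_hypointensity(vol, planar_pair)
        np.testing.assert_allclose(smap.values, 1.0, atol=1e-12)

    def test_hypometabolic_disc_ratio_matches_oracle(self, planar_pair):
        # uptake 60 inside a 6 mm xy-disc, 100 elsewhere
        cx, cy = 15.0, 13.0

        def f(x, y, z):
            inside = (x - cx) ** 2 + (y - cy) ** 2 < 6.0 ** 2
            return np.where(inside, 60.0, 100.0)

        vol = make_volume(f)
        (smap,) = pet_hypointensity(vol, planar_pair)
        # oracle: recompute raw samples and the area-weighted mean directly
        from fcdsurf.sampling import sample_at_fraction
        raw = sample_at_fraction(vol, planar_pair, 0.5).values
        areas = planar_pair.white.vertex_areas
        mean = (raw * areas).sum() / areas.sum()
        np.testing.assert_allclose(smap.values, raw / mean, atol=1e-12)
        v = planar_pair.white.vertices
        core = (v[:, 0] - cx) ** 2 + (v[:, 1] - cy) ** 2 < 3.0 ** 2
        assert np.all(smap.values[core] < 0.75)

    def test_scale_invariance(self, planar_pair):
        vol = make_volume(lambda x, y, z: 100.0 + np.sin(x / 4) * 10)
        scaled = ScalarVolume(vol.data * 7.3, vol.affine)
        (a,) = pet_hypointensity(vol, planar_pair)
        (b,) = pet_hypointensity(scaled, planar_pair)
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_nonpositive_mean_rejected(self, planar_pair):
        vol = make_volume(lambda x, y, z: np.full_like(x, -5.0))
        with pytest.raises(ValueError, match="PET"):
            pet_hypointensity(vol, planar_pair)


class TestAsymmetry:
    def test_equal_maps_zero(self):
        corr = HomotopicCorrespondence.identity(10)
        L = SurfaceScalarMap(np.arange(10) + 5.0, "f")
        aL, aR = interhemispheric_asymmetry(L, L, corr)
        np.testing.assert_allclose(aL.values, 0.0, atol=1e-12)
        np.testing.assert_allclose(aR.values, 0.0, atol=1e-12)

    def test_known_value(self):
        corr = HomotopicCorrespondence.identity(3)
        L = SurfaceScalarMap(np.full(3, 90.0), "f")
        R = SurfaceScalarMap(np.full(3, 110.0), "f")
        aL, _ = interhemispheric_asymmetry(L, R, corr)
        np.testing.assert_allclose(aL.values, -0.2, atol=1e-12)

    def test_antisymmetry_through_correspondence(self):
        rng = np.random.default_rng(5)
        n = 20
        perm = rng.permutation(n)
        corr = HomotopicCorrespondence(perm)
        L = SurfaceScalarMap(rng.uniform(1, 2, n), "f")
        R = SurfaceScalarMap(rng.uniform(1, 2, n), "f")
        aL, aR = interhemispheric_asymmetry(L, R, corr)
        np.testing.assert_allclose(aL.values,
                                   -aR.values[corr.left_to_right],
                                   atol=1e-12)

    def test_near_zero_denominator_masked(self):
        corr = HomotopicCorrespondence.identity(2)
        L = SurfaceScalarMap([1.0, 1.0], "f")
        R = SurfaceScalarMap([-1.0, 1.0], "f")
        aL, _ = interhemispheric_asymmetry(L, R, corr)
        assert np.isnan(aL.values[0]) and np.isfinite(aL.values[1])

    def test_mirror_symmetric_subject_has_zero_asymmetry(self):
        spec = CohortSpec(resolution=2, hemi_asym_amplitude=0.0,
                          thickness_variation=0.0, thickness_jitter=0.0,
                          noise_sd_t1=0.0, noise_sd_flair=0.0,
                          noise_sd_pet=0.0)
        subj = SyntheticSubject(spec, "sym", seed=4)
        geom = subj.geometry()
        corr = geom["corr"]
        thickL = cortical_thickness(geom["pairs"]["lh"])
        thickR = cortical_thickness(geom["pairs"]["rh"])
        aL, aR = interhemispheric_asymmetry(thickL, thickR, corr)
        np.testing.assert_allclose(aL.values, 0.0, atol=1e-9)
        vols = subj.volumes()
        petL, petR = pet_hypointensity(vols["pet"], geom["pairs"]["lh"],
                                       geom["pairs"]["rh"])
        pL, _ = interhemispheric_asymmetry(petL, petR, corr)
        np.testing.assert_allclose(np.nan_to_num(pL.values), 0.0, atol=1e-6)


class TestDoughnut:
    def test_constant_map_zero(self, plane):
        smap = SurfaceScalarMap(np.full(plane.n_vertices, 3.3), "c")
        out = doughnut_map(smap, plane, radius=6.0).values
        valid = np.isfinite(out)
        assert valid.any()
        np.testing.assert_allclose(out[valid], 0.0, atol=1e-9)

    def test_disc_indicator_matches_brute_force(self, plane):
        center = 7 * 15 + 7
        oracle_d = dijkstra_oracle(plane, center)
        indicator = (oracle_d <= 6.0).astype(float)
        smap = SurfaceScalarMap(indicator, "ind")
        out = doughnut_map(smap, plane, radius=6.0).values
        areas = plane.vertex_areas
        # brute-force disc/annulus means vertex by vertex
        for v in (center, 0, 60):
            d = dijkstra_oracle(plane, v)
            disc = d <= 6.0
            ring = (d > 6.0) & (d <= 12.0)
            expect = ((indicator[disc] * areas[disc]).sum() /
                      areas[disc].sum() -
                      (indicator[ring] * areas[ring]).sum() /
                      areas[ring].sum())
            assert out[v] == pytest.approx(expect, abs=1e-9)
        assert out[center] > 0

    def test_negation_antisymmetry(self, plane):
        rng = np.random.default_rng(8)
        vals = rng.standard_normal(plane.n_vertices)
        a = doughnut_map(SurfaceScalarMap(vals, "v"), plane, 6.0).values
        b = doughnut_map(SurfaceScalarMap(-vals, "v"), plane, 6.0).values
        np.testing.assert_allclose(b, -a, atol=1e-12, equal_nan=True)
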