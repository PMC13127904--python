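import numpy as np
import pytest

from camoevolve import renderer as rd
from camoevolve.genome import Genome
from camoevolve.pattern_gen import decode_genome, render_skin
from camoevolve._color import linear_to_lab, encode_png16


def uniform_skin(lab_value, size=64):
    """A skin with a uniform Lab colour everywhere (no markings)."""
    g = np.full(36, 0.5)
    g[16] = 1.0  # all ground
    g[31] = 0.5
    p = decode_genome(Genome(g))
    skin = render_skin(p, size=size, rd_grid=64, rd_max_steps=100)
    skin.lab[:] = np.asarray(lab_value)[None, None, :]
    for v in skin.variants.values():
        v[:] = np.asarray(lab_value)[None, None, :]
    return skin


class TestSphericalDeform:
    def test_uniform_stays_uniform(self):
        img = np.full((65, 65), 37.0)
        out = rd.spherical_deform(img)
        assert np.allclose(out, 37.0)

    def test_ring_spacing_compresses_toward_rim(self):
        """Concentric rings end up closer together near the rim."""
        size = 257
        c = (size - 1) / 2.0
        yy, xx = np.mgrid[0:size, 0:size]
        r = np.hypot(yy - c, xx - c) / (size / 2.0)
        img = np.cos(2 * np.pi * r * 8)  # 8 rings
        out = rd.spherical_deform(img)
        # along the horizontal mid-line, ring extrema positions
        row = out[size // 2, size // 2:]
        sign_flips = np.where(np.diff(np.sign(row)) != 0)[0]
        gaps = np.diff(sign_flips)
        # spacing decreases toward the rim (ignore the clipped outermost gap)
        assert gaps[0] > gaps[len(gaps) // 2] > gaps[-2]

    def test_round_trip_recovers_smooth_pattern(self):
        size = 129
        yy, xx = np.mgrid[0:size, 0:size].astype(float)
        img = 50 + 20 * np.sin(xx / 17.0) * np.cos(yy / 23.0)
        fwd = rd.spherical_deform(img)
        back = rd.spherical_deform(fwd, inverse=True)
        c = (size - 1) / 2.0
        r = np.hypot(yy - c, xx - c) / (size / 2.0)
        inner = r <= 0.9
        assert np.abs(back - img)[inner].mean() < 0.5


class TestPlaceTarget:
    def test_constraints_never_violated(self, small_scene_pair, rng):
        scn = small_scene_pair[0]
        d = scn.target_diameter
        h, w = scn.image.shape[:2]
        for _ in range(2000):
            x, y = rd.place_target(scn, rng)
            assert 2 * d <= x <= w - 2 * d and 2 * d <= y <= h - 2 * d
            assert np.hypot(x - w / 2, y - h / 2) >= 2 * d

    def test_seeded_position_is_fixed(self, small_scene_pair):
        scn = small_scene_pair[0]
        a = rd.place_target(scn, np.random.default_rng(5))
        b = rd.place_target(scn, np.random.default_rng(5))
        assert a == b

    def test_feasible_area_matches_geometry(self, small_scene_pair):
        """Acceptance fraction of unconstrained draws ~ analytic feasible
        area (margin rectangle minus the central exclusion disc)."""
        scn = small_scene_pair[0]
        d = scn.target_diameter
        h, w = scn.image.shape[:2]
        m = 2 * d
        rng = np.random.default_rng(17)
        n = 40000
        xs = rng.integers(m, w - m + 1, n)
        ys = rng.integers(m, h - m + 1, n)
        ok = np.hypot(xs - w / 2, ys - h / 2) >= m
        rect = (w - 2 * m + 1) * (h - 2 * m + 1)
        # numeric integral of the disc area clipped to the rectangle
        gx, gy = np.meshgrid(np.arange(m, w - m + 1), np.arange(m, h - m + 1))
        feasible = (np.hypot(gx - w / 2, gy - h / 2) >= m).mean()
        assert ok.mean() == pytest.approx(feasible, abs=0.02)

    def test_infeasible_geometry_raises(self, small_scene_pair):
        import dataclasses
        scn = small_scene_pair[0]
        tiny = dataclasses.replace(scn, image=scn.image[:100, :100])
        with pytest.raises(rd.ConfigurationError):
            rd.place_target(tiny, np.random.default_rng(0))


class TestCompositeTarget:
    def test_reflectance_identity_with_grey_skin(self, small_scene_pair):
        """An 8%-grey skin with zero gloss reproduces the scene's
        calibration-target appearance exactly (16-bit quantized)."""
        for scn in small_scene_pair:
            grey_lab = linear_to_lab(np.full((1, 1, 3), 0.08))[0, 0]
            skin = uniform_skin(grey_lab, size=64)
            stim = rd.composite_target(scn, skin, (2 * 40, 2 * 40),
                                       gloss_marking=0.0, gloss_ground=0.0)
            d = scn.target_diameter
            y, x = 80, 80
            patch = stim.image[y - d // 2:y - d // 2 + d,
                               x - d // 2:x - d // 2 + d]
            disc = rd._disc_mask(d)
            got = encode_png16(patch)[disc]
            want = encode_png16(scn.calib_appearance)[disc]
            assert np.array_equal(got, want)

    def test_gloss_difference_equals_gloss_layer(self, small_scene_pair):
        scn = small_scene_pair[0]
        dark = uniform_skin((20.0, 0.0, 0.0), size=64)
        off = rd.composite_target(scn, dark, (80, 80), 0.0, 0.0)
        on = rd.composite_target(scn, dark, (80, 80), 1.0, 1.0)
        d = scn.target_diameter
        disc = rd._disc_mask(d)
        diff = (on.image - off.image)[on.target_mask]
        layer = np.repeat(scn.gloss_layer[disc][:, None], 3, axis=1)
        assert np.allclose(diff, layer, atol=1e-5)

    def test_reflectance_is_multiplicative(self, small_scene_pair):
        scn = small_scene_pair[0]
        lab_lo = linear_to_lab(np.full((1, 1, 3), 0.05))[0, 0]
        lab_hi = linear_to_lab(np.full((1, 1, 3), 0.10))[0, 0]
        lo = rd.composite_target(scn, uniform_skin(lab_lo), (80, 80), 0.0, 0.0)
        hi = rd.composite_target(scn, uniform_skin(lab_hi), (80, 80), 0.0, 0.0)
        m = lo.target_mask & (hi.image[..., 0] < 0.99)
        ratio = hi.image[m] / np.maximum(lo.image[m], 1e-9)
        assert np.allclose(ratio, 2.0, atol=1e-3)

    def test_placement_violation_raises(self, small_scene_pair):
        scn = small_scene_pair[0]
        skin = uniform_skin((50.0, 0.0, 0.0))
        with pytest.raises(rd.PlacementError):
            rd.composite_target(scn, skin, (10, 10))

    def test_bad_alpha_raises(self, small_scene_pair):
        scn = small_scene_pair[0]
        skin = uniform_skin((50.0, 0.0, 0.0))
        with pytest.raises(ValueError):
            rd.composite_target(scn, skin, (80, 80), gloss_marking=1.5)


def test_save_stimulus(tmp_path, small_scene_pair):
    scn = small_scene_pair[0]
    skin = uniform_skin((50.0, 10.0, 10.0))
    stim = rd.composite_target(scn, skin, (80, 80), 0.0, 0.0,
                               provenance={"individual": "x"})
    rd.save_stimulus(stim, tmp_path / "s.png")
    assert (tmp_path / "s.png").exists()
    assert (tmp_path / "s.json").exists()
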