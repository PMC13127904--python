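import numpy as np
import pytest
from scipy import ndimage

from camoevolve import metrics as mt


# ---------------------------------------------------------------------------
# helpers

def disc(shape, centre, radius):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return (yy - centre[1]) ** 2 + (xx - centre[0]) ** 2 <= radius ** 2


def smooth_noise(shape, seed, sigma=3.0, amp=10.0, base=50.0):
    rng = np.random.default_rng(seed)
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    return base + amp * f / f.std()


def spatial_gabor(wavelength, theta_deg, sigma, odd=False):
    """Direct spatial-domain Gabor kernel (unit L2), for oracle use."""
    half = int(np.ceil(3 * sigma))
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1].astype(float)
    th = np.deg2rad(theta_deg)
    xp = xx * np.cos(th) + yy * np.sin(th)
    env = np.exp(-(xx ** 2 + yy ** 2) / (2 * sigma ** 2))
    carrier = np.sin(2 * np.pi * xp / wavelength) if odd else \
        np.cos(2 * np.pi * xp / wavelength)
    k = env * carrier
    if not odd:
        k -= env * k.sum() / env.sum()  # zero mean
    return k / np.sqrt((k ** 2).sum())


def gabrat_oracle(luminance, mask, sigma=3.0, n_points=180):
    """Brute-force GabRat: at each outline point, compute Gabor energy by
    direct dot products with kernels built exactly at the local tangent
    angle (dense angular sampling, no orientation interpolation)."""
    pts, tans = mt._outline_points(mask, n_points)
    wl = sigma / mt.SIGMA_FACTOR
    half = int(np.ceil(3 * sigma))
    padded = np.pad(luminance.astype(float), half + 1, mode="reflect")
    e_coh = e_false = 0.0
    for p_idx in range(n_points):
        r, c = pts[0, p_idx], pts[1, p_idx]
        tr, tc = tans[0, p_idx], tans[1, p_idx]
        theta_c = np.degrees(np.arctan2(-tc, tr))
        ri, ci = int(round(r)) + half + 1, int(round(c)) + half + 1
        patch = padded[ri - half:ri + half + 1, ci - half:ci + half + 1]
        for theta, acc in ((theta_c, "coh"), (theta_c + 90.0, "false")):
            ke = spatial_gabor(wl, theta, sigma)
            ko = spatial_gabor(wl, theta, sigma, odd=True)
            e = (patch * ke).sum() ** 2 + (patch * ko).sum() ** 2
            if acc == "coh":
                e_coh += e
            else:
                e_false += e
    return e_false / (e_false + e_coh)


# ---------------------------------------------------------------------------
# CIELAB

class TestToCielab:
    def test_white_point(self):
        lab = mt.to_cielab(np.ones((2, 2, 3)))
        assert lab[..., 0] == pytest.approx(100.0, abs=0.01)
        assert np.abs(lab[..., 1:]).max() < 0.5

    def test_neutral_grey(self):
        img = np.full((2, 2, 3), 118 / 255.0)
        lab = mt.to_cielab(img)
        assert np.abs(lab[..., 1:]).max() < 0.5

    def test_round_trip(self):
        from skimage import color
        rng = np.random.default_rng(1)
        lab = mt.to_cielab(rng.uniform(0.05, 0.95, (20, 20, 3)))  # in gamut
        back = mt.to_cielab(np.clip(color.lab2rgb(lab), 0, 1))
        assert np.abs(back - lab).mean() < 0.1


# ---------------------------------------------------------------------------
# Gabor contrast

class TestGaborContrast:
    def test_constant_image_zero_everywhere(self):
        img = np.full((96, 96), 42.0)
        for s in mt.SCALES:
            for o in mt.ORIENTATIONS:
                c = mt.gabor_contrast(img, s, o, diameter=40)
                assert c == pytest.approx(0.0, abs=1e-9)

    def test_vertical_grating_orientation_selectivity(self):
        wl = 16
        xx = np.arange(128)
        img = 50 + 20 * np.sign(np.sin(2 * np.pi * xx / wl))[None, :] \
            * np.ones((128, 1))
        c0 = mt.gabor_contrast(img, wl / 40, 0.0, diameter=40)
        c90 = mt.gabor_contrast(img, wl / 40, 90.0, diameter=40)
        assert c0 > 5 * c90

    def test_white_noise_isotropy(self):
        sums = {o: 0.0 for o in mt.ORIENTATIONS}
        for seed in range(10):
            img = np.random.default_rng(seed).standard_normal((128, 128))
            for o in mt.ORIENTATIONS:
                sums[o] += mt.gabor_contrast(img, 0.2, o, diameter=40)
        vals = np.array(list(sums.values()))
        assert vals.max() / vals.min() < 1.05

    def test_oversized_wavelength_skipped(self, caplog):
        img = np.zeros((32, 32))
        c = mt.gabor_contrast(img, 1.0, 0.0, diameter=64)
        assert np.isnan(c)


class TestDirectionalityVerticalness:
    @pytest.mark.parametrize("contrasts, expected", [
        ((2.0, 2.0, 2.0, 2.0), 1.0),
        ((4.0, 0.0, 0.0, 0.0), 4.0),
        ((3.0, 1.0, 1.0, 1.0), 2.0),
        ((0.0, 0.0, 0.0, 0.0), 1.0),
    ])
    def test_directionality_arithmetic(self, contrasts, expected):
        vals = {("L", 0.5, o): c for o, c in zip(mt.ORIENTATIONS, contrasts)}
        table = mt.ContrastTable(values=vals, diameter=40)
        assert mt.directionality(table, "L", 0.5) == pytest.approx(expected)

    def test_verticalness_signs_on_gratings(self):
        wl = 16
        xx, yy = np.meshgrid(np.arange(128), np.arange(128))
        for grating, expect_sign in (
            (np.sin(2 * np.pi * xx / wl), +1),  # vertical stripes
            (np.sin(2 * np.pi * yy / wl), -1),  # horizontal stripes
        ):
            lab = np.zeros((128, 128, 3))
            lab[..., 0] = 50 + 20 * grating
            table = mt.contrast_table(lab, diameter=40, channels=("L",),
                                      scales=(wl / 40,))
            v = mt.verticalness(table, "L", wl / 40)
            assert np.sign(v) == expect_sign

    def test_verticalness_of_isotropic_noise_is_small(self):
        lab = np.zeros((128, 128, 3))
        lab[..., 0] = np.random.default_rng(3).standard_normal((128, 128))
        table = mt.contrast_table(lab, diameter=40, channels=("L",),
                                  scales=(0.25,))
        c = table.orientation_mean("L", 0.25)
        assert abs(mt.verticalness(table, "L", 0.25)) < 0.1 * c


# ---------------------------------------------------------------------------
# camouflage differences

class TestCamouflageDifferences:
    def setup_method(self):
        self.shape = (120, 120)
        self.target = disc(self.shape, (60, 60), 20)
        self.surround = disc(self.shape, (60, 60), 50) & ~self.target

    def test_cloned_texture_gives_zero(self):
        lab = np.zeros(self.shape + (3,))
        lab[..., 0] = 50.0
        lab[..., 1] = 5.0
        lab[..., 2] = -3.0
        lum, col, pat = mt.camouflage_differences(
            lab, self.target, self.surround, 40)
        assert lum == pytest.approx(0.0, abs=1e-9)
        assert col == pytest.approx(0.0, abs=1e-9)
        assert pat == pytest.approx(0.0, abs=1e-8)

    def test_uniform_level_difference(self):
        lab = np.zeros(self.shape + (3,))
        lab[..., 0] = np.where(self.target, 60.0, 40.0)
        lum, col, pat = mt.camouflage_differences(
            lab, self.target, self.surround, 40)
        assert lum == pytest.approx(20.0)
        assert col == pytest.approx(0.0, abs=1e-9)

    def test_colour_difference_is_euclidean(self):
        lab = np.zeros(self.shape + (3,))
        lab[..., 1] = np.where(self.target, 10.0, 4.0)
        lab[..., 2] = np.where(self.target, -5.0, 3.0)
        _, col, _ = mt.camouflage_differences(
            lab, self.target, self.surround, 40)
        assert col == pytest.approx(10.0)  # sqrt(6^2 + 8^2)

    def test_symmetry_in_regions(self):
        lab = np.zeros(self.shape + (3,))
        lab[..., 0] = smooth_noise(self.shape, 5)
        a = mt.camouflage_differences(lab, self.target, self.surround, 40)
        b = mt.camouflage_differences(lab, self.surround, self.target, 40)
        assert a == pytest.approx(b)


# ---------------------------------------------------------------------------
# GabRat

class TestGabrat:
    def test_plain_disc_edge_is_coherent(self):
        img = np.full((120, 120), 30.0)
        m = disc(img.shape, (60, 60), 20)
        img[m] = 70.0
        assert mt.gabrat(img, m) < 0.1

    def test_invisible_outline_on_noise_is_chance_level(self):
        vals = [mt.gabrat(smooth_noise((120, 120), seed, sigma=2.0),
                          disc((120, 120), (60, 60), 20))
                for seed in range(6)]
        assert np.mean(vals) == pytest.approx(0.5, abs=0.15)

    def test_orthogonal_markings_increase_disruption(self):
        """Radial stripes crossing the outline: disruption strictly
        increases with their amplitude."""
        shape = (120, 120)
        m = disc(shape, (60, 60), 20)
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
        phi = np.arctan2(yy - 60.0, xx - 60.0)
        ratios = []
        for amp in (0.0, 5.0, 10.0, 20.0, 40.0):
            img = np.full(shape, 40.0)
            img[m] = 50.0
            stripes = amp * np.cos(12 * phi)
            band = disc(shape, (60, 60), 26)
            img[band] += stripes[band]
            ratios.append(mt.gabrat(img, m))
        assert all(b > a for a, b in zip(ratios, ratios[1:]))

    def test_agrees_with_brute_force_oracle(self):
        """20 random disc stimuli: the orientation-interpolated
        implementation matches dense-angle brute force within 0.05."""
        from tests.test_metrics import gabrat_oracle  # explicit
        rng = np.random.default_rng(99)
        worst = 0.0
        for i in range(20):
            img = smooth_noise((100, 100), 200 + i, sigma=2.5, amp=12.0)
            m = disc(img.shape, (50, 50), 16)
            img[m] += rng.uniform(-20, 20)
            got = mt.gabrat(img, m)
            want = gabrat_oracle(img, m)
            worst = max(worst, abs(got - want))
        assert worst < 0.05

    def test_degenerate_mask_raises(self):
        img = np.zeros((50, 50))
        with pytest.raises(ValueError):
            mt.gabrat(img, np.zeros((50, 50), dtype=bool))

    def test_translation_invariance(self):
        base = smooth_noise((160, 160), 7, sigma=2.0)
        m1 = disc((160, 160), (60, 60), 18)
        m2 = disc((160, 160), (95, 88), 18)
        img1 = base.copy(); img1[m1] += 15.0
        img2 = np.roll(base, (28, 35), axis=(0, 1)); img2[m2] += 15.0
        # same texture under the outline after translation
        assert mt.gabrat(img1, m1) == pytest.approx(
            mt.gabrat(img2, m2), abs=0.03)


# ---------------------------------------------------------------------------
# gradients, gloss, edge enhancement, background variation

class TestVerticalGradient:
    def test_uniform_is_zero(self):
        assert mt.vertical_gradient(np.full((40, 40), 7.0)) == 0.0

    @pytest.mark.parametrize("slope", [20.0, -20.0])
    def test_exact_ramp_recovered(self, slope):
        h = 64
        y_norm = (h - 1 - np.arange(h)) / (h - 1)
        img = 40.0 + slope * y_norm[:, None] * np.ones((1, h))
        assert mt.vertical_gradient(img) == pytest.approx(slope)

    def test_masked_ramp(self):
        h = 64
        y_norm = (h - 1 - np.arange(h)) / (h - 1)
        img = 40.0 + 20.0 * y_norm[:, None] * np.ones((1, h))
        m = disc((h, h), (32, 32), 25)
        # normalized to the mask's own extent: still positive, close to
        # the ramp over the disc's span
        got = mt.vertical_gradient(img, m)
        span = 20.0 * (50 / 63)
        assert got == pytest.approx(span, rel=0.05)


class TestGloss:
    def test_zero_gloss_gives_zero_deltas(self):
        a = np.full((30, 30), 50.0)
        m = np.ones((30, 30), dtype=bool)
        g = mt.gloss_measures(a, a, a + 10.0, m)
        assert g.delta_mean == 0.0 and g.delta_sd == 0.0
        assert g.relative == 0.0

    def test_full_gloss_is_relative_one(self):
        off = np.full((30, 30), 50.0)
        on = off + 8.0
        g = mt.gloss_measures(on, off, on, np.ones((30, 30), dtype=bool))
        assert g.delta_mean == pytest.approx(g.max_delta)
        assert g.relative == pytest.approx(1.0)

    def test_provenance_mismatch_raises(self, small_scene_pair):
        from camoevolve.renderer import composite_target
        from tests.test_renderer import uniform_skin
        scn = small_scene_pair[0]
        skin = uniform_skin((40.0, 0.0, 0.0))
        s1 = composite_target(scn, skin, (80, 80), 0.5, 0.5,
                              provenance={"individual": "a"})
        s2 = composite_target(scn, skin, (80, 80), 0.0, 0.0,
                              provenance={"individual": "b"})
        with pytest.raises(ValueError):
            mt.gloss_measures_from_stimuli(s1, s2, s2)

    def test_darker_skin_is_relatively_glossier(self, small_scene_pair):
        """With the same alpha, a dark skin gains relatively more
        luminance from the specular layer than a light skin."""
        from camoevolve.renderer import composite_target
        from camoevolve._color import linear_to_lab
        from tests.test_renderer import uniform_skin
        scn = small_scene_pair[0]
        rels = []
        for level in (20.0, 70.0):
            skin = uniform_skin((level, 0.0, 0.0))
            ims = {}
            for tag, alpha in (("on", 0.5), ("off", 0.0), ("max", 1.0)):
                st = composite_target(scn, skin, (80, 80), alpha, alpha)
                ims[tag] = linear_to_lab(st.image)[..., 0]
            g = mt.gloss_measures(ims["on"], ims["off"], ims["max"],
                                  st.target_mask)
            rels.append(g.delta_mean / max(g.max_delta, 1e-9))
        # relative gain of the on-state is larger for the darker skin
        assert rels[0] >= rels[1] - 1e-6


class TestEdgeEnhancement:
    def test_identical_variants_give_zero(self):
        lab = np.zeros((64, 64, 3))
        lab[..., 0] = smooth_noise((64, 64), 2)
        assert mt.edge_enhancement_measure(lab, lab, 64) == pytest.approx(0.0)

    def test_uniform_skin_gives_zero_for_any_strength(self):
        from camoevolve.genome import Genome
        from camoevolve.pattern_gen import decode_genome, render_skin
        g = np.full(36, 0.5)
        g[16] = 1.0  # no markings
        g[31] = 0.5
        for strength in (0.2, 0.9):
            g[24] = strength
            p = decode_genome(Genome(g))
            skin = render_skin(p, size=64, rd_grid=64, rd_max_steps=100)
            d = mt.edge_enhancement_measure(
                skin.lab, skin.variants["no_edge_enhancement"], 64)
            assert d == pytest.approx(0.0, abs=1e-9)

    def test_monotone_in_strength_gene(self):
        """Light markings on dark ground: the rim (light inner, dark outer
        edge) reinforces the boundary, so the contrast shift grows
        strictly with the strength gene."""
        from camoevolve.genome import Genome
        from camoevolve.pattern_gen import decode_genome, render_skin
        base = np.random.default_rng(8).random(36)
        base[16] = 0.5  # guaranteed markings
        base[7] = 0.9   # marking clearly lighter ...
        base[10] = 0.1  # ... than the ground
        base[26] = base[27] = base[28] = 0.5
        deltas = []
        for strength in np.linspace(0.0, 1.0, 5):
            g = base.copy()
            g[24] = strength
            p = decode_genome(Genome(g))
            skin = render_skin(p, size=64, rd_grid=64, rd_max_steps=300)
            deltas.append(mt.edge_enhancement_measure(
                skin.lab, skin.variants["no_edge_enhancement"], 64))
        assert deltas[0] == pytest.approx(0.0, abs=1e-9)
        assert all(b > a for a, b in zip(deltas, deltas[1:]))


class TestBackgroundVariation:
    def test_constant_channel_is_zero(self):
        assert mt.background_variation(np.full((96, 96), 3.0), 40) == \
            pytest.approx(0.0, abs=1e-9)

    def test_offset_invariance(self):
        img = smooth_noise((96, 96), 4)
        a = mt.background_variation(img, 40)
        b = mt.background_variation(img + 25.0, 40)
        assert a == pytest.approx(b, abs=1e-9)


def test_measure_stimulus_provenance_invariance(small_scene_pair):
    """Metrics depend on pixels, not on who the stimulus belongs to."""
    from camoevolve.renderer import composite_target
    from tests.test_renderer import uniform_skin
    scn = small_scene_pair[0]
    skin = uniform_skin((45.0, 5.0, 5.0))
    s1 = composite_target(scn, skin, (80, 80), 0.0, 0.0,
                          provenance={"individual": "a", "generation": 0})
    s2 = composite_target(scn, skin, (80, 80), 0.0, 0.0,
                          provenance={"individual": "z", "generation": 9})
    assert mt.measure_stimulus(s1) == mt.measure_stimulus(s2)
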