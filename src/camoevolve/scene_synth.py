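"""Synthetic habitat scenes: ground textures, depth maps, and lighting.

This module is the study's synthetic-data generator.  It emulates the kind
of calibrated ground-level photographs the pipeline consumes: a habitat is
an unlit albedo texture (multi-octave coloured noise around a base colour
plus discrete substrate elements - pebbles, grass blades, leaves) and a
surface-height map.  Illumination renders the habitat under either

* DIRECT light - a collimated sun at a given azimuth/elevation: Lambertian
  shading from surface normals, cast shadows ray-marched across the height
  field, shadowed pixels dimmed by a shade factor and shifted toward blue
  (shadow light comes from the sky, and Rayleigh scattering is
  wavelength-dependent), or
* DIFFUSE light - overcast-sky illumination: soft ambient-occlusion
  shading only, no directional term and no cast shadows.

Every scene also carries the appearance model of a grey 8%-reflectance
calibration button at desk scale (a hemisphere with a lighting-dependent
self-shading gradient) and a separate glossy-target highlight layer; the
renderer lights evolved patterns through these maps.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from ._color import lab_to_linear, linear_to_lab

AMBIENT = 0.25
SUN = 1.0
DIFFUSE_LEVEL = 0.75


@dataclasses.dataclass
class HabitatParams:
    habitat_id: str
    substrate: str  # bare | gravel | grass | leaflitter | veg
    base_lab: tuple[float, float, float]
    amp_3d: float  # mm; overall scale of surface relief
    element_density: float  # target fraction of area covered by elements
    element_size_mm: float = 8.0
    element_lab: tuple[float, float, float] = (45.0, 5.0, 12.0)
    noise_amp_l: float = 8.0
    noise_amp_ab: float = 4.0
    seed: int = 0


@dataclasses.dataclass
class HabitatModel:
    albedo: np.ndarray  # (H, W, 3) linear-light reflectance
    depth: np.ndarray  # (H, W) surface height, mm
    element_mask: np.ndarray  # (H, W) bool, pixels painted by elements
    params: HabitatParams
    scale: float  # px per mm


@dataclasses.dataclass
class Scene:
    image: np.ndarray  # (H, W, 3) linear-light RGB
    lighting: str  # DIRECT | DIFFUSE
    azimuth: float | None  # degrees; None for DIFFUSE
    elevation: float | None
    depth: np.ndarray  # mm
    scale: float  # px per mm
    target_diameter: int  # px
    calib_illum: np.ndarray  # (d, d) illumination incident on the button
    gloss_layer: np.ndarray  # (d, d) additive specular highlight (linear)
    shadow_mask: np.ndarray | None
    habitat_id: str
    scene_id: str

    @property
    def calib_appearance(self) -> np.ndarray:
        """Linear-RGB appearance of the grey 8%-reflectance button."""
        app = np.repeat(self.calib_illum[..., None] * 0.08, 3, axis=-1)
        return app.astype(self.image.dtype)


# ---------------------------------------------------------------------------
# habitat library: 28 synthetic habitats spanning five substrate classes.
# Columns: substrate, base (L*, a*, b*), 3D amplitude (mm), element density.
_LIBRARY_ROWS: list[tuple[str, tuple[float, float, float], float, float]] = [
    ("bare", (62.0, 2.0, 14.0), 0.0, 0.00),     # dry sand flat
    ("bare", (42.0, 4.0, 10.0), 0.5, 0.04),     # estuarine mud
    ("bare", (70.0, 1.0, 8.0), 0.8, 0.06),      # chalk path
    ("bare", (36.0, 2.0, 6.0), 1.2, 0.08),      # damp clay
    ("bare", (52.0, 3.0, 12.0), 1.5, 0.10),     # compacted earth
    ("gravel", (55.0, 2.0, 8.0), 3.0, 0.45),
    ("gravel", (48.0, 4.0, 12.0), 4.0, 0.55),
    ("gravel", (62.0, 1.0, 6.0), 5.0, 0.50),
    ("gravel", (40.0, 3.0, 10.0), 6.5, 0.60),
    ("gravel", (58.0, 5.0, 16.0), 8.0, 0.65),   # shingle beach
    ("gravel", (45.0, 2.0, 7.0), 5.5, 0.40),
    ("grass", (45.0, -18.0, 28.0), 4.0, 0.35),
    ("grass", (40.0, -22.0, 30.0), 6.0, 0.45),
    ("grass", (50.0, -14.0, 26.0), 8.0, 0.55),
    ("grass", (38.0, -20.0, 24.0), 10.0, 0.60),  # meadow sward
    ("grass", (47.0, -16.0, 32.0), 12.0, 0.65),
    ("grass", (43.0, -19.0, 27.0), 7.0, 0.50),
    ("leaflitter", (38.0, 8.0, 22.0), 2.0, 0.55),
    ("leaflitter", (32.0, 10.0, 18.0), 3.0, 0.60),
    ("leaflitter", (44.0, 6.0, 26.0), 4.0, 0.65),
    ("leaflitter", (28.0, 12.0, 16.0), 5.0, 0.70),  # closed woodland floor
    ("leaflitter", (36.0, 9.0, 20.0), 3.5, 0.60),
    ("veg", (40.0, -10.0, 18.0), 6.0, 0.40),    # heathland mix
    ("veg", (35.0, -6.0, 14.0), 8.0, 0.50),
    ("veg", (45.0, -12.0, 22.0), 9.0, 0.55),
    ("veg", (30.0, -4.0, 10.0), 11.0, 0.60),
    ("veg", (42.0, -8.0, 16.0), 12.0, 0.65),
    ("veg", (37.0, -11.0, 20.0), 7.0, 0.45),
]

_ELEMENT_LAB = {
    "bare": (50.0, 3.0, 10.0),
    "gravel": (55.0, 2.0, 6.0),
    "grass": (42.0, -24.0, 30.0),
    "leaflitter": (40.0, 10.0, 24.0),
    "veg": (38.0, -14.0, 18.0),
}

_ELEMENT_SIZE_MM = {
    "bare": 5.0, "gravel": 9.0, "grass": 2.5, "leaflitter": 14.0, "veg": 6.0,
}


def habitat_library(n: int = 28) -> list[HabitatParams]:
    """The shipped 28-habitat parameter table (first ``n`` rows)."""
    out = []
    for i, (sub, lab, amp, dens) in enumerate(_LIBRARY_ROWS[:n]):
        out.append(
            HabitatParams(
                habitat_id=f"hab{i:02d}", substrate=sub, base_lab=lab,
                amp_3d=amp, element_density=dens,
                element_size_mm=_ELEMENT_SIZE_MM[sub],
                element_lab=_ELEMENT_LAB[sub], seed=1000 + i,
            )
        )
    return out


# ---------------------------------------------------------------------------
# habitat construction

def _octave_noise(shape, rng, sigmas_px, amps):
    """Sum of unit-SD Gaussian-filtered noise fields; large octaves are
    synthesized at reduced resolution and upsampled (cost, not content)."""
    out = np.zeros(shape)
    for s, a in zip(sigmas_px, amps):
        ds = max(1, int(s / 4.0))
        small = (max(8, -(-shape[0] // ds)), max(8, -(-shape[1] // ds)))
        f = ndimage.gaussian_filter(rng.standard_normal(small), s / ds)
        sd = f.std()
        if sd > 0:
            f = f / sd
        if ds > 1:
            f = ndimage.zoom(f, ds, order=1)
        out += a * f[: shape[0], : shape[1]]
    return out


def _paint_ellipse(lab, depth, emask, cy, cx, ry, rx, ang, height, colour):
    h, w = depth.shape
    r = int(max(ry, rx)) + 2
    y0, y1 = max(0, cy - r), min(h, cy + r + 1)
    x0, x1 = max(0, cx - r), min(w, cx + r + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    ya, xa = (yy - cy).astype(float), (xx - cx).astype(float)
    ca, sa = np.cos(ang), np.sin(ang)
    u = (ca * xa + sa * ya) / rx
    v = (-sa * xa + ca * ya) / ry
    rr = u * u + v * v
    inside = rr <= 1.0
    dome = height * np.sqrt(np.clip(1.0 - rr, 0.0, 1.0))
    sub_d = depth[y0:y1, x0:x1]
    np.maximum(sub_d, np.where(inside, dome, 0.0), out=sub_d)
    for ch in range(3):
        lab[y0:y1, x0:x1, ch][inside] = colour[ch]
    emask[y0:y1, x0:x1] |= inside


def _paint_blade(lab, depth, emask, cy, cx, ang, length, width, height, colour):
    h, w = depth.shape
    dy, dx = np.sin(ang), np.cos(ang)
    half = length / 2.0
    r = int(half + width) + 2
    y0, y1 = max(0, cy - r), min(h, cy + r + 1)
    x0, x1 = max(0, cx - r), min(w, cx + r + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    ya, xa = (yy - cy).astype(float), (xx - cx).astype(float)
    t = np.clip(xa * dx + ya * dy, -half, half)
    dist2 = (xa - t * dx) ** 2 + (ya - t * dy) ** 2
    inside = dist2 <= width * width
    sub_d = depth[y0:y1, x0:x1]
    np.maximum(sub_d, np.where(inside, height, 0.0), out=sub_d)
    for ch in range(3):
        lab[y0:y1, x0:x1, ch][inside] = colour[ch]
    emask[y0:y1, x0:x1] |= inside


def make_habitat(
    params: HabitatParams,
    size: tuple[int, int] = (744, 952),
    scale: float = 80.0 / 30.0,
    seed: int | None = None,
) -> HabitatModel:
    """Build the unlit habitat: linear-RGB albedo + depth map (mm).

    The albedo is multi-octave coloured noise around the base colour with
    substrate elements painted on top; element heights are scaled by the
    habitat's 3D amplitude, so ``amp_3d = 0`` gives a perfectly flat map.
    """
    h, w = size
    rng = np.random.default_rng(params.seed if seed is None else seed)
    sig = [max(1.0, 3.0 * scale), max(2.0, 10.0 * scale), max(4.0, 30.0 * scale)]
    lab = np.empty((h, w, 3))
    lab[..., 0] = params.base_lab[0] + _octave_noise(
        (h, w), rng, sig, [0.5 * params.noise_amp_l, 0.6 * params.noise_amp_l,
                           0.7 * params.noise_amp_l])
    for ch, base in ((1, params.base_lab[1]), (2, params.base_lab[2])):
        lab[..., ch] = base + _octave_noise(
            (h, w), rng, sig, [0.4 * params.noise_amp_ab,
                               0.6 * params.noise_amp_ab,
                               0.8 * params.noise_amp_ab])
    depth = np.zeros((h, w))
    emask = np.zeros((h, w), dtype=bool)

    dens = params.element_density
    if dens > 0:
        r_px = max(1.5, params.element_size_mm * scale / 2.0)
        if params.substrate == "grass":
            # blades: length x width rectangles
            mean_area = 12.0 * scale * 2.0 * max(0.6, 0.9 * scale)
        elif params.substrate == "veg":
            mean_area = 0.5 * (15.0 * scale * 2.0 * max(0.6, 1.08 * scale)
                               + np.pi * (0.85 * r_px) ** 2)
        else:
            mean_area = np.pi * r_px * r_px
        n_elem = int(np.ceil(-np.log(max(1e-9, 1.0 - dens)) * h * w / mean_area))
        n_elem = min(n_elem, 6000)
        for _ in range(n_elem):
            cy, cx = int(rng.integers(0, h)), int(rng.integers(0, w))
            col = tuple(
                np.clip(c + rng.normal(0, s), lo, hi)
                for c, s, (lo, hi) in zip(
                    params.element_lab, (8.0, 4.0, 5.0),
                    ((3, 97), (-60, 60), (-60, 60)))
            )
            hgt = params.amp_3d * rng.uniform(0.4, 1.0)
            if params.substrate in ("gravel", "bare"):
                _paint_ellipse(lab, depth, emask, cy, cx,
                               r_px * rng.uniform(0.7, 1.3),
                               r_px * rng.uniform(0.7, 1.3),
                               rng.uniform(0, np.pi), hgt, col)
            elif params.substrate == "leaflitter":
                _paint_ellipse(lab, depth, emask, cy, cx,
                               r_px * rng.uniform(0.5, 1.0),
                               r_px * rng.uniform(0.9, 1.4),
                               rng.uniform(0, np.pi),
                               params.amp_3d * rng.uniform(0.1, 0.4), col)
            elif params.substrate == "grass":
                _paint_blade(lab, depth, emask, cy, cx,
                             rng.uniform(0, np.pi),
                             rng.uniform(8, 16) * scale,
                             max(0.6, 1.0 * scale * rng.uniform(0.6, 1.2)),
                             hgt, col)
            else:  # veg: mix of blades and leafy blobs
                if rng.random() < 0.5:
                    _paint_blade(lab, depth, emask, cy, cx,
                                 rng.uniform(0, np.pi),
                                 rng.uniform(10, 20) * scale,
                                 max(0.6, 1.2 * scale * rng.uniform(0.6, 1.2)),
                                 hgt, col)
                else:
                    _paint_ellipse(lab, depth, emask, cy, cx,
                                   r_px * rng.uniform(0.6, 1.1),
                                   r_px * rng.uniform(0.6, 1.1),
                                   rng.uniform(0, np.pi), hgt, col)

    albedo = np.clip(lab_to_linear(lab), 0.005, 0.95).astype(np.float32)
    return HabitatModel(albedo=albedo, depth=depth, element_mask=emask,
                        params=params, scale=scale)


# ---------------------------------------------------------------------------
# illumination

def _sun_vector(azimuth: float, elevation: float) -> np.ndarray:
    """Unit vector pointing from the ground toward the sun.

    Azimuth 0 puts the sun at the top of the image (light arrives from
    image-up); azimuth grows clockwise.  Image axes: x = columns,
    y = rows (down), z = up out of the ground.
    """
    az, el = np.deg2rad(azimuth), np.deg2rad(elevation)
    return np.array([np.cos(el) * np.sin(az), -np.cos(el) * np.cos(az), np.sin(el)])


def _surface_normals(depth: np.ndarray, scale: float) -> np.ndarray:
    sm = ndimage.gaussian_filter(depth, 1.0)
    dzdy, dzdx = np.gradient(sm)  # mm per px
    dzdy *= scale  # -> mm per mm
    dzdx *= scale
    n = np.stack([-dzdx, -dzdy, np.ones_like(depth)], axis=-1)
    return n / np.linalg.norm(n, axis=-1, keepdims=True)


def _cast_shadows(depth: np.ndarray, sun: np.ndarray, scale: float,
                  n_steps: int = 48) -> np.ndarray:
    """Height-field ray march (1 px steps) toward the sun; wraps at edges."""
    horiz = np.hypot(sun[0], sun[1])
    if horiz < 1e-9:
        return np.zeros_like(depth, dtype=bool)
    ux, uy = sun[0] / horiz, sun[1] / horiz
    rise_per_px = (sun[2] / horiz) / scale  # mm of ray rise per px travelled
    shadow = np.zeros_like(depth, dtype=bool)
    for t in range(1, n_steps + 1):
        dyi, dxi = int(round(t * uy)), int(round(t * ux))
        sampled = np.roll(depth, (-dyi, -dxi), axis=(0, 1))
        shadow |= sampled > depth + t * rise_per_px + 1e-6
    return shadow


def _hemisphere_normals(d: int) -> tuple[np.ndarray, np.ndarray]:
    c = (d - 1) / 2.0
    yy, xx = np.mgrid[0:d, 0:d]
    xu = (xx - c) / (d / 2.0)
    yu = (yy - c) / (d / 2.0)
    rr = xu * xu + yu * yu
    inside = rr <= 1.0
    zu = np.sqrt(np.clip(1.0 - rr, 0.0, 1.0))
    n = np.stack([xu, yu, zu], axis=-1)
    return n, inside


def illuminate(
    habitat: HabitatModel,
    lighting: str,
    azimuth: float | None = None,
    elevation: float | None = None,
    seed: int = 0,
    target_diameter: int = 80,
    shade_factor: float = 0.35,
    blue_shift: float = 8.0,
    scene_id: str | None = None,
) -> Scene:
    """Render a habitat under DIRECT or DIFFUSE lighting (see module docs)."""
    lighting = lighting.upper()
    if lighting not in ("DIRECT", "DIFFUSE"):
        raise ValueError(f"unknown lighting {lighting!r}")
    if lighting == "DIFFUSE" and azimuth is not None:
        raise ValueError("DIFFUSE scenes take no azimuth")
    depth = habitat.depth
    scale = habitat.scale
    d = int(target_diameter)
    n_hemi, inside = _hemisphere_normals(d)
    shadow = None

    if lighting == "DIRECT":
        azimuth = 0.0 if azimuth is None else float(azimuth)
        elevation = 40.0 if elevation is None else float(elevation)
        sun = _sun_vector(azimuth, elevation)
        normals = _surface_normals(depth, scale)
        lambert = np.clip(normals @ sun, 0.0, None)
        shadow = _cast_shadows(depth, sun, scale)
        e = AMBIENT + SUN * lambert
        e = np.where(shadow, shade_factor * e, e)
        image = habitat.albedo * e[..., None].astype(np.float32)
        if blue_shift != 0.0 and shadow.any():
            lab = linear_to_lab(image)
            lab[..., 2] -= blue_shift * shadow
            image = lab_to_linear(lab).astype(np.float32)
        # calibration button: Lambertian hemisphere; directional gradient
        # attenuated when the local surroundings are 3-D (obstructed light)
        h, w = depth.shape
        cy, cx = h // 2, w // 2
        rloc = int(2.5 * d / 2)
        local = depth[max(0, cy - rloc):cy + rloc, max(0, cx - rloc):cx + rloc]
        atten = 1.0 / (1.0 + local.std() / 8.0)
        lam_t = np.clip(n_hemi @ sun, 0.0, None)
        calib = AMBIENT + SUN * atten * lam_t
        calib[~inside] = AMBIENT
        half = sun + np.array([0.0, 0.0, 1.0])
        half /= np.linalg.norm(half)
        gloss = SUN * atten * np.clip(n_hemi @ half, 0.0, None) ** 60 * 0.9
        gloss[~inside] = 0.0
    else:
        elevation = None
        low = ndimage.gaussian_filter(depth, max(2.0, 8.0 * scale)) - depth
        norm = max(2.0 * depth.std(), 0.5)
        occl = np.clip(low / norm, 0.0, 1.0)
        e = DIFFUSE_LEVEL * (1.0 - 0.5 * occl)
        image = habitat.albedo * e[..., None].astype(np.float32)
        zu = n_hemi[..., 2]
        yu = n_hemi[..., 1]
        calib = DIFFUSE_LEVEL * (0.72 + 0.25 * zu + 0.08 * (-yu))
        calib[~inside] = DIFFUSE_LEVEL * 0.72
        gloss = 0.18 * DIFFUSE_LEVEL * zu ** 6
        gloss[~inside] = 0.0

    return Scene(
        image=image.astype(np.float32),
        lighting=lighting,
        azimuth=azimuth if lighting == "DIRECT" else None,
        elevation=elevation,
        depth=depth,
        scale=scale,
        target_diameter=d,
        calib_illum=calib,
        gloss_layer=gloss,
        shadow_mask=shadow,
        habitat_id=habitat.params.habitat_id,
        scene_id=scene_id or f"{habitat.params.habitat_id}-{lighting.lower()}-{seed}",
    )


def self_shading_gradient(scene: Scene) -> float:
    """Vertical gradient of the calibration button's illumination, measured
    along the lighting axis (targets are aligned with their self-shading
    gradient under direct light, so the lit side counts as "up"; diffuse
    scenes are measured as-is)."""
    from .metrics import vertical_gradient

    calib = scene.calib_illum
    if scene.lighting == "DIRECT" and scene.azimuth:
        calib = ndimage.rotate(calib, scene.azimuth, reshape=False,
                               order=1, mode="nearest")
    d = calib.shape[0]
    c = (d - 1) / 2.0
    yy, xx = np.mgrid[0:d, 0:d]
    disc = (yy - c) ** 2 + (xx - c) ** 2 <= (d / 2.0) ** 2
    return vertical_gradient(calib, disc)


def depth_variation(scene: Scene, region: np.ndarray | tuple | None = None) -> float:
    """3D variation: the standard deviation of depth (mm) in a region.

    ``region`` may be a boolean mask, a slice pair, or None (whole scene).
    The habitat-level value is the mean of this over the habitat's scenes.
    """
    if region is None:
        vals = scene.depth
    elif isinstance(region, np.ndarray) and region.dtype == bool:
        vals = scene.depth[region]
    else:
        vals = scene.depth[region]
    vals = np.asarray(vals)
    if vals.size == 0:
        raise ValueError("empty region")
    return float(vals.std())


def make_scene_set(
    params: HabitatParams,
    lighting: str,
    n_scenes: int = 24,
    size: tuple[int, int] = (744, 952),
    target_diameter: int = 80,
    seed: int = 0,
) -> list[Scene]:
    """A habitat's scene set under one lighting: ``n_scenes`` re-seeded
    layouts of the same habitat parameters (emulating repeat photographs
    of nearby patches)."""
    rng = np.random.default_rng((params.seed, seed))
    scale = target_diameter / 30.0  # the button is 30 mm across
    scenes = []
    for i in range(n_scenes):
        hab = make_habitat(params, size=size, scale=scale,
                           seed=int(rng.integers(1 << 31)))
        if lighting.upper() == "DIRECT":
            scn = illuminate(hab, "DIRECT",
                             azimuth=float(rng.uniform(0, 360)),
                             elevation=float(rng.uniform(30, 60)),
                             target_diameter=target_diameter,
                             scene_id=f"{params.habitat_id}-direct-{i}")
        else:
            scn = illuminate(hab, "DIFFUSE", target_diameter=target_diameter,
                             scene_id=f"{params.habitat_id}-diffuse-{i}")
        scenes.append(scn)
    return scenes
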