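"""Render evolved skins onto the hemispherical button inside a scene.

The flat target-skin is wrapped onto the button with a radial fisheye map
(hemisphere viewed from above), then composited with the reflectance model
of a calibrated photograph: the scene supplies the illumination that fell
on the grey 8%-reflectance calibration button, the known reflectance is
divided out, and the skin's reflectance is multiplied back in, all in
linear-light RGB.  Gloss is the scene's specular-highlight layer added
with genetically controlled alphas (separately for marking and ground
regions).  Placement obeys the no-go zones: the target centre is never
closer than two diameters to the image border or the image centre.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib

import numpy as np
from scipy import ndimage

from ._color import lab_to_linear, encode_srgb8
from .pattern_gen import TargetSkin
from .scene_synth import Scene


class PlacementError(ValueError):
    """Target centre violates the placement constraints."""


class ConfigurationError(ValueError):
    """Scene geometry admits no feasible target placement."""


@dataclasses.dataclass
class RenderedStimulus:
    image: np.ndarray  # (H, W, 3) linear-light RGB
    target_centre: tuple[int, int]  # (x, y) px
    target_diameter: int
    target_mask: np.ndarray  # (H, W) bool
    provenance: dict


def spherical_deform(
    img: np.ndarray,
    out_size: int | None = None,
    rotation_deg: float = 0.0,
    inverse: bool = False,
) -> np.ndarray:
    """Wrap a flat square pattern onto a hemisphere viewed from above.

    Forward map: a destination pixel at normalized radius r samples the
    source at radius (2/pi) asin(r), so pattern elements compress toward
    the rim exactly as arc length does on a sphere; the centre pixel is
    unmoved.  ``inverse=True`` applies the inverse map sin(pi/2 r) (used
    by round-trip checks).  ``rotation_deg`` rotates the pattern about the
    centre in the same resample.
    """
    if img.shape[0] != img.shape[1]:
        raise ValueError("skin must be square")
    src_size = img.shape[0]
    d = src_size if out_size is None else int(out_size)
    c = (d - 1) / 2.0
    yy, xx = np.mgrid[0:d, 0:d]
    xu = (xx - c) / (d / 2.0)
    yu = (yy - c) / (d / 2.0)
    r = np.hypot(xu, yu)
    rc = np.clip(r, 0.0, 1.0)
    r_src = np.sin(np.pi / 2.0 * rc) if inverse else (2.0 / np.pi) * np.arcsin(rc)
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(r > 1e-12, r_src / np.maximum(r, 1e-12), 0.0)
    th = np.deg2rad(rotation_deg)
    ca, sa = np.cos(th), np.sin(th)
    xs = scale * (ca * xu + sa * yu)
    ys = scale * (-sa * xu + ca * yu)
    cs = (src_size - 1) / 2.0
    rows = ys * (src_size / 2.0) + cs
    cols = xs * (src_size / 2.0) + cs
    if img.ndim == 2:
        return ndimage.map_coordinates(img, [rows, cols], order=1, mode="nearest")
    out = np.empty((d, d, img.shape[2]))
    for ch in range(img.shape[2]):
        out[..., ch] = ndimage.map_coordinates(
            img[..., ch], [rows, cols], order=1, mode="nearest")
    return out


def _disc_mask(d: int) -> np.ndarray:
    c = (d - 1) / 2.0
    yy, xx = np.mgrid[0:d, 0:d]
    return (yy - c) ** 2 + (xx - c) ** 2 <= (d / 2.0) ** 2


def check_placement(scene_shape: tuple[int, int], diameter: int,
                    centre: tuple[int, int]) -> bool:
    h, w = scene_shape
    x, y = centre
    m = 2 * diameter
    if not (m <= x <= w - m and m <= y <= h - m):
        return False
    return np.hypot(x - w / 2.0, y - h / 2.0) >= m


def place_target(
    scene: Scene,
    rng: np.random.Generator,
    diameter: int | None = None,
    max_tries: int = 20000,
) -> tuple[int, int]:
    """Uniform draw over the feasible region (two diameters clear of both
    the border and the image centre)."""
    d = scene.target_diameter if diameter is None else int(diameter)
    h, w = scene.image.shape[:2]
    m = 2 * d
    if w - 2 * m <= 0 or h - 2 * m <= 0:
        raise ConfigurationError(
            f"scene {w}x{h} leaves no room for a {d} px target")
    for _ in range(max_tries):
        x = int(rng.integers(m, w - m + 1))
        y = int(rng.integers(m, h - m + 1))
        if check_placement((h, w), d, (x, y)):
            return (x, y)
    raise ConfigurationError("no feasible placement found")


def composite_target(
    scene: Scene,
    skin: TargetSkin,
    centre: tuple[int, int],
    gloss_marking: float | None = None,
    gloss_ground: float | None = None,
    rotation_deg: float = 0.0,
    provenance: dict | None = None,
    enforce_placement: bool = True,
) -> RenderedStimulus:
    """Light the skin with the scene's calibration-target illumination and
    composite it at ``centre``.

    Per pixel, in linear RGB: the button's recorded appearance divided by
    its known 8% reflectance gives the incident illumination; multiplying
    by the skin's reflectance relights the pattern; the glossy-target
    layer is then added with the per-region alpha and the result clipped
    to the display range.
    """
    gm = skin.params.gloss_marking if gloss_marking is None else float(gloss_marking)
    gg = skin.params.gloss_ground if gloss_ground is None else float(gloss_ground)
    if not (0.0 <= gm <= 1.0 and 0.0 <= gg <= 1.0):
        raise ValueError("gloss alphas must lie in [0, 1]")
    d = scene.target_diameter
    h, w = scene.image.shape[:2]
    x, y = int(centre[0]), int(centre[1])
    if enforce_placement and not check_placement((h, w), d, (x, y)):
        raise PlacementError(
            f"centre {centre} violates the 2-diameter no-go zones")

    def_lab = spherical_deform(skin.lab, out_size=d, rotation_deg=rotation_deg)
    def_mark = spherical_deform(skin.marking_mask, out_size=d,
                                rotation_deg=rotation_deg)
    refl = np.clip(lab_to_linear(def_lab), 0.0, 1.0)
    illum = scene.calib_illum  # = button appearance / 0.08
    alpha = gm * def_mark + gg * (1.0 - def_mark)
    target = illum[..., None] * refl + (alpha * scene.gloss_layer)[..., None]
    target = np.clip(target, 0.0, 1.0)

    disc = _disc_mask(d)
    image = scene.image.copy()
    r0, c0 = y - d // 2, x - d // 2
    sub = image[r0:r0 + d, c0:c0 + d]
    sub[disc] = target[disc].astype(image.dtype)
    mask = np.zeros((h, w), dtype=bool)
    mask[r0:r0 + d, c0:c0 + d] = disc
    return RenderedStimulus(
        image=image,
        target_centre=(x, y),
        target_diameter=d,
        target_mask=mask,
        provenance=provenance or {},
    )


def save_stimulus(stim: RenderedStimulus, path: str | pathlib.Path) -> None:
    """PNG + JSON sidecar (centre, diameter, provenance)."""
    import imageio.v3 as iio

    path = pathlib.Path(path)
    iio.imwrite(path, encode_srgb8(stim.image))
    side = {
        "target_centre": list(stim.target_centre),
        "target_diameter": stim.target_diameter,
        "provenance": stim.provenance,
    }
    path.with_suffix(".json").write_text(json.dumps(side, indent=1))
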