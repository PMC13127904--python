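"""Camouflage and phenotype measurements in CIELAB.

Contrast is the standard deviation of the (signed, even-symmetric) Gabor
response of a channel, measured at six spatial scales relative to the
target diameter and four orientations.  Filters are applied in the
frequency domain (a Gabor is a Gaussian bump at the carrier frequency),
with reflection padding, DC removal and unit spatial L2 norm - so white
noise yields identical contrast at every orientation, and wavelengths up
to the image size remain measurable.  The orientation convention: a
0-degree filter responds maximally to vertically oriented stripes.

Measures:
 * luminance / colour / pattern difference between a target region and
   its local surround (|mean dL*|, Euclidean d(a*, b*), and the summed
   absolute contrast difference across scales in L*),
 * GabRat edge disruption - the ratio of Gabor edge energy orthogonal
   ("false") versus parallel ("coherent") to the target outline,
 * vertical luminance gradients (countershading; positive = lighter top),
 * gloss and edge-enhancement difference measures,
 * background variation (mean contrast across scales) per channel and
   for the depth map.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import fft as sfft
from scipy import ndimage
from skimage import color, measure

from ._color import linear_to_lab

logger = logging.getLogger(__name__)

SCALES: tuple[float, ...] = (1 / 64, 1 / 32, 1 / 16, 1 / 4, 1 / 2, 1.0)
EE_SCALES: tuple[float, ...] = (1 / 64, 1 / 32, 1 / 16, 1 / 8)
ORIENTATIONS: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)
SIGMA_FACTOR = 0.56  # Gabor envelope SD as a fraction of wavelength
LOCAL_FACTOR = 2.5  # local surround outer radius, x target radius
GLOBAL_FACTOR = 15.0  # global surround outer radius, x target radius

_CHANNEL_INDEX = {"L": 0, "a": 1, "b": 2}


def to_cielab(image: np.ndarray, encoded: bool = True) -> np.ndarray:
    """sRGB (D65) -> CIELAB.  ``encoded=False`` treats input as linear."""
    if encoded:
        return color.rgb2lab(np.clip(image, 0.0, 1.0))
    return linear_to_lab(image)


# ---------------------------------------------------------------------------
# frequency-domain Gabor bank

_KCACHE: dict[tuple, np.ndarray] = {}
_KCACHE_MAX = 512


def _gabor_freq_r(shape: tuple[int, int], wavelength: float, theta_deg: float,
                  odd: bool = False, single: bool = False) -> np.ndarray:
    """Gabor transfer function on the rfft2 grid (unit spatial L2 norm)."""
    key = (shape, round(wavelength, 6), round(theta_deg, 3) % 180.0, odd, single)
    hit = _KCACHE.get(key)
    if hit is not None:
        return hit
    h, w = shape
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.rfftfreq(w)[None, :]
    th = np.deg2rad(theta_deg)
    f0x, f0y = np.cos(th) / wavelength, np.sin(th) / wavelength
    sig = SIGMA_FACTOR * wavelength
    c = 2.0 * np.pi ** 2 * sig * sig
    gp = np.exp(-c * ((fx - f0x) ** 2 + (fy - f0y) ** 2))
    gm = np.exp(-c * ((fx + f0x) ** 2 + (fy + f0y) ** 2))
    if odd:
        K = -0.5j * (gp - gm)
    else:
        K = 0.5 * (gp + gm)
        K = K.astype(complex)
    K[0, 0] = 0.0  # zero-mean filter
    # spatial L2 norm via Parseval on the half-spectrum
    wgt = np.full(K.shape[1], 2.0)
    wgt[0] = 1.0
    if w % 2 == 0:
        wgt[-1] = 1.0
    l2 = np.sqrt((np.abs(K) ** 2 * wgt).sum() / (h * w))
    if l2 > 0:
        K = K / l2
    if single:
        K = K.astype(np.complex64)
    if len(_KCACHE) >= _KCACHE_MAX:
        _KCACHE.pop(next(iter(_KCACHE)))
    _KCACHE[key] = K
    return K


def _pad_to_fast(img: np.ndarray, pad: int) -> tuple[np.ndarray, int]:
    """Symmetric-pad by at least ``pad`` on each side, up to the next fast
    FFT length (never zero-pad: a step edge would alias into every band)."""
    h, w = img.shape
    pad = max(0, min(pad, h - 1, w - 1))
    ph = sfft.next_fast_len(h + 2 * pad)
    pw = sfft.next_fast_len(w + 2 * pad)
    out = img
    for axis, total in ((0, ph - h), (1, pw - w)):
        before = pad
        after = total - pad
        widths = [(0, 0), (0, 0)]
        while before > 0 or after > 0:
            n = out.shape[axis]
            b = min(before, n - 1)
            a = min(after, n - 1)
            widths[axis] = (b, a)
            out = np.pad(out, widths, mode="symmetric")
            before -= b
            after -= a
            widths[axis] = (0, 0)
    return out, pad


def gabor_responses(
    img: np.ndarray,
    specs: list[tuple[float, float]],
    pad: int | None = None,
    odd: bool = False,
    single: bool = False,
) -> dict[tuple[float, float], np.ndarray]:
    """Even (or odd) Gabor response maps for (wavelength, orientation) specs.

    One rfft of the reflection-padded image is shared by all filters.
    ``single=True`` runs the transforms in float32 (the per-trial fast
    path; float64 is the measurement-grade default).
    """
    if not specs:
        return {}
    if pad is None:
        pad = int(round(0.75 * max(wl for wl, _ in specs)))
    dtype = np.float32 if single else np.float64
    pimg, pad = _pad_to_fast(img.astype(dtype), pad)
    ph, pw = pimg.shape
    F = sfft.rfft2(pimg)
    out = {}
    h, w = img.shape
    for wl, th in specs:
        K = _gabor_freq_r((ph, pw), wl, th, odd=odd, single=single)
        resp = sfft.irfft2(F * K, s=(ph, pw))
        out[(wl, th)] = resp[pad:pad + h, pad:pad + w]
    return out


def gabor_contrast(
    channel: np.ndarray,
    scale: float,
    orientation: float,
    diameter: float,
    mask: np.ndarray | None = None,
    pad: int | None = None,
) -> float:
    """SD of the even Gabor response (wavelength = scale x diameter) over
    the region of interest.  Returns NaN (with a warning) when one
    wavelength does not fit in the raster."""
    wl = scale * diameter
    if wl > min(channel.shape):
        logger.warning("Gabor scale %.4g (wavelength %.1f px) exceeds the "
                       "%s raster; skipped", scale, wl, channel.shape)
        return float("nan")
    resp = gabor_responses(channel, [(wl, orientation)], pad=pad)[(wl, orientation)]
    vals = resp if mask is None else resp[mask]
    return float(vals.std())


@dataclasses.dataclass
class ContrastTable:
    """Contrast indexed by (channel, scale, orientation)."""

    values: dict[tuple[str, float, float], float]
    diameter: float

    def get(self, channel: str, scale: float, orientation: float) -> float:
        return self.values[(channel, scale, orientation)]

    def orientation_mean(self, channel: str, scale: float) -> float:
        v = [self.values[(channel, scale, o)] for o in ORIENTATIONS]
        return float(np.nanmean(v)) if not all(np.isnan(v)) else float("nan")


def contrast_table(
    lab: np.ndarray,
    diameter: float,
    mask: np.ndarray | None = None,
    channels: tuple[str, ...] = ("L", "a", "b"),
    scales: tuple[float, ...] = SCALES,
    orientations: tuple[float, ...] = ORIENTATIONS,
    pad: int | None = None,
) -> ContrastTable:
    """The full contrast bank for a Lab raster (NaN where a scale does not
    fit the raster)."""
    vals: dict[tuple[str, float, float], float] = {}
    fit = [s for s in scales if s * diameter <= min(lab.shape[:2])]
    for s in scales:
        if s not in fit:
            logger.warning("contrast_table: scale %.4g skipped for raster %s",
                           s, lab.shape[:2])
    specs = [(s * diameter, o) for s in fit for o in orientations]
    for ch in channels:
        maps = gabor_responses(lab[..., _CHANNEL_INDEX[ch]], specs, pad=pad)
        for s in scales:
            for o in orientations:
                if s in fit:
                    r = maps[(s * diameter, o)]
                    v = r if mask is None else r[mask]
                    vals[(ch, s, o)] = float(v.std())
                else:
                    vals[(ch, s, o)] = float("nan")
    return ContrastTable(values=vals, diameter=diameter)


def directionality(table: ContrastTable, channel: str, scale: float) -> float:
    """Max orientation contrast / mean orientation contrast, in [1, 4]."""
    v = np.array([table.get(channel, scale, o) for o in ORIENTATIONS])
    if np.any(np.isnan(v)):
        return float("nan")
    m = v.mean()
    if m <= 0.0:
        return 1.0  # isotropic by convention
    return float(v.max() / m)


def verticalness(table: ContrastTable, channel: str, scale: float) -> float:
    """contrast(0 deg) - contrast(90 deg): positive = vertical patterning."""
    return float(table.get(channel, scale, 0.0) - table.get(channel, scale, 90.0))


# ---------------------------------------------------------------------------
# region helpers

def disc_mask(shape: tuple[int, int], centre: tuple[float, float],
              radius: float) -> np.ndarray:
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return (yy - centre[1]) ** 2 + (xx - centre[0]) ** 2 <= radius * radius


def surround_masks(
    shape: tuple[int, int],
    centre: tuple[float, float],
    diameter: float,
    local_factor: float = LOCAL_FACTOR,
    global_factor: float = GLOBAL_FACTOR,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(target disc, local annulus, global annulus) masks; annuli exclude
    the target disc and are clipped at the image border."""
    r = diameter / 2.0
    target = disc_mask(shape, centre, r)
    local = disc_mask(shape, centre, local_factor * r) & ~target
    glob = disc_mask(shape, centre, global_factor * r) & ~target
    return target, local, glob


def camouflage_differences(
    lab: np.ndarray,
    target_mask: np.ndarray,
    surround_mask: np.ndarray,
    diameter: float,
    scales: tuple[float, ...] = SCALES,
    pad: int | None = None,
    single: bool = False,
) -> tuple[float, float, float]:
    """(luminance, colour, pattern) difference between target and surround.

    luminance = |mean dL*|; colour = Euclidean distance of the mean
    (a*, b*); pattern = sum over scales of |d contrast| in L*, with
    orientation-averaged contrasts.
    """
    tL = lab[..., 0][target_mask]
    sL = lab[..., 0][surround_mask]
    lum = abs(float(tL.mean() - sL.mean()))
    da = lab[..., 1][target_mask].mean() - lab[..., 1][surround_mask].mean()
    db = lab[..., 2][target_mask].mean() - lab[..., 2][surround_mask].mean()
    col = float(np.hypot(da, db))

    fit = [s for s in scales if s * diameter <= min(lab.shape[:2])]
    specs = [(s * diameter, o) for s in fit for o in ORIENTATIONS]
    maps = gabor_responses(lab[..., 0], specs, pad=pad, single=single)
    pat = 0.0
    for s in fit:
        ct = np.mean([maps[(s * diameter, o)][target_mask].std()
                      for o in ORIENTATIONS])
        cs = np.mean([maps[(s * diameter, o)][surround_mask].std()
                      for o in ORIENTATIONS])
        pat += abs(float(ct - cs))
    return lum, col, pat


# ---------------------------------------------------------------------------
# GabRat edge disruption

def _outline_points(mask: np.ndarray, n_points: int) -> tuple[np.ndarray, np.ndarray]:
    """Evenly spaced (row, col) samples along the mask outline + tangents."""
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise ValueError("degenerate mask: no outline")
    contour = max(contours, key=len)
    seg = np.diff(contour, axis=0)
    arc = np.concatenate([[0.0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))])
    if arc[-1] <= 0:
        raise ValueError("degenerate mask outline")
    s = np.linspace(0.0, arc[-1], n_points, endpoint=False)
    rows = np.interp(s, arc, contour[:, 0])
    cols = np.interp(s, arc, contour[:, 1])
    # closed-curve central-difference tangents
    tr = np.roll(rows, -1) - np.roll(rows, 1)
    tc = np.roll(cols, -1) - np.roll(cols, 1)
    return np.stack([rows, cols]), np.stack([tr, tc])


def gabrat(
    luminance: np.ndarray,
    target_mask: np.ndarray,
    sigma: float = 3.0,
    n_points: int = 180,
    n_orientations: int = 8,
    single: bool = False,
) -> float:
    """GabRat edge-disruption ratio in [0, 1].

    At points along the target outline, Gabor energy (envelope SD
    ``sigma`` px) is split into the component parallel to the local
    outline tangent ("coherent") and orthogonal to it ("false");
    the ratio sum(false) / (sum(false) + sum(coherent)) is high when
    markings cross the outline and break it up.  Energy at the tangent
    angle is linearly interpolated from ``n_orientations`` filter
    orientations; eight keeps the interpolation error well below the
    dense-angle value (four is visibly too coarse).
    """
    if target_mask.sum() < 16:
        raise ValueError("degenerate mask")
    pts, tans = _outline_points(target_mask, n_points)
    wl = sigma / SIGMA_FACTOR

    # restrict to a window around the outline for speed
    support = int(np.ceil(3 * sigma + wl))
    r0 = max(0, int(pts[0].min()) - support)
    r1 = min(luminance.shape[0], int(pts[0].max()) + support + 1)
    c0 = max(0, int(pts[1].min()) - support)
    c1 = min(luminance.shape[1], int(pts[1].max()) + support + 1)
    win = luminance[r0:r1, c0:c1]
    oris = tuple(180.0 * i / n_orientations for i in range(n_orientations))
    specs = [(wl, o) for o in oris]
    even = gabor_responses(win, specs, pad=support, single=single)
    odd = gabor_responses(win, specs, pad=support, odd=True, single=single)
    energy = {o: (even[(wl, o)].astype(float) ** 2
                  + odd[(wl, o)].astype(float) ** 2) for o in oris}

    prow = pts[0] - r0
    pcol = pts[1] - c0
    e_at = {o: ndimage.map_coordinates(energy[o], [prow, pcol], order=1)
            for o in oris}
    e_stack = np.stack([e_at[o] for o in oris])  # (n_orientations, n_points)
    step = 180.0 / n_orientations

    def interp_energy(theta_deg: np.ndarray) -> np.ndarray:
        t = np.mod(theta_deg, 180.0) / step
        i0 = np.floor(t).astype(int) % n_orientations
        i1 = (i0 + 1) % n_orientations
        fr = t - np.floor(t)
        idx = np.arange(theta_deg.size)
        return e_stack[i0, idx] * (1 - fr) + e_stack[i1, idx] * fr

    # filter orientation whose stripes run along the tangent (coherent)
    tr, tc = tans[0], tans[1]
    theta_coh = np.degrees(np.arctan2(-tc, tr))
    e_coh = interp_energy(theta_coh)
    e_false = interp_energy(theta_coh + 90.0)
    total = e_coh.sum() + e_false.sum()
    if total <= 0:
        return 0.5
    return float(e_false.sum() / total)


# ---------------------------------------------------------------------------
# gradients, gloss, edge enhancement, background variation

def vertical_gradient(raster: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Least-squares slope of row-mean value on normalized height.

    Height runs 0 at the bottom of the masked extent to 1 at its top, so a
    positive slope means the top is lighter (for L*).
    """
    if mask is None:
        mask = np.ones(raster.shape, dtype=bool)
    rows = np.where(mask.any(axis=1))[0]
    if rows.size < 2:
        raise ValueError("mask spans fewer than 2 rows")
    r_min, r_max = rows[0], rows[-1]
    counts = mask[r_min:r_max + 1].sum(axis=1).astype(float)
    sums = np.where(mask[r_min:r_max + 1], raster[r_min:r_max + 1], 0.0).sum(axis=1)
    valid = counts > 0
    means = sums[valid] / counts[valid]
    y = (r_max - np.arange(r_min, r_max + 1)[valid]) / max(1, r_max - r_min)
    w = counts[valid]
    ybar = (w * y).sum() / w.sum()
    mbar = (w * means).sum() / w.sum()
    denom = (w * (y - ybar) ** 2).sum()
    if denom <= 0:
        return 0.0
    return float((w * (y - ybar) * (means - mbar)).sum() / denom)


@dataclasses.dataclass
class GlossMeasures:
    delta_mean: float  # mean L*, gloss on - gloss off
    delta_sd: float  # SD of L*, on - off
    max_delta: float  # mean L*, alphas=1 - gloss off
    relative: float  # delta_mean / max_delta (0 when max_delta ~ 0)


def gloss_measures(
    lum_on: np.ndarray,
    lum_off: np.ndarray,
    lum_max: np.ndarray,
    mask: np.ndarray,
) -> GlossMeasures:
    """Luminance change with and without the gloss genes active, and with
    maximum gloss (darker targets appear inherently glossier, so the
    relative value normalizes by the target's own maximum)."""
    on, off, mx = lum_on[mask], lum_off[mask], lum_max[mask]
    d_mean = float(on.mean() - off.mean())
    d_sd = float(on.std() - off.std())
    d_max = float(mx.mean() - off.mean())
    rel = d_mean / d_max if abs(d_max) > 1e-9 else 0.0
    return GlossMeasures(d_mean, d_sd, d_max, rel)


def gloss_measures_from_stimuli(stim_on, stim_off, stim_max) -> GlossMeasures:
    keys = ("population_id", "individual", "generation")
    for a, b in ((stim_on, stim_off), (stim_on, stim_max)):
        pa = {k: a.provenance.get(k) for k in keys}
        pb = {k: b.provenance.get(k) for k in keys}
        if pa != pb:
            raise ValueError(f"mismatched provenance: {pa} vs {pb}")
    lab_on = linear_to_lab(stim_on.image)[..., 0]
    lab_off = linear_to_lab(stim_off.image)[..., 0]
    lab_mx = linear_to_lab(stim_max.image)[..., 0]
    return gloss_measures(lab_on, lab_off, lab_mx, stim_on.target_mask)


def edge_enhancement_measure(
    lab_with: np.ndarray,
    lab_without: np.ndarray,
    diameter: float,
    mask: np.ndarray | None = None,
    scales: tuple[float, ...] = EE_SCALES,
) -> float:
    """Summed change in orientation-averaged L* contrast at the four fine
    scales between the skin with and without edge enhancement."""
    total = 0.0
    for s in scales:
        cw = [gabor_contrast(lab_with[..., 0], s, o, diameter, mask=mask)
              for o in ORIENTATIONS]
        co = [gabor_contrast(lab_without[..., 0], s, o, diameter, mask=mask)
              for o in ORIENTATIONS]
        if np.any(np.isnan(cw)) or np.any(np.isnan(co)):
            continue
        total += float(np.mean(cw) - np.mean(co))
    return total


def background_variation(
    raster: np.ndarray,
    diameter: float,
    mask: np.ndarray | None = None,
    scales: tuple[float, ...] = SCALES,
    pad: int | None = None,
) -> float:
    """Mean contrast across all spatial scales (orientations averaged
    first, then scales) for one channel raster or a depth map."""
    fit = [s for s in scales if s * diameter <= min(raster.shape)]
    if not fit:
        return float("nan")
    specs = [(s * diameter, o) for s in fit for o in ORIENTATIONS]
    maps = gabor_responses(raster, specs, pad=pad)
    per_scale = []
    for s in fit:
        per_scale.append(np.mean([
            maps[(s * diameter, o)].std() if mask is None
            else maps[(s * diameter, o)][mask].std()
            for o in ORIENTATIONS]))
    return float(np.mean(per_scale))


def surround_stats(lab: np.ndarray, local_mask: np.ndarray,
                   global_mask: np.ndarray) -> dict[str, float]:
    out = {}
    for name, m in (("local", local_mask), ("global", global_mask)):
        for ch, idx in _CHANNEL_INDEX.items():
            out[f"{name}_mean_{ch}"] = float(lab[..., idx][m].mean())
    return out


# ---------------------------------------------------------------------------
# high-level per-stimulus measurement (the observer's input)

def measure_stimulus(stim, scene=None, pad: int | None = None,
                     extras: bool = False) -> dict[str, float]:
    """The camouflage MetricVector for one rendered stimulus.

    Works on a window around the local surround for speed; the four core
    metrics (luminance/colour/pattern difference, gabrat) always present,
    surround statistics added with ``extras=True``.
    """
    d = stim.target_diameter
    x, y = stim.target_centre
    r_out = int(np.ceil(LOCAL_FACTOR * d / 2.0)) + 2
    h, w = stim.image.shape[:2]
    r0, r1 = max(0, y - r_out), min(h, y + r_out + 1)
    c0, c1 = max(0, x - r_out), min(w, x + r_out + 1)
    lab = linear_to_lab(stim.image[r0:r1, c0:c1])
    centre = (x - c0, y - r0)
    target, local, _ = surround_masks(lab.shape[:2], centre, d,
                                      global_factor=LOCAL_FACTOR)
    lum, col, pat = camouflage_differences(lab, target, local, d, pad=pad,
                                           single=True)
    gr = gabrat(lab[..., 0], target, single=True)
    out = {
        "luminance_difference": lum,
        "colour_difference": col,
        "pattern_difference": pat,
        "gabrat": gr,
    }
    if extras:
        _, local_m, global_m = surround_masks((h, w), (x, y), d)
        lab_full = linear_to_lab(stim.image)
        out.update(surround_stats(lab_full, local_m, global_m))
        out["target_vertical_gradient_L"] = vertical_gradient(
            lab_full[..., 0], stim.target_mask)
    return out
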