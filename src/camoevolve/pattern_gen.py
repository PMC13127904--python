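"""Genome -> pattern parameters -> Gray-Scott markings -> target-skin image.

The phenotype of a prey target is a square CIELAB raster ("target-skin")
assembled from a Gray-Scott reaction-diffusion field.  Feed (F) and kill (k)
rates select the Turing regime (spots, stripes, labyrinths); the field is
thresholded at a genetically controlled quantile into a marking mask,
coloured with genetically controlled CIELAB colours, then run through a
countershading filter (a linear vertical L* ramp) and an edge-enhancement
filter (a signed difference-of-Gaussians rim along marking boundaries that
pictorially mimics the shadows forming at object edges).

Gene layout (36 decimal loci, each in [0, 1])
---------------------------------------------
====  =========================  =======================================
locus trait                      mapping (gene g -> parameter)
====  =========================  =======================================
0     feed rate F                0.01 + 0.08 g   (clipped to box)
1     kill rate k                0.045 + 0.025 g (clipped to box)
2     diffusion ratio Du/Dv      1.8 + 0.4 g  (Du fixed at 0.16)
3     integration length         steps = (0.25 + 0.75 g) x max_steps
4     nucleation seed            int(g x 2^20)  (heritable RNG stream)
5     nucleation density         n_spots = 30 + round(150 g)
6     nucleation radius          1.5 + 2 g cells (at the 128-cell scale)
7-9   marking colour L*,a*,b*    L: 10+80g, a: -50+100g, b: -50+100g
10-12 ground colour L*,a*,b*     same ranges
13-15 secondary marking colour   same ranges (marking interiors shade
                                 from secondary to primary colour)
16    marking threshold          quantile q = g
17    marking tone gamma         4^(g - 1/2)  in [1/2, 2]
18    marking edge softness      blur sigma = 2 g px (at 256 px skin)
19    pattern scale              zoom = 1.6 x 8^g (marking size ~1/16
                                 to ~1/2 of the target diameter)
20    pattern orientation        180 g degrees
21    anisotropy                 1 + 2 g (stretch along orientation)
22    countershading slope       80 (g - 1/2)  Delta-L* per unit height
23    countershading offset      20 (g - 1/2)  L*
24    edge-enhancement strength  15 g  (Delta-L* amplitude scale)
25    edge-enhancement width     sigma_out = 3 + 3 g px (sigma_in 1.5)
26-28 marking colour fine        +/- 4 per channel
29    feed rate fine             +/- 0.002
30    kill rate fine             +/- 0.000625
31    threshold fine             +/- 0.02
32    countershading slope fine  +/- 2
33    orientation fine           +/- 5 degrees
34    marking gloss alpha        g
35    ground gloss alpha         g
====  =========================  =======================================

Coarse+fine locus pairs give the GA a two-resolution encoding; all 36 loci
are phenotypically active.  With every gene at 0.5 the countershading slope
is exactly 0 and both gloss alphas are 0.5.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib

import numpy as np
from scipy import ndimage

from .genome import Genome

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


class NumericalStabilityError(RuntimeError):
    """Raised when the Gray-Scott integration produces non-finite values."""


# ---------------------------------------------------------------------------
# Gray-Scott reaction-diffusion

if _HAVE_NUMBA:

    @njit(cache=True)
    def _gs_chunk(u, v, un, vn, Du, Dv, F, k, dt, steps):  # pragma: no cover
        n, m = u.shape
        for _ in range(steps):
            for i in range(n):
                im = i - 1 if i > 0 else n - 1
                ip = i + 1 if i < n - 1 else 0
                for j in range(m):
                    jm = j - 1 if j > 0 else m - 1
                    jp = j + 1 if j < m - 1 else 0
                    lu = (
                        0.2 * (u[im, j] + u[ip, j] + u[i, jm] + u[i, jp])
                        + 0.05 * (u[im, jm] + u[im, jp] + u[ip, jm] + u[ip, jp])
                        - u[i, j]
                    )
                    lv = (
                        0.2 * (v[im, j] + v[ip, j] + v[i, jm] + v[i, jp])
                        + 0.05 * (v[im, jm] + v[im, jp] + v[ip, jm] + v[ip, jp])
                        - v[i, j]
                    )
                    uv2 = u[i, j] * v[i, j] * v[i, j]
                    un[i, j] = u[i, j] + dt * (Du * lu - uv2 + F * (1.0 - u[i, j]))
                    vn[i, j] = v[i, j] + dt * (Dv * lv + uv2 - (F + k) * v[i, j])
            u, un = un, u
            v, vn = vn, v
        return u, v


def _laplacian9(x: np.ndarray) -> np.ndarray:
    out = -x.copy()
    for shift, w in (((1, 0), 0.2), ((-1, 0), 0.2), ((0, 1), 0.2), ((0, -1), 0.2),
                     ((1, 1), 0.05), ((1, -1), 0.05), ((-1, 1), 0.05), ((-1, -1), 0.05)):
        out += w * np.roll(x, shift, axis=(0, 1))
    return out


def _gs_chunk_numpy(u, v, un, vn, Du, Dv, F, k, dt, steps):
    for _ in range(steps):
        lu = _laplacian9(u)
        lv = _laplacian9(v)
        uv2 = u * v * v
        u = u + dt * (Du * lu - uv2 + F * (1.0 - u))
        v = v + dt * (Dv * lv + uv2 - (F + k) * v)
    return u, v


def gray_scott(
    F: float,
    k: float,
    Du: float = 0.16,
    Dv: float = 0.08,
    grid: int = 128,
    steps: int = 5000,
    seed: int = 0,
    dt: float = 1.0,
    n_spots: int = 100,
    spot_radius: float = 2.0,
    normalize: bool = True,
) -> np.ndarray:
    """Integrate the Gray-Scott system and return the inhibitor field v.

    Explicit Euler on a periodic ``grid x grid`` lattice with a 9-point
    Laplacian: du/dt = Du lap(u) - u v^2 + F (1 - u);
    dv/dt = Dv lap(v) + u v^2 - (F + k) v.  u starts at 1 with seeded
    circular v nucleation spots.  The returned field is min-max normalized
    to [0, 1] unless ``normalize=False``.
    """
    if grid < 32:
        raise ValueError("grid must be >= 32")
    if steps < 1:
        raise ValueError("steps must be >= 1")
    if not (Du > Dv > 0):
        raise ValueError("require Du > Dv > 0")
    rng = np.random.default_rng(seed)
    u = np.ones((grid, grid))
    v = np.zeros((grid, grid))
    yy, xx = np.mgrid[0:grid, 0:grid]
    r = max(1.0, spot_radius * grid / 128.0)
    for _ in range(max(1, int(n_spots))):
        cy, cx = rng.integers(0, grid, 2)
        # periodic distance so spots wrap cleanly
        dy = np.minimum(np.abs(yy - cy), grid - np.abs(yy - cy))
        dx = np.minimum(np.abs(xx - cx), grid - np.abs(xx - cx))
        disc = dy * dy + dx * dx <= r * r
        u[disc] = 0.5
        v[disc] = 0.25
    u += 0.02 * rng.random((grid, grid))
    v += 0.02 * rng.random((grid, grid)) * (v > 0)

    chunk = 500
    done = 0
    stepper = _gs_chunk if _HAVE_NUMBA else _gs_chunk_numpy
    while done < steps:
        n_now = min(chunk, steps - done)
        # fresh buffers per chunk: the stepper may hand one of them back
        u, v = stepper(u, v, np.empty_like(u), np.empty_like(v), float(Du),
                       float(Dv), float(F), float(k), float(dt), n_now)
        done += n_now
        if not (np.isfinite(u).all() and np.isfinite(v).all()):
            raise NumericalStabilityError(
                f"Gray-Scott integration diverged (F={F}, k={k}, Du={Du}, "
                f"Dv={Dv}, dt={dt}, step<={done})"
            )
    if not normalize:
        return v.copy()
    lo, hi = v.min(), v.max()
    if hi - lo < 1e-12:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# genome codec

# parameter box for the reaction-diffusion rates (classic spot/stripe regime)
F_BOX = (0.01, 0.09)
K_BOX = (0.045, 0.070)


@dataclasses.dataclass
class PatternParams:
    """Decoded phenotype parameters (see the gene layout table above)."""

    feed: float
    kill: float
    du: float
    dv: float
    steps_fraction: float
    nucleation_seed: int
    n_spots: int
    spot_radius: float
    marking_lab: tuple[float, float, float]
    ground_lab: tuple[float, float, float]
    secondary_lab: tuple[float, float, float]
    threshold: float
    tone_gamma: float
    edge_softness: float
    scale_zoom: float
    orientation_deg: float
    anisotropy: float
    cs_slope: float
    cs_offset: float
    edge_strength: float
    edge_sigma_out: float
    gloss_marking: float
    gloss_ground: float

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("marking_lab", "ground_lab", "secondary_lab"):
            d[key] = list(d[key])
        return d


def _lab_from(genes: np.ndarray, i0: int) -> tuple[float, float, float]:
    return (
        10.0 + 80.0 * genes[i0],
        -50.0 + 100.0 * genes[i0 + 1],
        -50.0 + 100.0 * genes[i0 + 2],
    )


def decode_genome(g: Genome) -> PatternParams:
    """Total, deterministic map from a 36-gene chromosome to PatternParams."""
    x = g.genes
    if x.size != 36:
        raise ValueError("decode_genome expects a 36-gene chromosome")
    feed = np.clip(0.01 + 0.08 * x[0] + 0.004 * (x[29] - 0.5), *F_BOX)
    kill = np.clip(0.045 + 0.025 * x[1] + 0.00125 * (x[30] - 0.5), *K_BOX)
    ratio = 1.8 + 0.4 * x[2]
    du = 0.16
    dv = du / ratio
    mk = _lab_from(x, 7)
    fine = 8.0 * (x[26:29] - 0.5)
    marking = (
        float(np.clip(mk[0] + fine[0], 0.0, 100.0)),
        float(np.clip(mk[1] + fine[1], -60.0, 60.0)),
        float(np.clip(mk[2] + fine[2], -60.0, 60.0)),
    )
    return PatternParams(
        feed=float(feed),
        kill=float(kill),
        du=du,
        dv=float(dv),
        steps_fraction=float(0.25 + 0.75 * x[3]),
        nucleation_seed=int(x[4] * (1 << 20)),
        n_spots=int(30 + round(150 * x[5])),
        spot_radius=float(1.5 + 2.0 * x[6]),
        marking_lab=marking,
        ground_lab=_lab_from(x, 10),
        secondary_lab=_lab_from(x, 13),
        threshold=float(np.clip(x[16] + 0.04 * (x[31] - 0.5), 0.0, 1.0)),
        tone_gamma=float(4.0 ** (x[17] - 0.5)),
        edge_softness=float(2.0 * x[18]),
        scale_zoom=float(1.6 * 8.0 ** x[19]),
        orientation_deg=float(180.0 * x[20] + 10.0 * (x[33] - 0.5)),
        anisotropy=float(1.0 + 2.0 * x[21]),
        cs_slope=float(80.0 * (x[22] - 0.5) + 4.0 * (x[32] - 0.5)),
        cs_offset=float(20.0 * (x[23] - 0.5)),
        edge_strength=float(15.0 * x[24]),
        edge_sigma_out=float(3.0 + 3.0 * x[25]),
        gloss_marking=float(x[34]),
        gloss_ground=float(x[35]),
    )


# ---------------------------------------------------------------------------
# skin rendering

@dataclasses.dataclass
class TargetSkin:
    """Pre-rendering phenotype: a square CIELAB raster plus measurement
    variants (edge enhancement off; countershading neutral).  Gloss is a
    rendering-time property (alpha blending), so gloss-off variants are
    realized by compositing with zero alphas."""

    lab: np.ndarray  # (size, size, 3)
    marking_mask: np.ndarray  # (size, size) in [0, 1]
    mask: np.ndarray  # (size, size) bool circular mask
    variants: dict[str, np.ndarray]
    params: PatternParams
    size: int


_RD_CACHE: dict[tuple, np.ndarray] = {}
_RD_CACHE_MAX = 400


def _rd_field(p: PatternParams, rd_grid: int, rd_max_steps: int, seed: int) -> np.ndarray:
    steps = max(1, int(round(p.steps_fraction * rd_max_steps)))
    key = (
        round(p.feed, 9), round(p.kill, 9), round(p.dv, 9), steps,
        p.nucleation_seed, p.n_spots, round(p.spot_radius, 6), rd_grid, seed,
    )
    hit = _RD_CACHE.get(key)
    if hit is not None:
        return hit
    v = gray_scott(
        p.feed, p.kill, p.du, p.dv, grid=rd_grid, steps=steps,
        seed=(p.nucleation_seed ^ (seed * 2654435761)) % (1 << 31),
        n_spots=max(4, int(round(p.n_spots * (rd_grid / 128.0) ** 2))),
        spot_radius=p.spot_radius,
    )
    if len(_RD_CACHE) >= _RD_CACHE_MAX:
        _RD_CACHE.pop(next(iter(_RD_CACHE)))
    _RD_CACHE[key] = v
    return v


def _sample_field(v: np.ndarray, size: int, p: PatternParams) -> np.ndarray:
    """Resample the periodic RD field onto the skin grid with the genetic
    zoom, orientation and anisotropic stretch."""
    grid = v.shape[0]
    # pixels of the skin per RD cell, normalized to a 256 px reference skin
    px_per_cell = p.scale_zoom * size / 256.0
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    ya, xa = yy - c, xx - c
    th = np.deg2rad(p.orientation_deg)
    # rotate into pattern frame, stretch along the pattern axis
    xr = (np.cos(th) * xa + np.sin(th) * ya) / p.anisotropy
    yr = -np.sin(th) * xa + np.cos(th) * ya
    rows = (yr / px_per_cell) % grid
    cols = (xr / px_per_cell) % grid
    return ndimage.map_coordinates(v, [rows, cols], order=1, mode="grid-wrap")


def _y_norm(size: int) -> np.ndarray:
    """Normalized height: 0 at the bottom row, 1 at the top row."""
    rows = np.arange(size, dtype=float)
    return (1.0 - rows / (size - 1))[:, None] * np.ones((1, size))


def _assemble(
    vs: np.ndarray,
    p: PatternParams,
    size: int,
    cs_slope: float,
    cs_offset: float,
    edge_strength: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Build one Lab skin from the sampled field; returns (lab, marking mask)."""
    q = p.threshold
    if q <= 0.0:
        hard = np.ones_like(vs)
        vq = float(vs.min())
    elif q >= 1.0:
        hard = np.zeros_like(vs)
        vq = float(vs.max())
    else:
        vq = float(np.quantile(vs, q))
        hard = (vs >= vq).astype(float)
    soft = p.edge_softness * size / 256.0
    m = np.clip(ndimage.gaussian_filter(hard, soft), 0.0, 1.0) if soft > 0.05 else hard

    # marking interiors shade from the secondary to the primary colour
    span = max(vs.max() - vq, 1e-9)
    t = np.clip((vs - vq) / span, 0.0, 1.0) ** p.tone_gamma
    lab = np.empty((size, size, 3))
    for ch in range(3):
        colour = p.secondary_lab[ch] + (p.marking_lab[ch] - p.secondary_lab[ch]) * t
        lab[..., ch] = p.ground_lab[ch] + m * (colour - p.ground_lab[ch])

    # countershading: linear vertical ramp on L*, positive slope = lighter top
    lab[..., 0] += cs_slope * (_y_norm(size) - 0.5) + cs_offset

    # edge enhancement: signed difference-of-Gaussians rim of the marking
    # boundary (lightened inner edge, darkened outer edge)
    if edge_strength > 0.0 and hard.std() > 0:
        s = size / 256.0
        rim = ndimage.gaussian_filter(m, 1.5 * s) - ndimage.gaussian_filter(
            m, p.edge_sigma_out * s
        )
        lab[..., 0] += edge_strength * 2.0 * rim

    lab[..., 0] = np.clip(lab[..., 0], 0.0, 100.0)
    return lab, m


def render_skin(
    p: PatternParams,
    size: int = 256,
    seed: int = 0,
    rd_grid: int = 128,
    rd_max_steps: int = 3000,
) -> TargetSkin:
    """Render a target-skin (and its measurement variants) from parameters.

    The reaction-diffusion field runs on a periodic ``rd_grid`` lattice and
    is resampled to the skin with the genetic zoom/orientation/anisotropy.
    Variants share the same field so they differ only in the toggled filter.
    """
    v = _rd_field(p, rd_grid, rd_max_steps, seed)
    vs = _sample_field(v, size, p)
    lab, m = _assemble(vs, p, size, p.cs_slope, p.cs_offset, p.edge_strength)
    no_ee, _ = _assemble(vs, p, size, p.cs_slope, p.cs_offset, 0.0)
    neutral_cs, _ = _assemble(vs, p, size, 0.0, 0.0, p.edge_strength)
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    mask = (yy - c) ** 2 + (xx - c) ** 2 <= (size / 2.0) ** 2
    return TargetSkin(
        lab=lab,
        marking_mask=m,
        mask=mask,
        variants={"no_edge_enhancement": no_ee, "neutral_countershading": neutral_cs},
        params=p,
        size=size,
    )


def skin_from_genome(
    g: Genome,
    size: int = 256,
    seed: int = 0,
    rd_grid: int = 128,
    rd_max_steps: int = 3000,
) -> TargetSkin:
    """Decode then render: the full genome -> phenotype map."""
    return render_skin(decode_genome(g), size=size, seed=seed,
                       rd_grid=rd_grid, rd_max_steps=rd_max_steps)


def save_skin(skin: TargetSkin, path: str | pathlib.Path) -> None:
    """Write the skin as a 16-bit sRGB-encoded TIFF plus a JSON parameter
    sidecar.  (16-bit keeps the calibrated values; TIFF because the
    available writers have no 48-bit PNG support.)"""
    import tifffile
    from skimage import color

    path = pathlib.Path(path)
    srgb = np.clip(color.lab2rgb(skin.lab), 0.0, 1.0)
    tifffile.imwrite(path, (srgb * 65535.0 + 0.5).astype(np.uint16))
    path.with_suffix(".json").write_text(json.dumps(skin.params.to_dict(), indent=1))
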