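"""Seeded synthetic dermoscopy scenes with exported ground truth.

A scene is a smooth skin background carrying a darker elliptical lesion
(boundary perturbed by a low-order random Fourier series), optionally a
darker inner core (multitone lesion), dark curvilinear hairs (cubic
Bezier strokes, anti-aliased), bright bubble/gel spots, a smooth
multiplicative illumination field and additive Gaussian noise.  Skin and
lesion luminances live in two disjoint gray-level bands, by default
41–64 (lesion) and 157–181 (skin) on the 0–255 scale, so that before
noise the two masked histograms do not overlap.

Everything is driven by one ``numpy.random.Generator`` seeded from
``SceneParams.seed``, so scenes are bit-reproducible at the stored 8-bit
level across runs and platforms.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage

from . import io as dio
from .errors import ConfigError, InputError

_EDGE_RAMP = 3.0  # px over which the lesion boundary is blended


@dataclass
class SceneParams:
    """Generation parameters for one synthetic scene.

    Gray ranges are on the 0–255 scale; the lesion band must sit strictly
    below the skin band.  ``boundary_wobble`` is the relative amplitude of
    the radial Fourier perturbation of the lesion ellipse.
    """
    size: Tuple[int, int] = (256, 256)
    lesion_axes: Tuple[float, float] = (70.0, 55.0)
    lesion_center: Optional[Tuple[float, float]] = None  # None -> image centre
    boundary_wobble: float = 0.15
    lesion_gray_range: Tuple[float, float] = (41.0, 64.0)
    skin_gray_range: Tuple[float, float] = (157.0, 181.0)
    illumination_amp: float = 0.15
    n_hairs: int = 6
    hair_thickness_range: Tuple[float, float] = (1.5, 3.0)
    n_bubbles: int = 3
    noise_sigma: float = 0.01
    multitone: bool = False
    seed: int = 0

    def validate(self) -> "SceneParams":
        h, w = self.size
        if h < 64 or w < 64:
            raise ConfigError(f"scene size must be >= 64x64, got {self.size}")
        a, b = self.lesion_axes
        if a <= 0 or b <= 0:
            raise ConfigError(f"lesion_axes must be positive, got {self.lesion_axes}")
        if not 0 <= self.boundary_wobble <= 0.5:
            raise ConfigError(f"boundary_wobble must be in [0, 0.5], got {self.boundary_wobble}")
        cy, cx = self.center
        margin = 8.0
        reach_a = a * (1 + self.boundary_wobble) + margin
        reach_b = b * (1 + self.boundary_wobble) + margin
        if cy - reach_b < 0 or cy + reach_b > h or cx - reach_a < 0 or cx + reach_a > w:
            raise ConfigError("lesion ellipse (with wobble) must fit inside the image "
                              "with an 8-pixel margin")
        for name in ("lesion_gray_range", "skin_gray_range"):
            lo, hi = getattr(self, name)
            if not 0 <= lo < hi <= 255:
                raise ConfigError(f"{name} must satisfy 0 <= low < high <= 255, got {(lo, hi)}")
        if self.lesion_gray_range[1] >= self.skin_gray_range[0]:
            raise ConfigError("lesion_gray_range.high must be < skin_gray_range.low")
        if not 0 <= self.illumination_amp <= 0.5:
            raise ConfigError(f"illumination_amp must be in [0, 0.5], got {self.illumination_amp}")
        if self.n_hairs < 0 or self.n_bubbles < 0:
            raise ConfigError("n_hairs and n_bubbles must be >= 0")
        tmin, tmax = self.hair_thickness_range
        if not 0 < tmin <= tmax:
            raise ConfigError(f"hair_thickness_range must satisfy 0 < min <= max, "
                              f"got {self.hair_thickness_range}")
        if not 0 <= self.noise_sigma <= 0.1:
            raise ConfigError(f"noise_sigma must be in [0, 0.1], got {self.noise_sigma}")
        return self

    @property
    def center(self) -> Tuple[float, float]:
        if self.lesion_center is not None:
            return tuple(self.lesion_center)
        return (self.size[0] / 2.0, self.size[1] / 2.0)


@dataclass
class SyntheticScene:
    """A generated scene: artifacted image, the identical scene without
    hairs/bubbles, ground-truth masks, the multiplicative illumination
    field, and the parameters that made it."""
    image: np.ndarray         # (H, W, 3) in [0, 1]
    clean_image: np.ndarray   # (H, W, 3), no hairs/bubbles, same noise
    lesion_mask: np.ndarray   # (H, W) bool
    hair_mask: np.ndarray     # (H, W) bool
    illumination: np.ndarray  # (H, W) multiplicative field around 1
    params: SceneParams


def _smooth_field(rng: np.random.Generator, shape, lo: float, hi: float,
                  corr: float = 8.0) -> np.ndarray:
    """Smooth random texture filling [lo, hi] exactly (min->lo, max->hi)."""
    raw = ndimage.gaussian_filter(rng.standard_normal(shape), corr, mode="reflect")
    rmin, rmax = raw.min(), raw.max()
    if rmax - rmin < 1e-12:
        return np.full(shape, 0.5 * (lo + hi))
    return lo + (raw - rmin) * (hi - lo) / (rmax - rmin)


def _lesion_alpha(params: SceneParams, rng: np.random.Generator) -> np.ndarray:
    """Anti-aliased lesion coverage in [0, 1]; 0.5 level is the boundary."""
    h, w = params.size
    cy, cx = params.center
    a, b = params.lesion_axes
    rows = np.arange(h)[:, None] - cy
    cols = np.arange(w)[None, :] - cx
    theta = np.arctan2(rows, cols)
    rho = np.sqrt((cols / a) ** 2 + (rows / b) ** 2)
    # radial perturbation: <= 5 harmonics, unit-peak, scaled by wobble
    coef = rng.standard_normal(10)
    pert = np.zeros_like(theta)
    for k in range(1, 6):
        pert += coef[2 * k - 2] * np.cos(k * theta) + coef[2 * k - 1] * np.sin(k * theta)
    peak = np.abs(pert).max()
    if peak > 1e-12:
        pert = pert / peak
    m = 1.0 + params.boundary_wobble * pert
    # signed distance approximation in pixels, blended over a short ramp
    signed_px = (m - rho) * min(a, b)
    return np.clip(signed_px / _EDGE_RAMP + 0.5, 0.0, 1.0)


def _bezier_coverage(h: int, w: int, pts: np.ndarray, thickness: float) -> np.ndarray:
    """Anti-aliased coverage of one cubic Bezier stroke of given thickness."""
    # dense parameter sampling: ~2 samples per pixel of arc length
    chord = np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1))
    n = max(int(2 * chord), 64)
    t = np.linspace(0.0, 1.0, n)[:, None]
    p = ((1 - t) ** 3 * pts[0] + 3 * (1 - t) ** 2 * t * pts[1]
         + 3 * (1 - t) * t ** 2 * pts[2] + t ** 3 * pts[3])
    dist = np.full((h, w), np.inf)
    rad = int(np.ceil(thickness / 2 + 2))
    ys = np.clip(np.round(p[:, 0]).astype(int), 0, h - 1)
    xs = np.clip(np.round(p[:, 1]).astype(int), 0, w - 1)
    off = np.arange(-rad, rad + 1)
    for (py, px), iy, ix in zip(p, ys, xs):
        y0, y1 = max(iy - rad, 0), min(iy + rad, h - 1)
        x0, x1 = max(ix - rad, 0), min(ix + rad, w - 1)
        wy = np.arange(y0, y1 + 1)[:, None] - py
        wx = np.arange(x0, x1 + 1)[None, :] - px
        d = np.sqrt(wy * wy + wx * wx)
        np.minimum(dist[y0:y1 + 1, x0:x1 + 1], d, out=dist[y0:y1 + 1, x0:x1 + 1])
    return np.clip(thickness / 2 + 0.5 - dist, 0.0, 1.0)


def _random_edge_point(rng: np.random.Generator, h: int, w: int, side: int) -> np.ndarray:
    if side == 0:
        return np.array([0.0, rng.uniform(0, w - 1)])
    if side == 1:
        return np.array([h - 1.0, rng.uniform(0, w - 1)])
    if side == 2:
        return np.array([rng.uniform(0, h - 1), 0.0])
    return np.array([rng.uniform(0, h - 1), w - 1.0])


def generate_scene(params: SceneParams) -> SyntheticScene:
    """Render one scene deterministically from ``params.seed``.

    Stage order: lesion/skin composite -> multiplicative illumination ->
    hairs and bubbles (artifacted copy only) -> shared additive noise.
    The clean image therefore equals the artifacted image wherever no
    hair or bubble was drawn.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    h, w = params.size

    alpha = _lesion_alpha(params, rng)
    lesion_mask = alpha >= 0.5

    lo_l, hi_l = params.lesion_gray_range
    lo_s, hi_s = params.skin_gray_range
    skin = _smooth_field(rng, (h, w), lo_s / 255.0, hi_s / 255.0)
    lesion = _smooth_field(rng, (h, w), lo_l / 255.0, hi_l / 255.0)
    if params.multitone:
        # darker inner core over ~25% of the lesion (axes scaled by 1/2)
        core_shift = rng.uniform(20.0, 40.0) / 255.0
        cy, cx = params.center
        a, b = params.lesion_axes
        rows = np.arange(h)[:, None] - cy
        cols = np.arange(w)[None, :] - cx
        core = np.sqrt((cols / (a / 2)) ** 2 + (rows / (b / 2)) ** 2)
        core_alpha = np.clip((1 - core) * min(a, b) / 2 / _EDGE_RAMP + 0.5, 0, 1)
        lesion = np.clip(lesion - core_shift * core_alpha, 0.0, 1.0)
    base = alpha * lesion + (1 - alpha) * skin

    # multiplicative illumination: 1 + amp * g, g a unit-peak plane + bump
    plane_c = rng.uniform(-1, 1, size=2)
    yy = np.linspace(-1, 1, h)[:, None]
    xx = np.linspace(-1, 1, w)[None, :]
    g = plane_c[0] * yy + plane_c[1] * xx
    bump_c = rng.uniform(-0.8, 0.8, size=2)
    bump_sigma = rng.uniform(0.3, 0.5) * 2.0  # in normalized units
    g = g + rng.uniform(0.5, 1.5) * np.exp(
        -((yy - bump_c[0]) ** 2 + (xx - bump_c[1]) ** 2) / (2 * bump_sigma ** 2))
    peak = np.abs(g).max()
    if peak > 1e-12:
        g = g / peak
    illumination = 1.0 + params.illumination_amp * g
    lit = np.clip(base * illumination, 0.0, 1.0)

    # hairs: dark cubic Bezier strokes spanning the frame
    hair_cov = np.zeros((h, w))
    hair_lum = np.zeros((h, w))
    for _ in range(params.n_hairs):
        s0, s1 = rng.choice(4, size=2, replace=False)
        p0 = _random_edge_point(rng, h, w, s0)
        p3 = _random_edge_point(rng, h, w, s1)
        ctrl = rng.uniform([0, 0], [h - 1, w - 1], size=(2, 2))
        thickness = rng.uniform(*params.hair_thickness_range)
        cov = _bezier_coverage(h, w, np.vstack([p0, ctrl, p3]), thickness)
        lum = rng.uniform(0.03, 0.12)
        stronger = cov > hair_cov
        hair_lum = np.where(stronger, lum, hair_lum)
        hair_cov = np.maximum(hair_cov, cov)
    hair_mask = hair_cov > 0

    # bubbles: small bright anti-aliased discs
    bubble_cov = np.zeros((h, w))
    bubble_lum = np.zeros((h, w))
    for _ in range(params.n_bubbles):
        r = rng.uniform(2.0, 6.0)
        cy_b = rng.uniform(r + 1, h - r - 2)
        cx_b = rng.uniform(r + 1, w - r - 2)
        d = np.sqrt((np.arange(h)[:, None] - cy_b) ** 2 + (np.arange(w)[None, :] - cx_b) ** 2)
        cov = np.clip(r + 0.5 - d, 0.0, 1.0)
        lum = rng.uniform(0.92, 0.98)
        stronger = cov > bubble_cov
        bubble_lum = np.where(stronger, lum, bubble_lum)
        bubble_cov = np.maximum(bubble_cov, cov)

    artifacted = lit * (1 - hair_cov) + hair_lum * hair_cov
    artifacted = artifacted * (1 - bubble_cov) + bubble_lum * bubble_cov

    # one shared noise field so clean and artifacted stay identical off-artifact
    if params.noise_sigma > 0:
        noise = rng.normal(0.0, params.noise_sigma, size=(h, w))
    else:
        noise = 0.0
    image = np.clip(artifacted + noise, 0.0, 1.0)
    clean = np.clip(lit + noise, 0.0, 1.0)

    return SyntheticScene(
        image=np.repeat(image[:, :, None], 3, axis=2),
        clean_image=np.repeat(clean[:, :, None], 3, axis=2),
        lesion_mask=lesion_mask,
        hair_mask=hair_mask,
        illumination=illumination,
        params=params,
    )


def _params_to_dict(params: SceneParams) -> dict:
    d = dataclasses.asdict(params)
    for key, value in d.items():
        if isinstance(value, tuple):
            d[key] = list(value)
    return d


def params_from_dict(d: dict) -> SceneParams:
    """Inverse of the params.json serialization."""
    names = {f.name for f in dataclasses.fields(SceneParams)}
    unknown = set(d) - names
    if unknown:
        raise ConfigError(f"unknown scene parameter(s): {sorted(unknown)}")
    kwargs = dict(d)
    for key in ("size", "lesion_axes", "lesion_center", "lesion_gray_range",
                "skin_gray_range", "hair_thickness_range"):
        if kwargs.get(key) is not None:
            kwargs[key] = tuple(kwargs[key])
    return SceneParams(**kwargs).validate()


def write_scene(scene: SyntheticScene, out_dir, prefix: str = "") -> Path:
    """Write image.png, clean.png, lesion_mask.png, hair_mask.png and
    params.json (optionally name-prefixed) plus a manifest JSON listing
    the files, seed and parameters.  Returns the manifest path."""
    out_dir = Path(out_dir)
    if not out_dir.is_dir():
        raise InputError(f"output directory does not exist: {out_dir}")
    tag = f"{prefix}_" if prefix else ""
    files = {
        "image": f"{tag}image.png",
        "clean": f"{tag}clean.png",
        "lesion_mask": f"{tag}lesion_mask.png",
        "hair_mask": f"{tag}hair_mask.png",
        "params": f"{tag}params.json",
    }
    dio.write_image(scene.image, out_dir / files["image"])
    dio.write_image(scene.clean_image, out_dir / files["clean"])
    dio.write_mask(scene.lesion_mask, out_dir / files["lesion_mask"])
    dio.write_mask(scene.hair_mask, out_dir / files["hair_mask"])
    params_dict = _params_to_dict(scene.params)
    with open(out_dir / files["params"], "w") as fh:
        json.dump(params_dict, fh, indent=2)
    manifest_path = out_dir / f"{tag}manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump({"files": files, "seed": scene.params.seed, "params": params_dict},
                  fh, indent=2)
    return manifest_path
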