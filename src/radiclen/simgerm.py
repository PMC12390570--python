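"""Synthetic germination scenes with analytic 3-D ground truth.

Germinating elm seeds are photographed top-down in petri dishes; the radicle
elongates as a thin, curved tube that frequently lifts off the dish surface.
A 2-D projection of a lifted curve is *foreshortened*: its projected length is
strictly smaller than its true 3-D arc length, which is why pixel-counting
skeleton baselines under-measure curved radicles.  This module generates
scenes in which every instance carries its exact 3-D centerline, arc length,
and lift profile, so the foreshortening effect (and any method's response to
it) can be measured analytically.

The generator reproduces the descriptive statistics of real germination
imagery of elm: right-skewed radicle lengths (truncated log-normal with
median 28 mm and untruncated mean 30 mm, support 10-80 mm), four curvature
categories defined by the number of *deviation points* (strict local maxima
of the lift profile at least 1 mm above the dish), with marginal category
frequencies (8.9%, 54.5%, 28.8%, 7.8%) for 0 / 1 / 2 / >2 deviation points,
and a strong positive rank coupling between length and curvature category.
Scenes are rendered over black, white, or wood backgrounds, optionally on
1 cm grid paper, inside a dish of 44.5 mm inner radius.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import quad
from scipy.interpolate import CubicSpline
from scipy.spatial import cKDTree
from scipy.special import ndtr, ndtri

from .calib import mm_to_px

#: lift (mm) above the dish surface at which a local maximum counts as a
#: visible deviation point (about one string diameter).
Z_VISIBLE_MM = 1.0

DEFAULT_CATEGORY_WEIGHTS = (0.089, 0.545, 0.288, 0.078)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LengthLaw:
    """Truncated log-normal law for 3-D radicle arc length (mm).

    Defaults give median 28 mm and untruncated mean 30 mm; ``sigma = 0``
    degenerates to a point mass at ``exp(mu)``.
    """

    mu: float = math.log(28.0)
    sigma: float = math.sqrt(2.0 * math.log(30.0 / 28.0))
    lo_mm: float = 10.0
    hi_mm: float = 80.0

    def __post_init__(self):
        if not (0 < self.lo_mm < self.hi_mm):
            raise ValueError("truncation bounds must be positive and ordered")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")


@dataclass(frozen=True)
class GeneratorConfig:
    length_law: LengthLaw = field(default_factory=LengthLaw)
    category_weights: tuple = DEFAULT_CATEGORY_WEIGHTS
    coupling_strength: float = 0.9
    px_per_mm: float = 8.0
    grid_enabled: bool = True
    grid_mm: float = 10.0
    dish_radius_mm: float = 44.5
    background_style: str = "black"
    image_size: int = 768
    seed: int = 0
    tube_radius_mm: float = 0.7
    instances_range: tuple = (2, 6)
    overlap_tol: float = 0.05

    def __post_init__(self):
        w = np.asarray(self.category_weights, dtype=float)
        if w.shape != (4,) or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(
                "category_weights must be 4 nonnegative numbers summing to 1"
            )
        if self.px_per_mm <= 0:
            raise ValueError("px_per_mm must be positive")
        if not (0 <= self.coupling_strength < 1):
            raise ValueError("coupling_strength must lie in [0, 1)")
        if self.background_style not in ("black", "white", "wood"):
            raise ValueError(f"unknown background {self.background_style!r}")

    @staticmethod
    def tiny(**overrides) -> "GeneratorConfig":
        """Desk-scale preset: small images, coarse scale, thicker tubes."""
        base = GeneratorConfig(px_per_mm=2.0, image_size=192,
                               tube_radius_mm=1.3, instances_range=(1, 4))
        return replace(base, **overrides) if overrides else base


@dataclass(frozen=True)
class RadicleSpec:
    """Sampled ground-truth description of one radicle before rendering."""

    length_mm: float
    n_dev: int
    anchor: tuple  # (x, y) mm relative to dish center, y down
    heading: float  # initial growth direction, rad

    def __post_init__(self):
        if self.n_dev < 0:
            raise ValueError("n_dev must be nonnegative")


# ---------------------------------------------------------------------------
# spec sampling
# ---------------------------------------------------------------------------

def _sample_lengths(law: LengthLaw, n: int, rng: np.random.Generator):
    """Inverse-CDF sampling; returns (lengths_mm, latent standard-normal score).

    The latent score is the truncated quantile mapped through the normal
    inverse CDF; it is an exactly monotone function of the sampled length and
    drives the rank coupling with the curvature category.
    """
    if law.sigma == 0.0:
        val = float(np.clip(math.exp(law.mu), law.lo_mm, law.hi_mm))
        # no length variation -> no coupling signal available
        return np.full(n, val), rng.standard_normal(n)
    a = (math.log(law.lo_mm) - law.mu) / law.sigma
    b = (math.log(law.hi_mm) - law.mu) / law.sigma
    q = rng.uniform(0.0, 1.0, size=n)
    u = ndtr(a) + q * (ndtr(b) - ndtr(a))
    lengths = np.exp(law.mu + law.sigma * ndtri(u))
    latent = ndtri(np.clip(q, 1e-12, 1 - 1e-12))
    return lengths, latent


def _categories_from_latent(latent, weights, coupling, rng):
    """Threshold a Gaussian copula of the length score into 4 categories.

    ``y = c*latent + sqrt(1-c^2)*noise`` is standard normal marginally, so
    thresholds at the normal quantiles of the cumulative weights reproduce
    the marginal category frequencies exactly while the rank coupling with
    length is controlled by ``c``.
    """
    noise = rng.standard_normal(latent.shape)
    y = coupling * latent + math.sqrt(1.0 - coupling**2) * noise
    cuts = ndtri(np.cumsum(np.asarray(weights)[:-1]))
    return np.searchsorted(cuts, y, side="right")


def sample_radicle_specs(cfg: GeneratorConfig, n: int,
                         rng: np.random.Generator) -> list[RadicleSpec]:
    """Draw ``n`` radicle specs (length, category, placement) from ``cfg``."""
    lengths, latent = _sample_lengths(cfg.length_law, n, rng)
    cats = _categories_from_latent(latent, cfg.category_weights,
                                   cfg.coupling_strength, rng)
    n_dev = np.where(cats == 3, 3, cats)  # category ">2" realized as 3
    radii = cfg.dish_radius_mm * 0.55 * np.sqrt(rng.uniform(0, 1, size=n))
    phis = rng.uniform(0, 2 * np.pi, size=n)
    heads = rng.uniform(0, 2 * np.pi, size=n)
    return [
        RadicleSpec(float(L), int(d),
                    (float(r * np.cos(p)), float(r * np.sin(p))), float(h))
        for L, d, r, p, h in zip(lengths, n_dev, radii, phis, heads)
    ]


def sample_radicle_spec(cfg: GeneratorConfig,
                        rng: np.random.Generator) -> RadicleSpec:
    return sample_radicle_specs(cfg, 1, rng)[0]


# ---------------------------------------------------------------------------
# centerline construction
# ---------------------------------------------------------------------------

@dataclass
class Centerline3D:
    """Smooth 3-D centerline: cubic splines over a normalized parameter.

    The planar part is built at unit speed and scaled by ``planar_length_mm``;
    the lift profile is an analytic sum of Gaussian bumps evaluated through
    the same spline machinery.
    """

    spline_x: CubicSpline
    spline_y: CubicSpline
    spline_z: CubicSpline
    planar_length_mm: float
    bump_centers: np.ndarray
    bump_heights: np.ndarray
    bump_widths: np.ndarray

    def points(self, n: int = 1025) -> np.ndarray:
        """(n, 3) points sampled uniformly in parameter, mm units."""
        t = np.linspace(0.0, 1.0, n)
        return np.stack(
            [self.spline_x(t), self.spline_y(t), self.spline_z(t)], axis=1
        )

    def derivative_norm(self, t):
        dx = self.spline_x(t, 1)
        dy = self.spline_y(t, 1)
        dz = self.spline_z(t, 1)
        return np.sqrt(dx * dx + dy * dy + dz * dz)


def _lift_profile(n_dev: int, length_mm: float, rng: np.random.Generator):
    """Bump centers/heights/widths giving exactly ``n_dev`` visible maxima."""
    if n_dev == 0:
        return np.empty(0), np.empty(0), np.empty(0)
    lo, hi = 0.22, 0.92
    spacing = (hi - lo) / n_dev
    centers = lo + (np.arange(n_dev) + 0.5) * spacing
    centers = centers + rng.uniform(-0.18, 0.18, size=n_dev) * spacing
    heights = rng.uniform(1.8, 3.5, size=n_dev)
    # keep the total lift variation well below the arc length so a planar
    # component always remains (short radicles with many bumps)
    budget = 0.45 * length_mm
    total = 2.0 * heights.sum()
    if total > budget:
        heights *= budget / total
    heights = np.maximum(heights, 1.5 * Z_VISIBLE_MM)
    widths = spacing * rng.uniform(0.12, 0.18, size=n_dev)
    return centers, heights, widths


def _lift_eval(t, centers, heights, widths):
    t = np.asarray(t, dtype=float)
    z = np.zeros_like(t)
    for c, h, w in zip(centers, heights, widths):
        z += h * np.exp(-0.5 * ((t - c) / w) ** 2)
    return z


def _planar_unit_shape(length_mm, heading, dish_radius_mm, rng, knots=257):
    """Unit-length planar curve from a smooth random curvature profile.

    Total turning is scaled so long radicles curl enough to remain inside
    the dish; the sign of the dominant curl is random.
    """
    t = np.linspace(0.0, 1.0, knots)
    turn_min = length_mm / (0.8 * dish_radius_mm)
    total_turn = rng.uniform(turn_min + 0.3, turn_min + 2.2)
    sign = rng.choice([-1.0, 1.0])
    k_knots = np.linspace(0, 1, 7)
    kappa = sign * total_turn * (1.0 + 0.5 * rng.standard_normal(7))
    kappa_t = CubicSpline(k_knots, kappa)(t)
    theta = heading + np.concatenate(
        [[0.0], np.cumsum(0.5 * (kappa_t[1:] + kappa_t[:-1]) * np.diff(t))]
    )
    dx = np.cos(theta)
    dy = np.sin(theta)
    x = np.concatenate([[0.0], np.cumsum(0.5 * (dx[1:] + dx[:-1]) * np.diff(t))])
    y = np.concatenate([[0.0], np.cumsum(0.5 * (dy[1:] + dy[:-1]) * np.diff(t))])
    # renormalize to exact unit speed overall
    seg = np.hypot(np.diff(x), np.diff(y)).sum()
    return t, x / seg, y / seg


class GeometryError(RuntimeError):
    """Raised when no in-dish centerline could be constructed."""


def build_centerline(spec: RadicleSpec, rng: np.random.Generator,
                     dish_radius_mm: float = 44.5,
                     max_retries: int = 60) -> Centerline3D:
    """Construct a smooth 3-D centerline matching ``spec``.

    The planar scale is solved so the 3-D arc length equals
    ``spec.length_mm`` (well within 0.5%); construction retries with fresh
    draws when the curve would exit the dish or bump maxima merge.
    """
    from scipy.optimize import brentq

    margin = 2.0
    for attempt in range(max_retries):
        centers, heights, widths = _lift_profile(spec.n_dev, spec.length_mm, rng)
        t, ux, uy = _planar_unit_shape(
            spec.length_mm, spec.heading + attempt * 0.37, dish_radius_mm, rng
        )
        zk = _lift_eval(t, centers, heights, widths)
        dz = np.gradient(zk, t)

        def arc_of(lp):
            return np.trapezoid(np.sqrt(lp**2 + dz**2), t)

        if spec.n_dev == 0:
            lp = spec.length_mm  # planar: 3-D and planar lengths coincide
        else:
            if arc_of(1e-6) >= spec.length_mm:
                continue  # lift alone exceeds the target; redraw bumps
            lp = brentq(lambda s: arc_of(s) - spec.length_mm, 1e-6,
                        spec.length_mm * (1.0 + 1e-9), xtol=1e-10)
        px = spec.anchor[0] + lp * ux
        py = spec.anchor[1] + lp * uy
        if np.max(np.hypot(px, py)) > dish_radius_mm - margin:
            continue
        cl = Centerline3D(
            CubicSpline(t, px), CubicSpline(t, py), CubicSpline(t, zk),
            planar_length_mm=float(lp), bump_centers=centers,
            bump_heights=heights, bump_widths=widths,
        )
        if count_deviation_points(cl) == spec.n_dev:
            return cl
    raise GeometryError(
        f"could not place a {spec.length_mm:.1f} mm radicle inside the dish "
        f"after {max_retries} attempts"
    )


def arc_length(c: Centerline3D) -> float:
    """3-D arc length (mm) by adaptive quadrature of the speed."""
    probe = c.points(9)
    if not np.all(np.isfinite(probe)):
        raise ValueError("centerline has non-finite control points")
    val = quad(c.derivative_norm, 0.0, 1.0, limit=200, full_output=True)[0]
    return float(val)


def projected_length(c: Centerline3D) -> float:
    """Arc length (mm) of the planar (top-down) projection."""
    def speed2d(t):
        dx = c.spline_x(t, 1)
        dy = c.spline_y(t, 1)
        return np.sqrt(dx * dx + dy * dy)

    val = quad(speed2d, 0.0, 1.0, limit=200, full_output=True)[0]
    return float(val)


def count_deviation_points(c: Centerline3D, n_samples: int = 4097,
                           threshold_mm: float = Z_VISIBLE_MM) -> int:
    """Strict local maxima of the lift profile at or above the threshold."""
    t = np.linspace(0.0, 1.0, n_samples)
    z = np.asarray(c.spline_z(t))
    interior = (z[1:-1] > z[:-2]) & (z[1:-1] > z[2:])
    return int(np.sum(interior & (z[1:-1] >= threshold_mm)))


# ---------------------------------------------------------------------------
# scene rendering
# ---------------------------------------------------------------------------

@dataclass
class AnnotatedScene:
    image: np.ndarray  # (H, W, 3) uint8
    masks: list  # per-instance bool (H, W)
    boxes: np.ndarray  # (K, 4) [x1, y1, x2, y2), pixels
    lengths_mm: np.ndarray
    lengths_px: np.ndarray
    n_dev: np.ndarray
    grid_pitch_px: float
    seed: int
    centerlines: list = field(default_factory=list)


def _background(cfg: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    h = w = cfg.image_size
    if cfg.background_style == "black":
        base = np.array([30.0, 30.0, 32.0])
        img = base + rng.normal(0, 4.0, size=(h, w, 3))
    elif cfg.background_style == "white":
        base = np.array([230.0, 230.0, 226.0])
        img = base + rng.normal(0, 4.0, size=(h, w, 3))
    else:  # wood: low-frequency grain
        coarse = rng.normal(0, 1.0, size=(h // 16 + 2, w // 16 + 2))
        yy, xx = np.mgrid[0:h, 0:w]
        grain = coarse[yy // 16, xx // 16] * 12.0
        img = np.stack(
            [165.0 + grain, 125.0 + grain * 0.8, 82.0 + grain * 0.6], axis=-1
        )
        img += rng.normal(0, 3.0, size=(h, w, 3))
    if cfg.grid_enabled:
        pitch = cfg.px_per_mm * cfg.grid_mm
        center = cfg.image_size / 2.0
        line = np.array([110.0, 120.0, 140.0])
        kmax = int(center / pitch) + 1
        for k in range(-kmax, kmax + 1):
            pos = int(round(center + k * pitch))
            if 0 <= pos < w:
                img[:, pos] = 0.6 * img[:, pos] + 0.4 * line
            if 0 <= pos < h:
                img[pos, :] = 0.6 * img[pos, :] + 0.4 * line
    return img


def _draw_dish(img: np.ndarray, cfg: GeneratorConfig) -> None:
    h, w, _ = img.shape
    c = cfg.image_size / 2.0
    rr = cfg.dish_radius_mm * cfg.px_per_mm
    yy, xx = np.mgrid[0:h, 0:w]
    d = np.hypot(xx - c + 0.5, yy - c + 0.5)
    ring = np.clip(1.0 - np.abs(d - rr) / 2.0, 0, 1)[..., None]
    img *= 1.0 - 0.35 * ring
    img += 0.35 * ring * np.array([190.0, 195.0, 200.0])


def _render_instance(img, cfg, centerline, rng):
    """Anti-aliased tapering tube along the projected centerline.

    Returns (mask, alpha).  Lift is encoded visually: apparent width and
    brightness both increase with height above the dish (a closer object
    looks slightly larger and catches more light), so the 2-D image carries
    a cue for the 3-D shape.
    """
    h, w, _ = img.shape
    c = cfg.image_size / 2.0
    pts3 = centerline.points(2049)
    seg = np.hypot(*np.diff(pts3[:, :2], axis=0).T)
    total_px = seg.sum() * cfg.px_per_mm
    n_dense = max(int(total_px / 0.3), 64)
    t = np.linspace(0, 1, n_dense)
    x = centerline.spline_x(t) * cfg.px_per_mm + c
    y = centerline.spline_y(t) * cfg.px_per_mm + c
    z = np.asarray(centerline.spline_z(t))
    taper = 1.0 - 0.65 * t
    r_px = cfg.tube_radius_mm * cfg.px_per_mm * taper * (1.0 + 0.04 * z)

    pad = int(np.ceil(r_px.max())) + 3
    x0 = max(int(np.floor(x.min())) - pad, 0)
    x1 = min(int(np.ceil(x.max())) + pad, w - 1)
    y0 = max(int(np.floor(y.min())) - pad, 0)
    y1 = min(int(np.ceil(y.max())) + pad, h - 1)
    yy, xx = np.mgrid[y0:y1 + 1, x0:x1 + 1]
    tree = cKDTree(np.stack([x, y], axis=1))
    dist, idx = tree.query(
        np.stack([xx.ravel() + 0.0, yy.ravel() + 0.0], axis=1), k=1
    )
    alpha_win = np.clip(r_px[idx] + 0.5 - dist, 0.0, 1.0).reshape(yy.shape)

    alpha = np.zeros((h, w))
    alpha[y0:y1 + 1, x0:x1 + 1] = alpha_win
    tint = rng.uniform(-10, 10)
    color = np.array([228.0 + tint, 222.0 + tint, 200.0 + tint])
    bright = np.ones((h, w))
    bright[y0:y1 + 1, x0:x1 + 1] = np.clip(
        1.0 + 0.05 * z[idx].reshape(yy.shape), 1.0, 1.35
    )
    a3 = alpha[..., None]
    img *= 1.0 - a3
    img += a3 * np.clip(color * bright[..., None], 0, 255)
    mask = alpha > 0.5
    return mask, alpha


def _draw_seed_body(img, cfg, spec, rng):
    """Small elliptic seed (samara kernel) at the radicle anchor."""
    h, w, _ = img.shape
    c = cfg.image_size / 2.0
    cx = spec.anchor[0] * cfg.px_per_mm + c
    cy = spec.anchor[1] * cfg.px_per_mm + c
    a = 3.2 * cfg.px_per_mm
    b = 2.2 * cfg.px_per_mm
    ang = spec.heading + np.pi
    # shift the body behind the growth direction
    cx += 0.6 * a * np.cos(ang)
    cy += 0.6 * a * np.sin(ang)
    pad = int(np.ceil(a)) + 2
    x0, x1 = max(int(cx) - pad, 0), min(int(cx) + pad, w - 1)
    y0, y1 = max(int(cy) - pad, 0), min(int(cy) + pad, h - 1)
    if x1 <= x0 or y1 <= y0:
        return
    yy, xx = np.mgrid[y0:y1 + 1, x0:x1 + 1]
    u = (xx - cx) * np.cos(ang) + (yy - cy) * np.sin(ang)
    v = -(xx - cx) * np.sin(ang) + (yy - cy) * np.cos(ang)
    d = (u / a) ** 2 + (v / b) ** 2
    aa = np.clip((1.0 - d) * 4.0, 0, 1)[..., None]
    color = np.array([150.0, 118.0, 82.0]) + rng.uniform(-8, 8)
    img[y0:y1 + 1, x0:x1 + 1] *= 1.0 - aa
    img[y0:y1 + 1, x0:x1 + 1] += aa * color


def _tight_box(mask: np.ndarray) -> np.ndarray:
    ys, xs = np.nonzero(mask)
    return np.array([xs.min(), ys.min(), xs.max() + 1, ys.max() + 1],
                    dtype=float)


def render_scene(specs: list[RadicleSpec], cfg: GeneratorConfig,
                 rng: np.random.Generator, seed: int = 0) -> AnnotatedScene:
    """Render specs into an annotated image; overlaps are rejection-resampled."""
    img = _background(cfg, rng)
    _draw_dish(img, cfg)
    occupancy = np.zeros((cfg.image_size, cfg.image_size), dtype=bool)
    masks, boxes, centerlines, kept_specs = [], [], [], []
    for spec in specs:
        placed = None
        for attempt in range(40):
            cl = build_centerline(spec, rng, cfg.dish_radius_mm)
            pts = cl.points(257)[:, :2] * cfg.px_per_mm + cfg.image_size / 2.0
            # quick occupancy probe along the curve before rendering
            ij = np.clip(np.round(pts).astype(int), 0, cfg.image_size - 1)
            frac = occupancy[ij[:, 1], ij[:, 0]].mean()
            if frac <= cfg.overlap_tol:
                placed = cl
                break
            spec = replace(
                spec,
                anchor=tuple(
                    rng.uniform(-0.5, 0.5, 2) * cfg.dish_radius_mm
                ),
                heading=float(rng.uniform(0, 2 * np.pi)),
            )
        if placed is None:
            raise GeometryError("could not place instance without overlap")
        _draw_seed_body(img, cfg, spec, rng)
        mask, _ = _render_instance(img, cfg, placed, rng)
        if not mask.any():
            raise GeometryError("rendered instance produced an empty mask")
        occupancy |= mask
        masks.append(mask)
        boxes.append(_tight_box(mask))
        centerlines.append(placed)
        kept_specs.append(spec)

    pitch = cfg.px_per_mm * cfg.grid_mm
    lengths_mm = np.array([s.length_mm for s in kept_specs])
    lengths_px = mm_to_px(lengths_mm, pitch, cfg.grid_mm)
    image = np.clip(img, 0, 255).astype(np.uint8)
    return AnnotatedScene(
        image=image, masks=masks,
        boxes=np.array(boxes).reshape(-1, 4),
        lengths_mm=lengths_mm, lengths_px=lengths_px,
        n_dev=np.array([s.n_dev for s in kept_specs], dtype=int),
        grid_pitch_px=float(pitch), seed=seed, centerlines=centerlines,
    )


def generate_scene(cfg: GeneratorConfig, seed: int,
                   n_instances: int | None = None) -> AnnotatedScene:
    """One reproducible scene: all randomness flows from (cfg.seed, seed)."""
    rng = np.random.default_rng([cfg.seed, seed])
    if n_instances is None:
        lo, hi = cfg.instances_range
        n_instances = int(rng.integers(lo, hi + 1))
    specs = sample_radicle_specs(cfg, n_instances, rng)
    return render_scene(specs, cfg, rng, seed=seed)


def generate_dataset(cfg: GeneratorConfig, n_images: int, out_dir) -> dict:
    """Write a dataset (PNGs + COCO-dialect JSON + CSV + manifest) to disk."""
    from . import cocoio

    return cocoio.write_generated_dataset(cfg, n_images, out_dir)
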