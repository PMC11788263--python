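"""Synthetic radiograph phantoms with exact ground-truth decompositions.

Scenes are built additively: a smooth low-frequency background with two
elliptical lung fields, raised-cosine tubular "bones" with known upper /
lower edge polylines and centerlines, optional thin crossing corruptor
lines, and optional Gaussian noise.  Noise and corruptors are assigned to
the soft-tissue component so that ``cxr == soft + bone`` holds exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree
from skimage.draw import line as draw_line

from ribsep.edge_lists import CATEGORIES, BonePair, EdgeList


class ConfigurationError(ValueError):
    """Raised for invalid phantom configurations."""


@dataclass(frozen=True)
class PhantomConfig:
    shape: tuple[int, int] = (128, 128)
    n_anterior: int = 2
    n_posterior: int = 2
    n_clavicle: int = 1
    bone_peak: float = 0.3
    bone_halfwidth: float = 5.0
    background_scale: float = 24.0
    n_corruptors: int = 0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 2 or self.shape[0] < 64 or self.shape[1] < 64:
            raise ConfigurationError("shape must be at least (64, 64)")
        if not 0 < self.bone_peak <= 1:
            raise ConfigurationError("bone_peak must be in (0, 1]")
        if min(self.n_anterior, self.n_posterior, self.n_clavicle, self.n_corruptors) < 0:
            raise ConfigurationError("counts must be non-negative")
        if self.bone_halfwidth < 2:
            raise ConfigurationError("bone_halfwidth must be >= 2")
        if self.background_scale <= 0:
            raise ConfigurationError("background_scale must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")

    @property
    def n_bones(self) -> int:
        return self.n_anterior + self.n_posterior + self.n_clavicle


@dataclass
class PhantomScene:
    cxr: np.ndarray
    bone: np.ndarray
    soft: np.ndarray
    edge_masks: dict[str, np.ndarray]
    pairs: list[BonePair]
    lung_mask: np.ndarray
    corruptor_mask: np.ndarray
    config: PhantomConfig = field(default=None)  # type: ignore[assignment]

    @property
    def edge_lists(self) -> list[EdgeList]:
        out = []
        for p in self.pairs:
            out.extend([p.upper, p.lower])
        return out


def lung_dimming(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Two elliptical lung fields: (dimming image, binary lung mask)."""
    rows, cols = shape
    rr, cc = np.mgrid[0:rows, 0:cols].astype(float)
    mask = np.zeros(shape, dtype=bool)
    for cx in (0.28, 0.72):
        e = ((rr - 0.52 * rows) / (0.38 * rows)) ** 2 + (
            (cc - cx * cols) / (0.22 * cols)
        ) ** 2
        mask |= e <= 1.0
    # dimming transition kept low-frequency: the suppression model assumes
    # the background varies slowly at the scale of a bone cross-section
    dim = gaussian_filter(mask.astype(float), 8.0) * 0.15
    return dim, mask


def generate_background(config: PhantomConfig) -> tuple[np.ndarray, np.ndarray]:
    """Smooth seeded low-frequency field in [0, 0.8] plus a lung mask.

    The textured part is white noise low-passed at ``background_scale``
    pixels and scaled analytically (not data-adaptively) so that the field
    approaches a spatial constant as the scale grows.
    """
    rng = np.random.default_rng(config.seed)
    rows, cols = config.shape
    noise = rng.standard_normal((rows, cols))
    s = config.background_scale
    smooth = gaussian_filter(noise, s, mode="reflect")
    # white noise filtered by a 2-D Gaussian of sd s has std 1/(2*sqrt(pi)*s);
    # beyond ~image size the reflect boundary breaks that law, so the
    # amplitude compensation is capped there (the field then tends to a
    # spatial constant instead of blowing up)
    eff = min(s, min(config.shape) / 4.0)
    amp = 0.04 * (2.0 * np.sqrt(np.pi) * eff)
    field = 0.55 + amp * smooth
    dim, mask = lung_dimming(config.shape)
    field = np.clip(field - dim, 0.0, 0.8)
    return field, mask


def generate_bone(
    curve_control_points: np.ndarray,
    halfwidth: float,
    peak: float,
    shape: tuple[int, int],
) -> tuple[np.ndarray, EdgeList, EdgeList, EdgeList]:
    """Raised-cosine tube along a smooth near-horizontal centerline.

    Intensity is ``peak * 0.5 * (1 + cos(pi * d / halfwidth))`` at
    perpendicular distance ``d`` from the centerline, zero for
    ``d >= halfwidth``; support is clipped to the strict band between the
    +-halfwidth offset curves.  Returns (image, upper, lower, centerline)
    with one point per integer centerline column, ordered by column.
    """
    if halfwidth < 2:
        raise ValueError("halfwidth must be >= 2")
    rows, cols = shape
    cp = np.asarray(curve_control_points, dtype=float)
    if cp.ndim != 2 or cp.shape[1] != 2 or len(cp) < 2:
        raise ValueError("need >= 2 control points of (row, col)")
    if (cp[:, 0].min() < 0 or cp[:, 0].max() > rows - 1
            or cp[:, 1].min() < 0 or cp[:, 1].max() > cols - 1):
        warnings.warn("bone control points exit the image; clipping")
        cp[:, 0] = np.clip(cp[:, 0], 0, rows - 1)
        cp[:, 1] = np.clip(cp[:, 1], 0, cols - 1)

    order = np.argsort(cp[:, 1])
    cp = cp[order]
    if len(np.unique(cp[:, 1])) < len(cp):
        raise ValueError("control point columns must be distinct (near-horizontal bone)")

    c0, c1 = cp[0, 1], cp[-1, 1]
    if len(cp) >= 3:
        spline = CubicSpline(cp[:, 1], cp[:, 0], bc_type="natural")
        row_of = lambda c: spline(c)  # noqa: E731
        drow_of = lambda c: spline(c, 1)  # noqa: E731
    else:
        slope = (cp[1, 0] - cp[0, 0]) / (cp[1, 1] - cp[0, 1])
        row_of = lambda c: cp[0, 0] + slope * (np.asarray(c) - cp[0, 1])  # noqa: E731
        drow_of = lambda c: np.full_like(np.asarray(c, dtype=float), slope)  # noqa: E731

    # centerline / offset curves at integer columns
    cc = np.arange(np.ceil(c0), np.floor(c1) + 1)
    rr = np.asarray(row_of(cc), dtype=float)
    dr = np.asarray(drow_of(cc), dtype=float)
    # unit tangent (dr, 1)/norm ; normal (-1, dr)/norm points to smaller rows
    tn = np.sqrt(1.0 + dr**2)
    n_r, n_c = -1.0 / tn, dr / tn
    upper_pts = np.stack([rr + halfwidth * n_r, cc + halfwidth * n_c], axis=1)
    lower_pts = np.stack([rr - halfwidth * n_r, cc - halfwidth * n_c], axis=1)
    center_pts = np.stack([rr, cc], axis=1)
    for pts in (upper_pts, lower_pts, center_pts):
        np.clip(pts[:, 0], 0, rows - 1, out=pts[:, 0])
        np.clip(pts[:, 1], 0, cols - 1, out=pts[:, 1])

    image = np.zeros(shape, dtype=float)
    if peak > 0:
        fine_c = np.arange(c0, c1 + 0.05, 0.1)
        fine = np.stack([row_of(fine_c), fine_c], axis=1)
        tree = cKDTree(fine)
        r_lo = max(int(np.floor(rr.min() - halfwidth - 2)), 0)
        r_hi = min(int(np.ceil(rr.max() + halfwidth + 2)), rows - 1)
        # support restricted to columns covered by BOTH offset curves, so
        # the bone stays strictly inside the region its edge lists enclose
        c_lo = max(int(np.ceil(max(c0, upper_pts[0, 1], lower_pts[0, 1]))), 0)
        c_hi = min(int(np.floor(min(c1, upper_pts[-1, 1], lower_pts[-1, 1]))), cols - 1)
        pr, pc = np.mgrid[r_lo : r_hi + 1, c_lo : c_hi + 1]
        pix = np.stack([pr.ravel(), pc.ravel()], axis=1).astype(float)
        d, _ = tree.query(pix, workers=-1)
        prof = np.where(
            d < halfwidth, peak * 0.5 * (1.0 + np.cos(np.pi * d / halfwidth)), 0.0
        )
        sub = prof.reshape(pr.shape)
        # enforce support strictly between the offset curves, column-wise
        up_r = np.interp(np.arange(c_lo, c_hi + 1), upper_pts[:, 1], upper_pts[:, 0])
        lo_r = np.interp(np.arange(c_lo, c_hi + 1), lower_pts[:, 1], lower_pts[:, 0])
        rows_sub = np.arange(r_lo, r_hi + 1)[:, None]
        inside = (rows_sub > up_r[None, :]) & (rows_sub < lo_r[None, :])
        image[r_lo : r_hi + 1, c_lo : c_hi + 1] = np.where(inside, sub, 0.0)

    upper = EdgeList(upper_pts, role="upper")
    lower = EdgeList(lower_pts, role="lower")
    centerline = EdgeList(center_pts, role="centerline")
    return image, upper, lower, centerline


def _rasterize_polyline(points: np.ndarray, mask: np.ndarray) -> None:
    pts = np.rint(points).astype(int)
    pts[:, 0] = np.clip(pts[:, 0], 0, mask.shape[0] - 1)
    pts[:, 1] = np.clip(pts[:, 1], 0, mask.shape[1] - 1)
    for a, b in zip(pts[:-1], pts[1:]):
        rr, cc = draw_line(a[0], a[1], b[0], b[1])
        mask[rr, cc] = True


def _bone_layout(config: PhantomConfig, rng: np.random.Generator) -> list[tuple[str, np.ndarray]]:
    """Assign categories and control points: clavicles on top, ribs below."""
    rows, cols = config.shape
    n = config.n_bones
    if n == 0:
        return []
    base_rows = np.linspace(0.20 * rows, 0.82 * rows, n)
    cats = ["clavicle"] * config.n_clavicle
    rib_cats = []
    for i in range(max(config.n_anterior, config.n_posterior)):
        if i < config.n_anterior:
            rib_cats.append("anterior")
        if i < config.n_posterior:
            rib_cats.append("posterior")
    cats.extend(rib_cats)
    layout = []
    for cat, base in zip(cats, base_rows):
        c_pts = np.array([0.12 * cols, 0.38 * cols, 0.62 * cols, 0.88 * cols])
        # gentle sag keeps adjacent bones separated so profile sampling of
        # one bone does not reach into its neighbor
        if cat == "anterior":
            sag = rng.uniform(1.5, 2.5)  # bows downward in the middle
        elif cat == "posterior":
            sag = -rng.uniform(1.5, 2.5)  # bows upward
        else:
            sag = rng.uniform(-1.0, 1.0)
        jitter = rng.uniform(-1.0, 1.0, size=4)
        r_pts = base + jitter + np.array([0.0, sag, sag, 0.0])
        layout.append((cat, np.stack([r_pts, c_pts], axis=1)))
    return layout


def _corruptors(
    config: PhantomConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    rows, cols = config.shape
    img = np.zeros(config.shape, dtype=float)
    for _ in range(config.n_corruptors):
        c = int(rng.uniform(0.2 * cols, 0.8 * cols))
        c2 = int(np.clip(c + rng.uniform(-0.15, 0.15) * cols, 0, cols - 1))
        r0 = int(rng.uniform(0.05 * rows, 0.15 * rows))
        r1 = int(rng.uniform(0.85 * rows, 0.95 * rows))
        rr, cc = draw_line(r0, c, r1, c2)
        img[rr, cc] = 1.0
    img = gaussian_filter(img, 0.7) * 0.45
    return img, img > 0.02


def generate_phantom(config: PhantomConfig) -> PhantomScene:
    """Compose background + bones + corruptors + noise into one scene.

    Additivity is exact: ``soft = background + corruptors + noise`` and
    ``cxr = soft + bone``, so ``cxr - soft - bone == 0`` bitwise.
    """
    rng = np.random.default_rng(config.seed)
    background, lung_mask = generate_background(config)

    bone_total = np.zeros(config.shape, dtype=float)
    pairs: list[BonePair] = []
    edge_masks = {cat: np.zeros(config.shape, dtype=bool) for cat in CATEGORIES}
    for cat, cp in _bone_layout(config, rng):
        img, upper, lower, centerline = generate_bone(
            cp, config.bone_halfwidth, config.bone_peak, config.shape
        )
        bone_total += img
        upper = EdgeList(upper.points, cat, "upper")
        lower = EdgeList(lower.points, cat, "lower")
        centerline = EdgeList(centerline.points, cat, "centerline")
        pairs.append(BonePair(upper, lower, centerline))
        _rasterize_polyline(upper.points, edge_masks[cat])
        _rasterize_polyline(lower.points, edge_masks[cat])

    corr_img, corr_mask = _corruptors(config, rng)
    soft = background + corr_img
    if config.noise_sd > 0:
        soft = soft + rng.normal(0.0, config.noise_sd, size=config.shape)
    # quantize both components to a 2^-24 grid: their float64 sum is then
    # exact, so cxr - soft - bone == 0 bitwise in any evaluation order
    q = 2.0**24
    soft = np.round(soft * q) / q
    bone_total = np.round(bone_total * q) / q
    cxr = soft + bone_total
    return PhantomScene(
        cxr=cxr,
        bone=bone_total,
        soft=soft,
        edge_masks=edge_masks,
        pairs=pairs,
        lung_mask=lung_mask,
        corruptor_mask=corr_mask,
        config=config,
    )
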