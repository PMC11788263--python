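"""Straightening bones into profile images and mapping results back.

Each column of a profile image is an intensity profile sampled along the
local normal of the upper edge, from a fixed number of samples outside
the bone, across the bone to the matched point on the lower edge.  The
pixel correspondence is kept losslessly so profile-domain results can be
scattered back into image space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt, map_coordinates

from ribsep.edge_lists import BonePair, EdgeList


class NoOppositePointError(RuntimeError):
    """No lower-edge point lies within ``max_dist`` of the query point."""


class BoneTooShortError(RuntimeError):
    """Fewer than 5 profile columns could be sampled for a bone."""


@dataclass
class ProfileImage:
    """Straightened bone: axis 0 crosses the bone, axis 1 runs along it."""

    values: np.ndarray
    row_of_upper_edge: int
    row_of_lower_edge: int

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]


@dataclass
class SamplingMap:
    """Continuous (row, col) image coordinate of every profile pixel."""

    rows: np.ndarray  # same shape as the profile values
    cols: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.rows.shape


def tangent_normal(
    edge: EdgeList, index: int, window: int = 5, toward: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Unit tangent and unit normal at ``edge.points[index]``.

    The tangent is the centered finite difference over +-``window`` points
    (one-sided at the ends); the normal is the tangent rotated by 90
    degrees, oriented toward ``toward`` (e.g. a point of the paired lower
    edge) when given.
    """
    pts = edge.points
    n = len(pts)
    if n < 2:
        raise ValueError("edge must have at least 2 points")
    if not 0 <= index < n:
        raise IndexError("index out of range")
    lo = max(0, index - window)
    hi = min(n - 1, index + window)
    v = pts[hi] - pts[lo]
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError("degenerate tangent (coincident points)")
    t = v / norm
    nvec = np.array([-t[1], t[0]])  # 90-degree rotation of (row, col)
    if toward is not None:
        if np.dot(nvec, np.asarray(toward) - pts[index]) < 0:
            nvec = -nvec
    return t, nvec


def find_opposite_point(
    u: np.ndarray, normal: np.ndarray, lower: EdgeList, max_dist: float = 100.0
) -> np.ndarray:
    """Lower-edge point whose offset is most parallel to the normal.

    Minimizes the parallelogram height ``h = |det(normal, l_j - u)|``
    subject to ``|l_j - u| < max_dist``; ties go to the nearer point.
    """
    u = np.asarray(u, dtype=float)
    v = lower.points - u
    dist = np.linalg.norm(v, axis=1)
    ok = dist < max_dist
    if not ok.any():
        raise NoOppositePointError(
            f"no lower-edge point within {max_dist} px of {tuple(u)}"
        )
    h = np.abs(normal[0] * v[:, 1] - normal[1] * v[:, 0])
    h = np.where(ok, h, np.inf)
    # lexicographic argmin on (h, dist)
    best = np.lexsort((dist, h))[0]
    return lower.points[best].copy()


def _bilinear(image: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    rows = np.clip(rows, 0, image.shape[0] - 1)
    cols = np.clip(cols, 0, image.shape[1] - 1)
    return map_coordinates(image, [rows, cols], order=1, mode="nearest")


def _fill_dropped_columns(values: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Linearly interpolate columns whose opposite-point search failed."""
    if valid.all():
        return values
    idx = np.arange(values.shape[1])
    good = idx[valid]
    for r in range(values.shape[0]):
        values[r] = np.interp(idx, good, values[r, valid])
    return values


def sample_profiles(
    image: np.ndarray,
    pair: BonePair,
    n_outer: int = 10,
    n_inner: int = 40,
    max_dist: float = 100.0,
) -> tuple[ProfileImage, SamplingMap]:
    """Straighten one bone into a (n_outer + n_inner) x len(U) profile.

    For each upper-edge point ``u`` with a matched lower point ``l``:
    ``n_inner`` samples run evenly from ``u`` to ``l`` inclusive, and
    ``n_outer`` samples extend beyond ``u`` away from the bone at the same
    step, so the upper edge lands on row ``n_outer`` and the lower edge on
    the last row.  Bilinear interpolation; out-of-bounds samples clamp to
    the border.  Columns without an opposite point are dropped and filled
    by linear interpolation along the bone.
    """
    image = np.asarray(image, dtype=float)
    U = pair.upper.points
    n_cols = len(U)
    n_rows = n_outer + n_inner
    rows_map = np.zeros((n_rows, n_cols))
    cols_map = np.zeros((n_rows, n_cols))
    valid = np.zeros(n_cols, dtype=bool)
    # offsets in units of the u->l segment: inner t in [0, 1], outer t < 0
    step_idx = np.arange(n_rows, dtype=float) - n_outer  # -n_outer .. n_inner-1
    t = step_idx / (n_inner - 1)

    for j, u in enumerate(U):
        try:
            _, nvec = tangent_normal(pair.upper, j, toward=pair.lower.points.mean(axis=0))
            l = find_opposite_point(u, nvec, pair.lower, max_dist=max_dist)
        except (NoOppositePointError, ValueError):
            continue
        seg = l - u
        if np.linalg.norm(seg) == 0:
            continue
        rows_map[:, j] = u[0] + t * seg[0]
        cols_map[:, j] = u[1] + t * seg[1]
        valid[j] = True

    if valid.sum() < 5:
        raise BoneTooShortError(
            f"only {int(valid.sum())} of {n_cols} profile columns are valid"
        )
    if not valid.all():
        warnings.warn(
            f"{int((~valid).sum())} profile columns had no opposite point; interpolated"
        )
        rows_map = _fill_dropped_columns(rows_map, valid)
        cols_map = _fill_dropped_columns(cols_map, valid)

    rows_map = np.clip(rows_map, 0, image.shape[0] - 1)
    cols_map = np.clip(cols_map, 0, image.shape[1] - 1)
    values = _bilinear(image, rows_map, cols_map)
    profile = ProfileImage(values, row_of_upper_edge=n_outer, row_of_lower_edge=n_rows - 1)
    return profile, SamplingMap(rows_map, cols_map)


def sample_centerline_profiles(
    image: np.ndarray, centerline: EdgeList, each_side: int = 10
) -> tuple[ProfileImage, SamplingMap, dict]:
    """Profiles of 2 * each_side + 1 unit-step samples across a centerline.

    Returns the profile, the sampling map, and the row-band bookkeeping:
    the central band (default 11 rows) is treated as the edge and the
    outermost 5 rows on each side as background anchors.
    """
    if len(centerline) < 5:
        raise BoneTooShortError("centerline shorter than 5 points")
    image = np.asarray(image, dtype=float)
    pts = centerline.points
    n_cols = len(pts)
    n_rows = 2 * each_side + 1
    offsets = np.arange(-each_side, each_side + 1, dtype=float)
    rows_map = np.zeros((n_rows, n_cols))
    cols_map = np.zeros((n_rows, n_cols))
    for j in range(n_cols):
        _, nvec = tangent_normal(centerline, j)
        rows_map[:, j] = pts[j, 0] + offsets * nvec[0]
        cols_map[:, j] = pts[j, 1] + offsets * nvec[1]
    rows_map = np.clip(rows_map, 0, image.shape[0] - 1)
    cols_map = np.clip(cols_map, 0, image.shape[1] - 1)
    values = _bilinear(image, rows_map, cols_map)
    half_band = min(5, each_side)
    bands = {
        "edge_rows": (each_side - half_band, each_side + half_band),  # inclusive
        "background_rows": min(5, each_side),  # outermost rows on each side
    }
    profile = ProfileImage(values, row_of_upper_edge=0, row_of_lower_edge=n_rows - 1)
    return profile, SamplingMap(rows_map, cols_map), bands


def reverse_sample(
    profile: ProfileImage, smap: SamplingMap, shape: tuple[int, int]
) -> np.ndarray:
    """Scatter profile values back to image space.

    Each profile value goes to its nearest integer pixel (collisions are
    averaged); in-footprint pixels never hit are filled from their nearest
    assigned pixel; everything outside the sampled footprint stays 0.
    """
    out = np.zeros(shape, dtype=float)
    if profile.values.size == 0:
        return out
    rr = np.rint(smap.rows).astype(int).ravel()
    cc = np.rint(smap.cols).astype(int).ravel()
    rr = np.clip(rr, 0, shape[0] - 1)
    cc = np.clip(cc, 0, shape[1] - 1)
    vals = profile.values.ravel()
    acc = np.zeros(shape, dtype=float)
    cnt = np.zeros(shape, dtype=float)
    np.add.at(acc, (rr, cc), vals)
    np.add.at(cnt, (rr, cc), 1.0)
    assigned = cnt > 0
    out[assigned] = acc[assigned] / cnt[assigned]

    # fill interior holes of the sampled footprint by nearest assigned pixel
    footprint = _footprint_mask(smap, shape)
    holes = footprint & ~assigned
    if holes.any():
        _, (ir, ic) = distance_transform_edt(~assigned, return_indices=True)
        out[holes] = out[ir[holes], ic[holes]]
    return out


def _footprint_mask(smap: SamplingMap, shape: tuple[int, int]) -> np.ndarray:
    """Convex-ish footprint: pixels between consecutive sampled points.

    Marks every integer pixel on the segments between vertically and
    horizontally adjacent sample coordinates, then fills enclosed holes
    morphologically (cheap and adequate for dense sampling maps).
    """
    from scipy.ndimage import binary_closing

    mask = np.zeros(shape, dtype=bool)
    rr = np.rint(smap.rows).astype(int)
    cc = np.rint(smap.cols).astype(int)
    rr = np.clip(rr, 0, shape[0] - 1)
    cc = np.clip(cc, 0, shape[1] - 1)
    mask[rr.ravel(), cc.ravel()] = True
    return binary_closing(mask, np.ones((3, 3)), border_value=0)
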