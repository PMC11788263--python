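"""Ordered bone-edge polylines from binary edge masks.

A skeletonized edge mask is decomposed into ordered point lists by
classifying every skeleton pixel as a free end, connection point or
junction from its 8-neighborhood, walking the curves between terminals,
optionally merging broken fragments, and pairing upper with lower edges
into per-bone structures with a midpoint centerline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

CATEGORIES = ("anterior", "posterior", "clavicle")
ROLES = ("upper", "lower", "centerline")

FREE = 1
CONNECTION = 2
JUNCTION = 3


@dataclass
class EdgeList:
    """Ordered polyline of (row, col) points tracing one bone edge."""

    points: np.ndarray  # (n, 2) float array of (row, col)
    category: str = "anterior"
    role: str = "upper"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array of (row, col)")
        if len(self.points) < 2:
            raise ValueError("an edge list needs at least 2 points")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")

    def __len__(self) -> int:
        return len(self.points)

    def to_dict(self) -> dict:
        return {
            "category": self.category,
            "role": self.role,
            "points": self.points.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EdgeList":
        return cls(np.asarray(d["points"], float), d["category"], d["role"])


@dataclass
class BonePair:
    """Upper and lower edge of one bone plus the midpoint centerline."""

    upper: EdgeList
    lower: EdgeList
    centerline: EdgeList = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.upper.category != self.lower.category:
            raise ValueError("upper and lower edges must share a category")
        if self.centerline is None:
            self.centerline = _midpoint_centerline(self.upper, self.lower)

    @property
    def category(self) -> str:
        return self.upper.category


def _midpoint_centerline(upper: EdgeList, lower: EdgeList) -> EdgeList:
    """Centerline as midpoints of nearest-point correspondences from upper."""
    lo = lower.points
    mids = []
    for p in upper.points:
        j = np.argmin(np.sum((lo - p) ** 2, axis=1))
        mids.append((p + lo[j]) / 2.0)
    return EdgeList(np.asarray(mids), upper.category, "centerline")


def _check_binary(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    vals = np.unique(mask)
    if not np.all(np.isin(vals, (0, 1))) and mask.dtype != bool:
        raise ValueError("input mask must be binary")
    return mask.astype(bool)


_NBR = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


_RING = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


def classify_skeleton_points(skeleton: np.ndarray) -> np.ndarray:
    """Label each positive skeleton pixel as free (1), connection (2) or junction (3).

    The label comes from the 8-neighborhood crossing number (count of
    0 -> 1 transitions walking the neighbor ring): <= 1 transition means a
    free end or isolated pixel, 2 a connection point on a curve, >= 3 a
    junction where branches meet.  The raw positive-neighbor count would
    mislabel the pixels diagonally adjacent to a junction.
    Returns an int array of the skeleton's shape, 0 at background pixels.
    """
    sk = _check_binary(skeleton)
    padded = np.pad(sk, 1)
    h, w = sk.shape
    ring = np.stack(
        [padded[1 + di : 1 + di + h, 1 + dj : 1 + dj + w] for di, dj in _RING]
    ).astype(np.int8)
    nxt = np.roll(ring, -1, axis=0)
    transitions = ((ring == 0) & (nxt == 1)).sum(axis=0)
    labels = np.zeros(sk.shape, dtype=np.int8)
    labels[sk & (transitions <= 1)] = FREE
    labels[sk & (transitions == 2)] = CONNECTION
    labels[sk & (transitions >= 3)] = JUNCTION
    return labels


def _neighbors(p: tuple, positive: set) -> list:
    return [(p[0] + di, p[1] + dj) for di, dj in _NBR if (p[0] + di, p[1] + dj) in positive]


def _orient(points: np.ndarray) -> np.ndarray:
    """Canonical orientation: left-to-right, ties broken top-to-bottom."""
    a, b = points[0], points[-1]
    if (a[1], a[0]) > (b[1], b[0]):
        return points[::-1].copy()
    return points


def trace_edge_lists(skeleton: np.ndarray) -> list[EdgeList]:
    """Trace ordered point lists along a skeletonized binary mask.

    Walks from every free point through connection points, terminating at
    free or junction points; junction pixels are shared between all lists
    that reach them.  A pure cycle with no terminals is opened at its
    topmost-leftmost pixel.  Output is deterministic: lists are sorted by
    topmost-then-leftmost starting point and oriented left-to-right.
    """
    sk = _check_binary(skeleton)
    labels = classify_skeleton_points(sk)
    positive = set(map(tuple, np.argwhere(sk)))
    terminals = {p for p in positive if labels[p] in (FREE, JUNCTION)}

    visited_edges: set = set()  # undirected pixel-pixel steps already used
    lists: list[np.ndarray] = []

    def step_rank(cur: tuple, q: tuple) -> tuple:
        # prefer reaching a terminal, then 4-adjacency, then coordinates —
        # otherwise the walk cuts corners diagonally past junctions
        diagonal = (q[0] != cur[0]) and (q[1] != cur[1])
        return (q not in terminals, diagonal, q)

    def walk(start: tuple) -> None:
        for nxt in sorted(_neighbors(start, positive)):
            if frozenset((start, nxt)) in visited_edges:
                continue
            path = [start]
            prev, cur = start, nxt
            visited_edges.add(frozenset((start, nxt)))
            while True:
                path.append(cur)
                if cur in terminals:
                    break
                options = [
                    q
                    for q in _neighbors(cur, positive)
                    if q != prev and frozenset((cur, q)) not in visited_edges
                ]
                if not options:
                    break
                nxt2 = min(options, key=lambda q: step_rank(cur, q))
                visited_edges.add(frozenset((cur, nxt2)))
                prev, cur = cur, nxt2
            if len(path) >= 2:
                lists.append(np.asarray(path, dtype=float))

    for start in sorted(terminals):
        walk(start)

    # pure cycles have no terminals: open each at its topmost-leftmost pixel
    covered = {tuple(map(int, p)) for arr in lists for p in arr}
    remaining = sorted(positive - covered)
    while remaining:
        start = remaining[0]
        path = [start]
        prev, cur = None, start
        while True:
            options = [
                q
                for q in sorted(_neighbors(cur, positive))
                if q != prev and frozenset((cur, q)) not in visited_edges
            ]
            if not options:
                break
            nxt = options[0]
            visited_edges.add(frozenset((cur, nxt)))
            prev, cur = cur, nxt
            path.append(cur)
            if cur == start:
                break
        if len(path) >= 2:
            lists.append(np.asarray(path, dtype=float))
        covered.update(map(tuple, ((int(r), int(c)) for r, c in path)))
        remaining = sorted(positive - covered)

    # isolated single pixels cannot form a polyline and are dropped
    oriented = [_orient(arr) for arr in lists]
    oriented.sort(key=lambda a: (a[0][0], a[0][1], a[-1][0], a[-1][1]))
    return [EdgeList(arr) for arr in oriented]


def _end_tangent(points: np.ndarray, at_start: bool, k: int = 5) -> np.ndarray:
    if at_start:
        v = points[min(k, len(points) - 1)] - points[0]
    else:
        v = points[-1] - points[-min(k, len(points) - 1) - 1]
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def merge_edge_lists(
    lists: list[EdgeList],
    gap_tol: float = 10.0,
    angle_tol_deg: float = 30.0,
    manual_plan: list[tuple[int, int]] | None = None,
) -> list[EdgeList]:
    """Join fragments that belong to the same bone edge.

    Greedy merge of list pairs whose nearest endpoints lie within
    ``gap_tol`` pixels and whose end tangents differ by less than
    ``angle_tol_deg``; the gap is bridged by linear interpolation and the
    process iterates to a fixpoint.  ``manual_plan`` (pairs of indices
    into the *input* list) reproduces interactive connection: those pairs
    are merged unconditionally first.
    """
    pts = [el.points.copy() for el in lists]
    cats = [el.category for el in lists]
    roles = [el.role for el in lists]

    def joinable(a: np.ndarray, b: np.ndarray) -> tuple | None:
        # try 4 endpoint combinations; return (a_oriented, b_oriented, dist)
        best = None
        for fa in (False, True):
            for fb in (False, True):
                aa = a[::-1] if fa else a
                bb = b[::-1] if fb else b
                d = np.linalg.norm(aa[-1] - bb[0])
                ta = _end_tangent(aa, at_start=False)
                tb = _end_tangent(bb, at_start=True)
                cosang = float(np.clip(np.dot(ta, tb), -1, 1))
                ang = np.degrees(np.arccos(cosang))
                if d <= gap_tol and ang < angle_tol_deg:
                    if best is None or d < best[2]:
                        best = (aa, bb, d)
        return best

    def bridge(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        gap = np.linalg.norm(a[-1] - b[0])
        if gap > 1.5:
            n = int(np.ceil(gap))
            t = np.linspace(0, 1, n + 1)[1:-1]
            fill = a[-1] + t[:, None] * (b[0] - a[-1])
            return np.vstack([a, fill, b])
        return np.vstack([a, b])

    if manual_plan:
        for i, j in manual_plan:
            if pts[i] is None or pts[j] is None:
                continue
            jb = joinable(pts[i], pts[j])
            if jb is None:  # manual merges ignore tolerances: use closest ends
                a, b = pts[i], pts[j]
                combos = [
                    (a[::-1] if fa else a, b[::-1] if fb else b)
                    for fa in (0, 1)
                    for fb in (0, 1)
                ]
                aa, bb = min(combos, key=lambda ab: np.linalg.norm(ab[0][-1] - ab[1][0]))
            else:
                aa, bb = jb[0], jb[1]
            pts[i] = bridge(aa, bb)
            pts[j] = None

    changed = True
    while changed:
        changed = False
        n = len(pts)
        for i in range(n):
            if pts[i] is None:
                continue
            for j in range(i + 1, n):
                if pts[j] is None or cats[i] != cats[j]:
                    continue
                jb = joinable(pts[i], pts[j])
                if jb is not None:
                    pts[i] = bridge(jb[0], jb[1])
                    pts[j] = None
                    changed = True
        pts = [p for p in pts]

    out = []
    for p, c, r in zip(pts, cats, roles):
        if p is not None:
            out.append(EdgeList(_orient(p), c, r))
    out.sort(key=lambda el: (el.points[:, 0].min(), el.points[:, 1].min()))
    return out


def _mean_row_at_overlap(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Column-overlap length and mean rows of a and b over the shared columns."""
    lo = max(a[:, 1].min(), b[:, 1].min())
    hi = min(a[:, 1].max(), b[:, 1].max())
    if hi <= lo:
        return 0.0, np.nan, np.nan
    cols = np.linspace(lo, hi, 32)
    ra = np.interp(cols, a[np.argsort(a[:, 1]), 1], a[np.argsort(a[:, 1]), 0])
    rb = np.interp(cols, b[np.argsort(b[:, 1]), 1], b[np.argsort(b[:, 1]), 0])
    return hi - lo, float(ra.mean()), float(rb.mean())


def pair_upper_lower(lists: list[EdgeList]) -> list[BonePair]:
    """Pair edges of one category into bones (upper = smaller-row side).

    Each edge is matched to the candidate with maximal column-overlap arc
    whose mean row offset is the smallest positive; the centerline is the
    midpoint curve of nearest-point correspondences.  Edges that find no
    partner are excluded with a warning.
    """
    pairs: list[BonePair] = []
    used = set()
    by_cat: dict[str, list[int]] = {}
    for idx, el in enumerate(lists):
        by_cat.setdefault(el.category, []).append(idx)

    for cat, idxs in by_cat.items():
        # sort edges by mean row; adjacent edges pair up
        order = sorted(idxs, key=lambda i: lists[i].points[:, 0].mean())
        for i in order:
            if i in used:
                continue
            best_j, best_key = None, None
            for j in order:
                if j == i or j in used:
                    continue
                ov, ri, rj = _mean_row_at_overlap(lists[i].points, lists[j].points)
                if ov <= 0:
                    continue
                offset = rj - ri
                if offset <= 0:
                    continue
                key = (offset, -ov)
                if best_key is None or key < best_key:
                    best_key, best_j = key, j
            if best_j is None:
                continue
            used.add(i)
            used.add(best_j)
            up = EdgeList(lists[i].points, cat, "upper")
            lo = EdgeList(lists[best_j].points, cat, "lower")
            pairs.append(BonePair(up, lo))
        for i in idxs:
            if i not in used:
                warnings.warn(
                    f"unpaired {cat} edge (mean row "
                    f"{lists[i].points[:, 0].mean():.1f}) excluded"
                )
    pairs.sort(key=lambda p: p.upper.points[:, 0].mean())
    return pairs
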