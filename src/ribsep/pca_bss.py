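"""Bone suppression inside profile images.

Four stages: margin-anchored background filtering, 2-means detection of
corrupted profile columns, PCA reconstruction of the bone signal from the
leading principal components, and moving-average smoothing along the
bone direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from sklearn.cluster import KMeans

from ribsep.profile_geometry import ProfileImage


@dataclass
class BSSConfig:
    smooth_scale: int = 1000  # along-bone smoothing of the background estimate
    margin: int = 3  # samples per side used as background anchors
    var_threshold: float = 0.95
    smooth_kernel: int = 30
    k: int = 2
    seed: int = 0
    background_fit: str = "linear"  # or "quadratic" (edge reprocessing)

    def __post_init__(self) -> None:
        if not 0 < self.var_threshold <= 1:
            raise ValueError("var_threshold must be in (0, 1]")
        if self.margin < 1:
            raise ValueError("margin must be >= 1")
        if self.smooth_kernel < 1:
            raise ValueError("smooth_kernel must be >= 1")


@dataclass
class ProfileDecomposition:
    foreground: ProfileImage
    background: ProfileImage
    labels: np.ndarray  # per column: True = corrupted
    bone_profile: ProfileImage
    r: int
    explained: np.ndarray


def filter_background(
    profile: ProfileImage, config: BSSConfig | None = None
) -> tuple[ProfileImage, ProfileImage]:
    """Split a profile into foreground (bone) and low-frequency background.

    Per column, the background across the profile is the straight line
    between the means of the ``margin`` outermost samples at each end;
    the background image is then smoothed along the bone with a moving
    window of ``min(smooth_scale, n_cols)``.  Foreground + background
    reconstructs the input exactly.
    """
    config = config or BSSConfig()
    v = profile.values
    n_rows, n_cols = v.shape
    m = config.margin
    if n_rows <= 2 * m:
        raise ValueError(f"profile has {n_rows} rows; needs more than {2 * m}")
    rows = np.arange(n_rows, dtype=float)[:, None]
    if config.background_fit == "quadratic":
        # least-squares parabola per column through the two margin bands;
        # captures background curvature across short (edge) profiles, and
        # needs no along-bone smoothing since each fit pools 2*m rows
        band = np.r_[0:m, n_rows - m : n_rows]
        vand = np.vander(band.astype(float), 3)
        coef, *_ = np.linalg.lstsq(vand, v[band], rcond=None)
        background = np.vander(rows[:, 0], 3) @ coef
    else:
        top = v[:m].mean(axis=0)
        bot = v[-m:].mean(axis=0)
        # anchor the line at the centers of the two margin bands
        r_top = (m - 1) / 2.0
        r_bot = n_rows - 1 - (m - 1) / 2.0
        slope = (bot - top) / (r_bot - r_top)
        background = top[None, :] + (rows - r_top) * slope[None, :]
        window = int(min(config.smooth_scale, n_cols))
        if window > 1:
            background = uniform_filter1d(background, size=window, axis=1, mode="nearest")
    foreground = v - background
    mk = lambda a: ProfileImage(a, profile.row_of_upper_edge, profile.row_of_lower_edge)  # noqa: E731
    return mk(foreground), mk(background)


def cluster_profiles(
    foreground: ProfileImage, config: BSSConfig | None = None
) -> tuple[ProfileImage, np.ndarray]:
    """Detect corrupted columns by 2-means and replace them with the mean
    uncorrupted column.

    The majority cluster counts as uncorrupted; on an exact tie, the
    cluster whose centroid is nearer the global median column wins.
    Degenerate inputs (identical columns) are returned unchanged.
    """
    config = config or BSSConfig()
    v = foreground.values
    n_cols = v.shape[1]
    if n_cols < 4:
        raise ValueError("need at least 4 profile columns to cluster")
    X = v.T  # columns are observations
    if np.allclose(X.var(axis=0), 0):
        labels = np.zeros(n_cols, dtype=bool)
        return foreground, labels
    km = KMeans(n_clusters=config.k, n_init=10, random_state=config.seed)
    assign = km.fit_predict(X)
    counts = np.bincount(assign, minlength=config.k)
    if counts[0] != counts[1]:
        good = int(np.argmax(counts))
    else:
        med = np.median(X, axis=0)
        d = [np.linalg.norm(km.cluster_centers_[i] - med) for i in range(config.k)]
        good = int(np.argmin(d))
    corrupted = assign != good
    cleaned = v.copy()
    if corrupted.any() and (~corrupted).any():
        mean_good = v[:, ~corrupted].mean(axis=1)
        cleaned[:, corrupted] = mean_good[:, None]
    out = ProfileImage(cleaned, foreground.row_of_upper_edge, foreground.row_of_lower_edge)
    return out, corrupted


def pca_reconstruct(
    cleaned: ProfileImage, var_threshold: float = 0.95, include_mean: bool = True
) -> tuple[ProfileImage, int, np.ndarray]:
    """Rank-r PCA reconstruction of the bone signal.

    Columns are observations.  ``r`` is the minimal component count whose
    cumulative explained variance reaches ``var_threshold``; the output is
    the mean column plus the rank-r reconstruction.  Zero-variance input
    gives r = 0 and the replicated mean column.  ``include_mean=False``
    omits the mean column, keeping only column-to-column variation (used
    by edge reprocessing, where the mean holds background, not bone).
    """
    v = cleaned.values
    n_rows, n_cols = v.shape
    if n_cols < 2:
        raise ValueError("need at least 2 columns")
    mean_col = v.mean(axis=1, keepdims=True)
    base = mean_col if include_mean else np.zeros_like(mean_col)
    X = v - mean_col
    # SVD of the centered variable-by-observation matrix
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    var = s**2
    total = var.sum()
    if total <= 1e-30:
        recon = np.broadcast_to(base, v.shape).copy()
        out = ProfileImage(recon, cleaned.row_of_upper_edge, cleaned.row_of_lower_edge)
        return out, 0, np.zeros(len(s))
    explained = var / total
    cum = np.cumsum(explained)
    r = int(np.searchsorted(cum, var_threshold - 1e-12) + 1)
    recon = (U[:, :r] * s[:r]) @ Vt[:r] + base
    out = ProfileImage(recon, cleaned.row_of_upper_edge, cleaned.row_of_lower_edge)
    return out, r, explained


def smooth_along_length(bone_profile: ProfileImage, kernel: int = 30) -> ProfileImage:
    """Per-row moving average along the bone with edge replication."""
    if kernel < 1:
        raise ValueError("kernel must be >= 1")
    v = bone_profile.values
    if kernel == 1:
        out = v.copy()
    else:
        out = uniform_filter1d(v, size=kernel, axis=1, mode="nearest")
    return ProfileImage(out, bone_profile.row_of_upper_edge, bone_profile.row_of_lower_edge)


def suppress_profile(
    profile: ProfileImage, config: BSSConfig | None = None, include_mean: bool = True
) -> ProfileDecomposition:
    """Full in-profile pipeline: filter, cluster, PCA, smooth."""
    config = config or BSSConfig()
    foreground, background = filter_background(profile, config)
    cleaned, labels = cluster_profiles(foreground, config)
    bone, r, explained = pca_reconstruct(cleaned, config.var_threshold, include_mean)
    bone = smooth_along_length(bone, config.smooth_kernel)
    return ProfileDecomposition(
        foreground=foreground,
        background=background,
        labels=labels,
        bone_profile=bone,
        r=r,
        explained=explained,
    )
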