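"""Evaluation metrics for bone suppression.

Mean boundary distance between edge sets, Weber contrast and its relative
reduction with automatic bone/soft region derivation, relative mean
absolute bone error, the bone-suppression ratio, and PSNR/SSIM restricted
to the bone region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation, binary_erosion
from scipy.spatial import cKDTree
from skimage.metrics import peak_signal_noise_ratio, structural_similarity


class UndefinedMetricError(ValueError):
    """The metric is undefined for the given inputs (empty region etc.)."""


@dataclass
class RegionMasks:
    omega_b: np.ndarray  # bone region
    omega_s: np.ndarray  # soft-tissue region


@dataclass
class MetricsReport:
    mbd: float | None = None
    wc_i: float | None = None
    wc_is: float | None = None
    rwc: float | None = None
    rmae_b: float | None = None
    bsr: float | None = None
    psnr_s: float | None = None
    ssim_s: float | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def mbd(source: np.ndarray, target: np.ndarray) -> float:
    """Symmetric mean nearest-neighbor Euclidean distance in pixels.

    ``0.5 * (mean_i min_j |s_i - t_j| + mean_j min_i |t_j - s_i|)`` over
    the positive pixels of the two binary masks.
    """
    s = np.argwhere(np.asarray(source).astype(bool))
    t = np.argwhere(np.asarray(target).astype(bool))
    if len(s) == 0 or len(t) == 0:
        raise UndefinedMetricError("mbd requires two non-empty masks")
    d_st, _ = cKDTree(t).query(s, workers=-1)
    d_ts, _ = cKDTree(s).query(t, workers=-1)
    return 0.5 * (float(d_st.mean()) + float(d_ts.mean()))


def derive_regions(predicted_bone: np.ndarray, lung_mask: np.ndarray) -> RegionMasks:
    """Bone and soft-tissue regions from a predicted bone image.

    The bone mask is a 50%-of-maximum intensity threshold; the bone region
    is its 3x3 erosion, and the soft-tissue region is the lung field minus
    the 3x3 dilation of the bone mask.
    """
    bone = np.asarray(predicted_bone, dtype=float)
    if bone.min() < -1e-9:
        raise UndefinedMetricError("predicted bone image must be non-negative")
    peak = bone.max()
    if peak <= 0:
        raise UndefinedMetricError("all-zero bone image: bone region is empty")
    bone_mask = bone >= 0.5 * peak
    k = np.ones((3, 3), dtype=bool)
    omega_b = binary_erosion(bone_mask, structure=k)
    omega_s = np.asarray(lung_mask).astype(bool) & ~binary_dilation(bone_mask, structure=k)
    if not omega_b.any():
        raise UndefinedMetricError("bone region empty after erosion")
    return RegionMasks(omega_b=omega_b, omega_s=omega_s)


def weber_contrast(image: np.ndarray, regions: RegionMasks) -> float:
    """(mean over bone region - mean over soft region) / mean over soft region."""
    img = np.asarray(image, dtype=float)
    if not regions.omega_b.any() or not regions.omega_s.any():
        raise UndefinedMetricError("weber contrast needs non-empty regions")
    mean_b = img[regions.omega_b].mean()
    mean_s = img[regions.omega_s].mean()
    if mean_s == 0:
        raise UndefinedMetricError("soft-region mean is zero")
    return float((mean_b - mean_s) / mean_s)


def rwc(image: np.ndarray, soft_pred: np.ndarray, regions: RegionMasks) -> float:
    """Relative Weber contrast: (WC(I) - WC(I_S)) / WC(I); 1 is ideal."""
    wc_i = weber_contrast(image, regions)
    if wc_i == 0:
        raise UndefinedMetricError("original image has zero Weber contrast")
    wc_is = weber_contrast(soft_pred, regions)
    return float((wc_i - wc_is) / wc_i)


def rmae_b(bone_true: np.ndarray, bone_pred: np.ndarray, omega_b: np.ndarray) -> float:
    """Mean absolute bone error over the bone region, normalized by the
    true bone intensity range over that region."""
    ob = np.asarray(omega_b).astype(bool)
    if not ob.any():
        raise UndefinedMetricError("empty bone region")
    t = np.asarray(bone_true, dtype=float)[ob]
    p = np.asarray(bone_pred, dtype=float)[ob]
    rng = t.max() - t.min()
    if rng <= 0:
        raise UndefinedMetricError("true bone image has zero range over the region")
    return float(np.abs(t - p).mean() / rng)


def bsr(
    soft_true: np.ndarray,
    soft_pred: np.ndarray,
    bone_true: np.ndarray,
    omega_b: np.ndarray,
) -> float:
    """Bone-suppression ratio: 1 - residual error energy / bone energy
    over the bone region; 1 is perfect."""
    ob = np.asarray(omega_b).astype(bool)
    if not ob.any():
        raise UndefinedMetricError("empty bone region")
    bone_energy = float((np.asarray(bone_true, dtype=float)[ob] ** 2).sum())
    if bone_energy <= 0:
        raise UndefinedMetricError("zero bone energy over the region")
    err = np.asarray(soft_pred, dtype=float)[ob] - np.asarray(soft_true, dtype=float)[ob]
    return float(1.0 - (err**2).sum() / bone_energy)


def psnr_ssim_s(
    soft_true: np.ndarray, soft_pred: np.ndarray, omega_b: np.ndarray
) -> tuple[float, float]:
    """PSNR (dB) and SSIM of the predicted soft-tissue image within the
    bone region.

    Computed on the tight bounding box of the region with out-of-region
    pixels of the prediction neutralized to the truth; the data range is
    taken from the true image.  Identical inputs report PSNR +inf.
    """
    ob = np.asarray(omega_b).astype(bool)
    if not ob.any():
        raise UndefinedMetricError("empty bone region")
    rr, cc = np.nonzero(ob)
    sl = (slice(rr.min(), rr.max() + 1), slice(cc.min(), cc.max() + 1))
    t = np.asarray(soft_true, dtype=float)[sl]
    p = np.asarray(soft_pred, dtype=float).copy()
    p[~ob] = np.asarray(soft_true, dtype=float)[~ob]
    p = p[sl]
    rng = t.max() - t.min()
    if rng <= 0:
        rng = 1.0
    if np.array_equal(t, p):
        psnr = float("inf")
    else:
        psnr = float(peak_signal_noise_ratio(t, p, data_range=rng))
    win = min(7, min(t.shape) - (1 - min(t.shape) % 2))
    win = max(win, 3)
    ssim = float(structural_similarity(t, p, data_range=rng, win_size=win))
    return psnr, ssim


def evaluate_decomposition(
    image: np.ndarray,
    soft_true: np.ndarray,
    bone_true: np.ndarray,
    soft_pred: np.ndarray,
    bone_pred: np.ndarray,
    lung_mask: np.ndarray,
) -> MetricsReport:
    """All scalar metrics of one decomposition in a single report."""
    regions = derive_regions(bone_pred if bone_pred.max() > 0 else bone_true, lung_mask)
    wc_i = weber_contrast(image, regions)
    wc_is = weber_contrast(soft_pred, regions)
    psnr, ssim = psnr_ssim_s(soft_true, soft_pred, regions.omega_b)
    return MetricsReport(
        wc_i=wc_i,
        wc_is=wc_is,
        rwc=rwc(image, soft_pred, regions),
        rmae_b=rmae_b(bone_true, bone_pred, regions.omega_b),
        bsr=bsr(soft_true, soft_pred, bone_true, regions.omega_b),
        psnr_s=psnr,
        ssim_s=ssim,
    )
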