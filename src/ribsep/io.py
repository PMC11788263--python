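"""Reading and writing images and edge lists.

PNG (8/16-bit grayscale) is the canonical format; DICOM reading is
available when pydicom is installed.  Images are exchanged as float
arrays in [0, 1], normalized by the stored bit depth.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.transform import resize

from ribsep.edge_lists import EdgeList


class ImageReadError(ValueError):
    pass


def _read_dicom(path: Path) -> np.ndarray:
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImageReadError(
            "reading DICOM requires the optional pydicom dependency "
            "(pip install ribsep[dicom])"
        ) from exc
    ds = pydicom.dcmread(path)
    arr = ds.pixel_array.astype(float)
    bits = int(getattr(ds, "BitsStored", 16))
    arr = arr / (2**bits - 1)
    if getattr(ds, "PhotometricInterpretation", "MONOCHROME2") == "MONOCHROME1":
        arr = 1.0 - arr
    return arr


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale image as float64 in [0, 1].

    PNG intensities are divided by the full range of their bit depth;
    DICOM files honor BitsStored and MONOCHROME1 inversion.  Color images
    are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise ImageReadError(f"no such file: {path}")
    if path.suffix.lower() in (".dcm", ".dicom"):
        return _read_dicom(path)
    arr = iio.imread(path)
    if arr.ndim != 2:
        raise ImageReadError(f"{path} is not a single-channel grayscale image")
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(float) / 65535.0
    return arr.astype(float)


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write a [0, 1] float image as 16-bit grayscale PNG."""
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    iio.imwrite(Path(path), np.round(arr * 65535).astype(np.uint16))


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a binary mask as 8-bit PNG (0 / 255)."""
    iio.imwrite(Path(path), (np.asarray(mask).astype(bool) * 255).astype(np.uint8))


def read_mask(path: str | Path) -> np.ndarray:
    return read_image(path) > 0.5


def resize_to_working(image: np.ndarray, size: int = 512) -> np.ndarray:
    """Bilinear resize to size x size (anti-aliased when downsampling)."""
    if size < 64:
        raise ValueError("working size must be >= 64")
    image = np.asarray(image, dtype=float)
    if image.shape == (size, size):
        return image.copy()
    down = size < max(image.shape)
    return resize(image, (size, size), order=1, anti_aliasing=down, preserve_range=True)


def write_edge_lists(path: str | Path, lists: list[EdgeList]) -> None:
    Path(path).write_text(json.dumps([el.to_dict() for el in lists], indent=1))


def read_edge_lists(path: str | Path) -> list[EdgeList]:
    return [EdgeList.from_dict(d) for d in json.loads(Path(path).read_text())]
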