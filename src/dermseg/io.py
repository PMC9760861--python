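"""Reading and writing images, masks and log setup.

Internal conventions
--------------------
* Images are ``float64`` arrays in ``[0, 1]``, shape ``(H, W, 3)`` for RGB
  and ``(H, W)`` for luminance, row-major with 0-based ``(row, col)``
  coordinates.  Source bit depth is erased on read: 8-bit samples are
  divided by 255, 16-bit by 65535, floats are taken as already normalized.
* Binary masks are boolean ``(H, W)`` arrays; on disk they are
  single-channel 8-bit PNGs with 0 = background and 255 = foreground, and
  round-trip bit-exactly.
* Alpha channels are dropped with a logged warning; dermoscopy alpha
  carries no signal.
"""

from __future__ import annotations

import logging
import sys
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import FormatError, InputError

logger = logging.getLogger("dermseg")

_LEVELS = {"quiet": logging.WARNING, "info": logging.INFO, "debug": logging.DEBUG}


def setup_logging(level: str = "info") -> None:
    """Configure the package logger to write to stderr at *level*
    (one of ``quiet``, ``info``, ``debug``)."""
    if level not in _LEVELS:
        raise InputError(f"unknown log level {level!r}; expected one of {sorted(_LEVELS)}")
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(_LEVELS[level])


def _normalize_samples(arr: np.ndarray, path: Path) -> np.ndarray:
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    if np.issubdtype(arr.dtype, np.floating):
        out = arr.astype(np.float64)
        if not np.all(np.isfinite(out)):
            raise FormatError(f"{path}: non-finite float samples")
        return np.clip(out, 0.0, 1.0)
    raise FormatError(f"{path}: unsupported sample type {arr.dtype}; "
                      "expected 8-bit, 16-bit or float")


def read_image(path) -> np.ndarray:
    """Read a PNG/JPEG/TIFF image as an ``(H, W, 3)`` float array in [0, 1].

    Grayscale images are replicated to three channels; an alpha channel is
    dropped (with a warning).  Raises :class:`InputError` for a missing
    file and :class:`FormatError` for unsupported depth or channel count.
    """
    path = Path(path)
    if not path.is_file():
        raise InputError(f"image file not found: {path}")
    try:
        arr = np.asarray(iio.imread(path))
    except Exception as exc:  # plugins raise OSError/ValueError/RuntimeError
        raise FormatError(f"{path}: cannot decode image ({exc})") from exc
    if arr.ndim == 2:
        arr = arr[:, :, None]
    if arr.ndim != 3:
        raise FormatError(f"{path}: expected a 2-D image, got array of shape {arr.shape}")
    n_chan = arr.shape[2]
    if n_chan == 4:
        logger.warning("%s: dropping alpha channel", path)
        arr = arr[:, :, :3]
    elif n_chan == 2:  # gray + alpha
        logger.warning("%s: dropping alpha channel", path)
        arr = arr[:, :, :1]
    elif n_chan not in (1, 3):
        raise FormatError(f"{path}: unsupported channel count {n_chan}; expected 1, 3 or 4")
    out = _normalize_samples(arr, path)
    if out.shape[2] == 1:
        out = np.repeat(out, 3, axis=2)
    return out


def write_image(img: np.ndarray, path) -> None:
    """Write a float image in [0, 1] (gray or RGB) as an 8-bit PNG/JPEG/TIFF."""
    path = Path(path)
    arr = np.asarray(img, dtype=np.float64)
    q = np.clip(np.round(arr * 255.0), 0, 255).astype(np.uint8)
    try:
        iio.imwrite(path, q)
    except OSError as exc:
        raise InputError(f"cannot write image to {path}: {exc}") from exc


def read_mask(path) -> np.ndarray:
    """Read a single-channel 0/255 PNG mask as a boolean array."""
    path = Path(path)
    if not path.is_file():
        raise InputError(f"mask file not found: {path}")
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    return arr > 0


def write_mask(mask: np.ndarray, path) -> None:
    """Write a boolean mask as a single-channel 8-bit PNG (255 = true).

    ``read_mask(write_mask(m))`` is bit-exact.
    """
    path = Path(path)
    if path.suffix.lower() != ".png":
        raise InputError(f"mask path must end in .png, got {path}")
    mask = np.asarray(mask)
    if mask.dtype != np.bool_:
        raise InputError(f"mask must be boolean, got dtype {mask.dtype}")
    try:
        iio.imwrite(path, np.where(mask, 255, 0).astype(np.uint8))
    except OSError as exc:
        raise InputError(f"cannot write mask to {path}: {exc}") from exc


def validate_image(img: np.ndarray, name: str = "image", min_size: int = 1) -> np.ndarray:
    """Check an RGB image contract: (H, W, 3) floats in [0, 1], finite."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] != 3:
        raise InputError(f"{name}: expected (H, W, 3) array, got shape {img.shape}")
    _check_range(img, name)
    if min(img.shape[:2]) < min_size:
        raise InputError(f"{name}: minimum side is {min_size} px, got {img.shape[:2]}")
    return img


def validate_gray(img: np.ndarray, name: str = "image") -> np.ndarray:
    """Check a luminance image contract: (H, W) floats in [0, 1], finite."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise InputError(f"{name}: expected (H, W) array, got shape {img.shape}")
    _check_range(img, name)
    return img


def _check_range(img: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(img)):
        raise InputError(f"{name}: contains non-finite values")
    if img.min() < 0.0 or img.max() > 1.0:
        raise InputError(f"{name}: values outside [0, 1] "
                         f"(min {img.min():.4g}, max {img.max():.4g})")
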