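"""Luminance extraction, illumination equalization and the adaptive
sigmoidal contrast stretch.

The pipeline works on the CIELAB lightness channel (L*, D65 white,
rescaled to [0, 1]).  Smooth multiplicative brightness variation is
removed by dividing out a Gaussian estimate of the illumination field,
and a per-image logistic stretch centred on an automatically chosen
cutoff (Otsu by default) pushes skin and lesion luminances towards
opposite ends of [0, 1], which is what the downstream region-based
segmentation relies on.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import color
from skimage.filters import threshold_otsu

from .config import EnhanceParams
from .errors import DegenerateInputError
from .io import validate_gray, validate_image

_EPS = 1e-6


def to_luminance(img: np.ndarray) -> np.ndarray:
    """CIELAB L* of an sRGB image, rescaled from [0, 100] to [0, 1]."""
    img = validate_image(img, "img")
    lab = color.rgb2lab(img)
    return np.clip(lab[:, :, 0] / 100.0, 0.0, 1.0)


def equalize_illumination(lum: np.ndarray, p: EnhanceParams = None) -> np.ndarray:
    """Divide out a smooth multiplicative illumination estimate.

    The field B is a Gaussian blur of the luminance with
    std = background_kernel_frac * min(H, W) / 2; the output is
    ``clip(lum * mean(B) / max(B, eps), 0, 1)``, which preserves the
    global mean while flattening smooth brightness trends.  Lesions must
    be smaller than the kernel scale or they are partly treated as
    illumination.
    """
    lum = validate_gray(lum, "lum")
    p = (p or EnhanceParams()).validate()
    if lum.mean() <= 0.0:
        raise DegenerateInputError("equalize_illumination: image mean is zero")
    sigma = p.background_kernel_frac * min(lum.shape) / 2.0
    field = ndimage.gaussian_filter(lum, sigma, mode="reflect")
    out = lum * field.mean() / np.maximum(field, _EPS)
    return np.clip(out, 0.0, 1.0)


def sigmoid_cutoff(lum: np.ndarray, mode: str = "otsu") -> float:
    """Per-image cutoff of the sigmoid: the Otsu threshold of the 256-bin
    histogram, or the midpoint of the two class means at that threshold."""
    lum = validate_gray(lum, "lum")
    if np.ptp(lum) < 1e-12:
        raise DegenerateInputError("adaptive sigmoid: constant image has no two classes")
    t = float(threshold_otsu(lum, nbins=256))
    if mode == "otsu":
        return t
    low, high = lum[lum <= t], lum[lum > t]
    if low.size == 0 or high.size == 0:
        return t
    return float(0.5 * (low.mean() + high.mean()))


def adaptive_sigmoid(lum: np.ndarray, p: EnhanceParams = None) -> np.ndarray:
    """Logistic contrast stretch s(x) = 1 / (1 + exp(-gain * (x - c)))
    around the per-image cutoff c.  Strictly monotone in the input;
    s(c) = 0.5 exactly; for large gain it approaches the hard threshold
    at c."""
    lum = validate_gray(lum, "lum")
    p = (p or EnhanceParams()).validate()
    c = sigmoid_cutoff(lum, p.cutoff_mode)
    # exp argument bounded: gain * |x - c| <= gain, safe for gains < ~700
    return 1.0 / (1.0 + np.exp(-p.sigmoid_gain * (lum - c)))


def enhance(lum: np.ndarray, p: EnhanceParams = None, equalize: bool = True,
            sigmoid: bool = True) -> np.ndarray:
    """Convenience composition: equalization then sigmoid stretch."""
    p = (p or EnhanceParams()).validate()
    out = equalize_illumination(lum, p) if equalize else validate_gray(lum, "lum")
    if sigmoid:
        out = adaptive_sigmoid(out, p)
    return out
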