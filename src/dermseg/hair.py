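"""Hair artifact detection and removal.

Hairs are dark, thin, curvilinear occlusions.  Detection convolves the
inverted luminance with an even-symmetric directional Gabor bank and
takes the maximum response over orientation and wavelength; hysteresis
thresholding plus an elongation filter (component length and
eccentricity) turns the response into a binary hair mask while rejecting
compact structures such as bubbles and gel spots.  Removal is
neighbourhood-based region filling (NBRF): an onion-peel fill where each
masked boundary pixel takes the mean of its already-known 8-neighbours,
cycle after cycle, until the mask is exhausted.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, signal
from skimage import filters as skfilters
from skimage import measure, morphology

from .config import GaborBankParams, HairMaskParams
from .errors import InfeasibleError, InputError
from .io import validate_gray, validate_image

# thresholds on the max-normalized response never drop below these
# floors; quantiles of a response that is zero almost everywhere would
# otherwise select numerical noise
_HI_FLOOR = 0.15
_LO_FLOOR = 0.05


def gabor_kernel_even(wavelength: float, theta: float, sigma: float) -> np.ndarray:
    """Zero-DC even-symmetric (cosine) Gabor kernel.

    The isotropic Gaussian envelope has std ``sigma``; the carrier runs
    along orientation ``theta`` (radians) with the given wavelength.  The
    kernel mean is removed under the envelope weighting so a constant
    image produces an exactly zero response.
    """
    half = max(int(np.ceil(3.0 * sigma)), 1)
    y, x = np.mgrid[-half:half + 1, -half:half + 1]
    xr = x * np.cos(theta) + y * np.sin(theta)
    env = np.exp(-(x * x + y * y) / (2.0 * sigma * sigma))
    k = env * np.cos(2.0 * np.pi * xr / wavelength)
    k -= env * (k.sum() / env.sum())
    return k


def _convolve_reflect(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """FFT convolution with reflective edge handling."""
    ph, pw = kernel.shape[0] // 2, kernel.shape[1] // 2
    padded = np.pad(img, ((ph, ph), (pw, pw)), mode="reflect")
    out = signal.fftconvolve(padded, kernel, mode="same")
    return out[ph:ph + img.shape[0], pw:pw + img.shape[1]]


def gabor_line_response(lum: np.ndarray, bank: GaborBankParams = None) -> np.ndarray:
    """Maximum dark-line response of the directional Gabor bank, in [0, 1].

    The inverted luminance (1 - lum) is convolved with an even Gabor
    kernel for every orientation k*pi/n and wavelength; the pixelwise
    maximum is clipped below at zero and normalized by its own maximum
    (an all-zero map is returned when there is no structure at all).
    """
    lum = validate_gray(lum, "lum")
    bank = (bank or GaborBankParams()).validate()
    inv = 1.0 - lum
    best = np.zeros_like(inv)
    for lam in bank.wavelengths:
        sigma = bank.sigma_ratio * lam
        for k in range(bank.n_orientations):
            theta = k * np.pi / bank.n_orientations
            resp = _convolve_reflect(inv, gabor_kernel_even(lam, theta, sigma))
            np.maximum(best, resp, out=best)
    np.clip(best, 0.0, None, out=best)
    peak = best.max()
    if peak <= 1e-9:  # structure-free image up to convolution roundoff
        return np.zeros_like(best)
    return best / peak


def _lesion_dark_regions(lum: np.ndarray) -> np.ndarray:
    """Lesion-scale dark regions: the Otsu dark class opened with a disc
    of radius 3 (which erases hair-width structures), keeping components
    of at least 1% of the frame.  Thin dark lines produce nothing, only
    large dark blobs qualify."""
    if np.ptp(lum) < 1e-12:
        return np.zeros(lum.shape, dtype=bool)
    t = skfilters.threshold_otsu(lum, nbins=256)
    dark = morphology.opening(lum <= t, morphology.disk(3))
    labels = measure.label(dark, connectivity=2)
    big = np.zeros_like(dark)
    min_area = 0.01 * lum.size
    for region in measure.regionprops(labels):
        if region.area >= min_area:
            big[labels == region.label] = True
    return big


def detect_hairs(lum: np.ndarray, bank: GaborBankParams = None,
                 refine: HairMaskParams = None) -> np.ndarray:
    """Binary hair mask from the Gabor response.

    Hysteresis keeps pixels above the high-quantile response plus any
    pixel above the low quantile 8-connected to a kept pixel; a 3x3
    closing bridges gaps.  A narrow band around the boundary of any
    lesion-scale dark region is excluded (the rim of a lesion is a thin
    curved edge response that would otherwise masquerade as hair and
    tether the hair network to the lesion).  Components then pass a
    shape filter: long enough (``min_length``) and either elongated
    (``min_eccentricity``) or a thin dark web (``max_halfwidth`` /
    ``min_darkness``; crossing hairs merge into one network of low
    overall eccentricity).  Compact blobs (bubbles, gel, lesion cores)
    fail all branches.  Survivors are dilated by ``dilation_radius``.
    """
    lum = validate_gray(lum, "lum")
    bank = (bank or GaborBankParams()).validate()
    refine = (refine or HairMaskParams()).validate()
    resp = gabor_line_response(lum, bank)
    if resp.max() <= 0.0:  # already zeroed for structure-free images
        return np.zeros(lum.shape, dtype=bool)
    hi = max(np.quantile(resp, bank.high_quantile), _HI_FLOOR)
    lo = max(np.quantile(resp, bank.low_quantile), _LO_FLOOR)
    lo = min(lo, hi)
    hyst = skfilters.apply_hysteresis_threshold(resp, lo, hi)
    raw = hyst
    dark_big = _lesion_dark_regions(lum)
    rim_band = None
    if dark_big.any():
        rim_band = (morphology.dilation(dark_big, morphology.disk(3))
                    & ~morphology.erosion(dark_big, morphology.disk(4)))
        raw = hyst & ~rim_band
        rim_dist = ndimage.distance_transform_edt(dark_big)
    else:
        rim_dist = None
    closed = morphology.closing(raw, np.ones((3, 3), bool))
    labels = measure.label(closed, connectivity=2)
    # darkness of each candidate pixel relative to the local background
    background = ndimage.gaussian_filter(lum, 10.0, mode="reflect")
    darkness = background - lum
    halfwidth = ndimage.distance_transform_edt(closed)
    keep = np.zeros_like(closed)
    for region in measure.regionprops(labels):
        if region.axis_major_length < refine.min_length:
            continue
        comp = labels == region.label
        if rim_dist is not None and dark_big[comp].mean() > 0.95:
            # rim-parallel side-lobe ridges hug the lesion boundary at a
            # nearly constant offset; a hair crossing the lesion spans a
            # wide range of rim distances
            if np.std(rim_dist[comp]) < 2.5:
                continue
        elongated = region.eccentricity >= refine.min_eccentricity
        thin_dark_web = (np.quantile(halfwidth[comp], 0.99) <= refine.max_halfwidth
                         and darkness[comp].mean() >= refine.min_darkness)
        if elongated or thin_dark_web:
            keep[comp] = True
    if rim_band is not None and keep.any():
        # hairs continue through the excluded rim band; readmit band
        # pixels of the response that adjoin a kept component so the
        # strokes stay contiguous across the lesion boundary
        keep |= hyst & rim_band & morphology.dilation(keep, morphology.disk(6))
    if refine.dilation_radius > 0:
        keep = morphology.dilation(keep, morphology.disk(refine.dilation_radius))
    return keep


def detect_bright_spots(lum: np.ndarray, refine: HairMaskParams = None) -> np.ndarray:
    """Compact bright artifacts (bubbles, gel glints, specular spots).

    A pixel is a candidate when it exceeds its local background (Gaussian
    blur, sigma 10 px) by ``bubble_contrast`` and sits in the brightest
    1.5% of the frame; components larger than ``bubble_max_area`` or
    without disc-like solidity are rejected as skin structure (the skin
    just outside a dark lesion also has high local contrast, but it is
    neither globally bright nor compact).  Survivors are dilated by
    ``dilation_radius`` so they can be inpainted together with the hair
    mask.
    """
    lum = validate_gray(lum, "lum")
    refine = (refine or HairMaskParams()).validate()
    if np.ptp(lum) < 1e-12:
        return np.zeros(lum.shape, dtype=bool)
    residual = lum - ndimage.gaussian_filter(lum, 10.0, mode="reflect")
    cand = (residual > refine.bubble_contrast) & (lum > np.quantile(lum, 0.985))
    labels = measure.label(cand, connectivity=2)
    keep = np.zeros_like(cand)
    for region in measure.regionprops(labels):
        if region.area <= refine.bubble_max_area and region.solidity >= 0.5:
            keep[labels == region.label] = True
    if refine.dilation_radius > 0 and keep.any():
        keep = morphology.dilation(keep, morphology.disk(refine.dilation_radius))
    return keep


def nbrf_inpaint(img: np.ndarray, hair: np.ndarray) -> np.ndarray:
    """Neighbourhood-based region filling of masked pixels.

    Onion-peel cycles: every masked pixel with at least one unmasked
    8-neighbour is assigned the mean of those neighbours' values from the
    previous cycle (order-independent) and unmasked; repeat until the
    mask is empty.  Unmasked pixels are returned bit-identical; each
    filled value is a convex combination of original neighbourhood
    values.  A mask covering the whole image is infeasible.
    """
    img = validate_image(img, "img")
    hair = np.asarray(hair)
    if hair.shape != img.shape[:2]:
        raise InputError(f"mask shape {hair.shape} does not match image {img.shape[:2]}")
    if hair.dtype != np.bool_:
        raise InputError("hair mask must be boolean")
    if hair.all():
        raise InfeasibleError("cannot inpaint: mask covers the entire image")
    out = img.copy()
    mask = hair.copy()
    kernel = np.ones((3, 3))
    kernel[1, 1] = 0.0
    while mask.any():
        known = ~mask
        counts = ndimage.convolve(known.astype(np.float64), kernel, mode="constant")
        frontier = mask & (counts > 0)
        # a non-full mask always has a frontier, so this terminates
        sums = np.empty_like(out)
        for c in range(3):
            sums[:, :, c] = ndimage.convolve(out[:, :, c] * known, kernel, mode="constant")
        fy, fx = np.nonzero(frontier)
        out[fy, fx, :] = sums[fy, fx, :] / counts[fy, fx, None]
        mask[fy, fx] = False
    return np.clip(out, 0.0, 1.0)


def denoise_8neighbour(img: np.ndarray) -> np.ndarray:
    """3x3 mean filter (centre plus its 8 neighbours), reflective borders,
    applied per channel.  Affine intensity ramps away from the borders
    pass through unchanged."""
    img = validate_image(img, "img")
    out = np.empty_like(img)
    for c in range(3):
        out[:, :, c] = ndimage.uniform_filter(img[:, :, c], size=3, mode="reflect")
    return np.clip(out, 0.0, 1.0)
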