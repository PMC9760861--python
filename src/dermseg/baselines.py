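"""Comparison segmenters: Chan–Vese, geodesic active contour, Otsu
thresholding and two-component Gaussian-mixture (EM) thresholding.

All four share the hybrid module's initialization, stopping rule and
morphological post-processing, so benchmark comparisons isolate the data
term.  The lesion is taken to be the darker class throughout, matching
melanoma appearance and the generator's gray bands.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .config import BaselineParams, LevelSetParams, PostprocessParams
from .errors import DegenerateInputError, NumericalInstabilityError
from .io import validate_gray
from .levelset import (SegmentationResult, _finalize, curvature, dirac,
                       init_phi, postprocess_mask)


def segment_chanvese(lum: np.ndarray, p: BaselineParams = None,
                     post: PostprocessParams = None) -> SegmentationResult:
    """Two-constant Chan–Vese model.

    c1, c2 are the global means of the current inside/outside regions
    (phi > 0 and phi <= 0); phi is updated by
    dt * delta(phi) * (-l1 (I-c1)^2 + l2 (I-c2)^2 + mu * kappa), with the
    same diffusion regularization, stopping and post-processing as the
    hybrid segmenter.  Hard-region means are used because the diffusion
    regularization keeps phi a bounded step profile (|phi| ~ 2), under
    which smooth-Heaviside weighting would mix a fixed fraction of each
    region into the other mean and bias the recovered constants.
    """
    lum = validate_gray(lum, "lum")
    p = (p or BaselineParams()).validate()
    cv = p.cv
    ls = LevelSetParams()  # shared epsilon / diffusion / window bookkeeping
    state = init_phi(lum)
    c1 = c2 = None
    while state.iteration < cv.max_iter and not state.converged:
        phi = state.phi
        old_sign = phi > 0
        h = (phi > 0).astype(np.float64)
        c1 = float((h * lum).sum() / (h.sum() + 1e-10))
        c2 = float(((1 - h) * lum).sum() / ((1 - h).sum() + 1e-10))
        force = ls.force_scale * (cv.lambda1 * (lum - c1) ** 2
                                  - cv.lambda2 * (lum - c2) ** 2)
        phi = phi + cv.dt * dirac(phi, ls.epsilon) * (-force + cv.mu * curvature(phi))
        for _ in range(ls.rd_steps):
            phi = phi + ls.rd_dt * ndimage.laplace(phi, mode="reflect")
        np.clip(phi, -ls.phi_clip, ls.phi_clip, out=phi)
        if not np.all(np.isfinite(phi)):
            raise NumericalInstabilityError("Chan-Vese produced non-finite phi; reduce dt")
        state.phi = phi
        state.iteration += 1
        state.flipped_history.append(float(np.mean((phi > 0) != old_sign)))
        hist = state.flipped_history
        if len(hist) >= ls.tol_window and all(f < cv.tol for f in hist[-ls.tol_window:]):
            state.converged = True
    mask = postprocess_mask(state.phi > 0, post)
    result = SegmentationResult(mask=mask, phi=_finalize(mask, state.phi),
                                iterations=state.iteration, method="chanvese",
                                converged=state.converged)
    result.fitted_means = (c1, c2)
    return result


def segment_gac(lum: np.ndarray, p: BaselineParams = None,
                post: PostprocessParams = None) -> SegmentationResult:
    """Geodesic active contour.

    Edge map g = 1 / (1 + |grad(G_sigma * I)|^2); evolution
    phi_t = g |grad phi| (kappa + balloon) + grad g . grad phi.  With the
    positive-inside convention, balloon < 0 shrinks the initial box onto
    the lesion boundary.
    """
    lum = validate_gray(lum, "lum")
    p = (p or BaselineParams()).validate()
    gp = p.gac
    ls = LevelSetParams()
    smoothed = ndimage.gaussian_filter(lum, gp.edge_sigma, mode="reflect")
    gy, gx = np.gradient(smoothed)
    # gradient scaled to make the edge-stopping term effective on [0,1] images
    grad_sq = (gx * gx + gy * gy) * (4.0 / max(np.hypot(gx, gy).max(), 1e-8)) ** 2
    g = 1.0 / (1.0 + grad_sq)
    ggy, ggx = np.gradient(g)
    state = init_phi(lum)
    while state.iteration < gp.max_iter and not state.converged:
        phi = state.phi
        old_sign = phi > 0
        py, px = np.gradient(phi)
        grad_phi = np.sqrt(px * px + py * py)
        kappa = curvature(phi)
        phi = phi + gp.dt * (g * grad_phi * (kappa + gp.balloon) + ggy * py + ggx * px)
        if not np.all(np.isfinite(phi)):
            raise NumericalInstabilityError("GAC produced non-finite phi; reduce dt")
        state.phi = phi
        state.iteration += 1
        state.flipped_history.append(float(np.mean((phi > 0) != old_sign)))
        hist = state.flipped_history
        if len(hist) >= ls.tol_window and all(f < ls.tol for f in hist[-ls.tol_window:]):
            state.converged = True
    mask = postprocess_mask(state.phi > 0, post)
    return SegmentationResult(mask=mask, phi=_finalize(mask, state.phi),
                              iterations=state.iteration, method="gac",
                              converged=state.converged)


def otsu_threshold_scan(lum: np.ndarray, nbins: int = 256) -> float:
    """Exhaustive between-class-variance scan over histogram bin edges.
    Independent of :func:`skimage.filters.threshold_otsu`; used as a
    cross-check."""
    hist, edges = np.histogram(lum.ravel(), bins=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    total = hist.sum()
    best_t, best_var = centers[0], -1.0
    for i in range(1, nbins):
        w0 = hist[:i].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        m0 = (hist[:i] * centers[:i]).sum() / w0
        m1 = (hist[i:] * centers[i:]).sum() / w1
        var = w0 * w1 * (m0 - m1) ** 2
        if var > best_var:
            best_var, best_t = var, centers[i - 1]
    return float(best_t)


def segment_otsu(lum: np.ndarray, post: PostprocessParams = None) -> SegmentationResult:
    """Global Otsu threshold; the lesion is the class with the lower mean."""
    lum = validate_gray(lum, "lum")
    if np.ptp(lum) < 1e-12:
        raise DegenerateInputError("segment_otsu: constant image")
    t = float(threshold_otsu(lum, nbins=256))
    mask = postprocess_mask(lum <= t, post)
    result = SegmentationResult(mask=mask, phi=None, iterations=0, method="otsu",
                                converged=True)
    result.threshold = t
    return result


def fit_gmm_1d(values: np.ndarray, max_iter: int = 200, tol: float = 1e-6,
               n_init: int = 5, seed: int = 0):
    """EM fit of a two-component univariate Gaussian mixture.

    Runs ``n_init`` k-means-style restarts and keeps the best
    log-likelihood.  Returns (means, stds, weights, responsibility of
    component 0, log-likelihood trace of the winning run).  The trace is
    non-decreasing, the classic EM monotonicity property.
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    if np.ptp(x) < 1e-12:
        raise DegenerateInputError("EM: constant data has no two components")
    rng = np.random.default_rng(seed)
    var_floor = max(1e-6, 1e-4 * np.var(x))
    best = None
    for init in range(n_init):
        if init == 0:
            mu = np.array([np.quantile(x, 0.25), np.quantile(x, 0.75)])
        else:
            mu = rng.choice(x, size=2, replace=False)
        sd = np.full(2, max(np.std(x) / 2, np.sqrt(var_floor)))
        w = np.array([0.5, 0.5])
        trace = []
        converged = False
        for _ in range(max_iter):
            # E step
            log_p = np.empty((x.size, 2))
            for k in range(2):
                log_p[:, k] = (np.log(w[k] + 1e-300)
                               - 0.5 * np.log(2 * np.pi * sd[k] ** 2)
                               - 0.5 * ((x - mu[k]) / sd[k]) ** 2)
            m = log_p.max(axis=1, keepdims=True)
            log_sum = m[:, 0] + np.log(np.exp(log_p - m).sum(axis=1))
            ll = float(log_sum.sum())
            resp = np.exp(log_p - log_sum[:, None])
            if trace and abs(ll - trace[-1]) < tol * abs(trace[-1] + 1e-300):
                trace.append(ll)
                converged = True
                break
            trace.append(ll)
            # M step
            nk = resp.sum(axis=0) + 1e-300
            w = nk / x.size
            mu = (resp * x[:, None]).sum(axis=0) / nk
            var = (resp * (x[:, None] - mu) ** 2).sum(axis=0) / nk
            sd = np.sqrt(np.maximum(var, var_floor))
        if not converged:
            warnings.warn("EM did not converge within max_iter; using best iterate",
                          RuntimeWarning, stacklevel=2)
        if best is None or trace[-1] > best[-1][-1]:
            best = (mu.copy(), sd.copy(), w.copy(), resp[:, 0].copy(), trace)
    if abs(best[0][0] - best[0][1]) < 0.02 * np.ptp(x):
        warnings.warn("EM mixture components are nearly identical; the "
                      "two-class split is unidentifiable", RuntimeWarning,
                      stacklevel=2)
    return best


def segment_em(lum: np.ndarray, p: BaselineParams = None,
               post: PostprocessParams = None) -> SegmentationResult:
    """Two-component Gaussian-mixture thresholding of the luminance
    histogram; each pixel goes to the component with the higher
    posterior, and the lesion is the lower-mean component."""
    lum = validate_gray(lum, "lum")
    p = (p or BaselineParams()).validate()
    mu, sd, w, resp0, trace = fit_gmm_1d(lum, max_iter=p.em.max_iter,
                                         tol=p.em.tol, n_init=p.em.n_init)
    lesion_comp = int(np.argmin(mu))
    resp_lesion = resp0 if lesion_comp == 0 else 1.0 - resp0
    mask = postprocess_mask((resp_lesion > 0.5).reshape(lum.shape), post)
    result = SegmentationResult(mask=mask, phi=None, iterations=len(trace),
                                method="em", converged=True)
    result.mixture_means = tuple(sorted(float(v) for v in mu))
    result.loglik_trace = trace
    return result


_METHODS = {
    "chanvese": segment_chanvese,
    "gac": segment_gac,
    "otsu": lambda lum, p=None, post=None: segment_otsu(lum, post),
    "em": segment_em,
}


def segment_baseline(method: str, lum: np.ndarray, p: BaselineParams = None,
                     post: PostprocessParams = None) -> SegmentationResult:
    """Dispatch a baseline segmenter by name (chanvese, gac, otsu, em)."""
    if method not in _METHODS:
        raise ValueError(f"unknown baseline method {method!r}; "
                         f"expected one of {sorted(_METHODS)}")
    return _METHODS[method](lum, p, post)
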