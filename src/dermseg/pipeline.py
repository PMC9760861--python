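"""End-to-end segmentation pipeline.

Fixed stage order: read -> denoise -> hair detect -> inpaint ->
luminance -> equalize -> sigmoid -> level set -> postprocess.  Any stage
can be disabled in the config; a disabled stage passes its input
through.  All intermediates and per-stage timings are retained on the
returned :class:`PipelineRun` so every number in the result is
re-derivable.  Baseline methods replace only the final segmentation
stage; by convention they consume the plain luminance (no equalization
or sigmoid), which is how they are benchmarked against the hybrid
method.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from . import baselines as bl
from . import enhance as enh
from . import hair as hairmod
from . import levelset as ls
from .config import PipelineConfig
from .errors import DermsegError
from .io import validate_image

METHODS = ("hybrid", "chanvese", "gac", "otsu", "em")


@dataclass
class PipelineRun:
    """All retained stage outputs of one pipeline execution."""
    config: PipelineConfig
    input_image: np.ndarray
    denoised: np.ndarray
    hair_mask: np.ndarray
    bubble_mask: np.ndarray
    inpainted: np.ndarray
    luminance: np.ndarray
    equalized: np.ndarray
    enhanced: np.ndarray
    result: ls.SegmentationResult
    timings: Dict[str, float] = field(default_factory=dict)


def _stage(timings: Dict[str, float], name: str, fn, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        out = fn(*args, **kwargs)
    except DermsegError as exc:
        raise type(exc)(f"[stage {name}] {exc}") from exc
    timings[name] = time.perf_counter() - t0
    return out


def run_pipeline(image: np.ndarray, config: Optional[PipelineConfig] = None,
                 method: str = "hybrid") -> PipelineRun:
    """Run the full pipeline on an RGB image in [0, 1].

    Deterministic given (image, config).  ``method`` selects the final
    segmenter: the hybrid level set consumes the enhanced image, the
    baselines consume the raw luminance of the (hair-cleaned) image.
    """
    config = (config or PipelineConfig()).validate()
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    image = validate_image(image, "image", min_size=64)
    timings: Dict[str, float] = {}

    if config.stages.denoise:
        denoised = _stage(timings, "denoise", hairmod.denoise_8neighbour, image)
    else:
        denoised = image
        timings["denoise"] = 0.0

    if config.stages.hair:
        lum0 = enh.to_luminance(denoised)
        hair_mask = _stage(timings, "hair_detect", hairmod.detect_hairs, lum0,
                           config.gabor, config.hair_mask)
        bubble_mask = _stage(timings, "bubble_detect", hairmod.detect_bright_spots,
                             lum0, config.hair_mask)
        artifact_mask = hair_mask | bubble_mask
        if artifact_mask.all():
            artifact_mask = hair_mask
        inpainted = _stage(timings, "inpaint", hairmod.nbrf_inpaint, denoised,
                           artifact_mask)
    else:
        hair_mask = np.zeros(image.shape[:2], dtype=bool)
        bubble_mask = np.zeros(image.shape[:2], dtype=bool)
        inpainted = denoised
        timings["hair_detect"] = timings["bubble_detect"] = timings["inpaint"] = 0.0

    luminance = _stage(timings, "luminance", enh.to_luminance, inpainted)

    if config.stages.equalize:
        equalized = _stage(timings, "equalize", enh.equalize_illumination,
                           luminance, config.enhance)
    else:
        equalized = luminance
        timings["equalize"] = 0.0

    if config.stages.sigmoid:
        enhanced = _stage(timings, "sigmoid", enh.adaptive_sigmoid,
                          equalized, config.enhance)
    else:
        enhanced = equalized
        timings["sigmoid"] = 0.0

    if method == "hybrid":
        result = _stage(timings, "levelset", ls.segment_hybrid, enhanced,
                        config.levelset, config.postprocess)
    else:
        result = _stage(timings, method, bl.segment_baseline, method,
                        luminance, config.baselines, config.postprocess)

    return PipelineRun(config=config, input_image=image, denoised=denoised,
                       hair_mask=hair_mask, bubble_mask=bubble_mask,
                       inpainted=inpainted, luminance=luminance,
                       equalized=equalized, enhanced=enhanced, result=result,
                       timings=timings)
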