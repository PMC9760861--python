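"""Pipeline configuration: parameter dataclasses and validated YAML loading.

Every stage of the pipeline owns a small dataclass of numeric parameters.
``load_config`` reads a YAML mapping, applies documented defaults for
absent sections/keys, and rejects unknown keys and out-of-range values
with a :class:`ConfigError` naming the offending key.

YAML schema (all sections optional)::

    seed: 0
    stages:                     # enable/disable pipeline stages
      denoise: true
      hair: true
      equalize: true
      sigmoid: true
    hair:
      n_orientations: 12
      wavelengths: [4, 8]
      sigma_ratio: 0.5
      high_quantile: 0.93
      low_quantile: 0.75
      min_length: 15
      min_eccentricity: 0.9
      max_halfwidth: 7
      min_darkness: 0.05
      dilation_radius: 1
      bubble_contrast: 0.08
      bubble_max_area: 200
    enhance:
      background_kernel_frac: 0.25
      sigmoid_gain: 10
      cutoff_mode: otsu         # or: midpoint
    levelset:
      lambda1: 1.0
      lambda2: 1.0
      mu: 0.2
      scales: [15, 31]
      scale_weights: null       # null -> equal weights
      global_weight: 0.5        # blend of the global (Chan-Vese) fitting force
      force_scale: 255.0        # gray-level scale of the fitting residuals
      phi_clip: 2.0             # binary-step range of phi
      epsilon: 1.0
      dt: 0.1
      rd_steps: 2
      rd_dt: 0.1
      max_iter: 500
      tol: 1.0e-4
      tol_window: 10
    postprocess:
      closing_radius: 5
      dilation_radius: 1
    baselines:
      cv:  {lambda1: 1.0, lambda2: 1.0, mu: 0.2, dt: 0.1, max_iter: 500, tol: 1.0e-4}
      gac: {edge_sigma: 2.0, balloon: -1.0, dt: 0.25, max_iter: 500}
      em:  {max_iter: 200, tol: 1.0e-6, n_init: 5}
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from .errors import ConfigError


# ---------------------------------------------------------------------------
# stage parameter dataclasses
# ---------------------------------------------------------------------------

@dataclass
class GaborBankParams:
    """Directional Gabor bank for dark-line (hair) detection.

    ``n_orientations`` even-symmetric kernels at angles k*180/n, each at
    every wavelength (pixels); kernel std is ``sigma_ratio * wavelength``.
    The hysteresis thresholds are quantiles of the pooled normalized
    response.
    """
    n_orientations: int = 12
    wavelengths: Sequence[float] = (4.0, 8.0)
    sigma_ratio: float = 0.5
    high_quantile: float = 0.93
    low_quantile: float = 0.75

    def validate(self) -> "GaborBankParams":
        if self.n_orientations < 4:
            raise ConfigError(f"hair.n_orientations must be >= 4, got {self.n_orientations}")
        self.wavelengths = tuple(float(w) for w in _as_seq(self.wavelengths, "hair.wavelengths"))
        if not self.wavelengths or any(w <= 0 for w in self.wavelengths):
            raise ConfigError(f"hair.wavelengths must be positive, got {self.wavelengths}")
        if not 0 < self.sigma_ratio:
            raise ConfigError(f"hair.sigma_ratio must be > 0, got {self.sigma_ratio}")
        for key in ("high_quantile", "low_quantile"):
            v = getattr(self, key)
            if not 0 < v < 1:
                raise ConfigError(f"hair.{key} must be in (0, 1), got {v}")
        if not self.low_quantile < self.high_quantile:
            raise ConfigError("hair.low_quantile must be < hair.high_quantile "
                              f"({self.low_quantile} >= {self.high_quantile})")
        return self


@dataclass
class HairMaskParams:
    """Refinement of the raw hair response into a binary mask.

    A component survives if it is at least ``min_length`` long and either
    elongated (eccentricity >= ``min_eccentricity``) or a thin dark web:
    crossing hairs fuse into a single connected network whose overall
    eccentricity is low, so such networks are recognised by their local
    half-width (99th-percentile distance transform <= ``max_halfwidth``)
    combined
    with being darker than the local background by ``min_darkness``
    (which rejects the bright side-lobe rings that bubbles leave in the
    line response).  Survivors are dilated by ``dilation_radius``.
    """
    min_length: float = 15.0
    min_eccentricity: float = 0.9
    max_halfwidth: float = 7.0
    min_darkness: float = 0.05
    dilation_radius: int = 1
    bubble_contrast: float = 0.08
    bubble_max_area: int = 200

    def validate(self) -> "HairMaskParams":
        if self.min_length < 1:
            raise ConfigError(f"hair.min_length must be >= 1, got {self.min_length}")
        if not 0 <= self.min_eccentricity <= 1:
            raise ConfigError(f"hair.min_eccentricity must be in [0, 1], got {self.min_eccentricity}")
        if self.max_halfwidth <= 0:
            raise ConfigError(f"hair.max_halfwidth must be > 0, got {self.max_halfwidth}")
        if self.min_darkness < 0:
            raise ConfigError(f"hair.min_darkness must be >= 0, got {self.min_darkness}")
        if self.dilation_radius < 0:
            raise ConfigError(f"hair.dilation_radius must be >= 0, got {self.dilation_radius}")
        if self.bubble_contrast <= 0:
            raise ConfigError(f"hair.bubble_contrast must be > 0, got {self.bubble_contrast}")
        if self.bubble_max_area < 1:
            raise ConfigError(f"hair.bubble_max_area must be >= 1, got {self.bubble_max_area}")
        return self


@dataclass
class EnhanceParams:
    """Illumination equalization and adaptive sigmoid contrast.

    ``background_kernel_frac`` sets the Gaussian illumination-estimate
    scale as a fraction of min(H, W); lesions must be smaller than this
    scale.  ``sigmoid_gain`` is the slope of the logistic stretch around
    the per-image cutoff (Otsu threshold or class-mean midpoint).
    """
    background_kernel_frac: float = 0.25
    sigmoid_gain: float = 10.0
    cutoff_mode: str = "otsu"

    def validate(self) -> "EnhanceParams":
        if not 0 < self.background_kernel_frac <= 0.5:
            raise ConfigError("enhance.background_kernel_frac must be in (0, 0.5], "
                              f"got {self.background_kernel_frac}")
        if self.sigmoid_gain <= 0:
            raise ConfigError(f"enhance.sigmoid_gain must be > 0, got {self.sigmoid_gain}")
        if self.cutoff_mode not in ("otsu", "midpoint"):
            raise ConfigError(f"enhance.cutoff_mode must be 'otsu' or 'midpoint', "
                              f"got {self.cutoff_mode!r}")
        return self


@dataclass
class LevelSetParams:
    """Multiscale local-binary-fitting level set with reaction–diffusion
    regularization.

    ``scales`` are odd Gaussian window sizes (pixels) of the local fitting
    means; ``scale_weights`` (normalized to sum 1) weight each scale's
    force.  ``global_weight`` blends in the coarsest member of the same
    binary-fitting family — the global (Chan–Vese) fitting force — which
    supplies the long-range pull that finite windows cannot (a purely
    local force is exactly zero inside any homogeneous region, so the
    initial box would never be expelled from the surrounding skin).
    ``force_scale`` evaluates the fitting residual products on the 0–255
    gray-level scale on which binary-fitting parameter values are
    conventionally stated; ``phi_clip`` keeps phi in the binary-step
    range so the diffusion regularization cannot drift the zero level
    toward the larger-amplitude side.  ``epsilon`` is the width of the
    smooth Heaviside.  Convergence is declared when the fraction of sign
    flips of phi stays below ``tol`` for ``tol_window`` consecutive
    iterations.
    """
    lambda1: float = 1.0
    lambda2: float = 1.0
    mu: float = 0.2
    scales: Sequence[int] = (15, 31)
    scale_weights: Optional[Sequence[float]] = None
    global_weight: float = 0.5
    force_scale: float = 255.0
    phi_clip: float = 2.0
    epsilon: float = 1.0
    dt: float = 0.1
    rd_steps: int = 2
    rd_dt: float = 0.1
    max_iter: int = 500
    tol: float = 1e-4
    tol_window: int = 10

    def validate(self) -> "LevelSetParams":
        for key in ("lambda1", "lambda2", "mu"):
            if getattr(self, key) < 0:
                raise ConfigError(f"levelset.{key} must be >= 0, got {getattr(self, key)}")
        self.scales = tuple(int(s) for s in _as_seq(self.scales, "levelset.scales"))
        if not self.scales or any(s < 3 or s % 2 == 0 for s in self.scales):
            raise ConfigError(f"levelset.scales must be odd and >= 3, got {self.scales}")
        if self.scale_weights is not None:
            w = tuple(float(v) for v in _as_seq(self.scale_weights, "levelset.scale_weights"))
            if len(w) != len(self.scales) or any(v < 0 for v in w) or sum(w) <= 0:
                raise ConfigError("levelset.scale_weights must be non-negative, match "
                                  f"scales in length and have positive sum, got {w}")
            self.scale_weights = tuple(v / sum(w) for v in w)
        if not 0 <= self.global_weight <= 1:
            raise ConfigError(f"levelset.global_weight must be in [0, 1], "
                              f"got {self.global_weight}")
        if self.force_scale <= 0:
            raise ConfigError(f"levelset.force_scale must be > 0, got {self.force_scale}")
        if self.phi_clip <= 0:
            raise ConfigError(f"levelset.phi_clip must be > 0, got {self.phi_clip}")
        if self.epsilon <= 0:
            raise ConfigError(f"levelset.epsilon must be > 0, got {self.epsilon}")
        if self.dt <= 0 or self.rd_dt <= 0:
            raise ConfigError("levelset.dt and levelset.rd_dt must be > 0, "
                              f"got {self.dt}, {self.rd_dt}")
        if self.rd_dt > 0.25:
            raise ConfigError(f"levelset.rd_dt must be <= 0.25 (explicit heat-step "
                              f"stability), got {self.rd_dt}")
        if self.rd_steps < 0:
            raise ConfigError(f"levelset.rd_steps must be >= 0, got {self.rd_steps}")
        if self.max_iter < 1:
            raise ConfigError(f"levelset.max_iter must be >= 1, got {self.max_iter}")
        if self.tol <= 0:
            raise ConfigError(f"levelset.tol must be > 0, got {self.tol}")
        if self.tol_window < 1:
            raise ConfigError(f"levelset.tol_window must be >= 1, got {self.tol_window}")
        return self

    @property
    def weights(self) -> tuple:
        if self.scale_weights is None:
            return tuple(1.0 / len(self.scales) for _ in self.scales)
        return tuple(self.scale_weights)


@dataclass
class PostprocessParams:
    """Morphological clean-up of the raw segmentation: closing,
    hole-filling, largest component, final dilation."""
    closing_radius: int = 5
    dilation_radius: int = 1

    def validate(self) -> "PostprocessParams":
        if self.closing_radius < 0:
            raise ConfigError(f"postprocess.closing_radius must be >= 0, got {self.closing_radius}")
        if self.dilation_radius < 0:
            raise ConfigError(f"postprocess.dilation_radius must be >= 0, got {self.dilation_radius}")
        return self


@dataclass
class ChanVeseParams:
    lambda1: float = 1.0
    lambda2: float = 1.0
    mu: float = 0.2
    dt: float = 0.1
    max_iter: int = 500
    tol: float = 1e-4

    def validate(self) -> "ChanVeseParams":
        if self.dt <= 0 or self.max_iter < 1 or self.tol <= 0:
            raise ConfigError("baselines.cv: dt, max_iter, tol must be positive")
        if self.lambda1 < 0 or self.lambda2 < 0 or self.mu < 0:
            raise ConfigError("baselines.cv: lambda1, lambda2, mu must be >= 0")
        return self


@dataclass
class GacParams:
    """Geodesic active contour.  ``balloon`` > 0 expands the region
    (positive-inside phi), < 0 shrinks it; the default shrinks the
    initial bounding box onto the lesion."""
    edge_sigma: float = 2.0
    balloon: float = -1.0
    dt: float = 0.25
    max_iter: int = 500

    def validate(self) -> "GacParams":
        if self.edge_sigma <= 0:
            raise ConfigError(f"baselines.gac.edge_sigma must be > 0, got {self.edge_sigma}")
        if self.dt <= 0 or self.max_iter < 1:
            raise ConfigError("baselines.gac: dt and max_iter must be positive")
        return self


@dataclass
class EmParams:
    max_iter: int = 200
    tol: float = 1e-6
    n_init: int = 5

    def validate(self) -> "EmParams":
        if self.max_iter < 1 or self.tol <= 0 or self.n_init < 1:
            raise ConfigError("baselines.em: max_iter, tol, n_init must be positive")
        return self


@dataclass
class BaselineParams:
    cv: ChanVeseParams = field(default_factory=ChanVeseParams)
    gac: GacParams = field(default_factory=GacParams)
    em: EmParams = field(default_factory=EmParams)

    def validate(self) -> "BaselineParams":
        self.cv.validate()
        self.gac.validate()
        self.em.validate()
        return self


@dataclass
class StageToggles:
    """Per-stage on/off switches; a disabled stage passes its input through."""
    denoise: bool = True
    hair: bool = True
    equalize: bool = True
    sigmoid: bool = True

    def validate(self) -> "StageToggles":
        for key in ("denoise", "hair", "equalize", "sigmoid"):
            if not isinstance(getattr(self, key), bool):
                raise ConfigError(f"stages.{key} must be boolean")
        return self


@dataclass
class PipelineConfig:
    """Full validated pipeline configuration."""
    stages: StageToggles = field(default_factory=StageToggles)
    gabor: GaborBankParams = field(default_factory=GaborBankParams)
    hair_mask: HairMaskParams = field(default_factory=HairMaskParams)
    enhance: EnhanceParams = field(default_factory=EnhanceParams)
    levelset: LevelSetParams = field(default_factory=LevelSetParams)
    postprocess: PostprocessParams = field(default_factory=PostprocessParams)
    baselines: BaselineParams = field(default_factory=BaselineParams)
    seed: Optional[int] = None

    def validate(self) -> "PipelineConfig":
        self.stages.validate()
        self.gabor.validate()
        self.hair_mask.validate()
        self.enhance.validate()
        self.levelset.validate()
        self.postprocess.validate()
        self.baselines.validate()
        if self.seed is not None and (not isinstance(self.seed, int) or self.seed < 0):
            raise ConfigError(f"seed must be a non-negative integer, got {self.seed!r}")
        return self


# ---------------------------------------------------------------------------
# YAML loading
# ---------------------------------------------------------------------------

def _as_seq(value, key) -> list:
    if isinstance(value, (list, tuple)):
        return list(value)
    raise ConfigError(f"{key} must be a list, got {type(value).__name__}")


def _fill(obj, section: dict, prefix: str):
    """Assign the keys of *section* onto dataclass *obj*, rejecting unknowns."""
    if section is None:
        return obj
    if not isinstance(section, dict):
        raise ConfigError(f"config section {prefix!r} must be a mapping")
    names = {f.name for f in dataclasses.fields(obj)}
    for key, value in section.items():
        if key not in names:
            raise ConfigError(f"unknown config key {prefix}.{key}")
        setattr(obj, key, value)
    return obj


# hair section is flat in YAML but maps onto two dataclasses
_HAIR_BANK_KEYS = {f.name for f in dataclasses.fields(GaborBankParams)}
_HAIR_MASK_KEYS = {f.name for f in dataclasses.fields(HairMaskParams)}


def config_from_dict(data: Optional[dict]) -> PipelineConfig:
    """Build a validated :class:`PipelineConfig` from a (possibly empty)
    nested mapping, applying defaults for everything absent."""
    cfg = PipelineConfig()
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    known = {"stages", "hair", "enhance", "levelset", "postprocess", "baselines", "seed"}
    for key in data:
        if key not in known:
            raise ConfigError(f"unknown config key {key}")
    _fill(cfg.stages, data.get("stages"), "stages")
    hair = data.get("hair") or {}
    if not isinstance(hair, dict):
        raise ConfigError("config section 'hair' must be a mapping")
    for key, value in hair.items():
        if key in _HAIR_BANK_KEYS:
            setattr(cfg.gabor, key, value)
        elif key in _HAIR_MASK_KEYS:
            setattr(cfg.hair_mask, key, value)
        else:
            raise ConfigError(f"unknown config key hair.{key}")
    _fill(cfg.enhance, data.get("enhance"), "enhance")
    _fill(cfg.levelset, data.get("levelset"), "levelset")
    _fill(cfg.postprocess, data.get("postprocess"), "postprocess")
    bl = data.get("baselines") or {}
    if not isinstance(bl, dict):
        raise ConfigError("config section 'baselines' must be a mapping")
    for key in bl:
        if key not in ("cv", "gac", "em"):
            raise ConfigError(f"unknown config key baselines.{key}")
    _fill(cfg.baselines.cv, bl.get("cv"), "baselines.cv")
    _fill(cfg.baselines.gac, bl.get("gac"), "baselines.gac")
    _fill(cfg.baselines.em, bl.get("em"), "baselines.em")
    if "seed" in data:
        cfg.seed = data["seed"]
    return cfg.validate()


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML config file; an empty file yields the
    documented defaults."""
    path = Path(path)
    if not path.is_file():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        try:
            data = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"{path}: invalid YAML ({exc})") from exc
    return config_from_dict(data)
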