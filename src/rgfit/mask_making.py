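"""Robust bad-pixel mask making from calibration frame stacks.

Under a dark field or a near-flat bright field every healthy pixel should
behave alike, so simple per-pixel temporal statistics (deliberately
non-robust, so defects bias them visibly) become feature maps in which bad
pixels stand out.  Each feature map is then modelled robustly in sliding
windows — a constant per window, estimated with FLkOS/MSSE so the defective
pixels themselves cannot distort it — and every pixel gets an abnormality
SNR: its feature value's distance from the window model in units of the
window's robust scale.  Pixels whose |SNR| reaches the threshold on feature
i get bit i set in an 8-bit mask code; 0 means a good pixel.

The feature registry ships the temporal mean and temporal standard
deviation, which between them separate hot pixels (mean offset, positive
mean-SNR), dead pixels (stuck value: extreme negative mean-SNR and
collapsed std) and flickering pixels (inflated std).  Further per-pixel
statistics can be registered by name.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from rgfit.background import BackgroundConfig, DetectorImage, fit_background
from rgfit.model_fitting import FlkosConfig
from rgfit.robust_core import MsseConfig

__all__ = [
    "FrameStack",
    "FeatureMap",
    "BadPixelMask",
    "FEATURE_REGISTRY",
    "register_feature",
    "compute_feature_maps",
    "abnormality_map",
    "make_mask",
]


@dataclass
class FrameStack:
    """A stack of calibration frames (n_frames x rows x cols)."""

    frames: np.ndarray
    acquisition_kind: str = "dark_field"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("frames must be a 3D stack with n_frames >= 2")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames must be finite")
        if self.acquisition_kind not in ("dark_field", "flat_bright_field"):
            raise ValueError(f"unknown acquisition_kind {self.acquisition_kind!r}")


@dataclass
class FeatureMap:
    """A named per-pixel statistic of a frame stack."""

    name: str
    values: np.ndarray


@dataclass
class BadPixelMask:
    """Per-pixel 8-bit defect code: 0 = good, bit i = feature i abnormal."""

    codes: np.ndarray
    feature_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if self.codes.dtype != np.uint8:
            raise ValueError("mask codes must be uint8")

    @property
    def n_bad(self) -> int:
        return int(np.count_nonzero(self.codes))

    def per_feature_counts(self) -> dict[str, int]:
        return {
            name: int(np.count_nonzero(self.codes & (1 << i)))
            for i, name in enumerate(self.feature_names)
        }


def _temporal_std(frames: np.ndarray) -> np.ndarray:
    # explicit two-pass accumulation per frame: much faster than
    # ndarray.std along axis 0 on large stacks (no stack-sized temporaries)
    # and numerically fine for detector-count magnitudes
    mu = frames.mean(axis=0)
    acc = np.zeros_like(mu)
    for frame in frames:
        d = frame - mu
        acc += d * d
    return np.sqrt(acc / frames.shape[0])


FEATURE_REGISTRY: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "temporal_mean": lambda frames: frames.mean(axis=0),
    "temporal_std": _temporal_std,
}

DEFAULT_FEATURES = ("temporal_mean", "temporal_std")


def register_feature(name: str, func: Callable[[np.ndarray], np.ndarray]) -> None:
    """Add a per-pixel statistic (stack -> 2D map) to the registry."""
    FEATURE_REGISTRY[name] = func


def compute_feature_maps(
    stack: FrameStack, features: Sequence[str] = DEFAULT_FEATURES
) -> list[FeatureMap]:
    """Per-pixel statistical feature maps of a calibration stack."""
    maps = []
    for name in features:
        if name not in FEATURE_REGISTRY:
            raise KeyError(f"unknown feature {name!r}; register it first")
        maps.append(FeatureMap(name=name, values=FEATURE_REGISTRY[name](stack.frames)))
    return maps


def abnormality_map(
    feature: FeatureMap,
    win: int = 64,
    flkos_cfg: FlkosConfig | None = None,
    msse_cfg: MsseConfig | None = None,
    valid_mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Per-pixel abnormality SNR of a feature map.

    The feature is modelled as a constant per ``win`` x ``win`` window using
    the robust background machinery (horizontal-plane model); the map is
    ``(value - window model) / window scale`` with the sign preserved, so
    deficient pixels come out negative.  A perfectly uniform window has zero
    scale and zero residuals and yields SNR 0 (set ``minimum_residual`` for
    quantized data).
    """
    if msse_cfg is None:
        msse_cfg = MsseConfig(model_dof=1)
    if flkos_cfg is None:
        flkos_cfg = FlkosConfig(rng_seed=0)
    image = DetectorImage(feature.values, valid_mask)
    cfg = BackgroundConfig(
        win_x=win, win_y=win, num_model_params=1,
        minimum_residual=msse_cfg.minimum_residual,
    )
    maps = fit_background(image, cfg, flkos_cfg, msse_cfg)
    diff = feature.values - maps.mean_map
    scale = np.maximum(maps.scale_map, msse_cfg.minimum_residual)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = diff / scale
    out[(diff == 0) & (scale == 0)] = 0.0
    return out


def make_mask(
    stack: FrameStack,
    features: Sequence[str] = DEFAULT_FEATURES,
    threshold: float = 6.0,
    win: int = 64,
    flkos_cfg: FlkosConfig | None = None,
    msse_cfg: MsseConfig | None = None,
    valid_mask: Optional[np.ndarray] = None,
) -> BadPixelMask:
    """Build an 8-bit bad-pixel mask from a calibration stack.

    For each selected feature i, pixels whose abnormality |SNR| is at or
    above ``threshold`` get bit i set.  At most 8 features fit in the
    8-bit code.
    """
    features = tuple(features)
    if len(features) > 8:
        raise ValueError("at most 8 features fit in an 8-bit mask code")
    maps = compute_feature_maps(stack, features)
    codes = np.zeros(stack.frames.shape[1:], dtype=np.uint8)
    for i, fmap in enumerate(maps):
        snr_map = abnormality_map(fmap, win, flkos_cfg, msse_cfg, valid_mask)
        with np.errstate(invalid="ignore"):
            bad = np.abs(snr_map) >= threshold
        bad &= np.isfinite(snr_map) | np.isinf(snr_map)
        codes[bad] |= np.uint8(1 << i)
    return BadPixelMask(codes=codes, feature_names=features)
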