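"""Per-pixel robust background mean and scale maps for detector images.

The image is tiled with windows; inside each window the background is fitted
robustly — either a tiltable plane (``num_model_params=4``: three plane
parameters plus the noise scale) or a horizontal plane, i.e. a constant
(``num_model_params=1``).  Every pixel covered by a window receives the
model's predicted value and the window's robust scale.  With
``num_strides > 1`` the tiling is repeated at shifted offsets and the
per-pixel values are averaged across the shifted tilings, which smooths the
block artefacts of a single tiling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from rgfit.model_fitting import FlkosConfig, RobustFitResult, fit_plane, fit_value
from rgfit.robust_core import MsseConfig

__all__ = ["DetectorImage", "BackgroundConfig", "BackgroundMaps", "fit_background"]


@dataclass
class DetectorImage:
    """A 2D detector frame with an optional per-pixel validity mask.

    Indexing is 0-based row-major ``(row, col)``.  ``valid_mask`` is True
    for usable pixels; ``None`` means all pixels are usable.
    """

    intensities: np.ndarray
    valid_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be a 2D array")
        if self.valid_mask is not None:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.intensities.shape:
                raise ValueError("mask shape must equal image shape")
        valid = self.mask
        if not np.all(np.isfinite(self.intensities[valid])):
            raise ValueError("valid pixels must be finite")

    @property
    def mask(self) -> np.ndarray:
        if self.valid_mask is None:
            return np.ones(self.intensities.shape, dtype=bool)
        return self.valid_mask

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape


@dataclass(frozen=True)
class BackgroundConfig:
    """Windowing for background estimation.

    ``win_x`` is the window extent along columns, ``win_y`` along rows;
    ``None`` means the full image extent.  ``num_model_params`` selects the
    background model: 4 = tiltable plane (3 parameters) + scale,
    1 = horizontal plane (constant) + scale.  ``num_strides`` repeats the
    tiling at ``round(i * win / num_strides)`` offsets per axis.
    """

    win_x: Optional[int] = None
    win_y: Optional[int] = None
    num_model_params: int = 4
    num_strides: int = 1
    minimum_residual: float = 0.0

    def __post_init__(self) -> None:
        if self.num_model_params not in (1, 4):
            raise ValueError("num_model_params must be 1 or 4")
        if self.num_strides < 1:
            raise ValueError("num_strides must be >= 1")


@dataclass
class BackgroundMaps:
    """Background model value and noise scale per pixel; invalid pixels
    carry NaN."""

    mean_map: np.ndarray
    scale_map: np.ndarray


def _window_starts(extent: int, win: int, offset: int) -> list[int]:
    """Anchor rows/cols of a tiling shifted by ``offset``; a clipped partial
    window covers the leading edge when the offset is nonzero."""
    starts = list(range(offset, extent, win))
    if offset > 0:
        starts.insert(0, 0)
    return starts


def _fit_window(
    vals: np.ndarray,
    rr: np.ndarray,
    cc: np.ndarray,
    config: BackgroundConfig,
    flkos_cfg: FlkosConfig,
    msse_cfg: MsseConfig,
) -> RobustFitResult:
    if config.num_model_params == 4:
        return fit_plane(cc, rr, vals, flkos_cfg, msse_cfg)
    return fit_value(vals, flkos_cfg, msse_cfg)


def _predict(fit: RobustFitResult, rr: np.ndarray, cc: np.ndarray) -> np.ndarray:
    if fit.model.kind == "plane":
        a, b, c = fit.model.params
        return a * cc + b * rr + c
    return np.full(rr.shape, fit.model.params[0])


def fit_background(
    image: DetectorImage | np.ndarray,
    config: BackgroundConfig | None = None,
    flkos_cfg: FlkosConfig | None = None,
    msse_cfg: MsseConfig | None = None,
) -> BackgroundMaps:
    """Estimate per-pixel background mean and noise-scale maps.

    Each window with at least ``k_min + 1`` valid pixels is fitted robustly;
    its pixels receive the model prediction and the window's scale.  Windows
    too sparse to fit borrow the model of the nearest fitted window of the
    same tiling.  Per-pixel values are averaged over the stride-shifted
    tilings.

    Raises
    ------
    ValueError
        If no window anywhere has enough valid pixels, or on an invalid
        ``num_model_params``.
    """
    if not isinstance(image, DetectorImage):
        image = DetectorImage(image)
    if config is None:
        config = BackgroundConfig()
    p = 3 if config.num_model_params == 4 else 1
    if msse_cfg is None:
        msse_cfg = MsseConfig(model_dof=p, minimum_residual=config.minimum_residual)
    if flkos_cfg is None:
        flkos_cfg = FlkosConfig(rng_seed=0)

    rows, cols = image.shape
    win_y = config.win_y if config.win_y is not None else rows
    win_x = config.win_x if config.win_x is not None else cols
    win_y, win_x = min(win_y, rows), min(win_x, cols)
    valid = image.mask
    vals_img = image.intensities
    min_pts = msse_cfg.k_min + 1

    sum_mean = np.zeros((rows, cols))
    sum_scale = np.zeros((rows, cols))
    n_cover = np.zeros((rows, cols), dtype=int)

    any_fitted = False
    for si in range(config.num_strides):
        for sj in range(config.num_strides):
            oy = round(si * win_y / config.num_strides)
            ox = round(sj * win_x / config.num_strides)
            windows = []  # (r0, r1, c0, c1, fit or None)
            for r0 in _window_starts(rows, win_y, oy):
                r1 = min(r0 + win_y, rows)
                if r0 == 0 and oy > 0:
                    r1 = oy
                for c0 in _window_starts(cols, win_x, ox):
                    c1 = min(c0 + win_x, cols)
                    if c0 == 0 and ox > 0:
                        c1 = ox
                    m = valid[r0:r1, c0:c1]
                    fit = None
                    if int(np.count_nonzero(m)) >= min_pts:
                        rr, cc = np.nonzero(m)
                        fit = _fit_window(
                            vals_img[r0:r1, c0:c1][rr, cc],
                            (rr + r0).astype(float),
                            (cc + c0).astype(float),
                            config,
                            flkos_cfg,
                            msse_cfg,
                        )
                        any_fitted = True
                    windows.append((r0, r1, c0, c1, fit))

            fitted = [w for w in windows if w[4] is not None]
            for r0, r1, c0, c1, fit in windows:
                if fit is None:
                    if not fitted:
                        continue
                    yc, xc = (r0 + r1) / 2, (c0 + c1) / 2
                    fit = min(
                        fitted,
                        key=lambda w: ((w[0] + w[1]) / 2 - yc) ** 2
                        + ((w[2] + w[3]) / 2 - xc) ** 2,
                    )[4]
                rr, cc = np.mgrid[r0:r1, c0:c1]
                pred = _predict(fit, rr.astype(float), cc.astype(float))
                sum_mean[r0:r1, c0:c1] += pred
                sum_scale[r0:r1, c0:c1] += fit.sigma
                n_cover[r0:r1, c0:c1] += 1

    if not any_fitted:
        raise ValueError(
            f"no window contains the k_min + 1 = {min_pts} valid pixels "
            "needed for a robust fit; enlarge the window or relax the mask"
        )

    with np.errstate(invalid="ignore", divide="ignore"):
        mean_map = sum_mean / n_cover
        scale_map = sum_scale / n_cover
    mean_map[~valid] = np.nan
    scale_map[~valid] = np.nan
    mean_map[n_cover == 0] = np.nan
    scale_map[n_cover == 0] = np.nan
    return BackgroundMaps(mean_map=mean_map, scale_map=scale_map)
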