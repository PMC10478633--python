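"""Robust geometric model fitting with FLkOS + MSSE.

FLkOS (fast least kth-order statistics) minimizes the worst fitting error of
the true data points without knowing how many there are.  The user supplies a
conservative guess ``likely_ratio``: when the points are sorted by their
distance to the current model estimate, everything up to rank
``k = ceil(likely_ratio * N)`` is presumed to belong to the structure.  Each
iteration least-squares-fits the model to a block of points whose residual
ranks end at k, re-sorts, and repeats; because the sampling is guided by the
ranks rather than random, the fit locks onto the structure and ignores the
outliers beyond rank k.  MSSE then converts the final residuals into a noise
scale and an inlier segmentation.

Supported models: a constant (value) for 1D data, a line ``y = b*x + a`` for
2D and a plane ``z = a*x + b*y + c`` for 3D.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from rgfit.robust_core import MsseConfig, msse

__all__ = [
    "GeometricModel",
    "FlkosConfig",
    "RobustFitResult",
    "flkos_fit",
    "fit_value",
    "fit_line",
    "fit_plane",
    "median_of_fits",
]

_MODEL_DOF = {"value": 1, "line": 2, "plane": 3}


@dataclass(frozen=True)
class GeometricModel:
    """A fitted structural model: value ``a``, line ``b*x + a`` or plane
    ``a*x + b*y + c``.

    ``params`` ordering: value ``(a,)``; line ``(slope, intercept)``;
    plane ``(a, b, c)``.
    """

    kind: str
    params: tuple

    def __post_init__(self) -> None:
        if self.kind not in _MODEL_DOF:
            raise ValueError(f"unknown model kind {self.kind!r}")
        if len(self.params) != _MODEL_DOF[self.kind]:
            raise ValueError(
                f"{self.kind} model needs {_MODEL_DOF[self.kind]} parameters, "
                f"got {len(self.params)}"
            )

    @property
    def dof(self) -> int:
        return _MODEL_DOF[self.kind]

    def predict(self, points: np.ndarray) -> np.ndarray:
        """Predicted response for each point's explanatory coordinates."""
        pts = _as_points(points, self.kind)
        if self.kind == "value":
            return np.full(pts.shape[0], self.params[0])
        if self.kind == "line":
            slope, intercept = self.params
            return slope * pts[:, 0] + intercept
        a, b, c = self.params
        return a * pts[:, 0] + b * pts[:, 1] + c

    def residuals_sq(self, points: np.ndarray) -> np.ndarray:
        """Squared algebraic distance of each point to the model."""
        pts = _as_points(points, self.kind)
        return (pts[:, -1] - self.predict(pts)) ** 2


@dataclass(frozen=True)
class FlkosConfig:
    """FLkOS optimizer settings.

    Parameters
    ----------
    likely_ratio : float
        Fraction of the data presumed to belong to the structure; sets the
        anchor rank k.  Default 0.5 — within any reasonably large detector
        window at least half of the pixels are background.
    certain_ratio : float
        Fraction highly likely to be inliers; sets the size of the sampled
        rank block.  Default 0.3.
    opt_iters : int
        Iteration budget.  Default 12.
    fit2skewed : bool
        When on, ``certain_ratio`` decays linearly to a 0.05 floor over the
        iterations, which concentrates the final fits on a thin residual
        shell and suits unimodal skewed noise (Gaussian convolved with an
        exponential, as produced by Poisson processes plus system noise).
    downsampled_size : int, optional
        Fit on a seeded uniform subsample of this size, then flag all points
        against the fitted model; a speed knob for large vectors.
    model_value_init : sequence of float, optional
        Initial model parameters; when given, the first residual sort uses
        them instead of a random starting subset.
    rng_seed : int, optional
        Seed for all sampling; fixing it makes every fit bit-reproducible.
    """

    likely_ratio: float = 0.5
    certain_ratio: float = 0.3
    opt_iters: int = 12
    fit2skewed: bool = False
    downsampled_size: Optional[int] = None
    model_value_init: Optional[Sequence[float]] = None
    rng_seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0 < self.certain_ratio <= self.likely_ratio <= 1):
            raise ValueError(
                "require 0 < certain_ratio <= likely_ratio <= 1, got "
                f"certain_ratio={self.certain_ratio}, likely_ratio={self.likely_ratio}"
            )
        if self.opt_iters < 1:
            raise ValueError("opt_iters must be >= 1")


@dataclass(frozen=True)
class RobustFitResult:
    """Fitted model, robust noise scale and the induced inlier segmentation.

    ``inlier_flags`` are exactly the points whose absolute residual (after
    the ``minimum_residual`` floor) is within ``threshold = lambda * sigma``.
    """

    model: GeometricModel
    sigma: float
    k_inliers: int
    inlier_flags: np.ndarray
    threshold: float

    @property
    def params(self) -> tuple:
        return self.model.params


def _as_points(points: np.ndarray, kind: str) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if kind == "value":
        if pts.ndim == 1:
            pts = pts[:, None]
    if pts.ndim != 2 or pts.shape[1] != _MODEL_DOF[kind]:
        raise ValueError(
            f"{kind} model expects points of shape (N, {_MODEL_DOF[kind]}) "
            f"(or (N,) for value), got {pts.shape}"
        )
    return pts


def _design(pts: np.ndarray, kind: str) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix and response for ordinary least squares."""
    if kind == "value":
        return np.ones((pts.shape[0], 1)), pts[:, 0]
    if kind == "line":
        return np.column_stack([pts[:, 0], np.ones(pts.shape[0])]), pts[:, 1]
    return np.column_stack([pts[:, 0], pts[:, 1], np.ones(pts.shape[0])]), pts[:, 2]


def _ols_coef(A: np.ndarray, y: np.ndarray) -> np.ndarray:
    # normal equations (p <= 3, so conditioning is not a concern at window
    # scale); fall back to lstsq on a singular subset
    try:
        return np.linalg.solve(A.T @ A, A.T @ y)
    except np.linalg.LinAlgError:
        return np.linalg.lstsq(A, y, rcond=None)[0]


def _ols(pts: np.ndarray, kind: str) -> GeometricModel:
    A, y = _design(pts, kind)
    coef = _ols_coef(A, y)
    return GeometricModel(kind=kind, params=tuple(float(c) for c in coef))


def _check_design_rank(pts: np.ndarray, kind: str) -> None:
    if kind == "value":
        return
    A, _ = _design(pts, kind)
    if np.linalg.matrix_rank(A.T @ A) < A.shape[1]:
        what = "all x identical" if kind == "line" else "collinear (x, y) support"
        raise ValueError(
            f"rank-deficient design for {kind} fit ({what}); "
            "the model parameters are not identifiable"
        )


def _flags_from_threshold(
    r2: np.ndarray, sigma: float, msse_cfg: MsseConfig
) -> tuple[np.ndarray, float]:
    threshold = msse_cfg.lambda_cutoff * sigma
    r_eff = np.sqrt(np.maximum(r2, msse_cfg.minimum_residual**2))
    flags = r_eff <= threshold
    return flags, float(threshold)


def flkos_fit(
    points: np.ndarray,
    kind: str,
    config: FlkosConfig | None = None,
    msse_cfg: MsseConfig | None = None,
) -> RobustFitResult:
    """Robustly fit a value/line/plane to points with FLkOS, then estimate
    the noise scale with MSSE.

    Parameters
    ----------
    points : array of shape (N, m)
        Data points; the last column is the modelled response.  1D arrays
        are accepted for ``kind='value'``.
    kind : {'value', 'line', 'plane'}
        Structural model to fit.
    config, msse_cfg : optional
        Optimizer and scale-estimator settings.

    Returns
    -------
    RobustFitResult

    Raises
    ------
    ValueError
        On too few points or a rank-deficient design (all x identical for a
        line, collinear support for a plane).
    """
    if config is None:
        config = FlkosConfig()
    p = _MODEL_DOF[kind]
    if msse_cfg is None:
        msse_cfg = MsseConfig(model_dof=p)
    elif msse_cfg.model_dof != p:
        msse_cfg = replace(msse_cfg, model_dof=p)

    pts = _as_points(points, kind)
    n = pts.shape[0]
    if n < msse_cfg.k_min + 1:
        raise ValueError(
            f"need at least k_min + 1 = {msse_cfg.k_min + 1} points, got {n}"
        )
    if not np.all(np.isfinite(pts)):
        raise ValueError("points must be finite")
    _check_design_rank(pts, kind)

    rng = np.random.default_rng(config.rng_seed)

    fit_pts = pts
    if config.downsampled_size is not None and config.downsampled_size < n:
        sub = rng.choice(n, size=config.downsampled_size, replace=False)
        fit_pts = pts[np.sort(sub)]

    model = _flkos_optimize(fit_pts, kind, config, rng)

    # The optimizer's own prior says at least certain_ratio*N points are
    # certainly inliers, so the MSSE walk may start there: starting at a
    # tiny k_min on large windows risks a spurious early stop (the scale
    # accumulated from the few smallest residuals is unstable).
    k_start = max(msse_cfg.k_min, min(math.ceil(config.certain_ratio * n), n - 1))
    msse_eff = replace(msse_cfg, k_min=k_start)

    # Two refinement steps bring the estimate from the rank-block fit's
    # variance down to near the efficiency of least squares on the true
    # structure while keeping its robustness:
    # (1) a trimmed fit on the k points nearest the best iterate (k is the
    #     structure-size prior), which recentres the model;
    # (2) a reweighted fit on the points MSSE accepts around the trimmed
    #     model, which uses the whole segmented structure.
    r2 = model.residuals_sq(pts)
    k = min(max(math.ceil(config.likely_ratio * n), p + 1), n)
    nearest = np.argpartition(r2, k - 1)[:k]
    model = _ols(pts[nearest], kind)

    r2 = model.residuals_sq(pts)
    scale = msse(r2, msse_eff)
    flags, _ = _flags_from_threshold(r2, scale.sigma, msse_cfg)
    # in skewed mode the symmetric lambda*sigma band is not a valid
    # acceptance region (it re-admits the heavy tail), so the reweighted
    # step is skipped and the trimmed fit stands
    if not config.fit2skewed and int(np.count_nonzero(flags)) > p:
        model = _ols(pts[flags], kind)
        r2 = model.residuals_sq(pts)
        scale = msse(r2, msse_eff)
    flags, threshold = _flags_from_threshold(r2, scale.sigma, msse_cfg)
    return RobustFitResult(
        model=model,
        sigma=scale.sigma,
        k_inliers=int(np.count_nonzero(flags)),
        inlier_flags=flags,
        threshold=threshold,
    )


def _flkos_optimize(
    pts: np.ndarray, kind: str, config: FlkosConfig, rng: np.random.Generator
) -> GeometricModel:
    n = pts.shape[0]
    p = _MODEL_DOF[kind]
    k = min(max(math.ceil(config.likely_ratio * n), p + 1), n)
    A, y = _design(pts, kind)

    def block_size(it: int) -> int:
        ratio = config.certain_ratio
        if config.fit2skewed and config.opt_iters > 1:
            # linear decay from the starting ratio to a 0.05 floor
            frac = it / (config.opt_iters - 1)
            ratio = ratio + frac * (0.05 - ratio)
        return min(max(p + 1, math.ceil(ratio * n)), k)

    if config.model_value_init is not None:
        init = np.asarray(config.model_value_init, dtype=float)
        order = np.argsort((y - A @ init) ** 2, kind="stable")
        subset = order[k - block_size(0) : k]
    else:
        subset = rng.choice(n, size=block_size(0), replace=False)
        subset = np.sort(subset)

    best_coef: np.ndarray | None = None
    best_kth = np.inf
    seen: set[bytes] = set()
    for it in range(config.opt_iters):
        coef = _ols_coef(A[subset], y[subset])
        r2 = (y - A @ coef) ** 2
        s = block_size(it)
        # only the rank block [k-s, k) and the kth value are needed, so a
        # partial partition replaces a full sort
        kth_spec = [k - 1] if s == k else [k - s, k - 1]
        order = np.argpartition(r2, kth_spec)
        kth = r2[order[k - 1]]
        if kth < best_kth:
            best_kth = kth
            best_coef = coef
        subset = np.sort(order[k - s : k])
        key = subset.tobytes()
        if key in seen:
            break
        seen.add(key)
    assert best_coef is not None
    return GeometricModel(kind=kind, params=tuple(float(c) for c in best_coef))


def fit_value(
    data: np.ndarray,
    config: FlkosConfig | None = None,
    msse_cfg: MsseConfig | None = None,
) -> RobustFitResult:
    """Robust mean and noise scale of a 1D vector contaminated by outliers."""
    return flkos_fit(np.asarray(data, dtype=float), "value", config, msse_cfg)


def fit_line(
    x: np.ndarray,
    y: np.ndarray,
    config: FlkosConfig | None = None,
    msse_cfg: MsseConfig | None = None,
) -> RobustFitResult:
    """Robust line fit ``y = slope*x + intercept``; result params are
    (slope, intercept) and the noise scale is in ``sigma``."""
    pts = np.column_stack([np.asarray(x, float), np.asarray(y, float)])
    return flkos_fit(pts, "line", config, msse_cfg)


def fit_plane(
    x: np.ndarray,
    y: np.ndarray,
    z: np.ndarray,
    config: FlkosConfig | None = None,
    msse_cfg: MsseConfig | None = None,
) -> RobustFitResult:
    """Robust plane fit ``z = a*x + b*y + c``; params are (a, b, c)."""
    pts = np.column_stack(
        [np.asarray(x, float), np.asarray(y, float), np.asarray(z, float)]
    )
    return flkos_fit(pts, "plane", config, msse_cfg)


def median_of_fits(
    data: np.ndarray,
    config: FlkosConfig | None = None,
    msse_cfg: MsseConfig | None = None,
    repeats: int = 3,
) -> RobustFitResult:
    """Repeat :func:`fit_value` with distinct derived seeds and return the
    elementwise median of the fitted parameters and scale.

    The first repeat uses the configured seed unchanged, so ``repeats=1`` is
    identical to a single :func:`fit_value` call.  Flags are recomputed from
    the median model and median scale.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    if config is None:
        config = FlkosConfig()
    if msse_cfg is None:
        msse_cfg = MsseConfig(model_dof=1)

    fits = []
    for i in range(repeats):
        if i == 0:
            cfg_i = config
        else:
            base = config.rng_seed if config.rng_seed is not None else 0
            derived = int(np.random.SeedSequence([base, i]).generate_state(1)[0] % (2**31))
            cfg_i = replace(config, rng_seed=derived)
        fits.append(fit_value(data, cfg_i, msse_cfg))

    params = tuple(
        float(np.median([f.params[j] for f in fits]))
        for j in range(len(fits[0].params))
    )
    sigma = float(np.median([f.sigma for f in fits]))
    model = GeometricModel(kind="value", params=params)
    r2 = model.residuals_sq(np.asarray(data, dtype=float))
    if msse_cfg.model_dof != 1:
        msse_cfg = replace(msse_cfg, model_dof=1)
    flags, threshold = _flags_from_threshold(r2, sigma, msse_cfg)
    return RobustFitResult(
        model=model,
        sigma=sigma,
        k_inliers=int(np.count_nonzero(flags)),
        inlier_flags=flags,
        threshold=threshold,
    )
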