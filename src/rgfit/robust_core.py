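"""Robust scale estimation (MSSE) and the statistical-separability SNR.

MSSE (modified selective statistical estimator) takes the squared fitting
errors of all data points to an already-fitted model and decides how many of
the smallest ones are consistent with a single Gaussian noise process.  The
sorted squared residuals are accumulated one at a time; the walk stops at the
first point whose squared residual exceeds ``lambda_cutoff**2`` times the
variance accumulated so far.  The square root of that variance is the robust
noise scale, and the accepted points are the inliers.

``lambda_cutoff`` is the Gaussian cutoff: more than 95% of a Gaussian lies
within 2 standard deviations of its mean and more than 99% within 4, so
values between 2 and 4 are standard; 3 is the default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MsseConfig", "ScaleEstimate", "msse", "msse_weighted", "snr"]


@dataclass(frozen=True)
class MsseConfig:
    """Parameters of the MSSE stopping rule.

    Parameters
    ----------
    lambda_cutoff : float
        Gaussian cutoff λ; a point is an inlier while its residual is within
        λ times the accumulated scale.  Default 3.0, typical range [2, 4].
    k_min : int
        Minimum number of points accepted unconditionally; the walk over the
        sorted residuals starts here.  Default 12.
    minimum_residual : float
        Floor applied to the absolute residual before squaring.  Zero (the
        default) disables it; a positive value prevents the scale collapsing
        to zero on quantized integer data.
    model_dof : int
        Number of parameters p of the model that produced the residuals
        (1 value, 2 line, 3 plane); used in the k - p variance denominator.
    """

    lambda_cutoff: float = 3.0
    k_min: int = 12
    minimum_residual: float = 0.0
    model_dof: int = 1

    def __post_init__(self) -> None:
        if self.lambda_cutoff <= 0:
            raise ValueError(f"lambda_cutoff must be > 0, got {self.lambda_cutoff}")
        if self.k_min <= self.model_dof:
            raise ValueError(
                f"k_min ({self.k_min}) must exceed model_dof ({self.model_dof})"
            )
        if self.minimum_residual < 0:
            raise ValueError("minimum_residual must be >= 0")


@dataclass(frozen=True)
class ScaleEstimate:
    """Robust noise scale plus the inlier segmentation that produced it."""

    sigma: float
    k_inliers: int
    inlier_flags: np.ndarray  # boolean, original point order

    def __post_init__(self) -> None:
        assert self.k_inliers == int(np.count_nonzero(self.inlier_flags))


def _as_squared_residuals(residuals: np.ndarray) -> np.ndarray:
    r2 = np.asarray(residuals, dtype=float)
    if r2.ndim != 1:
        raise ValueError("residuals must be a 1D vector of squared errors")
    if r2.size < 1:
        raise ValueError("residuals must contain at least one point")
    if np.any(r2 < 0) or not np.all(np.isfinite(r2)):
        raise ValueError("squared residuals must be finite and non-negative")
    return r2


def _msse_core(
    r2_sorted: np.ndarray, weights_sorted: np.ndarray | None, config: MsseConfig
) -> tuple[float, int]:
    """Walk the sorted (optionally weighted) squared residuals.

    Returns (sigma, k_stop) where k_stop is the number of accepted points.
    The weighted variance is normalized so that the estimate is invariant to
    a common rescaling of the weights and reduces bit-exactly to the
    unweighted walk when all weights are 1:

        sigma_k^2 = [sum_{j<=k} w_j r_(j)^2] * (k / sum_{j<=k} w_j) / (k - p)
    """
    n = r2_sorted.size
    p = config.model_dof
    r2e = np.maximum(r2_sorted, config.minimum_residual**2)
    if weights_sorted is None:
        wsum = np.arange(1, n + 1, dtype=float)
        wr2 = np.cumsum(r2e)
    else:
        wsum = np.cumsum(weights_sorted)
        wr2 = np.cumsum(weights_sorted * r2e)

    ks = np.arange(1, n + 1, dtype=float)
    denom = ks - p
    with np.errstate(divide="ignore", invalid="ignore"):
        sig2 = wr2 * (ks / wsum) / denom
    # sum of zero weights can occur only below k_min (guarded by caller)
    sig2 = np.where(wsum > 0, sig2, 0.0)

    lam2 = config.lambda_cutoff**2
    k_min = config.k_min
    # Accept point k+1 while r_(k+1)^2 <= lambda^2 sigma_k^2.  sigma_k
    # depends only on the first k sorted residuals, so the stopping index is
    # the first violation and the scan vectorizes.
    viol = r2e[k_min:] > lam2 * sig2[k_min - 1 : n - 1]
    k = k_min + int(np.argmax(viol)) if viol.any() else n
    sigma = float(np.sqrt(max(sig2[k - 1], 0.0)))
    return sigma, k


def msse(residuals: np.ndarray, config: MsseConfig | None = None) -> ScaleEstimate:
    """Estimate the Gaussian noise scale from squared fitting errors.

    Parameters
    ----------
    residuals : array-like
        Non-negative squared residuals, one per data point.
    config : MsseConfig, optional
        Stopping-rule parameters; defaults are λ=3, k_min=12.

    Returns
    -------
    ScaleEstimate
        Robust scale, inlier count and per-point flags in original order.

    Raises
    ------
    ValueError
        If fewer than ``k_min + 1`` points are supplied.
    """
    if config is None:
        config = MsseConfig()
    r2 = _as_squared_residuals(residuals)
    n = r2.size
    if n < config.k_min + 1:
        raise ValueError(
            f"MSSE needs at least k_min + 1 = {config.k_min + 1} points, got {n}"
        )
    order = np.argsort(r2, kind="stable")
    sigma, k = _msse_core(r2[order], None, config)
    flags = np.zeros(n, dtype=bool)
    flags[order[:k]] = True
    return ScaleEstimate(sigma=sigma, k_inliers=k, inlier_flags=flags)


def msse_weighted(
    residuals: np.ndarray,
    weights: np.ndarray,
    config: MsseConfig | None = None,
) -> ScaleEstimate:
    """Weighted MSSE: zero-weight points are excluded, the rest contribute
    their squared residuals in proportion to their weight.

    Binary 0/1 weights reproduce :func:`msse` on the positively weighted
    subset exactly, and multiplying all weights by a common factor leaves
    the estimate unchanged.
    """
    if config is None:
        config = MsseConfig()
    r2 = _as_squared_residuals(residuals)
    w = np.asarray(weights, dtype=float)
    if w.shape != r2.shape:
        raise ValueError("weights must have the same length as residuals")
    if np.any(w < 0) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be finite and non-negative")

    active = w > 0
    n_active = int(np.count_nonzero(active))
    if n_active < config.k_min + 1:
        raise ValueError(
            f"MSSEWeighted needs at least k_min + 1 = {config.k_min + 1} points "
            f"with positive weight, got {n_active}"
        )
    idx = np.flatnonzero(active)
    r2a, wa = r2[idx], w[idx]
    order = np.argsort(r2a, kind="stable")
    sigma, k = _msse_core(r2a[order], wa[order], config)
    flags = np.zeros(r2.size, dtype=bool)
    flags[idx[order[:k]]] = True
    return ScaleEstimate(sigma=sigma, k_inliers=k, inlier_flags=flags)


def snr(x_p, mu_b, sigma_b):
    """Statistical-separability signal-to-noise ratio (x_p - mu_B) / sigma_B.

    Sign-preserving: values below the background model get negative SNR,
    so deficient (dead) pixels are as separable as hot ones.  Accepts
    scalars or broadcastable arrays.
    """
    sigma_b = np.asarray(sigma_b, dtype=float)
    if np.any(sigma_b <= 0):
        raise ValueError(
            "sigma_b must be > 0; apply a scale floor (e.g. minimum_residual) "
            "before computing SNR on degenerate backgrounds"
        )
    out = (np.asarray(x_p, dtype=float) - np.asarray(mu_b, dtype=float)) / sigma_b
    return float(out) if out.ndim == 0 else out
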