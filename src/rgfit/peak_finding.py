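"""Robust Bragg-peak finding for serial-crystallography frames.

Peaks are detected in three steps: (i) candidate pixels are strict local
maxima whose intensity exceeds the median of their local window; (ii) the
background around each candidate is modelled robustly with a tilted plane in
a window centred on the candidate, giving the candidate an SNR in units of
the local robust noise scale; (iii) candidates at or above the SNR threshold
are grown into connected peak regions of pixels above the local background,
and summarized as a peak list.

Because the background is modelled locally and robustly, nearby peaks and
intensity gradients (e.g. the water ring) do not inflate the scale estimate
and weak peaks remain separable.  A frame is a "hit" when it contains more
peaks than a count threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from rgfit.background import DetectorImage
from rgfit.model_fitting import FlkosConfig, GeometricModel, fit_plane
from rgfit.robust_core import MsseConfig, snr as _snr

__all__ = [
    "Peak",
    "PeakList",
    "PeakFinderConfig",
    "find_candidates",
    "evaluate_candidate",
    "grow_peak",
    "find_peaks",
    "is_hit",
]

# scale floor when the fitted window is exactly noise-free
_SIGMA_EPS = 1e-12


@dataclass(frozen=True)
class Peak:
    """One detected Bragg peak."""

    centroid_row: float
    centroid_col: float
    total_intensity: float
    n_pixels: int
    snr: float
    seed_row: int
    seed_col: int


@dataclass
class PeakList:
    """Detected peaks of one frame."""

    peaks: list[Peak] = field(default_factory=list)
    frame_id: int = 0

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def to_dataframe(self) -> pd.DataFrame:
        cols = [
            "frame",
            "seed_row",
            "seed_col",
            "centroid_row",
            "centroid_col",
            "n_pixels",
            "total_intensity",
            "snr",
        ]
        rows = [
            (
                self.frame_id,
                p.seed_row,
                p.seed_col,
                p.centroid_row,
                p.centroid_col,
                p.n_pixels,
                p.total_intensity,
                p.snr,
            )
            for p in self.peaks
        ]
        return pd.DataFrame(rows, columns=cols)


@dataclass(frozen=True)
class PeakFinderConfig:
    """Peak-finder hyper-parameters.

    ``window`` is the edge of the square local window used both for the
    candidate median threshold and for the robust background fit (default
    32 pixels).  ``snr_threshold`` accepts a candidate when its SNR is at or
    above it (default 6).  ``max_peaks`` caps how many candidates, taken in
    decreasing intensity order, are evaluated per frame.
    ``min_peaks_for_hit`` classifies a frame as a hit when strictly more
    peaks than this are found.
    """

    window: int = 32
    snr_threshold: float = 6.0
    max_peaks: int = 8192
    min_peaks_for_hit: int = 15

    def __post_init__(self) -> None:
        if self.window < 4:
            raise ValueError("window too small to support a robust fit")
        if self.snr_threshold <= 0:
            raise ValueError("snr_threshold must be > 0")


def _clip_window(
    shape: tuple[int, int], seed: tuple[int, int], window: int
) -> tuple[int, int, int, int]:
    r, c = seed
    half = window // 2
    r0 = max(r - half, 0)
    c0 = max(c - half, 0)
    r1 = min(r0 + window, shape[0])
    c1 = min(c0 + window, shape[1])
    r0 = max(r1 - window, 0)
    c0 = max(c1 - window, 0)
    return r0, r1, c0, c1


def _tile_median(work: np.ndarray, valid: np.ndarray, window: int) -> np.ndarray:
    """Median of each pixel's local region, the region being its
    ``window``-sized tile of the frame."""
    rows, cols = work.shape
    out = np.empty_like(work)
    for r0 in range(0, rows, window):
        for c0 in range(0, cols, window):
            tile = work[r0 : r0 + window, c0 : c0 + window]
            tv = tile[valid[r0 : r0 + window, c0 : c0 + window]]
            out[r0 : r0 + window, c0 : c0 + window] = (
                np.median(tv) if tv.size else np.inf
            )
    return out


def find_candidates(
    image: DetectorImage | np.ndarray, config: PeakFinderConfig | None = None
) -> list[tuple[int, int]]:
    """Candidate peak pixels: valid strict maxima of their 3x3 neighbourhood
    that also exceed the median of their local window, sorted by intensity
    descending and capped at ``max_peaks``."""
    if not isinstance(image, DetectorImage):
        image = DetectorImage(image)
    if config is None:
        config = PeakFinderConfig()
    vals = image.intensities
    valid = image.mask
    work = np.where(valid, vals, -np.inf)

    neighbor_max = ndimage.maximum_filter(
        work, footprint=np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], bool),
        mode="constant", cval=-np.inf,
    )
    local_median = _tile_median(work, valid, config.window)
    cand = valid & (work > neighbor_max) & (work > local_median)

    rr, cc = np.nonzero(cand)
    if rr.size == 0:
        return []
    order = np.argsort(vals[rr, cc], kind="stable")[::-1]
    order = order[: config.max_peaks]
    return [(int(rr[i]), int(cc[i])) for i in order]


def _candidate_rng_seed(base_seed: Optional[int], seed: tuple[int, int]) -> int:
    """Per-candidate deterministic seed, independent of evaluation order."""
    base = base_seed if base_seed is not None else 0
    return int(np.random.SeedSequence([base, seed[0], seed[1]]).generate_state(1)[0] % (2**31))


def evaluate_candidate(
    image: DetectorImage,
    seed: tuple[int, int],
    config: PeakFinderConfig,
    flkos_cfg: FlkosConfig | None = None,
    msse_cfg: MsseConfig | None = None,
):
    """Fit a robust plane to the window around ``seed`` and return
    ``(snr, fit)`` where ``fit`` is the local background model.

    Returns ``(None, None)`` when the clipped window holds too few valid
    pixels or the fit is degenerate (the candidate is discarded).
    """
    if flkos_cfg is None:
        flkos_cfg = FlkosConfig()
    if msse_cfg is None:
        msse_cfg = MsseConfig(model_dof=3)
    flkos_cfg = replace(
        flkos_cfg, rng_seed=_candidate_rng_seed(flkos_cfg.rng_seed, seed)
    )
    r0, r1, c0, c1 = _clip_window(image.shape, seed, config.window)
    sub_mask = image.mask[r0:r1, c0:c1]
    if int(np.count_nonzero(sub_mask)) < msse_cfg.k_min + 1:
        return None, None
    rr, cc = np.nonzero(sub_mask)
    vals = image.intensities[r0:r1, c0:c1][rr, cc]
    try:
        fit = fit_plane(
            (cc + c0).astype(float), (rr + r0).astype(float), vals, flkos_cfg, msse_cfg
        )
    except (ValueError, np.linalg.LinAlgError):
        return None, None
    a, b, c = fit.model.params
    mu_b = a * seed[1] + b * seed[0] + c
    sigma_b = max(fit.sigma, msse_cfg.minimum_residual, _SIGMA_EPS)
    return float(_snr(image.intensities[seed], mu_b, sigma_b)), fit


def grow_peak(
    image: DetectorImage,
    seed: tuple[int, int],
    background_fit,
    config: PeakFinderConfig,
    snr_value: float = np.nan,
    claimed: Optional[np.ndarray] = None,
) -> Peak:
    """Grow a peak by 4-connected flood fill from ``seed`` over valid,
    unclaimed pixels above the local background plane, confined to the
    seed's window.  Marks grown pixels in ``claimed`` in place."""
    r0, r1, c0, c1 = _clip_window(image.shape, seed, config.window)
    model = getattr(background_fit, "model", background_fit)
    a, b, c = model.params
    if claimed is None:
        claimed = np.zeros(image.shape, dtype=bool)

    vals = image.intensities
    valid = image.mask
    member_r: list[int] = []
    member_c: list[int] = []
    excess: list[float] = []
    stack = [seed]
    while stack:
        r, cpx = stack.pop()
        if not (r0 <= r < r1 and c0 <= cpx < c1):
            continue
        if claimed[r, cpx] or not valid[r, cpx]:
            continue
        bg = a * cpx + b * r + c
        if vals[r, cpx] <= bg and (r, cpx) != seed:
            continue
        claimed[r, cpx] = True
        member_r.append(r)
        member_c.append(cpx)
        excess.append(vals[r, cpx] - bg)
        stack.extend([(r - 1, cpx), (r + 1, cpx), (r, cpx - 1), (r, cpx + 1)])

    w = np.maximum(np.asarray(excess), 0.0)
    mr = np.asarray(member_r, dtype=float)
    mc = np.asarray(member_c, dtype=float)
    if w.sum() > 0:
        crow = float(np.sum(mr * w) / w.sum())
        ccol = float(np.sum(mc * w) / w.sum())
    else:
        crow, ccol = float(seed[0]), float(seed[1])
    return Peak(
        centroid_row=crow,
        centroid_col=ccol,
        total_intensity=float(np.sum(excess)),
        n_pixels=len(member_r),
        snr=float(snr_value),
        seed_row=int(seed[0]),
        seed_col=int(seed[1]),
    )


def _evaluate_candidates_batch(
    image: DetectorImage,
    seeds: list[tuple[int, int]],
    config: PeakFinderConfig,
    flkos_cfg: FlkosConfig,
    msse_cfg: MsseConfig,
    chunk: int = 2048,
):
    """Vectorized FLkOS plane fit + MSSE over many same-size windows.

    Runs the same guided-sampling recursion as :func:`evaluate_candidate`
    (per-candidate derived seeds, rank block ending at k, best-kth model
    tracking) but batched across candidates in local window coordinates.
    Applicable only to fully valid images whose extent admits uncropped
    windows.  Returns (snr, models, sigmas) aligned with ``seeds``.
    """
    win = config.window
    n = win * win
    p = 3
    k = min(max(math.ceil(flkos_cfg.likely_ratio * n), p + 1), n)
    s = min(max(p + 1, math.ceil(flkos_cfg.certain_ratio * n)), k)
    kth_spec = [k - 1] if s == k else [k - s, k - 1]

    # local design: point j = r*win + c -> (x=c, y=r, 1)
    loc = np.arange(n)
    A = np.column_stack([(loc % win).astype(float), (loc // win).astype(float),
                         np.ones(n)])

    sw = np.lib.stride_tricks.sliding_window_view(image.intensities, (win, win))
    origins = np.array([_clip_window(image.shape, sd, win)[::2] for sd in seeds])
    seed_arr = np.asarray(seeds)

    lam2 = msse_cfg.lambda_cutoff**2
    floor2 = msse_cfg.minimum_residual**2
    k_start = max(msse_cfg.k_min, min(math.ceil(flkos_cfg.certain_ratio * n), n - 1))
    ks = np.arange(1, n + 1, dtype=float)

    snrs = np.empty(len(seeds))
    models: list[GeometricModel] = []
    sigmas = np.empty(len(seeds))
    for lo in range(0, len(seeds), chunk):
        sel = slice(lo, min(lo + chunk, len(seeds)))
        org = origins[sel]
        Y = sw[org[:, 0], org[:, 1]].reshape(-1, n)
        C = Y.shape[0]

        S = np.empty((C, s), dtype=np.intp)
        for i in range(C):
            rng = np.random.default_rng(
                _candidate_rng_seed(flkos_cfg.rng_seed, tuple(seed_arr[lo + i]))
            )
            S[i] = np.sort(rng.choice(n, size=s, replace=False))

        best_coef = np.zeros((C, 3))
        best_kth = np.full(C, np.inf)
        G = np.empty((C, 3, 3))
        bvec = np.empty((C, 3))
        # the iteration's residual ranking tolerates single precision; the
        # final scale estimate below is redone in double
        Y32 = Y.astype(np.float32)
        A32 = A.astype(np.float32)
        for _ in range(flkos_cfg.opt_iters):
            # normal-equation moments of the subset; x, y follow from the
            # flat window indices, so no design-matrix gather is needed
            xs = (S % win).astype(float)
            ys = (S // win).astype(float)
            vs = np.take_along_axis(Y, S, axis=1)
            G[:, 0, 0] = np.sum(xs * xs, axis=1)
            G[:, 0, 1] = G[:, 1, 0] = np.sum(xs * ys, axis=1)
            G[:, 0, 2] = G[:, 2, 0] = np.sum(xs, axis=1)
            G[:, 1, 1] = np.sum(ys * ys, axis=1)
            G[:, 1, 2] = G[:, 2, 1] = np.sum(ys, axis=1)
            G[:, 2, 2] = s
            bvec[:, 0] = np.sum(xs * vs, axis=1)
            bvec[:, 1] = np.sum(ys * vs, axis=1)
            bvec[:, 2] = np.sum(vs, axis=1)
            coef = np.linalg.solve(G, bvec[..., None])[..., 0]
            r2 = (Y32 - coef.astype(np.float32) @ A32.T) ** 2
            order = np.argpartition(r2, kth_spec, axis=1)
            kth = np.take_along_axis(r2, order[:, k - 1 : k], axis=1)[:, 0]
            better = kth < best_kth
            best_kth[better] = kth[better]
            best_coef[better] = coef[better]
            S = np.sort(order[:, k - s : k], axis=1)

        xv, yv = A[:, 0], A[:, 1]

        def _weighted_refit(m: np.ndarray) -> np.ndarray:
            G[:, 0, 0] = m @ (xv * xv)
            G[:, 0, 1] = G[:, 1, 0] = m @ (xv * yv)
            G[:, 0, 2] = G[:, 2, 0] = m @ xv
            G[:, 1, 1] = m @ (yv * yv)
            G[:, 1, 2] = G[:, 2, 1] = m @ yv
            G[:, 2, 2] = m.sum(axis=1)
            mY = m * Y
            bvec[:, 0] = mY @ xv
            bvec[:, 1] = mY @ yv
            bvec[:, 2] = mY.sum(axis=1)
            return np.linalg.solve(G, bvec[..., None])[..., 0]

        def _batch_msse(r2: np.ndarray) -> np.ndarray:
            r2s = np.maximum(np.sort(r2, axis=1), floor2)
            sig2 = np.cumsum(r2s, axis=1) / np.maximum(ks - p, 1)
            viol = r2s[:, k_start:] > lam2 * sig2[:, k_start - 1 : n - 1]
            k_stop = np.where(viol.any(axis=1), k_start + viol.argmax(axis=1), n)
            return np.sqrt(sig2[np.arange(C), k_stop - 1])

        # refinements mirroring the serial fitters: a trimmed refit on the
        # k nearest points, then a reweighted refit on the MSSE inlier band
        r2 = (Y - best_coef @ A.T) ** 2
        order = np.argpartition(r2, k - 1, axis=1)
        m = np.zeros((C, n))
        np.put_along_axis(m, order[:, :k], 1.0, axis=1)
        best_coef = _weighted_refit(m)

        r2 = (Y - best_coef @ A.T) ** 2
        sig = _batch_msse(r2)
        band = np.maximum(r2, floor2) <= (msse_cfg.lambda_cutoff * sig[:, None]) ** 2
        narrow = band.sum(axis=1) <= p
        m2 = np.where(narrow[:, None], m > 0, band).astype(float)
        best_coef = _weighted_refit(m2)

        r2 = (Y - best_coef @ A.T) ** 2
        sig = _batch_msse(r2)

        seed_loc_x = (seed_arr[sel.start : sel.stop, 1] - org[:, 1]).astype(float)
        seed_loc_y = (seed_arr[sel.start : sel.stop, 0] - org[:, 0]).astype(float)
        mu = (best_coef[:, 0] * seed_loc_x + best_coef[:, 1] * seed_loc_y
              + best_coef[:, 2])
        x_p = image.intensities[seed_arr[sel, 0], seed_arr[sel, 1]]
        sig_eff = np.maximum(sig, max(msse_cfg.minimum_residual, _SIGMA_EPS))
        snrs[sel] = (x_p - mu) / sig_eff
        sigmas[sel] = sig
        # translate the local-coordinate plane back to frame coordinates
        for i in range(C):
            a, bb, cc = best_coef[i]
            c_glob = cc - a * org[i, 1] - bb * org[i, 0]
            models.append(GeometricModel("plane", (float(a), float(bb), float(c_glob))))
    return snrs, models, sigmas


def find_peaks(
    image: DetectorImage | np.ndarray,
    config: PeakFinderConfig | None = None,
    flkos_cfg: FlkosConfig | None = None,
    msse_cfg: MsseConfig | None = None,
    frame_id: int = 0,
) -> PeakList:
    """Run the full three-step robust peak finder on one frame.

    Deterministic for a fixed ``flkos_cfg.rng_seed``: each candidate's
    guided sampling is seeded from the base seed and the candidate's own
    coordinates, so results do not depend on evaluation order.  Fully
    valid frames take a vectorized fast path that evaluates all candidate
    windows at once; masked frames fall back to per-candidate fits.
    """
    if not isinstance(image, DetectorImage):
        image = DetectorImage(image)
    if config is None:
        config = PeakFinderConfig()
    if flkos_cfg is None:
        flkos_cfg = FlkosConfig()
    if msse_cfg is None:
        msse_cfg = MsseConfig(model_dof=3)
    candidates = find_candidates(image, config)
    claimed = np.zeros(image.shape, dtype=bool)
    out = PeakList(frame_id=frame_id)

    batchable = (
        image.valid_mask is None
        and not flkos_cfg.fit2skewed
        and flkos_cfg.model_value_init is None
        and flkos_cfg.downsampled_size is None
        and min(image.shape) >= config.window
        and len(candidates) > 0
    )
    if batchable:
        snrs, models, _ = _evaluate_candidates_batch(
            image, candidates, config, flkos_cfg, msse_cfg
        )
        for seed, snr_value, model in zip(candidates, snrs, models):
            if claimed[seed] or snr_value < config.snr_threshold:
                continue
            out.peaks.append(
                grow_peak(image, seed, model, config,
                          snr_value=float(snr_value), claimed=claimed)
            )
        return out

    for seed in candidates:
        if claimed[seed]:
            continue
        snr_value, fit = evaluate_candidate(image, seed, config, flkos_cfg, msse_cfg)
        if snr_value is None or snr_value < config.snr_threshold:
            continue
        out.peaks.append(
            grow_peak(image, seed, fit, config, snr_value=snr_value, claimed=claimed)
        )
    return out


def is_hit(peaks: PeakList | int, min_peaks_for_hit: int) -> bool:
    """A frame is a hit when it has strictly more peaks than the threshold."""
    count = peaks if isinstance(peaks, int) else len(peaks)
    return count > min_peaks_for_hit
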