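"""Seeded synthetic-data generators with known ground truth.

Every generator draws from a fixed, named pseudo-random algorithm (PCG64),
so a given seed reproduces the same arrays bit-for-bit on any platform.
Each returns the data plus a :class:`SyntheticTruth` that records the
planted model parameters and per-point labels or defect coordinates.
Labels follow the generative recipe, not the realized values: an outlier
drawn inside the inlier band keeps its outlier label, which is the
irreducible label noise of any recovery test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from rgfit.background import DetectorImage
from rgfit.mask_making import FrameStack

__all__ = [
    "SyntheticTruth",
    "rng_for",
    "gen_1d_dataset",
    "gen_line_dataset",
    "gen_plane_dataset",
    "gen_diffraction_pattern",
    "gen_random_peaks",
    "gen_frame_stack",
]


@dataclass
class SyntheticTruth:
    """Ground truth of a synthetic data set."""

    params: dict
    noise_sigma: float
    seed: int
    inlier_labels: Optional[np.ndarray] = None  # True = inlier
    peaks: list = field(default_factory=list)  # (row, col, amplitude, width)
    defects: dict = field(default_factory=dict)  # kind -> array of (row, col)


def rng_for(seed: int) -> np.random.Generator:
    """The package-wide fixture generator: PCG64 under the given seed."""
    return np.random.Generator(np.random.PCG64(seed))


def gen_1d_dataset(
    n: int = 1000,
    inlier_frac: float = 0.7,
    mu: float = 0.0,
    sigma: float = 0.5,
    outlier_low: float = 1.5,
    outlier_high: float = 6.5,
    seed: int = 0,
) -> tuple[np.ndarray, SyntheticTruth]:
    """Gaussian inliers N(mu, sigma^2) plus uniform outliers in
    [outlier_low, outlier_high], shuffled.

    The defaults plant a structure at 0 and an off-structure uniform cloud
    in [1.5, 6.5]; the inlier scale of 0.5 keeps the cloud visibly separated
    from the Gaussian (it starts 3 scales above the mean), the regime the
    outlier-segmentation demos depict."""
    rng = rng_for(seed)
    n_in = math.ceil(inlier_frac * n)
    data = np.concatenate(
        [
            rng.normal(mu, sigma, size=n_in),
            rng.uniform(outlier_low, outlier_high, size=n - n_in),
        ]
    )
    labels = np.concatenate([np.ones(n_in, bool), np.zeros(n - n_in, bool)])
    perm = rng.permutation(n)
    truth = SyntheticTruth(
        params={"mu": mu},
        noise_sigma=sigma,
        seed=seed,
        inlier_labels=labels[perm],
    )
    return data[perm], truth


def gen_line_dataset(
    n: int = 1000,
    slope: float = 2.0,
    intercept: float = 1.0,
    sigma: float = 0.25,
    outlier_frac: float = 0.3,
    bbox: tuple[float, float, float, float] = (0.0, 10.0, -5.0, 30.0),
    seed: int = 0,
) -> tuple[np.ndarray, SyntheticTruth]:
    """2D points on y = slope*x + intercept with Gaussian vertical noise,
    plus uniform outliers in the bounding box (x0, x1, y0, y1)."""
    rng = rng_for(seed)
    n_out = math.floor(outlier_frac * n)
    n_in = n - n_out
    x0, x1, y0, y1 = bbox
    x_in = rng.uniform(x0, x1, size=n_in)
    y_in = slope * x_in + intercept + rng.normal(0.0, sigma, size=n_in)
    x_out = rng.uniform(x0, x1, size=n_out)
    y_out = rng.uniform(y0, y1, size=n_out)
    pts = np.column_stack(
        [np.concatenate([x_in, x_out]), np.concatenate([y_in, y_out])]
    )
    labels = np.concatenate([np.ones(n_in, bool), np.zeros(n_out, bool)])
    perm = rng.permutation(n)
    truth = SyntheticTruth(
        params={"slope": slope, "intercept": intercept},
        noise_sigma=sigma,
        seed=seed,
        inlier_labels=labels[perm],
    )
    return pts[perm], truth


def gen_plane_dataset(
    grid_shape: tuple[int, int] = (32, 32),
    a: float = 0.1,
    b: float = 0.2,
    c: float = 50.0,
    sigma: float = 2.0,
    outlier_frac: float = 0.1,
    boost: float = 40.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, SyntheticTruth]:
    """Grid-sampled plane z = a*x + b*y + c with Gaussian noise; a random
    ``outlier_frac`` of pixels is boosted by ``boost`` (a planted peak-like
    excess).  Returns flat (x, y, z, truth) with x = column, y = row."""
    rng = rng_for(seed)
    rows, cols = grid_shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    x = xx.ravel().astype(float)
    y = yy.ravel().astype(float)
    z = a * x + b * y + c + rng.normal(0.0, sigma, size=x.size)
    n_out = math.floor(outlier_frac * x.size)
    out_idx = rng.choice(x.size, size=n_out, replace=False)
    z[out_idx] += boost
    labels = np.ones(x.size, bool)
    labels[out_idx] = False
    truth = SyntheticTruth(
        params={"a": a, "b": b, "c": c},
        noise_sigma=sigma,
        seed=seed,
        inlier_labels=labels,
    )
    return x, y, z, truth


def gen_random_peaks(
    shape: tuple[int, int],
    n_peaks: int,
    amplitude: float,
    width: float = 1.5,
    seed: int = 0,
    margin: int = 20,
    min_sep: float = 24.0,
) -> list[tuple[int, int, float, float]]:
    """Random well-separated peak specs (row, col, amplitude, width) with a
    margin from the frame edges; rejection-sampled under the seed."""
    rng = rng_for(seed)
    peaks: list[tuple[int, int, float, float]] = []
    attempts = 0
    while len(peaks) < n_peaks and attempts < 10000:
        attempts += 1
        r = int(rng.integers(margin, shape[0] - margin))
        c = int(rng.integers(margin, shape[1] - margin))
        if all((r - pr) ** 2 + (c - pc) ** 2 >= min_sep**2 for pr, pc, *_ in peaks):
            peaks.append((r, c, amplitude, width))
    if len(peaks) < n_peaks:
        raise ValueError("could not place the requested peaks; relax min_sep")
    return peaks


def gen_diffraction_pattern(
    shape: tuple[int, int] = (256, 256),
    bg_plane: tuple[float, float, float] = (0.5, 0.25, 100.0),
    noise_sigma: float = 3.0,
    peaks: Sequence[tuple[int, int, float, float]] = (),
    seed: int = 0,
    poisson: bool = False,
) -> tuple[DetectorImage, SyntheticTruth]:
    """A synthetic diffraction frame: tilted-plane background
    ``a*col + b*row + c`` plus Gaussian noise plus 2D Gaussian spots.

    Each peak spec is (row, col, amplitude, width); the nominal spot SNR is
    amplitude / noise_sigma.  With ``poisson`` the noisy frame is replaced
    by a Poisson draw around the noiseless intensity.
    """
    rng = rng_for(seed)
    rows, cols = shape
    a, b, c = bg_plane
    yy, xx = np.mgrid[0:rows, 0:cols]
    clean = a * xx + b * yy + c
    for r, cpx, amp, width in peaks:
        clean = clean + amp * np.exp(
            -((yy - r) ** 2 + (xx - cpx) ** 2) / (2.0 * width**2)
        )
    if poisson:
        img = rng.poisson(np.maximum(clean, 0.0)).astype(float)
    else:
        img = clean + rng.normal(0.0, noise_sigma, size=shape)
    truth = SyntheticTruth(
        params={"bg_plane": bg_plane},
        noise_sigma=noise_sigma,
        seed=seed,
        peaks=[tuple(p) for p in peaks],
    )
    return DetectorImage(img), truth


def gen_frame_stack(
    shape: tuple[int, int] = (512, 512),
    n_frames: int = 100,
    base_level: float = 100.0,
    noise_sigma: float = 5.0,
    n_hot: int = 30,
    n_dead: int = 10,
    n_flicker: int = 20,
    hot_offset: Optional[float] = None,
    flicker_factor: float = 5.0,
    dead_value: float = 0.0,
    seed: int = 0,
) -> tuple[FrameStack, SyntheticTruth]:
    """A dark-field-like calibration stack with planted defects.

    Healthy pixels draw i.i.d. N(base_level, noise_sigma^2) per frame.
    Hot pixels carry a mean offset (default 20 noise sigmas), dead pixels
    are stuck at ``dead_value`` with zero variance, flickering pixels have
    their per-frame noise inflated by ``flicker_factor``.
    """
    if hot_offset is None:
        hot_offset = 20.0 * noise_sigma
    rng = rng_for(seed)
    rows, cols = shape
    frames = rng.normal(base_level, noise_sigma, size=(n_frames, rows, cols))

    n_defect = n_hot + n_dead + n_flicker
    flat = rng.choice(rows * cols, size=n_defect, replace=False)
    coords = np.column_stack(np.unravel_index(flat, shape))
    hot = coords[:n_hot]
    dead = coords[n_hot : n_hot + n_dead]
    flicker = coords[n_hot + n_dead :]

    frames[:, hot[:, 0], hot[:, 1]] += hot_offset
    frames[:, dead[:, 0], dead[:, 1]] = dead_value
    frames[:, flicker[:, 0], flicker[:, 1]] = rng.normal(
        base_level, flicker_factor * noise_sigma, size=(n_frames, len(flicker))
    )

    truth = SyntheticTruth(
        params={"base_level": base_level, "hot_offset": hot_offset,
                "flicker_factor": flicker_factor, "dead_value": dead_value},
        noise_sigma=noise_sigma,
        seed=seed,
        defects={"hot": hot, "dead": dead, "flicker": flicker},
    )
    return FrameStack(frames=frames, acquisition_kind="dark_field"), truth
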