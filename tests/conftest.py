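
import pytest

from rgfit.fixtures import (
    gen_1d_dataset,
    gen_diffraction_pattern,
    gen_line_dataset,
    gen_random_peaks,
)
from rgfit.model_fitting import FlkosConfig


@pytest.fixture
def seventy_thirty():
    """The canonical 70% N(10, 2^2) + 30% uniform [40, 100] vector."""
    data, truth = gen_1d_dataset(
        n=1000, inlier_frac=0.7, mu=10, sigma=2,
        outlier_low=40, outlier_high=100, seed=42,
    )
    return data, truth


@pytest.fixture
def line_data():
    return gen_line_dataset(n=1000, slope=2.0, intercept=1.0, sigma=0.25,
                            outlier_frac=0.3, seed=7)


@pytest.fixture
def peak_frame():
    """A 256x256 ramp-background frame with 10 well-separated planted peaks
    of nominal SNR 10."""
    peaks = gen_random_peaks((256, 256), 10, amplitude=30.0, seed=3)
    image, truth = gen_diffraction_pattern(
        (256, 256), noise_sigma=3.0, peaks=peaks, seed=3
    )
    return image, truth


@pytest.fixture
def seeded_flkos():
    return FlkosConfig(rng_seed=0)


def match_peaks(found, planted, radius=6.0):
    """(n_matched_planted, n_matched_found) under a centroid radius."""
    r2 = radius**2
    matched_planted = sum(
        any((fr - r) ** 2 + (fc - c) ** 2 <= r2 for fr, fc in found)
        for r, c in planted
    )
    matched_found = sum(
        any((fr - r) ** 2 + (fc - c) ** 2 <= r2 for r, c in planted)
        for fr, fc in found
    )
    return matched_planted, matched_found
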