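"""Between-scan noise statistics and clipped-pixel fractions.

The photon noise of an acquisition is measured as the *between-scan
variance*: for each pixel, the sample variance of its values across the
repeated frames of one stack.  Aggregating per-pixel variances by the
rounded averaged intensity gives the per-intensity noise profile whose
shape diagnoses clipping — the variance grows roughly linearly with
intensity in the unclipped range and collapses near the grayscale ceiling
where most frames saturate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InsufficientDataError
from .simulate import ScanStack, average_stack

__all__ = [
    "NoiseProfile",
    "ClipFractionProfile",
    "between_scan_variance",
    "noise_profile",
    "clipped_fraction",
]


@dataclass
class NoiseProfile:
    """Mean between-scan variance per intensity level k in [0..c_a].

    ``variance[k]`` is NaN for levels not present in the averaged image
    (``n[k] == 0``).
    """

    variance: np.ndarray
    n: np.ndarray
    c_a: int
    gain_V: float
    offset_pct: float
    microscope_id: str = "sim"

    @property
    def levels(self) -> np.ndarray:
        return np.arange(self.c_a + 1)

    def present(self) -> np.ndarray:
        return self.n > 0

    def log_variance(self, floor: float = 1e-12) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.log(np.maximum(self.variance, floor))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"k": self.levels, "mean_variance": self.variance, "n": self.n}
        )


@dataclass
class ClipFractionProfile:
    """Fraction of frames clipped, per pixel and aggregated per level.

    ``upper_map``/``lower_map`` give, for each pixel, the fraction of
    frames exactly at ``c_a`` / exactly at 0.  ``upper_by_level`` and
    ``lower_by_level`` are the means of those fractions over pixels whose
    rounded averaged intensity equals k.
    """

    upper_map: np.ndarray
    lower_map: np.ndarray
    upper_by_level: np.ndarray
    lower_by_level: np.ndarray
    n: np.ndarray
    c_a: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": np.arange(self.c_a + 1),
                "upper_fraction": self.upper_by_level,
                "lower_fraction": self.lower_by_level,
                "n": self.n,
            }
        )


def between_scan_variance(stack: ScanStack) -> np.ndarray:
    """Per-pixel sample variance across frames (denominator n-1)."""
    if stack.n_scans < 2:
        raise InsufficientDataError("between-scan variance needs >= 2 frames")
    return stack.float_frames().var(axis=0, ddof=1)


def _level_index(stack: ScanStack) -> np.ndarray:
    avg = average_stack(stack).pixels
    return np.rint(avg).astype(np.int64).ravel()


def _level_mean(values: np.ndarray, k: np.ndarray, n_levels: int):
    counts = np.bincount(k, minlength=n_levels)
    sums = np.bincount(k, weights=values, minlength=n_levels)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return means, counts


def noise_profile(stack: ScanStack) -> NoiseProfile:
    """Group per-pixel variances by rounded averaged intensity."""
    var = between_scan_variance(stack).ravel()
    k = _level_index(stack)
    n_levels = stack.config.c_a + 1
    means, counts = _level_mean(var, k, n_levels)
    return NoiseProfile(
        variance=means,
        n=counts,
        c_a=stack.config.c_a,
        gain_V=stack.config.gain_V,
        offset_pct=stack.config.offset_pct,
        microscope_id=stack.microscope_id,
    )


def clipped_fraction(stack: ScanStack) -> ClipFractionProfile:
    """Fraction of frames clipped at either grayscale boundary.

    A frame value counts as clipped iff it equals ``c_a`` exactly (upper)
    or 0 exactly (lower); a true value coincidentally at the boundary is
    indistinguishable from a censored one and is counted, consistent with
    the censoring model used by the error estimators.
    """
    frames = stack.frames
    c_a = stack.config.c_a
    upper_map = (frames == c_a).mean(axis=0)
    lower_map = (frames == 0).mean(axis=0)
    k = _level_index(stack)
    n_levels = c_a + 1
    up_by_level, counts = _level_mean(upper_map.ravel(), k, n_levels)
    lo_by_level, _ = _level_mean(lower_map.ravel(), k, n_levels)
    return ClipFractionProfile(
        upper_map=upper_map,
        lower_map=lower_map,
        upper_by_level=up_by_level,
        lower_by_level=lo_by_level,
        n=counts,
        c_a=c_a,
    )
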