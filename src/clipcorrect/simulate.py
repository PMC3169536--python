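"""Synthetic confocal scan stacks with gain/offset-dependent noise and clipping.

A confocal acquisition averages several sequential scans (frames) of the
same specimen.  Each frame is contaminated by photon shot noise whose
variance grows linearly with the mean signal and exponentially with the
photomultiplier (PMT) gain voltage; the PMT offset subtracts a fixed number
of intensity units from every pixel before digitization.  Frame values
falling outside the 8-bit grayscale range are clipped at the boundaries
(over-saturation at ``c_a``, under-saturation at 0), which is the error
source modelled by the rest of this package.

The simulator is the package's ground-truth oracle: every estimator is
validated against stacks generated here, where the true pre-clipping mean
of every pixel is known exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import ndtr

from .exceptions import ConfigurationError, GenerationError, StructuralError

__all__ = [
    "GroundTruthField",
    "AcquisitionConfig",
    "ScanStack",
    "AveragedImage",
    "ClippingErrorField",
    "simulate_scan_stack",
    "average_stack",
    "true_clipping_error",
    "expected_clipping_error",
    "make_training_collection",
    "synth_embryo_pattern",
]

_SQRT2PI = math.sqrt(2.0 * math.pi)


def _phi(x: np.ndarray) -> np.ndarray:
    return np.exp(-0.5 * np.square(x)) / _SQRT2PI


def _pos_part_mean(alpha: np.ndarray) -> np.ndarray:
    """E[(Z + alpha)^+] for standard normal Z."""
    return alpha * ndtr(alpha) + _phi(alpha)


@dataclass(frozen=True)
class GroundTruthField:
    """True (pre-clipping, pre-offset) per-pixel mean intensity.

    Values are continuous grayscale units and may exceed the grayscale
    range: a specimen brighter than the dynamic range is exactly the case
    in which clipping errors arise.
    """

    mu: np.ndarray

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=float)
        if mu.ndim != 2 or mu.shape[0] < 1 or mu.shape[1] < 1:
            raise ConfigurationError("truth field must be a 2-D array")
        if not np.all(np.isfinite(mu)):
            raise ConfigurationError("truth field must be finite")
        object.__setattr__(self, "mu", mu)

    @property
    def height(self) -> int:
        return self.mu.shape[0]

    @property
    def width(self) -> int:
        return self.mu.shape[1]


@dataclass(frozen=True)
class AcquisitionConfig:
    """Acquisition settings and the between-scan noise law.

    The noise law is ``var(mu) = noise_a * exp(gain_V / g0) * mu + noise_b``
    (variance linear in the true mean, exponential in the PMT voltage).
    ``offset_pct`` follows the instrument convention of non-positive
    percentages; ``offset_units_per_pct`` converts it to the number of
    intensity units subtracted from the signal before clipping at 0.
    """

    gain_V: float = 500.0
    offset_pct: float = 0.0
    offset_units_per_pct: float = 10.0
    n_scans: int = 8
    noise_a: float = 0.05
    noise_b: float = 1.0
    g0: float = 100.0
    c_a: int = 255
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_scans < 2:
            raise ConfigurationError("n_scans must be >= 2")
        if self.c_a < 1 or (self.c_a + 1) & self.c_a != 0:
            # any 2**bits - 1 is accepted; 255 is the canonical 8-bit ceiling
            raise ConfigurationError("c_a must be 2**bits - 1")
        if self.noise_a < 0 or self.noise_b < 0:
            raise ConfigurationError("noise coefficients must be >= 0")
        if self.g0 <= 0:
            raise ConfigurationError("g0 must be > 0")
        if self.offset_units_per_pct <= 0:
            raise ConfigurationError("offset_units_per_pct must be > 0")

    @property
    def offset_units(self) -> float:
        """Intensity units subtracted from every pixel (non-negative)."""
        return abs(self.offset_pct) * self.offset_units_per_pct

    def noise_variance(self, mu: np.ndarray) -> np.ndarray:
        """Between-scan variance of the raw signal at true mean ``mu``."""
        mu = np.maximum(np.asarray(mu, dtype=float), 0.0)
        return self.noise_a * math.exp(self.gain_V / self.g0) * mu + self.noise_b

    def noise_sigma(self, mu: np.ndarray) -> np.ndarray:
        return np.sqrt(self.noise_variance(mu))


@dataclass
class ScanStack:
    """``n_scans`` co-registered integer frames plus acquisition metadata."""

    frames: np.ndarray
    config: AcquisitionConfig
    microscope_id: str = "sim"

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        if frames.ndim != 3:
            raise StructuralError("frames must be a (n_scans, H, W) array")
        if frames.shape[0] != self.config.n_scans:
            raise StructuralError(
                f"stack has {frames.shape[0]} frames, config says "
                f"{self.config.n_scans}"
            )
        if frames.min() < 0 or frames.max() > self.config.c_a:
            raise StructuralError("frame values outside [0, c_a]")
        self.frames = frames

    @property
    def n_scans(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def float_frames(self) -> np.ndarray:
        return self.frames.astype(np.float64)


@dataclass
class AveragedImage:
    """Per-pixel arithmetic mean across the frames of one stack."""

    pixels: np.ndarray
    c_a: int = 255

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)

    @property
    def rounded(self) -> np.ndarray:
        """8-bit rendering (nearest-integer) of the averaged image."""
        return np.rint(self.pixels).astype(np.uint8 if self.c_a <= 255 else np.uint16)


@dataclass
class ClippingErrorField:
    """Exact per-pixel clipping errors of the averaged image.

    ``upper`` is the expected loss from over-saturation, ``lower`` the
    expected inflation from under-saturation, ``total`` the absolute
    displacement of the averaged value from the true (offset-subtracted,
    unclipped) mean.
    """

    upper: np.ndarray
    lower: np.ndarray
    total: np.ndarray


def simulate_scan_stack(
    truth: GroundTruthField,
    config: AcquisitionConfig,
    rng: np.random.Generator | None = None,
    microscope_id: str = "sim",
) -> ScanStack:
    """Draw one multi-frame acquisition of ``truth`` under ``config``.

    Per pixel and frame: the raw signal is Normal with mean ``mu`` and the
    config's noise variance; the offset (in intensity units) is subtracted;
    the result is clipped to ``[0, c_a]`` and rounded to an integer.
    Deterministic given ``config.seed`` (or an explicit ``rng``).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    mu = truth.mu
    sigma = config.noise_sigma(mu)
    raw = rng.normal(
        loc=mu[None, :, :], scale=sigma[None, :, :],
        size=(config.n_scans,) + mu.shape,
    )
    shifted = raw - config.offset_units
    clipped = np.clip(shifted, 0.0, float(config.c_a))
    frames = np.rint(clipped).astype(np.uint8 if config.c_a <= 255 else np.uint16)
    return ScanStack(frames=frames, config=config, microscope_id=microscope_id)


def average_stack(stack: ScanStack) -> AveragedImage:
    """Arithmetic per-pixel mean over the frames of a stack."""
    if stack.frames.shape[0] < 1:
        raise StructuralError("empty stack")
    return AveragedImage(pixels=stack.float_frames().mean(axis=0), c_a=stack.config.c_a)


def expected_clipping_error(
    truth: GroundTruthField, config: AcquisitionConfig
) -> ClippingErrorField:
    """Closed-form per-pixel clipping error under the Normal noise model.

    With raw signal X ~ N(mu, sigma^2(mu)) and V = X - offset_units, the
    averaged value converges to E[clip(V, 0, c_a)], so

    * upper loss  = E[(V - c_a)^+] = sigma * h((m - c_a)/sigma),
    * lower gain  = E[(-V)^+]      = sigma * h(-m/sigma),

    with m = mu - offset_units and h(a) = a*Phi(a) + phi(a).  Frame
    rounding (variance ~1/12) is ignored; it does not shift expectations.
    """
    m = truth.mu - config.offset_units
    sigma = config.noise_sigma(truth.mu)
    c_a = float(config.c_a)
    with np.errstate(divide="ignore", invalid="ignore"):
        upper = np.where(
            sigma > 0,
            sigma * _pos_part_mean((m - c_a) / np.where(sigma > 0, sigma, 1.0)),
            np.maximum(m - c_a, 0.0),
        )
        lower = np.where(
            sigma > 0,
            sigma * _pos_part_mean(-m / np.where(sigma > 0, sigma, 1.0)),
            np.maximum(-m, 0.0),
        )
    return ClippingErrorField(upper=upper, lower=lower, total=np.abs(lower - upper))


def true_clipping_error(
    truth: GroundTruthField,
    config: AcquisitionConfig,
    n_mc: int = 10_000,
    seed: int | None = None,
) -> ClippingErrorField:
    """Monte-Carlo per-pixel clipping error under the full generative model.

    Unlike :func:`expected_clipping_error` this includes offset
    subtraction, clipping *and* integer rounding exactly as the simulator
    applies them, so it is the reference for end-to-end tests.  ``n_mc``
    draws are used per pixel (>= 1e4 recommended); intended for small
    fields.
    """
    if n_mc < 1:
        raise ConfigurationError("n_mc must be >= 1")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    mu = truth.mu.ravel()
    sigma = config.noise_sigma(truth.mu).ravel()
    m_true = mu - config.offset_units
    c_a = float(config.c_a)

    n_pix = mu.size
    upper = np.empty(n_pix)
    lower = np.empty(n_pix)
    mean_clipped = np.empty(n_pix)
    # chunk so the draw matrix stays ~2e7 doubles
    block = max(1, int(2e7 // n_mc))
    for start in range(0, n_pix, block):
        sl = slice(start, min(start + block, n_pix))
        draws = rng.normal(mu[sl], sigma[sl], size=(n_mc, sl.stop - sl.start))
        shifted = draws - config.offset_units
        upper[sl] = np.maximum(shifted - c_a, 0.0).mean(axis=0)
        lower[sl] = np.maximum(-shifted, 0.0).mean(axis=0)
        mean_clipped[sl] = np.rint(np.clip(shifted, 0.0, c_a)).mean(axis=0)
    shape = truth.mu.shape
    return ClippingErrorField(
        upper=upper.reshape(shape),
        lower=lower.reshape(shape),
        total=np.abs(mean_clipped - m_true).reshape(shape),
    )


def _derived_seed(master: int, truth_index: int, gain_V: float, offset_pct: float) -> int:
    """Stable per-stack seed from the master seed and the grid coordinates."""
    key = (
        int(master),
        int(truth_index),
        int(round(gain_V * 1000.0)),
        int(round(abs(offset_pct) * 1000.0)),
    )
    ss = np.random.SeedSequence(key)
    return int(ss.generate_state(1)[0])


def make_training_collection(
    truths: Sequence[GroundTruthField],
    grid: Sequence[tuple[float, float]],
    base_config: AcquisitionConfig,
    seed: int,
) -> list[ScanStack]:
    """One simulated stack per (truth, grid point).

    ``grid`` lists (gain_V, offset_pct) pairs, mirroring the acquisition
    design in which each specimen is scanned repeatedly at different PMT
    settings.  Per-stack seeds are derived deterministically from the
    master seed and the grid coordinates, so two runs with the same seed
    produce bit-identical stacks.
    """
    if len(grid) == 0:
        raise ConfigurationError("grid must be non-empty")
    stacks: list[ScanStack] = []
    for i, truth in enumerate(truths):
        for gain_V, offset_pct in grid:
            cfg = replace(
                base_config,
                gain_V=float(gain_V),
                offset_pct=float(offset_pct),
                seed=_derived_seed(seed, i, gain_V, offset_pct),
            )
            stacks.append(simulate_scan_stack(truth, cfg))
    return stacks


def synth_embryo_pattern(
    n_nuclei: int,
    intensity_range: tuple[float, float] = (10.0, 250.0),
    shape: tuple[int, int] = (256, 256),
    radius: int = 6,
    margin: int = 2,
    background: float = 2.0,
    seed: int | None = None,
):
    """Synthetic embryo-like fixture: truth field, nuclear mask, true pattern.

    Disk-shaped, non-overlapping nuclei are placed on a jittered grid.  The
    nuclear intensity follows a smooth bell-shaped profile along the x axis
    (a one-dimensional expression stripe), spanning ``intensity_range``
    from the field edges to the stripe centre.  Returns
    ``(GroundTruthField, mask, pattern)`` where ``mask`` is a {0,1} uint8
    image and ``pattern`` is a DataFrame with exact per-nucleus means of
    the truth field (columns: id, x, y, intensity, n_pixels).
    """
    import pandas as pd
    from skimage.measure import label, regionprops

    if n_nuclei < 1:
        raise ConfigurationError("n_nuclei must be >= 1")
    lo, hi = float(intensity_range[0]), float(intensity_range[1])
    if hi < lo:
        raise ConfigurationError("intensity_range must be (lo, hi) with hi >= lo")
    H, W = shape
    cell = 2 * radius + 2 * margin + 1
    rows, cols = H // cell, W // cell
    if rows * cols < n_nuclei:
        raise GenerationError(
            f"cannot place {n_nuclei} non-overlapping nuclei of radius "
            f"{radius} in a {H}x{W} field"
        )
    rng = np.random.default_rng(seed)
    cells = rng.choice(rows * cols, size=n_nuclei, replace=False)

    yy, xx = np.mgrid[0:H, 0:W]
    # bell-shaped stripe along x: peak `hi` at the field centre, `lo` at edges
    xc, width = W / 2.0, W / 4.0
    prof = np.exp(-0.5 * ((xx[0] - xc) / width) ** 2)
    profile_1d = lo + (hi - lo) * (prof - prof.min()) / (prof.max() - prof.min())

    truth = np.full((H, W), float(background))
    mask = np.zeros((H, W), dtype=np.uint8)
    for c in cells:
        r_i, c_i = divmod(int(c), cols)
        # jitter keeps each disk inside its cell with >= 2 px to the next
        # cell's disk, so 8-connected labeling cannot merge neighbours
        jy = rng.integers(0, max(2 * margin - 1, 1))
        jx = rng.integers(0, max(2 * margin - 1, 1))
        cy = r_i * cell + radius + jy
        cx = c_i * cell + radius + jx
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
        mask[disk] = 1
        # smooth within-nucleus variation along the stripe axis
        truth[disk] = profile_1d[xx[disk]]

    labels = label(mask, connectivity=2)
    records = []
    for prop in regionprops(labels, intensity_image=truth):
        cy, cx = prop.centroid
        records.append(
            {
                "id": int(prop.label),
                "x": float(cx),
                "y": float(cy),
                "intensity": float(prop.intensity_mean),
                "n_pixels": int(prop.area),
            }
        )
    pattern = pd.DataFrame.from_records(records)
    return GroundTruthField(mu=truth), mask, pattern
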