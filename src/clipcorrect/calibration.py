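"""Cross-instrument standardization of PMT gain and offset.

Identical PMT settings produce different noise levels on different
microscopes (and lasers), yet the noise level at a given intensity is
what determines the clipping error.  Two instruments are therefore put on
a common scale:

* **offset** is converted from percent to *intensity units subtracted per
  percent* by scanning one specimen twice at the same gain and two offset
  values: the mean pixel difference divided by the offset difference is
  the conversion factor;
* **gain** is standardized by an *additive voltage shift*: since the
  between-scan variance grows exponentially with gain, a multiplicative
  noise mismatch between instruments corresponds to a constant shift of
  the voltage axis, found by matching the instrument's log-noise curve to
  a reference table of log noise versus intensity at standardized gains.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .exceptions import CalibrationError
from .noise import noise_profile
from .simulate import (
    AcquisitionConfig,
    AveragedImage,
    GroundTruthField,
    ScanStack,
    simulate_scan_stack,
)

__all__ = [
    "CalibrationRecord",
    "ReferenceNoiseTable",
    "calibrate_offset",
    "calibrate_gain",
    "standardize",
    "build_reference_table",
    "load_packaged_reference",
]


@dataclass
class CalibrationRecord:
    """Maps one instrument's PMT scales onto the reference scale."""

    microscope_id: str = "reference"
    offset_units_per_pct: float = 1.0
    gain_shift_V: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.offset_units_per_pct > 0:
            raise CalibrationError("offset_units_per_pct must be > 0")
        if not np.isfinite(self.gain_shift_V):
            raise CalibrationError("gain_shift_V must be finite")


IDENTITY_CALIBRATION = CalibrationRecord(
    microscope_id="identity", offset_units_per_pct=1.0, gain_shift_V=0.0
)


@dataclass
class ReferenceNoiseTable:
    """Log between-scan noise vs intensity at standardized, zero-offset gains.

    ``table`` has columns ``gain_V``, ``k``, ``log_variance``; rows are
    restricted to intensity levels essentially uncorrupted by clipping.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gain_V", "k", "log_variance"}
        if not required.issubset(self.table.columns):
            raise CalibrationError(
                f"reference table must have columns {sorted(required)}"
            )
        self.table = self.table.sort_values(["k", "gain_V"]).reset_index(drop=True)

    @property
    def gain_range(self) -> tuple[float, float]:
        g = self.table["gain_V"]
        return float(g.min()), float(g.max())

    def interpolate(self, gain_V: float) -> pd.Series:
        """Per-level log variance at ``gain_V``, linear in gain at fixed k.

        Levels whose gain coverage does not bracket ``gain_V`` are
        dropped.
        """
        lo, hi = self.gain_range
        if not (lo <= gain_V <= hi):
            raise CalibrationError(
                f"gain {gain_V} V outside reference range [{lo}, {hi}] V"
            )
        out = {}
        for k, grp in self.table.groupby("k"):
            g = grp["gain_V"].to_numpy()
            if g.min() <= gain_V <= g.max() and len(g) >= 2:
                out[int(k)] = float(
                    np.interp(gain_V, g, grp["log_variance"].to_numpy())
                )
        return pd.Series(out, name="log_variance")


def calibrate_offset(
    imageA: AveragedImage | np.ndarray,
    imageB: AveragedImage | np.ndarray,
    offA_pct: float,
    offB_pct: float,
    min_usable_fraction: float = 0.10,
) -> float:
    """Intensity units subtracted per percent of offset.

    ``imageA``/``imageB`` are averaged images of the *same specimen at the
    same gain* scanned at two offsets.  Pixels clipped at zero in either
    image carry no information about the subtraction and are excluded.
    The mean difference divided by the offset difference, arranged
    positive, is the conversion factor.
    """
    a = imageA.pixels if isinstance(imageA, AveragedImage) else np.asarray(imageA, float)
    b = imageB.pixels if isinstance(imageB, AveragedImage) else np.asarray(imageB, float)
    if a.shape != b.shape:
        raise CalibrationError("images must have the same shape")
    if offA_pct == offB_pct:
        raise CalibrationError("offsets must differ")
    usable = (a > 0) & (b > 0)
    frac = usable.mean()
    if frac < min_usable_fraction:
        raise CalibrationError(
            f"only {frac:.1%} of pixels usable (< {min_usable_fraction:.0%}); "
            "calibration unreliable"
        )
    units = float(np.mean(a[usable] - b[usable]) / (offB_pct - offA_pct))
    units = abs(units)
    if units < 1e-9:
        warnings.warn(
            "offset calibration is ~0 units/%: the two images are "
            "indistinguishable; result implausible",
            stacklevel=2,
        )
    return units


def _usable_levels(profile, sigma_margin: float = 2.0, n_min: int = 30) -> np.ndarray:
    """Levels whose variance is informative about gain.

    Levels within ``sigma_margin`` standard deviations of either clipping
    threshold are excluded — there the variance collapses and reflects
    clipping, not the PMT.
    """
    k = profile.levels.astype(float)
    var = profile.variance
    with np.errstate(invalid="ignore"):
        sd = np.sqrt(var)
        good = (
            (profile.n >= n_min)
            & np.isfinite(var)
            & (var > 0)
            & (k - sigma_margin * sd > 0)
            & (k + sigma_margin * sd < profile.c_a)
        )
    return np.flatnonzero(good)


def calibrate_gain(
    stack: ScanStack,
    reference: ReferenceNoiseTable,
    shift_min: float = -150.0,
    shift_max: float = 350.0,
    step: float = 5.0,
    min_overlap: int = 10,
) -> float:
    """Additive gain shift aligning a zero-offset stack with the reference.

    The shift Delta minimizing the sum of squared differences between the
    stack's log noise profile and the reference interpolated at
    ``gain_V + Delta`` (over shared unclipped intensity levels) is found
    by grid search with the given ``step``, then refined locally.
    """
    if stack.config.offset_units != 0:
        raise CalibrationError("gain calibration requires a zero-offset stack")
    profile = noise_profile(stack)
    levels = _usable_levels(profile)
    if levels.size == 0:
        raise CalibrationError("no usable intensity levels in the stack")
    obs = profile.log_variance()[levels]
    gain = stack.config.gain_V
    ref_lo, ref_hi = reference.gain_range

    def sse(delta: float) -> float:
        g = gain + delta
        if not (ref_lo <= g <= ref_hi):
            return np.inf
        ref = reference.interpolate(g)
        shared = np.intersect1d(levels, ref.index.to_numpy())
        if shared.size < min_overlap:
            return np.inf
        diff = profile.log_variance()[shared] - ref.loc[shared].to_numpy()
        return float(np.mean(diff**2))

    grid = np.arange(shift_min, shift_max + 0.5 * step, step)
    scores = np.array([sse(d) for d in grid])
    if not np.any(np.isfinite(scores)):
        raise CalibrationError(
            "no overlap between the stack's levels and the reference table"
        )
    best = grid[int(np.argmin(scores))]
    res = minimize_scalar(
        sse, bounds=(max(best - step, shift_min), min(best + step, shift_max)),
        method="bounded", options={"xatol": 0.05},
    )
    return float(res.x) if np.isfinite(res.fun) else float(best)


def standardize(
    gain_V: float, offset_pct: float, record: CalibrationRecord
) -> tuple[float, float]:
    """(standardized gain in V, offset in intensity units).

    The gain shift is additive and the offset conversion linear, so the
    map is affine and invertible given the record.
    """
    return (
        gain_V + record.gain_shift_V,
        abs(offset_pct) * record.offset_units_per_pct,
    )


def build_reference_table(
    gains=tuple(range(250, 751, 25)),
    base_config: AcquisitionConfig | None = None,
    truth: GroundTruthField | None = None,
    seed: int = 20110804,
    k_step: int = 2,
    n_min: int = 30,
) -> ReferenceNoiseTable:
    """Generate a reference noise table from simulated zero-offset stacks.

    One stack per gain is simulated on an intensity gradient covering the
    full grayscale range; the per-level log variance is tabulated for
    levels far enough from both clipping thresholds.  The table shipped
    with the package (``data/reference_noise.tsv``) was produced by this
    function at the default settings.
    """
    if base_config is None:
        base_config = AcquisitionConfig(offset_pct=0.0)
    if truth is None:
        grad = np.tile(np.linspace(0.0, 255.0, 256), (256, 1))
        truth = GroundTruthField(mu=grad)
    rows = []
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(gains))
    for g, child in zip(gains, children):
        cfg = AcquisitionConfig(
            gain_V=float(g),
            offset_pct=0.0,
            offset_units_per_pct=base_config.offset_units_per_pct,
            n_scans=base_config.n_scans,
            noise_a=base_config.noise_a,
            noise_b=base_config.noise_b,
            g0=base_config.g0,
            c_a=base_config.c_a,
        )
        stack = simulate_scan_stack(truth, cfg, rng=np.random.default_rng(child))
        prof = noise_profile(stack)
        levels = _usable_levels(prof, n_min=n_min)
        levels = levels[levels % k_step == 0]
        logv = prof.log_variance()[levels]
        for k, lv in zip(levels, logv):
            rows.append({"gain_V": float(g), "k": int(k), "log_variance": float(lv)})
    return ReferenceNoiseTable(table=pd.DataFrame(rows))


def load_packaged_reference() -> ReferenceNoiseTable:
    """Load the reference noise table shipped with the package."""
    path = importlib.resources.files("clipcorrect").joinpath(
        "data/reference_noise.tsv"
    )
    with importlib.resources.as_file(path) as p:
        table = pd.read_csv(p, sep="\t", comment="#")
    return ReferenceNoiseTable(table=table)
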