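"""Readers and writers for the package's exchange formats.

Images (frames, averaged images, masks) are 8-bit grayscale TIFF or PNG;
a scan stack is either a list of numbered single-frame files or one
multi-page TIFF.  Tabular artifacts — noise and error profiles,
regression models, calibration records, expression patterns — are
tab-delimited text with ``#`` comment/metadata lines, chosen so that
every file in a pipeline can be inspected and version-controlled.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .calibration import CalibrationRecord, ReferenceNoiseTable
from .censored import PixelErrorProfile
from .exceptions import FormatError, InsufficientDataError
from .regression import PerIntensityErrorRegression
from .simulate import AcquisitionConfig, AveragedImage, ScanStack

__all__ = [
    "ScanProtocol",
    "read_image",
    "write_image",
    "read_scan_stack",
    "write_scan_stack",
    "read_pattern",
    "write_pattern",
    "write_profile",
    "read_profile",
    "write_model",
    "read_model",
    "write_calibration",
    "read_calibration",
    "write_reference_table",
    "read_reference_table",
    "read_config",
]

PATTERN_COLUMNS = ["id", "x", "y", "intensity"]


@dataclass(frozen=True)
class ScanProtocol:
    """Acquisition metadata normally found in the microscope's protocol."""

    gain_V: float
    offset_pct: float
    microscope_id: str = "unknown"
    laser: str = "unknown"
    n_scans: int = 8
    offset_units_per_pct: float = 1.0

    def __post_init__(self) -> None:
        if self.gain_V <= 0:
            raise FormatError("gain_V must be > 0")
        if self.n_scans < 2:
            raise FormatError("n_scans must be >= 2")


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------

def read_image(path: str | Path) -> np.ndarray:
    """Read one 8-bit grayscale image (TIFF or PNG)."""
    path = Path(path)
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except Exception as exc:  # decoding failure gets the file named
        raise FormatError(f"cannot decode image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise FormatError(f"{path} is not a single-channel 2-D image")
    if arr.dtype != np.uint8:
        raise FormatError(f"{path} is not 8-bit (dtype {arr.dtype})")
    return arr


def write_image(path: str | Path, image: np.ndarray | AveragedImage) -> None:
    """Write an 8-bit grayscale image; rounds an averaged image."""
    if isinstance(image, AveragedImage):
        image = image.rounded
    image = np.asarray(image)
    if image.dtype != np.uint8:
        if image.min() < 0 or image.max() > 255:
            raise FormatError("image values outside [0, 255]")
        image = np.rint(image).astype(np.uint8)
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image)
    else:
        iio.imwrite(path, image)


def read_scan_stack(
    paths: Sequence[str | Path] | str | Path, protocol: ScanProtocol,
    **config_kwargs,
) -> ScanStack:
    """Assemble a stack from frame files or one multi-page TIFF.

    All frames must decode to 8-bit grayscale images of one shape; the
    offending file is named otherwise.
    """
    if isinstance(paths, (str, Path)):
        arr = tifffile.imread(paths)
        if arr.ndim == 2:
            raise InsufficientDataError(
                f"{paths} holds a single frame; a stack needs >= 2"
            )
        if arr.dtype != np.uint8:
            raise FormatError(f"{paths} is not 8-bit (dtype {arr.dtype})")
        frames = np.asarray(arr)
    else:
        if len(paths) < 2:
            raise InsufficientDataError("a stack needs >= 2 frame files")
        images = []
        shape = None
        for p in paths:
            img = read_image(p)
            if shape is None:
                shape = img.shape
            elif img.shape != shape:
                raise FormatError(
                    f"{p} has shape {img.shape}, expected {shape}"
                )
            images.append(img)
        frames = np.stack(images)
    config = AcquisitionConfig(
        gain_V=protocol.gain_V,
        offset_pct=protocol.offset_pct,
        offset_units_per_pct=protocol.offset_units_per_pct,
        n_scans=frames.shape[0],
        **config_kwargs,
    )
    return ScanStack(frames=frames, config=config, microscope_id=protocol.microscope_id)


def write_scan_stack(stack: ScanStack, target: str | Path, multipage: bool = False):
    """Write frames as numbered TIFFs in a directory, or one multi-page TIFF.

    Returns the list of files written.
    """
    target = Path(target)
    if multipage:
        tifffile.imwrite(target, stack.frames.astype(np.uint8))
        return [target]
    target.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(stack.frames):
        p = target / f"scan_{i:02d}.tif"
        tifffile.imwrite(p, frame.astype(np.uint8))
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# delimited text tables
# ---------------------------------------------------------------------------

def _fmt(x) -> str:
    if isinstance(x, (bool, np.bool_)):
        return str(int(x))
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    return format(float(x), ".10g")


def _write_table(path, df: pd.DataFrame, comments: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for c in comments:
            fh.write(f"# {c}\n" if not c.startswith("#") else f"{c}\n")
        fh.write("\t".join(df.columns) + "\n")
        for row in df.itertuples(index=False):
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def _read_table(path):
    comments = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                comments.append(line.rstrip("\n"))
            else:
                break
    df = pd.read_csv(path, sep="\t", comment="#")
    return df, comments


def read_pattern(path: str | Path, columns: Sequence[str] | None = None) -> pd.DataFrame:
    """Read an expression-pattern table.

    Whitespace- or tab-delimited, ``#`` comments, positional columns
    ``id x y intensity [n_pixels]`` unless ``columns`` overrides the
    mapping.  Comment lines are preserved on ``df.attrs['comments']`` and
    written back by :func:`write_pattern`.  A non-numeric intensity is
    reported with its line number.
    """
    path = Path(path)
    comments = []
    data_rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                comments.append(stripped)
                continue
            data_rows.append((lineno, stripped.split()))
    if not data_rows:
        df = pd.DataFrame(columns=PATTERN_COLUMNS)
        df.attrs["comments"] = comments
        return df
    ncol = len(data_rows[0][1])
    if columns is None:
        if ncol == 4:
            columns = PATTERN_COLUMNS
        elif ncol >= 5:
            columns = PATTERN_COLUMNS + ["n_pixels"] + [
                f"extra{i}" for i in range(ncol - 5)
            ]
        else:
            raise FormatError(
                f"{path}: expected >= 4 columns (id x y intensity), got {ncol}"
            )
    parsed = []
    for lineno, fields in data_rows:
        if len(fields) != len(columns):
            raise FormatError(
                f"{path}:{lineno}: expected {len(columns)} fields, got {len(fields)}"
            )
        row = {}
        for name, value in zip(columns, fields):
            try:
                row[name] = int(value) if name == "id" else float(value)
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric value {value!r} in column "
                    f"{name}"
                ) from exc
        parsed.append(row)
    df = pd.DataFrame(parsed)
    df.attrs["comments"] = comments
    return df


def write_pattern(path: str | Path, pattern: pd.DataFrame) -> None:
    """Write a pattern preserving any comments captured at read time."""
    comments = list(pattern.attrs.get("comments", []))
    with open(path, "w") as fh:
        for c in comments:
            fh.write(c + "\n")
        for row in pattern.itertuples(index=False):
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def write_profile(path, profile: PixelErrorProfile) -> None:
    df = profile.to_frame()
    _write_table(
        path,
        df,
        comments=[f"c_a={profile.c_a}", f"c_b={profile.c_b:.10g}"],
    )


def read_profile(path) -> pd.DataFrame:
    df, _ = _read_table(path)
    return df


def write_model(path, model: PerIntensityErrorRegression) -> None:
    """Persist a fitted regression model as one row per intensity level."""
    df = pd.DataFrame(
        {
            "k": np.arange(model.c_a + 1),
            "beta0": model.coef_[:, 0],
            "beta_offset": model.coef_[:, 1],
            "beta_gain": model.coef_[:, 2],
            "r2": model.r2_,
            "n": model.n_obs_,
            "sign": model.sign_,
            "fitted": model.fitted_levels_.astype(int),
        }
    )
    _write_table(
        path,
        df,
        comments=[
            f"g0={model.g0:.10g}",
            f"n_min={model.n_min}",
            f"ceiling={model.ceiling}",
            f"c_a={model.c_a}",
        ],
    )


def _comment_meta(comments) -> dict:
    meta = {}
    for c in comments:
        body = c.lstrip("# ").strip()
        if "=" in body:
            key, _, value = body.partition("=")
            meta[key.strip()] = value.strip()
    return meta


def read_model(path) -> PerIntensityErrorRegression:
    df, comments = _read_table(path)
    meta = _comment_meta(comments)
    model = PerIntensityErrorRegression(
        g0=float(meta.get("g0", 100.0)),
        n_min=int(meta.get("n_min", 5)),
        ceiling=int(meta.get("ceiling", 250)),
        c_a=int(meta.get("c_a", 255)),
    )
    n_levels = model.c_a + 1
    if len(df) != n_levels:
        raise FormatError(f"{path}: expected {n_levels} rows, got {len(df)}")
    model.coef_ = df[["beta0", "beta_offset", "beta_gain"]].to_numpy(float)
    model.r2_ = df["r2"].to_numpy(float)
    model.n_obs_ = df["n"].to_numpy(int)
    model.sign_ = df["sign"].to_numpy(int)
    model.fitted_levels_ = df["fitted"].to_numpy(int).astype(bool)
    model.coef_se_ = np.full((n_levels, 3), np.nan)
    model.dof_ = np.zeros(n_levels, dtype=int)
    model.unfitted_reason_ = {}
    return model


def write_calibration(path, record: CalibrationRecord) -> None:
    df = pd.DataFrame(
        [
            {
                "microscope_id": record.microscope_id,
                "offset_units_per_pct": record.offset_units_per_pct,
                "gain_shift_V": record.gain_shift_V,
            }
        ]
    )
    with open(path, "w") as fh:
        fh.write("# clipcorrect calibration record\n")
        fh.write("\t".join(df.columns) + "\n")
        row = df.iloc[0]
        fh.write(
            f"{row.microscope_id}\t{_fmt(row.offset_units_per_pct)}\t"
            f"{_fmt(row.gain_shift_V)}\n"
        )


def read_calibration(path) -> CalibrationRecord:
    df, _ = _read_table(path)
    row = df.iloc[0]
    return CalibrationRecord(
        microscope_id=str(row["microscope_id"]),
        offset_units_per_pct=float(row["offset_units_per_pct"]),
        gain_shift_V=float(row["gain_shift_V"]),
    )


def write_reference_table(path, reference: ReferenceNoiseTable) -> None:
    _write_table(
        path,
        reference.table,
        comments=["reference between-scan noise: log variance by gain and level"],
    )


def read_reference_table(path) -> ReferenceNoiseTable:
    df, _ = _read_table(path)
    return ReferenceNoiseTable(table=df)


def read_config(path) -> dict[str, str]:
    """Flat ``key = value`` configuration file; ``#`` comments allowed."""
    out = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            body = line.split("#", 1)[0].strip()
            if not body:
                continue
            if "=" not in body:
                raise FormatError(f"{path}:{lineno}: expected key=value")
            key, _, value = body.partition("=")
            out[key.strip()] = value.strip()
    return out
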