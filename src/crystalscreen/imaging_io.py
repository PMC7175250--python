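"""Calibrated image, plate-manifest and per-crystal-table I/O.

Every downstream stage of the screening pipeline consumes the types defined
here.  Images are single-channel brightfield micrographs (8- or 16-bit TIFF
or PNG) with an explicit spatial calibration in micrometres per pixel; the
instrument's own metadata tags are deliberately ignored because the assay
protocol records the calibration externally.

Concentrations are stored in a single canonical unit, nanomolar, which keeps
the whole screening range (tens of nM to hundreds of µM) in comfortably
exact floating-point territory.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

#: conversion factors from manifest unit strings to the canonical nanomolar
UNIT_TO_NM = {
    "nm": 1.0,
    "um": 1e3,
    "µm": 1e3,
    "μm": 1e3,  # greek mu
    "mm": 1e6,
    "m": 1e9,
}

#: class vocabulary: code -> short name
CLASS_NAMES = {0: "COM", 1: "COD", 2: "nd", 3: "noise"}
CLASS_CODES = tuple(sorted(CLASS_NAMES))

MANIFEST_COLUMNS = [
    "experiment_id",
    "well_id",
    "field_index",
    "compound",
    "concentration",
    "unit",
    "timepoint",
    "image_path",
    "is_control",
]

MIN_SIDE = 64  # px; anything smaller is not a usable field of view


class CalibrationError(ValueError):
    """Raised for a missing or non-physical pixel-size calibration."""


class ManifestError(ValueError):
    """Raised for a malformed plate manifest."""


@dataclass(frozen=True)
class AcquisitionMeta:
    """Identity of one acquired field of view within a screening plate.

    ``concentration_nm`` is the compound concentration in nanomolar;
    control wells (no inhibitor) carry concentration 0 and
    ``is_control=True``.
    """

    experiment_id: str
    well_id: str
    field_index: int
    compound: str
    concentration_nm: float
    timepoint_h: float
    is_control: bool

    def key(self) -> tuple[str, str, int]:
        return (self.experiment_id, self.well_id, self.field_index)


@dataclass
class FieldImage:
    """A calibrated single-channel field of view.

    Parameters
    ----------
    pixels
        2-D array of non-negative intensities, dtype uint8 or uint16.
    pixel_size
        Micrometres per pixel, strictly positive.
    bit_depth
        8 or 16; intensities must lie within the corresponding range.
    meta
        Optional acquisition metadata.
    """

    pixels: np.ndarray
    pixel_size: float
    bit_depth: int = 16
    meta: AcquisitionMeta | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(
                f"FieldImage requires a single-channel 2-D grid, got shape {px.shape}"
            )
        if min(px.shape) < MIN_SIDE:
            raise ValueError(
                f"image sides must be >= {MIN_SIDE} px, got shape {px.shape}"
            )
        if not np.isfinite(self.pixel_size) or self.pixel_size <= 0:
            raise CalibrationError(f"pixel_size must be finite and > 0, got {self.pixel_size}")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if px.min() < 0 or px.max() > 2**self.bit_depth - 1:
            raise ValueError("intensities outside the declared bit-depth range")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def intensity_range(self) -> int:
        return 2**self.bit_depth - 1

    def normalized(self) -> np.ndarray:
        """Intensities rescaled to [0, 1] floats by the bit-depth range."""
        return self.pixels.astype(np.float64) / self.intensity_range


def concentration_to_nm(value: float, unit: str) -> float:
    """Convert a concentration in ``unit`` (nm/µm/mm/m, molar) to nanomolar."""
    key = str(unit).strip().lower()
    if key not in UNIT_TO_NM:
        raise ManifestError(f"unknown concentration unit {unit!r}")
    return float(value) * UNIT_TO_NM[key]


def read_image(path: str | Path, pixel_size: float,
               meta: AcquisitionMeta | None = None) -> FieldImage:
    """Read a single-channel 8/16-bit TIFF or PNG into a :class:`FieldImage`.

    Intensities are preserved losslessly; multi-channel input is rejected
    because the assay uses exactly one brightfield channel.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        px = tifffile.imread(path)
    else:
        px = iio.imread(path)
    px = np.asarray(px)
    if px.ndim == 3 and px.shape[-1] == 1:
        px = px[..., 0]
    if px.ndim != 2:
        raise ValueError(f"{path.name}: expected single-channel image, got shape {px.shape}")
    if px.size == 0:
        raise ValueError(f"{path.name}: empty image")
    if px.dtype == np.uint8:
        depth = 8
    elif px.dtype == np.uint16:
        depth = 16
    else:
        raise ValueError(f"{path.name}: unsupported dtype {px.dtype}, expected uint8/uint16")
    return FieldImage(px, pixel_size=pixel_size, bit_depth=depth, meta=meta)


def write_image(image: FieldImage | np.ndarray, path: str | Path) -> Path:
    """Write an image to TIFF or PNG, preserving dtype exactly."""
    path = Path(path)
    px = image.pixels if isinstance(image, FieldImage) else np.asarray(image)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, px)
    else:
        iio.imwrite(path, px)
    return path


def load_manifest(path: str | Path) -> list[tuple[Path, AcquisitionMeta]]:
    """Load a plate manifest CSV into (image path, metadata) records.

    The schema is experiment_id, well_id, field_index, compound,
    concentration, unit, timepoint, image_path, is_control.  Concentrations
    are converted to nanomolar; duplicate (experiment, well, field) keys and
    control rows with nonzero concentration are rejected.  Row order does
    not matter: records are returned sorted by key.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"experiment_id": str, "well_id": str, "compound": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"manifest missing column(s): {', '.join(missing)}")
    records: list[tuple[Path, AcquisitionMeta]] = []
    for row in df.itertuples(index=False):
        try:
            conc = concentration_to_nm(float(row.concentration), row.unit)
        except (TypeError, ValueError) as exc:
            raise ManifestError(
                f"unparseable concentration {row.concentration!r} {row.unit!r}"
            ) from exc
        is_control = _parse_flag(row.is_control)
        if is_control and conc != 0:
            raise ManifestError(
                f"control row {row.experiment_id}/{row.well_id} has nonzero concentration"
            )
        meta = AcquisitionMeta(
            experiment_id=str(row.experiment_id),
            well_id=str(row.well_id),
            field_index=int(row.field_index),
            compound=str(row.compound),
            concentration_nm=conc,
            timepoint_h=float(row.timepoint),
            is_control=is_control,
        )
        records.append((Path(str(row.image_path)), meta))
    keys = [m.key() for _, m in records]
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise ManifestError(f"duplicate (experiment, well, field) key(s): {dupes}")
    records.sort(key=lambda rec: rec[1].key())
    return records


def _parse_flag(value) -> bool:
    if isinstance(value, str):
        return value.strip().lower() in ("1", "true", "yes")
    return bool(value)


# --- per-crystal tables -----------------------------------------------------

#: identity columns written ahead of the feature block
TABLE_ID_COLUMNS = ["experiment_id", "well_id", "field_index", "segment_id"]


def write_crystal_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a per-crystal table (ids + features + label) to CSV.

    Values round-trip at full float precision.  If a ``label`` column is
    present it must use the 4-class vocabulary {0, 1, 2, 3}.
    """
    path = Path(path)
    if "label" in table.columns and len(table):
        bad = set(np.unique(table["label"])) - set(CLASS_CODES)
        if bad:
            raise ValueError(f"labels outside the class vocabulary {CLASS_CODES}: {sorted(bad)}")
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    return path


def read_crystal_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"experiment_id": str, "well_id": str},
                     float_precision="round_trip")
    if "label" in df.columns:
        df["label"] = df["label"].astype(int)
    return df


def save_overlay(image: FieldImage, label_map: np.ndarray, path: str | Path,
                 labels: dict[int, int] | None = None) -> Path:
    """Write a QC PNG with segment contours colored by class.

    ``labels`` maps segment id -> class code; unlabeled segments are drawn
    in white.  Purely diagnostic output.
    """
    from skimage.segmentation import find_boundaries

    class_colors = {
        0: (230, 60, 60),    # COM, red
        1: (60, 120, 230),   # COD, blue
        2: (240, 180, 40),   # n.d., amber
        3: (150, 150, 150),  # noise, gray
    }
    base = (image.normalized() * 255).astype(np.uint8)
    rgb = np.stack([base] * 3, axis=-1)
    boundaries = find_boundaries(label_map, mode="inner")
    for seg_id in np.unique(label_map):
        if seg_id == 0:
            continue
        color = class_colors.get((labels or {}).get(int(seg_id), -1), (255, 255, 255))
        sel = boundaries & (label_map == seg_id)
        rgb[sel] = color
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, rgb)
    return path
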