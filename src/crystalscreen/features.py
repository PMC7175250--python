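"""Per-crystal descriptors: 6 shape, 5 intensity, 4 texture features.

Shape features come from the segment mask via standard region properties
(equivalent-ellipse axes from the second central moments; perimeter from the
weighted boundary-step estimator), calibrated to micrometres by the pixel
size.  Intensity features are plain statistics of the pixels under the mask.
Texture features are Haralick statistics of a gray-level co-occurrence
matrix (GLCM) computed over the segment's bounding box restricted to the
mask: intensities are quantized to 32 levels over the full bit-depth range
(not per-region min-max, so that a global intensity shift moves the GLCM
predictably), pairs are counted at distance 1 px for the four standard
angles, symmetrized, normalized, and the four angles averaged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skimage.feature import graycoprops
from skimage.measure import regionprops

from .imaging_io import FieldImage
from .segmentation import CrystalSegment

#: canonical order of the 15 descriptors; CSV headers use exactly these names
FEATURE_NAMES = [
    "area",
    "perimeter",
    "major_axis",
    "minor_axis",
    "eccentricity",
    "circularity",
    "mean_intensity",
    "intensity_variance",
    "min_intensity",
    "max_intensity",
    "intensity_spread",
    "glcm_correlation",
    "glcm_contrast",
    "glcm_homogeneity",
    "glcm_energy",
]

GLCM_LEVELS = 32

# distance-1 offsets (row, col) for angles 0, 45, 90, 135 degrees
_GLCM_OFFSETS = [(0, 1), (-1, 1), (-1, 0), (-1, -1)]

#: GLCM feature values of a constant-intensity (or single-pixel) region
_CONSTANT_GLCM = {
    "glcm_correlation": 1.0,
    "glcm_contrast": 0.0,
    "glcm_homogeneity": 1.0,
    "glcm_energy": 1.0,
}


def extract_features(image: FieldImage, label_map: np.ndarray,
                     segment: CrystalSegment) -> dict[str, float]:
    """Feature vector for one segment, as a name -> value mapping."""
    table = extract_all(image, label_map, [segment])
    return {name: float(table.iloc[0][name]) for name in FEATURE_NAMES}


def extract_all(image: FieldImage, label_map: np.ndarray,
                segments: list[CrystalSegment]) -> pd.DataFrame:
    """Feature table (one row per segment, columns = FEATURE_NAMES + segment_id)."""
    if label_map.shape != image.shape:
        raise ValueError("label map shape does not match image")
    ps = image.pixel_size
    rows = []
    wanted = {s.segment_id for s in segments}
    props = {rp.label: rp for rp in regionprops(label_map, intensity_image=image.pixels)}
    for seg in segments:
        rp = props.get(seg.segment_id)
        if rp is None:
            raise ValueError(f"segment {seg.segment_id} not present in label map")
        rows.append(_one_row(rp, image, label_map, ps))
    df = pd.DataFrame(rows)
    df.insert(0, "segment_id", [s.segment_id for s in segments])
    assert set(df["segment_id"]) == wanted
    return df


def _one_row(rp, image: FieldImage, label_map: np.ndarray, ps: float) -> dict[str, float]:
    area_um2 = rp.area * ps**2
    perimeter_um = rp.perimeter * ps
    if perimeter_um > 0:
        circularity = 4.0 * np.pi * area_um2 / perimeter_um**2
    else:
        circularity = 1.0  # single pixel / degenerate: maximally compact
    values = image.pixels[rp.slice][rp.image].astype(np.float64)
    q75, q25 = np.percentile(values, [75, 25])
    row = {
        "area": area_um2,
        "perimeter": perimeter_um,
        "major_axis": rp.axis_major_length * ps,
        "minor_axis": rp.axis_minor_length * ps,
        "eccentricity": rp.eccentricity,
        "circularity": circularity,
        "mean_intensity": values.mean(),
        "intensity_variance": values.var(),
        "min_intensity": values.min(),
        "max_intensity": values.max(),
        "intensity_spread": (q75 - q25) / image.intensity_range,
    }
    row.update(_glcm_features(image.pixels[rp.slice], rp.image, image.intensity_range))
    return row


def masked_glcm(pixels: np.ndarray, mask: np.ndarray, intensity_range: int,
                levels: int = GLCM_LEVELS) -> np.ndarray:
    """Symmetric co-occurrence count matrices restricted to a mask.

    Returns an array of shape (levels, levels, 1, 4): one symmetric count
    matrix per angle (0/45/90/135 degrees, distance 1).  Only pixel pairs
    with both members inside the mask are counted.  Quantization uses the
    full ``intensity_range`` so the matrices are comparable across regions.
    """
    pixels = np.asarray(pixels)
    mask = np.asarray(mask, dtype=bool)
    quant = np.minimum(
        (pixels.astype(np.float64) * levels / (intensity_range + 1)).astype(np.intp),
        levels - 1,
    )
    out = np.zeros((levels, levels, 1, 4), dtype=np.float64)
    for k, (dr, dc) in enumerate(_GLCM_OFFSETS):
        a, b, va, vb = _shifted_pairs(quant, mask, dr, dc)
        valid = va & vb
        if not valid.any():
            continue
        codes = a[valid] * levels + b[valid]
        counts = np.bincount(codes, minlength=levels * levels).reshape(levels, levels)
        out[:, :, 0, k] = counts + counts.T  # symmetric
    return out


def _shifted_pairs(quant, mask, dr, dc):
    h, w = quant.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    a = quant[r0:r1, c0:c1]
    va = mask[r0:r1, c0:c1]
    b = quant[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    vb = mask[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    return a, b, va, vb


def _glcm_features(bbox_pixels: np.ndarray, bbox_mask: np.ndarray,
                   intensity_range: int) -> dict[str, float]:
    glcm = masked_glcm(bbox_pixels, bbox_mask, intensity_range)
    per_angle_total = glcm.sum(axis=(0, 1))[0]
    if not per_angle_total.any():
        return dict(_CONSTANT_GLCM)
    valid = per_angle_total > 0
    # placeholder mass in empty angle slots so graycoprops stays finite;
    # those slots are excluded from the average below
    glcm[0, 0, 0, ~valid] = 1.0
    out = {}
    for prop, name in [
        ("correlation", "glcm_correlation"),
        ("contrast", "glcm_contrast"),
        ("homogeneity", "glcm_homogeneity"),
        ("energy", "glcm_energy"),
    ]:
        vals = graycoprops(glcm, prop)[0]
        out[name] = float(vals[valid].mean())
    return out
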