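"""Cell-assay image readouts: crystal-occupied area and dead-cell counts.

Two quantifications accompany the screening assay.  On DIC images of
confluent renal epithelial monolayers, adherent crystals appear as
high-relief, high-local-contrast objects on a comparatively flat cell
background, so the occupied-area fraction is measured by local-variance
thresholding followed by hole filling.  On red-fluorescence viability
images, dead cells appear as bright compact dots; they are counted as
above-threshold connected components within a dot-size band, with touching
dots split by watershed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import filters, morphology

from .imaging_io import FieldImage
from .segmentation import split_touching


@dataclass
class AdhesionParams:
    """Local-variance texture segmentation of crystal-occupied area.

    ``std_threshold`` is the local standard deviation (as a fraction of the
    bit-depth range) above which a pixel counts as crystal; flat cell
    background sits well below it, crystal relief well above.
    """

    window: int = 7
    std_threshold: float = 0.04
    min_object_px: int = 25


@dataclass
class DotParams:
    """Band-pass bright-dot detection for dead-cell counting."""

    threshold_mode: str = "automatic"   # Otsu; "fixed" uses `threshold`
    threshold: float | None = None
    min_contrast: float = 0.1           # below this dynamic range: blank image
    min_dot_px: int = 4
    max_dot_px: int = 400
    split_min_distance: int = 3


def crystal_occupied_area(image: FieldImage,
                          params: AdhesionParams | None = None) -> float:
    """Fraction of the field covered by adherent crystals, in [0, 1]."""
    params = params or AdhesionParams()
    img = image.normalized()
    mean = ndi.uniform_filter(img, params.window)
    sq = ndi.uniform_filter(img * img, params.window)
    local_std = np.sqrt(np.clip(sq - mean**2, 0, None))
    mask = local_std > params.std_threshold
    mask = morphology.closing(mask, morphology.disk(2))
    mask = ndi.binary_fill_holes(mask)
    # the sliding window flags pixels within window/2 of crystal texture:
    # erode by that margin to recover the true footprint
    mask = morphology.erosion(mask, morphology.disk(params.window // 2))
    labels, _ = ndi.label(mask)
    counts = np.bincount(labels.ravel())
    keep = counts >= params.min_object_px
    keep[0] = False
    return float(keep[labels].mean())


def count_dead_cells(image: FieldImage, params: DotParams | None = None) -> int:
    """Number of red-fluorescent dead-cell dots in the field."""
    params = params or DotParams()
    img = image.normalized()
    if np.ptp(img) < params.min_contrast:
        return 0
    if params.threshold_mode == "fixed":
        thr = float(params.threshold)
    else:
        thr = filters.threshold_otsu(img)
    mask = img > thr
    labels = split_touching(mask, smooth_sigma=0.5,
                            min_distance=params.split_min_distance)
    count = 0
    sizes = np.bincount(labels.ravel())
    for size in sizes[1:]:
        if params.min_dot_px <= size <= params.max_dot_px:
            count += 1
    return int(count)


def summarize_conditions(per_image: pd.DataFrame, value: str,
                         keys: list[str] | None = None) -> pd.DataFrame:
    """Mean and SD of an image-level readout per condition, % of control.

    ``per_image`` needs the condition key columns (default experiment_id,
    compound, concentration_nm) and the readout column; rows with
    concentration 0 are the in-experiment control.  Output adds
    ``normalized_pct`` = condition mean / control mean x 100, computed
    within each experiment.
    """
    keys = keys or ["experiment_id", "compound", "concentration_nm"]
    agg = (per_image.groupby(keys, sort=True)[value]
           .agg(["mean", "std", "count"]).reset_index())
    out = []
    for exp, grp in agg.groupby("experiment_id", sort=True):
        ctrl = grp[grp["concentration_nm"] == 0]
        if len(ctrl) != 1 or ctrl["mean"].iloc[0] == 0:
            raise ValueError(f"experiment {exp}: missing or zero control")
        g = grp.copy()
        g["normalized_pct"] = g["mean"] / ctrl["mean"].iloc[0] * 100.0
        out.append(g)
    return pd.concat(out, ignore_index=True)


# --- synthetic fixtures for the cell assays ---------------------------------

def render_adhesion_field(coverage: float, seed: int = 0, size: int = 256,
                          noise_sd: float = 0.01) -> tuple[FieldImage, float]:
    """DIC-like synthetic field with a known crystal coverage fraction.

    Crystal patches are rendered as high-contrast speckle texture on a flat
    background; returns the image and the realized ground-truth coverage.
    """
    if not 0 <= coverage <= 1:
        raise ValueError("coverage must be in [0, 1]")
    rng = np.random.default_rng(seed)
    img = 0.5 + rng.normal(0, noise_sd, (size, size))
    mask = np.zeros((size, size), dtype=bool)
    if coverage >= 0.999:
        mask[:] = True
    else:
        target = coverage * size * size
        attempts = 0
        while mask.sum() < target and attempts < 10_000:
            r = rng.uniform(4, 12)
            cy, cx = rng.uniform(r, size - r, 2)
            yy, xx = np.ogrid[0:size, 0:size]
            mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
            attempts += 1
    img[mask] = 0.5 + rng.normal(0, 0.12, int(mask.sum()))
    scale = 65535
    px = np.clip(np.round(img * scale), 0, scale).astype(np.uint16)
    return FieldImage(px, pixel_size=0.1, bit_depth=16), float(mask.mean())


def render_dot_field(n_dots: int, seed: int = 0, size: int = 256,
                     dot_sigma: float = 2.0, background: float = 0.05,
                     amplitude: float = 0.6) -> FieldImage:
    """Fluorescence-like field with ``n_dots`` well-separated bright dots."""
    rng = np.random.default_rng(seed)
    img = background + rng.normal(0, 0.005, (size, size))
    margin = int(6 * dot_sigma)
    centers: list[tuple[float, float]] = []
    for _ in range(n_dots):
        for _ in range(5000):
            cy, cx = rng.uniform(margin, size - margin, 2)
            if all((cy - oy) ** 2 + (cx - ox) ** 2 > (8 * dot_sigma) ** 2
                   for oy, ox in centers):
                centers.append((cy, cx))
                break
        else:
            raise RuntimeError(f"cannot place {n_dots} separated dots in {size} px")
    yy, xx = np.mgrid[0:size, 0:size]
    for cy, cx in centers:
        img += amplitude * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * dot_sigma**2))
    scale = 65535
    px = np.clip(np.round(img * scale), 0, scale).astype(np.uint16)
    return FieldImage(px, pixel_size=0.65, bit_depth=16)
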