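"""End-to-end measurement pipeline: segment -> features -> classify -> quantify.

Convenience drivers that string the per-module operations together for a
set of acquired (or generated) fields of view.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .classification import ClassifierModel, classify
from .features import extract_all
from .imaging_io import AcquisitionMeta, FieldImage, read_image
from .quantification import dose_response, normalize_to_control, quantify_wells
from .segmentation import SegmentationParams, segment_crystals


def measure_field(image: FieldImage, model: ClassifierModel,
                  params: SegmentationParams | None = None) -> pd.DataFrame:
    """Per-crystal table (metadata + area + label) for one field of view."""
    label_map, segments = segment_crystals(image, params)
    if not segments:
        return pd.DataFrame()
    feats = extract_all(image, label_map, segments)
    feats["label"] = classify(model, feats)
    meta = image.meta
    if meta is not None:
        feats.insert(0, "experiment_id", meta.experiment_id)
        feats.insert(1, "well_id", meta.well_id)
        feats.insert(2, "field_index", meta.field_index)
        feats.insert(3, "compound", meta.compound)
        feats.insert(4, "concentration_nm", meta.concentration_nm)
    return feats


def measure_fields(fields: list[FieldImage], model: ClassifierModel,
                   params: SegmentationParams | None = None) -> pd.DataFrame:
    """Concatenated per-crystal table over many fields."""
    tables = [measure_field(img, model, params) for img in fields]
    tables = [t for t in tables if len(t)]
    if not tables:
        return pd.DataFrame()
    return pd.concat(tables, ignore_index=True)


def measure_manifest(records: list[tuple[Path, AcquisitionMeta]], pixel_size: float,
                     model: ClassifierModel,
                     params: SegmentationParams | None = None,
                     base_dir: str | Path | None = None) -> pd.DataFrame:
    """Run the pipeline over every image referenced by a loaded manifest."""
    fields = []
    for path, meta in records:
        full = Path(base_dir) / path if base_dir is not None else path
        fields.append(read_image(full, pixel_size=pixel_size, meta=meta))
    return measure_fields(fields, model, params)


def crystals_to_inhibition(crystals: pd.DataFrame, threshold: float = 0.05,
                           com_denominator: str = "total"):
    """Per-crystal table -> per-condition normalization -> MIC results."""
    wells = quantify_wells(crystals)
    normalized = normalize_to_control(wells)
    return dose_response(normalized, threshold=threshold,
                         com_denominator=com_denominator)
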