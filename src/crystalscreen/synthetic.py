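"""Ground-truthed synthetic brightfield crystal scenes and dose series.

The generator emulates the phenomenology of CaOx crystallization imaged in
brightfield: COM crystals as small compact rhomboid/hexagonal polygons
(mean length 10 µm), COD crystals as projections of tetragonal bipyramids —
elongated diamonds with mean length 20 µm, stretched into needles by an
elongation factor under high inhibitor — "not defined" structures as
irregular star-shaped blobs, and background-noise objects as small dark
debris specks plus sub-resolution speckle.  Objects have a dark rim and a
textured mid-gray interior on a bright background, so edge-based
segmentation is the natural solver.  Per-image illumination gradients,
focus blur jitter and sensor noise are on by default to exercise the
robustness concerns of real brightfield acquisition.

Every scene carries an exact instance-level ground truth: the true label
map, class, rasterized pixel area and nominal length of each object.
Generation is fully deterministic for a fixed spec (the seed is part of the
spec): the same spec renders bit-identical images.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import polygon as draw_polygon
from skimage.morphology import disk, erosion

from . import imaging_io
from .imaging_io import AcquisitionMeta, FieldImage
from .features import FEATURE_NAMES, extract_all
from .segmentation import SegmentationParams, segment_crystals

#: class proportions of the annotated training set; COM and COD dominate
TRAINING_PROPORTIONS = {0: 0.40, 1: 0.25, 2: 0.18, 3: 0.17}
TRAINING_N_IMAGES = 13


class PlacementError(RuntimeError):
    """Requested object counts cannot be placed at the overlap setting."""


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic field of view.

    Lengths are in µm; intensity levels and amplitudes are fractions of the
    bit-depth range.  ``cod_elongation`` >= 1 stretches COD crystals along
    their long axis and thins them (the needle phenotype under high
    inhibitor).  The seed is part of the spec: rendering is a pure function
    of the spec.
    """

    height: int = 960
    width: int = 960
    pixel_size: float = 0.32          # µm / px
    bit_depth: int = 16
    n_com: int = 100
    n_cod: int = 30
    n_nd: int = 10
    n_noise: int = 10
    com_length_um: float = 10.0
    com_length_sigma: float = 0.22    # lognormal shape (log-sd)
    cod_length_um: float = 20.0
    cod_length_sigma: float = 0.18
    cod_elongation: float = 1.0
    background_level: float = 0.75
    rim_level: float = 0.30
    interior_level: float = 0.58
    texture_amplitude: float = 0.05
    nd_texture_amplitude: float = 0.11
    illumination_amplitude: float = 0.08
    blur_sigma: float = 0.8
    blur_jitter: float = 0.4
    noise_sd: float = 0.012
    speckle_fraction: float = 3e-4    # sub-resolution speckle pixel density
    overlap_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_com", "n_cod", "n_nd", "n_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.com_length_um <= 0 or self.cod_length_um <= 0:
            raise ValueError("lengths must be > 0")
        if self.cod_elongation < 1:
            raise ValueError("cod_elongation must be >= 1")


@dataclass
class GroundTruth:
    """Exact instance-level truth of a rendered scene.

    ``instances`` has one row per object: instance_id, true_class,
    true_area_px, true_area_um2 (both from the rasterized polygon, so they
    match the label map exactly) and true_length_um.
    """

    label_map: np.ndarray
    instances: pd.DataFrame


def render_scene(spec: SceneSpec) -> tuple[FieldImage, GroundTruth]:
    """Render one brightfield-like field and its ground truth."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    ps = spec.pixel_size

    # object geometry plan: (class, polygon vertices, nominal length µm)
    plan = []
    for _ in range(spec.n_com):
        length = spec.com_length_um * rng.lognormal(-spec.com_length_sigma**2 / 2,
                                                    spec.com_length_sigma)
        plan.append((0, _com_polygon(length / ps, rng), length))
    for _ in range(spec.n_cod):
        length = spec.cod_length_um * rng.lognormal(-spec.cod_length_sigma**2 / 2,
                                                    spec.cod_length_sigma)
        plan.append((1, _cod_polygon(length / ps, spec.cod_elongation, rng),
                     length * spec.cod_elongation))
    for _ in range(spec.n_nd):
        radius = rng.uniform(3.0, 7.5)
        plan.append((2, _star_polygon(radius / ps, rng), 2 * radius))
    for _ in range(spec.n_noise):
        radius = rng.uniform(1.7, 2.7)
        plan.append((3, _star_polygon(radius / ps, rng, jag=0.3), 2 * radius))

    centers = _place(plan, h, w, spec.overlap_prob, rng)

    label_map = np.zeros((h, w), dtype=np.int32)
    img = _background(spec, rng)
    records = []
    for inst_id, ((cls, verts, length), (cy, cx)) in enumerate(zip(plan, centers), start=1):
        rr, cc = draw_polygon(verts[:, 0] + cy, verts[:, 1] + cx, shape=(h, w))
        if len(rr) == 0:
            rr, cc = np.array([int(cy)]), np.array([int(cx)])
        r0, r1 = rr.min(), rr.max() + 1
        c0, c1 = cc.min(), cc.max() + 1
        local = np.zeros((r1 - r0, c1 - c0), dtype=bool)
        local[rr - r0, cc - c0] = True
        label_map[r0:r1, c0:c1][local] = inst_id
        _paint(img[r0:r1, c0:c1], local, cls, spec, rng)
        records.append({
            "instance_id": inst_id,
            "true_class": cls,
            "true_area_px": int(local.sum()),
            "true_area_um2": float(local.sum()) * ps**2,
            "true_length_um": float(length),
        })
    # overlapping objects may have overwritten earlier pixels: refresh areas
    if spec.overlap_prob > 0:
        counts = np.bincount(label_map.ravel(), minlength=len(plan) + 1)
        for rec in records:
            rec["true_area_px"] = int(counts[rec["instance_id"]])
            rec["true_area_um2"] = float(counts[rec["instance_id"]]) * ps**2

    img = _finish(img, spec, rng)
    field = FieldImage(img, pixel_size=ps, bit_depth=spec.bit_depth)
    return field, GroundTruth(label_map=label_map, instances=pd.DataFrame(records))


# --- geometry ---------------------------------------------------------------

def _rotate(verts: np.ndarray, angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return verts @ np.array([[c, -s], [s, c]]).T


def _com_polygon(length_px: float, rng) -> np.ndarray:
    """Compact rhomboid with truncated tips (hexagon-like COM projection)."""
    a = length_px / 2.0
    b = a * rng.uniform(0.55, 0.80)
    t = rng.uniform(0.15, 0.35)  # tip truncation fraction
    verts = np.array([
        (-a * (1 - t), -b * t), (-a * (1 - t), b * t),
        (0, b), (a * (1 - t), b * t),
        (a * (1 - t), -b * t), (0, -b),
    ])[:, ::-1]  # (row, col)
    return _rotate(verts, rng.uniform(0, np.pi))


def _cod_polygon(length_px: float, elongation: float, rng) -> np.ndarray:
    """Elongated diamond: projection of a tetragonal bipyramid."""
    a = length_px * elongation / 2.0
    b = length_px * 0.45 / (2.0 * elongation) * rng.uniform(0.85, 1.15)
    verts = np.array([(-a, 0), (0, b), (a, 0), (0, -b)], dtype=float)
    return _rotate(verts, rng.uniform(0, np.pi))


def _star_polygon(radius_px: float, rng, jag: float = 0.45) -> np.ndarray:
    """Irregular star-shaped blob for debris / undefined structures."""
    k = int(rng.integers(7, 12))
    angles = np.sort(rng.uniform(0, 2 * np.pi, k))
    radii = radius_px * (1 + jag * rng.uniform(-1, 1, k))
    radii = np.maximum(radii, 1.0)
    return np.stack([radii * np.sin(angles), radii * np.cos(angles)], axis=1)


def _bounding_radius(verts: np.ndarray) -> float:
    return float(np.sqrt((verts**2).sum(axis=1)).max())


def _place(plan, h, w, overlap_prob, rng, margin: int = 3,
           max_attempts: int = 1000) -> list[tuple[float, float]]:
    """Non-overlapping center placement by bounding-circle rejection.

    Large objects are placed first (better packing); the returned centers
    are in the original plan order.
    """
    order = sorted(range(len(plan)), key=lambda i: -_bounding_radius(plan[i][1]))
    centers_by_index: dict[int, tuple[float, float]] = {}
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    for i in order:
        cls, verts, _ = plan[i]
        r = _bounding_radius(verts)
        if 2 * r + 2 > min(h, w):
            raise PlacementError(f"object of radius {r:.0f} px does not fit the field")
        allow_overlap = rng.random() < overlap_prob
        for attempt in range(max_attempts):
            cy = rng.uniform(r + 1, h - r - 1)
            cx = rng.uniform(r + 1, w - r - 1)
            if allow_overlap or all(
                (cy - oy) ** 2 + (cx - ox) ** 2 > (r + orad + margin) ** 2
                for (oy, ox), orad in zip(centers, radii)
            ):
                break
        else:
            raise PlacementError(
                f"could not place {len(plan)} objects in a {h}x{w} field "
                f"(stuck after {len(centers)} placements)"
            )
        centers.append((cy, cx))
        radii.append(r)
        centers_by_index[i] = (cy, cx)
    return [centers_by_index[i] for i in range(len(plan))]


# --- appearance -------------------------------------------------------------

def _background(spec: SceneSpec, rng) -> np.ndarray:
    h, w = spec.height, spec.width
    yy, xx = np.mgrid[0:h, 0:w]
    theta = rng.uniform(0, 2 * np.pi)
    ramp = ((yy / h - 0.5) * np.sin(theta) + (xx / w - 0.5) * np.cos(theta))
    return spec.background_level * (1.0 + spec.illumination_amplitude * ramp * 2)


def _paint(img: np.ndarray, mask: np.ndarray, cls: int, spec: SceneSpec, rng) -> None:
    n_inside = int(mask.sum())
    if cls == 3:
        # small dark debris speck, no rim/interior distinction
        level = spec.rim_level + rng.uniform(0.0, 0.15)
        img[mask] = level + rng.normal(0, spec.texture_amplitude, n_inside)
        return
    rim_width = 2
    interior = mask & erosion(mask, disk(rim_width))
    rim = mask & ~interior
    amp = spec.nd_texture_amplitude if cls == 2 else spec.texture_amplitude
    base = spec.interior_level * rng.uniform(0.92, 1.08)
    img[interior] = base + rng.normal(0, amp, int(interior.sum()))
    img[rim] = spec.rim_level * rng.uniform(0.9, 1.1) + rng.normal(
        0, spec.texture_amplitude / 2, int(rim.sum())
    )


def _finish(img: np.ndarray, spec: SceneSpec, rng) -> np.ndarray:
    h, w = img.shape
    n_speckle = int(spec.speckle_fraction * img.size)
    if n_speckle:
        rr = rng.integers(0, h, n_speckle)
        cc = rng.integers(0, w, n_speckle)
        img[rr, cc] += rng.choice([-1.0, 1.0], n_speckle) * rng.uniform(0.05, 0.15, n_speckle)
    sigma = max(spec.blur_sigma + rng.uniform(-1, 1) * spec.blur_jitter, 0.0)
    if sigma:
        img = ndi.gaussian_filter(img, sigma)
    img = img + rng.normal(0, spec.noise_sd, img.shape)
    scale = 2**spec.bit_depth - 1
    return np.clip(np.round(img * scale), 0, scale).astype(
        np.uint16 if spec.bit_depth == 16 else np.uint8
    )


# --- segment <-> ground-truth matching --------------------------------------

def match_segments(label_map: np.ndarray, truth: GroundTruth,
                   min_iou: float = 0.3) -> dict[int, tuple[int, float]]:
    """Assign each segment the class of its best-overlapping true instance.

    Returns segment_id -> (class, IoU with the best instance).  Segments
    overlapping no instance at IoU >= ``min_iou`` are labeled class 3
    (spurious segmentation = background noise), mirroring how spurious
    detections were treated in the annotated training data.
    """
    seg = np.asarray(label_map)
    gt = truth.label_map
    n_seg, n_gt = int(seg.max()), int(gt.max())
    if n_seg == 0:
        return {}
    joint = seg.astype(np.int64) * (n_gt + 1) + gt
    counts = np.bincount(joint.ravel(), minlength=(n_seg + 1) * (n_gt + 1))
    inter = counts.reshape(n_seg + 1, n_gt + 1)
    seg_sizes = inter.sum(axis=1)
    gt_sizes = inter.sum(axis=0)
    gt_class = dict(zip(truth.instances["instance_id"], truth.instances["true_class"]))
    out: dict[int, tuple[int, float]] = {}
    for s in range(1, n_seg + 1):
        best_gt = int(np.argmax(inter[s, 1:])) + 1 if n_gt else 0
        i = inter[s, best_gt] if n_gt else 0
        union = seg_sizes[s] + gt_sizes[best_gt] - i if n_gt else seg_sizes[s]
        iou = i / union if union else 0.0
        if n_gt and iou >= min_iou:
            out[s] = (int(gt_class[best_gt]), float(iou))
        else:
            out[s] = (3, float(iou))
    return out


# --- dose series ------------------------------------------------------------

@dataclass(frozen=True)
class DoseSeriesSpec:
    """A full screening plate for one compound.

    ``concentrations_nm`` is the tested grid; the four effect sequences
    (aligned with it) express the inhibitor's action relative to control:
    ``total_scale`` multiplies expected crystal counts (COM/COD/n.d.),
    ``com_size_scale`` multiplies the COM length, ``com_to_cod_shift``
    moves that fraction of expected COM count to COD (polymorph shift), and
    ``cod_elongation`` stretches COD toward needles.  The layout is the
    assay default: N experiments x (control + grid) x 2 wells x 5 fields.
    """

    compound: str = "inhibitor"
    concentrations_nm: tuple[float, ...] = (100.0, 300.0, 1000.0, 3000.0)
    total_scale: tuple[float, ...] = (0.8, 0.4, 0.02, 0.01)
    com_size_scale: tuple[float, ...] | None = None       # default: all 1
    com_to_cod_shift: tuple[float, ...] | None = None     # default: all 0
    cod_elongation: tuple[float, ...] | None = None       # default: all 1
    n_experiments: int = 3
    wells_per_sample: int = 2
    fields_per_well: int = 5
    timepoint_h: float = 7.0
    base_scene: SceneSpec = field(default_factory=lambda: SceneSpec(
        height=384, width=384, n_com=12, n_cod=4, n_nd=3, n_noise=3))
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.concentrations_nm)
        for name in ("total_scale", "com_size_scale", "com_to_cod_shift", "cod_elongation"):
            val = getattr(self, name)
            if val is not None and len(val) != k:
                raise ValueError(f"{name} must align with the concentration grid")
        if any(not 0 <= s <= 1 for s in self.total_scale):
            raise ValueError("total_scale factors must be in [0, 1]")
        if self.com_to_cod_shift and any(not 0 <= s <= 1 for s in self.com_to_cod_shift):
            raise ValueError("com_to_cod_shift factors must be in [0, 1]")
        if self.cod_elongation and any(e < 1 for e in self.cod_elongation):
            raise ValueError("cod_elongation factors must be >= 1")

    def effects_at(self, idx: int | None) -> tuple[float, float, float, float]:
        """(total_scale, size_scale, shift, elongation) at grid index, control if None."""
        if idx is None:
            return 1.0, 1.0, 0.0, 1.0
        return (
            self.total_scale[idx],
            self.com_size_scale[idx] if self.com_size_scale else 1.0,
            self.com_to_cod_shift[idx] if self.com_to_cod_shift else 0.0,
            self.cod_elongation[idx] if self.cod_elongation else 1.0,
        )


def generate_dose_series(
    spec: DoseSeriesSpec, out_dir: str | Path | None = None
) -> tuple[list[tuple[FieldImage, GroundTruth]], pd.DataFrame]:
    """Generate a full dose-series plate.

    Returns the rendered fields with their ground truths, and a manifest
    table (one row per field, schema of :data:`imaging_io.MANIFEST_COLUMNS`
    plus ``field_id`` and an image path that is filled in when ``out_dir``
    is given, in which case images, the manifest CSV and the ground-truth
    instance table are also written to disk).
    """
    root = np.random.default_rng(spec.seed)
    fields: list[tuple[FieldImage, GroundTruth]] = []
    rows = []
    conditions: list[int | None] = [None] + list(range(len(spec.concentrations_nm)))
    for exp in range(1, spec.n_experiments + 1):
        # per-experiment global variability: crystallization yield differs
        exp_yield = root.uniform(0.8, 1.2)
        for idx in conditions:
            conc = 0.0 if idx is None else float(spec.concentrations_nm[idx])
            scale, size_scale, shift, elong = spec.effects_at(idx)
            for well in range(1, spec.wells_per_sample + 1):
                for fld in range(1, spec.fields_per_well + 1):
                    seed = int(root.integers(0, 2**31 - 1))
                    rng = np.random.default_rng(seed)
                    base = spec.base_scene
                    lam_com = base.n_com * exp_yield * scale
                    lam_cod = base.n_cod * exp_yield * scale
                    lam_nd = base.n_nd * exp_yield * scale
                    n_com_shifted = rng.poisson(lam_com * (1 - shift))
                    scene = replace(
                        base,
                        n_com=int(n_com_shifted),
                        n_cod=int(rng.poisson(lam_cod + lam_com * shift * 0.5)),
                        n_nd=int(rng.poisson(lam_nd)),
                        n_noise=int(rng.poisson(base.n_noise)),
                        com_length_um=base.com_length_um * size_scale,
                        cod_elongation=base.cod_elongation * elong,
                        seed=seed,
                    )
                    image, truth = render_scene(scene)
                    well_id = f"{spec.compound}-c{0 if idx is None else idx + 1}-w{well}"
                    meta = AcquisitionMeta(
                        experiment_id=f"E{exp}",
                        well_id=well_id,
                        field_index=fld,
                        compound=spec.compound if idx is not None else "control",
                        concentration_nm=conc,
                        timepoint_h=spec.timepoint_h,
                        is_control=idx is None,
                    )
                    image.meta = meta
                    fields.append((image, truth))
                    rows.append({
                        "experiment_id": meta.experiment_id,
                        "well_id": meta.well_id,
                        "field_index": fld,
                        "compound": meta.compound,
                        "concentration": conc,
                        "unit": "nm",
                        "timepoint": spec.timepoint_h,
                        "image_path": "",
                        "is_control": meta.is_control,
                    })
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        gt_rows = []
        for i, ((image, truth), row) in enumerate(zip(fields, manifest.to_dict("records"))):
            name = f"{row['experiment_id']}_{row['well_id']}_f{row['field_index']}.tif"
            imaging_io.write_image(image, out / name)
            manifest.loc[i, "image_path"] = name
            inst = truth.instances.copy()
            inst.insert(0, "field_id", name)
            gt_rows.append(inst)
        manifest.to_csv(out / "manifest.csv", index=False)
        pd.concat(gt_rows, ignore_index=True).to_csv(out / "ground_truth.csv", index=False)
    return fields, manifest


def ground_truth_normalized_areas(
    fields: list[tuple[FieldImage, GroundTruth]], manifest: pd.DataFrame
) -> pd.DataFrame:
    """Exact per-condition normalized crystal areas from the ground truth.

    The oracle counterpart of the measurement pipeline: sums true crystal
    areas (classes 0-2) per condition and normalizes to the in-experiment
    control.
    """
    rows = []
    for (image, truth), rec in zip(fields, manifest.to_dict("records")):
        inst = truth.instances
        if len(inst):
            crystal_area = inst.loc[inst["true_class"].isin([0, 1, 2]), "true_area_um2"].sum()
            com_area = inst.loc[inst["true_class"] == 0, "true_area_um2"].sum()
        else:
            crystal_area = com_area = 0.0
        rows.append({
            "experiment_id": rec["experiment_id"],
            "compound": rec["compound"],
            "concentration_nm": float(rec["concentration"]),
            "area": crystal_area,
            "com_area": com_area,
        })
    df = pd.DataFrame(rows)
    agg = df.groupby(["experiment_id", "compound", "concentration_nm"], sort=True).sum(
        numeric_only=True).reset_index()
    out = []
    for exp, grp in agg.groupby("experiment_id"):
        denom = float(grp.loc[grp["concentration_nm"] == 0, "area"].iloc[0])
        g = grp.copy()
        g["normalized_total"] = g["area"] / denom * 100.0
        g["normalized_COM"] = g["com_area"] / denom * 100.0
        out.append(g)
    return pd.concat(out, ignore_index=True)


# --- training fixture -------------------------------------------------------

def make_training_fixture(
    n_crystals: int = 1710,
    seed: int = 1,
    n_images: int = TRAINING_N_IMAGES,
    scene: SceneSpec | None = None,
    params: SegmentationParams | None = None,
) -> pd.DataFrame:
    """Labeled training table emulating the 13-image annotated dataset.

    Renders ``n_images`` scenes under varying illumination and focus,
    totalling ``n_crystals`` ground-truth objects with class imbalance
    toward COM and COD, runs segmentation and feature extraction, and
    attaches ground-truth labels by segment-instance matching (spurious
    segments become class 3).  Returns a table with image_id, segment_id,
    the 15 features, label and the matched IoU.
    """
    if n_crystals < 20:
        raise ValueError("need n_crystals >= 20 for a usable fixture")
    base = scene or SceneSpec()
    params = params or SegmentationParams()
    rng = np.random.default_rng(seed)
    per_image = _split_counts(n_crystals, n_images, TRAINING_PROPORTIONS, rng)
    tables = []
    for i, counts in enumerate(per_image, start=1):
        img_seed = int(rng.integers(0, 2**31 - 1))
        scene_i = replace(
            base,
            n_com=counts[0], n_cod=counts[1], n_nd=counts[2], n_noise=counts[3],
            seed=img_seed,
        )
        image, truth = render_scene(scene_i)
        label_map, segments = segment_crystals(image, params)
        if not segments:
            continue
        feats = extract_all(image, label_map, segments)
        matched = match_segments(label_map, truth)
        feats["label"] = [matched[s.segment_id][0] for s in segments]
        feats["match_iou"] = [matched[s.segment_id][1] for s in segments]
        feats.insert(0, "image_id", f"train-{i:02d}")
        tables.append(feats)
    table = pd.concat(tables, ignore_index=True)
    # segmentation can merge or miss the odd object; top up any class that
    # fell below the downstream CV's per-class minimum with extra scenes
    for attempt in range(20):
        counts = table["label"].value_counts()
        short = [cls for cls in (0, 1, 2, 3) if counts.get(cls, 0) < 5]
        if not short:
            break
        extra_spec = replace(
            base,
            n_com=8 if 0 in short else 0, n_cod=6 if 1 in short else 0,
            n_nd=6 if 2 in short else 0, n_noise=6 if 3 in short else 0,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        image, truth = render_scene(extra_spec)
        label_map, segments = segment_crystals(image, params)
        if not segments:
            continue
        feats = extract_all(image, label_map, segments)
        matched = match_segments(label_map, truth)
        feats["label"] = [matched[s.segment_id][0] for s in segments]
        feats["match_iou"] = [matched[s.segment_id][1] for s in segments]
        feats.insert(0, "image_id", f"train-extra-{attempt}")
        table = pd.concat([table, feats[feats["label"].isin(short)]],
                          ignore_index=True)
    return table


def _split_counts(n_total: int, n_images: int, proportions: dict[int, float],
                  rng, min_per_class: int = 5) -> list[tuple[int, int, int, int]]:
    """Deterministic near-even split of per-class totals across images.

    Every class gets at least ``min_per_class`` objects (the fold count of
    the downstream cross-validation), taken from the largest class.
    """
    totals = {}
    assigned = 0
    for cls in sorted(proportions):
        if cls == max(proportions):
            totals[cls] = n_total - assigned
        else:
            totals[cls] = int(round(n_total * proportions[cls]))
            assigned += totals[cls]
    largest = max(totals, key=totals.get)
    for cls in totals:
        if totals[cls] < min_per_class:
            totals[largest] -= min_per_class - totals[cls]
            totals[cls] = min_per_class
    out = []
    for i in range(n_images):
        counts = []
        for cls in (0, 1, 2, 3):
            base_count = totals[cls] // n_images
            extra = 1 if i < totals[cls] % n_images else 0
            counts.append(base_count + extra)
        out.append(tuple(counts))
    return out
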