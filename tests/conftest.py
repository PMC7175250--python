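"""Shared fixtures: all test inputs are generated programmatically."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import crystalscreen as cs


def noise_free_scene_spec(seed: int, **overrides) -> cs.SceneSpec:
    """A clean, non-touching scene where segmentation should be exact."""
    defaults = dict(
        height=512, width=512, n_com=8, n_cod=3, n_nd=1, n_noise=0,
        noise_sd=0.0, blur_jitter=0.0, blur_sigma=0.8,
        illumination_amplitude=0.0, speckle_fraction=0.0, seed=seed,
    )
    defaults.update(overrides)
    return cs.SceneSpec(**defaults)


@pytest.fixture(scope="session")
def full_training_table() -> pd.DataFrame:
    """The default annotated benchmark fixture: 13 images, >= 1710 crystals."""
    return cs.make_training_fixture(n_crystals=1710, seed=1)


@pytest.fixture(scope="session")
def small_model():
    """A classifier trained on a reduced fixture, for pipeline tests."""
    table = cs.make_training_fixture(n_crystals=400, seed=7)
    model, _ = cs.train(table, seed=7)
    return model


@pytest.fixture()
def uniform_disc_image():
    """A filled disc of radius 20 px at uniform intensity 100."""
    size = 96
    yy, xx = np.mgrid[0:size, 0:size]
    mask = (yy - 48) ** 2 + (xx - 48) ** 2 <= 20**2
    px = np.zeros((size, size), dtype=np.uint16)
    px[mask] = 100
    image = cs.FieldImage(px, pixel_size=1.0, bit_depth=16)
    label_map = mask.astype(np.int32)
    seg = cs.CrystalSegment(
        segment_id=1, pixel_area=int(mask.sum()), area=float(mask.sum()),
        bbox=(28, 28, 69, 69), centroid=(48.0, 48.0),
    )
    return image, label_map, seg


def segment_from_mask(mask: np.ndarray, pixel_size: float = 1.0) -> cs.CrystalSegment:
    rows, cols = np.nonzero(mask)
    return cs.CrystalSegment(
        segment_id=1,
        pixel_area=int(mask.sum()),
        area=float(mask.sum()) * pixel_size**2,
        bbox=(int(rows.min()), int(cols.min()), int(rows.max()) + 1, int(cols.max()) + 1),
        centroid=(float(rows.mean()), float(cols.mean())),
    )


def brute_force_ellipse(mask: np.ndarray) -> tuple[float, float, float]:
    """Independent moment oracle: (major, minor, eccentricity) in px.

    Second central moments of the pixel-center coordinates; the equivalent
    ellipse has axes 4 * sqrt(eigenvalue of the covariance matrix).
    """
    rows, cols = np.nonzero(mask)
    r = rows - rows.mean()
    c = cols - cols.mean()
    n = len(rows)
    cov = np.array([
        [np.sum(r * r) / n, np.sum(r * c) / n],
        [np.sum(r * c) / n, np.sum(c * c) / n],
    ])
    lam = np.sort(np.linalg.eigvalsh(cov))[::-1]
    major = 4.0 * np.sqrt(lam[0])
    minor = 4.0 * np.sqrt(max(lam[1], 0.0))
    ecc = np.sqrt(1.0 - lam[1] / lam[0]) if lam[0] > 0 else 0.0
    return major, minor, ecc
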