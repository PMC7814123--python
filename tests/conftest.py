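"""Shared fixtures and independent oracles for the pixinorm test suite.

The two expensive synthetic studies (the full-size calibration dilution
series and the 16-donor cohort) are session-scoped so every test that
needs them shares one simulation.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import pixinorm as pn
from pixinorm.imaging import PixiConfig, correct_and_invert, crop_borders, pixi_process

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def dense_gaussian_background(img: np.ndarray, sigma: float) -> np.ndarray:
    """Brute-force Gaussian background: explicit sampled kernel, edge
    padding, dense 2-D convolution. Independent of the pipeline's
    separable filtering path."""
    from scipy.signal import convolve2d

    radius = int(4.0 * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=float)
    k1 = np.exp(-(x**2) / (2.0 * sigma**2))
    k1 /= k1.sum()
    kernel = np.outer(k1, k1)
    padded = np.pad(np.asarray(img, dtype=float), radius, mode="edge")
    return convolve2d(padded, kernel, mode="valid")


def reference_pixi(img: np.ndarray, sigma: float, crop: float) -> float:
    """Brute-force total pixel intensity via the dense-convolution oracle."""
    bg = dense_gaussian_background(img, sigma)
    signal = np.clip(bg - img, 0.0, None)
    h, w = signal.shape
    dy, dx = int(np.floor(crop * h)), int(np.floor(crop * w))
    return float(signal[dy : h - dy, dx : w - dx].sum())


def draw_disk(
    shape: tuple[int, int], center: tuple[float, float], radius: float,
    depth: float, background: float = 0.9,
) -> np.ndarray:
    """A flat field with one hard-edged dark disk (value background-depth)."""
    yy, xx = np.indices(shape)
    img = np.full(shape, background, dtype=float)
    mask = (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2
    img[mask] = background - depth
    return img


# ---------------------------------------------------------------------------
# Session-scoped synthetic studies
# ---------------------------------------------------------------------------

SERIES_DENSITIES = pn.synthgen.DEFAULT_SERIES_DENSITIES
SERIES_CROPS = (0.0, 0.05, 0.10, 0.25)


@pytest.fixture(scope="session")
def dilution_series_intensities() -> pd.DataFrame:
    """Full-size dilution series (6 densities x 14 replicates, generator
    defaults, seed 42) quantified at several crop fractions.

    Columns: plated_cells, attached_cells_per_well, crop, intensity.
    """
    series = pn.simulate_dilution_series(n_replicates=14, seed=42)
    rows = []
    for image, truth, plated in series:
        bg = pn.estimate_background(image, 50.0)
        signal = correct_and_invert(image, bg)
        for crop in SERIES_CROPS:
            rows.append(
                {
                    "plated_cells": plated,
                    "attached_cells_per_well": truth.cells_per_well,
                    "crop": crop,
                    "intensity": float(crop_borders(signal, crop).sum()),
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def cohort_pipeline() -> dict:
    """16-donor cohort (counting noise CV 12%, seed 1) run through the
    full imaging -> calibration -> fluxparams -> normstats pipeline."""
    bundle = pn.simulate_cohort(n_donors=16, seed=1, counting_cv=0.12)
    cfg = PixiConfig()
    rows = []
    for (plate, well), image in bundle.images.items():
        res = pixi_process(image, cfg)
        rows.append(
            dict(
                plate_id=plate, well_id=well,
                total_pixel_intensity=res.total_pixel_intensity,
                processed_h=res.processed_height_px,
                processed_w=res.processed_width_px,
                crop_fraction=cfg.crop_fraction,
                background_sigma_px=cfg.background_sigma_px,
            )
        )
    pixi_df = pd.DataFrame(rows)
    curves = pn.fit_plate_curves(pixi_df, bundle.layout)
    intensities = pixi_df.set_index(["plate_id", "well_id"])["total_pixel_intensity"]
    cells_map = {
        (r.plate_id, r.well_id): pn.pixi_cells(
            curves[r.plate_id],
            float(intensities.loc[(r.plate_id, r.well_id)]),
            plate_id=r.plate_id,
        ).cells
        for r in bundle.layout[bundle.layout["role"] == "assay"].itertuples()
    }
    params = pn.extract_all_wells(bundle.rates)
    normalized = pn.normalize_table(params, bundle.layout, cells_map)
    report = pn.build_report(normalized)
    return {
        "bundle": bundle,
        "pixi_df": pixi_df,
        "curves": curves,
        "cells_map": cells_map,
        "normalized": normalized,
        "report": report,
    }


@pytest.fixture
def small_well_spec() -> pn.WellSimSpec:
    """A cheap imaging spec for unit tests (same optics, smaller frame)."""
    return pn.WellSimSpec(
        target_cells=500, seed=7, image_px=(128, 128), plating_cv=0.0
    )


@pytest.fixture
def tiny_bundle(tmp_path):
    """A minimal on-disk simulated bundle for workflow/CLI tests."""
    bundle = pn.simulate_cohort(
        n_donors=3, seed=11, n_assay_wells=4, n_calibration_replicates=3,
        image_px=(128, 128),
    )
    paths = pn.synthgen.write_bundle(bundle, tmp_path / "bundle")
    return bundle, paths
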