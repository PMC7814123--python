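"""Brightfield well-image processing for PIXI normalization.

The PIXI (pixel-intensity) quantification turns a single brightfield image
of the inner-probe area of an XF-plate well into one scalar, the *total
pixel intensity*, that tracks how much of the field is occupied by cells.
Non-adherent cells (PBMCs, monocytes) appear as dark objects on a bright
background, so the pipeline is:

1. estimate a background image with a wide Gaussian low-pass filter,
2. subtract and invert, so that cells become positive signal on a ~zero
   background (negative residuals are clipped),
3. crop a fraction of each border to discard plate-edge artefacts,
4. sum the remaining pixels.

All functions are pure: they never mutate their inputs and hold no state,
so callers may parallelize over wells freely.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "PixiValidationError",
    "WellImage",
    "PixiConfig",
    "PixiResult",
    "estimate_background",
    "correct_and_invert",
    "crop_borders",
    "total_pixel_intensity",
    "pixi_process",
    "load_well_image",
    "process_directory",
    "write_pixi_csv",
    "read_pixi_csv",
]

_WELL_ID_RE = re.compile(r"^[A-H](0[1-9]|1[0-2])$")

#: CSV header for per-well PIXI results.
PIXI_CSV_COLUMNS = [
    "plate_id",
    "well_id",
    "total_pixel_intensity",
    "processed_h",
    "processed_w",
    "crop_fraction",
    "background_sigma_px",
]


class PixiValidationError(ValueError):
    """Raised when an image, grid or configuration violates its contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WellImage:
    """A grayscale image of one well's inner-probe area.

    Pixel values are stored as floats in [0, 1], rescaled from the source
    bit depth by its full-scale maximum (255 or 65535) — never by per-image
    min/max, which would destroy cross-well comparability.
    """

    plate_id: str
    well_id: str
    pixels: np.ndarray  # 2-D float array in [0, 1], row-major, origin top-left
    bit_depth_source: int = 16

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise PixiValidationError(
                f"well image must be a 2-D grid, got ndim={px.ndim}"
            )
        if px.shape[0] < 16 or px.shape[1] < 16:
            raise PixiValidationError(
                f"well image must be at least 16x16 px, got {px.shape}"
            )
        if not np.all(np.isfinite(px)):
            raise PixiValidationError("well image contains non-finite pixels")
        if px.min() < 0.0 or px.max() > 1.0:
            raise PixiValidationError(
                "pixel values must lie in [0, 1]; rescale by the source "
                "bit-depth maximum before constructing a WellImage"
            )
        if not _WELL_ID_RE.match(self.well_id):
            raise PixiValidationError(
                f"well_id {self.well_id!r} does not match the 96-well "
                "pattern (row A-H, column 01-12)"
            )
        if self.bit_depth_source not in (8, 16):
            raise PixiValidationError(
                f"bit_depth_source must be 8 or 16, got {self.bit_depth_source}"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class PixiConfig:
    """Tunable parameters of the PIXI pipeline.

    background_sigma_px
        Scale of the Gaussian low-pass used to estimate the background.
        Default 50 px, roughly ten lymphocyte diameters at a 4x-objective
        pixel pitch of ~1.7 um/px — wide enough that individual cells do
        not survive into the background estimate.
    crop_fraction
        Fraction of each border removed after inversion (default 0.05).
    clip_negative
        Clip pixels brighter than their local background to zero signal.
    """

    background_sigma_px: float = 50.0
    crop_fraction: float = 0.05
    clip_negative: bool = True

    def __post_init__(self) -> None:
        if not self.background_sigma_px > 0:
            raise PixiValidationError(
                f"background_sigma_px must be > 0, got {self.background_sigma_px}"
            )
        if not (0.0 <= self.crop_fraction <= 0.45):
            raise PixiValidationError(
                f"crop_fraction must lie in [0, 0.45], got {self.crop_fraction}"
            )


@dataclass(frozen=True)
class PixiResult:
    """Per-well PIXI quantification output."""

    plate_id: str
    well_id: str
    total_pixel_intensity: float
    processed_height_px: int
    processed_width_px: int
    config_used: PixiConfig = field(default_factory=PixiConfig)


# ---------------------------------------------------------------------------
# Pipeline steps
# ---------------------------------------------------------------------------


def _as_grid(obj: WellImage | np.ndarray) -> np.ndarray:
    if isinstance(obj, WellImage):
        return obj.pixels
    grid = np.asarray(obj, dtype=float)
    if grid.ndim != 2:
        raise PixiValidationError(f"expected a 2-D grid, got ndim={grid.ndim}")
    if not np.all(np.isfinite(grid)):
        raise PixiValidationError("grid contains non-finite values")
    return grid


def estimate_background(image: WellImage | np.ndarray, sigma_px: float) -> np.ndarray:
    """Gaussian low-pass background estimate of a well image.

    Boundary pixels are handled by edge replication so the background does
    not darken toward the frame edge. Returns a grid of identical shape
    with values in [0, 1] (for inputs in [0, 1]).
    """
    if not sigma_px > 0:
        raise PixiValidationError(f"sigma_px must be > 0, got {sigma_px}")
    grid = _as_grid(image)
    return ndimage.gaussian_filter(grid, sigma=sigma_px, mode="nearest")


def correct_and_invert(
    image: WellImage | np.ndarray,
    background: np.ndarray,
    clip_negative: bool = True,
) -> np.ndarray:
    """Background-subtract and invert so dark objects become positive signal.

    Computed as ``background - original`` (subtract-then-negate): a flat
    region maps to ~0 and a cell darker than its local background to a
    positive value, so empty wells score zero and total intensity scales
    with cell-occupied area. With ``clip_negative`` pixels brighter than
    their local background are set to 0.
    """
    grid = _as_grid(image)
    bg = np.asarray(background, dtype=float)
    if bg.shape != grid.shape:
        raise PixiValidationError(
            f"background shape {bg.shape} does not match image shape {grid.shape}"
        )
    signal = bg - grid
    if clip_negative:
        signal = np.clip(signal, 0.0, None)
    return signal


def crop_borders(grid: np.ndarray, fraction: float) -> np.ndarray:
    """Remove ``floor(fraction * dim)`` rows/columns from every border.

    Each side loses the same floored count; with odd dimensions the centre
    keeps the remainder, so the output is always a contiguous sub-grid.
    """
    grid = _as_grid(grid)
    if not (0.0 <= fraction < 0.5):
        raise PixiValidationError(
            f"crop fraction must lie in [0, 0.5), got {fraction} "
            "(0.5 or more would leave an empty image)"
        )
    h, w = grid.shape
    dy = int(np.floor(fraction * h))
    dx = int(np.floor(fraction * w))
    return grid[dy : h - dy, dx : w - dx]


def total_pixel_intensity(grid: np.ndarray, allow_signed: bool = False) -> float:
    """Sum all pixel values of a processed (inverted, cropped) grid."""
    grid = _as_grid(grid)
    if not allow_signed and grid.min() < 0:
        raise PixiValidationError(
            "grid contains negative values; enable clipping upstream "
            "(clip_negative=True) or pass allow_signed=True to sum signed "
            "intensities explicitly"
        )
    return float(grid.sum())


def pixi_process(image: WellImage, config: PixiConfig | None = None) -> PixiResult:
    """Run the four-step PIXI pipeline on one well image."""
    cfg = config or PixiConfig()
    bg = estimate_background(image, cfg.background_sigma_px)
    signal = correct_and_invert(image, bg, clip_negative=cfg.clip_negative)
    cropped = crop_borders(signal, cfg.crop_fraction)
    total = total_pixel_intensity(cropped, allow_signed=not cfg.clip_negative)
    return PixiResult(
        plate_id=image.plate_id,
        well_id=image.well_id,
        total_pixel_intensity=total,
        processed_height_px=cropped.shape[0],
        processed_width_px=cropped.shape[1],
        config_used=cfg,
    )


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def _rescale_raw(raw: np.ndarray) -> tuple[np.ndarray, int]:
    """Rescale integer images by their bit-depth full scale to [0, 1]."""
    if raw.dtype == np.uint8:
        return raw.astype(float) / 255.0, 8
    if raw.dtype == np.uint16:
        return raw.astype(float) / 65535.0, 16
    if np.issubdtype(raw.dtype, np.floating):
        return raw.astype(float), 16
    raise PixiValidationError(
        f"unsupported image dtype {raw.dtype}; expected uint8, uint16 or float"
    )


def parse_image_filename(path: str | Path) -> tuple[str, str]:
    """Parse the ``<plate>_<well>.tif`` filename convention."""
    stem = Path(path).stem
    if "_" not in stem:
        raise PixiValidationError(
            f"cannot parse plate/well from {Path(path).name!r}; expected "
            "'<plate>_<well>' and no layout mapping was given"
        )
    plate_id, well_id = stem.rsplit("_", 1)
    return plate_id, well_id


def load_well_image(
    path: str | Path,
    plate_id: str | None = None,
    well_id: str | None = None,
    page: int | None = None,
) -> WellImage:
    """Load a single-well grayscale TIFF or PNG as a :class:`WellImage`.

    For multi-page TIFFs pass ``page`` to select one well per page.
    Identity defaults to the ``<plate>_<well>`` filename convention.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        raw = tifffile.imread(path, key=page) if page is not None else tifffile.imread(path)
    else:
        import imageio.v3 as iio

        raw = iio.imread(path)
    raw = np.asarray(raw)
    if raw.ndim == 3 and raw.shape[-1] in (3, 4):  # collapse RGB(A) to gray
        raw = raw[..., :3].mean(axis=-1).astype(raw.dtype)
    if raw.ndim == 3 and page is None:
        raise PixiValidationError(
            f"{path.name} is a multi-page image; pass page= to select a well"
        )
    pixels, bit_depth = _rescale_raw(raw)
    if plate_id is None or well_id is None:
        p, w = parse_image_filename(path)
        plate_id = plate_id or p
        well_id = well_id or w
    return WellImage(plate_id=plate_id, well_id=well_id, pixels=pixels,
                     bit_depth_source=bit_depth)


def process_directory(
    images_dir: str | Path,
    config: PixiConfig | None = None,
) -> pd.DataFrame:
    """PIXI-process every TIFF/PNG in a directory (one well per file).

    Returns a DataFrame with the standard per-well result columns, sorted
    by plate and well.
    """
    images_dir = Path(images_dir)
    if not images_dir.is_dir():
        raise FileNotFoundError(f"image directory not found: {images_dir}")
    cfg = config or PixiConfig()
    paths = sorted(
        p for p in images_dir.iterdir()
        if p.suffix.lower() in (".tif", ".tiff", ".png")
    )
    if not paths:
        raise PixiValidationError(f"no TIFF/PNG images found in {images_dir}")
    rows = []
    for p in paths:
        result = pixi_process(load_well_image(p), cfg)
        rows.append(
            {
                "plate_id": result.plate_id,
                "well_id": result.well_id,
                "total_pixel_intensity": result.total_pixel_intensity,
                "processed_h": result.processed_height_px,
                "processed_w": result.processed_width_px,
                "crop_fraction": cfg.crop_fraction,
                "background_sigma_px": cfg.background_sigma_px,
            }
        )
    return (
        pd.DataFrame(rows, columns=PIXI_CSV_COLUMNS)
        .sort_values(["plate_id", "well_id"])
        .reset_index(drop=True)
    )


def write_pixi_csv(results: pd.DataFrame | Iterable[PixiResult], path: str | Path) -> None:
    """Write per-well PIXI results to CSV with the documented header."""
    if not isinstance(results, pd.DataFrame):
        results = pd.DataFrame(
            {
                "plate_id": r.plate_id,
                "well_id": r.well_id,
                "total_pixel_intensity": r.total_pixel_intensity,
                "processed_h": r.processed_height_px,
                "processed_w": r.processed_width_px,
                "crop_fraction": r.config_used.crop_fraction,
                "background_sigma_px": r.config_used.background_sigma_px,
            }
            for r in results
        )
    results.loc[:, PIXI_CSV_COLUMNS].to_csv(path, index=False)


def read_pixi_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(PIXI_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise PixiValidationError(f"PIXI results CSV missing columns: {sorted(missing)}")
    return df
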