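"""Quadratic calibration of total pixel intensity to cell number.

A dilution series of known plated cell counts, imaged on the same plate as
the assay wells, anchors a per-plate second-order polynomial

    cells(I) = c0 + c1 * I + c2 * I**2

fitted by least squares with cell number as the response. Fitting in this
direction makes the intensity-to-cells transform single-valued by
construction (no root selection). Evaluating the curve on an assay well's
total pixel intensity yields its "PIXI-analyzed cell number".

Calibration is per plate (and per donor): a curve refuses to predict for
another plate unless explicitly overridden, because illumination and
plating conditions are plate-specific.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CalibrationError",
    "CalibrationPoint",
    "CalibrationCurve",
    "CellEstimate",
    "fit_calibration",
    "pixi_cells",
    "correlation_r2",
    "curves_to_json",
    "curves_from_json",
    "fit_plate_curves",
]

#: Mild extrapolation window beyond the fitted intensity domain.
EXTRAPOLATION_LOW = 0.8
EXTRAPOLATION_HIGH = 1.2


class CalibrationError(ValueError):
    """Raised for degenerate designs or out-of-domain predictions."""


@dataclass(frozen=True)
class CalibrationPoint:
    """One calibration well: known plated count and measured intensity."""

    well_id: str
    plated_cells: int
    total_pixel_intensity: float

    def __post_init__(self) -> None:
        if self.plated_cells <= 0:
            raise CalibrationError(
                f"plated_cells must be positive, got {self.plated_cells}"
            )
        if not np.isfinite(self.total_pixel_intensity):
            raise CalibrationError("total_pixel_intensity must be finite")


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted per-plate quadratic mapping intensity -> cell number.

    ``fit_r2`` is the coefficient of determination of the quadratic fit;
    ``pearson_r2`` the squared Pearson correlation of plated cells with
    intensity (the linear-association diagnostic). The quadratic nests the
    linear predictor, so ``fit_r2 >= pearson_r2`` always.
    """

    plate_id: str
    c0: float
    c1: float
    c2: float
    intensity_domain: tuple[float, float]
    fit_r2: float
    pearson_r2: float
    n_points: int
    donor: str = ""
    warnings: tuple[str, ...] = field(default_factory=tuple)

    def predict(self, intensity: float) -> float:
        return self.c0 + self.c1 * intensity + self.c2 * intensity**2


@dataclass(frozen=True)
class CellEstimate:
    """A PIXI-analyzed cell number with provenance flags."""

    cells: float
    intensity: float
    plate_id: str
    extrapolated: bool

    def __float__(self) -> float:
        return self.cells


def correlation_r2(x: Sequence[float], y: Sequence[float]) -> float:
    """Squared Pearson product-moment correlation of two equal-length series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise CalibrationError(
            f"x and y must be equal-length 1-D series, got {x.shape} and {y.shape}"
        )
    if x.size < 3:
        raise CalibrationError(f"need at least 3 points, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise CalibrationError("zero variance in x or y; correlation undefined")
    r = stats.pearsonr(x, y).statistic
    return float(r * r)


def fit_calibration(
    points: Sequence[CalibrationPoint],
    plate_id: str = "",
    donor: str = "",
) -> CalibrationCurve:
    """Least-squares quadratic of plated cells on total pixel intensity.

    Requires at least 4 points spanning at least 3 distinct plated-cell
    levels. A quadratic that decreases anywhere on the fitted intensity
    domain is recorded as a warning (not an error): mild edge
    non-monotonicity occurs with noisy replicates and predictions remain
    single-valued.
    """
    if len(points) < 4:
        raise CalibrationError(
            f"need at least 4 calibration points, got {len(points)}"
        )
    cells = np.array([p.plated_cells for p in points], dtype=float)
    intensity = np.array([p.total_pixel_intensity for p in points], dtype=float)
    if len(np.unique(cells)) < 3:
        raise CalibrationError(
            "need at least 3 distinct plated-cell levels for a quadratic fit"
        )
    if np.ptp(intensity) == 0:
        raise CalibrationError(
            "all intensities identical: degenerate design, cannot calibrate"
        )
    # Fit in a scaled intensity variable for conditioning, then unscale.
    scale = intensity.max()
    coef_scaled = np.polynomial.polynomial.polyfit(intensity / scale, cells, 2)
    c0 = float(coef_scaled[0])
    c1 = float(coef_scaled[1] / scale)
    c2 = float(coef_scaled[2] / scale**2)

    pred = c0 + c1 * intensity + c2 * intensity**2
    ss_res = float(np.sum((cells - pred) ** 2))
    ss_tot = float(np.sum((cells - cells.mean()) ** 2))
    fit_r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    pearson_r2 = correlation_r2(cells, intensity)

    i_min, i_max = float(intensity.min()), float(intensity.max())
    warnings: list[str] = []
    # Derivative c1 + 2*c2*I is linear: checking the endpoints suffices.
    if min(c1 + 2 * c2 * i_min, c1 + 2 * c2 * i_max) < 0:
        warnings.append(
            "calibration quadratic is decreasing on part of the fitted "
            f"intensity domain [{i_min:.4g}, {i_max:.4g}]"
        )
    return CalibrationCurve(
        plate_id=plate_id,
        c0=c0,
        c1=c1,
        c2=c2,
        intensity_domain=(i_min, i_max),
        fit_r2=fit_r2,
        pearson_r2=pearson_r2,
        n_points=len(points),
        donor=donor,
        warnings=tuple(warnings),
    )


def pixi_cells(
    curve: CalibrationCurve,
    intensity: float,
    plate_id: str | None = None,
    allow_cross_plate: bool = False,
) -> CellEstimate:
    """Convert a total pixel intensity into a PIXI-analyzed cell number.

    The intensity must fall within a mild extrapolation window of
    [0.8 * I_min, 1.2 * I_max] around the fitted domain; outside the
    domain itself the estimate is flagged ``extrapolated``. Quadratics are
    untrustworthy outside their support, hence the hard window.
    """
    if plate_id is not None and plate_id != curve.plate_id and not allow_cross_plate:
        raise CalibrationError(
            f"curve was fitted on plate {curve.plate_id!r} but intensity is "
            f"from plate {plate_id!r}; pass allow_cross_plate=True to override"
        )
    if not np.isfinite(intensity) or intensity < 0:
        raise CalibrationError(f"intensity must be finite and >= 0, got {intensity}")
    i_min, i_max = curve.intensity_domain
    if not (EXTRAPOLATION_LOW * i_min <= intensity <= EXTRAPOLATION_HIGH * i_max):
        raise CalibrationError(
            f"intensity {intensity:.4g} is outside the calibration window "
            f"[{EXTRAPOLATION_LOW * i_min:.4g}, {EXTRAPOLATION_HIGH * i_max:.4g}] "
            f"for plate {curve.plate_id!r}; re-calibrate with a wider "
            "dilution series"
        )
    cells = curve.predict(intensity)
    if cells <= 0:
        raise CalibrationError(
            f"calibration predicts a non-positive cell number ({cells:.4g}) "
            f"at intensity {intensity:.4g}; the curve is invalid there"
        )
    return CellEstimate(
        cells=float(cells),
        intensity=float(intensity),
        plate_id=curve.plate_id,
        extrapolated=not (i_min <= intensity <= i_max),
    )


# ---------------------------------------------------------------------------
# Table-level helpers and JSON round-trip
# ---------------------------------------------------------------------------


def fit_plate_curves(
    pixi_results: pd.DataFrame,
    layout: pd.DataFrame,
) -> dict[str, CalibrationCurve]:
    """Fit one curve per plate from PIXI results joined to a plate layout.

    ``layout`` columns: plate_id, well_id, donor, plated_cells, role; only
    wells with role == "calibration" enter the fit.
    """
    required = {"plate_id", "well_id", "donor", "plated_cells", "role"}
    missing = required - set(layout.columns)
    if missing:
        raise CalibrationError(f"layout is missing columns: {sorted(missing)}")
    merged = pixi_results.merge(layout, on=["plate_id", "well_id"], how="inner")
    cal = merged[merged["role"] == "calibration"]
    if cal.empty:
        raise CalibrationError(
            "no wells with role == 'calibration' found in the layout"
        )
    curves: dict[str, CalibrationCurve] = {}
    for plate_id, grp in cal.groupby("plate_id", sort=True):
        donors = grp["donor"].unique()
        points = [
            CalibrationPoint(
                well_id=row.well_id,
                plated_cells=int(row.plated_cells),
                total_pixel_intensity=float(row.total_pixel_intensity),
            )
            for row in grp.itertuples()
        ]
        curves[str(plate_id)] = fit_calibration(
            points, plate_id=str(plate_id), donor=",".join(map(str, donors))
        )
    return curves


def curves_to_json(curves: dict[str, CalibrationCurve], path: str | Path) -> None:
    payload = [
        {
            "plate_id": c.plate_id,
            "donor": c.donor,
            "c0": c.c0,
            "c1": c.c1,
            "c2": c.c2,
            "i_min": c.intensity_domain[0],
            "i_max": c.intensity_domain[1],
            "fit_r2": c.fit_r2,
            "pearson_r2": c.pearson_r2,
            "n_points": c.n_points,
            "warnings": list(c.warnings),
        }
        for c in curves.values()
    ]
    Path(path).write_text(json.dumps(payload, indent=2))


def curves_from_json(path: str | Path) -> dict[str, CalibrationCurve]:
    payload = json.loads(Path(path).read_text())
    curves = {}
    for rec in payload:
        curves[rec["plate_id"]] = CalibrationCurve(
            plate_id=rec["plate_id"],
            c0=rec["c0"],
            c1=rec["c1"],
            c2=rec["c2"],
            intensity_domain=(rec["i_min"], rec["i_max"]),
            fit_r2=rec["fit_r2"],
            pearson_r2=rec["pearson_r2"],
            n_points=rec["n_points"],
            donor=rec.get("donor", ""),
            warnings=tuple(rec.get("warnings", ())),
        )
    return curves
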