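"""Synthetic well images and XF rate traces with exact ground truth.

No public datasets exist for brightfield-normalized PBMC flux assays, so
every stage of the pipeline is validated against this generator, which
emulates the two measured modalities:

- **Well images**: a bright, slightly shaded field in which each cell is
  a radially smoothed (cosine-tapered) dark disk. A PBMC-like mixture of
  platelets, lymphocytes and monocytes sets the diameter and darkness
  distributions. Overlapping cells resolve to the darkest value, which
  saturates total intensity at high confluence — the physical reason a
  second-order (rather than linear) calibration is appropriate. Placed
  counts are returned exactly, so calibration error can be benchmarked
  against truth.

- **Rate traces**: per-cycle OCR/ECAR proportional to cell number with
  phase multipliers for FCCP (uncoupling), antimycin A/rotenone
  (non-mitochondrial floor; OCR stays at the floor through the monensin
  phase) and monensin (maximal glycolysis). A density-inhibition term
  makes per-cell ECAR decline at high plating density, reproducing the
  sub-linear glycolytic-rate behaviour seen in crowded wells.

All randomness flows through a single ``numpy`` Generator per call;
identical seeds reproduce outputs bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .fluxparams import (
    GrConfig,
    InjectionScheme,
    RateMeasurement,
    default_scheme,
    glycolytic_rate,
    write_scheme_yaml,
)
from .imaging import WellImage

__all__ = [
    "SynthError",
    "CellPopSpec",
    "WellSimSpec",
    "TraceSimSpec",
    "GroundTruth",
    "default_populations",
    "render_well_image",
    "cells_in_frame",
    "frame_fraction",
    "simulate_xf_trace",
    "trace_truth",
    "simulate_dilution_series",
    "simulate_cohort",
    "write_bundle",
    "WELL_GROWTH_AREA_MM2",
]

#: Growth area of a 96-well assay plate well (mm^2); the imaged frame
#: covers only part of it, so per-well densities are scaled down to
#: in-frame counts via the frame/well area ratio.
WELL_GROWTH_AREA_MM2 = 32.0

#: Reject rendering when the expected cell-covered (union) area exceeds
#: this fraction of the frame: beyond it the darkness map is saturated
#: and the monolayer model is no longer meaningful.
MAX_EXPECTED_COVERAGE = 0.95


class SynthError(ValueError):
    """Raised for simulation specs outside the model's validity."""


@dataclass(frozen=True)
class CellPopSpec:
    """One cell population in the rendered mixture."""

    name: str
    diameter_um: float
    diameter_sd_um: float
    fraction: float
    optical_depth: float  # darkening below background at the cell centre

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction <= 1.0):
            raise SynthError(f"fraction must be in [0,1], got {self.fraction}")
        if not (0.0 < self.optical_depth <= 1.0):
            raise SynthError(
                f"optical_depth must be in (0,1], got {self.optical_depth}"
            )
        if self.diameter_um <= 0 or self.diameter_sd_um < 0:
            raise SynthError("diameters must be positive (sd >= 0)")


def default_populations() -> tuple[CellPopSpec, ...]:
    """A plausible PBMC-like mixture (platelets, lymphocytes, monocytes)."""
    return (
        CellPopSpec("platelet", 2.5, 0.5, 0.20, 0.10),
        CellPopSpec("lymphocyte", 8.0, 1.0, 0.65, 0.35),
        CellPopSpec("monocyte", 16.0, 2.0, 0.15, 0.45),
    )


@dataclass(frozen=True)
class WellSimSpec:
    """Imaging conditions for one simulated well.

    The default frame, 994 x 994 px at 1.7 um/px, approximates a
    4x-objective field over the inner-probe area. ``target_cells`` is the
    intended *in-frame* count; the realized (attached) count is drawn
    with multiplicative plating noise of CV ``plating_cv``.
    """

    target_cells: int
    seed: int = 0
    image_px: tuple[int, int] = (994, 994)
    um_per_px: float = 1.7
    background_level: float = 0.85
    illumination_gradient: float = 0.10  # fractional corner-to-corner shading
    noise_sd: float = 0.01
    plating_cv: float = 0.05

    def __post_init__(self) -> None:
        if self.target_cells <= 0:
            raise SynthError(f"target_cells must be positive, got {self.target_cells}")
        if not (0.0 < self.background_level < 1.0):
            raise SynthError("background_level must lie in (0,1)")
        if self.illumination_gradient < 0 or self.noise_sd < 0 or self.plating_cv < 0:
            raise SynthError("gradient, noise_sd and plating_cv must be >= 0")
        if self.um_per_px <= 0:
            raise SynthError("um_per_px must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """Exact placed counts for one rendered well."""

    attached_cells: int  # total placed in the frame
    per_population: dict[str, int]
    cells_per_well: float  # frame count scaled up by the well/frame area ratio


def frame_fraction(spec: WellSimSpec) -> float:
    """Fraction of the well growth area covered by the imaged frame."""
    h, w = spec.image_px
    frame_mm2 = (h * spec.um_per_px / 1000.0) * (w * spec.um_per_px / 1000.0)
    return frame_mm2 / WELL_GROWTH_AREA_MM2


def cells_in_frame(cells_per_well: float, spec: WellSimSpec) -> int:
    """Expected in-frame cell count for a per-well plating density."""
    return int(round(cells_per_well * frame_fraction(spec)))


def _mean_cell_area_px2(pops: Sequence[CellPopSpec], um_per_px: float) -> float:
    area = 0.0
    for p in pops:
        r_mu = p.diameter_um / 2.0 / um_per_px
        r_sd = p.diameter_sd_um / 2.0 / um_per_px
        area += p.fraction * np.pi * (r_mu**2 + r_sd**2)  # E[pi r^2]
    return area


def render_well_image(
    spec: WellSimSpec,
    pops: Sequence[CellPopSpec] | None = None,
    plate_id: str = "SIM",
    well_id: str = "A01",
) -> tuple[WellImage, GroundTruth]:
    """Render one well image and return it with its exact ground truth."""
    pops = tuple(pops) if pops is not None else default_populations()
    if abs(sum(p.fraction for p in pops) - 1.0) > 1e-9:
        raise SynthError("population fractions must sum to 1")
    h, w = spec.image_px
    rng = np.random.default_rng(spec.seed)

    # Validity check on the *expected union coverage* under uniform
    # placement: 1 - exp(-n * mean_area / frame_area).
    mean_area = _mean_cell_area_px2(pops, spec.um_per_px)
    lam = spec.target_cells * mean_area / (h * w)
    if 1.0 - np.exp(-lam) > MAX_EXPECTED_COVERAGE:
        raise SynthError(
            f"expected cell coverage {100 * (1 - np.exp(-lam)):.1f}% of the "
            f"frame exceeds {100 * MAX_EXPECTED_COVERAGE:.0f}%: "
            "super-confluent, outside the monolayer model's validity"
        )

    if spec.plating_cv > 0:
        attached = int(round(spec.target_cells * (1 + rng.normal(0, spec.plating_cv))))
        attached = max(attached, 0)
    else:
        attached = spec.target_cells
    counts = rng.multinomial(attached, [p.fraction for p in pops])

    darkness = np.zeros((h, w), dtype=np.float64)
    per_pop: dict[str, int] = {}
    for pop, n_pop in zip(pops, counts):
        per_pop[pop.name] = int(n_pop)
        if n_pop == 0:
            continue
        r_mu = pop.diameter_um / 2.0 / spec.um_per_px
        r_sd = pop.diameter_sd_um / 2.0 / spec.um_per_px
        radii = np.clip(rng.normal(r_mu, r_sd, n_pop), 0.3, None)
        radii = np.round(radii * 4) / 4  # quarter-pixel bins to reuse profiles
        xs = rng.uniform(0, w, n_pop)
        ys = rng.uniform(0, h, n_pop)
        for r in np.unique(radii):
            half = int(np.ceil(r)) + 1
            ax = np.arange(-half, half + 1)
            dist = np.hypot(*np.meshgrid(ax, ax))
            # Cosine-tapered disk: full depth at centre, zero at radius r.
            profile = pop.optical_depth * 0.5 * (
                1.0 + np.cos(np.pi * np.minimum(dist / r, 1.0))
            )
            sel = radii == r
            for x, y in zip(xs[sel], ys[sel]):
                cx, cy = int(round(x)), int(round(y))
                y0, y1 = max(cy - half, 0), min(cy + half + 1, h)
                x0, x1 = max(cx - half, 0), min(cx + half + 1, w)
                patch = profile[
                    y0 - (cy - half) : y1 - (cy - half),
                    x0 - (cx - half) : x1 - (cx - half),
                ]
                view = darkness[y0:y1, x0:x1]
                np.maximum(view, patch, out=view)  # darkest value wins

    yy, xx = np.meshgrid(
        np.linspace(0.0, 1.0, h), np.linspace(0.0, 1.0, w), indexing="ij"
    )
    shade = 1.0 - spec.illumination_gradient * (yy + xx) / 2.0
    img = (spec.background_level - darkness) * shade
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, (h, w))
    img = np.clip(img, 0.0, 1.0)

    well = WellImage(plate_id=plate_id, well_id=well_id, pixels=img)
    truth = GroundTruth(
        attached_cells=int(attached),
        per_population=per_pop,
        cells_per_well=attached / frame_fraction(spec),
    )
    return well, truth


# ---------------------------------------------------------------------------
# Rate traces
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TraceSimSpec:
    """Kinetic ground truth for one simulated well, per 1e5 cells.

    Defaults are scaled so a 225k-cell well shows a basal OCR near
    29 pmol/min and a basal ECAR near 6.4 mpH/min, the magnitudes typical
    of resting PBMC assays. ``gr_density_inhibition`` is the fractional
    per-cell ECAR decline per 1e5 cells, emulating crowding-limited
    glycolysis.
    """

    per_cell_ocr: float = 13.0  # pmol/min per 1e5 cells, baseline
    fccp_mult: float = 2.0
    aa_rot_mult: float = 0.15
    per_cell_ecar: float = 3.2  # mpH/min per 1e5 cells, baseline
    monensin_mult: float = 1.8
    gr_density_inhibition: float = 0.05  # per 1e5 cells
    noise_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("per_cell_ocr", "fccp_mult", "aa_rot_mult",
                     "per_cell_ecar", "monensin_mult"):
            if getattr(self, name) <= 0:
                raise SynthError(f"{name} must be positive")
        if self.monensin_mult < 1.0:
            raise SynthError("monensin_mult must be >= 1 (stimulation)")
        if self.gr_density_inhibition < 0 or self.noise_cv < 0:
            raise SynthError("gr_density_inhibition and noise_cv must be >= 0")


#: Phase multipliers applied to the baseline per-cell rates. OCR falls to
#: the non-mitochondrial floor once antimycin A/rotenone are injected and
#: stays there through monensin; ECAR responds only to monensin.
def _phase_multipliers(spec: TraceSimSpec, phase: str) -> tuple[float, float]:
    ocr = {
        "baseline": 1.0,
        "fccp": spec.fccp_mult,
        "aa_rot": spec.aa_rot_mult,
        "monensin": spec.aa_rot_mult,
    }.get(phase, 1.0)
    ecar = spec.monensin_mult if phase == "monensin" else 1.0
    return ocr, ecar


def _density_factor(cells: float, spec: TraceSimSpec) -> float:
    factor = 1.0 - spec.gr_density_inhibition * cells / 1e5
    if factor <= 0:
        raise SynthError(
            f"gr_density_inhibition {spec.gr_density_inhibition} drives ECAR "
            f"<= 0 at {cells:.0f} cells; lower the inhibition or the density"
        )
    return factor


def simulate_xf_trace(
    cells: float,
    spec: TraceSimSpec,
    scheme: InjectionScheme | None = None,
    well_id: str = "A01",
    rng: np.random.Generator | None = None,
    cycle_min: float = 5.0,
    time_offset_min: float = 0.0,
) -> list[RateMeasurement]:
    """Simulate one well's per-cycle OCR/ECAR trace."""
    if cells <= 0:
        raise SynthError(f"cells must be positive, got {cells}")
    scheme = scheme or default_scheme()
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    density = _density_factor(cells, spec)
    trace = []
    for phase, cycles in scheme.phases:
        ocr_mult, ecar_mult = _phase_multipliers(spec, phase)
        for cycle in cycles:
            ocr_noise = 1.0 + (rng.normal(0, spec.noise_cv) if spec.noise_cv else 0.0)
            ecar_noise = 1.0 + (rng.normal(0, spec.noise_cv) if spec.noise_cv else 0.0)
            ocr = spec.per_cell_ocr * cells / 1e5 * ocr_mult * ocr_noise
            ecar = spec.per_cell_ecar * cells / 1e5 * density * ecar_mult * ecar_noise
            trace.append(
                RateMeasurement(
                    well_id=well_id,
                    cycle=cycle,
                    time_min=time_offset_min + cycle * cycle_min,
                    ocr=ocr,
                    ecar=ecar,
                )
            )
    return trace


def trace_truth(
    cells: float, spec: TraceSimSpec, cfg: GrConfig | None = None
) -> dict[str, float]:
    """Noiseless expected assay parameters for a simulated well."""
    cfg = cfg or GrConfig()
    density = _density_factor(cells, spec)
    basal_ocr = spec.per_cell_ocr * cells / 1e5
    nonmito = basal_ocr * spec.aa_rot_mult
    basal_ecar = spec.per_cell_ecar * cells / 1e5 * density
    return {
        "initial_ocr": basal_ocr,
        "basal_ocr": basal_ocr,
        "uncoupled_ocr": basal_ocr * spec.fccp_mult,
        "nonmito_ocr": nonmito,
        "basal_gr": glycolytic_rate(basal_ecar, basal_ocr - nonmito, cfg),
        "monensin_gr": basal_ecar * spec.monensin_mult,
    }


# ---------------------------------------------------------------------------
# Study-level simulations
# ---------------------------------------------------------------------------

#: The dilution-series densities used to build calibration curves
#: (cells per well).
DEFAULT_SERIES_DENSITIES = (50_000, 100_000, 150_000, 200_000, 250_000, 300_000)


def _well_id(index: int) -> str:
    if not (0 <= index < 96):
        raise SynthError(f"well index {index} outside a 96-well plate")
    return f"{chr(ord('A') + index // 12)}{index % 12 + 1:02d}"


def simulate_dilution_series(
    densities: Sequence[int] = DEFAULT_SERIES_DENSITIES,
    n_replicates: int = 14,
    seed: int = 42,
    base_spec: WellSimSpec | None = None,
    pops: Sequence[CellPopSpec] | None = None,
    plate_id: str = "SIM",
) -> list[tuple[WellImage, GroundTruth, int]]:
    """Render a calibration dilution series.

    Returns one ``(image, truth, plated_cells_per_well)`` triple per well;
    per-well plating densities are converted to in-frame targets through
    the frame/well area ratio. Seeds are derived per well from ``seed``
    for bit-for-bit reproducibility.
    """
    base = base_spec or WellSimSpec(target_cells=1, seed=seed)
    root = np.random.default_rng(seed)
    out = []
    idx = 0
    for density in densities:
        for _ in range(n_replicates):
            spec = replace(
                base,
                target_cells=cells_in_frame(density, base),
                seed=int(root.integers(0, 2**31 - 1)),
            )
            image, truth = render_well_image(
                spec, pops, plate_id=plate_id, well_id=_well_id(idx)
            )
            out.append((image, truth, int(density)))
            idx += 1
    return out


@dataclass(frozen=True)
class SimBundle:
    """All artifacts of a simulated study, ready for the workflow."""

    images: dict[tuple[str, str], WellImage]  # (plate_id, well_id) -> image
    layout: pd.DataFrame
    rates: pd.DataFrame
    scheme: InjectionScheme
    truth: pd.DataFrame


def simulate_cohort(
    n_donors: int = 16,
    seed: int = 0,
    assay_cells: int = 225_000,
    n_assay_wells: int = 8,
    calibration_densities: Sequence[int] = (75_000, 150_000, 225_000, 300_000),
    n_calibration_replicates: int = 4,
    counting_cv: float = 0.12,
    biological_cv: float = 0.12,
    image_px: tuple[int, int] = (256, 256),
    base_well_spec: WellSimSpec | None = None,
    trace_spec: TraceSimSpec | None = None,
    pops: Sequence[CellPopSpec] | None = None,
) -> SimBundle:
    """Simulate a multi-donor study, one plate per donor.

    Each donor's plate carries a volumetrically prepared calibration
    dilution series (densities accurate up to per-well plating noise) and
    a block of assay wells seeded from a counted cell suspension. The
    donor-level counting/seeding error — a single multiplicative factor
    of CV ``counting_cv`` shared by all of that donor's assay wells —
    shifts the cells actually delivered away from the intended density.
    Brightfield images see the delivered cells, so PIXI normalization can
    remove this error; normalizing by the intended count cannot. Donors
    additionally differ biologically (per-cell OCR and ECAR scaled by
    independent factors of CV ``biological_cv``).

    The default 256 x 256 px frame keeps whole-cohort simulation cheap
    while preserving the imaging physics (same pixel pitch and optics as
    the full-size frame).
    """
    if n_donors < 3:
        raise SynthError(f"need >= 3 donors, got {n_donors}")
    root = np.random.default_rng(seed)
    base = base_well_spec or WellSimSpec(target_cells=1, image_px=image_px)
    tspec = trace_spec or TraceSimSpec()
    scheme = default_scheme()

    images: dict[tuple[str, str], WellImage] = {}
    layout_rows, rates_rows, truth_rows = [], [], []
    for d in range(n_donors):
        donor = f"D{d + 1:02d}"
        plate = f"P{d + 1:02d}"
        bias = max(1.0 + root.normal(0, counting_cv), 0.2)
        ocr_scale = max(1.0 + root.normal(0, biological_cv), 0.2)
        ecar_scale = max(1.0 + root.normal(0, biological_cv), 0.2)
        donor_tspec = replace(
            tspec,
            per_cell_ocr=tspec.per_cell_ocr * ocr_scale,
            per_cell_ecar=tspec.per_cell_ecar * ecar_scale,
        )
        trace_rng = np.random.default_rng(root.integers(0, 2**31 - 1))
        idx = 0
        for density in calibration_densities:
            for _ in range(n_calibration_replicates):
                well = _well_id(idx)
                idx += 1
                spec = replace(
                    base,
                    target_cells=cells_in_frame(density, base),
                    seed=int(root.integers(0, 2**31 - 1)),
                )
                image, truth = render_well_image(spec, pops, plate, well)
                images[(plate, well)] = image
                layout_rows.append(
                    dict(plate_id=plate, well_id=well, donor=donor,
                         plated_cells=int(density), role="calibration")
                )
                truth_rows.append(
                    dict(plate_id=plate, well_id=well, donor=donor,
                         role="calibration", intended_cells=int(density),
                         attached_cells_per_well=truth.cells_per_well,
                         donor_bias=1.0)
                )
        for _ in range(n_assay_wells):
            well = _well_id(idx)
            idx += 1
            target_well = assay_cells * bias
            spec = replace(
                base,
                target_cells=cells_in_frame(target_well, base),
                seed=int(root.integers(0, 2**31 - 1)),
            )
            image, truth = render_well_image(spec, pops, plate, well)
            images[(plate, well)] = image
            layout_rows.append(
                dict(plate_id=plate, well_id=well, donor=donor,
                     plated_cells=int(assay_cells), role="assay")
            )
            truth_rows.append(
                dict(plate_id=plate, well_id=well, donor=donor, role="assay",
                     intended_cells=int(assay_cells),
                     attached_cells_per_well=truth.cells_per_well,
                     donor_bias=bias)
            )
            trace = simulate_xf_trace(
                truth.cells_per_well, donor_tspec, scheme,
                well_id=well, rng=trace_rng,
            )
            for m in trace:
                rates_rows.append(
                    dict(plate_id=plate, well_id=m.well_id, cycle=m.cycle,
                         time_min=m.time_min, ocr_pmol_min=m.ocr,
                         ecar_mpH_min=m.ecar)
                )
    return SimBundle(
        images=images,
        layout=pd.DataFrame(layout_rows),
        rates=pd.DataFrame(rates_rows),
        scheme=scheme,
        truth=pd.DataFrame(truth_rows),
    )


def write_bundle(bundle: SimBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write a simulated bundle to disk in the workflow's input formats."""
    import tifffile

    out_dir = Path(out_dir)
    images_dir = out_dir / "images"
    images_dir.mkdir(parents=True, exist_ok=True)
    for (plate, well), image in bundle.images.items():
        raw = np.round(image.pixels * 65535.0).astype(np.uint16)
        tifffile.imwrite(images_dir / f"{plate}_{well}.tif", raw)
    paths = {
        "images": images_dir,
        "layout": out_dir / "layout.csv",
        "rates": out_dir / "rates.csv",
        "scheme": out_dir / "scheme.yaml",
        "truth": out_dir / "ground_truth.csv",
    }
    bundle.layout.to_csv(paths["layout"], index=False)
    bundle.rates.to_csv(paths["rates"], index=False)
    write_scheme_yaml(bundle.scheme, paths["scheme"])
    bundle.truth.to_csv(paths["truth"], index=False)
    return paths
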