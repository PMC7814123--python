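"""Normalization of assay parameters and accuracy/precision statistics.

Raw per-well rates scale with the number of cells actually present, so
they are rescaled to a common reference cell number either by the
*standard* route (divide by the intended plated count) or the *PIXI*
route (divide by the image-derived cell number):

    normalized = raw * reference_cells / cells_used

Whether PIXI normalization helps is quantified with replicate-group
statistics:

- accuracy: the mean absolute standard score (z-score) of technical
  replicates within a group — smaller means individual wells predict the
  group mean better;
- precision: the interquartile range of the signed standard scores —
  smaller means replicates scatter less around the group mean;
- between-donor spread: the coefficient of variation (CV) of donor-level
  means, and the percentage by which each donor moved closer to the group
  mean under PIXI normalization.

Conventions used throughout: sample (n-1) standard deviation; quartiles
by linear interpolation between order statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NormStatsError",
    "ReplicateGroup",
    "AccuracyPrecisionSummary",
    "ImprovementRecord",
    "DonorImprovement",
    "DEFAULT_REFERENCE_CELLS",
    "normalize_rate",
    "normalize_table",
    "cv_percent",
    "standard_scores",
    "score_summary",
    "donor_improvement",
]

#: Default reference cell number (the standard assay plating density).
DEFAULT_REFERENCE_CELLS = 225_000

#: Threshold (in %) above which a donor counts as meaningfully improved/worsened.
IMPROVEMENT_THRESHOLD_PCT = 5.0


class NormStatsError(ValueError):
    """Raised for degenerate replicate groups or mismatched inputs."""


@dataclass(frozen=True)
class ReplicateGroup:
    """Technical replicates of one parameter for one donor and density."""

    donor: str
    density_level: int
    parameter_name: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) < 3:
            raise NormStatsError(
                f"replicate group ({self.donor}, {self.density_level}, "
                f"{self.parameter_name}) needs >= 3 values for score "
                f"statistics, got {len(self.values)}"
            )
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))

    @property
    def key(self) -> tuple[str, int]:
        return (self.donor, self.density_level)


@dataclass(frozen=True)
class AccuracyPrecisionSummary:
    """Average |z| and z-IQR before/after normalization, plus effects."""

    parameter_name: str
    avg_abs_standard_score_before: float
    avg_abs_standard_score_after: float
    avg_iqr_before: float
    avg_iqr_after: float
    effect_score: float
    effect_iqr: float
    n_groups: int


@dataclass(frozen=True)
class ImprovementRecord:
    """Per-donor relative distance to the group mean under each method."""

    donor: str
    parameter_name: str
    dist_before: float
    dist_after: float
    pct_closer: float | None  # None when dist_before == 0 (undefined)


@dataclass(frozen=True)
class DonorImprovement:
    """Donor-level improvement records with cohort-level counts."""

    records: tuple[ImprovementRecord, ...]
    n_improved_gt_threshold: int
    n_worsened_gt_threshold: int
    mean_improvement_improvers: float | None
    mean_decline_worseners: float | None
    threshold_pct: float = IMPROVEMENT_THRESHOLD_PCT


# ---------------------------------------------------------------------------
# Elementary statistics
# ---------------------------------------------------------------------------


def normalize_rate(raw: float, cells: float, reference_cells: float) -> float:
    """Rescale a raw rate from ``cells`` to ``reference_cells``."""
    if cells <= 0:
        raise NormStatsError(f"cells must be positive, got {cells}")
    if reference_cells <= 0:
        raise NormStatsError(
            f"reference_cells must be positive, got {reference_cells}"
        )
    return raw * reference_cells / cells


def cv_percent(values: Sequence[float]) -> float:
    """Coefficient of variation in percent: 100 * sample sd / mean."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise NormStatsError(f"CV needs at least 2 values, got {x.size}")
    mean = x.mean()
    if mean == 0:
        raise NormStatsError("CV undefined for zero mean")
    return float(100.0 * x.std(ddof=1) / mean)


def standard_scores(values: Sequence[float]) -> np.ndarray:
    """Signed z-scores (x - mean) / sample sd; mean 0 and sample sd 1."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise NormStatsError(f"standard scores need >= 3 values, got {x.size}")
    sd = x.std(ddof=1)
    if sd == 0:
        raise NormStatsError("standard scores undefined for zero spread")
    return (x - x.mean()) / sd


def _group_stats(group: ReplicateGroup) -> tuple[float, float]:
    z = standard_scores(group.values)
    q25, q75 = np.percentile(z, [25, 75])  # linear interpolation
    return float(np.abs(z).mean()), float(q75 - q25)


# ---------------------------------------------------------------------------
# Replicate-group summaries
# ---------------------------------------------------------------------------


def score_summary(
    groups_before: Sequence[ReplicateGroup],
    groups_after: Sequence[ReplicateGroup],
) -> AccuracyPrecisionSummary:
    """Average per-group mean |z| and z-IQR before vs after normalization.

    ``before``/``after`` groups must cover the same (donor, density) keys
    and a single parameter. Effects are ``after - before``: negative
    values mean the second normalization brought replicates closer to
    their group mean.
    """
    if not groups_before or not groups_after:
        raise NormStatsError("both group lists must be non-empty")
    params = {g.parameter_name for g in groups_before} | {
        g.parameter_name for g in groups_after
    }
    if len(params) != 1:
        raise NormStatsError(
            f"score_summary handles one parameter at a time, got {sorted(params)}"
        )
    before = {g.key: g for g in groups_before}
    after = {g.key: g for g in groups_after}
    if set(before) != set(after):
        unmatched = set(before).symmetric_difference(after)
        raise NormStatsError(
            f"unmatched (donor, density) keys between before and after: "
            f"{sorted(unmatched)}"
        )
    abs_b, iqr_b, abs_a, iqr_a = [], [], [], []
    for key in sorted(before):
        ab, ib = _group_stats(before[key])
        aa, ia = _group_stats(after[key])
        abs_b.append(ab)
        iqr_b.append(ib)
        abs_a.append(aa)
        iqr_a.append(ia)
    avg = lambda v: float(np.mean(v))
    return AccuracyPrecisionSummary(
        parameter_name=params.pop(),
        avg_abs_standard_score_before=avg(abs_b),
        avg_abs_standard_score_after=avg(abs_a),
        avg_iqr_before=avg(iqr_b),
        avg_iqr_after=avg(iqr_a),
        effect_score=avg(abs_a) - avg(abs_b),
        effect_iqr=avg(iqr_a) - avg(iqr_b),
        n_groups=len(before),
    )


def donor_improvement(
    values_std: Mapping[str, float],
    values_pixi: Mapping[str, float],
    parameter_name: str = "",
) -> DonorImprovement:
    """How much closer each donor moved to the group mean under PIXI.

    The two methods shift group means (PIXI rescales every donor), so raw
    distances are not comparable; each donor's absolute deviation is
    scaled by its own method's group mean first:

        rel_dist = |x_d - mean(x)| / mean(x)
        pct_closer = 100 * (rel_std - rel_pixi) / rel_std

    Donors with zero standard-route distance are flagged (pct undefined)
    and excluded from the counts and means.
    """
    if set(values_std) != set(values_pixi):
        raise NormStatsError(
            "donor sets differ between methods: "
            f"{sorted(set(values_std).symmetric_difference(values_pixi))}"
        )
    donors = sorted(values_std)
    if len(donors) < 3:
        raise NormStatsError(f"need >= 3 donors, got {len(donors)}")
    xs = np.array([values_std[d] for d in donors], dtype=float)
    xp = np.array([values_pixi[d] for d in donors], dtype=float)
    if xs.mean() == 0 or xp.mean() == 0:
        raise NormStatsError("group mean is zero; relative distances undefined")
    rel_s = np.abs(xs - xs.mean()) / abs(xs.mean())
    rel_p = np.abs(xp - xp.mean()) / abs(xp.mean())

    records = []
    for d, rs, rp in zip(donors, rel_s, rel_p):
        pct = 100.0 * (rs - rp) / rs if rs > 0 else None
        records.append(
            ImprovementRecord(
                donor=d,
                parameter_name=parameter_name,
                dist_before=float(rs),
                dist_after=float(rp),
                pct_closer=pct,
            )
        )
    pcts = np.array([r.pct_closer for r in records if r.pct_closer is not None])
    improvers = pcts[pcts > 0]
    worseners = pcts[pcts < 0]
    return DonorImprovement(
        records=tuple(records),
        n_improved_gt_threshold=int((pcts > IMPROVEMENT_THRESHOLD_PCT).sum()),
        n_worsened_gt_threshold=int((pcts < -IMPROVEMENT_THRESHOLD_PCT).sum()),
        mean_improvement_improvers=(
            float(improvers.mean()) if improvers.size else None
        ),
        mean_decline_worseners=(
            float(-worseners.mean()) if worseners.size else None
        ),
    )


# ---------------------------------------------------------------------------
# Table-level normalization
# ---------------------------------------------------------------------------


def normalize_table(
    params: pd.DataFrame,
    layout: pd.DataFrame,
    pixi_cells_by_well: Mapping[tuple[str, str], float],
    reference_cells: float = DEFAULT_REFERENCE_CELLS,
    parameter_names: Sequence[str] = (
        "initial_ocr",
        "basal_ocr",
        "uncoupled_ocr",
        "basal_gr",
        "monensin_gr",
    ),
) -> pd.DataFrame:
    """Build the long-format normalized-parameter table.

    ``params`` is the per-well output of flux-parameter extraction (with a
    plate_id column), ``layout`` maps wells to donor/plated_cells/role and
    ``pixi_cells_by_well`` maps (plate_id, well_id) of assay wells to
    their PIXI-analyzed cell numbers. One output row per well, parameter
    and method with columns: plate_id, well_id, donor, density_level,
    parameter, method, raw_value, cells_used, normalized_value.
    """
    merged = params.merge(layout, on=["plate_id", "well_id"], how="inner")
    assay = merged[merged["role"] == "assay"]
    if assay.empty:
        raise NormStatsError("no wells with role == 'assay' in the layout")
    rows = []
    for row in assay.itertuples():
        key = (row.plate_id, row.well_id)
        if key not in pixi_cells_by_well:
            raise NormStatsError(f"no PIXI cell number for assay well {key}")
        cells = {"standard": float(row.plated_cells),
                 "pixi": float(pixi_cells_by_well[key])}
        for param in parameter_names:
            raw = getattr(row, param, None)
            if raw is None or pd.isna(raw):
                continue
            for method, n_cells in cells.items():
                rows.append(
                    {
                        "plate_id": row.plate_id,
                        "well_id": row.well_id,
                        "donor": row.donor,
                        "density_level": int(row.plated_cells),
                        "parameter": param,
                        "method": method,
                        "raw_value": float(raw),
                        "cells_used": n_cells,
                        "normalized_value": normalize_rate(
                            float(raw), n_cells, reference_cells
                        ),
                    }
                )
    return pd.DataFrame(rows)


def replicate_groups_from_table(
    normalized: pd.DataFrame, parameter: str, method: str, min_n: int = 3
) -> list[ReplicateGroup]:
    """Collect (donor, density) replicate groups for one parameter/method."""
    sel = normalized[
        (normalized["parameter"] == parameter) & (normalized["method"] == method)
    ]
    groups = []
    for (donor, density), grp in sel.groupby(["donor", "density_level"], sort=True):
        if len(grp) < min_n:
            continue
        groups.append(
            ReplicateGroup(
                donor=str(donor),
                density_level=int(density),
                parameter_name=parameter,
                values=tuple(grp["normalized_value"]),
            )
        )
    return groups
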