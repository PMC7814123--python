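"""Extraction of XF assay parameters from OCR/ECAR measurement cycles.

A Seahorse-style extracellular-flux run records, per well and per
measurement cycle, an oxygen consumption rate (OCR, pmol O2/min) and an
extracellular acidification rate (ECAR, mpH/min). Serial injections split
the cycles into phases; the default mitochondrial/glycolytic scheme is

    baseline (cycles 1-3) -> FCCP (4-6) -> antimycin A + rotenone (7-9)
    -> monensin (10-12)

and is fully overridable via a YAML scheme file (e.g. for real-time
activation protocols with a concanavalin-A phase).

ECAR mixes glycolytic lactate export with acidification from
mitochondrial CO2. The glycolytic rate (GR) subtracts the CO2
contribution: mitochondrial OCR is converted to a proton-production rate
with the CO2-contribution factor (max H+ per O2, default 0.61) and back
into medium-acidification units through the buffer factor, effective
micro-chamber volume and volume scaling constant:

    GR = ECAR - ccf * mito_OCR / (BF * V_chamber * Kvol)

With the CO2-contribution factor set to 0 the correction is disabled and
GR equals ECAR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FluxError",
    "RateMeasurement",
    "InjectionScheme",
    "GrConfig",
    "AssayParameters",
    "default_scheme",
    "glycolytic_rate",
    "extract_parameters",
    "extract_all_wells",
    "read_rates_csv",
    "read_scheme_yaml",
    "write_scheme_yaml",
    "write_parameters_csv",
]

RATES_CSV_COLUMNS = ["well_id", "cycle", "time_min", "ocr_pmol_min", "ecar_mpH_min"]


class FluxError(ValueError):
    """Raised for malformed traces, schemes or rate configurations."""


@dataclass(frozen=True)
class RateMeasurement:
    """One measurement cycle of one well."""

    well_id: str
    cycle: int
    time_min: float
    ocr: float  # pmol O2/min
    ecar: float  # mpH/min

    def __post_init__(self) -> None:
        if self.cycle < 1:
            raise FluxError(f"cycle index must be >= 1, got {self.cycle}")
        if self.time_min < 0:
            raise FluxError(f"time_min must be >= 0, got {self.time_min}")
        if not (np.isfinite(self.ocr) and np.isfinite(self.ecar)):
            raise FluxError(
                f"non-finite rate in well {self.well_id} cycle {self.cycle}"
            )


@dataclass(frozen=True)
class InjectionScheme:
    """Ordered phases covering cycles 1..N contiguously; baseline first."""

    phases: tuple[tuple[str, range], ...]

    def __post_init__(self) -> None:
        if not self.phases:
            raise FluxError("scheme must contain at least one phase")
        if self.phases[0][0] != "baseline":
            raise FluxError(
                f"first phase must be 'baseline', got {self.phases[0][0]!r}"
            )
        expected_start = 1
        for name, cycles in self.phases:
            if len(cycles) == 0:
                raise FluxError(f"phase {name!r} covers no cycles")
            if cycles.step != 1:
                raise FluxError(f"phase {name!r} cycle range must be contiguous")
            if cycles.start != expected_start:
                raise FluxError(
                    f"phase {name!r} starts at cycle {cycles.start}, expected "
                    f"{expected_start}: phases must be disjoint, contiguous "
                    "and ordered"
                )
            expected_start = cycles.stop

    @property
    def n_cycles(self) -> int:
        return self.phases[-1][1].stop - 1

    def cycles_of(self, phase_name: str) -> range | None:
        for name, cycles in self.phases:
            if name == phase_name:
                return cycles
        return None


def default_scheme() -> InjectionScheme:
    """The 12-cycle mitochondrial/glycolytic scheme (3 cycles per phase)."""
    return InjectionScheme(
        phases=(
            ("baseline", range(1, 4)),
            ("fccp", range(4, 7)),
            ("aa_rot", range(7, 10)),
            ("monensin", range(10, 13)),
        )
    )


@dataclass(frozen=True)
class GrConfig:
    """Constants of the mitochondrial-CO2 correction of ECAR.

    ccf_h_per_o2
        CO2-contribution factor: maximal H+ produced per O2 consumed by
        complete oxidation, default 0.61. Set to 0 to disable the
        correction (GR then equals ECAR).
    buffer_factor_mm_per_ph
        Buffering power of the assay medium, mM H+ per pH unit
        (default 2.60, assay-medium RPMI convention).
    chamber_volume_ul
        Effective measurement micro-chamber volume, uL (default 2.28 for
        a 96-well cartridge).
    kvol
        Dimensionless volume-scaling constant of the transient
        micro-chamber (default 1.60).
    uncoupled_stat
        Summary of the FCCP phase OCR: "max" (uncoupler responses peak
        then decay; default) or "mean".
    """

    ccf_h_per_o2: float = 0.61
    buffer_factor_mm_per_ph: float = 2.60
    chamber_volume_ul: float = 2.28
    kvol: float = 1.60
    uncoupled_stat: str = "max"

    def __post_init__(self) -> None:
        if self.ccf_h_per_o2 < 0:
            raise FluxError(f"ccf_h_per_o2 must be >= 0, got {self.ccf_h_per_o2}")
        for name in ("buffer_factor_mm_per_ph", "chamber_volume_ul", "kvol"):
            if getattr(self, name) <= 0:
                raise FluxError(f"{name} must be positive, got {getattr(self, name)}")
        if self.uncoupled_stat not in ("max", "mean"):
            raise FluxError(
                f"uncoupled_stat must be 'max' or 'mean', got {self.uncoupled_stat!r}"
            )

    @property
    def divisor(self) -> float:
        """BF * V * Kvol: converts pmol H+/min back to mpH/min."""
        return self.buffer_factor_mm_per_ph * self.chamber_volume_ul * self.kvol


@dataclass(frozen=True)
class AssayParameters:
    """Per-well scalars derived from one OCR/ECAR trace.

    ``initial_ocr`` is the cycle-1 OCR; ``basal_ocr`` the baseline-phase
    mean, reported raw (without non-mitochondrial subtraction) —
    ``nonmito_ocr`` is exposed separately so callers can subtract.
    ``monensin_gr`` is None when the scheme has no monensin phase.
    """

    well_id: str
    initial_ocr: float
    basal_ocr: float
    uncoupled_ocr: float
    nonmito_ocr: float
    basal_gr: float
    monensin_gr: float | None = None
    qc_flags: tuple[str, ...] = field(default_factory=tuple)


def glycolytic_rate(ecar: float, mito_ocr: float, cfg: GrConfig) -> float:
    """CO2-corrected glycolytic rate in mpH/min.

    ``mito_ocr`` is the mitochondrial OCR of the same phase (phase OCR
    minus non-mitochondrial OCR), supplied by the caller. Negative
    ``mito_ocr`` is computed as-is; QC flagging is the caller's job.
    """
    if not (np.isfinite(ecar) and np.isfinite(mito_ocr)):
        raise FluxError("ecar and mito_ocr must be finite")
    return ecar - cfg.ccf_h_per_o2 * mito_ocr / cfg.divisor


def _phase_values(
    by_cycle: dict[int, RateMeasurement], cycles: range, attr: str
) -> np.ndarray:
    return np.array([getattr(by_cycle[c], attr) for c in cycles], dtype=float)


def extract_parameters(
    trace: Sequence[RateMeasurement],
    scheme: InjectionScheme | None = None,
    cfg: GrConfig | None = None,
) -> AssayParameters:
    """Derive the five XF assay parameters from one well's trace.

    - initial OCR: cycle-1 OCR;
    - basal OCR: mean OCR of the baseline phase (raw, no subtraction);
    - FCCP-uncoupled OCR: max (or mean, per config) OCR of the FCCP phase;
    - non-mitochondrial OCR: mean OCR of the antimycin/rotenone phase;
    - basal GR: CO2-corrected baseline ECAR, with mito OCR = basal OCR
      minus non-mitochondrial OCR;
    - monensin GR: max per-cycle GR of the monensin phase. Antimycin A and
      rotenone precede monensin in the scheme, so mitochondrial OCR is 0
      there and monensin GR equals the phase's maximal ECAR.
    """
    scheme = scheme or default_scheme()
    cfg = cfg or GrConfig()
    if not trace:
        raise FluxError("empty trace")
    well_id = trace[0].well_id
    by_cycle: dict[int, RateMeasurement] = {}
    for m in trace:
        if m.well_id != well_id:
            raise FluxError(
                f"trace mixes wells {well_id!r} and {m.well_id!r}; extract one "
                "well at a time"
            )
        if m.cycle in by_cycle:
            raise FluxError(f"duplicate cycle {m.cycle} in well {well_id}")
        by_cycle[m.cycle] = m
    missing = [c for c in range(1, scheme.n_cycles + 1) if c not in by_cycle]
    if missing:
        raise FluxError(
            f"well {well_id}: missing cycle(s) {missing} required by the "
            f"{scheme.n_cycles}-cycle scheme"
        )
    times = [by_cycle[c].time_min for c in sorted(by_cycle)]
    if np.any(np.diff(times) <= 0):
        raise FluxError(f"well {well_id}: time_min must be strictly increasing")

    for required in ("baseline", "fccp", "aa_rot"):
        if scheme.cycles_of(required) is None:
            raise FluxError(f"scheme is missing required phase {required!r}")

    initial_ocr = float(by_cycle[1].ocr)
    basal_cycles = scheme.cycles_of("baseline")
    fccp_cycles = scheme.cycles_of("fccp")
    aarot_cycles = scheme.cycles_of("aa_rot")

    basal_ocr = float(_phase_values(by_cycle, basal_cycles, "ocr").mean())
    fccp_ocr = _phase_values(by_cycle, fccp_cycles, "ocr")
    uncoupled_ocr = float(fccp_ocr.max() if cfg.uncoupled_stat == "max" else fccp_ocr.mean())
    nonmito_ocr = float(_phase_values(by_cycle, aarot_cycles, "ocr").mean())

    qc: list[str] = []
    if nonmito_ocr < 0:
        qc.append(f"negative non-mitochondrial OCR ({nonmito_ocr:.3g} pmol/min)")
    basal_mito = basal_ocr - nonmito_ocr
    if basal_mito < 0:
        qc.append(f"negative basal mitochondrial OCR ({basal_mito:.3g} pmol/min)")

    basal_ecar = float(_phase_values(by_cycle, basal_cycles, "ecar").mean())
    basal_gr = glycolytic_rate(basal_ecar, basal_mito, cfg)

    monensin_gr = None
    mon_cycles = scheme.cycles_of("monensin")
    if mon_cycles is not None:
        mon_ecar = _phase_values(by_cycle, mon_cycles, "ecar")
        monensin_gr = float(max(glycolytic_rate(e, 0.0, cfg) for e in mon_ecar))

    return AssayParameters(
        well_id=well_id,
        initial_ocr=initial_ocr,
        basal_ocr=basal_ocr,
        uncoupled_ocr=uncoupled_ocr,
        nonmito_ocr=nonmito_ocr,
        basal_gr=basal_gr,
        monensin_gr=monensin_gr,
        qc_flags=tuple(qc),
    )


# ---------------------------------------------------------------------------
# Table-level processing and file I/O
# ---------------------------------------------------------------------------


def read_rates_csv(
    path: str | Path, column_map: dict[str, str] | None = None
) -> pd.DataFrame:
    """Read a per-well rates table.

    Expected columns: well_id, cycle, time_min, ocr_pmol_min, ecar_mpH_min;
    an optional plate_id column distinguishes multi-plate exports. A
    ``column_map`` of {source_name: standard_name} adapts minimal exports
    of vendor "Rate" tables.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = set(RATES_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise FluxError(f"rates CSV missing columns: {sorted(missing)}")
    return df


def extract_all_wells(
    rates: pd.DataFrame,
    scheme: InjectionScheme | None = None,
    cfg: GrConfig | None = None,
) -> pd.DataFrame:
    """Run :func:`extract_parameters` for every well of a rates table."""
    scheme = scheme or default_scheme()
    cfg = cfg or GrConfig()
    has_plate = "plate_id" in rates.columns
    keys = ["plate_id", "well_id"] if has_plate else ["well_id"]
    rows = []
    for key, grp in rates.groupby(keys, sort=True):
        trace = [
            RateMeasurement(
                well_id=str(row.well_id),
                cycle=int(row.cycle),
                time_min=float(row.time_min),
                ocr=float(row.ocr_pmol_min),
                ecar=float(row.ecar_mpH_min),
            )
            for row in grp.itertuples()
        ]
        params = extract_parameters(trace, scheme, cfg)
        rec = {
            "well_id": params.well_id,
            "initial_ocr": params.initial_ocr,
            "basal_ocr": params.basal_ocr,
            "uncoupled_ocr": params.uncoupled_ocr,
            "nonmito_ocr": params.nonmito_ocr,
            "basal_gr": params.basal_gr,
            "monensin_gr": params.monensin_gr,
            "qc_flags": ";".join(params.qc_flags),
        }
        if has_plate:
            rec = {"plate_id": str(key[0]), **rec}
        rows.append(rec)
    return pd.DataFrame(rows)


def write_parameters_csv(params: pd.DataFrame, path: str | Path) -> None:
    params.to_csv(path, index=False)


def read_scheme_yaml(path: str | Path) -> InjectionScheme:
    """Read an injection scheme from YAML.

    Format: ``phases: [{name: baseline, cycles: [1, 3]}, ...]`` with
    inclusive cycle bounds.
    """
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict) or "phases" not in data:
        raise FluxError(f"scheme YAML {path} must contain a 'phases' list")
    phases = []
    for entry in data["phases"]:
        name = entry["name"]
        lo, hi = entry["cycles"]
        phases.append((str(name), range(int(lo), int(hi) + 1)))
    return InjectionScheme(phases=tuple(phases))


def write_scheme_yaml(scheme: InjectionScheme, path: str | Path) -> None:
    data = {
        "phases": [
            {"name": name, "cycles": [cycles.start, cycles.stop - 1]}
            for name, cycles in scheme.phases
        ]
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
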