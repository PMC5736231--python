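"""CT lesion-measurement tables: reading, summarizing, overlay curves.

The measurement schema is one row per lesion with its three axis diameters,
its offset from the center of a box enclosing the lungs, the diameter of the
airway it touches (empty when it touches none), and the distance from the
lesion boundary to the nearest airway of at least 1, 2, 4 and 6 mm diameter.
Those distances are directly comparable to the simulated off-road distance.
A seeded synthetic generator emulates the schema (calibrated to the study
cohort: 21 lesions, diameters ~10-36 mm, mean 16 mm, median 13 mm) so the
whole comparison stage is testable without patient data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidConfigError

__all__ = [
    "CT_COLUMNS",
    "CT_TOOL_SIZES",
    "CTLesionRecord",
    "CTCohortSummary",
    "read_ct_table",
    "write_ct_table",
    "ct_summary",
    "ct_reachable_curve",
    "ct_offroad_points",
    "synth_ct_table",
    "SynthCTParams",
]

CT_TOOL_SIZES = (1.0, 2.0, 4.0, 6.0)
CT_COLUMNS = ["lesion_id", "dx_mm", "dy_mm", "dz_mm",
              "offset_x_mm", "offset_y_mm", "offset_z_mm",
              "contact_airway_mm",
              "dist_to_1mm", "dist_to_2mm", "dist_to_4mm", "dist_to_6mm"]


@dataclass
class CTLesionRecord:
    lesion_id: str
    dx_mm: float
    dy_mm: float
    dz_mm: float
    offset_mm: Optional[np.ndarray] = None     # from lung-box center
    contact_airway_mm: Optional[float] = None  # None = touches no airway
    dist_to_airway_mm: dict[float, float] = field(default_factory=dict)

    @property
    def mean_diameter_mm(self) -> float:
        return (self.dx_mm + self.dy_mm + self.dz_mm) / 3.0

    def validate(self) -> None:
        if not all(np.isfinite([self.dx_mm, self.dy_mm, self.dz_mm])):
            raise InvalidConfigError(f"{self.lesion_id}: non-finite diameter")
        present = [(t, d) for t, d in sorted(self.dist_to_airway_mm.items())
                   if d is not None and np.isfinite(d)]
        dists = [d for _, d in present]
        if any(b < a - 1e-9 for a, b in zip(dists, dists[1:])):
            raise InvalidConfigError(
                f"{self.lesion_id}: distances must be non-decreasing in airway threshold")


@dataclass
class CTCohortSummary:
    n: int
    min_diameter_mm: float
    max_diameter_mm: float
    mean_diameter_mm: float
    median_diameter_mm: float
    n_touching_airway: int
    contact_diameter_histogram: dict[float, int]


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------

def _read_frame(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        return pd.read_excel(path)
    return pd.read_csv(path, comment="#")


def read_ct_table(path) -> list[CTLesionRecord]:
    """Read a CT measurement table (CSV or spreadsheet).

    Rows whose three axis diameters cannot be parsed are skipped with a
    warning; unknown columns warn; an empty table is an error.  Empty cells
    for contact diameter or distances mean "not measured / no contact".
    """
    df = _read_frame(path)
    if df.empty:
        raise InvalidConfigError(f"{path}: CT table is empty")
    unknown = [c for c in df.columns if c not in CT_COLUMNS]
    if unknown:
        warnings.warn(f"{path}: ignoring unknown columns {unknown}", stacklevel=2)
    records: list[CTLesionRecord] = []
    for i, row in df.iterrows():
        diams = pd.to_numeric(
            pd.Series([row.get("dx_mm"), row.get("dy_mm"), row.get("dz_mm")]),
            errors="coerce")
        if diams.isna().any():
            warnings.warn(f"{path}: row {i} has no parsable diameters; skipped",
                          stacklevel=2)
            continue
        offset = None
        offs = pd.to_numeric(
            pd.Series([row.get("offset_x_mm"), row.get("offset_y_mm"),
                       row.get("offset_z_mm")]), errors="coerce")
        if not offs.isna().any():
            offset = offs.to_numpy(dtype=float)
        contact = pd.to_numeric(pd.Series([row.get("contact_airway_mm")]),
                                errors="coerce").iloc[0]
        dists = {}
        for t in CT_TOOL_SIZES:
            v = pd.to_numeric(pd.Series([row.get(f"dist_to_{t:g}mm")]),
                              errors="coerce").iloc[0]
            if not pd.isna(v):
                dists[t] = float(v)
        rec = CTLesionRecord(
            lesion_id=str(row.get("lesion_id", i)),
            dx_mm=float(diams.iloc[0]), dy_mm=float(diams.iloc[1]),
            dz_mm=float(diams.iloc[2]),
            offset_mm=offset,
            contact_airway_mm=None if pd.isna(contact) else float(contact),
            dist_to_airway_mm=dists,
        )
        rec.validate()
        records.append(rec)
    if not records:
        raise InvalidConfigError(f"{path}: no valid lesion rows")
    return records


def write_ct_table(records: Sequence[CTLesionRecord], path) -> None:
    rows = []
    for r in records:
        off = r.offset_mm if r.offset_mm is not None else [np.nan] * 3
        rows.append({
            "lesion_id": r.lesion_id,
            "dx_mm": r.dx_mm, "dy_mm": r.dy_mm, "dz_mm": r.dz_mm,
            "offset_x_mm": off[0], "offset_y_mm": off[1], "offset_z_mm": off[2],
            "contact_airway_mm": r.contact_airway_mm,
            **{f"dist_to_{t:g}mm": r.dist_to_airway_mm.get(t) for t in CT_TOOL_SIZES},
        })
    pd.DataFrame(rows, columns=CT_COLUMNS).to_csv(path, index=False, float_format="%.9g")


# --------------------------------------------------------------------------
# summaries and curves
# --------------------------------------------------------------------------

def ct_summary(records: Sequence[CTLesionRecord]) -> CTCohortSummary:
    if not records:
        raise InvalidConfigError("need at least one CT record")
    d = np.array([r.mean_diameter_mm for r in records])
    touching = [r for r in records if r.contact_airway_mm is not None]
    hist: dict[float, int] = {}
    for r in touching:
        hist[r.contact_airway_mm] = hist.get(r.contact_airway_mm, 0) + 1
    return CTCohortSummary(
        n=len(records),
        min_diameter_mm=float(d.min()), max_diameter_mm=float(d.max()),
        mean_diameter_mm=float(d.mean()), median_diameter_mm=float(np.median(d)),
        n_touching_airway=len(touching),
        contact_diameter_histogram=dict(sorted(hist.items())),
    )


def ct_reachable_curve(records: Sequence[CTLesionRecord],
                       diameter_bin: tuple[float, float],
                       tool_grid: Sequence[float] = CT_TOOL_SIZES
                       ) -> Optional[pd.DataFrame]:
    """Percent of lesions in the diameter bin whose contact airway is at
    least as wide as each tool (no-contact lesions count as unreachable at
    every tool size).  Returns None for an empty bin."""
    lo, hi = diameter_bin
    if not hi > lo:
        raise InvalidConfigError("diameter bin must have hi > lo")
    in_bin = [r for r in records if lo <= r.mean_diameter_mm <= hi]
    if not in_bin:
        return None
    tools = np.asarray(tool_grid, dtype=float)
    contact = np.array([r.contact_airway_mm if r.contact_airway_mm is not None
                        else -np.inf for r in in_bin])
    pct = [100.0 * float((contact >= t).mean()) for t in tools]
    return pd.DataFrame({"tool_mm": tools, "percent_reachable": pct,
                         "n_lesions": len(in_bin)})


def ct_offroad_points(records: Sequence[CTLesionRecord]) -> pd.DataFrame:
    """Measured lesion-boundary-to-airway distances keyed by tool size, for
    overlay on simulated off-road curves.  A lesion touching an airway at
    least as wide as the tool has off-road 0; otherwise the measured distance
    to the nearest airway of the tool's size is used (NaN if unmeasured)."""
    rows = []
    for r in records:
        for t in CT_TOOL_SIZES:
            if r.contact_airway_mm is not None and r.contact_airway_mm >= t:
                d = 0.0
            else:
                d = r.dist_to_airway_mm.get(t, np.nan)
            rows.append({"lesion_id": r.lesion_id,
                         "lesion_mm": r.mean_diameter_mm,
                         "tool_mm": t, "offroad_mm": d})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# synthetic stand-in tables
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SynthCTParams:
    """Calibration of the synthetic CT cohort (a stand-in for measured data).

    Lesion mean diameters are lognormal truncated to ``diameter_range_mm``;
    the defaults give a truncated distribution with median ~13.5 mm and mean
    ~15.6 mm, the closest a truncated lognormal gets to the measured cohort
    (range ~10-36 mm, mean 16 mm, median 13 mm).  About ``p_contact`` of
    lesions touch an airway, mostly a 1-2 mm one; distances to wider airways
    grow stochastically with the threshold.
    """

    diameter_median_mm: float = 9.0  # untruncated lognormal median
    diameter_sigma: float = 0.74
    diameter_range_mm: tuple[float, float] = (8.0, 40.0)
    p_contact: float = 0.45
    contact_diameters_mm: tuple[float, ...] = (1.0, 2.0, 3.0, 5.0)
    contact_weights: tuple[float, ...] = (0.4, 0.4, 0.1, 0.1)
    base_distance_scale_mm: float = 4.0
    increment_scale_mm: float = 5.0
    offset_halfspan_mm: tuple[float, float, float] = (140.0, 110.0, 80.0)


def synth_ct_table(n: int = 21, seed: int = 0,
                   params: SynthCTParams = SynthCTParams()) -> list[CTLesionRecord]:
    """Generate a synthetic CT measurement table (seed-reproducible)."""
    if n < 1:
        raise InvalidConfigError("n must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = params.diameter_range_mm
    records = []
    for i in range(n):
        d = 0.0
        while not (lo <= d <= hi):
            d = float(rng.lognormal(np.log(params.diameter_median_mm),
                                    params.diameter_sigma))
        e1, e2 = rng.uniform(-0.1, 0.1, size=2)
        dx, dy = d * (1 + e1), d * (1 + e2)
        dz = 3 * d - dx - dy  # keeps the mean of the three axes exactly d
        contact = None
        if rng.random() < params.p_contact:
            contact = float(rng.choice(params.contact_diameters_mm,
                                       p=params.contact_weights))
        dists: dict[float, float] = {}
        prev = 0.0
        for t in CT_TOOL_SIZES:
            if contact is not None and contact >= t:
                dists[t] = 0.0
                continue
            if prev == 0.0:
                prev = float(rng.gamma(2.0, params.base_distance_scale_mm / 2.0))
            else:
                prev = prev + float(rng.gamma(1.5, params.increment_scale_mm / 1.5))
            dists[t] = round(prev, 1)
            prev = dists[t]
        hx, hy, hz = params.offset_halfspan_mm
        offset = np.array([rng.uniform(-hx, hx), rng.uniform(-hy, hy),
                           rng.uniform(-hz, hz)])
        rec = CTLesionRecord(
            lesion_id=f"synthetic-{i + 1}",
            dx_mm=round(dx, 1), dy_mm=round(dy, 1), dz_mm=round(3 * d - dx - dy, 1),
            offset_mm=np.round(offset, 1),
            contact_airway_mm=contact,
            dist_to_airway_mm=dists,
        )
        records.append(rec)
    return records
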