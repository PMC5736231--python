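"""Lesion reachability and off-road distance statistics.

For every sampled lesion center, spheres of diameter 1-50 mm (1 mm steps)
are tested for contact against the airway tree; the *contact profile*
records, per lesion diameter, the largest airway diameter touched.  From the
profiles follow

* the percent-reachable matrix: the share of lesions touching an airway at
  least as wide as the tool, over a tool grid of 1-9 mm (0.5 mm steps), and
* the off-road distance: how far a tool of diameter T must travel through
  parenchyma beyond the wall of the smallest airway it fits in before
  touching the lesion boundary.  On the growing-sphere grid this is
  ``r2 - r1`` where ``r1`` is the lesion radius and ``r2`` the smallest grid
  radius whose contact set reaches diameter >= T; lesions with no qualifying
  contact up to the 25 mm maximum grid radius carry an unreachable marker
  (NaN) and are excluded from summary means, with their count reported.

Reachability uses "airway diameter >= tool diameter" uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .airway_model import AirwayTree
from .errors import InvalidConfigError
from .geometry import TriSurface, capsule_clearances, lesion_airway_contact

__all__ = [
    "LESION_DIAMETER_GRID",
    "TOOL_GRID",
    "SUMMARY_LESION_SIZES",
    "LesionContactProfile",
    "ContactProfileSet",
    "contact_profile",
    "contact_profiles",
    "percent_reachable",
    "ReachabilityTable",
    "offroad_distance",
    "offroad_table",
    "summarize_offroad",
    "place_points_in_model",
]

LESION_DIAMETER_GRID = np.arange(1.0, 51.0, 1.0)       # mm
TOOL_GRID = np.arange(1.0, 9.01, 0.5)                  # mm
SUMMARY_LESION_SIZES = (10.0, 20.0, 30.0, 40.0, 50.0)  # mm
PLACEMENT_TOOL_SIZES = (1.0, 2.0, 4.0, 6.0)            # mm


@dataclass
class LesionContactProfile:
    """Largest contacted airway diameter per lesion diameter, for one lesion."""

    lesion_id: int
    phase: str
    replicate: int
    lesion_diameters: np.ndarray
    max_contact_diameter: np.ndarray  # NaN where no airway is touched

    def contact_at(self, lesion_diameter: float) -> float:
        i = int(np.searchsorted(self.lesion_diameters, lesion_diameter))
        if i >= len(self.lesion_diameters) or self.lesion_diameters[i] != lesion_diameter:
            raise InvalidConfigError(f"lesion diameter {lesion_diameter} not on the grid")
        return float(self.max_contact_diameter[i])


@dataclass
class ContactProfileSet:
    """Contact profiles for a whole lesion set (matrix lesions x diameters)."""

    phase: str
    replicate: int
    lesion_diameters: np.ndarray          # (D,)
    max_contact: np.ndarray               # (n, D), NaN = no contact
    min_clearance: Optional[np.ndarray] = None  # (n,) smallest clearance to any airway

    def __len__(self) -> int:
        return len(self.max_contact)

    def __getitem__(self, i: int) -> LesionContactProfile:
        return LesionContactProfile(i, self.phase, self.replicate,
                                    self.lesion_diameters, self.max_contact[i])

    def column(self, lesion_diameter: float) -> np.ndarray:
        j = int(np.searchsorted(self.lesion_diameters, lesion_diameter))
        if j >= len(self.lesion_diameters) or self.lesion_diameters[j] != lesion_diameter:
            raise InvalidConfigError(f"lesion diameter {lesion_diameter} not on the grid")
        return self.max_contact[:, j]

    def no_contact_count(self, lesion_diameter: float) -> int:
        return int(np.isnan(self.column(lesion_diameter)).sum())


def _profiles_from_clearances(clearances: np.ndarray, diameters: np.ndarray,
                              grid: np.ndarray) -> np.ndarray:
    """(n, D) running maxima of airway diameters whose surface clearance is
    within each grid lesion radius."""
    order = np.argsort(clearances, axis=1, kind="stable")
    cs = np.take_along_axis(clearances, order, axis=1)
    ds = np.take_along_axis(np.broadcast_to(diameters, clearances.shape), order, axis=1)
    running = np.maximum.accumulate(ds, axis=1)
    radii = grid / 2.0
    out = np.full((len(clearances), len(grid)), np.nan)
    for i in range(len(clearances)):
        counts = np.searchsorted(cs[i], radii, side="right")
        hit = counts > 0
        out[i, hit] = running[i, counts[hit] - 1]
    return out


def contact_profiles(centers: np.ndarray, tree: AirwayTree,
                     phase: Optional[str] = None, replicate: int = 1,
                     lesion_diameters: np.ndarray = LESION_DIAMETER_GRID,
                     chunk: int = 512) -> ContactProfileSet:
    """Analytic fast path: capsule clearances for all lesions at once."""
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    _, _, _, diams = tree.segment_arrays()
    grid = np.asarray(lesion_diameters, dtype=float)
    max_contact = np.empty((len(centers), len(grid)))
    min_clear = np.empty(len(centers))
    for lo in range(0, len(centers), chunk):
        hi = min(lo + chunk, len(centers))
        clear = capsule_clearances(centers[lo:hi], tree)
        max_contact[lo:hi] = _profiles_from_clearances(clear, diams, grid)
        min_clear[lo:hi] = clear.min(axis=1)
    return ContactProfileSet(phase=phase or tree.phase, replicate=replicate,
                             lesion_diameters=grid, max_contact=max_contact,
                             min_clearance=min_clear)


Airway = Union[AirwayTree, tuple[TriSurface, np.ndarray]]


def contact_profile(lesion_center, airway: Airway, lesion_id: int = 0,
                    phase: str = "inspiration", replicate: int = 1,
                    lesion_diameters: np.ndarray = LESION_DIAMETER_GRID) -> LesionContactProfile:
    """Contact profile of a single lesion (tree fast path or mesh path)."""
    grid = np.asarray(lesion_diameters, dtype=float)
    if isinstance(airway, AirwayTree):
        ps = contact_profiles(np.asarray(lesion_center, dtype=float)[None, :],
                              airway, phase=phase, replicate=replicate,
                              lesion_diameters=grid)
        return LesionContactProfile(lesion_id, ps.phase, replicate, grid,
                                    ps.max_contact[0])
    vals = np.full(len(grid), np.nan)
    for j, d in enumerate(grid):
        touched = lesion_airway_contact(lesion_center, d, airway)
        if len(touched):
            vals[j] = touched.max()
    return LesionContactProfile(lesion_id, phase, replicate, grid, vals)


# --------------------------------------------------------------------------
# percent reachable
# --------------------------------------------------------------------------

@dataclass
class ReachabilityTable:
    phase: str
    replicate: int
    tool_grid: np.ndarray       # (T,)
    lesion_diameters: np.ndarray  # (D,)
    percent: np.ndarray         # (T, D) in [0, 100]

    def at(self, tool: float, lesion_diameter: float) -> float:
        ti = int(np.argmin(np.abs(self.tool_grid - tool)))
        if abs(self.tool_grid[ti] - tool) > 1e-9:
            raise InvalidConfigError(f"tool size {tool} not on the grid")
        di = int(np.argmin(np.abs(self.lesion_diameters - lesion_diameter)))
        if abs(self.lesion_diameters[di] - lesion_diameter) > 1e-9:
            raise InvalidConfigError(f"lesion diameter {lesion_diameter} not on the grid")
        return float(self.percent[ti, di])

    def to_long_df(self) -> pd.DataFrame:
        t, d = np.meshgrid(self.tool_grid, self.lesion_diameters, indexing="ij")
        return pd.DataFrame({
            "phase": self.phase, "replicate": self.replicate,
            "tool_mm": t.ravel(), "lesion_mm": d.ravel(),
            "percent_reachable": self.percent.ravel(),
        })


def percent_reachable(profiles: ContactProfileSet,
                      tool_grid: np.ndarray = TOOL_GRID) -> ReachabilityTable:
    """percent(T, L) = 100 x share of lesions whose contact set at lesion
    diameter L includes an airway of diameter >= T."""
    if len(profiles) == 0:
        raise InvalidConfigError("no contact profiles given")
    tools = np.asarray(tool_grid, dtype=float)
    mc = profiles.max_contact  # (n, D); NaN compares False
    with np.errstate(invalid="ignore"):
        pct = np.stack([100.0 * (mc >= t).mean(axis=0) for t in tools])
    return ReachabilityTable(profiles.phase, profiles.replicate, tools,
                             profiles.lesion_diameters, pct)


# --------------------------------------------------------------------------
# off-road distance
# --------------------------------------------------------------------------

def _r2_grid(profiles: ContactProfileSet, tool_diameter: float) -> np.ndarray:
    """Per lesion: smallest grid radius whose contact set reaches the tool
    diameter (NaN when none does)."""
    if not tool_diameter > 0:
        raise InvalidConfigError("tool diameter must be positive")
    with np.errstate(invalid="ignore"):
        ok = profiles.max_contact >= tool_diameter  # (n, D)
    first = ok.argmax(axis=1)
    any_ok = ok.any(axis=1)
    r2 = np.where(any_ok, profiles.lesion_diameters[first] / 2.0, np.nan)
    return r2


def offroad_distance(profile: LesionContactProfile, lesion_diameter: float,
                     tool_diameter: float) -> float:
    """Off-road distance of one lesion on the growing-sphere grid: r2 - r1
    floored at 0 (NaN = unreachable within the grid)."""
    if not tool_diameter > 0:
        raise InvalidConfigError("tool diameter must be positive")
    if not np.any(np.isclose(profile.lesion_diameters, lesion_diameter)):
        raise InvalidConfigError(f"lesion diameter {lesion_diameter} not on the grid")
    r1 = lesion_diameter / 2.0
    with np.errstate(invalid="ignore"):
        ok = profile.max_contact_diameter >= tool_diameter
    if not ok.any():
        return float("nan")
    r2 = profile.lesion_diameters[int(ok.argmax())] / 2.0
    return float(max(r2 - r1, 0.0))


def offroad_table(profiles: ContactProfileSet, lesion_diameter: float,
                  tool_grid: np.ndarray = TOOL_GRID) -> pd.DataFrame:
    """Per-lesion off-road distances (one column per tool size; NaN =
    unreachable within the 25 mm maximum grid radius)."""
    r1 = lesion_diameter / 2.0
    data = {"lesion_id": np.arange(len(profiles))}
    for t in np.asarray(tool_grid, dtype=float):
        r2 = _r2_grid(profiles, t)
        data[f"tool_{t:g}mm"] = np.maximum(r2 - r1, 0.0)
    df = pd.DataFrame(data)
    df.insert(1, "phase", profiles.phase)
    df.insert(2, "replicate", profiles.replicate)
    df.insert(3, "lesion_mm", lesion_diameter)
    return df


def summarize_offroad(profiles: ContactProfileSet,
                      lesion_sizes: Sequence[float] = SUMMARY_LESION_SIZES,
                      tool_grid: np.ndarray = TOOL_GRID) -> pd.DataFrame:
    """Mean and SD of the off-road distance per (lesion size, tool size),
    excluding unreachable lesions (their count is reported; cells where more
    than half the lesions are unreachable are flagged)."""
    rows = []
    for L in lesion_sizes:
        r1 = L / 2.0
        for t in np.asarray(tool_grid, dtype=float):
            r2 = _r2_grid(profiles, t)
            vals = np.maximum(r2 - r1, 0.0)
            reachable = vals[~np.isnan(vals)]
            n_unreach = int(np.isnan(vals).sum())
            rows.append({
                "phase": profiles.phase, "replicate": profiles.replicate,
                "lesion_mm": L, "tool_mm": t,
                "mean_offroad_mm": float(reachable.mean()) if len(reachable) else np.nan,
                "sd_offroad_mm": float(reachable.std(ddof=1)) if len(reachable) > 1 else np.nan,
                "n_reachable": int(len(reachable)),
                "n_unreachable": n_unreach,
                "mostly_unreachable": n_unreach > len(vals) / 2,
            })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# placing measured lesions into the model
# --------------------------------------------------------------------------

def place_points_in_model(points: np.ndarray, tree: AirwayTree,
                          tool_sizes: Sequence[float] = PLACEMENT_TOOL_SIZES) -> pd.DataFrame:
    """For each point (model coordinates) and tool size: distance to the
    nearest airway of diameter >= tool, and that airway's diameter.
    Unqualifying tool sizes give +inf distance and NaN diameter."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    _, _, _, diams = tree.segment_arrays()
    clear = capsule_clearances(points, tree)
    rows = []
    for i, p in enumerate(points):
        for t in tool_sizes:
            keep = diams >= t
            if not keep.any():
                rows.append({"point_id": i, "tool_mm": float(t),
                             "offroad_mm": np.inf, "nearest_airway_mm": np.nan})
                continue
            c = clear[i, keep]
            j = int(np.argmin(c))
            rows.append({
                "point_id": i, "tool_mm": float(t),
                "offroad_mm": float(max(c[j], 0.0)),
                "nearest_airway_mm": float(diams[keep][j]),
            })
    return pd.DataFrame(rows)
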