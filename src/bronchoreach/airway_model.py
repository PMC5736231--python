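"""Deterministic 3D airway-tree generation by duct branching with space division.

The bronchial tree is grown inside a two-lobed lung volume by recursively
splitting the space owned by each branch tip with a plane through the tip,
assigning each half to one child.  Child diameters follow Murray's law
(``d_child = d_parent * q**(1/3)`` with ``q`` the child's share of parental
air flow, taken proportional to the sub-region volume), child directions
point at the sub-region's center of mass, and child lengths are a fixed
multiple of the diameter, clipped to stay inside the lung.  Tips are expanded
in order of decreasing flow so a global branch-count cap prunes only the
smallest-flow periphery.  The whole construction is deterministic: identical
configuration and region give a bit-identical tree.

Coordinates are millimeters; x runs patient left→right, y caudal→cranial,
z postero→anterior, with the origin at the center of the lung bounding box.
Generation 0 is the trachea.
"""

from __future__ import annotations

import heapq
import io
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .errors import InvalidConfigError

__all__ = [
    "GrowthConfig",
    "AirwayBranch",
    "AirwayTree",
    "LungRegion",
    "make_lung_region",
    "generate_tree",
    "scale_to_phase",
    "tree_stats",
    "tree_to_csv",
    "tree_from_csv",
]


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GrowthConfig:
    """Inputs of the airway-tree generator.

    Defaults reproduce the study conditions: a whole-lung tree of 3311
    branches, trachea diameter 14.5 mm, Murray exponent 3, branch length
    three times the branch diameter, smallest admissible airway 0.1 mm,
    lung capacity 1.0 at end of inspiration and 0.35 at expiration.
    ``inspiratory_time`` and ``posture`` are carried as metadata only.
    """

    root_origin: tuple[float, float, float] = (0.0, 95.0, 0.0)
    root_direction: tuple[float, float, float] = (0.0, -1.0, 0.0)
    trachea_diameter: float = 14.5
    diameter_exponent: float = 3.0
    length_to_diameter_ratio: float = 3.0
    min_diameter: float = 0.1
    max_branches: int = 3311
    region_of_interest: str = "whole lung"
    capacity_inspiration: float = 1.0
    capacity_expiration: float = 0.35
    inspiratory_time: float = 0.4  # metadata only
    posture: str = "supine"  # metadata only

    def validate(self) -> None:
        if not (self.trachea_diameter > self.min_diameter > 0):
            raise InvalidConfigError(
                "require trachea_diameter > min_diameter > 0, got "
                f"{self.trachea_diameter} and {self.min_diameter}"
            )
        if not (0 < self.capacity_expiration <= self.capacity_inspiration <= 1):
            raise InvalidConfigError(
                "require 0 < capacity_expiration <= capacity_inspiration <= 1"
            )
        if self.max_branches < 1:
            raise InvalidConfigError("max_branches must be >= 1")
        if self.diameter_exponent <= 0:
            raise InvalidConfigError("diameter_exponent must be > 0")
        if self.length_to_diameter_ratio <= 0:
            raise InvalidConfigError("length_to_diameter_ratio must be > 0")
        d = np.asarray(self.root_direction, dtype=float)
        if not np.isfinite(d).all() or np.linalg.norm(d) == 0:
            raise InvalidConfigError("root_direction must be a nonzero vector")


# --------------------------------------------------------------------------
# lung region
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class _HalfEllipsoid:
    """One lung: an ellipsoid clipped by a basal plane and a mediastinal plane."""

    center: np.ndarray        # (3,)
    semi_axes: np.ndarray     # (3,)
    y_floor: float            # keep y >= y_floor (diaphragm)
    x_clip: float             # mediastinal plane position
    x_sign: int               # +1 keep x >= x_clip (right), -1 keep x <= x_clip

    def contains(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        u = (pts - self.center) / self.semi_axes
        inside = (u * u).sum(axis=1) <= 1.0
        inside &= pts[:, 1] >= self.y_floor
        if self.x_sign > 0:
            inside &= pts[:, 0] >= self.x_clip
        else:
            inside &= pts[:, 0] <= self.x_clip
        return inside

    def volume(self) -> float:
        # ellipsoid volume minus the spherical-ellipsoid cap below y_floor;
        # the mediastinal plane is tangent by construction and removes nothing.
        a, b, c = self.semi_axes
        full = 4.0 / 3.0 * np.pi * a * b * c
        t = (self.center[1] - self.y_floor) / b  # cap from -b up to -t*b
        t = float(np.clip(t, -1.0, 1.0))
        cap = np.pi * a * c * b * (2.0 / 3.0 - t + t**3 / 3.0)
        return float(full - cap)

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        lo = self.center - self.semi_axes
        hi = self.center + self.semi_axes
        lo[1] = max(lo[1], self.y_floor)
        if self.x_sign > 0:
            lo[0] = max(lo[0], self.x_clip)
        else:
            hi[0] = min(hi[0], self.x_clip)
        return lo, hi


# full-inspiration (capacity 1.0) reference anatomy, millimeters.  Total
# volume ~6.0 L (adult total lung capacity); the right lung holds ~53% of it.
_RIGHT_FULL = dict(center=(79.0, 0.0, 0.0), semi_axes=(71.0, 127.0, 86.0),
                   y_floor=-100.0, x_clip=8.0, x_sign=1)
_LEFT_FULL = dict(center=(-74.5, 0.0, 0.0), semi_axes=(66.5, 124.0, 84.0),
                  y_floor=-100.0, x_clip=-8.0, x_sign=-1)


@dataclass(frozen=True)
class LungRegion:
    """Two disjoint convex lung components (paired truncated half-ellipsoids).

    ``capacity`` is the lung volume as a fraction of the full-inspiration
    volume; all linear dimensions scale with ``capacity**(1/3)`` about the
    origin (the lung-box center).
    """

    right: _HalfEllipsoid
    left: _HalfEllipsoid
    capacity: float = 1.0

    @property
    def sides(self) -> dict[str, _HalfEllipsoid]:
        return {"right": self.right, "left": self.left}

    def contains(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return self.right.contains(pts) | self.left.contains(pts)

    def side_of(self, pts: np.ndarray) -> np.ndarray:
        """'right', 'left' or '' per point."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        out = np.full(len(pts), "", dtype=object)
        out[self.right.contains(pts)] = "right"
        out[self.left.contains(pts)] = "left"
        return out

    def volume(self) -> float:
        return self.right.volume() + self.left.volume()

    def bounding_box(self, side: Optional[str] = None) -> tuple[np.ndarray, np.ndarray]:
        if side is not None:
            return self.sides[side].bounding_box()
        lo_r, hi_r = self.right.bounding_box()
        lo_l, hi_l = self.left.bounding_box()
        return np.minimum(lo_r, lo_l), np.maximum(hi_r, hi_l)

    def voxel_centers(self, pitch: float = 3.0) -> np.ndarray:
        """Centers of a regular grid of spacing ``pitch`` that lie inside."""
        lo, hi = self.bounding_box()
        axes = [np.arange(lo[i] + pitch / 2.0, hi[i], pitch) for i in range(3)]
        grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
        return grid[self.contains(grid)]

    def voxel_volume(self, pitch: float = 3.0) -> float:
        return float(len(self.voxel_centers(pitch)) * pitch**3)


def make_lung_region(config: GrowthConfig, capacity: Optional[float] = None,
                     asymmetric: bool = True) -> LungRegion:
    """Build the lung volume at a given capacity fraction.

    ``capacity`` defaults to ``config.capacity_inspiration``.  With
    ``asymmetric`` (default) the right lung is larger than the left,
    reflecting the cardiac notch; with ``asymmetric=False`` the left lung
    mirrors the right.
    """
    config.validate()
    if capacity is None:
        capacity = config.capacity_inspiration
    if not (capacity > 0):
        raise InvalidConfigError(f"capacity must be positive, got {capacity}")
    s = float(capacity) ** (1.0 / 3.0)

    def _scaled(p: dict, x_sign: int) -> _HalfEllipsoid:
        return _HalfEllipsoid(
            center=np.asarray(p["center"], dtype=float) * s,
            semi_axes=np.asarray(p["semi_axes"], dtype=float) * s,
            y_floor=p["y_floor"] * s,
            x_clip=p["x_clip"] * s,
            x_sign=x_sign,
        )

    right = _scaled(_RIGHT_FULL, 1)
    if asymmetric:
        left = _scaled(_LEFT_FULL, -1)
    else:
        mirrored = dict(_RIGHT_FULL)
        mirrored["center"] = (-_RIGHT_FULL["center"][0], 0.0, 0.0)
        mirrored["x_clip"] = -_RIGHT_FULL["x_clip"]
        left = _scaled(mirrored, -1)
    return LungRegion(right=right, left=left, capacity=float(capacity))


# --------------------------------------------------------------------------
# tree data structures
# --------------------------------------------------------------------------

@dataclass
class AirwayBranch:
    id: int
    parent_id: Optional[int]
    start: np.ndarray
    end: np.ndarray
    diameter: float
    flow_fraction: float
    generation: int

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.end - self.start))

    @property
    def direction(self) -> np.ndarray:
        v = self.end - self.start
        return v / np.linalg.norm(v)

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


@dataclass
class AirwayTree:
    branches: list[AirwayBranch]
    root_id: int
    phase: str
    lung_region: Optional[LungRegion] = None
    config: Optional[GrowthConfig] = None

    def __len__(self) -> int:
        return len(self.branches)

    def branch(self, branch_id: int) -> AirwayBranch:
        return self._by_id()[branch_id]

    def _by_id(self) -> dict[int, AirwayBranch]:
        return {b.id: b for b in self.branches}

    def children_of(self) -> dict[int, list[AirwayBranch]]:
        kids: dict[int, list[AirwayBranch]] = {}
        for b in self.branches:
            if b.parent_id is not None:
                kids.setdefault(b.parent_id, []).append(b)
        return kids

    # vectorized geometry views (used by the analytic contact fast path)
    def segment_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(starts, ends, radii, diameters) as float arrays ordered by branch."""
        starts = np.array([b.start for b in self.branches], dtype=float)
        ends = np.array([b.end for b in self.branches], dtype=float)
        radii = np.array([b.radius for b in self.branches], dtype=float)
        return starts, ends, radii, radii * 2.0


# --------------------------------------------------------------------------
# growth
# --------------------------------------------------------------------------

def _principal_normal(pts: np.ndarray, direction: np.ndarray) -> np.ndarray:
    """Unit normal of the splitting plane: the direction of largest spatial
    extent of ``pts`` within the plane perpendicular to ``direction``.

    The returned plane therefore contains ``direction``.  Sign is fixed by
    convention (largest-magnitude component positive) for determinism.
    """
    x = pts - pts.mean(axis=0)
    x = x - np.outer(x @ direction, direction)
    cov = x.T @ x
    w, v = np.linalg.eigh(cov)
    n = v[:, int(np.argmax(w))]
    # remove any numerical component along the branch direction
    n = n - (n @ direction) * direction
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        # degenerate point set; fall back to an arbitrary perpendicular
        ref = np.array([1.0, 0.0, 0.0])
        if abs(direction[0]) > 0.9:
            ref = np.array([0.0, 0.0, 1.0])
        n = np.cross(direction, ref)
        norm = np.linalg.norm(n)
    n = n / norm
    k = int(np.argmax(np.abs(n)))
    if n[k] < 0:
        n = -n
    return n


def _clip_endpoint(tip: np.ndarray, direction: np.ndarray, length: float,
                   centroid: np.ndarray, region: LungRegion,
                   generation: int) -> np.ndarray:
    """End point of a new branch, shortened if needed to stay in the lung.

    The trachea and main bronchi (generations 0-1) are allowed to traverse
    the mediastinal corridor, so no clipping is applied there.
    """
    dist_c = float(np.linalg.norm(centroid - tip))
    t = min(length, dist_c) if dist_c > 0 else length
    end = tip + t * direction
    if generation <= 1 or bool(region.contains(end[None, :])[0]):
        return end
    # walk toward the sub-region centroid (inside a convex component) until
    # the endpoint falls inside; deterministic fixed scan
    for frac in np.linspace(1.0, 0.05, 20):
        cand = tip + (frac * t) * direction
        if bool(region.contains(cand[None, :])[0]):
            return cand
    return end  # keep geometric length; midpoint test tolerates boundary cases


def generate_tree(config: GrowthConfig, region: LungRegion, *,
                  voxel_pitch: float = 3.0, min_region_voxels: int = 2) -> AirwayTree:
    """Grow the airway tree (deterministic; no randomness anywhere).

    Each growable tip owns a set of lung voxels; expansion splits that set by
    a plane through the tip containing the branch direction, creates one
    child per half (flow split proportional to voxel counts, Murray-law
    diameters, centroid-directed, length ``ratio * d`` clipped to the lung),
    and stops at a tip when a child diameter would fall below
    ``config.min_diameter`` or the owned sub-region is smaller than
    ``min_region_voxels`` voxels.  Tips are expanded largest-flow-first and
    growth stops globally at ``config.max_branches`` branches.
    """
    config.validate()
    voxels = region.voxel_centers(voxel_pitch)
    if len(voxels) == 0:
        raise InvalidConfigError("lung region is empty")

    root = np.asarray(config.root_origin, dtype=float)
    lo, hi = region.bounding_box()
    pad = 2.0 * config.length_to_diameter_ratio * config.trachea_diameter
    if np.any(root < lo - pad) or np.any(root > hi + pad):
        raise InvalidConfigError(
            f"root_origin {tuple(root)} lies outside the lung region extent"
        )
    direction = np.asarray(config.root_direction, dtype=float)
    direction = direction / np.linalg.norm(direction)

    trachea_len = config.length_to_diameter_ratio * config.trachea_diameter
    trachea = AirwayBranch(
        id=0, parent_id=None, start=root, end=root + trachea_len * direction,
        diameter=float(config.trachea_diameter), flow_fraction=1.0, generation=0,
    )
    if region.voxel_volume(voxel_pitch) < np.pi / 4 * config.trachea_diameter**2 * trachea_len:
        warnings.warn("lung region too small for the trachea; returning a "
                      "single-branch tree", stacklevel=2)
        return AirwayTree(branches=[trachea], root_id=0,
                          phase="inspiration", lung_region=region, config=config)

    branches = [trachea]
    owned = {0: np.arange(len(voxels))}
    # max-heap on flow fraction; insertion counter breaks ties deterministically
    heap: list[tuple[float, int, int]] = [(-1.0, 0, 0)]
    counter = 1
    next_id = 1
    inv_exp = 1.0 / config.diameter_exponent

    while heap and len(branches) + 2 <= config.max_branches:
        _, _, tip_id = heapq.heappop(heap)
        tip = branches[tip_id]
        idx = owned.pop(tip_id)
        if len(idx) < 2 * min_region_voxels:
            continue
        pts = voxels[idx]
        d = tip.direction
        normal = _principal_normal(pts, d)
        side = (pts - tip.end) @ normal > 0.0
        n_pos, n_neg = int(side.sum()), int((~side).sum())
        if n_pos < min_region_voxels or n_neg < min_region_voxels:
            # plane through the tip leaves one side (nearly) empty: split at
            # the owned region's median along the same normal instead
            offs = (pts - pts.mean(axis=0)) @ normal
            side = offs > np.median(offs)
            n_pos, n_neg = int(side.sum()), int((~side).sum())
            if n_pos < min_region_voxels or n_neg < min_region_voxels:
                continue
        parts = (idx[side], idx[~side])
        total = float(len(idx))
        qs = (len(parts[0]) / total, len(parts[1]) / total)
        d_children = [tip.diameter * q**inv_exp for q in qs]
        if min(d_children) < config.min_diameter:
            continue  # tip becomes terminal
        # both children are created atomically so that every bifurcation
        # conserves flow (and hence d^3 under Murray's law) exactly
        children: list[tuple[AirwayBranch, np.ndarray]] = []
        for part_idx, q, d_child in zip(parts, qs, d_children):
            centroid = voxels[part_idx].mean(axis=0)
            vec = centroid - tip.end
            norm = np.linalg.norm(vec)
            if norm < 1e-9:
                break
            child_dir = vec / norm
            length = config.length_to_diameter_ratio * d_child
            end = _clip_endpoint(tip.end, child_dir, length, centroid, region,
                                 tip.generation + 1)
            children.append((AirwayBranch(
                id=-1, parent_id=tip_id, start=tip.end.copy(), end=end,
                diameter=float(d_child),
                flow_fraction=tip.flow_fraction * q,
                generation=tip.generation + 1,
            ), part_idx))
        if len(children) < 2:
            continue  # degenerate geometry: tip becomes terminal
        for child, part_idx in children:
            child.id = next_id
            branches.append(child)
            owned[child.id] = part_idx
            heapq.heappush(heap, (-child.flow_fraction, counter, child.id))
            counter += 1
            next_id += 1

    return AirwayTree(branches=branches, root_id=0, phase="inspiration",
                      lung_region=region, config=config)


def scale_to_phase(tree: AirwayTree, capacity_fraction: float) -> AirwayTree:
    """Isotropically rescale a full-inspiration tree to another capacity.

    Coordinates and diameters are multiplied by ``capacity_fraction**(1/3)``
    about the lung-box center (the coordinate origin); topology, flow
    fractions and generations are untouched.
    """
    if not (capacity_fraction > 0):
        raise InvalidConfigError("capacity_fraction must be in (0, 1]")
    s = float(capacity_fraction) ** (1.0 / 3.0)
    scaled = [
        replace(b, start=b.start * s, end=b.end * s, diameter=b.diameter * s)
        for b in tree.branches
    ]
    phase = "inspiration" if np.isclose(capacity_fraction, 1.0) else "expiration"
    region = None
    if tree.config is not None:
        region = make_lung_region(tree.config, capacity=capacity_fraction)
    return AirwayTree(branches=scaled, root_id=tree.root_id, phase=phase,
                      lung_region=region, config=tree.config)


# --------------------------------------------------------------------------
# summaries and serialization
# --------------------------------------------------------------------------

def tree_stats(tree: AirwayTree) -> dict:
    """Gross morphometry: branch count, generation histogram, proximal diameters."""
    gens = np.array([b.generation for b in tree.branches])
    diams = np.array([b.diameter for b in tree.branches])
    hist = {int(g): int((gens == g).sum()) for g in np.unique(gens)}
    by_gen = lambda g: sorted(float(d) for d in diams[gens == g])  # noqa: E731
    return {
        "n_branches": len(tree.branches),
        "generation_histogram": hist,
        "trachea_diameter_mm": float(diams[gens == 0][0]),
        "main_bronchi_diameters_mm": by_gen(1),
        "lobar_bronchi_diameters_mm": by_gen(2),
        "min_diameter_mm": float(diams.min()),
        "max_generation": int(gens.max()),
        "phase": tree.phase,
    }


_CSV_COLUMNS = ["id", "parent_id", "start_x", "start_y", "start_z",
                "end_x", "end_y", "end_z", "diameter_mm", "flow_fraction",
                "generation"]


def tree_to_csv(tree: AirwayTree, path_or_buf) -> None:
    rows = [
        (b.id, b.parent_id if b.parent_id is not None else -1,
         *b.start, *b.end, b.diameter, b.flow_fraction, b.generation)
        for b in tree.branches
    ]
    df = pd.DataFrame(rows, columns=_CSV_COLUMNS)
    df.to_csv(path_or_buf, index=False, float_format="%.9g")


def tree_from_csv(path_or_buf, phase: str = "inspiration") -> AirwayTree:
    df = pd.read_csv(path_or_buf, comment="#")
    branches = [
        AirwayBranch(
            id=int(r.id),
            parent_id=None if int(r.parent_id) < 0 else int(r.parent_id),
            start=np.array([r.start_x, r.start_y, r.start_z], dtype=float),
            end=np.array([r.end_x, r.end_y, r.end_z], dtype=float),
            diameter=float(r.diameter_mm),
            flow_fraction=float(r.flow_fraction),
            generation=int(r.generation),
        )
        for r in df.itertuples()
    ]
    roots = [b.id for b in branches if b.parent_id is None]
    if len(roots) != 1:
        raise InvalidConfigError(f"branch table must have exactly one root, found {len(roots)}")
    return AirwayTree(branches=branches, root_id=roots[0], phase=phase)
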