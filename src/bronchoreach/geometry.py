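"""Triangular surface meshes and the geometric queries of the study.

Two query paths coexist on purpose:

* a *mesh path* — airway tube / lesion sphere surfaces, per-face local airway
  diameters found by casting a ray from each face centroid to the opposite
  wall, and containment by generalized winding number — which mirrors the
  mesh-based measurement procedure and is used at fidelity-test scale;
* an *analytic fast path* — each airway branch treated as a capsule (segment
  with radius), lesion-airway contact and nearest-airway distances computed
  as vectorized sphere-capsule clearances — which is exact for the tube
  geometry and fast enough for thousands of lesions against thousands of
  branches.

Both paths answer the same question ("which airway diameters does a lesion
sphere touch?") and are cross-checked against each other in the test suite.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import trimesh

from .airway_model import AirwayTree
from .errors import InvalidConfigError, MeshFormatError

__all__ = [
    "TriSurface",
    "tube_surface",
    "sphere_surface",
    "face_diameters",
    "point_in_surface",
    "winding_numbers",
    "lesion_airway_contact",
    "nearest_airway_distance",
    "capsule_clearances",
    "write_vtk",
    "read_vtk",
]

DIAMETER_ATTR = "diameter_mm"
CAP_ATTR = "is_cap"

# opposite-face search gives up beyond this distance (about twice the largest
# expected airway diameter) to avoid pairing faces across different lumens
OPPOSITE_FACE_CUTOFF = 40.0


# --------------------------------------------------------------------------
# surface container
# --------------------------------------------------------------------------

@dataclass
class TriSurface:
    """A triangle mesh: (n,3) float vertices, (m,3) int faces, per-face attrs."""

    vertices: np.ndarray
    faces: np.ndarray
    face_attrs: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise MeshFormatError("face indices out of range")

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def face_centroids(self) -> np.ndarray:
        return self.vertices[self.faces].mean(axis=1)

    def face_normals(self) -> np.ndarray:
        tri = self.vertices[self.faces]
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return n / norm

    def is_closed(self) -> bool:
        """True iff every edge is shared by exactly two faces."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                       self.faces[:, [2, 0]]])
        e = np.sort(e, axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        return bool((counts == 2).all())

    def median_edge_length(self) -> float:
        tri = self.vertices[self.faces]
        e = np.linalg.norm(np.stack([tri[:, 1] - tri[:, 0],
                                     tri[:, 2] - tri[:, 1],
                                     tri[:, 0] - tri[:, 2]]), axis=-1)
        return float(np.median(e))

    def translated(self, offset) -> "TriSurface":
        return TriSurface(self.vertices + np.asarray(offset, dtype=float),
                          self.faces.copy(),
                          {k: v.copy() for k, v in self.face_attrs.items()})

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces,
                               process=False)


# --------------------------------------------------------------------------
# surface construction
# --------------------------------------------------------------------------

def _branch_frame(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal (u, v) perpendicular to ``direction``."""
    ref = np.array([1.0, 0.0, 0.0])
    if abs(direction[0]) > 0.9:
        ref = np.array([0.0, 0.0, 1.0])
    u = np.cross(direction, ref)
    u /= np.linalg.norm(u)
    v = np.cross(direction, u)
    return u, v


def tube_surface(tree: AirwayTree, circumferential_segments: int = 12,
                 axial_step: Optional[float] = None) -> TriSurface:
    """Triangulated airway surface: one cylinder per branch, with caps on the
    root start and on every terminal tip; per-face attributes record the
    generating branch's diameter and whether the face is a cap.

    With the default ``axial_step=None`` each branch is a single cylindrical
    segment; give a step (mm) to subdivide branches into rings no farther
    apart than that, which densifies the vertex sampling used by the
    mesh-path contact test on long branches.
    """
    if circumferential_segments < 6:
        raise InvalidConfigError("need at least 6 circumferential segments")
    if len(tree.branches) == 0:
        raise InvalidConfigError("cannot mesh an empty tree")

    S = circumferential_segments
    ang = 2.0 * np.pi * np.arange(S) / S
    cos, sin = np.cos(ang), np.sin(ang)

    has_children = {b.parent_id for b in tree.branches if b.parent_id is not None}
    verts: list[np.ndarray] = []
    faces: list[tuple[int, int, int]] = []
    f_diam: list[float] = []
    f_cap: list[bool] = []
    f_branch: list[int] = []

    def add_ring(center, u, v, r):
        base = len(verts)
        for c, s in zip(cos, sin):
            verts.append(center + r * (c * u + s * v))
        return base

    for b in tree.branches:
        d = b.direction
        u, v = _branch_frame(d)
        r = b.radius
        n_axial = 1
        if axial_step is not None and axial_step > 0:
            n_axial = max(1, int(np.ceil(b.length / axial_step)))
        stations = [b.start + (b.end - b.start) * k / n_axial
                    for k in range(n_axial + 1)]
        rings = [add_ring(p, u, v, r) for p in stations]
        ring0, ring1 = rings[0], rings[-1]
        for lo_ring, hi_ring in zip(rings[:-1], rings[1:]):
            for i in range(S):
                j = (i + 1) % S
                a0, a1 = lo_ring + i, lo_ring + j
                b0, b1 = hi_ring + i, hi_ring + j
                # (u, v, d) is right-handed, so this winding is
                # counter-clockwise seen from outside (outward normals)
                faces.append((a0, a1, b1))
                faces.append((a0, b1, b0))
                f_diam.extend([b.diameter, b.diameter])
                f_cap.extend([False, False])
                f_branch.extend([b.id, b.id])

        cap_specs = []
        if b.parent_id is None:
            cap_specs.append((ring0, b.start, -d))   # root start cap
        if b.id not in has_children:
            cap_specs.append((ring1, b.end, d))      # terminal tip cap
        for ring, center, outward in cap_specs:
            c_idx = len(verts)
            verts.append(center.astype(float).copy())
            for i in range(S):
                j = (i + 1) % S
                tri = (c_idx, ring + i, ring + j)
                # orient the fan so its normal points along ``outward``
                p = np.array([verts[k] for k in tri])
                n = np.cross(p[1] - p[0], p[2] - p[0])
                if n @ outward < 0:
                    tri = (c_idx, ring + j, ring + i)
                faces.append(tri)
                f_diam.append(b.diameter)
                f_cap.append(True)
                f_branch.append(b.id)

    return TriSurface(
        vertices=np.array(verts), faces=np.array(faces),
        face_attrs={
            DIAMETER_ATTR: np.array(f_diam),
            CAP_ATTR: np.array(f_cap, dtype=bool),
            "branch_id": np.array(f_branch, dtype=np.int64),
        },
    )


def sphere_surface(center, diameter: float, refinement: int = 2) -> TriSurface:
    """Closed icosphere of the given diameter (refinement 0 = icosahedron)."""
    if not diameter > 0:
        raise InvalidConfigError(f"lesion diameter must be positive, got {diameter}")
    ico = trimesh.creation.icosphere(subdivisions=int(refinement), radius=1.0)
    v = np.asarray(ico.vertices, dtype=float)
    # snap exactly onto the sphere
    v = v / np.linalg.norm(v, axis=1, keepdims=True) * (diameter / 2.0)
    return TriSurface(vertices=v + np.asarray(center, dtype=float),
                      faces=np.asarray(ico.faces, dtype=np.int64))


# --------------------------------------------------------------------------
# per-face airway diameters (opposite-face ray cast)
# --------------------------------------------------------------------------

def _ray_triangle_batch(origins: np.ndarray, directions: np.ndarray,
                        tri: np.ndarray) -> np.ndarray:
    """Möller-Trumbore for R rays against T triangles; returns (R, T) hit
    distances (+inf where no hit).  Dense — intended for fidelity-test scale.
    """
    eps = 1e-12
    v0, e1, e2 = tri[:, 0], tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]
    out = np.full((len(origins), len(tri)), np.inf)
    for i, (o, dvec) in enumerate(zip(origins, directions)):
        p = np.cross(dvec, e2)
        det = np.einsum("ij,ij->i", e1, p)
        ok = np.abs(det) > eps
        inv = np.zeros_like(det)
        inv[ok] = 1.0 / det[ok]
        t_vec = o - v0
        u = np.einsum("ij,ij->i", t_vec, p) * inv
        q = np.cross(t_vec, e1)
        v = q @ dvec * inv
        t = np.einsum("ij,ij->i", e2, q) * inv
        hit = ok & (u >= -1e-9) & (v >= -1e-9) & (u + v <= 1 + 1e-9) & (t > eps)
        out[i, hit] = t[hit]
    return out


def face_diameters(surface: TriSurface, cutoff: float = OPPOSITE_FACE_CUTOFF,
                   chunk: int = 512) -> np.ndarray:
    """Local lumen diameter at every face, NaN where undetermined.

    From each face centroid a ray is cast along the inward normal; the first
    face it strikes whose wall faces the opposite way is the "opposite face",
    and the centroid-to-hit distance is the local diameter.  The value is NaN
    when nothing is hit within ``cutoff`` millimeters, when the nearest hit
    is a cap face, or when the hit face is not opposing.
    """
    normals = surface.face_normals()
    centroids = surface.face_centroids()
    tri = surface.vertices[surface.faces]
    is_cap = surface.face_attrs.get(
        CAP_ATTR, np.zeros(surface.n_faces, dtype=bool))

    diam = np.full(surface.n_faces, np.nan)
    eps = 1e-6
    for lo in range(0, surface.n_faces, chunk):
        hi = min(lo + chunk, surface.n_faces)
        dirs = -normals[lo:hi]
        origins = centroids[lo:hi] + eps * dirs
        t = _ray_triangle_batch(origins, dirs, tri)
        t[t > cutoff] = np.inf
        # a face is "opposing" when the ray exits through it from inside:
        # its outward normal continues along the ray direction
        opposing = dirs @ normals.T > 1e-9
        t[~opposing] = np.inf
        for k in range(hi - lo):
            row = t[k]
            j = int(np.argmin(row))
            if np.isfinite(row[j]) and not is_cap[j]:
                diam[lo + k] = row[j] + eps
    return diam


# --------------------------------------------------------------------------
# containment
# --------------------------------------------------------------------------

def winding_numbers(surface: TriSurface, points: np.ndarray,
                    chunk: Optional[int] = None) -> np.ndarray:
    """Generalized winding number of each point w.r.t. the oriented surface.

    Sum of signed solid angles (van Oosterom-Strackee) over all triangles,
    normalized by 4*pi: ~1 inside a closed outward-oriented surface, ~0
    outside, 1/2 on the boundary.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    tri = surface.vertices[surface.faces]
    if chunk is None:
        # keep the (points x faces x 3) temporaries around ~100 MB
        chunk = max(1, int(1.5e6 / max(surface.n_faces, 1)))
    w = np.empty(len(pts))
    for lo in range(0, len(pts), chunk):
        p = pts[lo:lo + chunk]
        a = tri[None, :, 0] - p[:, None]
        b = tri[None, :, 1] - p[:, None]
        c = tri[None, :, 2] - p[:, None]
        la = np.linalg.norm(a, axis=-1)
        lb = np.linalg.norm(b, axis=-1)
        lc = np.linalg.norm(c, axis=-1)
        det = np.einsum("ptj,ptj->pt", a, np.cross(b, c))
        denom = (la * lb * lc + np.einsum("ptj,ptj->pt", a, b) * lc
                 + np.einsum("ptj,ptj->pt", b, c) * la
                 + np.einsum("ptj,ptj->pt", c, a) * lb)
        w[lo:lo + chunk] = np.arctan2(det, denom).sum(axis=1) / (2.0 * np.pi)
    return w


def point_in_surface(surface: TriSurface, points: np.ndarray) -> np.ndarray:
    """Inside/outside mask for a *closed* surface (boundary counts as inside)."""
    if not surface.is_closed():
        raise MeshFormatError("containment requires a closed surface")
    return winding_numbers(surface, points) >= 0.5 - 1e-9


# --------------------------------------------------------------------------
# lesion-airway contact and distances
# --------------------------------------------------------------------------

def _point_segment_distance(points: np.ndarray, starts: np.ndarray,
                            ends: np.ndarray) -> np.ndarray:
    """(N, M) Euclidean distances from N points to M segments."""
    points = np.atleast_2d(points)
    seg = ends - starts                              # (M,3)
    seg_len2 = np.einsum("mj,mj->m", seg, seg)
    seg_len2 = np.where(seg_len2 == 0, 1.0, seg_len2)
    rel = points[:, None, :] - starts[None, :, :]    # (N,M,3)
    t = np.clip(np.einsum("nmj,mj->nm", rel, seg) / seg_len2, 0.0, 1.0)
    closest = starts[None] + t[..., None] * seg[None]
    return np.linalg.norm(points[:, None, :] - closest, axis=-1)


def capsule_clearances(points: np.ndarray, tree: AirwayTree,
                       chunk: int = 512) -> np.ndarray:
    """(N, M) signed clearance from each point to each branch *surface*:
    point-to-axis distance minus branch radius (negative inside the lumen).
    """
    starts, ends, radii, _ = tree.segment_arrays()
    points = np.atleast_2d(np.asarray(points, dtype=float))
    out = np.empty((len(points), len(radii)))
    for lo in range(0, len(points), chunk):
        hi = min(lo + chunk, len(points))
        out[lo:hi] = _point_segment_distance(points[lo:hi], starts, ends) - radii
    return out


Airway = Union[AirwayTree, tuple[TriSurface, np.ndarray]]


def lesion_airway_contact(lesion_center, lesion_diameter: float,
                          airway: Airway) -> np.ndarray:
    """Sorted unique diameters (mm) of all airways touched by a lesion sphere.

    ``airway`` is either an :class:`AirwayTree` (analytic capsule fast path)
    or a ``(TriSurface, face_diameters)`` pair (mesh path: a face is touched
    when any of its vertices or its centroid lies within the lesion radius;
    faces with NaN diameter contribute nothing).  Returns an empty array when
    nothing is touched.
    """
    if not lesion_diameter > 0:
        raise InvalidConfigError("lesion diameter must be positive")
    center = np.asarray(lesion_center, dtype=float)
    r = lesion_diameter / 2.0

    if isinstance(airway, AirwayTree):
        clear = capsule_clearances(center[None, :], airway)[0]
        _, _, _, diams = airway.segment_arrays()
        return np.unique(diams[clear <= r])

    surface, fdm = airway
    fdm = np.asarray(fdm, dtype=float)
    if len(fdm) != surface.n_faces:
        raise InvalidConfigError("face-diameter map length mismatch")
    vert_hit = np.linalg.norm(surface.vertices - center, axis=1) <= r
    face_hit = vert_hit[surface.faces].any(axis=1)
    face_hit |= np.linalg.norm(surface.face_centroids() - center, axis=1) <= r
    touched = fdm[face_hit]
    return np.unique(touched[np.isfinite(touched)])


def nearest_airway_distance(point, tree: AirwayTree,
                            min_diameter: float = 0.0) -> float:
    """Distance from a point to the surface of the nearest airway whose
    diameter is at least ``min_diameter`` (0 inside such an airway; +inf when
    no branch qualifies).
    """
    if len(tree.branches) == 0:
        raise InvalidConfigError("tree is empty")
    starts, ends, radii, diams = tree.segment_arrays()
    keep = diams >= min_diameter
    if not keep.any():
        return float("inf")
    d = _point_segment_distance(np.asarray(point, dtype=float)[None, :],
                                starts[keep], ends[keep])[0] - radii[keep]
    return float(max(d.min(), 0.0))


# --------------------------------------------------------------------------
# VTK legacy ASCII polydata I/O
# --------------------------------------------------------------------------

def write_vtk(surface: TriSurface, path, scalar_attr: Optional[str] = DIAMETER_ATTR,
              title: str = "bronchoreach surface") -> None:
    """Write legacy ASCII VTK polydata (POINTS + triangle POLYGONS, plus one
    optional per-face CELL_DATA scalar; NaN encodes a missing value)."""
    lines = ["# vtk DataFile Version 3.0", title, "ASCII", "DATASET POLYDATA",
             f"POINTS {len(surface.vertices)} float"]
    lines += [" ".join(f"{x:.9g}" for x in v) for v in surface.vertices]
    m = surface.n_faces
    lines.append(f"POLYGONS {m} {4 * m}")
    lines += [f"3 {a} {b} {c}" for a, b, c in surface.faces]
    if scalar_attr is not None and scalar_attr in surface.face_attrs:
        vals = np.asarray(surface.face_attrs[scalar_attr], dtype=float)
        lines.append(f"CELL_DATA {m}")
        lines.append(f"SCALARS {scalar_attr} float 1")
        lines.append("LOOKUP_TABLE default")
        lines += [f"{v:.9g}" if np.isfinite(v) else "nan" for v in vals]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vtk(path) -> TriSurface:
    """Read legacy ASCII VTK polydata written by :func:`write_vtk` (or any
    POINTS/POLYGONS triangle polydata with an optional face scalar)."""
    with open(path) as fh:
        raw = fh.read().splitlines()

    def err(lineno, msg):
        raise MeshFormatError(f"{path}:{lineno + 1}: {msg}")

    i = 0
    n_pts = None
    verts: list[float] = []
    faces: list[tuple[int, int, int]] = []
    attrs: dict[str, np.ndarray] = {}
    while i < len(raw):
        tok = raw[i].split()
        if not tok:
            i += 1
            continue
        key = tok[0].upper()
        if key == "POINTS":
            n_pts = int(tok[1])
            i += 1
            while len(verts) < 3 * n_pts:
                if i >= len(raw):
                    err(i - 1, "unexpected end of file in POINTS")
                try:
                    verts.extend(float(x) for x in raw[i].split())
                except ValueError:
                    err(i, "malformed POINTS line")
                i += 1
        elif key == "POLYGONS":
            n_poly = int(tok[1])
            i += 1
            for _ in range(n_poly):
                if i >= len(raw):
                    err(i - 1, "unexpected end of file in POLYGONS")
                nums = raw[i].split()
                if int(nums[0]) != 3:
                    err(i, f"non-triangle polygon with {nums[0]} vertices is unsupported")
                faces.append((int(nums[1]), int(nums[2]), int(nums[3])))
                i += 1
        elif key == "CELL_DATA":
            i += 1
        elif key == "SCALARS":
            name = tok[1]
            i += 1
            if i < len(raw) and raw[i].upper().startswith("LOOKUP_TABLE"):
                i += 1
            vals: list[float] = []
            while i < len(raw) and len(vals) < len(faces):
                vals.extend(float(x) for x in raw[i].split())
                i += 1
            attrs[name] = np.array(vals)
        else:
            i += 1
    if n_pts is None:
        raise MeshFormatError(f"{path}: no POINTS section found")
    if len(verts) != 3 * n_pts:
        raise MeshFormatError(f"{path}: expected {n_pts} points, parsed {len(verts) // 3}")
    return TriSurface(vertices=np.array(verts).reshape(-1, 3),
                      faces=np.array(faces, dtype=np.int64).reshape(-1, 3),
                      face_attrs=attrs)
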