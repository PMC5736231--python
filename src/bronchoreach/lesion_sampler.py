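"""Spatial sampling of lesion locations inside the lung bounding boxes.

Lesion centers are drawn from per-axis histogram PDFs defined on normalized
[0, 1] coordinates of each lung side's axis-aligned bounding box, plus a
left/right side PDF.  The default PDFs are qualitative stand-ins for the
lesion-location distribution reported by the NELSON screening trial: mass
shifted to the lateral (peripheral) third of each lung, to the cranial half,
uniform antero-posteriorly, and favoring the right lung.  All four are
overridable from a plain-text config file.

The study design draws 3 replicate sets of 1000 lesions per respiratory
phase (6 sets total); expiration sets are drawn against the expiration-phase
boxes, not rescaled copies of the inspiration sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .airway_model import GrowthConfig, LungRegion, make_lung_region
from .errors import InvalidConfigError

__all__ = [
    "AxisPDF",
    "SidePDF",
    "LesionSet",
    "default_nelson_pdfs",
    "bounding_box",
    "sample_lesions",
    "generate_study_design",
    "load_pdf_config",
    "save_pdf_config",
]


@dataclass(frozen=True)
class AxisPDF:
    """Histogram PDF on the normalized [0, 1] coordinate of one axis.

    Axis conventions: x is medial→lateral (mirrored between sides), y is
    caudal→cranial, z is postero→anterior.
    """

    axis: str
    edges: np.ndarray
    probs: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "edges", np.asarray(self.edges, dtype=float))
        object.__setattr__(self, "probs", np.asarray(self.probs, dtype=float))
        if np.any(np.diff(self.edges) <= 0):
            raise InvalidConfigError(f"{self.axis}: bin edges must be strictly increasing")
        if len(self.probs) != len(self.edges) - 1:
            raise InvalidConfigError(f"{self.axis}: need one probability per bin")
        if np.any(self.probs < 0) or abs(self.probs.sum() - 1.0) > 1e-9:
            raise InvalidConfigError(f"{self.axis}: probabilities must be >= 0 and sum to 1")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Draw n normalized coordinates (uniform within the chosen bin)."""
        bins = rng.choice(len(self.probs), size=n, p=self.probs)
        u = rng.random(n)
        lo = self.edges[bins]
        hi = self.edges[bins + 1]
        return lo + u * (hi - lo)

    def cdf(self, x: np.ndarray) -> np.ndarray:
        cum = np.concatenate([[0.0], np.cumsum(self.probs)])
        return np.interp(x, self.edges, cum)


@dataclass(frozen=True)
class SidePDF:
    p_right: float
    p_left: float

    def __post_init__(self):
        if self.p_right < 0 or self.p_left < 0 or abs(self.p_right + self.p_left - 1.0) > 1e-9:
            raise InvalidConfigError("side probabilities must be >= 0 and sum to 1")


def default_nelson_pdfs() -> tuple[AxisPDF, AxisPDF, AxisPDF, SidePDF]:
    """Default axis and side PDFs (NELSON-like qualitative structure).

    x: half the mass in the lateral (peripheral) third; y: 62% of the mass in
    the cranial half; z: uniform; side: right lung favored.
    """
    x = AxisPDF("x", [0.0, 1 / 3, 2 / 3, 1.0], [0.20, 0.30, 0.50])
    y = AxisPDF("y", [0.0, 0.25, 0.5, 0.75, 1.0], [0.14, 0.24, 0.30, 0.32])
    z = AxisPDF("z", [0.0, 0.25, 0.5, 0.75, 1.0], [0.25, 0.25, 0.25, 0.25])
    side = SidePDF(p_right=0.55, p_left=0.45)
    return x, y, z, side


# --------------------------------------------------------------------------
# PDF config file (flat key=value, comma-separated numbers)
# --------------------------------------------------------------------------

def save_pdf_config(path, pdfs: tuple[AxisPDF, AxisPDF, AxisPDF, SidePDF]) -> None:
    x, y, z, side = pdfs
    with open(path, "w") as fh:
        for p in (x, y, z):
            fh.write(f"{p.axis}_edges = {','.join(f'{e:.9g}' for e in p.edges)}\n")
            fh.write(f"{p.axis}_probs = {','.join(f'{q:.9g}' for q in p.probs)}\n")
        fh.write(f"side_right = {side.p_right:.9g}\n")
        fh.write(f"side_left = {side.p_left:.9g}\n")


def load_pdf_config(path) -> tuple[AxisPDF, AxisPDF, AxisPDF, SidePDF]:
    values: dict[str, list[float]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise InvalidConfigError(f"{path}:{lineno}: expected 'key = values'")
            key, _, val = line.partition("=")
            try:
                values[key.strip()] = [float(v) for v in val.replace(",", " ").split()]
            except ValueError as exc:
                raise InvalidConfigError(f"{path}:{lineno}: {exc}") from exc
    try:
        x = AxisPDF("x", values["x_edges"], values["x_probs"])
        y = AxisPDF("y", values["y_edges"], values["y_probs"])
        z = AxisPDF("z", values["z_edges"], values["z_probs"])
        side = SidePDF(values["side_right"][0], values["side_left"][0])
    except KeyError as exc:
        raise InvalidConfigError(f"{path}: missing PDF key {exc}") from exc
    return x, y, z, side


# --------------------------------------------------------------------------
# bounding boxes and sampling
# --------------------------------------------------------------------------

def bounding_box(region: LungRegion) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Tight per-side axis-aligned boxes {'right': (lo, hi), 'left': (lo, hi)}."""
    boxes = {side: region.bounding_box(side) for side in ("right", "left")}
    for side, (lo, hi) in boxes.items():
        if np.any(hi <= lo):
            raise InvalidConfigError(f"{side} lung box is empty")
    return boxes


@dataclass
class LesionSet:
    """Sampled lesion centers for one (phase, replicate)."""

    coords: np.ndarray  # (n, 3) mm
    phase: str
    replicate: int
    seed: int
    sides: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))
    pdf_provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.coords)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "lesion_id": np.arange(len(self.coords)),
            "phase": self.phase,
            "replicate": self.replicate,
            "x_mm": self.coords[:, 0],
            "y_mm": self.coords[:, 1],
            "z_mm": self.coords[:, 2],
        })

    def to_csv(self, path_or_buf) -> None:
        self.to_dataframe().to_csv(path_or_buf, index=False, float_format="%.9g")


def _map_axis(u: np.ndarray, lo: float, hi: float, mirror: bool) -> np.ndarray:
    return (hi - u * (hi - lo)) if mirror else (lo + u * (hi - lo))


def sample_lesions(pdfs: tuple[AxisPDF, AxisPDF, AxisPDF, SidePDF],
                   boxes: dict[str, tuple[np.ndarray, np.ndarray]],
                   n: int, seed: int, clip_to_region: bool = False,
                   region: Optional[LungRegion] = None,
                   phase: str = "inspiration", replicate: int = 1) -> LesionSet:
    """Draw ``n`` lesion centers: side first, then x, y, z independently from
    the axis PDFs rescaled to that side's box (x mirrored so the PDF is in
    medial→lateral coordinates for both lungs).

    With ``clip_to_region`` the draws are rejection-sampled until they fall
    inside the lung volume itself (off by default: the plain bounding-box
    containment is the baseline behavior).
    """
    if n < 1:
        raise InvalidConfigError("n must be >= 1")
    x_pdf, y_pdf, z_pdf, side_pdf = pdfs
    if clip_to_region and region is None:
        raise InvalidConfigError("clip_to_region requires the lung region")
    rng = np.random.default_rng(seed)

    coords = np.empty((n, 3))
    sides = np.empty(n, dtype=object)
    filled = 0
    attempts = 0
    while filled < n:
        m = n - filled
        attempts += m
        s = np.where(rng.random(m) < side_pdf.p_right, "right", "left")
        pts = np.empty((m, 3))
        ux, uy, uz = x_pdf.sample(rng, m), y_pdf.sample(rng, m), z_pdf.sample(rng, m)
        for side_name, mirror in (("right", False), ("left", True)):
            mask = s == side_name
            if not mask.any():
                continue
            lo, hi = boxes[side_name]
            pts[mask, 0] = _map_axis(ux[mask], lo[0], hi[0], mirror)
            pts[mask, 1] = _map_axis(uy[mask], lo[1], hi[1], False)
            pts[mask, 2] = _map_axis(uz[mask], lo[2], hi[2], False)
        if clip_to_region:
            ok = region.contains(pts)
        else:
            ok = np.ones(m, dtype=bool)
        k = int(ok.sum())
        coords[filled:filled + k] = pts[ok]
        sides[filled:filled + k] = s[ok]
        filled += k
        if attempts >= 100 * n and filled < attempts / 100.0:
            raise InvalidConfigError(
                "rejection acceptance below 1%: the PDFs are inconsistent with the lung region")

    return LesionSet(coords=coords, phase=phase, replicate=replicate, seed=int(seed),
                     sides=sides,
                     pdf_provenance={
                         "x": (list(x_pdf.edges), list(x_pdf.probs)),
                         "y": (list(y_pdf.edges), list(y_pdf.probs)),
                         "z": (list(z_pdf.edges), list(z_pdf.probs)),
                         "side": (side_pdf.p_right, side_pdf.p_left),
                         "clip_to_region": clip_to_region,
                     })


# fixed integer offsets deriving one sub-seed per (phase, replicate)
_PHASE_OFFSET = {"inspiration": 0, "expiration": 100_000}
_REPLICATE_OFFSET = 1_000


def subseed(master_seed: int, phase: str, replicate: int) -> int:
    return (int(master_seed) + _PHASE_OFFSET[phase]
            + _REPLICATE_OFFSET * int(replicate)) % (2**31)


def generate_study_design(seed: int, config: Optional[GrowthConfig] = None,
                          pdfs=None, n: int = 1000, replicates: int = 3,
                          clip_to_region: bool = False) -> list[LesionSet]:
    """The full lesion design: ``replicates`` sets of ``n`` lesions per
    respiratory phase (default 3 x 1000 x 2 phases = 6 sets), each drawn with
    its own sub-seed against its phase's lung bounding boxes.
    """
    if config is None:
        config = GrowthConfig()
    if pdfs is None:
        pdfs = default_nelson_pdfs()
    sets = []
    for phase, capacity in (("inspiration", config.capacity_inspiration),
                            ("expiration", config.capacity_expiration)):
        region = make_lung_region(config, capacity=capacity)
        boxes = bounding_box(region)
        for rep in range(1, replicates + 1):
            sets.append(sample_lesions(
                pdfs, boxes, n=n, seed=subseed(seed, phase, rep),
                clip_to_region=clip_to_region, region=region,
                phase=phase, replicate=rep))
    return sets
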