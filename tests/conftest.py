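"""Shared fixtures: small airway trees, lung regions, and the full-scale
default study (session-scoped; all fixtures are generated in-process)."""

from __future__ import annotations

import numpy as np
import pytest

from bronchoreach.airway_model import (GrowthConfig, generate_tree,
                                       make_lung_region)
from bronchoreach.cli_report import StudyConfig, run_study

MASTER_SEED = 0  # canonical seed for every seeded test


@pytest.fixture(scope="session")
def default_config() -> GrowthConfig:
    return GrowthConfig()


@pytest.fixture(scope="session")
def lung_region(default_config):
    return make_lung_region(default_config)


@pytest.fixture(scope="session")
def default_tree(default_config, lung_region):
    """The full 3311-branch inspiration tree."""
    return generate_tree(default_config, lung_region)


@pytest.fixture(scope="session")
def small_tree(default_config, lung_region):
    """A ~51-branch tree for brute-force oracle comparisons."""
    cfg = GrowthConfig(max_branches=51)
    return generate_tree(cfg, lung_region)


@pytest.fixture(scope="session")
def default_bundle():
    """The full default study (2 phases x 3 replicates x 1000 lesions)."""
    return run_study(StudyConfig(seed=MASTER_SEED))


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def point_segment_distance_scalar(p, a, b) -> float:
    """Plain scalar point-to-segment distance (oracle implementation)."""
    p, a, b = (np.asarray(v, dtype=float) for v in (p, a, b))
    ab = b - a
    denom = float(ab @ ab)
    t = 0.0 if denom == 0 else float(np.clip((p - a) @ ab / denom, 0.0, 1.0))
    return float(np.linalg.norm(p - (a + t * ab)))


def brute_force_contact(center, lesion_diameter, tree) -> np.ndarray:
    """Oracle: per-branch capsule-distance scan, one branch at a time."""
    r = lesion_diameter / 2.0
    touched = set()
    for b in tree.branches:
        d = point_segment_distance_scalar(center, b.start, b.end) - b.radius
        if d <= r:
            touched.add(b.diameter)
    return np.array(sorted(touched))


def brute_force_nearest(point, tree, min_diameter) -> float:
    best = np.inf
    for b in tree.branches:
        if b.diameter < min_diameter:
            continue
        d = point_segment_distance_scalar(point, b.start, b.end) - b.radius
        best = min(best, max(d, 0.0))
    return float(best)


def ray_parity_inside(surface, points, rng) -> np.ndarray:
    """Oracle: single-ray crossing parity (random but seeded direction)."""
    from bronchoreach.geometry import _ray_triangle_batch
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    tri = surface.vertices[surface.faces]
    pts = np.atleast_2d(points)
    dirs = np.tile(direction, (len(pts), 1))
    t = _ray_triangle_batch(pts, dirs, tri)
    crossings = np.isfinite(t).sum(axis=1)
    return crossings % 2 == 1
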