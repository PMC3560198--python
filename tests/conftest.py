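"""Shared fixtures: one fully generated + analysed synthetic section.

The default 50-fibre section (seed 42) is generated once per session and
reused by every test that needs realistic imagery, keeping the suite
fast while exercising the full pipeline.
"""

from __future__ import annotations

import numpy as np
import pytest

from myofibre import analyze_channel_set
from myofibre.synthetic import SectionSpec, generate_section


@pytest.fixture(scope="session")
def section42():
    """(ChannelSet, GroundTruth) of the default 50-fibre section, seed 42."""
    return generate_section(SectionSpec(seed=42))


@pytest.fixture(scope="session")
def analysis42(section42):
    """Full pipeline result on the seed-42 section."""
    channels, _ = section42
    return analyze_channel_set(channels)


def brute_force_min_feret(points: np.ndarray, step_deg: float = 0.05) -> float:
    """Oracle: minimum projection width over a dense angle grid."""
    pts = np.asarray(points, dtype=float)
    angles = np.deg2rad(np.arange(0.0, 180.0, step_deg))
    dirs = np.stack([np.cos(angles), np.sin(angles)])  # (2, n_angles)
    proj = pts @ dirs
    widths = proj.max(axis=0) - proj.min(axis=0)
    return float(widths.min())


def random_convex_polygon(rng: np.random.Generator, n_points: int = 30) -> np.ndarray:
    """Vertices of the convex hull of a random Gaussian point cloud."""
    from scipy.spatial import ConvexHull

    pts = rng.normal(scale=20.0, size=(n_points, 2)) + rng.uniform(0, 50, size=2)
    hull = ConvexHull(pts)
    return pts[hull.vertices]
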