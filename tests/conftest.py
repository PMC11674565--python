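"""Shared fixtures: a scaled-down MRT lattice and imaging conditions.

Unit tests run on a half-pitch lattice (25 µm beams at 200 µm pitch)
and small images so each synthetic render takes a fraction of a second;
the acceptance tests use the full reference geometry.
"""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from mrtbio import BeamGeometry, ImagingConfig, generate, generate_uniform


@pytest.fixture(scope="session")
def test_geometry() -> BeamGeometry:
    """Scaled-down striped field: 25 µm peaks, 200 µm pitch, PVDR 8.9."""
    return BeamGeometry(
        peak_width=25.0, pitch=200.0, pvdr=8.9, valley_dose=0.5, n_beams=3
    )


@pytest.fixture(scope="session")
def small_config() -> ImagingConfig:
    """Small image (455 x 195 µm, two full periods) with ~150 nuclei."""
    return ImagingConfig(
        image_width=700, image_height=300, n_nuclei=150, nucleus_radius_mean=5.0,
        nucleus_radius_sd=0.6, seed=0,
    )


@pytest.fixture(scope="session")
def mrt_bundle(test_geometry, small_config):
    return generate(test_geometry, small_config.with_seed(11))


@pytest.fixture(scope="session")
def uniform_bundle(small_config):
    return generate_uniform(0.5, small_config.with_seed(12))


def match_detections(detected_xy: np.ndarray, true_xy: np.ndarray, radius_um: float):
    """Greedy bipartite matching of detections to truth within a radius.

    Returns (hits, n_true, n_detected) for recall/precision computation.
    """
    if len(detected_xy) == 0 or len(true_xy) == 0:
        return 0, len(true_xy), len(detected_xy)
    tree = cKDTree(detected_xy)
    used: set[int] = set()
    hits = 0
    for p in true_xy:
        for i in sorted(
            tree.query_ball_point(p, radius_um),
            key=lambda i: float(np.hypot(*(detected_xy[i] - p))),
        ):
            if i not in used:
                used.add(i)
                hits += 1
                break
    return hits, len(true_xy), len(detected_xy)
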