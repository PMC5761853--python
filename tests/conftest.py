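import numpy as np
import pytest

import mvlattice as mv


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def small_map(rng):
    """A 64x64 random rough surface at 7 nm/px."""
    return mv.HeightMap(rng.normal(0.0, 3.0, (64, 64)), 7.0)


@pytest.fixture(scope="session")
def hex_field():
    """Default hexagonal field (a=169 nm) with ground truth, one seed."""
    return mv.generate_field(mv.LatticeSpec("hexagonal", a=169.0), seed=11)


@pytest.fixture(scope="session")
def rhombic_field():
    """Default rhombic field (a=185 nm, theta=80 deg) with ground truth."""
    return mv.generate_field(
        mv.LatticeSpec("rhombic", a=185.0, theta_deg=80.0), seed=21
    )


def match_detections(positions_nm, truth_nm, radius_nm=30.0):
    """(recall, precision) by nearest-neighbor matching at a radius."""
    from scipy import spatial

    if len(positions_nm) == 0 or len(truth_nm) == 0:
        return 0.0, 0.0
    d_t, _ = spatial.cKDTree(positions_nm).query(truth_nm)
    d_p, _ = spatial.cKDTree(truth_nm).query(positions_nm)
    return float(np.mean(d_t <= radius_nm)), float(np.mean(d_p <= radius_nm))
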