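"""Shared fixtures: study-condition models and small synthetic data sets."""

from __future__ import annotations

import numpy as np
import pytest

from barlattice.lattice import (
    MAJOR_CLASS_GEOMETRY,
    MAJOR_CLASS_SYMMETRY,
    HelicalSymmetry,
    TubeGeometry,
)
from barlattice.segments import CTFParams
from barlattice.simulate import build_tube_volume, default_tube_model


@pytest.fixture(scope="session")
def sym():
    return MAJOR_CLASS_SYMMETRY


@pytest.fixture(scope="session")
def geom():
    return MAJOR_CLASS_GEOMETRY


@pytest.fixture(scope="session")
def tube_model():
    return default_tube_model()


@pytest.fixture(scope="session")
def ctf():
    return CTFParams(defocus=1.5, pixel_size=3.0)


@pytest.fixture(scope="session")
def tube_volume(tube_model):
    """Major-class tube at the working scale (96³, 3 Å voxels)."""
    return build_tube_volume(tube_model, 3.0, 96)


@pytest.fixture(scope="session")
def fine_tube_volume(tube_model):
    """Finer grid (160³, 2 Å) for radial measurements."""
    return build_tube_volume(tube_model, 2.0, 160)


@pytest.fixture(scope="session")
def membrane_volume(tube_model):
    return build_tube_volume(tube_model, 2.0, 160, with_protein=False)


@pytest.fixture(scope="session")
def fine_symmetrized(fine_tube_volume, sym):
    """Fine-grid volume symmetrized once (shared: symmetrize is costly)."""
    from barlattice.reconstruct import symmetrize

    return symmetrize(fine_tube_volume, sym, k_range=10)


@pytest.fixture(scope="session")
def fine_symmetrized_twice(fine_symmetrized, sym):
    from barlattice.reconstruct import symmetrize

    return symmetrize(fine_symmetrized, sym, k_range=10)


def correlation(a: np.ndarray, b: np.ndarray) -> float:
    x = np.asarray(a, dtype=np.float64).ravel()
    y = np.asarray(b, dtype=np.float64).ravel()
    x = x - x.mean()
    y = y - y.mean()
    return float(x @ y / np.sqrt((x @ x) * (y @ y)))
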