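"""Shared fixtures: study phantoms, desk-scale geometry, and a cache of
noiseless forward projections so independent tests do not recompute them."""

from __future__ import annotations

import numpy as np
import pytest

from cbctiq.acquisition import desk_geometry, project_angles, protocol_angles, study_protocols
from cbctiq.phantoms import make_cylinder_phantom, make_pelvis_phantom
from cbctiq.reconstruction import desk_settings


@pytest.fixture(scope="session")
def geometry():
    return desk_geometry()


@pytest.fixture(scope="session")
def settings():
    return desk_settings()


@pytest.fixture(scope="session")
def water_phantom():
    return make_cylinder_phantom(spacing_mm=1.0)


@pytest.fixture(scope="session")
def half_phantom():
    return make_cylinder_phantom(spacing_mm=1.0, fill="half")


@pytest.fixture(scope="session")
def pelvis_phantom():
    return make_pelvis_phantom(spacing_mm=1.0)


@pytest.fixture(scope="session")
def protocols_by_name():
    return {p.name: p for p in study_protocols()}


@pytest.fixture(scope="session")
def ideal_projections(geometry, water_phantom, half_phantom, pelvis_phantom, protocols_by_name):
    """Memoized noiseless projections: (phantom_key, protocol_name) -> array."""
    phantoms = {"water": water_phantom, "half": half_phantom, "pelvis": pelvis_phantom}
    cache: dict[tuple[str, str], np.ndarray] = {}

    def get(phantom_key: str, protocol_name: str) -> np.ndarray:
        key = (phantom_key, protocol_name)
        if key not in cache:
            proto = protocols_by_name[protocol_name]
            cache[key] = project_angles(
                phantoms[phantom_key], geometry, protocol_angles(proto)
            )
        return cache[key]

    return get
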