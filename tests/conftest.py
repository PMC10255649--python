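"""Shared fixtures: deterministic phantoms and cached simulation runs."""

from dataclasses import replace

import pytest

from toothmc.geometry import GeometryParams, embed_in_bounding_box, generate_tooth_model
from toothmc.io import make_fixture
from toothmc.optics import load_media
from toothmc.transport import SimulationConfig, auto_probes, run_simulation


@pytest.fixture(scope="session")
def tiny_bundle():
    """Two-layer slab phantom with mismatched indices (oracle tests)."""
    return make_fixture("tiny")


@pytest.fixture(scope="session")
def tiny_run(tiny_bundle):
    src, dets = tiny_bundle["plan"].resolve(tiny_bundle["grid"])
    return run_simulation(
        tiny_bundle["grid"], tiny_bundle["media"], tiny_bundle["config"], src, dets
    )


@pytest.fixture(scope="session")
def coarse_tooth():
    """Calibrated crown at 0.1 mm pitch (fast geometry checks)."""
    return generate_tooth_model(GeometryParams(pitch_mm=0.1))


@pytest.fixture(scope="session")
def small_tooth_grid():
    """Crown at 0.15 mm pitch embedded in its bounding box (end-to-end runs)."""
    bundle = make_fixture("small")
    return bundle["grid"]


def _run(grid, wavelength_nm, mode, wsr, n_photons, seed=5, radius=None, sds=None):
    media = load_media(wavelength_nm)
    if sds is None:
        sds = (0.25, 0.75, 1.5) if mode == "reflectance" else (7.0,)
    if radius is None:
        radius = 0.2 if mode == "reflectance" else 1.0
    src, dets = auto_probes(grid, mode, sds, radius_mm=radius)
    cfg = SimulationConfig(n_photons=n_photons, seed=seed, wsr=wsr)
    return run_simulation(grid, media, cfg, src, dets)


@pytest.fixture(scope="session")
def tooth_runs(small_tooth_grid):
    """Lazily cached tooth runs keyed by (wavelength, mode, wsr, n_photons)."""
    cache = {}

    def get(wavelength_nm, mode, wsr=True, n_photons=1_000_000):
        key = (wavelength_nm, mode, wsr, n_photons)
        if key not in cache:
            cache[key] = _run(small_tooth_grid, wavelength_nm, mode, wsr, n_photons)
        return cache[key]

    return get
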