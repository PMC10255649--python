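"""Transport engine: conservation, closed-form oracles, determinism, gating."""

import math
from dataclasses import replace

import numpy as np
import pytest

from toothmc.errors import ConfigurationError, NoDetectionError
from toothmc.geometry import make_slab
from toothmc.io import make_fixture
from toothmc.optics import MediumTable, OpticalProperties
from toothmc.transport import (
    SimulationConfig,
    SourceSpec,
    auto_probes,
    batch_error_rate,
    convergence_rate,
    launch_photon,
    propagate_packet,
    run_simulation,
)

ABSORBER = MediumTable(
    wavelength_nm=633,
    media={
        0: OpticalProperties(10.0, 10.0, 0.9, 1.0),
        1: OpticalProperties(1.0, 1e-9, 0.0, 1.0),  # pure absorber, matched index
        2: OpticalProperties(0.2, 10.0, 0.9, 1.0),
        3: OpticalProperties(0.035, 10.0, 0.97, 1.39),
    },
)


def _absorber_slab_run(thickness_mm, n_photons=100_000, seed=3):
    grid = make_slab([(1, thickness_mm)], pitch_mm=0.05, lateral_mm=2.0, pad_voxels=4)
    src, dets = auto_probes(
        grid, "transmittance", (thickness_mm + 0.1,), radius_mm=1.2
    )
    cfg = SimulationConfig(n_photons=n_photons, seed=seed, wsr=True)
    return run_simulation(grid, ABSORBER, cfg, src, dets)


@pytest.mark.parametrize("thickness", [0.5, 1.0, 2.0])
def test_beer_lambert_slab_transmission(thickness):
    """Ballistic transmission through a pure absorber equals exp(-mu_a d)."""
    res = _absorber_slab_run(thickness)
    n = res.config.n_photons
    p = math.exp(-1.0 * thickness)
    se = math.sqrt(p * (1 - p) / n)
    assert res.detected_weight / res.launched_weight == pytest.approx(p, abs=3 * se)


def test_energy_ledger_conservation(tiny_run, tiny_bundle):
    for res in (
        tiny_run,
        run_simulation(
            tiny_bundle["grid"],
            tiny_bundle["media"],
            replace(tiny_bundle["config"], wsr=False),
            *tiny_bundle["plan"].resolve(tiny_bundle["grid"]),
        ),
    ):
        total = res.absorbed_weight + res.escaped_weight + res.residual_weight
        assert total == pytest.approx(res.launched_weight, rel=1e-6)


def test_no_absorption_conserves_escape():
    """With mu_a = 0 and matched indices, all launched weight escapes."""
    grid = make_slab([(1, 0.5)], pitch_mm=0.05, lateral_mm=1.0, pad_voxels=2)
    media = MediumTable(
        wavelength_nm=633,
        media={
            0: OpticalProperties(0.0, 20.0, 0.0, 1.0),
            1: OpticalProperties(0.0, 5.0, 0.8, 1.0),
            2: OpticalProperties(0.2, 10.0, 0.9, 1.0),
            3: OpticalProperties(0.035, 10.0, 0.97, 1.39),
        },
    )
    src, dets = auto_probes(grid, "transmittance", (0.6,), radius_mm=1.0)
    cfg = SimulationConfig(n_photons=2000, seed=1, wsr=True, roulette_threshold=0.0)
    res = run_simulation(grid, media, cfg, src, dets)
    assert res.absorbed_weight == pytest.approx(0.0, abs=1e-12)
    assert res.escaped_weight + res.residual_weight == pytest.approx(
        res.launched_weight, rel=1e-9
    )
    assert np.all(res.fluence >= 0) and np.all(np.isfinite(res.fluence))


def test_same_seed_is_bit_identical(tiny_bundle, tiny_run):
    src, dets = tiny_bundle["plan"].resolve(tiny_bundle["grid"])
    again = run_simulation(
        tiny_bundle["grid"], tiny_bundle["media"], tiny_bundle["config"], src, dets
    )
    assert np.array_equal(again.records, tiny_run.records)
    assert again.detected_weight == tiny_run.detected_weight
    assert np.array_equal(again.fluence, tiny_run.fluence)


def test_matched_index_wsr_equivalence():
    """With all refractive indices equal, the WSR flag changes nothing."""
    bundle = make_fixture("tiny", matched_index=True)
    src, dets = bundle["plan"].resolve(bundle["grid"])
    runs = [
        run_simulation(
            bundle["grid"], bundle["media"], replace(bundle["config"], wsr=wsr), src, dets
        )
        for wsr in (True, False)
    ]
    assert np.array_equal(runs[0].records, runs[1].records)
    assert runs[0].detected_weight == runs[1].detected_weight


def test_detected_weight_decreases_with_absorption(tiny_bundle, tiny_run):
    """Raising dentin-layer mu_a by 50% strictly lowers detected weight."""
    base_props = tiny_bundle["media"].media[2]
    harder = MediumTable(
        wavelength_nm=633,
        media={
            **tiny_bundle["media"].media,
            2: OpticalProperties(
                base_props.mu_a * 1.5, base_props.mu_s, base_props.g, base_props.n
            ),
        },
    )
    src, dets = tiny_bundle["plan"].resolve(tiny_bundle["grid"])
    res = run_simulation(tiny_bundle["grid"], harder, tiny_bundle["config"], src, dets)
    assert res.detected_weight < tiny_run.detected_weight


def test_time_gating(tiny_run):
    cfg = tiny_run.config
    assert np.all(tiny_run.records["t_ns"] <= cfg.t_end_ns)
    gates = np.floor(tiny_run.records["t_ns"] / cfg.t_step_ns).astype(int)
    gates = np.minimum(gates, cfg.n_gates - 1)
    assert np.array_equal(gates, tiny_run.records["gate"])
    occupancy = np.bincount(tiny_run.records["gate"], minlength=cfg.n_gates)
    assert occupancy.sum() == tiny_run.records.shape[0]


def test_launch_photon_specular_weight(tiny_bundle):
    grid = make_slab([(1, 1.0)], pitch_mm=0.05, lateral_mm=2.0, pad_voxels=4)
    media = MediumTable(
        wavelength_nm=633,
        media={
            0: OpticalProperties(10.0, 10.0, 0.9, 1.0),
            1: OpticalProperties(0.04, 1.5, 0.7, 1.63),  # enamel
            2: OpticalProperties(0.3, 26.0, 0.93, 1.54),
            3: OpticalProperties(0.035, 10.0, 0.97, 1.39),
        },
    )
    src, _ = auto_probes(grid, "transmittance", (1.1,), radius_mm=1.0)
    wsr_cfg = SimulationConfig(n_photons=10, seed=0, wsr=True)
    packet = launch_photon(src, grid, media, wsr_cfg, j=0)
    assert packet.t_ns == 0.0
    assert packet.w == pytest.approx(1 - (0.63 / 2.63) ** 2, abs=1e-9)
    packet = launch_photon(src, grid, media, replace(wsr_cfg, wsr=False), j=0)
    assert packet.w == 1.0


def test_propagate_packet_matches_run_records(tiny_bundle, tiny_run):
    """The single-packet surface reproduces a detected record exactly."""
    src, dets = tiny_bundle["plan"].resolve(tiny_bundle["grid"])
    rec = tiny_run.records[0]
    status, single = propagate_packet(
        int(rec["j"]), tiny_bundle["grid"], tiny_bundle["media"],
        tiny_bundle["config"], src, dets,
    )
    assert status == "detected"
    for f in ("w", "t_ns", "pp_enamel", "pp_dentin", "pp_pulp"):
        assert single[f] == rec[f]


def test_convergence_rate_values():
    assert convergence_rate(5e8) == pytest.approx(4.47e-5, rel=1e-3)
    assert convergence_rate(1) == 1.0
    assert convergence_rate(10**6) == pytest.approx(1e-3, rel=1e-12)
    with pytest.raises(ConfigurationError):
        convergence_rate(0)


def test_batch_error_rate():
    assert batch_error_rate([2, 2, 2, 2, 2]) == 0.0
    assert batch_error_rate([1, 3]) == pytest.approx(math.sqrt(2) / 2, rel=1e-12)
    with pytest.raises(ConfigurationError):
        batch_error_rate([1.0])
    with pytest.raises(NoDetectionError):
        batch_error_rate([0.0, 0.0])


def test_batch_error_scales_as_inverse_sqrt_n():
    """The batch CV drops roughly as 1/sqrt(N) over a 10x photon range."""
    lo = _absorber_slab_run(1.0, n_photons=20_000, seed=9)
    hi = _absorber_slab_run(1.0, n_photons=200_000, seed=9)
    ratio = batch_error_rate(lo.batch_totals) / batch_error_rate(hi.batch_totals)
    assert math.sqrt(10) / 2.5 < ratio < math.sqrt(10) * 2.5


def test_config_validation():
    with pytest.raises(ConfigurationError):
        SimulationConfig(n_photons=0)
    with pytest.raises(ConfigurationError):
        SimulationConfig(n_photons=100, t_end_ns=1.0, t_step_ns=0.3)
    with pytest.raises(ConfigurationError):
        SourceSpec((0, 0, 0), (0.5, 0.5, 0.7071))  # not axis-aligned
    cfg = SimulationConfig(n_photons=100)
    assert cfg.n_gates == 10


def test_transmittance_sds_must_exceed_thickness():
    grid = make_slab([(1, 2.0)], pitch_mm=0.1, lateral_mm=2.0)
    with pytest.raises(ConfigurationError):
        auto_probes(grid, "transmittance", (1.0,))
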