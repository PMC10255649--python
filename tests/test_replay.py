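"""Photon replay and Jacobians: bit-identity, map consistency, perturbation."""

import math
from dataclasses import replace as dc_replace

import numpy as np
import pytest

from toothmc.analysis import summarize_pathlengths
from toothmc.errors import ConfigurationError, NoDetectionError, ReplayIntegrityError
from toothmc.geometry import VoxelGrid
from toothmc.optics import MediumTable, OpticalProperties
from toothmc.replay import (
    SensitivityVolume,
    contribution_table,
    jacobian_mu_a,
    jacobian_mu_s,
    replay_detected,
)
from toothmc.transport import RECORD_DTYPE, run_simulation


def _records(rows):
    """Build a record array from dicts of field values."""
    rec = np.zeros(len(rows), dtype=RECORD_DTYPE)
    rec["w"] = 1.0
    for i, row in enumerate(rows):
        for k, v in row.items():
            rec[i][k] = v
    return rec


@pytest.fixture(scope="module")
def tiny_replay(tiny_run):
    return replay_detected(tiny_run, tol=1e-12)


def test_replay_reproduces_every_record(tiny_replay):
    # replay_detected raises ReplayIntegrityError on any mismatch; reaching
    # here means every packet replayed bit-for-bit within 1e-12
    mpp, nsc, wdp = tiny_replay
    assert np.all(mpp.values >= 0)
    assert np.all(nsc.values >= 0)


def test_replay_integrity_error_on_tampered_record(tiny_run):
    tampered = tiny_run.records.copy()
    tampered["w"][0] *= 1.0 + 1e-6
    bad_run = dc_replace(tiny_run, records=tampered)
    with pytest.raises(ReplayIntegrityError, match="record 0"):
        replay_detected(bad_run)


def test_mpp_map_sums_to_mtp(tiny_run, tiny_replay):
    """Summing MPP over voxels equals the mean total pathlength."""
    mpp = tiny_replay[0]
    summary = summarize_pathlengths(tiny_run.records)
    assert mpp.all_gates.sum() == pytest.approx(summary.mtp_mm, rel=1e-6)


def test_single_photon_mpp_is_its_chords(tiny_run):
    """For one detected photon the MPP map integrates to its total pathlength."""
    single = dc_replace(tiny_run, records=tiny_run.records[:1])
    mpp, _, _ = replay_detected(single)
    rec = tiny_run.records[0]
    total = rec["pp_enamel"] + rec["pp_dentin"] + rec["pp_pulp"]
    assert mpp.all_gates.sum() == pytest.approx(total, rel=1e-9)
    assert mpp.normalization == rec["w"]


def test_per_gate_maps_sum_to_all_gates(tiny_run, tiny_replay):
    mpp_gated, nsc_gated, _ = replay_detected(tiny_run, per_gate=True)
    assert np.abs(mpp_gated.values.sum(axis=0) - tiny_replay[0].all_gates).max() < 1e-9
    assert np.abs(nsc_gated.values.sum(axis=0) - tiny_replay[1].all_gates).max() < 1e-9


def test_jacobian_mu_a_is_negated_mpp(tiny_replay):
    mpp = tiny_replay[0]
    jac = jacobian_mu_a(mpp)
    assert np.array_equal(jac.values, -mpp.values)
    assert np.all(jac.values <= 0)
    assert jac.kind == "jac_mua"
    zero = SensitivityVolume(np.zeros((1, 2, 2, 2)), "mpp", "all", 1.0, 0.1)
    assert not jacobian_mu_a(zero).values.any()
    with pytest.raises(ConfigurationError):
        jacobian_mu_a(jac)


def test_jacobian_mu_s_pointwise_arithmetic():
    labels = np.full((1, 1, 3), 2, dtype=np.uint8)
    labels[0, 0, 2] = 0
    grid = VoxelGrid(labels=labels, pitch_mm=1.0)
    media = MediumTable(
        wavelength_nm=633,
        media={
            0: OpticalProperties(10, 10, 0.9, 1.0),
            1: OpticalProperties(0.04, 1.5, 0.7, 1.63),
            2: OpticalProperties(0.3, 2.0, 0.93, 1.54),  # mu_s = 2
            3: OpticalProperties(0.035, 10, 0.97, 1.39),
        },
    )
    mpp = SensitivityVolume(np.array([[[[3.0, 5.0, 0.0]]]]), "mpp", "all", 1.0, 1.0)
    nsc = SensitivityVolume(np.array([[[[10.0, 10.0, 0.0]]]]), "nsc_mean", "all", 1.0, 1.0)
    jac = jacobian_mu_s(nsc, mpp, media, grid)
    # Nsc/mu_s - MPP: 10/2 - 3 = 2; scattering-neutral voxel 10/2 - 5 = 0
    assert jac.values[0, 0, 0, 0] == pytest.approx(2.0)
    assert jac.values[0, 0, 0, 1] == pytest.approx(0.0)
    assert jac.values[0, 0, 0, 2] == 0.0  # untraversed non-tissue voxel

    bad_media = MediumTable(
        wavelength_nm=633,
        media={**media.media, 2: OpticalProperties(0.3, 0.0, 0.0, 1.54)},
    )
    with pytest.raises(ConfigurationError):
        jacobian_mu_s(nsc, mpp, bad_media, grid)


def test_jacobian_validated_by_finite_difference(tiny_bundle, tiny_run):
    """-MPP_tissue predicts the log-signal change under a small mu_a bump."""
    dmua = 0.02
    summary = summarize_pathlengths(tiny_run.records)
    predicted = -dmua * summary.mpp_mm["dentin"]
    props = tiny_bundle["media"].media[2]
    perturbed = MediumTable(
        wavelength_nm=633,
        media={
            **tiny_bundle["media"].media,
            2: OpticalProperties(props.mu_a + dmua, props.mu_s, props.g, props.n),
        },
    )
    src, dets = tiny_bundle["plan"].resolve(tiny_bundle["grid"])
    res2 = run_simulation(
        tiny_bundle["grid"], perturbed, tiny_bundle["config"], src, dets
    )
    direct = math.log(res2.detected_weight / tiny_run.detected_weight)

    def se_log(res):
        t = res.batch_totals
        return t.std(ddof=1) / t.mean() / math.sqrt(len(t))

    combined = math.hypot(se_log(tiny_run), se_log(res2))
    assert abs(predicted - direct) < 3 * combined


def test_contribution_table_arithmetic():
    all_pulp = _records([{"pp_pulp": 4.0}, {"pp_pulp": 1.0}])
    table = contribution_table(all_pulp)
    assert table["pulp"]["contribution_pct"] == pytest.approx(100.0)
    assert table["enamel"]["contribution_pct"] == 0.0

    mixed = _records(
        [
            {"w": 1.0, "pp_enamel": 2.0, "pp_dentin": 1.0},
            {"w": 3.0, "pp_enamel": 6.0, "pp_pulp": 2.0},
        ]
    )
    table = contribution_table(mixed)
    # weighted sums: enamel 1*2+3*6=20, dentin 1, pulp 6
    assert table["enamel"]["weighted_detected_photons"] == pytest.approx(20.0)
    total_pct = sum(v["contribution_pct"] for v in table.values())
    assert total_pct == pytest.approx(100.0, abs=1e-9)

    with pytest.raises(NoDetectionError):
        contribution_table(np.zeros(0, dtype=RECORD_DTYPE))


def test_contribution_table_on_run(tiny_run, tiny_replay):
    """Record-level and voxel-level weighted pathlength sums agree."""
    table = contribution_table(tiny_run.records, tiny_run.grid)
    _, _, wdp = tiny_replay
    vox_total = wdp.all_gates.sum() * tiny_run.grid.voxel_volume_mm3
    rec_total = sum(
        v["weighted_detected_photons"] for v in table.values()
    ) * tiny_run.grid.voxel_volume_mm3
    assert rec_total == pytest.approx(vox_total, rel=1e-9)
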