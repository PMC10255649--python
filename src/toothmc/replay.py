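"""Perturbation Monte Carlo by photon replay: voxelwise sensitivities.

The forward run stores, for every detected packet, its exit weight and the
counter-based random-stream handle that generated it.  Replay re-propagates
exactly those packets (bit-for-bit the same path) while accumulating, per
voxel Vi and time gate T,

* the weighted chord sum  sum_j Wj * PP_j(Vi, T), and
* the weighted scattering-event count  sum_j Wj * Nsc_j(Vi, T),

both normalized by the total detected weight over *all* gates, giving the
mean partial pathlength map MPP(Vi, T) and mean scattering count Nsc(Vi, T).
From these the absorption and scattering Jacobians follow as

    J_mu_a(Vi, T) = -MPP(Vi, T)
    J_mu_s(Vi, T) =  Nsc(Vi, T) / mu_s(Vi) - MPP(Vi, T)

The weighted-detected-photon spatial-sensitivity map is the unnormalized
weighted chord sum divided by the voxel volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import kernels
from .errors import ConfigurationError, NoDetectionError, ReplayIntegrityError
from .geometry import VoxelGrid
from .optics import MediumTable
from .transport import RunResult, _kernel_args

__all__ = [
    "SensitivityVolume",
    "replay_detected",
    "jacobian_mu_a",
    "jacobian_mu_s",
    "contribution_table",
]

TISSUES = ("enamel", "dentin", "pulp")


@dataclass
class SensitivityVolume:
    """A voxelwise map with its normalization metadata.

    ``values`` has shape (n_gates, nx, ny, nz); a single gate slab means the
    map integrates all time gates.  ``kind`` is one of 'mpp' (mm), 'nsc_mean'
    (counts), 'jac_mua' / 'jac_mus', or 'wdp' (weighted detected photons per
    voxel volume).  ``normalization`` is the total detected weight sum_j Wj
    over all detected photons used as the denominator of the normalized maps.
    """

    values: np.ndarray
    kind: str
    time_gate: object  # "all" or number of gates
    normalization: float
    pitch_mm: float

    @property
    def all_gates(self) -> np.ndarray:
        """Map summed over time gates."""
        return self.values.sum(axis=0)

    def gate(self, t: int) -> np.ndarray:
        return self.values[t]


def replay_detected(
    result: RunResult,
    per_gate: bool = False,
    tol: float = 1e-9,
):
    """Replay all detected packets of ``result``.

    Returns ``(mpp, nsc_mean, wdp)`` as :class:`SensitivityVolume` objects.
    Raises :class:`ReplayIntegrityError` if any replayed packet fails to
    reproduce its recorded exit weight, exit time, or per-tissue pathlengths
    within ``tol``.
    """
    result.require_detection()
    grid, media, cfg = result.grid, result.media, result.config
    args = _kernel_args(grid, media, cfg, result.source, result.detectors)
    records = result.records
    n_gates = cfg.n_gates if per_gate else 1
    shape = (n_gates,) + grid.shape
    path_acc = np.zeros(shape, dtype=np.float64)
    nsc_acc = np.zeros(shape, dtype=np.float64)
    rec_pp = np.stack([records[f] for f in ("pp_enamel", "pp_dentin", "pp_pulp")], axis=1)
    bad = kernels.replay_batch(
        np.uint64(cfg.seed),
        records["j"].astype(np.int64),
        records["w"].astype(np.float64),
        records["t_ns"].astype(np.float64),
        np.ascontiguousarray(rec_pp, dtype=np.float64),
        records["gate"].astype(np.int64),
        args["labels"], args["pitch"], args["ox"], args["oy"], args["oz"],
        args["mua"], args["mus"], args["g_arr"], args["nref"], args["ambient_n"],
        args["sx"], args["sy"], args["sz"],
        args["dx0"], args["dy0"], args["dz0"], args["beam_r"], args["src_axis"],
        args["det_axis"], args["det_plane"], args["det_c1"], args["det_c2"],
        args["det_r2"],
        args["wsr"], args["t_end"], args["roulette_thr"], args["roulette_p"],
        args["max_steps"],
        path_acc, nsc_acc, tol,
    )
    if bad >= 0:
        raise ReplayIntegrityError(
            f"record {bad} (photon {int(records['j'][bad])}) did not replay "
            f"to its recorded exit state within {tol}"
        )
    w_total = float(records["w"].sum())
    gate_meta = cfg.n_gates if per_gate else "all"
    mpp = SensitivityVolume(path_acc / w_total, "mpp", gate_meta, w_total, grid.pitch_mm)
    nsc = SensitivityVolume(nsc_acc / w_total, "nsc_mean", gate_meta, w_total, grid.pitch_mm)
    wdp = SensitivityVolume(
        path_acc / grid.voxel_volume_mm3, "wdp", gate_meta, w_total, grid.pitch_mm
    )
    return mpp, nsc, wdp


def jacobian_mu_a(mpp_map: SensitivityVolume) -> SensitivityVolume:
    """Absorption Jacobian: pointwise negation of the MPP map (<= 0 everywhere)."""
    if mpp_map.kind != "mpp":
        raise ConfigurationError("jacobian_mu_a expects an MPP-type map")
    return SensitivityVolume(
        -mpp_map.values,
        "jac_mua",
        mpp_map.time_gate,
        mpp_map.normalization,
        mpp_map.pitch_mm,
    )


def jacobian_mu_s(
    nsc_map: SensitivityVolume,
    mpp_map: SensitivityVolume,
    media: MediumTable,
    grid: VoxelGrid,
) -> SensitivityVolume:
    """Scattering Jacobian: Nsc(Vi,T)/mu_s(Vi) - MPP(Vi,T) on tooth voxels."""
    if nsc_map.kind != "nsc_mean" or mpp_map.kind != "mpp":
        raise ConfigurationError("jacobian_mu_s expects (nsc_mean, mpp) maps")
    if nsc_map.time_gate != mpp_map.time_gate or (
        nsc_map.normalization != mpp_map.normalization
    ):
        raise ConfigurationError("nsc and mpp maps must share gate and normalization")
    mus = np.array([media.media[k].mu_s for k in range(4)])
    if np.any(mus[1:] <= 0):
        raise ConfigurationError("mu_s must be > 0 in every tissue for jacobian_mu_s")
    mus_vox = mus[grid.labels]
    tooth = grid.labels > 0
    values = np.zeros_like(mpp_map.values)
    for gidx in range(values.shape[0]):
        values[gidx][tooth] = (
            nsc_map.values[gidx][tooth] / mus_vox[tooth] - mpp_map.values[gidx][tooth]
        )
    return SensitivityVolume(
        values, "jac_mus", mpp_map.time_gate, mpp_map.normalization, mpp_map.pitch_mm
    )


def contribution_table(records: np.ndarray, grid: VoxelGrid | None = None):
    """Per-tissue weighted detected photons and percentage contribution.

    The weighted detected photons of tissue i is sum_j Wj * PP_j(i); divided
    by the voxel volume when ``grid`` is given (matching the voxelwise map
    convention).  Percentages sum to 100.
    """
    if records.shape[0] == 0:
        raise NoDetectionError("contribution table needs at least one detected photon")
    w = records["w"]
    weighted = np.array(
        [float((w * records[f"pp_{t}"]).sum()) for t in TISSUES]
    )
    total = weighted.sum()
    if total <= 0:
        raise NoDetectionError("detected photons carry no tissue pathlength")
    pct = 100.0 * weighted / total
    if grid is not None:
        weighted = weighted / grid.voxel_volume_mm3
    return {
        t: {"weighted_detected_photons": weighted[i], "contribution_pct": pct[i]}
        for i, t in enumerate(TISSUES)
    }
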