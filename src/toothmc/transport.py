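"""Photon-packet transport: run configuration, probes, and the simulation driver.

The driver launches packets in batches through the numba kernel
(:mod:`toothmc.kernels`), collects detected-packet records, the voxelwise
fluence map, and an energy ledger, and retains per-batch detected-weight
totals for the coefficient-of-variation error estimate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from . import kernels
from .errors import ConfigurationError, EmptyGeometryError, NoDetectionError
from .geometry import VoxelGrid
from .kernels import C_MM_PER_NS, photon_stream_state, propagate_one
from .optics import MediumTable

log = logging.getLogger("toothmc.transport")

__all__ = [
    "SourceSpec",
    "DetectorSpec",
    "SimulationConfig",
    "PhotonPacket",
    "RunResult",
    "RECORD_DTYPE",
    "auto_probes",
    "launch_photon",
    "propagate_packet",
    "run_simulation",
    "convergence_rate",
    "batch_error_rate",
]

RECORD_DTYPE = np.dtype(
    [
        ("j", "i8"),
        ("det", "i4"),
        ("gate", "i4"),
        ("w", "f8"),
        ("t_ns", "f8"),
        ("pp_enamel", "f8"),
        ("pp_dentin", "f8"),
        ("pp_pulp", "f8"),
        ("nsc_enamel", "i8"),
        ("nsc_dentin", "i8"),
        ("nsc_pulp", "i8"),
    ]
)

PP_FIELDS = ("pp_enamel", "pp_dentin", "pp_pulp")
NSC_FIELDS = ("nsc_enamel", "nsc_dentin", "nsc_pulp")


@dataclass(frozen=True)
class SourceSpec:
    """Gaussian pencil beam launched onto a flat tissue face.

    ``center_mm`` lies on the source face plane; ``direction`` is the inward
    unit vector along a grid axis; ``beam_waist_mm`` is the 1/e^2 *radius*
    (default 0.1 mm, i.e. a 200 um probe).
    """

    center_mm: tuple
    direction: tuple = (0.0, 0.0, 1.0)
    beam_waist_mm: float = 0.1

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise ConfigurationError("source direction must be a unit vector")
        if self.axis is None:
            raise ConfigurationError("source direction must be axis-aligned")
        if self.beam_waist_mm <= 0:
            raise ConfigurationError("beam_waist_mm must be > 0")

    @property
    def axis(self):
        d = np.asarray(self.direction, dtype=float)
        for a in range(3):
            if abs(abs(d[a]) - 1.0) < 1e-12:
                return a
        return None


@dataclass(frozen=True)
class DetectorSpec:
    """Circular detector disc on a flat tissue face.

    ``mode`` is 'reflectance' (same face as the source) or 'transmittance'
    (opposite face); ``sds_mm`` the center-to-center source-detector
    separation; ``axis`` the face-normal grid axis.
    """

    center_mm: tuple
    radius_mm: float = 0.1
    mode: str = "reflectance"
    sds_mm: float = 0.0
    axis: int = 2

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ConfigurationError("detector radius must be > 0")
        if self.mode not in ("reflectance", "transmittance"):
            raise ConfigurationError(f"unknown detector mode {self.mode!r}")
        if self.axis not in (0, 1, 2):
            raise ConfigurationError("detector axis must be 0, 1, or 2")

    @property
    def plane_mm(self) -> float:
        return float(self.center_mm[self.axis])


@dataclass(frozen=True)
class SimulationConfig:
    """Run controls: photon count, seed, boundary-reflection flag, gating.

    ``wsr`` toggles Fresnel reflection/refraction at every index-mismatched
    boundary including the specular loss at launch; with ``wsr=False`` packets
    cross boundaries undeflected and at full weight.  The 1 ns time frame is
    divided into ``t_end_ns / t_step_ns`` gates (default 10).  Russian
    roulette uses the standard multilayer-code values (threshold 1e-4,
    survival 0.1).
    """

    n_photons: int
    seed: int = 0
    wsr: bool = True
    t_end_ns: float = 1.0
    t_step_ns: float = 0.1
    roulette_threshold: float = 1e-4
    roulette_survival: float = 0.1
    n_batches: int = 5
    max_steps: int = 10_000_000

    def __post_init__(self) -> None:
        if self.n_photons < 1:
            raise ConfigurationError("n_photons must be >= 1")
        if self.t_end_ns <= 0 or self.t_step_ns <= 0:
            raise ConfigurationError("time frame and step must be > 0")
        gates = self.t_end_ns / self.t_step_ns
        if abs(gates - round(gates)) > 1e-9:
            raise ConfigurationError(
                f"t_end_ns / t_step_ns must be an integer gate count (got {gates})"
            )
        if not (0 < self.roulette_survival <= 1):
            raise ConfigurationError("roulette survival must lie in (0, 1]")
        if self.n_batches < 1 or self.n_batches > self.n_photons:
            raise ConfigurationError("n_batches must lie in [1, n_photons]")

    @property
    def n_gates(self) -> int:
        return int(round(self.t_end_ns / self.t_step_ns))


@dataclass
class PhotonPacket:
    """State of one photon packet (inspection/testing surface)."""

    pos_mm: np.ndarray
    direction: np.ndarray
    w: float
    t_ns: float
    pp_mm: np.ndarray
    nsc: np.ndarray
    rng_state_handle: tuple  # (seed, photon index)


@dataclass
class RunResult:
    """Aggregated output of :func:`run_simulation`.

    ``escaped_weight`` includes the detected weight (detected packets leave
    the tissue); ``detected_weight`` is also reported separately.  Energy
    conservation: launched = absorbed + escaped + residual (to 1e-6 relative),
    where ``absorbed_weight`` contains volumetric deposits plus the net
    Russian-roulette weight balance.
    """

    records: np.ndarray
    fluence: np.ndarray
    launched_weight: float
    absorbed_weight: float
    escaped_weight: float
    detected_weight: float
    residual_weight: float
    batch_totals: np.ndarray
    config: SimulationConfig
    source: SourceSpec
    detectors: tuple
    wavelength_nm: float
    grid: VoxelGrid
    media: MediumTable

    @property
    def no_detection(self) -> bool:
        return self.records.shape[0] == 0

    def require_detection(self) -> None:
        if self.no_detection:
            raise NoDetectionError("run detected no photons")

    def records_for(self, det: int) -> np.ndarray:
        return self.records[self.records["det"] == det]


def _tooth_face_slices(grid: VoxelGrid, axis: int = 2):
    mask = grid.tooth_mask()
    if not mask.any():
        raise EmptyGeometryError("grid contains no tooth voxels")
    other = tuple(a for a in range(3) if a != axis)
    occupied = np.where(mask.any(axis=other))[0]
    return int(occupied[0]), int(occupied[-1])


def _face_centroid(grid: VoxelGrid, axis: int, index: int):
    sl = [slice(None)] * 3
    sl[axis] = index
    face = grid.tooth_mask()[tuple(sl)]
    idx = np.argwhere(face)
    other = [a for a in range(3) if a != axis]
    centroid = {}
    for k, a in enumerate(other):
        centroid[a] = grid.origin_mm[a] + (idx[:, k].mean() + 0.5) * grid.pitch_mm
    return centroid


def auto_probes(
    grid: VoxelGrid,
    mode: str,
    sds_mm=(0.25, 0.75, 1.5),
    radius_mm: float = 0.1,
    axis: int = 2,
    beam_waist_mm: float = 0.1,
):
    """Place the source and detector(s) on the flat crown faces.

    Reflectance: detectors share the occlusal (low-index) face with the
    source, offset along +x by each SDS.  Transmittance: one detector per SDS
    on the opposite face, offset laterally so the 3D center-to-center
    distance equals the SDS (default 7 mm across the 6 mm crown).
    """
    if mode not in ("reflectance", "transmittance"):
        raise ConfigurationError(f"unknown geometry mode {mode!r}")
    if np.isscalar(sds_mm):
        sds_mm = (float(sds_mm),)
    lo, hi = _tooth_face_slices(grid, axis)
    top_plane = grid.origin_mm[axis] + lo * grid.pitch_mm
    bot_plane = grid.origin_mm[axis] + (hi + 1) * grid.pitch_mm
    thickness = bot_plane - top_plane
    centroid = _face_centroid(grid, axis, lo)
    other = [a for a in range(3) if a != axis]

    center = [0.0, 0.0, 0.0]
    center[axis] = top_plane
    for a in other:
        center[a] = centroid[a]
    direction = [0.0, 0.0, 0.0]
    direction[axis] = 1.0
    src = SourceSpec(tuple(center), tuple(direction), beam_waist_mm)

    detectors = []
    for sds in sds_mm:
        c = list(center)
        if mode == "reflectance":
            c[other[0]] += sds
            c[axis] = top_plane
        else:
            if sds < thickness:
                raise ConfigurationError(
                    f"transmittance SDS {sds} mm shorter than the {thickness:.2f} mm crown"
                )
            c[other[0]] += math.sqrt(sds**2 - thickness**2)
            c[axis] = bot_plane
        detectors.append(
            DetectorSpec(tuple(c), radius_mm=radius_mm, mode=mode, sds_mm=sds, axis=axis)
        )
    return src, tuple(detectors)


def _detector_arrays(detectors):
    n = len(detectors)
    det_axis = np.empty(n, dtype=np.int64)
    det_plane = np.empty(n, dtype=np.float64)
    det_c1 = np.empty(n, dtype=np.float64)
    det_c2 = np.empty(n, dtype=np.float64)
    det_r2 = np.empty(n, dtype=np.float64)
    for i, d in enumerate(detectors):
        det_axis[i] = d.axis
        det_plane[i] = d.plane_mm
        lat = [a for a in range(3) if a != d.axis]
        det_c1[i] = d.center_mm[lat[0]]
        det_c2[i] = d.center_mm[lat[1]]
        det_r2[i] = d.radius_mm**2
    return det_axis, det_plane, det_c1, det_c2, det_r2


def _kernel_args(grid, media, cfg, src, detectors):
    media.require_transport()
    mua, mus, g_arr, nref = media.as_arrays()
    det_arrays = _detector_arrays(detectors)
    return dict(
        labels=grid.labels,
        pitch=float(grid.pitch_mm),
        ox=float(grid.origin_mm[0]),
        oy=float(grid.origin_mm[1]),
        oz=float(grid.origin_mm[2]),
        mua=mua,
        mus=mus,
        g_arr=g_arr,
        nref=nref,
        ambient_n=float(media.ambient_n),
        sx=float(src.center_mm[0]),
        sy=float(src.center_mm[1]),
        sz=float(src.center_mm[2]),
        dx0=float(src.direction[0]),
        dy0=float(src.direction[1]),
        dz0=float(src.direction[2]),
        beam_r=float(src.beam_waist_mm),
        src_axis=int(src.axis),
        det_axis=det_arrays[0],
        det_plane=det_arrays[1],
        det_c1=det_arrays[2],
        det_c2=det_arrays[3],
        det_r2=det_arrays[4],
        wsr=bool(cfg.wsr),
        t_end=float(cfg.t_end_ns),
        roulette_thr=float(cfg.roulette_threshold),
        roulette_p=float(cfg.roulette_survival),
        max_steps=int(cfg.max_steps),
    )


def launch_photon(
    src: SourceSpec,
    grid: VoxelGrid,
    media: MediumTable,
    cfg: SimulationConfig,
    j: int = 0,
) -> PhotonPacket:
    """Launch packet ``j`` of the run and return its initial state.

    Mirrors the kernel's launch block: beam position sampled from the
    truncated Gaussian profile of the packet's own random stream, weight 1
    minus the specular Fresnel loss under WSR, elapsed time zero.
    """
    state = photon_stream_state(np.uint64(cfg.seed), np.int64(j))
    r = 0.0
    for _ in range(64):
        state, u = kernels._u01(state)
        r = src.beam_waist_mm * math.sqrt(-0.5 * math.log(u))
        if r <= 2.0 * src.beam_waist_mm:
            break
    state, u = kernels._u01(state)
    phi = 2.0 * math.pi * u
    pos = np.asarray(src.center_mm, dtype=float).copy()
    other = [a for a in range(3) if a != src.axis]
    pos[other[0]] += r * math.cos(phi)
    pos[other[1]] += r * math.sin(phi)

    idx = np.floor((pos - grid.origin_mm) / grid.pitch_mm).astype(int)
    a = src.axis
    k = int(round((pos[a] - grid.origin_mm[a]) / grid.pitch_mm))
    idx[a] = k if src.direction[a] > 0 else k - 1
    if np.any(idx < 0) or np.any(idx >= np.array(grid.shape)):
        raise ConfigurationError("launch point is not adjacent to the tissue surface")
    lab = int(grid.labels[tuple(idx)])

    w = 1.0
    if cfg.wsr:
        _, _, _, nref = media.as_arrays()
        if nref[lab] != media.ambient_n:
            from .optics import fresnel_reflectance

            ci = abs(float(src.direction[a]))
            w -= fresnel_reflectance(media.ambient_n, float(nref[lab]), ci)
    return PhotonPacket(
        pos_mm=pos,
        direction=np.asarray(src.direction, dtype=float),
        w=w,
        t_ns=0.0,
        pp_mm=np.zeros(3),
        nsc=np.zeros(3, dtype=np.int64),
        rng_state_handle=(int(cfg.seed), int(j)),
    )


def propagate_packet(
    j: int,
    grid: VoxelGrid,
    media: MediumTable,
    cfg: SimulationConfig,
    src: SourceSpec,
    detectors,
):
    """Propagate packet ``j`` to its terminal event (single-packet surface).

    Returns ``(status, record)`` where ``status`` is one of 'absorbed',
    'detected', 'escaped', 'time_expired', 'step_limit' and ``record`` the
    exit state in :data:`RECORD_DTYPE` layout.
    """
    args = _kernel_args(grid, media, cfg, src, detectors)
    out = np.empty(kernels.OUT_SIZE, dtype=np.float64)
    dummy = np.zeros((1, 1, 1), dtype=np.float64)
    state = photon_stream_state(np.uint64(cfg.seed), np.int64(j))
    propagate_one(
        state,
        args["labels"], args["pitch"], args["ox"], args["oy"], args["oz"],
        args["mua"], args["mus"], args["g_arr"], args["nref"], args["ambient_n"],
        args["sx"], args["sy"], args["sz"],
        args["dx0"], args["dy0"], args["dz0"], args["beam_r"], args["src_axis"],
        args["det_axis"], args["det_plane"], args["det_c1"], args["det_c2"], args["det_r2"],
        args["wsr"], args["t_end"], args["roulette_thr"], args["roulette_p"],
        args["max_steps"],
        dummy, False, 0.0, dummy, dummy, False,
        out,
    )
    names = {0: "absorbed", 1: "detected", 2: "escaped", 3: "time_expired", 4: "step_limit"}
    rec = np.zeros(1, dtype=RECORD_DTYPE)[0]
    rec["j"] = j
    rec["det"] = int(out[kernels.OUT_DET])
    rec["w"] = out[kernels.OUT_W]
    rec["t_ns"] = out[kernels.OUT_T]
    rec["gate"] = min(int(out[kernels.OUT_T] / cfg.t_step_ns), cfg.n_gates - 1)
    for i, f in enumerate(PP_FIELDS):
        rec[f] = out[kernels.OUT_PP + i]
    for i, f in enumerate(NSC_FIELDS):
        rec[f] = int(out[kernels.OUT_NSC + i])
    return names[int(out[kernels.OUT_STATUS])], rec


def run_simulation(
    grid: VoxelGrid,
    media: MediumTable,
    cfg: SimulationConfig,
    src: SourceSpec,
    detectors,
) -> RunResult:
    """Run the full Monte Carlo simulation.

    Photons are launched in ``cfg.n_batches`` contiguous batches whose
    per-photon random streams are keyed by the global photon index, so batch
    structure does not change any photon's path.  The fluence map is
    normalized to deposited weight / (mu_a * voxel volume * n_photons).
    """
    if len(detectors) == 0:
        raise ConfigurationError("at least one detector is required")
    args = _kernel_args(grid, media, cfg, src, detectors)
    n = cfg.n_photons
    edges = np.linspace(0, n, cfg.n_batches + 1).astype(np.int64)
    fluence_raw = np.zeros(grid.shape, dtype=np.float64)
    ledger = np.zeros(5, dtype=np.float64)
    batch_totals = np.zeros(cfg.n_batches, dtype=np.float64)
    chunks = []
    for b in range(cfg.n_batches):
        j0, j1 = int(edges[b]), int(edges[b + 1])
        cap = j1 - j0
        rec_j = np.empty(cap, dtype=np.int64)
        rec_det = np.empty(cap, dtype=np.int32)
        rec_w = np.empty(cap, dtype=np.float64)
        rec_t = np.empty(cap, dtype=np.float64)
        rec_pp = np.empty((cap, 3), dtype=np.float64)
        rec_nsc = np.empty((cap, 3), dtype=np.float64)
        det_before = ledger[3]
        count = kernels.run_photon_batch(
            np.uint64(cfg.seed), j0, j1,
            args["labels"], args["pitch"], args["ox"], args["oy"], args["oz"],
            args["mua"], args["mus"], args["g_arr"], args["nref"], args["ambient_n"],
            args["sx"], args["sy"], args["sz"],
            args["dx0"], args["dy0"], args["dz0"], args["beam_r"], args["src_axis"],
            args["det_axis"], args["det_plane"], args["det_c1"], args["det_c2"],
            args["det_r2"],
            args["wsr"], args["t_end"], args["roulette_thr"], args["roulette_p"],
            args["max_steps"],
            fluence_raw,
            rec_j, rec_det, rec_w, rec_t, rec_pp, rec_nsc,
            ledger,
        )
        batch_totals[b] = ledger[3] - det_before
        log.info(
            "batch %d/%d: launched %d, detected %d packets (weight %.4g)",
            b + 1, cfg.n_batches, j1 - j0, count, batch_totals[b],
        )
        chunk = np.zeros(count, dtype=RECORD_DTYPE)
        chunk["j"] = rec_j[:count]
        chunk["det"] = rec_det[:count]
        chunk["w"] = rec_w[:count]
        chunk["t_ns"] = rec_t[:count]
        chunk["gate"] = np.minimum(
            (rec_t[:count] / cfg.t_step_ns).astype(np.int32), cfg.n_gates - 1
        )
        for i, f in enumerate(PP_FIELDS):
            chunk[f] = rec_pp[:count, i]
        for i, f in enumerate(NSC_FIELDS):
            chunk[f] = rec_nsc[:count, i].astype(np.int64)
        chunks.append(chunk)
    records = np.concatenate(chunks) if chunks else np.zeros(0, dtype=RECORD_DTYPE)

    mua_vox = args["mua"][grid.labels]
    fluence = np.zeros_like(fluence_raw)
    nzero = mua_vox > 0
    fluence[nzero] = fluence_raw[nzero] / (
        mua_vox[nzero] * grid.voxel_volume_mm3 * n
    )

    return RunResult(
        records=records,
        fluence=fluence,
        launched_weight=float(ledger[0]),
        absorbed_weight=float(ledger[1]),
        escaped_weight=float(ledger[2] + ledger[3]),
        detected_weight=float(ledger[3]),
        residual_weight=float(ledger[4]),
        batch_totals=batch_totals,
        config=cfg,
        source=src,
        detectors=tuple(detectors),
        wavelength_nm=media.wavelength_nm,
        grid=grid,
        media=media,
    )


def convergence_rate(n_photons: int) -> float:
    """Monte Carlo convergence rate, 1/sqrt(Nph).

    At the reference photon count of 5e8 this evaluates to 4.47e-5, i.e.
    0.00004 to one significant figure.
    """
    if n_photons < 1:
        raise ConfigurationError("n_photons must be >= 1")
    return 1.0 / math.sqrt(n_photons)


def batch_error_rate(batch_totals) -> float:
    """Coefficient of variation of per-batch detected weights (sd / mean)."""
    totals = np.asarray(batch_totals, dtype=float)
    if totals.size < 2:
        raise ConfigurationError("error estimation needs at least 2 batches")
    mean = totals.mean()
    if mean <= 0:
        raise NoDetectionError("mean detected weight is zero; error rate undefined")
    return float(totals.std(ddof=1) / mean)


def rerun_with(result: RunResult, **cfg_updates) -> RunResult:
    """Re-run a simulation with selected config fields replaced (same probes)."""
    cfg = replace(result.config, **cfg_updates)
    return run_simulation(result.grid, result.media, cfg, result.source, result.detectors)
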