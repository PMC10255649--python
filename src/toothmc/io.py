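"""Configuration parsing, run persistence, and fixture generation.

Configs are strict-key JSON; label volumes are NRRD; detected-photon records
are TSV with a sidecar JSON schema; every run directory carries a manifest
with content checksums so a run can be reproduced and re-loaded exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .geometry import GeometryParams, VoxelGrid, embed_in_bounding_box, generate_tooth_model, make_slab
from .nrrdio import load_grid, save_grid, write_nrrd
from .optics import MediumTable, OpticalProperties, load_media
from .transport import (
    RECORD_DTYPE,
    RunResult,
    SimulationConfig,
    auto_probes,
    run_simulation,
)

__all__ = [
    "ProbePlan",
    "load_config",
    "make_fixture",
    "write_records_tsv",
    "read_records_tsv",
    "write_run",
    "load_run",
]

_CONFIG_KEYS = {
    "wavelength_nm",
    "mode",
    "n_photons",
    "seed",
    "wsr",
    "sds_mm",
    "detector_radius_mm",
    "beam_waist_mm",
    "t_end_ns",
    "t_step_ns",
    "roulette_threshold",
    "roulette_survival",
    "n_batches",
}

_DEFAULT_SDS = {"reflectance": (0.25, 0.75, 1.5), "transmittance": (7.0,)}


@dataclass(frozen=True)
class ProbePlan:
    """Geometry-independent probe description resolved against a grid.

    ``resolve(grid)`` places the source on the occlusal face and the
    detector discs per mode and SDS list (see
    :func:`toothmc.transport.auto_probes`).
    """

    mode: str
    sds_mm: tuple
    detector_radius_mm: float = 0.1
    beam_waist_mm: float = 0.1

    def resolve(self, grid: VoxelGrid):
        return auto_probes(
            grid,
            self.mode,
            self.sds_mm,
            radius_mm=self.detector_radius_mm,
            beam_waist_mm=self.beam_waist_mm,
        )


def _config_from_payload(payload: dict):
    unknown = set(payload) - _CONFIG_KEYS
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    for key in ("wavelength_nm", "mode", "n_photons"):
        if key not in payload:
            raise ConfigurationError(f"config is missing required key '{key}'")
    mode = payload["mode"]
    if mode not in _DEFAULT_SDS:
        raise ConfigurationError(f"config key 'mode' must be reflectance/transmittance (got {mode!r})")
    sds = payload.get("sds_mm", _DEFAULT_SDS[mode])
    if np.isscalar(sds):
        sds = (float(sds),)
    try:
        cfg = SimulationConfig(
            n_photons=int(payload["n_photons"]),
            seed=int(payload.get("seed", 0)),
            wsr=bool(payload.get("wsr", True)),
            t_end_ns=float(payload.get("t_end_ns", 1.0)),
            t_step_ns=float(payload.get("t_step_ns", 0.1)),
            roulette_threshold=float(payload.get("roulette_threshold", 1e-4)),
            roulette_survival=float(payload.get("roulette_survival", 0.1)),
            n_batches=int(payload.get("n_batches", 5)),
        )
    except ConfigurationError as exc:
        raise ConfigurationError(f"invalid simulation config: {exc}") from exc
    plan = ProbePlan(
        mode=mode,
        sds_mm=tuple(float(s) for s in sds),
        detector_radius_mm=float(payload.get("detector_radius_mm", 0.1)),
        beam_waist_mm=float(payload.get("beam_waist_mm", 0.1)),
    )
    media = load_media(int(payload["wavelength_nm"]))
    return cfg, plan, media


def load_config(path):
    """Parse a strict-key JSON run config.

    Returns ``(SimulationConfig, ProbePlan, MediumTable)``; the probe plan
    becomes concrete ``SourceSpec``/``DetectorSpec`` objects once resolved
    against a geometry.  Unknown keys and invariant violations raise
    :class:`ConfigurationError` naming the offending key.
    """
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ConfigurationError(f"{path} is not valid JSON: {exc}") from exc
    return _config_from_payload(payload)


def make_fixture(scale: str, matched_index: bool = False):
    """Deterministic test phantoms.

    ``"tiny"`` is a two-layer slab (1 mm of a weak scatterer over 1 mm of a
    strong scatterer) at 0.05 mm pitch for oracle tests; ``matched_index``
    makes every refractive index 1.0 so boundary physics is inert.
    ``"small"`` is the calibrated crown at 0.15 mm pitch (~1e5 tooth voxels)
    for end-to-end tests.  Returns a dict with keys ``grid``, ``media``,
    ``config``, ``plan``.
    """
    if scale == "tiny":
        grid = make_slab([(1, 1.0), (2, 1.0)], pitch_mm=0.05, lateral_mm=2.0, pad_voxels=4)
        n1, n2 = (1.0, 1.0) if matched_index else (1.4, 1.55)
        media = MediumTable(
            wavelength_nm=633,
            media={
                0: OpticalProperties(10.0, 10.0, 0.9, 1.0),
                1: OpticalProperties(0.5, 5.0, 0.8, n1),
                2: OpticalProperties(0.2, 10.0, 0.9, n2),
                3: OpticalProperties(0.035, 10.0, 0.97, 1.39),
            },
        )
        cfg = SimulationConfig(n_photons=2000, seed=7, wsr=True)
        plan = ProbePlan(mode="transmittance", sds_mm=(2.1,), detector_radius_mm=1.2)
    elif scale == "small":
        tooth = generate_tooth_model(GeometryParams(pitch_mm=0.15))
        grid = embed_in_bounding_box(tooth, pad_voxels=6)
        media = load_media(633)
        cfg = SimulationConfig(n_photons=50_000, seed=7, wsr=True)
        plan = ProbePlan(mode="transmittance", sds_mm=(7.0,), detector_radius_mm=1.0)
    else:
        raise ConfigurationError(f"unknown fixture scale {scale!r}")
    return {"grid": grid, "media": media, "config": cfg, "plan": plan}


# ---------------------------------------------------------------------------
# records and run persistence
# ---------------------------------------------------------------------------

_RECORD_SCHEMA = {
    "j": "launch index of the photon packet (replay handle with the run seed)",
    "det": "detector index the packet exited onto",
    "gate": "time gate index, floor(t_exit / t_step)",
    "w": "exit statistical weight",
    "t_ns": "exit time (ns)",
    "pp_enamel": "partial pathlength in enamel (mm)",
    "pp_dentin": "partial pathlength in dentin (mm)",
    "pp_pulp": "partial pathlength in pulp (mm)",
    "nsc_enamel": "scattering events in enamel",
    "nsc_dentin": "scattering events in dentin",
    "nsc_pulp": "scattering events in pulp",
}


def write_records_tsv(path, records: np.ndarray) -> None:
    df = pd.DataFrame({name: records[name] for name in records.dtype.names})
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    schema = {
        "columns": [
            {"name": n, "dtype": str(RECORD_DTYPE[n]), "description": _RECORD_SCHEMA[n]}
            for n in records.dtype.names
        ]
    }
    Path(str(path) + ".schema.json").write_text(json.dumps(schema, indent=2))


def read_records_tsv(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    records = np.zeros(len(df), dtype=RECORD_DTYPE)
    for name in RECORD_DTYPE.names:
        records[name] = df[name].to_numpy().astype(RECORD_DTYPE[name])
    return records


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_run(result: RunResult, outdir, plan: ProbePlan | None = None) -> Path:
    """Persist a run: records, fluence, geometry, energy ledger, manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_records_tsv(outdir / "records.tsv", result.records)
    write_nrrd(
        outdir / "fluence.nrrd",
        result.fluence.astype(np.float32),
        result.grid.pitch_mm,
        result.grid.origin_mm,
    )
    save_grid(outdir / "geometry.nrrd", result.grid)
    (outdir / "media.json").write_text(result.media.to_json())
    ledger = {
        "launched_weight": result.launched_weight,
        "absorbed_weight": result.absorbed_weight,
        "escaped_weight": result.escaped_weight,
        "detected_weight": result.detected_weight,
        "residual_weight": result.residual_weight,
        "batch_totals": result.batch_totals.tolist(),
        "seed": result.config.seed,
        "config": asdict(result.config),
        "source": {
            "center_mm": list(result.source.center_mm),
            "direction": list(result.source.direction),
            "beam_waist_mm": result.source.beam_waist_mm,
        },
        "detectors": [
            {
                "center_mm": list(d.center_mm),
                "radius_mm": d.radius_mm,
                "mode": d.mode,
                "sds_mm": d.sds_mm,
                "axis": d.axis,
            }
            for d in result.detectors
        ],
        "wavelength_nm": result.wavelength_nm,
    }
    (outdir / "ledger.json").write_text(json.dumps(ledger, indent=2))
    files = ["records.tsv", "records.tsv.schema.json", "fluence.nrrd",
             "geometry.nrrd", "media.json", "ledger.json"]
    manifest = {
        "package": "toothmc",
        "version": _package_version(),
        "seed": result.config.seed,
        "created": datetime.now(timezone.utc).isoformat(),
        "outputs": {f: _sha256(outdir / f) for f in files},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir


def load_run(run_dir) -> RunResult:
    """Reconstruct a RunResult from a persisted run directory."""
    from .nrrdio import read_nrrd
    from .transport import DetectorSpec, SourceSpec

    run_dir = Path(run_dir)
    ledger = json.loads((run_dir / "ledger.json").read_text())
    grid = load_grid(run_dir / "geometry.nrrd")
    media = MediumTable.from_json((run_dir / "media.json").read_text())
    records = read_records_tsv(run_dir / "records.tsv")
    fluence, _, _ = read_nrrd(run_dir / "fluence.nrrd")
    cfg = SimulationConfig(**ledger["config"])
    src = SourceSpec(
        tuple(ledger["source"]["center_mm"]),
        tuple(ledger["source"]["direction"]),
        ledger["source"]["beam_waist_mm"],
    )
    detectors = tuple(
        DetectorSpec(
            tuple(d["center_mm"]),
            radius_mm=d["radius_mm"],
            mode=d["mode"],
            sds_mm=d["sds_mm"],
            axis=d["axis"],
        )
        for d in ledger["detectors"]
    )
    return RunResult(
        records=records,
        fluence=fluence.astype(np.float64),
        launched_weight=ledger["launched_weight"],
        absorbed_weight=ledger["absorbed_weight"],
        escaped_weight=ledger["escaped_weight"],
        detected_weight=ledger["detected_weight"],
        residual_weight=ledger["residual_weight"],
        batch_totals=np.asarray(ledger["batch_totals"], dtype=float),
        config=cfg,
        source=src,
        detectors=detectors,
        wavelength_nm=ledger["wavelength_nm"],
        grid=grid,
        media=media,
    )


def run_from_config(config_path, grid: VoxelGrid) -> RunResult:
    """Load a config, resolve probes on ``grid``, and run the simulation."""
    cfg, plan, media = load_config(config_path)
    src, detectors = plan.resolve(grid)
    return run_simulation(grid, media, cfg, src, detectors)


def _package_version() -> str:
    try:
        from importlib.metadata import version

        return version("toothmc")
    except Exception:
        return "unknown"
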