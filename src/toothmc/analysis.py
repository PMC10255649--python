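"""Post-processing of runs and replays: pathlength statistics, depth
profiles, boundary-reflection comparisons, and the published contribution
reference table."""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .errors import ComparisonError, ConfigurationError, NoDetectionError
from .geometry import VoxelGrid
from .transport import RunResult

__all__ = [
    "PathlengthSummary",
    "DepthProfile",
    "summarize_pathlengths",
    "depth_profile",
    "compare_wsr",
    "load_reference_contributions",
    "pulp_wsr_relative_increase_pct",
    "pulp_wavelength_ratio",
]

TISSUES = ("enamel", "dentin", "pulp")


@dataclass
class PathlengthSummary:
    """Weighted pathlength statistics of the detected photons.

    ``mpp_mm`` holds the mean partial pathlength per tissue
    (sum_j Wj PPj(i) / sum_j Wj), ``mtp_mm`` their sum (mean total
    pathlength).  Histograms are weighted by detected weight Wj, so each
    tissue's weighted counts sum to the total detected weight.
    """

    mpp_mm: dict
    mtp_mm: float
    total_mean_mm: float
    total_sd_mm: float
    detected_weight: float
    histograms: dict  # tissue -> (bin_edges_mm, weighted_counts)


@dataclass
class DepthProfile:
    """A voxel map collapsed into axial slabs measured from the source face."""

    bin_centers_mm: np.ndarray
    values: np.ndarray
    argmax_mm: float


def summarize_pathlengths(records: np.ndarray, bin_mm: float = 0.1) -> PathlengthSummary:
    """Per-tissue MPP, MTP, and weighted pathlength histograms from records."""
    if records.shape[0] == 0:
        raise NoDetectionError("no detected photons to summarize")
    if bin_mm <= 0:
        raise ConfigurationError("bin_mm must be > 0")
    w = records["w"].astype(float)
    w_sum = float(w.sum())
    mpp = {t: float((w * records[f"pp_{t}"]).sum() / w_sum) for t in TISSUES}
    total = sum(records[f"pp_{t}"].astype(float) for t in TISSUES)
    mean = float((w * total).sum() / w_sum)
    var = float((w * (total - mean) ** 2).sum() / w_sum)
    hists = {}
    top = max(float(total.max()), bin_mm)
    edges = np.arange(0.0, top + bin_mm, bin_mm)
    for t in TISSUES:
        counts, _ = np.histogram(records[f"pp_{t}"], bins=edges, weights=w)
        hists[t] = (edges, counts)
    return PathlengthSummary(
        mpp_mm=mpp,
        mtp_mm=float(sum(mpp.values())),
        total_mean_mm=mean,
        total_sd_mm=float(np.sqrt(var)),
        detected_weight=w_sum,
        histograms=hists,
    )


def depth_profile(
    volume: np.ndarray,
    grid: VoxelGrid,
    bin_mm: float,
    axis: int = 2,
    source_face_mm: float | None = None,
) -> DepthProfile:
    """Sum a voxel map over axial slabs of width ``bin_mm``.

    Depth is measured from the source face along the beam axis; slabs are
    half-open; the argmax ties break toward the smallest depth.
    """
    if bin_mm <= 0:
        raise ConfigurationError("bin_mm must be > 0")
    vol = np.asarray(volume, dtype=float)
    if vol.ndim == 4:  # gate-resolved map: integrate the gates
        vol = vol.sum(axis=0)
    if vol.shape != grid.shape:
        raise ConfigurationError("volume map must live on the geometry grid")
    if source_face_mm is None:
        tooth = grid.tooth_mask()
        other = tuple(a for a in range(3) if a != axis)
        occupied = np.where(tooth.any(axis=other))[0]
        source_face_mm = grid.origin_mm[axis] + occupied[0] * grid.pitch_mm
    depth = grid.voxel_centers(axis) - source_face_mm
    other = tuple(a for a in range(3) if a != axis)
    per_slice = vol.sum(axis=other)
    keep = depth >= 0
    depth, per_slice = depth[keep], per_slice[keep]
    n_bins = int(np.ceil((depth.max() + 1e-12) / bin_mm)) if depth.size else 1
    which = np.minimum((depth / bin_mm).astype(int), n_bins - 1)
    values = np.bincount(which, weights=per_slice, minlength=n_bins)
    centers = (np.arange(n_bins) + 0.5) * bin_mm
    return DepthProfile(
        bin_centers_mm=centers,
        values=values,
        argmax_mm=float(centers[int(np.argmax(values))]),
    )


def _comparable_meta(result: RunResult) -> tuple:
    cfg = result.config
    return (
        cfg.n_photons,
        cfg.seed,
        cfg.t_end_ns,
        cfg.t_step_ns,
        cfg.roulette_threshold,
        cfg.roulette_survival,
        cfg.n_batches,
        result.wavelength_nm,
        tuple(result.source.center_mm),
        tuple(result.source.direction),
        tuple((d.center_mm, d.radius_mm, d.mode, d.sds_mm) for d in result.detectors),
    )


def compare_wsr(result_wsr: RunResult, result_wosr: RunResult) -> dict:
    """Compare runs that differ only in the boundary-reflection flag.

    Reports total detected weight, per-tissue weighted pathlength
    contributions, their WSR / W-OSR ratios, and the direction of each
    difference.
    """
    if _comparable_meta(result_wsr) != _comparable_meta(result_wosr):
        raise ComparisonError("runs differ in more than the wsr flag")

    def tissue_weights(res):
        w = res.records["w"].astype(float)
        return {t: float((w * res.records[f"pp_{t}"]).sum()) for t in TISSUES}

    tw_wsr = tissue_weights(result_wsr)
    tw_wosr = tissue_weights(result_wosr)

    def ratio(a, b):
        if a == b:  # covers 0/0 for identical inputs
            return 1.0
        return float("inf") if b == 0 else a / b

    out = {
        "detected_weight": {
            "wsr": result_wsr.detected_weight,
            "wosr": result_wosr.detected_weight,
            "ratio": ratio(result_wsr.detected_weight, result_wosr.detected_weight),
        },
        "tissues": {},
    }
    for t in TISSUES:
        out["tissues"][t] = {
            "wsr": tw_wsr[t],
            "wosr": tw_wosr[t],
            "ratio": ratio(tw_wsr[t], tw_wosr[t]),
            "direction": (
                "wsr_higher"
                if tw_wsr[t] > tw_wosr[t]
                else ("equal" if tw_wsr[t] == tw_wosr[t] else "wosr_higher")
            ),
        }
    out["detected_weight"]["direction"] = (
        "wsr_higher"
        if result_wsr.detected_weight > result_wosr.detected_weight
        else (
            "equal"
            if result_wsr.detected_weight == result_wosr.detected_weight
            else "wosr_higher"
        )
    )
    return out


def load_reference_contributions() -> pd.DataFrame:
    """Published pulp-contribution table shipped as package data.

    Columns: wavelength_nm, geometry, sds_mm, weighted detected photons and
    pulp contribution (%) with and without surface reflection.
    """
    ref = resources.files("toothmc.data") / "reference_contributions.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def pulp_wsr_relative_increase_pct(
    table: pd.DataFrame, wavelength_nm: int, geometry: str
) -> float:
    """Relative increase (%) of pulp contribution from W/OSR to WSR."""
    rows = table[
        (table.wavelength_nm == wavelength_nm) & (table.geometry == geometry)
    ]
    if len(rows) != 1:
        raise ConfigurationError(
            f"expected one {geometry} row at {wavelength_nm} nm, found {len(rows)}"
        )
    row = rows.iloc[0]
    return float(
        100.0 * (row.contrib_wsr_pct - row.contrib_wosr_pct) / row.contrib_wosr_pct
    )


def pulp_wavelength_ratio(
    table: pd.DataFrame, sds_mm: float, reflection: str = "wsr"
) -> float:
    """Ratio of weighted detected pulp photons, 1310 nm over 633 nm, at one SDS."""
    col = {"wsr": "wdp_wsr", "wosr": "wdp_wosr"}[reflection]
    sel = table[(table.geometry == "reflectance") & (table.sds_mm == sds_mm)]
    a = sel[sel.wavelength_nm == 1310][col]
    b = sel[sel.wavelength_nm == 633][col]
    if len(a) != 1 or len(b) != 1:
        raise ConfigurationError(f"no unique reflectance rows at SDS {sds_mm} mm")
    return float(a.iloc[0] / b.iloc[0])
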