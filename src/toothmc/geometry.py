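"""Parametric voxelized molar-crown generator and voxel-grid bookkeeping.

A real segmented molar mesh is not distributed with the package, so the
generator builds a smooth stand-in with the same compartment topology: an
outer enamel superellipsoid truncated flat at the occlusal (source-facing)
and root-side faces, a nested dentin body exposed only at the root-side face,
and an innermost pulp chamber with a short root-canal stem, fully enclosed by
dentin.  The dentin and pulp surface scales are calibrated by bisection so
the voxel-counted volume fractions hit requested targets (default
enamel/dentin/pulp = 0.44/0.52/0.04).

Conventions: voxel indices are 0-based; world coordinates are mm; a voxel
spans ``[origin + i*pitch, origin + (i+1)*pitch)`` per axis (half-open); the
beam axis is z with the occlusal face at the low-z end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, EmptyGeometryError
from .optics import OpticalProperties

__all__ = [
    "VoxelGrid",
    "GeometryParams",
    "generate_tooth_model",
    "compute_volume_fractions",
    "embed_in_bounding_box",
    "make_slab",
]

LABEL_BOUNDING, LABEL_ENAMEL, LABEL_DENTIN, LABEL_PULP = 0, 1, 2, 3


@dataclass
class VoxelGrid:
    """Labeled 3D voxel volume with physical pitch.

    ``labels`` is a C-contiguous uint8 array indexed ``[ix, iy, iz]`` with
    values 0 (bounding medium), 1 (enamel), 2 (dentin), 3 (pulp).
    ``origin_mm`` is the world coordinate of the corner of voxel (0,0,0).
    """

    labels: np.ndarray
    pitch_mm: float
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    pad_voxels: int = 0
    pad_props: OpticalProperties | None = None

    def __post_init__(self) -> None:
        self.labels = np.ascontiguousarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 3:
            raise ConfigurationError("labels must be a 3D array")
        if self.labels.max(initial=0) > 3:
            raise ConfigurationError("labels must lie in {0, 1, 2, 3}")
        if self.pitch_mm <= 0:
            raise ConfigurationError("pitch_mm must be > 0")
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)

    @property
    def shape(self):
        return self.labels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return self.pitch_mm**3

    def tooth_mask(self) -> np.ndarray:
        return self.labels > 0

    def tooth_voxel_count(self) -> int:
        return int(np.count_nonzero(self.labels))

    def axial_extent_mm(self, axis: int = 2) -> float:
        """Extent of tooth-labeled voxels along ``axis`` in mm."""
        mask = self.tooth_mask()
        if not mask.any():
            raise EmptyGeometryError("grid contains no tooth voxels")
        other = tuple(a for a in range(3) if a != axis)
        occupied = np.where(mask.any(axis=other))[0]
        return float((occupied[-1] - occupied[0] + 1) * self.pitch_mm)

    def voxel_centers(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        return self.origin_mm[axis] + (np.arange(n) + 0.5) * self.pitch_mm


@dataclass(frozen=True)
class GeometryParams:
    """Parameters of the synthetic molar-crown model.

    ``crown_thickness_mm`` is the axial (beam-axis) extent of the crown;
    ``target_fractions`` the (enamel, dentin, pulp) volume fractions among
    tooth voxels; ``pitch_mm`` the cubic voxel edge; ``shape_seed`` seeds the
    optional surface perturbation of relative magnitude ``perturb``
    (default 0: the shape is purely deterministic in the other parameters).
    """

    crown_thickness_mm: float = 6.0
    target_fractions: tuple = (0.44, 0.52, 0.04)
    pitch_mm: float = 0.05
    shape_seed: int = 0
    perturb: float = 0.0
    fraction_tol: float = 0.0025

    def __post_init__(self) -> None:
        names = ("enamel", "dentin", "pulp")
        if len(self.target_fractions) != 3:
            raise ConfigurationError("target_fractions must have three entries")
        for name, f in zip(names, self.target_fractions):
            if f <= 0:
                raise ConfigurationError(
                    f"target fraction for {name} must be > 0 (got {f})"
                )
        if abs(sum(self.target_fractions) - 1.0) > 1e-9:
            raise ConfigurationError("target_fractions must sum to 1")
        if self.crown_thickness_mm <= 0:
            raise ConfigurationError("crown_thickness_mm must be > 0")
        if self.pitch_mm <= 0:
            raise ConfigurationError("pitch_mm must be > 0")


def _bisect_fraction(fn, target, lo, hi, tol, what, max_iter=60):
    """Monotone bisection of ``fn`` (voxel-counted fraction) to ``target``.

    The bracket halves every iteration; returns the best parameter found.
    Raises ConfigurationError when the target is outside [fn(lo), fn(hi)].
    """
    f_lo, f_hi = fn(lo), fn(hi)
    if not (f_lo <= target <= f_hi):
        raise ConfigurationError(
            f"{what} fraction target {target:.4f} unreachable "
            f"(attainable range [{f_lo:.4f}, {f_hi:.4f}])"
        )
    best_x, best_err = lo, abs(f_lo - target)
    if abs(f_hi - target) < best_err:
        best_x, best_err = hi, abs(f_hi - target)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = fn(mid)
        err = abs(f_mid - target)
        if err < best_err:
            best_x, best_err = mid, err
        if err <= tol:
            return mid
        if f_mid < target:
            lo = mid
        else:
            hi = mid
    if best_err <= 2 * tol:
        return best_x
    raise ConfigurationError(
        f"{what} fraction calibration did not converge "
        f"(best |error| = {best_err:.5f}, tolerance {tol})"
    )


def generate_tooth_model(params: GeometryParams | None = None) -> VoxelGrid:
    """Generate the calibrated three-compartment crown model.

    Returns a :class:`VoxelGrid` without bounding padding (use
    :func:`embed_in_bounding_box` before transport).  Deterministic for fixed
    parameters; compartment fractions match ``params.target_fractions``
    within ±0.005.
    """
    params = params or GeometryParams()
    h = params.crown_thickness_mm
    pitch = params.pitch_mm
    e_frac, d_frac, p_frac = params.target_fractions

    # outer crown: lateral semi-axis a, axial superellipsoid exponent 4,
    # axial half-extent 0.8*h so the z-clip at [0, h] leaves flat faces
    a = 5.0 * h / 6.0
    zc, cz, q = 0.5 * h, 0.8 * h, 4.0
    if params.perturb > 0:
        rng = np.random.default_rng(params.shape_seed)
        a *= 1.0 + params.perturb * (2 * rng.random() - 1)
        cz *= 1.0 + params.perturb * (2 * rng.random() - 1)

    nz = max(2, round(h / pitch))
    nlat = int(math.ceil(2 * a / pitch)) + 4
    origin = np.array([-0.5 * nlat * pitch, -0.5 * nlat * pitch, 0.0])
    x = origin[0] + (np.arange(nlat) + 0.5) * pitch
    z = (np.arange(nz) + 0.5) * pitch
    X, Y = np.meshgrid(x, x, indexing="ij")
    R2 = (X**2 + Y**2)[:, :, None]  # broadcast over z
    Z = z[None, None, :]

    def axial_factor(center, half, zv):
        return 1.0 - ((zv - center) / half) ** q

    outer = R2 <= a * a * axial_factor(zc, cz, Z)
    n_tooth = int(np.count_nonzero(outer))
    if n_tooth == 0:
        raise EmptyGeometryError("outer crown surface encloses no voxels")

    # dentin body: same family, scaled laterally by u, axial span (t_e, 1.3h)
    # so it is capped by enamel at the top and exposed at the root-side face;
    # a lateral enamel margin keeps the sides enclosed
    t_e = 0.2 * h  # occlusal enamel cap thickness
    zc_d = 0.5 * (t_e + 1.3 * h)
    cz_d = 0.5 * (1.3 * h - t_e)
    margin = max(0.2 * h / 6.0, 1.5 * pitch)
    side_cap = (a - margin) ** 2 * axial_factor(zc, cz, Z)

    def dentin_mask(u):
        lat = (u * a) ** 2 * axial_factor(zc_d, cz_d, Z)
        return R2 <= np.minimum(lat, side_cap)

    target_d = d_frac + p_frac  # dentin body includes the future pulp
    u_d = _bisect_fraction(
        lambda u: np.count_nonzero(dentin_mask(u)) / n_tooth,
        target_d, 0.05, 0.999, params.fraction_tol, "dentin",
    )
    dentin = dentin_mask(u_d)

    # pulp: chamber ellipsoid plus a root-canal stem, restricted to the
    # 6-connected erosion of the dentin body so pulp never touches enamel or
    # the exterior (the stem stops short of the root-side face)
    dentin_interior = ndimage.binary_erosion(dentin, border_value=0)
    z_pc = t_e + 0.35 * h
    stem_r = 0.06 * h
    stem = (R2 <= stem_r**2) & (Z >= z_pc) & (Z <= 0.9 * h)

    def pulp_mask(v):
        lat = (v * u_d * a * 0.8) ** 2
        cp = v * 0.3 * h
        chamber = R2 / lat + ((Z - z_pc) / cp) ** 2 <= 1.0
        return (chamber | stem) & dentin_interior

    v_p = _bisect_fraction(
        lambda v: np.count_nonzero(pulp_mask(v)) / n_tooth,
        p_frac, 0.02, 1.0, params.fraction_tol, "pulp",
    )
    pulp = pulp_mask(v_p)

    labels = np.zeros(outer.shape, dtype=np.uint8)
    labels[outer] = LABEL_ENAMEL
    labels[dentin] = LABEL_DENTIN
    labels[pulp] = LABEL_PULP
    return VoxelGrid(labels=labels, pitch_mm=pitch, origin_mm=origin)


def compute_volume_fractions(grid: VoxelGrid):
    """(enamel, dentin, pulp) fractions among tooth voxels (labels 1-3)."""
    counts = np.bincount(grid.labels.ravel(), minlength=4)
    total = counts[1] + counts[2] + counts[3]
    if total == 0:
        raise EmptyGeometryError("grid contains no tooth voxels")
    return (counts[1] / total, counts[2] / total, counts[3] / total)


def embed_in_bounding_box(
    grid: VoxelGrid,
    pad_voxels: int,
    pad_props: OpticalProperties | None = None,
) -> VoxelGrid:
    """Surround the grid with a label-0 shell of ``pad_voxels`` on all faces.

    The bounding medium is the computational absorber that terminates photons
    leaving the tooth; its optical properties (default mu_a = mu_s = 10/mm,
    g = 0.9, n = 1.0) live in the medium table, and ``pad_props`` is recorded
    on the returned grid for provenance.
    """
    pad_voxels = int(pad_voxels)
    if pad_voxels < 1:
        raise ConfigurationError("pad_voxels must be >= 1 (the box must exist)")
    if pad_props is None:
        pad_props = OpticalProperties(mu_a=10.0, mu_s=10.0, g=0.9, n=1.0)
    labels = np.pad(grid.labels, pad_voxels, mode="constant", constant_values=0)
    origin = grid.origin_mm - pad_voxels * grid.pitch_mm
    return VoxelGrid(
        labels=labels,
        pitch_mm=grid.pitch_mm,
        origin_mm=origin,
        pad_voxels=pad_voxels,
        pad_props=pad_props,
    )


def make_slab(
    layers,
    pitch_mm: float = 0.05,
    lateral_mm: float = 2.0,
    pad_voxels: int = 4,
) -> VoxelGrid:
    """Axially layered slab phantom embedded in a bounding box.

    ``layers`` is a sequence of ``(label, thickness_mm)`` stacked along +z
    starting at z = 0.  Used by the oracle tests (Beer-Lambert, replay,
    Jacobian finite differences) where closed-form answers exist.
    """
    nlat = max(2, round(lateral_mm / pitch_mm))
    n_per = []
    for label, th in layers:
        if label not in (1, 2, 3):
            raise ConfigurationError("slab layers must use tooth labels 1-3")
        n = round(th / pitch_mm)
        if abs(n * pitch_mm - th) > 1e-9 or n < 1:
            raise ConfigurationError(
                f"layer thickness {th} mm is not a positive multiple of the pitch"
            )
        n_per.append((label, n))
    nz = sum(n for _, n in n_per)
    labels = np.zeros((nlat, nlat, nz), dtype=np.uint8)
    iz = 0
    for label, n in n_per:
        labels[:, :, iz : iz + n] = label
        iz += n
    origin = np.array([-0.5 * nlat * pitch_mm, -0.5 * nlat * pitch_mm, 0.0])
    grid = VoxelGrid(labels=labels, pitch_mm=pitch_mm, origin_mm=origin)
    return embed_in_bounding_box(grid, pad_voxels)
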