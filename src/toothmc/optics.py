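"""Per-compartment optical properties and elementary photon-physics kernels.

The kernels here are the single source of truth for the physics used by the
transport engine: exponential free-path sampling, Henyey--Greenstein (HG)
deflection-cosine sampling, unpolarized Fresnel reflectance at index-mismatched
boundaries, Snell refraction, and rotation of a direction vector into a new
scattering frame.  All are ``numba.njit`` functions so the same compiled code
runs inside the transport loop and is directly callable from Python for
testing.

Shipped property tables (``data/properties_633nm.json`` and
``data/properties_1310nm.json``) hold absorption coefficient ``mu_a`` (1/mm),
scattering coefficient ``mu_s`` (1/mm), anisotropy ``g`` (mean cosine of the
deflection angle) and refractive index ``n`` for enamel, dentin, pulp and the
absorbing bounding medium that surrounds the tooth, at 633 nm and 1310 nm.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
from numba import njit

from .errors import ConfigurationError, VacuumMediumError

__all__ = [
    "OpticalProperties",
    "MediumTable",
    "LABEL_NAMES",
    "load_media",
    "sample_step_length",
    "hg_cos_theta",
    "fresnel_reflectance",
    "scatter_direction",
    "snell_cos_t",
]

#: voxel label -> compartment name (0 is the absorbing bounding medium)
LABEL_NAMES = {0: "bounding", 1: "enamel", 2: "dentin", 3: "pulp"}
NAME_LABELS = {v: k for k, v in LABEL_NAMES.items()}


@dataclass(frozen=True)
class OpticalProperties:
    """Optical properties of one homogeneous medium at one wavelength.

    Parameters
    ----------
    mu_a : float
        Absorption coefficient, 1/mm (>= 0).
    mu_s : float
        Scattering coefficient, 1/mm (>= 0).
    g : float
        Scattering anisotropy, mean cosine of the HG deflection angle,
        0 <= g < 1.
    n : float
        Refractive index (>= 1).
    """

    mu_a: float
    mu_s: float
    g: float
    n: float

    def __post_init__(self) -> None:
        if self.mu_a < 0 or self.mu_s < 0:
            raise ConfigurationError(
                f"mu_a and mu_s must be nonnegative (got {self.mu_a}, {self.mu_s})"
            )
        if not (0.0 <= self.g < 1.0):
            raise ConfigurationError(f"anisotropy g must satisfy 0 <= g < 1 (got {self.g})")
        if self.n < 1.0:
            raise ConfigurationError(f"refractive index must be >= 1 (got {self.n})")

    @property
    def mu_t(self) -> float:
        """Total interaction coefficient mu_a + mu_s, 1/mm."""
        return self.mu_a + self.mu_s


@dataclass(frozen=True)
class MediumTable:
    """Optical properties for every voxel label at a single wavelength.

    ``media`` maps labels 0..3 (bounding, enamel, dentin, pulp) to
    :class:`OpticalProperties`; ``ambient_n`` is the refractive index of the
    surrounding air used for the specular loss at launch.
    """

    wavelength_nm: float
    media: dict
    ambient_n: float = 1.0

    def __post_init__(self) -> None:
        for label in (0, 1, 2, 3):
            if label not in self.media:
                raise ConfigurationError(f"MediumTable missing label {label}")

    def as_arrays(self):
        """Return (mu_a, mu_s, g, n) as float64 arrays indexed by label."""
        mua = np.array([self.media[k].mu_a for k in range(4)])
        mus = np.array([self.media[k].mu_s for k in range(4)])
        g = np.array([self.media[k].g for k in range(4)])
        n = np.array([self.media[k].n for k in range(4)])
        return mua, mus, g, n

    def require_transport(self) -> None:
        """Transport needs mu_t > 0 in every medium (no vacuum)."""
        for label, props in self.media.items():
            if props.mu_t <= 0:
                raise VacuumMediumError(
                    f"medium {LABEL_NAMES.get(label, label)} has mu_t <= 0"
                )

    def with_bounding(self, props: OpticalProperties) -> "MediumTable":
        """Return a copy with the label-0 (bounding medium) properties replaced."""
        media = dict(self.media)
        media[0] = props
        return MediumTable(self.wavelength_nm, media, self.ambient_n)

    def to_json(self) -> str:
        payload = {
            "wavelength_nm": self.wavelength_nm,
            "ambient_n": self.ambient_n,
            "media": {
                LABEL_NAMES[k]: {
                    "mu_a": v.mu_a,
                    "mu_s": v.mu_s,
                    "g": v.g,
                    "n": v.n,
                }
                for k, v in sorted(self.media.items())
            },
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "MediumTable":
        payload = json.loads(text)
        try:
            media = {
                NAME_LABELS[name]: OpticalProperties(**props)
                for name, props in payload["media"].items()
            }
            return cls(
                wavelength_nm=payload["wavelength_nm"],
                media=media,
                ambient_n=payload.get("ambient_n", 1.0),
            )
        except (KeyError, TypeError) as exc:
            raise ConfigurationError(f"malformed medium table: {exc}") from exc


def load_media(wavelength_nm: int) -> MediumTable:
    """Load the shipped property table for 633 or 1310 nm."""
    if int(wavelength_nm) not in (633, 1310):
        raise ConfigurationError(
            f"no shipped property table at {wavelength_nm} nm (have 633, 1310)"
        )
    ref = resources.files("toothmc.data") / f"properties_{int(wavelength_nm)}nm.json"
    return MediumTable.from_json(ref.read_text())


# ---------------------------------------------------------------------------
# physics kernels (numba; callable from Python and from the transport loop)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _sample_step_length(mu_t, delta):
    return -math.log(delta) / mu_t


def sample_step_length(mu_t: float, delta: float) -> float:
    """Exponential free path: step = -ln(delta)/mu_t, in mm.

    ``delta`` is a uniform random deviate in (0, 1); ``mu_t`` the total
    interaction coefficient of the current medium (1/mm).
    """
    if mu_t <= 0:
        raise VacuumMediumError(f"mu_t must be > 0 (got {mu_t})")
    if not (0.0 < delta < 1.0):
        raise ConfigurationError(f"delta must lie in (0, 1) (got {delta})")
    return float(_sample_step_length(mu_t, delta))


@njit(cache=True)
def _hg_cos_theta(g, delta):
    if g < 1e-12:
        return 2.0 * delta - 1.0
    f = (1.0 - g * g) / (1.0 - g + 2.0 * g * delta)
    ct = (1.0 + g * g - f * f) / (2.0 * g)
    if ct > 1.0:
        ct = 1.0
    elif ct < -1.0:
        ct = -1.0
    return ct


def hg_cos_theta(g: float, delta: float) -> float:
    """Sample the cosine of the HG deflection angle by inverse CDF.

    For g > 0 this is the standard closed form
    ``(1 + g^2 - ((1-g^2)/(1-g+2g*delta))^2) / (2g)``; the printed form
    degenerates at g = 0, where the analytic isotropic limit ``2*delta - 1``
    is used instead.
    """
    if not (0.0 <= g < 1.0):
        raise ConfigurationError(f"anisotropy g must satisfy 0 <= g < 1 (got {g})")
    if not (0.0 < delta < 1.0):
        raise ConfigurationError(f"delta must lie in (0, 1) (got {delta})")
    return float(_hg_cos_theta(g, delta))


@njit(cache=True)
def _fresnel_reflectance(n_in, n_out, cos_i):
    if n_in == n_out:
        return 0.0
    if cos_i > 1.0:
        cos_i = 1.0
    sin_i2 = 1.0 - cos_i * cos_i
    ratio = n_in / n_out
    sin_t2 = ratio * ratio * sin_i2
    if sin_t2 >= 1.0:
        return 1.0  # total internal reflection
    cos_t = math.sqrt(1.0 - sin_t2)
    rs = (n_in * cos_i - n_out * cos_t) / (n_in * cos_i + n_out * cos_t)
    rp = (n_in * cos_t - n_out * cos_i) / (n_in * cos_t + n_out * cos_i)
    return 0.5 * (rs * rs + rp * rp)


def fresnel_reflectance(n_in: float, n_out: float, cos_theta_i: float) -> float:
    """Unpolarized Fresnel power reflectance (mean of s and p coefficients).

    Returns 1.0 past the critical angle when ``n_in > n_out``.
    """
    if n_in < 1.0 or n_out < 1.0:
        raise ConfigurationError("refractive indices must be >= 1")
    if not (0.0 <= cos_theta_i <= 1.0):
        raise ConfigurationError(f"cos_theta_i must lie in [0, 1] (got {cos_theta_i})")
    return float(_fresnel_reflectance(n_in, n_out, cos_theta_i))


@njit(cache=True)
def _snell_cos_t(n_in, n_out, cos_i):
    # cosine of the transmitted angle; caller must have excluded TIR
    sin_i2 = 1.0 - cos_i * cos_i
    ratio = n_in / n_out
    sin_t2 = ratio * ratio * sin_i2
    return math.sqrt(1.0 - sin_t2)


def snell_cos_t(n_in: float, n_out: float, cos_theta_i: float) -> float:
    """Cosine of the refracted angle from Snell's law (no TIR allowed)."""
    r = fresnel_reflectance(n_in, n_out, cos_theta_i)
    if r >= 1.0:
        raise ConfigurationError("incidence beyond the critical angle has no refracted ray")
    return float(_snell_cos_t(n_in, n_out, cos_theta_i))


@njit(cache=True)
def _scatter_direction(ux, uy, uz, cos_theta, phi):
    sin_theta = math.sqrt(max(0.0, 1.0 - cos_theta * cos_theta))
    cp = math.cos(phi)
    sp = math.sin(phi)
    if abs(uz) > 0.99999:
        # degenerate frame: incident direction along +/- z
        vx = sin_theta * cp
        vy = sin_theta * sp
        vz = cos_theta * (1.0 if uz >= 0.0 else -1.0)
    else:
        den = math.sqrt(1.0 - uz * uz)
        vx = sin_theta * (ux * uz * cp - uy * sp) / den + ux * cos_theta
        vy = sin_theta * (uy * uz * cp + ux * sp) / den + uy * cos_theta
        vz = -sin_theta * cp * den + uz * cos_theta
    norm = math.sqrt(vx * vx + vy * vy + vz * vz)
    return vx / norm, vy / norm, vz / norm


def scatter_direction(dir_in, cos_theta: float, phi: float):
    """Rotate a unit direction by deflection cosine ``cos_theta`` and azimuth ``phi``.

    Standard local-frame rotation used in multilayer photon-packet codes; the
    near-vertical incident direction is handled by the degenerate-frame branch.
    """
    d = np.asarray(dir_in, dtype=float)
    if abs(np.linalg.norm(d) - 1.0) > 1e-9:
        raise ConfigurationError("dir_in must be a unit vector")
    return np.array(_scatter_direction(d[0], d[1], d[2], float(cos_theta), float(phi)))
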