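"""Photon-physics kernels: closed forms, distributional moments, invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from numba import njit

from toothmc.errors import ConfigurationError, VacuumMediumError
from toothmc.kernels import _u01, photon_stream_state
from toothmc.optics import (
    MediumTable,
    OpticalProperties,
    _hg_cos_theta,
    fresnel_reflectance,
    hg_cos_theta,
    load_media,
    sample_step_length,
    scatter_direction,
    snell_cos_t,
)


@pytest.mark.parametrize(
    "mu_t, delta, expected",
    [
        (1.0, math.exp(-1.0), 1.0),
        (26.3, 0.5, math.log(2) / 26.3),  # dentin mu_a + mu_s at 633 nm
    ],
)
def test_step_length_closed_form(mu_t, delta, expected):
    assert sample_step_length(mu_t, delta) == pytest.approx(expected, rel=1e-12)


def test_step_length_limit_and_domain():
    assert sample_step_length(1.0, 1 - 1e-12) < 1e-10
    with pytest.raises(VacuumMediumError):
        sample_step_length(0.0, 0.5)
    with pytest.raises(ConfigurationError):
        sample_step_length(1.0, 0.0)


@pytest.mark.parametrize(
    "g, delta, expected",
    [
        (0.0, 0.75, 0.5),  # isotropic limit 2*delta - 1
        (0.9, 0.5, (1.81 - 0.19**2) / 1.8),
        (0.7, 1 - 1e-13, 1.0),  # fully forward at delta -> 1
    ],
)
def test_hg_cos_theta_closed_form(g, delta, expected):
    assert hg_cos_theta(g, delta) == pytest.approx(expected, abs=1e-9)


def test_hg_domain_error():
    with pytest.raises(ConfigurationError):
        hg_cos_theta(1.0, 0.5)
    with pytest.raises(ConfigurationError):
        hg_cos_theta(-0.1, 0.5)


def test_hg_continuity_at_isotropic_limit():
    for delta in np.arange(0.1, 0.95, 0.1):
        assert abs(hg_cos_theta(1e-6, delta) - (2 * delta - 1)) < 1e-4


@njit(cache=True)
def _hg_mean(g, n, seed):
    state = photon_stream_state(np.uint64(seed), np.int64(0))
    total = 0.0
    total2 = 0.0
    for _ in range(n):
        state, u = _u01(state)
        ct = _hg_cos_theta(g, u)
        total += ct
        total2 += ct * ct
    mean = total / n
    var = total2 / n - mean * mean
    return mean, var


@pytest.mark.parametrize("g", [0.0, 0.7, 0.85, 0.93, 0.97])
def test_hg_mean_cosine_equals_g(g):
    """The HG anisotropy is the mean deflection cosine: sample mean == g."""
    n = 1_000_000
    mean, var = _hg_mean(g, n, 42)
    se = math.sqrt(var / n)
    assert abs(mean - g) < 3 * se + 1e-12


@pytest.mark.parametrize(
    "n_in, n_out, cos_i, expected",
    [
        (1.5, 1.5, 0.3, 0.0),  # matched media
        (1.0, 1.63, 1.0, (0.63 / 2.63) ** 2),  # air -> enamel, normal incidence
        (1.63, 1.0, math.cos(math.radians(45)), 1.0),  # past the critical angle
    ],
)
def test_fresnel_closed_forms(n_in, n_out, cos_i, expected):
    assert fresnel_reflectance(n_in, n_out, cos_i) == pytest.approx(expected, abs=1e-9)


@given(
    n_in=st.floats(1.0, 2.0),
    n_out=st.floats(1.0, 2.0),
    cos_i=st.floats(0.0, 1.0),
)
@settings(deadline=None, max_examples=200)
def test_fresnel_is_a_probability(n_in, n_out, cos_i):
    r = fresnel_reflectance(n_in, n_out, cos_i)
    assert 0.0 <= r <= 1.0


@given(cos_i=st.floats(0.01, 0.9999))
@settings(deadline=None, max_examples=100)
def test_snell_consistency_when_transmitted(cos_i):
    """Whenever R < 1 the refracted ray satisfies n_in sin(i) = n_out sin(t)."""
    n_in, n_out = 1.63, 1.0
    if fresnel_reflectance(n_in, n_out, cos_i) < 1.0:
        cos_t = snell_cos_t(n_in, n_out, cos_i)
        sin_i = math.sqrt(1 - cos_i**2)
        sin_t = math.sqrt(1 - cos_t**2)
        assert n_in * sin_i == pytest.approx(n_out * sin_t, abs=1e-9)


def test_scatter_direction_reference_cases():
    d = np.array([0.0, 0.0, 1.0])
    assert np.allclose(scatter_direction(d, 1.0, 0.3), d, atol=1e-9)
    out = scatter_direction(d, 0.0, 0.0)
    assert np.allclose(out, [1.0, 0.0, 0.0], atol=1e-9)
    rng = np.random.default_rng(1)
    v = rng.normal(size=3)
    v /= np.linalg.norm(v)
    back = scatter_direction(v, -1.0, 1.2)
    assert np.allclose(back, -v, atol=1e-7)


@given(
    theta=st.floats(0.01, math.pi - 0.01),
    azim=st.floats(0.0, 2 * math.pi),
    ct=st.floats(-1.0, 1.0),
    phi=st.floats(0.0, 2 * math.pi),
)
@settings(deadline=None, max_examples=200)
def test_scatter_direction_preserves_norm_and_angle(theta, azim, ct, phi):
    d = np.array(
        [math.sin(theta) * math.cos(azim), math.sin(theta) * math.sin(azim), math.cos(theta)]
    )
    d /= np.linalg.norm(d)
    out = scatter_direction(d, ct, phi)
    assert np.linalg.norm(out) == pytest.approx(1.0, abs=1e-9)
    assert float(out @ d) == pytest.approx(ct, abs=1e-7)


def test_scatter_direction_rejects_non_unit_input():
    with pytest.raises(ConfigurationError):
        scatter_direction([0, 0, 2.0], 0.5, 0.0)


# --- property tables -------------------------------------------------------

EXPECTED_PROPERTIES = {
    633: {
        "enamel": (0.04, 1.5, 0.7, 1.63),
        "dentin": (0.30, 26.0, 0.93, 1.54),
        "pulp": (0.035, 10.0, 0.97, 1.39),
    },
    1310: {
        "enamel": (0.12, 3.0, 0.93, 1.63),
        "dentin": (0.40, 25.0, 0.97, 1.54),
        "pulp": (0.09, 3.75, 0.85, 1.39),
    },
}
LABELS = {"enamel": 1, "dentin": 2, "pulp": 3}


@pytest.mark.parametrize("wavelength", [633, 1310])
def test_shipped_property_tables(wavelength):
    table = load_media(wavelength)
    assert table.ambient_n == 1.0
    for tissue, (mu_a, mu_s, g, n) in EXPECTED_PROPERTIES[wavelength].items():
        props = table.media[LABELS[tissue]]
        assert (props.mu_a, props.mu_s, props.g, props.n) == (mu_a, mu_s, g, n)


def test_medium_table_json_round_trip():
    table = load_media(633)
    again = MediumTable.from_json(table.to_json())
    assert again == table


def test_invalid_optical_properties_rejected():
    with pytest.raises(ConfigurationError):
        OpticalProperties(mu_a=-1.0, mu_s=1.0, g=0.5, n=1.4)
    with pytest.raises(ConfigurationError):
        OpticalProperties(mu_a=0.1, mu_s=1.0, g=1.0, n=1.4)
    with pytest.raises(ConfigurationError):
        OpticalProperties(mu_a=0.1, mu_s=1.0, g=0.5, n=0.9)
    with pytest.raises(ConfigurationError):
        load_media(800)
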