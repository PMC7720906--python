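"""Per-event random-variable draws as pure functions of explicit uniforms.

Every sampler maps one (or more) uniform(0,1) variates to a physical
quantity, so the transport engine can be driven either by a live RNG or
by a recorded variate stream (the basis of the scalar-vs-compiled
equivalence oracle).

Note on the step-length CDF: the free path between elastic scattering
events follows the standard exponential law with CDF 1 - exp(-mu_s l)
and inverse -ln(1 - xi)/mu_s.  Some published statements of this law
carry a spurious extra mu_s factor inside the exponential CDF (which
would not be bounded in [0, 1]); the bounded form used here is the only
self-consistent one and matches the absorption roulette convention
``absorbed iff xi < 1 - exp(-mu_a l)``.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "sample_step_length",
    "sample_azimuth",
    "sample_polar_hg",
    "absorption_occurs",
    "sample_shift_wavelength",
    "fresnel_reflectance",
    "reflect_or_transmit",
    "rotate_direction",
    "reflect",
    "refract",
]

_G_ISOTROPIC_EPS = 1e-6  # |g| below this uses the isotropic limit


def sample_step_length(xi1: float, mu_s: float) -> float:
    """Free path (mm) between scattering events: -ln(1 - xi1)/mu_s."""
    if mu_s <= 0:
        raise ValueError("mu_s must be positive (void gaps are handled by geometry)")
    return -math.log1p(-xi1) / mu_s


def sample_azimuth(xi2: float) -> float:
    """Azimuthal scattering angle, uniform on [0, 2*pi)."""
    return 2.0 * math.pi * xi2


def hg_cos_theta(xi3: float, g: float) -> float:
    """Cosine of the Henyey-Greenstein polar deflection angle."""
    if abs(g) >= 1.0:
        raise ValueError("anisotropy g must satisfy |g| < 1")
    if abs(g) < _G_ISOTROPIC_EPS:
        return 2.0 * xi3 - 1.0
    frac = (1.0 - g * g) / (1.0 - g + 2.0 * g * xi3)
    ct = (1.0 + g * g - frac * frac) / (2.0 * g)
    return min(1.0, max(-1.0, ct))


def sample_polar_hg(xi3: float, g: float) -> float:
    """Polar deflection angle in [0, pi] from the HG inverse CDF."""
    return math.acos(hg_cos_theta(xi3, g))


def absorption_occurs(xi4: float, mu_a: float, l: float) -> bool:
    """Russian-roulette absorption over a traveled length l (mm).

    The photon is absorbed iff xi4 < 1 - exp(-mu_a l); otherwise it
    survives the segment.
    """
    if mu_a < 0 or l < 0:
        raise ValueError("mu_a and l must be nonnegative")
    return xi4 < -math.expm1(-mu_a * l)


def sample_shift_wavelength(xi: float, cdf: np.ndarray) -> int | None:
    """Inverse-CDF wavelength selection for a Raman/fluorescence shift.

    Returns the smallest grid index whose CDF value exceeds ``xi`` (the
    shortest wavelength whose cumulative probability wins), or ``None``
    when ``xi`` exceeds the total event probability (elastic outcome).
    """
    cdf = np.asarray(cdf)
    if cdf.size == 0 or xi >= cdf[-1]:
        return None
    return int(np.searchsorted(cdf, xi, side="right"))


def fresnel_reflectance(n1: float, n2: float, theta1: float) -> float:
    """Unpolarized Fresnel reflectance at a planar interface.

    Average of the two orthogonal polarizations; returns 1.0 beyond the
    critical angle (total internal reflection).
    """
    ci = math.cos(theta1)
    si = math.sin(theta1)
    s2 = (n1 / n2) * si
    if s2 >= 1.0:
        return 1.0
    ct = math.sqrt(1.0 - s2 * s2)
    rs = (n1 * ci - n2 * ct) / (n1 * ci + n2 * ct)
    rp = (n1 * ct - n2 * ci) / (n1 * ct + n2 * ci)
    return 0.5 * (rs * rs + rp * rp)


def reflect_or_transmit(xi7: float, reflectance: float) -> str:
    """Bernoulli boundary decision: ``'REFLECT'`` iff xi7 < R."""
    if not (0.0 <= reflectance <= 1.0):
        raise ValueError("reflectance must lie in [0, 1]")
    return "REFLECT" if xi7 < reflectance else "TRANSMIT"


def _rotate_cs(ux: float, uy: float, uz: float,
               ct: float, st: float, cp: float, sp: float):
    """Direction rotation given cos/sin of the deflection and azimuth.

    Hot-path form shared (expression for expression) with the compiled
    kernel; ``rotate_direction`` is the validated public wrapper.
    """
    if abs(uz) > 1.0 - 1e-12:
        sign = 1.0 if uz >= 0.0 else -1.0
        ox = st * cp
        oy = sign * st * sp
        oz = sign * ct
    else:
        den = math.sqrt(1.0 - uz * uz)
        inv_den = 1.0 / den
        ox = st * (ux * uz * cp - uy * sp) * inv_den + ux * ct
        oy = st * (uy * uz * cp + ux * sp) * inv_den + uy * ct
        oz = -st * cp * den + uz * ct
    inv_norm = 1.0 / math.sqrt(ox * ox + oy * oy + oz * oz)
    return ox * inv_norm, oy * inv_norm, oz * inv_norm


def rotate_direction(u, theta: float, phi: float) -> np.ndarray:
    """Rotate unit vector ``u`` by polar angle theta, azimuth phi about u.

    Standard local-frame Monte Carlo direction update, with the
    |u_z| ~ 1 special case handled separately.
    """
    u = np.asarray(u, dtype=float)
    if abs(u[0] * u[0] + u[1] * u[1] + u[2] * u[2] - 1.0) > 1e-9:
        raise ValueError("direction must be a unit vector")
    return np.array(_rotate_cs(
        float(u[0]), float(u[1]), float(u[2]),
        math.cos(theta), math.sin(theta), math.cos(phi), math.sin(phi),
    ))


def reflect(d: np.ndarray, normal: np.ndarray) -> np.ndarray:
    """Mirror direction ``d`` about a surface with unit ``normal``."""
    d = np.asarray(d, dtype=float)
    normal = np.asarray(normal, dtype=float)
    return d - 2.0 * float(d @ normal) * normal


def refract(d: np.ndarray, normal: np.ndarray, n1: float, n2: float):
    """Snell refraction of ``d`` across a surface with normal facing the ray.

    ``normal`` must satisfy d . normal < 0 (pointing back toward the
    incident side).  Returns ``(reflectance, refracted_direction)``;
    beyond the critical angle the reflectance is 1 and the direction is
    ``None``.
    """
    d = np.asarray(d, dtype=float)
    normal = np.asarray(normal, dtype=float)
    ci = -float(d @ normal)
    eta = n1 / n2
    s2 = eta * eta * (1.0 - ci * ci)
    if s2 >= 1.0:
        return 1.0, None
    ct = math.sqrt(1.0 - s2)
    rs = (n1 * ci - n2 * ct) / (n1 * ci + n2 * ct)
    rp = (n1 * ct - n2 * ci) / (n1 * ct + n2 * ci)
    refr = eta * d + (eta * ci - ct) * normal
    return 0.5 * (rs * rs + rp * rp), refr
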