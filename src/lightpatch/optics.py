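"""Scalar interface optics for lossless dielectric media.

This is the verified kernel every other module builds on: critical angles,
Snell refraction, unpolarized Fresnel power splitting, and the numerical
aperture of a step-index fiber.

Conventions
-----------
* Angles at interfaces are measured from the surface normal.
* All public inputs and outputs are in degrees; internal math uses radians.
* Incidence exactly at the critical angle is treated as total internal
  reflection (the grazing transmitted wave carries zero power anyway).
* Fresnel coefficients are the unpolarized power coefficients, i.e. the
  average of the s- and p-polarized reflectances.  The light source modelled
  downstream is a multimode fiber with no defined polarization state.
* All media are lossless here; tissue attenuation lives in
  :mod:`lightpatch.tissue`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "Medium",
    "InterfaceResult",
    "critical_angle",
    "snell_refract",
    "fresnel_unpolarized",
    "numerical_aperture",
]


@dataclass(frozen=True)
class Medium:
    """A lossless optical medium: a short label and a refractive index."""

    name: str
    n: float

    def __post_init__(self) -> None:
        if not (self.n > 0.0 and math.isfinite(self.n)):
            raise ValueError(f"refractive index must be positive and finite, got {self.n!r}")


@dataclass(frozen=True)
class InterfaceResult:
    """Outcome of a single refraction event at a planar index step.

    ``refracted_angle`` is ``None`` when total internal reflection occurs.
    Power fractions satisfy ``transmittance + reflectance == 1``.
    """

    incident_angle: float
    refracted_angle: float | None
    tir: bool
    transmittance: float
    reflectance: float


def _check_index(n: float, label: str) -> None:
    if not (n > 0.0 and math.isfinite(n)):
        raise ValueError(f"{label} must be a positive finite refractive index, got {n!r}")


def _check_angle(theta_deg: float) -> None:
    if not (0.0 <= theta_deg <= 90.0):
        raise ValueError(f"incidence angle must lie in [0, 90] degrees, got {theta_deg!r}")


def critical_angle(n_in: float, n_out: float) -> float:
    """Critical angle, in degrees, for light going from ``n_in`` into ``n_out``.

    Only defined for propagation from the denser into the rarer medium,
    ``n_in > n_out``; returns ``arcsin(n_out / n_in)`` in degrees.

    >>> round(critical_angle(1.49, 1.4), 2)   # patch -> tissue
    69.97
    >>> round(critical_angle(1.49, 1.0003), 2)  # patch -> air
    42.17
    """
    _check_index(n_in, "n_in")
    _check_index(n_out, "n_out")
    if n_in <= n_out:
        raise ValueError(
            "no total internal reflection exists for this pair: requires n_in > n_out, "
            f"got n_in={n_in}, n_out={n_out}"
        )
    return math.degrees(math.asin(n_out / n_in))


def fresnel_unpolarized(theta_in: float, n_in: float, n_out: float) -> tuple[float, float]:
    """Unpolarized power ``(transmittance, reflectance)`` at an index step.

    The s- and p-polarized power reflectances are averaged.  At or beyond the
    critical angle the result is ``(0, 1)``.  At normal incidence the
    reflectance reduces to ``((n_in - n_out) / (n_in + n_out))**2``.
    """
    _check_angle(theta_in)
    _check_index(n_in, "n_in")
    _check_index(n_out, "n_out")
    theta = math.radians(theta_in)
    cos_i = math.cos(theta)
    sin_t = n_in * math.sin(theta) / n_out
    if sin_t >= 1.0:
        return 0.0, 1.0
    cos_t = math.sqrt(1.0 - sin_t * sin_t)
    r_s = ((n_in * cos_i - n_out * cos_t) / (n_in * cos_i + n_out * cos_t)) ** 2
    r_p = ((n_out * cos_i - n_in * cos_t) / (n_out * cos_i + n_in * cos_t)) ** 2
    reflectance = 0.5 * (r_s + r_p)
    return 1.0 - reflectance, reflectance


def snell_refract(theta_in: float, n_in: float, n_out: float) -> InterfaceResult:
    """Refract a ray at a planar interface between two media.

    Returns the refracted angle from Snell's law
    ``n_in * sin(theta_in) = n_out * sin(theta_out)`` together with the
    unpolarized Fresnel power split.  Beyond (or exactly at) the critical
    angle the event is total internal reflection: ``tir`` is set, the
    refracted angle is absent and all power is reflected.
    """
    _check_angle(theta_in)
    _check_index(n_in, "n_in")
    _check_index(n_out, "n_out")
    sin_t = n_in * math.sin(math.radians(theta_in)) / n_out
    transmittance, reflectance = fresnel_unpolarized(theta_in, n_in, n_out)
    if sin_t >= 1.0:
        return InterfaceResult(
            incident_angle=theta_in,
            refracted_angle=None,
            tir=True,
            transmittance=0.0,
            reflectance=1.0,
        )
    return InterfaceResult(
        incident_angle=theta_in,
        refracted_angle=math.degrees(math.asin(sin_t)),
        tir=False,
        transmittance=transmittance,
        reflectance=reflectance,
    )


def numerical_aperture(n_core: float, n_clad: float) -> float:
    """Numerical aperture ``sqrt(n_core**2 - n_clad**2)`` of a step-index fiber.

    Bounds the acceptance/emission cone of the unmodified (flat-end) fiber.
    """
    _check_index(n_core, "n_core")
    _check_index(n_clad, "n_clad")
    if n_core <= n_clad:
        raise ValueError(f"requires n_core > n_clad, got n_core={n_core}, n_clad={n_clad}")
    return math.sqrt(n_core * n_core - n_clad * n_clad)
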