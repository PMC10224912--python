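"""Parametric axisymmetric geometry of the tapered fiber, air cavity and patch.

Coordinate convention (used everywhere downstream): the z-axis is the fiber
axis, +z points in the propagation direction, and the origin sits at the apex
of the air cavity.  All geometry is in micrometres.

The air cavity is the exact mold left by the tapered fiber before it was
retracted by the pull distance ``d``: the cavity wall is the taper profile
mirrored about the apex, the retracted fiber surface is the same profile
shifted back by ``d``.  The air region is the set difference of the two
solids; it closes where the cylindrical fiber shaft refills its own mold,
at ``z = -(taper_length + d)``.
"""

from __future__ import annotations

import math
import warnings
from collections.abc import Callable
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .optics import Medium

__all__ = [
    "TaperProfile",
    "AirGapGeometry",
    "PatchSlab",
    "DeviceConfig",
    "taper_radius",
    "surface_tangent_angle",
    "ray_surface_intersection",
    "scattering_condition",
]

#: Pull distances outside this range are accepted with a warning only.
STUDIED_D_RANGE_UM = (0.0, 120.0)


@dataclass(frozen=True)
class TaperProfile:
    """Radius profile F(z) of a heat-pulled fiber taper.

    ``z`` is the distance from the fiber tip in micrometres.  The default
    family is a power law

        F(z) = tip_radius + (base_radius - tip_radius) * (z / taper_length)**p

    for ``z <= taper_length`` and the constant shaft radius beyond.  A custom
    monotone profile with the same endpoints can be injected through
    ``radius_fn`` (it then replaces the power law; the endpoints are still
    clamped to ``tip_radius`` and ``base_radius``).
    """

    tip_radius: float = 0.5
    base_radius: float = 50.0
    taper_length: float = 280.0
    shape_exponent: float = 2.0
    radius_fn: Callable[[float], float] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not (0.0 < self.tip_radius < self.base_radius):
            raise ValueError(
                f"requires 0 < tip_radius < base_radius, got {self.tip_radius}, {self.base_radius}"
            )
        if not self.taper_length > 0.0:
            raise ValueError(f"taper_length must be positive, got {self.taper_length}")
        if not self.shape_exponent > 0.0:
            raise ValueError(f"shape_exponent must be positive, got {self.shape_exponent}")


def taper_radius(profile: TaperProfile, z):
    """Fiber radius (um) at distance ``z`` (um) from the tip.

    Accepts a scalar or an array; negative ``z`` is a validation error.
    """
    z_arr = np.asarray(z, dtype=float)
    if np.any(z_arr < 0.0):
        raise ValueError("z must be >= 0 (distance from the fiber tip)")
    if profile.radius_fn is not None:
        fn = np.vectorize(profile.radius_fn, otypes=[float])
        out = np.where(
            z_arr >= profile.taper_length,
            profile.base_radius,
            np.where(z_arr <= 0.0, profile.tip_radius, fn(np.minimum(z_arr, profile.taper_length))),
        )
    else:
        frac = np.clip(z_arr / profile.taper_length, 0.0, 1.0)
        out = profile.tip_radius + (profile.base_radius - profile.tip_radius) * frac**profile.shape_exponent
    if np.isscalar(z) or z_arr.ndim == 0:
        return float(out)
    return out


def _profile_slope(profile: TaperProfile, z: float) -> float:
    """dF/dz at ``z`` (> 0); zero on the cylindrical shaft."""
    if z >= profile.taper_length:
        return 0.0
    if profile.radius_fn is not None:
        h = 1e-3 * profile.taper_length
        lo = max(z - h, 0.0)
        hi = min(z + h, profile.taper_length)
        return (taper_radius(profile, hi) - taper_radius(profile, lo)) / (hi - lo)
    p = profile.shape_exponent
    return (
        p
        * (profile.base_radius - profile.tip_radius)
        / profile.taper_length
        * (z / profile.taper_length) ** (p - 1.0)
    )


def surface_tangent_angle(profile: TaperProfile, z) -> tuple:
    """Wall angles at ``z``: (alpha_t, alpha_t_prime), both in degrees.

    ``alpha_t`` is the angle between the local tangent plane of the surface
    of revolution and the fiber axis, ``arctan(dF/dz)``; its companion
    ``alpha_t_prime = 90 - alpha_t`` is the angle between the surface normal
    and the axis.  On the cylindrical shaft ``alpha_t = 0``; exactly at the
    apex (``z == 0``) the flat tip cap gives ``alpha_t = 90``.
    """
    z_arr = np.asarray(z, dtype=float)
    if np.any(z_arr < 0.0):
        raise ValueError("z must be >= 0 (distance from the fiber tip)")
    slope = np.vectorize(lambda zz: _profile_slope(profile, zz), otypes=[float])(z_arr)
    alpha_t = np.degrees(np.arctan(slope))
    alpha_t = np.where(z_arr == 0.0, 90.0, alpha_t)
    if np.isscalar(z) or z_arr.ndim == 0:
        return float(alpha_t), 90.0 - float(alpha_t)
    return alpha_t, 90.0 - alpha_t


@dataclass(frozen=True)
class AirGapGeometry:
    """The pulled-fiber air cavity: pull distance ``d`` and the mold profile."""

    d: float = 15.0
    cavity_profile: TaperProfile = field(default_factory=TaperProfile)

    def __post_init__(self) -> None:
        if self.d < 0.0:
            raise ValueError(f"pull distance d must be >= 0 um, got {self.d}")
        lo, hi = STUDIED_D_RANGE_UM
        if self.d == lo or self.d > hi:
            warnings.warn(
                f"pull distance d={self.d} um lies outside the studied range "
                f"({lo}, {hi}] um; results are extrapolations",
                stacklevel=2,
            )

    # --- surfaces of revolution -------------------------------------------
    def cavity_radius(self, z: float) -> float:
        """Cavity wall radius at axial position ``z <= 0``."""
        return float(taper_radius(self.cavity_profile, max(-z, 0.0)))

    def fiber_radius(self, z: float) -> float:
        """Retracted fiber radius at ``z <= -d`` (the fiber tip sits at -d)."""
        s = -(z + self.d)
        if s < 0.0:
            raise ValueError("the retracted fiber only occupies z <= -d")
        return float(taper_radius(self.cavity_profile, s))

    @property
    def z_min(self) -> float:
        """Axial position where the air annulus closes behind the taper."""
        return -(self.cavity_profile.taper_length + self.d)

    def contains(self, point) -> bool:
        """Membership test for the air region (open set)."""
        x, y, z = (float(c) for c in point)
        if not (self.z_min < z < 0.0):
            return False
        rho = math.hypot(x, y)
        if rho >= self.cavity_radius(z):
            return False
        if z <= -self.d and rho <= self.fiber_radius(z):
            return False
        return True


@dataclass(frozen=True)
class PatchSlab:
    """The refractive patch: a thin disk with the fiber axis in its mid-plane.

    ``thickness`` equals the diameter of a standard fiber; ``tip_offset``
    places the cavity apex relative to the patch centre (default: at the
    centre) in patch-plane millimetres.
    """

    thickness: float = 125.0
    disk_radius_mm: float = 12.5
    tip_offset: tuple = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not self.thickness > 0.0:
            raise ValueError("thickness must be positive")
        if not self.disk_radius_mm > 0.0:
            raise ValueError("disk_radius_mm must be positive")


@dataclass(frozen=True)
class DeviceConfig:
    """Full optical description of one patch device."""

    media: dict
    taper: TaperProfile = field(default_factory=TaperProfile)
    gap: AirGapGeometry = field(default_factory=AirGapGeometry)
    slab: PatchSlab = field(default_factory=PatchSlab)

    def __post_init__(self) -> None:
        missing = {"air", "patch", "tissue"} - set(self.media)
        if missing:
            raise ValueError(f"media map must include entries named {sorted(missing)}")
        for key, medium in self.media.items():
            if not isinstance(medium, Medium):
                raise TypeError(f"media[{key!r}] must be a Medium, got {type(medium)}")

    def index(self, name: str) -> float:
        return self.media[name].n


def scattering_condition(alpha_i: float, alpha_t_prime: float) -> bool:
    """Diagnostic for the lateral-scattering regime: ``alpha_i < alpha_t_prime``.

    When the half-divergence of the incident light is smaller than the angle
    between the cavity-wall normal and the axis, refraction at the air/patch
    wall bends rays away from the axis and light is scattered further
    laterally.  Strict inequality; the ray engine always uses actual
    refraction, never this shortcut.
    """
    for label, val in (("alpha_i", alpha_i), ("alpha_t_prime", alpha_t_prime)):
        if not (0.0 <= val <= 90.0):
            raise ValueError(f"{label} must lie in [0, 90] degrees, got {val}")
    return alpha_i < alpha_t_prime


# ---------------------------------------------------------------------------
# Ray / surface-of-revolution intersection (pure-Python reference)
# ---------------------------------------------------------------------------

_STEP_FLOOR_UM = 0.02
_REFINE_TOL_UM = 1e-6


def _signed_gaps(gap: AirGapGeometry, x: float, y: float, z: float) -> tuple[float, float]:
    """(g_cavity, g_fiber): negative while the point is inside the air region.

    g_cavity = rho - cavity_radius(z)  (wall hit when it reaches 0 from below)
    g_fiber  = fiber_radius(z) - rho   (only meaningful for z <= -d)
    """
    rho = math.hypot(x, y)
    g_c = rho - gap.cavity_radius(z)
    g_f = gap.fiber_radius(z) - rho if z <= -gap.d else -math.inf
    return g_c, g_f


def ray_surface_intersection(origin, direction, gap: AirGapGeometry):
    """First intersection of a ray with the boundary of the air region.

    Returns ``(point, normal, kind)`` where ``normal`` is the unit normal
    pointing into the air region and ``kind`` is one of ``"cavity_wall"``,
    ``"cavity_cap"``, ``"fiber_wall"``, ``"fiber_cap"``; or ``None`` when the
    ray leaves the domain through the closed shaft annulus.

    Bracketing by adaptive marching plus Brent root refinement on the signed
    radial distance to the surface of revolution; positional accuracy is well
    below 1e-3 um.  This is the reference implementation used for pluggable
    taper profiles and for cross-checking the accelerated kernel.
    """
    o = np.asarray(origin, dtype=float)
    u = np.asarray(direction, dtype=float)
    u = u / np.linalg.norm(u)
    if not gap.contains(o):
        raise ValueError("ray origin must lie inside the air region")

    profile = gap.cavity_profile
    tip_r = profile.tip_radius
    d = gap.d
    t = 1e-7
    t_max = 4.0 * (-gap.z_min + 100.0)

    def point_at(t_):
        return o + t_ * u

    g_c_prev, g_f_prev = _signed_gaps(gap, *point_at(t))
    z_prev = float(o[2] + t * u[2])
    while t < t_max:
        step = max(_STEP_FLOOR_UM, 0.3 * min(abs(g_c_prev), abs(g_f_prev) if math.isfinite(g_f_prev) else abs(g_c_prev)))
        t_new = t + step
        x, y, z = point_at(t_new)

        # plane crossings are resolved exactly before wall tests
        if z >= 0.0 and u[2] > 0.0:  # apex plane of the cavity
            t_plane = (0.0 - o[2]) / u[2]
            px, py, _ = point_at(t_plane)
            if math.hypot(px, py) <= tip_r + 1e-9:
                return (
                    np.array([px, py, 0.0]),
                    np.array([0.0, 0.0, -1.0]),
                    "cavity_cap",
                )
            # otherwise the wall was grazed right at the rim; fall through
        if z_prev > -d and z <= -d and u[2] < 0.0 and d > 0.0:  # fiber tip plane
            t_plane = (-d - o[2]) / u[2]
            px, py, _ = point_at(t_plane)
            if math.hypot(px, py) <= tip_r + 1e-9:
                return (
                    np.array([px, py, -d]),
                    np.array([0.0, 0.0, 1.0]),
                    "fiber_cap",
                )
        if z <= gap.z_min:
            return None

        g_c, g_f = _signed_gaps(gap, x, y, z)
        if g_c >= 0.0:
            t_hit = brentq(
                lambda tt: _signed_gaps(gap, *point_at(tt))[0], t, t_new, xtol=_REFINE_TOL_UM
            ) if g_c > 0.0 else t_new
            hx, hy, hz = point_at(t_hit)
            m = _profile_slope(profile, max(-hz, 0.0))
            rho = math.hypot(hx, hy)
            n = np.array([-hx / rho, -hy / rho, -m])
            n /= np.linalg.norm(n)
            return np.array([hx, hy, hz]), n, "cavity_wall"
        if math.isfinite(g_f) and g_f >= 0.0:
            # when the fiber-tip plane was crossed within this step, start the
            # bracket just past the plane where the gap function is finite
            t_lo = t if math.isfinite(g_f_prev) else (-d - o[2]) / u[2] + 1e-9

            def _gf(tt):
                return _signed_gaps(gap, *point_at(tt))[1]

            t_hit = brentq(_gf, t_lo, t_new, xtol=_REFINE_TOL_UM) if _gf(t_lo) < 0.0 else t_lo
            hx, hy, hz = point_at(t_hit)
            m = _profile_slope(profile, max(-(hz + d), 0.0))
            rho = math.hypot(hx, hy)
            n = np.array([hx / rho, hy / rho, m])
            n /= np.linalg.norm(n)
            return np.array([hx, hy, hz]), n, "fiber_wall"
        t, g_c_prev, g_f_prev, z_prev = t_new, g_c, g_f, z
    return None
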