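"""Power-weighted Monte Carlo ray tracing through the air gap and patch slab.

The tracer follows every emitted ray from the retracted fiber tip through the
air cavity (interacting with the cavity wall, the cavity apex cap, and the
retracted fiber surface) until its power enters the patch, escapes backwards,
or is pruned; slab transport then carries patch rays to the tissue-side,
air-side and edge boundaries.

Splitting at interfaces is deterministic two-branch (transmitted weight T,
reflected weight R) rather than Russian roulette: at this problem scale
reproducibility is worth more than variance efficiency, and because the
transmitted branch always terminates (it is recorded, or moved to a loss
ledger for fiber re-entry), each ray remains a single weighted path.  Pruned
power is always accumulated in the loss ledger, never silently dropped.

Power that re-enters the retracted fiber through its cladding surface is
terminated into the ledger: no re-guiding along the fiber is modelled, the
model only tracks power that leaves the gap.  Rays exactly at a critical
angle undergo total internal reflection, consistent with
:mod:`lightpatch.optics`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels
from .geometry import DeviceConfig, PatchSlab, ray_surface_intersection
from .metrics import AngularPowerDistribution
from .optics import fresnel_unpolarized

__all__ = [
    "EmissionSpec",
    "Ray",
    "RayBundle",
    "TraceSettings",
    "GapExitRecords",
    "ExitRecordSet",
    "sample_emission",
    "interact",
    "trace_gap",
    "trace_gap_records",
    "transport_slab",
    "simulate_device",
]

ANGULAR_DENSITIES = ("uniform-solid-angle", "cosine-weighted", "side-weighted")
SIDE_LABELS = ("tissue", "air", "edge")


@dataclass(frozen=True)
class EmissionSpec:
    """Angular emission model of the sub-wavelength taper tip.

    The tip (1 um, below the working wavelength) is treated as a point source
    radiating into a cone of half-angle ``theta_max`` about +z.  The default
    65 deg half-angle corresponds to a 130 deg full divergence.  Densities:

    * ``uniform-solid-angle`` (default): cos(theta) uniform on
      [cos(theta_max), 1];
    * ``cosine-weighted``: density per solid angle proportional to cos(theta);
    * ``side-weighted``: density proportional to sin(theta) beyond a 30 deg
      knee (flat below it) — the taper forces extra emission sideways, but no
      measured distribution exists, so this is an exploratory option.
    """

    theta_max: float = 65.0
    angular_density: str = "uniform-solid-angle"
    n_rays: int = 100_000
    seed: int = 0
    side_knee: float = 30.0

    def __post_init__(self) -> None:
        if not (0.0 < self.theta_max <= 90.0):
            raise ValueError(f"theta_max must lie in (0, 90] degrees, got {self.theta_max}")
        if self.n_rays < 1:
            raise ValueError("n_rays must be >= 1")
        if self.angular_density not in ANGULAR_DENSITIES:
            raise ValueError(
                f"angular_density must be one of {ANGULAR_DENSITIES}, got {self.angular_density!r}"
            )


@dataclass(frozen=True)
class Ray:
    origin: np.ndarray
    direction: np.ndarray
    weight: float
    medium: str = "air"
    depth: int = 0

    def __post_init__(self) -> None:
        if abs(np.linalg.norm(self.direction) - 1.0) > 1e-12:
            raise ValueError("direction must be a unit vector")
        if not (0.0 < self.weight <= 1.0):
            raise ValueError("weight must lie in (0, 1]")


@dataclass
class RayBundle:
    """A set of power-weighted rays; total emitted power is 1 by construction."""

    origins: np.ndarray
    directions: np.ndarray
    weights: np.ndarray
    medium: str = "air"
    seed: int | None = None

    def __post_init__(self) -> None:
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("emission weights must sum to 1")

    def __len__(self) -> int:
        return len(self.weights)


@dataclass(frozen=True)
class TraceSettings:
    """Tracer controls; the oracle flags exist for tests and cross-checks."""

    max_depth: int = 8
    weight_cutoff: float = 1e-4
    ideal_interfaces: bool = False  # slab only: T=1 below critical, 0 beyond
    single_pass: bool = False  # slab only: stop each path after one surface


@dataclass
class GapExitRecords:
    """Per-ray patch-entry events produced by the gap stage (um frame)."""

    positions: np.ndarray
    directions: np.ndarray
    weights: np.ndarray
    ledger: dict


@dataclass
class ExitRecordSet:
    """Per-ray exit events from the patch slab.

    Patch-plane coordinates: ``x_mm`` runs along the fiber axis (+z of the
    tracing frame), ``y_mm`` transverse in the patch plane; the slab normal is
    the tracing frame's y axis.  ``exit_angle_deg`` is measured from the local
    outward surface normal after refraction into the destination medium.
    """

    side: np.ndarray
    x_mm: np.ndarray
    y_mm: np.ndarray
    exit_angle_deg: np.ndarray
    weight: np.ndarray
    ledger: dict
    input_power: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "side": [SIDE_LABELS[s] for s in self.side],
                "x_mm": self.x_mm,
                "y_mm": self.y_mm,
                "exit_angle_deg": self.exit_angle_deg,
                "weight": self.weight,
            }
        )


# ---------------------------------------------------------------------------
# emission
# ---------------------------------------------------------------------------


def sample_emission(spec: EmissionSpec, tip_position=(0.0, 0.0, 0.0)) -> RayBundle:
    """Draw ``spec.n_rays`` equal-weight directions in the emission cone.

    Fully reproducible from ``spec.seed``; identical specs give bit-identical
    bundles.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_rays
    theta_max = math.radians(spec.theta_max)
    cos_max = math.cos(theta_max)

    if spec.angular_density == "uniform-solid-angle":
        cos_t = rng.uniform(cos_max, 1.0, n)
    elif spec.angular_density == "cosine-weighted":
        sin2 = rng.uniform(0.0, math.sin(theta_max) ** 2, n)
        cos_t = np.sqrt(1.0 - sin2)
    else:  # side-weighted: rejection against a unit envelope
        sin_knee = math.sin(math.radians(spec.side_knee))
        cos_t = np.empty(n)
        filled = 0
        while filled < n:
            need = n - filled
            cand = rng.uniform(cos_max, 1.0, max(2 * need, 128))
            accept_p = np.maximum(np.sqrt(1.0 - cand**2), sin_knee)
            keep = cand[rng.uniform(0.0, 1.0, cand.size) < accept_p]
            take = min(need, keep.size)
            cos_t[filled : filled + take] = keep[:take]
            filled += take

    phi = rng.uniform(0.0, 2.0 * math.pi, n)
    sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, 1.0))
    directions = np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])
    origins = np.tile(np.asarray(tip_position, dtype=float), (n, 1))
    weights = np.full(n, 1.0 / n)
    return RayBundle(origins=origins, directions=directions, weights=weights, seed=spec.seed)


# ---------------------------------------------------------------------------
# single interaction (reference implementation, also the unit-test surface)
# ---------------------------------------------------------------------------


def interact(
    ray: Ray,
    point: np.ndarray,
    normal: np.ndarray,
    n_in: float,
    n_out: float,
    settings: TraceSettings = TraceSettings(),
) -> list[Ray]:
    """Split a ray at an interface into up to two weighted children.

    ``normal`` must be a unit vector on the incident side.  The refracted
    child carries weight ``w * T`` with the Snell direction; the reflected
    child carries ``w * R`` mirrored about the normal.  Children below the
    weight cutoff or beyond the depth limit are dropped (the full tracer
    ledgers them; this single-event helper simply omits them).
    """
    n_hat = np.asarray(normal, dtype=float)
    nn = np.linalg.norm(n_hat)
    if not nn > 1e-12:
        raise ValueError("degenerate surface normal")
    n_hat = n_hat / nn
    u = ray.direction
    cos_i = -float(np.dot(u, n_hat))
    if cos_i < 0.0:
        n_hat = -n_hat
        cos_i = -cos_i
    cos_i = min(cos_i, 1.0)
    theta_i = math.degrees(math.acos(cos_i))
    transmittance, reflectance = fresnel_unpolarized(theta_i, n_in, n_out)

    children: list[Ray] = []
    depth = ray.depth + 1
    if depth <= settings.max_depth:
        if transmittance > 0.0 and ray.weight * transmittance > settings.weight_cutoff:
            eta = n_in / n_out
            k = 1.0 - eta * eta * (1.0 - cos_i * cos_i)
            t_dir = eta * u + (eta * cos_i - math.sqrt(k)) * n_hat
            t_dir = t_dir / np.linalg.norm(t_dir)
            children.append(
                Ray(np.asarray(point, float), t_dir, ray.weight * transmittance, "transmitted", depth)
            )
        if reflectance > 0.0 and ray.weight * reflectance > settings.weight_cutoff:
            r_dir = u + 2.0 * cos_i * n_hat
            r_dir = r_dir / np.linalg.norm(r_dir)
            children.append(
                Ray(np.asarray(point, float), r_dir, ray.weight * reflectance, ray.medium, depth)
            )
    return children


# ---------------------------------------------------------------------------
# gap stage
# ---------------------------------------------------------------------------


def _no_gap_records(bundle: RayBundle, device: DeviceConfig) -> GapExitRecords:
    """d = 0 limit: the emission cone refracts at a virtual flat index step.

    With no air cavity the taper output enters the patch directly; each
    emitted direction is Snell-mapped at a plane normal to the axis and
    Fresnel-weighted, the reflected remainder returns into the fiber.
    """
    n_air = device.index("air")
    n_patch = device.index("patch")
    uz = np.clip(bundle.directions[:, 2], -1.0, 1.0)
    sin_i = np.sqrt(np.clip(1.0 - uz**2, 0.0, 1.0))
    sin_t = np.clip(sin_i * n_air / n_patch, 0.0, 1.0)
    cos_t = np.sqrt(1.0 - sin_t**2)
    trans = np.array(
        [
            fresnel_unpolarized(math.degrees(math.asin(min(s, 1.0))), n_air, n_patch)[0]
            for s in sin_i
        ]
    )
    scale = np.where(sin_i > 0.0, sin_t / np.where(sin_i > 0.0, sin_i, 1.0), 0.0)
    directions = np.column_stack(
        [bundle.directions[:, 0] * scale, bundle.directions[:, 1] * scale, cos_t]
    )
    norms = np.linalg.norm(directions, axis=1)
    directions /= norms[:, None]
    weights = bundle.weights * trans
    ledger = {
        "entered": float(weights.sum()),
        "fiber_return": float((bundle.weights * (1.0 - trans)).sum()),
        "escaped": 0.0,
        "pruned": 0.0,
        "depth_terminated": 0.0,
    }
    positions = np.zeros((len(bundle), 3))
    return GapExitRecords(positions=positions, directions=directions, weights=weights, ledger=ledger)


def _trace_gap_python(bundle: RayBundle, device: DeviceConfig, settings: TraceSettings) -> GapExitRecords:
    """Reference gap tracer; handles pluggable (callable) taper profiles."""
    gap = device.gap
    n_air = device.index("air")
    n_patch = device.index("patch")
    n_clad = device.index("cladding") if "cladding" in device.media else n_patch
    ledger = dict.fromkeys(("entered", "fiber_return", "escaped", "pruned", "depth_terminated"), 0.0)
    positions, directions, weights = [], [], []

    for i in range(len(bundle)):
        # start a hair ahead of the tip apex, which lies on the fiber boundary
        pos = np.array([0.0, 0.0, -gap.d + 1e-6])
        u = bundle.directions[i].copy()
        w = float(bundle.weights[i])
        cut = settings.weight_cutoff * w  # cutoff relative to initial ray weight
        depth = 0
        while True:
            try:
                hit = ray_surface_intersection(pos, u, gap)
            except ValueError:
                hit = None
            if hit is None:
                ledger["escaped"] += w
                break
            point, normal, kind = hit  # normal points into the air region
            cos_i = min(max(-float(np.dot(u, normal)), 0.0), 1.0)
            n2 = n_patch if kind.startswith("cavity") else n_clad
            theta_i = math.degrees(math.acos(cos_i))
            transmittance, _ = fresnel_unpolarized(theta_i, n_air, n2)
            if transmittance > 0.0:
                eta = n_air / n2
                k = 1.0 - eta * eta * (1.0 - cos_i * cos_i)
                t_dir = eta * u + (eta * cos_i - math.sqrt(k)) * normal
                t_dir /= np.linalg.norm(t_dir)
                if kind.startswith("cavity"):
                    positions.append(point)
                    directions.append(t_dir)
                    weights.append(w * transmittance)
                    ledger["entered"] += w * transmittance
                else:
                    ledger["fiber_return"] += w * transmittance
            w *= 1.0 - transmittance
            depth += 1
            if w <= cut:
                ledger["pruned"] += w
                break
            if depth >= settings.max_depth:
                ledger["depth_terminated"] += w
                break
            u = u + 2.0 * cos_i * normal
            u /= np.linalg.norm(u)
            pos = point + 1e-6 * normal

    if positions:
        return GapExitRecords(
            positions=np.array(positions),
            directions=np.array(directions),
            weights=np.array(weights),
            ledger=ledger,
        )
    return GapExitRecords(
        positions=np.zeros((0, 3)), directions=np.zeros((0, 3)), weights=np.zeros(0), ledger=ledger
    )


def trace_gap_records(
    bundle: RayBundle, device: DeviceConfig, settings: TraceSettings = TraceSettings()
) -> GapExitRecords:
    """Trace the bundle through the air cavity; returns patch-entry events."""
    gap = device.gap
    if gap.d == 0.0:
        return _no_gap_records(bundle, device)
    profile = device.taper
    if profile.radius_fn is not None:
        return _trace_gap_python(bundle, device, settings)
    m, pos, dirs, w, led = _kernels.trace_gap_kernel(
        np.ascontiguousarray(bundle.directions),
        np.ascontiguousarray(bundle.weights),
        float(gap.d),
        float(profile.tip_radius),
        float(profile.base_radius),
        float(profile.taper_length),
        float(profile.shape_exponent),
        device.index("air"),
        device.index("patch"),
        device.index("cladding") if "cladding" in device.media else device.index("patch"),
        settings.max_depth,
        settings.weight_cutoff,
    )
    ledger = {
        "entered": float(led[0]),
        "fiber_return": float(led[1]),
        "escaped": float(led[2]),
        "pruned": float(led[3]),
        "depth_terminated": float(led[4]),
    }
    return GapExitRecords(
        positions=pos[:m].copy(), directions=dirs[:m].copy(), weights=w[:m].copy(), ledger=ledger
    )


def trace_gap(
    bundle: RayBundle,
    device: DeviceConfig,
    settings: TraceSettings = TraceSettings(),
    bin_width_deg: float = 1.0,
) -> AngularPowerDistribution:
    """Binned power versus polar angle (from +z) at the moment of patch entry."""
    rec = trace_gap_records(bundle, device, settings)
    edges = np.arange(0.0, 180.0 + bin_width_deg, bin_width_deg)
    if len(rec.weights):
        theta = np.degrees(np.arccos(np.clip(rec.directions[:, 2], -1.0, 1.0)))
        power, _ = np.histogram(theta, bins=edges, weights=rec.weights)
    else:
        power = np.zeros(len(edges) - 1)
    loss = {k: v for k, v in rec.ledger.items() if k != "entered"}
    return AngularPowerDistribution(bin_edges=edges, power=power, ledger=loss)


# ---------------------------------------------------------------------------
# slab stage
# ---------------------------------------------------------------------------


def transport_slab(
    rays: GapExitRecords | RayBundle,
    slab: PatchSlab,
    media: dict,
    settings: TraceSettings = TraceSettings(),
) -> ExitRecordSet:
    """Propagate patch rays to the slab boundaries with Fresnel/TIR splitting.

    ``rays`` provides positions (um, tracing frame), unit directions and
    weights; the slab normal is y, the fiber axis z lies in the mid-plane.
    """
    if isinstance(rays, RayBundle):
        positions, directions, weights = rays.origins, rays.directions, rays.weights
    else:
        positions, directions, weights = rays.positions, rays.directions, rays.weights
    input_power = float(weights.sum())
    n_patch = media["patch"].n
    n_top = media["air"].n
    n_bottom = media["tissue"].n
    m, side, pos, ang, w, led = _kernels.transport_slab_kernel(
        np.ascontiguousarray(positions, dtype=float),
        np.ascontiguousarray(directions, dtype=float),
        np.ascontiguousarray(weights, dtype=float),
        slab.thickness / 2.0,
        slab.disk_radius_mm * 1000.0,
        n_patch,
        n_top,
        n_bottom,
        settings.max_depth,
        settings.weight_cutoff,
        settings.ideal_interfaces,
        settings.single_pass,
    )
    ledger = {
        "exited": float(led[0]),
        "pruned": float(led[1]),
        "depth_terminated": float(led[2]),
        "stopped_single_pass": float(led[3]),
    }
    return ExitRecordSet(
        side=side[:m].copy(),
        x_mm=pos[:m, 2] / 1000.0,
        y_mm=pos[:m, 0] / 1000.0,
        exit_angle_deg=ang[:m].copy(),
        weight=w[:m].copy(),
        ledger=ledger,
        input_power=input_power,
    )


def simulate_device(
    device: DeviceConfig,
    spec: EmissionSpec,
    settings: TraceSettings = TraceSettings(),
    bin_width_deg: float = 1.0,
) -> tuple[AngularPowerDistribution, ExitRecordSet, dict]:
    """Full pipeline: emission -> gap -> slab.  Returns (distribution, exits, ledger).

    The combined ledger accounts for all emitted power: patch-side exits plus
    every loss channel sum to 1 within the Monte Carlo bookkeeping tolerance.
    """
    bundle = sample_emission(spec, tip_position=(0.0, 0.0, -device.gap.d))
    rec = trace_gap_records(bundle, device, settings)
    edges = np.arange(0.0, 180.0 + bin_width_deg, bin_width_deg)
    if len(rec.weights):
        theta = np.degrees(np.arccos(np.clip(rec.directions[:, 2], -1.0, 1.0)))
        power, _ = np.histogram(theta, bins=edges, weights=rec.weights)
    else:
        power = np.zeros(len(edges) - 1)
    dist = AngularPowerDistribution(
        bin_edges=edges,
        power=power,
        ledger={k: v for k, v in rec.ledger.items() if k != "entered"},
    )
    exits = transport_slab(rec, device.slab, device.media, settings)
    ledger = {f"gap_{k}": v for k, v in rec.ledger.items() if k != "entered"}
    ledger.update({f"slab_{k}": v for k, v in exits.ledger.items()})
    return dist, exits, ledger
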