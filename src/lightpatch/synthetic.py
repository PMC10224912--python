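"""Synthetic fixtures: every stage of the pipeline is testable offline.

Provides the reference device, deterministic pull-distance sweep plans,
ground-truth beam images emulating the fluorescent-dye light-path experiment,
and degenerate oracle geometries.  Every fixture regenerates bit-exactly from
its (generator, parameters, seed) triple; ground-truth records live next to,
never inside, the estimator inputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .config import dump_device, load_device
from .geometry import DeviceConfig
from .metrics import BeamImage, render_beam_image

__all__ = [
    "SweepPlan",
    "default_device",
    "make_d_sweep_plan",
    "make_beam_image_fixture",
    "degenerate_geometries",
    "write_fixture_catalog",
]

#: pull distances (um) covering the rise, plateau and decline regimes
DEFAULT_SWEEP_D_UM = (0.5, 1.0, 2.0, 5.0, 10.0, 15.0, 20.0, 25.0, 40.0, 60.0, 80.0, 120.0)

NOISE_PEAK_COUNTS = {"none": 2**16 - 1, "moderate": 2**12, "high": 2**8}


def default_device() -> DeviceConfig:
    """The reference device: 280 um taper, 1 um tip, 100 um fiber, d = 15 um,
    indices air 1.0003 / patch 1.49 / tissue 1.4 / core 1.4613 / cladding
    1.4562, slab 125 um thick and 25 mm across."""
    return load_device(None)


@dataclass(frozen=True)
class SweepPlan:
    """A deterministic pull-distance sweep: sorted d values and per-d seeds."""

    d_um: tuple
    seeds: tuple
    base_seed: int

    def __post_init__(self) -> None:
        if len(self.d_um) != len(self.seeds):
            raise ValueError("d_um and seeds must have equal length")


def make_d_sweep_plan(base_seed: int = 1234, d_values=DEFAULT_SWEEP_D_UM) -> SweepPlan:
    """Sorted, duplicate-free sweep plan with seeds derived as base + index."""
    ds = tuple(sorted(set(float(d) for d in d_values)))
    if any(d < 0 for d in ds):
        raise ValueError("pull distances must be >= 0")
    seeds = tuple(int(base_seed) + i for i in range(len(ds)))
    return SweepPlan(d_um=ds, seeds=seeds, base_seed=int(base_seed))


def make_beam_image_fixture(
    true_divergence_deg: float,
    medium_n: float = 1.40,
    noise: str = "none",
    seed: int = 0,
    n_rays: int = 3001,
    pitch_um: float = 2.0,
    axial_extent_um: float = 1000.0,
) -> tuple[BeamImage, dict]:
    """A noisy beam image with known ground truth, like a dye light-path shot.

    A meridional fan of ``n_rays`` rays with the requested full divergence is
    rendered from an apex near the left image border; the transverse extent
    is sized so the beam never clips.  Poisson shot noise is applied on a
    16-bit scale whose peak count depends on the noise level
    (none / moderate / high -> 2^16 / 2^12 / 2^8).  Returns the image and a
    separate ground-truth record.
    """
    if not (0.0 < true_divergence_deg < 180.0):
        raise ValueError("true divergence must lie in (0, 180) degrees")
    if noise not in NOISE_PEAK_COUNTS:
        raise ValueError(f"noise must be one of {sorted(NOISE_PEAK_COUNTS)}")
    half = math.radians(true_divergence_deg / 2.0)
    angles = np.linspace(-half, half, n_rays)
    directions = np.column_stack(
        [np.sin(angles), np.zeros(n_rays), np.cos(angles)]
    )
    weights = np.full(n_rays, 1.0 / n_rays)
    margin = 40.0 * pitch_um
    half_extent = math.tan(half) * (axial_extent_um + margin) * 1.1 + 25.0 * pitch_um
    origins = np.tile([0.0, 0.0, 0.0], (n_rays, 1))
    image = render_beam_image(
        origins,
        directions,
        weights,
        extent_um=(-margin, axial_extent_um, -half_extent, half_extent),
        pitch_um=pitch_um,
        blur_sigma_px=2.0,
    )
    peak = NOISE_PEAK_COUNTS[noise]
    scaled = image.data / image.data.max() * peak
    rng = np.random.default_rng(seed)
    if noise == "none":
        counts = np.round(scaled)
    else:
        counts = rng.poisson(scaled).astype(float)
    counts = np.clip(counts, 0, 2**16 - 1).astype(np.uint16)
    fixture = BeamImage(
        data=counts,
        pitch_um=pitch_um,
        meta={"medium_n": medium_n, "noise": noise, "seed": seed, "peak_counts": peak},
    )
    truth = {
        "true_divergence_deg": float(true_divergence_deg),
        "medium_n": float(medium_n),
        "noise": noise,
        "seed": int(seed),
        "n_rays": int(n_rays),
        "pitch_um": float(pitch_um),
    }
    return fixture, truth


def degenerate_geometries() -> dict:
    """Oracle test doubles, each with its closed-form expectation attached.

    * ``flat_wall``: the cavity wall replaced by a plane normal to the axis
      (a huge flat apex cap), so every gap event is a single flat-interface
      refraction with a closed-form answer per ray.
    * ``symmetric_slab``: identical media above and below the patch; the
      tissue/air split must be symmetric.
    * ``index_matched_slab``: no index step at the slab faces; all power must
      exit on the first pass.
    """
    base = default_device()
    flat_taper = replace(base.taper, tip_radius=5000.0, base_radius=5001.0, taper_length=1.0)
    flat_wall = replace(base, taper=flat_taper, gap=replace(base.gap, cavity_profile=flat_taper))

    sym_media = dict(base.media)
    sym_media["tissue"] = replace(base.media["air"], name="tissue")
    symmetric = replace(base, media=sym_media)

    matched_media = {
        name: replace(m, n=base.media["patch"].n) for name, m in base.media.items()
    }
    matched = replace(base, media=matched_media)

    return {
        "flat_wall": {
            "device": flat_wall,
            "expectation": "per-ray flat-interface Snell/Fresnel refraction",
        },
        "symmetric_slab": {
            "device": symmetric,
            "expectation": "tissue and air exit totals equal within MC error",
        },
        "index_matched_slab": {
            "device": matched,
            "expectation": "all slab power exits on the first pass",
        },
    }


def write_fixture_catalog(out_dir, base_seed: int = 1234) -> Path:
    """Materialize the fixture suite on disk with a regeneration manifest."""
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []

    device = default_device()
    dump_device(device, out / "default_device.toml")
    entries.append(
        {"name": "default_device", "file": "default_device.toml", "generator": "default_device", "seed": None}
    )

    plan = make_d_sweep_plan(base_seed)
    (out / "d_sweep_plan.json").write_text(
        json.dumps({"d_um": plan.d_um, "seeds": plan.seeds, "base_seed": plan.base_seed}, indent=1)
    )
    entries.append(
        {"name": "d_sweep_plan", "file": "d_sweep_plan.json", "generator": "make_d_sweep_plan", "seed": base_seed}
    )

    for angle, noise in ((40.0, "none"), (130.0, "moderate")):
        img, truth = make_beam_image_fixture(angle, noise=noise, seed=base_seed)
        name = f"beam_{int(angle)}deg_{noise}"
        tifffile.imwrite(out / f"{name}.tiff", img.data)
        (out / f"{name}.groundtruth.json").write_text(json.dumps(truth, indent=1))
        entries.append(
            {"name": name, "file": f"{name}.tiff", "generator": "make_beam_image_fixture", "seed": base_seed}
        )

    (out / "catalog.json").write_text(json.dumps({"fixtures": entries}, indent=1))
    return out / "catalog.json"
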