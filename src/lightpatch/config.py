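"""TOML serialization of device configurations.

The schema embeds units in key names (``*_um``, ``*_mm``) to prevent unit
bugs; the shipped default file reproduces the reference device verbatim.
"""

from __future__ import annotations

import tomllib
from importlib import resources
from pathlib import Path

from .geometry import AirGapGeometry, DeviceConfig, PatchSlab, TaperProfile
from .optics import Medium

__all__ = ["load_device", "loads_device", "dump_device", "dumps_device", "default_device_path"]


def default_device_path():
    """Traversable path of the packaged default device TOML."""
    return resources.files("lightpatch.data") / "default_device.toml"


def loads_device(text: str) -> DeviceConfig:
    raw = tomllib.loads(text)
    for section in ("media", "taper", "gap", "slab"):
        if section not in raw:
            raise KeyError(f"device config is missing the [{section}] section")
    media = {name: Medium(name, float(n)) for name, n in raw["media"].items()}
    t = raw["taper"]
    try:
        taper = TaperProfile(
            tip_radius=float(t["tip_radius_um"]),
            base_radius=float(t["base_radius_um"]),
            taper_length=float(t["taper_length_um"]),
            shape_exponent=float(t.get("shape_exponent", 2.0)),
        )
        gap = AirGapGeometry(d=float(raw["gap"]["d_um"]), cavity_profile=taper)
        s = raw["slab"]
        slab = PatchSlab(
            thickness=float(s["thickness_um"]),
            disk_radius_mm=float(s["disk_radius_mm"]),
        )
    except KeyError as exc:
        raise KeyError(f"device config is missing key {exc.args[0]!r}") from exc
    return DeviceConfig(media=media, taper=taper, gap=gap, slab=slab)


def load_device(path=None) -> DeviceConfig:
    """Load a device description from TOML; ``None`` loads the packaged default."""
    if path is None:
        return loads_device(default_device_path().read_text())
    return loads_device(Path(path).read_text())


def dumps_device(device: DeviceConfig) -> str:
    lines = ["[media]"]
    for name, medium in device.media.items():
        lines.append(f"{name} = {medium.n!r}")
    t = device.taper
    lines += [
        "",
        "[taper]",
        f"tip_radius_um = {t.tip_radius!r}",
        f"base_radius_um = {t.base_radius!r}",
        f"taper_length_um = {t.taper_length!r}",
        f"shape_exponent = {t.shape_exponent!r}",
        "",
        "[gap]",
        f"d_um = {device.gap.d!r}",
        "",
        "[slab]",
        f"thickness_um = {device.slab.thickness!r}",
        f"disk_radius_mm = {device.slab.disk_radius_mm!r}",
        "",
    ]
    return "\n".join(lines)


def dump_device(device: DeviceConfig, path) -> None:
    Path(path).write_text(dumps_device(device))
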