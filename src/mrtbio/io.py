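"""Plain-text configuration and image-bundle I/O.

Geometry and imaging configurations are stored as flat, diff-friendly
``key: value`` text.  Synthetic bundles are written as two
single-channel 16-bit TIFFs (``<stem>_dapi.tif``, ``<stem>_fitc.tif``)
with CSV truth tables and a config sidecar.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd
import tifffile

from .geometry import BeamGeometry
from .simulate import GroundTruth, ImagingConfig, SyntheticBundle

__all__ = [
    "read_geometry",
    "write_geometry",
    "read_imaging_config",
    "write_imaging_config",
    "save_bundle",
    "load_bundle_images",
]

_GEOMETRY_KEYS = {
    "peak_width_um": ("peak_width", float),
    "pitch_um": ("pitch", float),
    "pvdr": ("pvdr", float),
    "valley_dose_gy": ("valley_dose", float),
    "broadening_sigma_um": ("broadening_sigma", float),
    "n_beams": ("n_beams", int),
    "phase_um": ("phase", float),
}


def _read_kv(path: Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise ValueError(f"malformed config line (expected 'key: value'): {line!r}")
        key, value = line.split(":", 1)
        out[key.strip()] = value.strip()
    return out


def write_geometry(geometry: BeamGeometry, path) -> Path:
    path = Path(path)
    lines = [
        f"peak_width_um: {geometry.peak_width}",
        f"pitch_um: {geometry.pitch}",
        f"pvdr: {geometry.pvdr}",
        f"valley_dose_gy: {geometry.valley_dose}",
        f"broadening_sigma_um: {geometry.broadening_sigma}",
        f"n_beams: {geometry.n_beams}",
        f"phase_um: {geometry.phase}",
    ]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_geometry(path) -> BeamGeometry:
    raw = _read_kv(Path(path))
    kwargs = {}
    for key, value in raw.items():
        if key not in _GEOMETRY_KEYS:
            raise ValueError(f"unknown geometry key {key!r}")
        name, cast = _GEOMETRY_KEYS[key]
        kwargs[name] = cast(float(value)) if cast is int else cast(value)
    return BeamGeometry(**kwargs)


def write_imaging_config(config: ImagingConfig, path) -> Path:
    path = Path(path)
    lines = []
    for f in dataclasses.fields(config):
        value = getattr(config, f.name)
        lines.append(f"{f.name}: {'none' if value is None else value}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_imaging_config(path) -> ImagingConfig:
    raw = _read_kv(Path(path))
    fields = {f.name: f for f in dataclasses.fields(ImagingConfig)}
    kwargs = {}
    for key, value in raw.items():
        if key not in fields:
            raise ValueError(f"unknown imaging config key {key!r}")
        if value.lower() == "none":
            kwargs[key] = None
        elif key in ("image_width", "image_height", "n_nuclei", "placement_attempts", "seed"):
            kwargs[key] = int(float(value))
        else:
            kwargs[key] = float(value)
    return ImagingConfig(**kwargs)


def save_bundle(bundle: SyntheticBundle, directory, stem: str) -> dict[str, Path]:
    """Write a bundle's channels, truth tables and config sidecar.

    Returns the written paths keyed by artifact name.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "dapi": directory / f"{stem}_dapi.tif",
        "fitc": directory / f"{stem}_fitc.tif",
        "nuclei": directory / f"{stem}_nuclei.csv",
        "foci": directory / f"{stem}_foci.csv",
        "config": directory / f"{stem}_config.txt",
    }
    tifffile.imwrite(paths["dapi"], bundle.nuclear_channel)
    tifffile.imwrite(paths["fitc"], bundle.foci_channel)
    bundle.truth.nuclei.to_csv(paths["nuclei"], index=False)
    bundle.truth.foci.to_csv(paths["foci"], index=False)
    write_imaging_config(bundle.config, paths["config"])
    if bundle.geometry is not None:
        paths["geometry"] = directory / f"{stem}_geometry.txt"
        write_geometry(bundle.geometry, paths["geometry"])
    return paths


def load_bundle_images(directory, stem: str):
    """Read back the channel pair written by :func:`save_bundle`."""
    directory = Path(directory)
    dapi = tifffile.imread(directory / f"{stem}_dapi.tif")
    fitc = tifffile.imread(directory / f"{stem}_fitc.tif")
    return dapi, fitc


def load_truth(directory, stem: str) -> GroundTruth:
    directory = Path(directory)
    return GroundTruth(
        nuclei=pd.read_csv(directory / f"{stem}_nuclei.csv"),
        foci=pd.read_csv(directory / f"{stem}_foci.csv"),
    )
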