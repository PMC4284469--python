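"""File formats: track CSV, scenario YAML, raster PNG + sidecar, manifests.

Track CSV schema: header ``frame,time_s,x_um,y_um``, one file per filament.
Scenario configs are YAML mappings validated against the simulator schema.
Rasters export as 8-bit grayscale PNG (0 background, 255 filament) with a
JSON sidecar recording the pixel size and world origin.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .simulate import Raster
from .tracks import Track

SCHEMA_VERSION = "1"
TRACK_COLUMNS = ["frame", "time_s", "x_um", "y_um"]


class ScenarioError(ValueError):
    """Malformed scenario config; carries the offending key."""

    def __init__(self, key: str, message: str):
        self.key = key
        super().__init__(f"config key '{key}': {message}")


def read_track_csv(path) -> Track:
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    times = df["time_s"].to_numpy(dtype=float)
    if not np.all(np.diff(times) > 0):
        raise ValueError(f"{path}: time_s must be strictly increasing")
    return Track(times=times, positions=df[["x_um", "y_um"]].to_numpy(dtype=float))


def write_track_csv(path, track: Track) -> None:
    df = pd.DataFrame(
        {
            "frame": np.arange(len(track.times)),
            "time_s": track.times,
            "x_um": track.positions[:, 0],
            "y_um": track.positions[:, 1],
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")


_SCENARIO_SCHEMA = {
    "agar_percent": (float, True),
    "plate_radius_um": (float, False),
    "seed": (int, False),
    "dt_s": (float, False),
    "duration_s": (float, False),
    "kappa_per_um": (float, False),
    "width_um": (float, False),
    "segment_length_um": (float, False),
    "doubling_time_s": (float, False),
    "period_min_s": (float, False),
    "period_max_s": (float, False),
    "filaments": (list, True),
}


def validate_scenario(scenario: dict) -> dict:
    """Validate and normalize a scenario dict; raise ScenarioError on faults."""
    if not isinstance(scenario, dict):
        raise ScenarioError("<root>", "scenario must be a mapping")
    out = dict(scenario)
    for key, (typ, required) in _SCENARIO_SCHEMA.items():
        if key not in out or out[key] is None:
            if required:
                raise ScenarioError(key, "required key missing")
            continue
        val = out[key]
        if typ is float:
            try:
                out[key] = float(val)
            except (TypeError, ValueError):
                raise ScenarioError(key, f"expected a number, got {val!r}") from None
        elif typ is int:
            if not isinstance(val, (int, np.integer)) or isinstance(val, bool):
                raise ScenarioError(key, f"expected an integer, got {val!r}")
        elif typ is list and not isinstance(val, list):
            raise ScenarioError(key, f"expected a list, got {type(val).__name__}")
    agar = out["agar_percent"]
    if not 0 < agar <= 3:
        raise ScenarioError(
            "agar_percent", f"{agar} outside the allowed range (0, 3] % w/v"
        )
    if not out["filaments"]:
        raise ScenarioError("filaments", "at least one filament is required")
    for i, f in enumerate(out["filaments"]):
        for k in ("x_um", "y_um", "heading_deg", "length_um"):
            if k not in f:
                raise ScenarioError(f"filaments[{i}].{k}", "required key missing")
        if not float(f["length_um"]) > 0:
            raise ScenarioError(f"filaments[{i}].length_um", "must be > 0")
    return out


def load_scenario(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return validate_scenario(data)


def save_scenario(path, scenario: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scenario, fh, sort_keys=True)


def save_raster_png(path, raster: Raster) -> None:
    """8-bit grayscale PNG plus a JSON sidecar with the geometry metadata."""
    path = Path(path)
    img = np.where(raster.pixels, 255, 0).astype(np.uint8)
    iio.imwrite(path, img)
    sidecar = path.with_suffix(path.suffix + ".json")
    with open(sidecar, "w") as fh:
        json.dump(
            {
                "pixel_size_um": raster.pixel_size,
                "x_min_um": raster.x_min,
                "y_max_um": raster.y_max,
                "schema_version": SCHEMA_VERSION,
            },
            fh,
            indent=2,
        )


def load_raster_png(path) -> Raster:
    path = Path(path)
    img = iio.imread(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh)
        return Raster(
            pixels=img > 127,
            pixel_size=meta["pixel_size_um"],
            x_min=meta["x_min_um"],
            y_max=meta["y_max_um"],
        )
    return Raster(pixels=img > 127, pixel_size=1.0, x_min=0.0, y_max=float(img.shape[0]))


def vertices_to_csv(path, filaments, clock: float) -> None:
    """State snapshot: one row per vertex (filament id, index, x, y, time)."""
    rows = []
    for fil in filaments:
        for j, (x, y) in enumerate(fil.vertices):
            rows.append((fil.fid, j, x, y, clock))
    pd.DataFrame(
        rows, columns=["filament_id", "vertex_index", "x_um", "y_um", "time_s"]
    ).to_csv(path, index=False, float_format="%.6f")


def config_hash(obj) -> str:
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(
    out_dir, subcommand: str, config, seed, outputs: list[str]
) -> Path:
    """Every CLI run emits exactly one manifest recording how to repeat it."""
    from importlib.metadata import PackageNotFoundError, version

    try:
        pkg_version = version("phormidium")
    except PackageNotFoundError:
        pkg_version = "unknown"
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "subcommand": subcommand,
        "config_hash": config_hash(config),
        "seed": seed,
        "package_version": pkg_version,
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "outputs": sorted(outputs),
        "schema_version": SCHEMA_VERSION,
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return path
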