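"""File I/O: movies (TIFF / NPZ), configs (YAML/JSON), run manifests.

Conventions: persisted phase fields are in radians; every reported Delta
column is in rad/2pi and labeled as such in CSV headers (mixing the two
units is the most likely reproduction bug).  A movie on disk is either a
TIFF stack (one frame per time point, 32-bit float) or an ``.npz``
archive; the sampling interval and pixel size travel in a JSON sidecar
(``<stem>.json``) or are supplied explicitly.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field as dc_field
from pathlib import Path
from typing import Any

import numpy as np
import tifffile
import yaml

from .envelope_phase import MovieGrid

__all__ = [
    "RunManifest",
    "read_movie",
    "write_movie",
    "read_config",
    "make_config",
    "write_ground_truth",
]


@dataclass
class RunManifest:
    command: str
    config: dict
    seeds: list[int]
    version: str
    inputs: dict[str, str] = dc_field(default_factory=dict)    # path -> sha256
    outputs: dict[str, str] = dc_field(default_factory=dict)
    timestamp: str = dc_field(default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S"))

    def add_output(self, path: str | Path) -> None:
        self.outputs[str(path)] = sha256_file(path)

    def add_input(self, path: str | Path) -> None:
        self.inputs[str(path)] = sha256_file(path)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=_jsonable) + "\n")


def _jsonable(x: Any):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _sidecar(path: Path) -> dict:
    side = path.with_suffix(".json")
    if side.exists():
        return json.loads(side.read_text())
    return {}


def read_movie(
    path: str | Path,
    sampling_interval: float | None = None,
    pixel_size: float | None = None,
) -> MovieGrid:
    """Load a movie from a TIFF stack or ``.npz`` archive.

    Metadata (sampling interval in hours, pixel size in mm) is taken
    from explicit arguments first, then from the JSON sidecar.  Missing
    metadata raises a descriptive error.  Non-finite pixels are masked.
    """
    path = Path(path)
    meta = _sidecar(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        frames = tifffile.imread(path)     # (T, H, W)
        if frames.ndim == 2:
            frames = frames[None]
        data = np.moveaxis(frames, 0, -1).astype(float)
        time_axis = None
    elif path.suffix.lower() == ".npz":
        with np.load(path) as z:
            data = np.asarray(z["intensities"], dtype=float)
            time_axis = np.asarray(z["time_axis"], dtype=float) if "time_axis" in z else None
            meta = {**{k: z[k].item() for k in ("sampling_interval", "pixel_size") if k in z},
                    **meta}
    else:
        raise ValueError(f"unsupported movie format: {path.suffix!r}")

    si = sampling_interval if sampling_interval is not None else meta.get("sampling_interval")
    ps = pixel_size if pixel_size is not None else meta.get("pixel_size")
    if time_axis is None:
        if si is None:
            raise ValueError(
                "sampling interval unknown: pass --sampling-interval or provide a "
                f"JSON sidecar ({path.with_suffix('.json').name}) with 'sampling_interval'"
            )
        time_axis = np.arange(data.shape[-1]) * float(si)
    if ps is None:
        raise ValueError(
            "pixel size unknown: pass --pixel-size or provide a JSON sidecar "
            f"({path.with_suffix('.json').name}) with 'pixel_size'"
        )
    mask = np.all(np.isfinite(data), axis=-1)
    return MovieGrid(intensities=np.nan_to_num(data), time_axis=time_axis,
                     pixel_size=float(ps), mask=mask)


def write_movie(movie: MovieGrid, path: str | Path) -> Path:
    """Write a movie as float32 TIFF (frames = time points) or ``.npz``,
    plus a JSON metadata sidecar.  Returns the sidecar path."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        frames = np.moveaxis(movie.intensities, -1, 0).astype(np.float32)
        tifffile.imwrite(path, frames)
    elif path.suffix.lower() == ".npz":
        np.savez_compressed(
            path,
            intensities=movie.intensities,
            time_axis=movie.time_axis,
            sampling_interval=movie.sampling_interval,
            pixel_size=movie.pixel_size,
        )
    else:
        raise ValueError(f"unsupported movie format: {path.suffix!r}")
    side = path.with_suffix(".json")
    side.write_text(
        json.dumps(
            {
                "sampling_interval": movie.sampling_interval,
                "pixel_size": movie.pixel_size,
                "n_frames": int(movie.shape[2]),
                "grid_shape": [int(movie.shape[0]), int(movie.shape[1])],
            },
            indent=2,
        )
        + "\n"
    )
    return side


def write_ground_truth(truth, prefix: str | Path) -> list[Path]:
    """Persist a :class:`~scnwave.synthetic_data.GroundTruth` as JSON + CSV."""
    import pandas as pd

    prefix = Path(prefix)
    jpath = prefix.with_suffix(".truth.json")
    cpath = prefix.with_suffix(".truth.csv")
    jpath.write_text(
        json.dumps(
            {
                "true_delta_rad_per_2pi": truth.true_delta,
                "true_velocity_mm_per_h": truth.true_velocity,
                "n_defect_pixels": int(truth.defect_mask.sum()),
            },
            indent=2,
            default=_jsonable,
        )
        + "\n"
    )
    h, w = truth.phase_offset_map.shape
    rows, cols = np.mgrid[0:h, 0:w]
    pd.DataFrame(
        {
            "row": rows.ravel(),
            "col": cols.ravel(),
            "phase_offset_rad_per_2pi": truth.phase_offset_map.ravel(),
            "amplitude_counts": truth.amplitude_map.ravel(),
            "defect": truth.defect_mask.ravel().astype(int),
        }
    ).to_csv(cpath, index=False)
    return [jpath, cpath]


def read_config(path: str | Path, allowed_keys: set[str]) -> dict:
    """Read a YAML/JSON config and reject unknown keys (no silent defaults)."""
    path = Path(path)
    text = path.read_text()
    cfg = yaml.safe_load(text) if path.suffix.lower() in {".yaml", ".yml"} else json.loads(text)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    unknown = set(cfg) - allowed_keys
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}; allowed: {sorted(allowed_keys)}")
    return cfg


def make_config(cls, cfg: dict):
    """Build a dataclass config (SimConfig / SyntheticMovieSpec) from a dict,
    rejecting unknown keys."""
    allowed = set(cls.__dataclass_fields__)
    unknown = set(cfg) - allowed
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    obj = cls(**{k: (tuple(v) if isinstance(v, list) else v) for k, v in cfg.items()})
    if hasattr(obj, "validate"):
        obj.validate()
    return obj
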