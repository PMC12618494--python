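"""TIFF/CSV/JSON/YAML round-tripping and run configuration.

Image stacks are written as multi-page TIFF with the acquisition metadata
(pixel size, frame interval, channel names, camera parameters) embedded as
JSON in the file description, so a written stack reads back losslessly.
Tables use fixed CSV headers shared with the consuming modules. The run
configuration is one flat-ish YAML mapping; a stable hash of its canonical
JSON rendering plus the global seed is recorded in every run log.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from pathlib import Path
from typing import Any

import numpy as np
import tifffile
import yaml

from .errors import ConfigurationError, FormatError
from .stack import CameraModel, ImageStack

__all__ = [
    "read_stack",
    "write_stack",
    "load_config",
    "config_hash",
    "write_run_log",
    "DEFAULT_CONFIG",
]

# provenance of defaults: geometry, frame intervals and the colocalization
# radius follow the experimental layout this package emulates; photon
# budget, background, gain and detection thresholds are generator/analysis
# defaults with no measured counterpart and are always logged with a run.
DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 1,
    "geometry": {
        "radius_um": 10.0,
        "capillary_length_um": 40.0,
        "capillary_width_um": 1.5,
        "chamber_height_um": 1.5,
        "constriction_height_um": 0.4,
    },
    "camera": {
        "pixel_size_um": 0.16,
        "frame_interval_s": 1.0,
        "exposure_s": 0.1,
        "photons_per_frame": 400.0,
        "background_photons": 5.0,
        "em_gain": 30.0,
        "read_noise_counts": 10.0,
        "psf_sigma_um": 0.16,
    },
    "detection": {"snr_min": 5.0},
    "linking": {"max_disp_um": 1.0, "max_gap_frames": 2},
    "clustering": {"radius_um": 0.32, "max_frame_gap": 5, "min_detections": 2},
    "segmentation": {
        "smoothing_sigma_um": 0.25,
        "threshold_method": "otsu",
        "min_area_um2": 1.0,
        "background_open_um": 6.0,
    },
    "fitting": {"arrival_model": "mono", "bi_min_improvement": 0.25},
    "dose_response": {"quantiles": [0.159, 0.841]},
}


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write an ImageStack as multi-page TIFF with JSON metadata."""
    meta = {
        "camera": dataclasses.asdict(stack.camera),
        "channel_names": list(stack.channel_names),
    }
    tifffile.imwrite(
        str(path),
        stack.counts.astype(np.float32),
        description=json.dumps(meta),
        photometric="minisblack",
    )


def read_stack(
    path: str | Path,
    fallback_camera: CameraModel | None = None,
) -> ImageStack:
    """Read a TIFF stack written by :func:`write_stack` (or a plain TIFF).

    Metadata is taken from the embedded JSON description; a plain TIFF
    without metadata loads only when ``fallback_camera`` supplies pixel size
    and frame interval, with a warning. Corrupt files raise a format error
    with no partial result.
    """
    try:
        with tifffile.TiffFile(str(path)) as tif:
            data = tif.asarray()
            description = tif.pages[0].description
    except (tifffile.TiffFileError, FileNotFoundError, OSError) as exc:
        raise FormatError(f"cannot read TIFF stack {path}: {exc}") from exc
    camera = None
    channel_names = None
    if description:
        try:
            meta = json.loads(description)
            camera = CameraModel(**meta["camera"])
            channel_names = tuple(meta["channel_names"])
        except (json.JSONDecodeError, KeyError, TypeError):
            camera = None
    if camera is None:
        if fallback_camera is None:
            raise FormatError(
                f"{path} has no embedded acquisition metadata and no fallback "
                "camera model was provided"
            )
        warnings.warn(
            f"{path}: missing acquisition metadata; using configured camera values",
            stacklevel=2,
        )
        camera = fallback_camera
    data = np.asarray(data)
    if channel_names is not None and data.ndim == 4 and data.shape[1] != len(channel_names):
        raise FormatError(
            f"{path}: {data.shape[1]} channels but metadata names {len(channel_names)}"
        )
    if channel_names is None:
        n_ch = data.shape[1] if data.ndim == 4 else 1
        channel_names = tuple(f"ch{i}" for i in range(n_ch))
    return ImageStack(counts=data, camera=camera, channel_names=channel_names)


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None = None) -> dict[str, Any]:
    """Load the YAML run configuration, merged over the documented defaults."""
    if path is None:
        return json.loads(json.dumps(DEFAULT_CONFIG))
    try:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
    except yaml.YAMLError as exc:
        raise FormatError(f"cannot parse config {path}: {exc}") from exc
    if not isinstance(user, dict):
        raise ConfigurationError(f"config {path} must be a mapping")
    return _merge(DEFAULT_CONFIG, user)


def config_hash(config: dict[str, Any]) -> str:
    """Stable short hash of the canonical JSON rendering of a config."""
    canon = json.dumps(config, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_run_log(
    path: str | Path,
    subcommand: str,
    config: dict[str, Any],
    inputs: dict[str, Any],
    outputs: dict[str, Any],
) -> None:
    """JSON run log: command, parameters, seed, config hash, in/outputs."""
    from . import __version__

    log = {
        "subcommand": subcommand,
        "version": __version__,
        "seed": config.get("seed"),
        "config_hash": config_hash(config),
        "config": config,
        "inputs": inputs,
        "outputs": outputs,
    }
    Path(path).write_text(json.dumps(log, indent=2, default=str))
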