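"""Reading and writing the package's on-disk artifacts.

Slides and masks travel as PNG (masks single-channel 0/255); score maps as
16-bit PNG (score x 65535) with a JSON sidecar recording the grid geometry;
configs as YAML; metric reports as CSV.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from .errors import ConfigError
from .slide import BinaryMask, ScoreMap, SlideImage

__all__ = [
    "read_slide_png",
    "write_slide_png",
    "read_mask_png",
    "write_mask_png",
    "read_score_map",
    "write_score_map",
    "write_config_yaml",
    "read_config_yaml",
]


def read_slide_png(path) -> SlideImage:
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    return SlideImage(arr.astype(np.uint8), source_id=Path(path).stem)


def write_slide_png(path, slide: SlideImage) -> None:
    iio.imwrite(path, slide.pixels)


def read_mask_png(path, role: str = "annotation") -> BinaryMask:
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return BinaryMask(arr > 127, role=role)


def write_mask_png(path, mask: BinaryMask) -> None:
    iio.imwrite(path, (mask.values.astype(np.uint8) * 255))


def write_score_map(path, smap: ScoreMap) -> None:
    """16-bit PNG (score x 65535, NaN -> 0) + JSON sidecar with geometry."""
    path = Path(path)
    vals = np.nan_to_num(smap.scores, nan=0.0)
    iio.imwrite(path, np.round(vals * 65535).astype(np.uint16))
    sidecar = {
        "grid_origin": list(smap.grid_origin),
        "stride": int(smap.stride),
        "downscale": float(smap.downscale),
        "missing_cells": np.argwhere(np.isnan(smap.scores)).tolist(),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def read_score_map(path) -> ScoreMap:
    path = Path(path)
    arr = iio.imread(path).astype(float) / 65535.0
    meta = json.loads(path.with_suffix(".json").read_text())
    for r, c in meta.get("missing_cells", []):
        arr[r, c] = np.nan
    return ScoreMap(
        scores=arr,
        stride=int(meta["stride"]),
        grid_origin=tuple(meta["grid_origin"]),
        downscale=float(meta["downscale"]),
    )


def write_config_yaml(path, cfg) -> None:
    if dataclasses.is_dataclass(cfg):
        cfg = dataclasses.asdict(cfg)
    Path(path).write_text(yaml.safe_dump(_plain(cfg), sort_keys=True))


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def read_config_yaml(path, cls=None):
    data = yaml.safe_load(Path(path).read_text())
    if cls is None:
        return data
    try:
        return cls(**data)
    except TypeError as exc:
        raise ConfigError(f"invalid {cls.__name__} config in {path}: {exc}") from exc
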