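"""Image and table I/O, configuration and run provenance.

All images travel as plain TIFF: 8/16-bit integer (or float) single-plane
images map to :class:`~furrowseg.core.IntensityImage`, multi-page files to
z-stacks.  Masks are written as 8-bit TIFF (0/255), label images as 16-bit,
intensities as 32-bit float.  Tabular outputs are CSV; configuration is
YAML or JSON; provenance is JSON and round-trips losslessly, because with
strategy-resolved thresholds the provenance file is what makes a run
repeatable.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

from . import __version__
from .core import FishStack, IntensityImage

_SUPPORTED_DTYPES = ("uint8", "uint16", "int16", "int32", "float32", "float64")


def read_image(path, pixel_size_um: float | None = None):
    """Read a TIFF into an :class:`IntensityImage` (single plane) or a 3-D array.

    Integer 8/16-bit data are mapped to non-negative floats; multi-page
    files return the raw ``(z, y, x)`` array (use :func:`read_fish_stack`
    to assemble a two-channel FISH acquisition).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    data = tifffile.imread(path)
    if str(data.dtype) not in _SUPPORTED_DTYPES:
        raise ValueError(f"unsupported TIFF bit depth / dtype: {data.dtype}")
    data = np.clip(np.asarray(data, dtype=float), 0.0, None)
    if data.ndim == 2:
        kwargs = {} if pixel_size_um is None else {"pixel_size_um": pixel_size_um}
        return IntensityImage(data, **kwargs)
    if data.ndim == 3:
        return data
    raise ValueError(f"expected a 2-D image or 3-D stack, got shape {data.shape}")


def read_fish_stack(
    spot_path,
    nucleus_path,
    z_step_um: float,
    pixel_size_um: float | None = None,
) -> FishStack:
    """Assemble a FishStack from a spot-channel stack and a nucleus image."""
    spots = tifffile.imread(Path(spot_path))
    nuclei = tifffile.imread(Path(nucleus_path))
    spots = np.clip(np.asarray(spots, dtype=float), 0.0, None)
    if spots.ndim == 2:
        spots = spots[None]
    kwargs = {} if pixel_size_um is None else {"pixel_size_um": pixel_size_um}
    return FishStack(
        spot_channel=spots,
        nucleus_channel=np.clip(np.asarray(nuclei, dtype=float), 0.0, None),
        z_step_um=z_step_um,
        **kwargs,
    )


def write_intensity(path, pixels: np.ndarray) -> None:
    """Write an intensity image or stack as 32-bit float TIFF."""
    tifffile.imwrite(
        Path(path), np.asarray(pixels, dtype=np.float32), photometric="minisblack"
    )


def write_mask(path, mask: np.ndarray) -> None:
    """Write a binary mask as 8-bit TIFF (foreground = 255)."""
    tifffile.imwrite(Path(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))


def write_labels(path, labels: np.ndarray) -> None:
    """Write a label image as 16-bit TIFF."""
    labels = np.asarray(labels)
    if labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels do not fit a 16-bit TIFF")
    tifffile.imwrite(Path(path), labels.astype(np.uint16))


def load_config(path) -> dict:
    """Load a YAML or JSON configuration mapping."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"configuration in {path} must be a mapping")
    return data


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


@dataclass
class RunProvenance:
    """Everything needed to repeat a run: version, config, seeds, thresholds."""

    config: dict
    seeds: dict
    thresholds: dict = field(default_factory=dict)
    tool_version: str = __version__
    timestamp: str = field(default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S"))

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(_jsonable(dataclasses.asdict(self)),
                                         indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "RunProvenance":
        data = json.loads(Path(path).read_text())
        return cls(**data)
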