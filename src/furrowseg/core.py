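"""Core data containers shared across the package.

The containers mirror the objects that flow through the analysis: a 2-D
intensity image with a physical pixel size, the 1-pixel-wide furrow-canal
network mask, integer label images for enclosed compartments, and a 3-D
FISH stack.  They are thin dataclasses over numpy arrays; all algorithms
live in the dedicated modules.

Conventions
-----------
* pixel coordinates are (row, col), 0-based;
* skeletons / network masks use 8-connectivity, compartment labels use
  4-connectivity (the standard duality that stops label regions leaking
  diagonally across a 1-pixel skeleton);
* physical lengths are micrometres, converted through ``pixel_size_um``
  (default 0.104 um/px, a typical confocal surface-view sampling).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: default physical sampling, micrometres per pixel
DEFAULT_PIXEL_SIZE_UM = 0.104


class FurrowsegError(Exception):
    """Base class for package errors."""


class LatticeSizingError(FurrowsegError):
    """Image too small for the requested number of nuclei."""


class DegenerateImageError(FurrowsegError):
    """An automatic threshold cannot be computed (e.g. constant image)."""


class NoNetworkError(FurrowsegError):
    """No plausible furrow-canal network was found in the image."""


@dataclass
class IntensityImage:
    """A single-channel non-negative intensity image with pixel size.

    Parameters
    ----------
    pixels : ndarray
        2-D array of non-negative intensities (float or integer).
    pixel_size_um : float
        Physical size of one pixel in micrometres.
    """

    pixels: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2-D image, got ndim={self.pixels.ndim}")
        if min(self.pixels.shape) < 16:
            raise ValueError(f"image too small: {self.pixels.shape} (need >=16 per axis)")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if np.any(self.pixels < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def um_to_px(self, length_um: float) -> float:
        return length_um / self.pixel_size_um


@dataclass
class NetworkMask:
    """Binary mask whose foreground is a 1-pixel-wide skeleton (8-connected)."""

    mask: np.ndarray
    connectivity: int = 8

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("network mask must be 2-D")

    def is_one_pixel_wide(self) -> bool:
        """True when no 2x2 all-foreground block exists in the mask."""
        m = self.mask
        blocks = m[:-1, :-1] & m[:-1, 1:] & m[1:, :-1] & m[1:, 1:]
        return not bool(blocks.any())


@dataclass
class CompartmentLabels:
    """Integer label image of enclosed regions (0 = background/network).

    ``kind`` distinguishes cells (regions enclosed by the strong furrow
    network) from nucleus compartments (regions enclosed by the full
    network including weak residual links).  Labels are consecutive
    1..L and each region is 4-connected.
    """

    labels: np.ndarray
    kind: str = "cell"  # {"cell", "nucleus_compartment"}
    boundary_excluded: bool = True

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label image must be 2-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integers")
        if self.kind not in ("cell", "nucleus_compartment"):
            raise ValueError(f"unknown label kind {self.kind!r}")

    @property
    def n_labels(self) -> int:
        return int(self.labels.max())


@dataclass
class FishStack:
    """A 3-D FISH acquisition: spot channel stack plus a nucleus channel.

    ``depth_um`` is the physical depth spanned by the stack; genotyping
    projections conventionally cover ~4 um so that both alleles' nascent
    transcription sites fall inside the projected volume.
    """

    spot_channel: np.ndarray  # (z, y, x)
    nucleus_channel: np.ndarray  # (y, x) or (z, y, x)
    z_step_um: float
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        self.spot_channel = np.asarray(self.spot_channel)
        self.nucleus_channel = np.asarray(self.nucleus_channel)
        if self.spot_channel.ndim != 3 or self.spot_channel.shape[0] < 1:
            raise ValueError("spot channel must be a (z, y, x) stack with >=1 slice")
        if self.nucleus_channel.shape[-2:] != self.spot_channel.shape[-2:]:
            raise ValueError("channels must share the x-y shape")
        if self.z_step_um <= 0:
            raise ValueError("z_step_um must be positive")

    @property
    def n_slices(self) -> int:
        return self.spot_channel.shape[0]

    @property
    def depth_um(self) -> float:
        return self.n_slices * self.z_step_um


@dataclass
class EmbryoSummary:
    """Per-embryo fidelity metrics.

    ``ratio`` is the mononucleate-cells-to-nuclei ratio (1.0 in an intact
    embryo); ``is_multinucleate`` records whether any scored cell enclosed
    two or more nucleus compartments.
    """

    embryo_id: str
    n_nuclei_assayed: int
    n_mononucleate_cells: int
    ratio: float
    is_multinucleate: bool
    factin_mean: float | None = None
    genotype: str | None = None
    temperature: float | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 <= self.ratio <= 1.0 + 1e-12):
            raise ValueError(f"ratio must lie in [0, 1], got {self.ratio}")
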