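"""Morphological segmentation of furrow-canal networks in surface views.

The furrow canals of a cellularizing embryo appear in a surface view as a
bright, roughly hexagonal network enclosing one nucleus per nascent cell.
Segmentation proceeds in six steps:

1. coarse Gaussian smoothing of the raw image (retain only the coarse
   furrow-canal features);
2. an intensity threshold on the smoothed image, giving a preliminary
   network mask;
3. iterative thinning of that mask to a 1-pixel-wide network;
4. fine Gaussian smoothing of the raw image plus a *low* threshold that
   also captures the weak residual furrow-canal links present in
   multinucleate cells, followed by morphological closing, thinning, and
   removal of short spurs / disconnected link fragments;
5. the union of the thinned step-2 mask and the step-4 mask is dilated and
   inverted to yield a preliminary nucleus-compartment mask, whose holes
   are filled;
6. a *high* threshold on the step-1 image is inverted and intersected with
   the step-5 mask to eliminate boundary artifacts of thinning; regions
   touching the image border are also discarded, since partially imaged
   cells cannot be scored.

Cells are the regions enclosed by the strong (step-2/3) network; nucleus
compartments the regions enclosed by the full network including weak
links.  Each compartment is assigned to the cell with which it shares the
majority of its area, and the final cell label image is the union of its
member compartments, which makes spatial containment exact by
construction.

Thresholds were selected manually in the original workflow; here they are
a strategy parameter (Otsu-based default, quantile and fixed overrides)
and every resolved value is logged and recorded in the provenance of a
:func:`segment` run.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.morphology import closing, dilation, disk, thin

from .core import (
    CompartmentLabels,
    DegenerateImageError,
    IntensityImage,
    NetworkMask,
    NoNetworkError,
)

logger = logging.getLogger(__name__)

#: foreground fraction above which a "network" mask is considered noise
MAX_NETWORK_FRACTION = 0.45


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable parameters of the six-step procedure.

    ``sigma_coarse_px`` sets the step-1 smoothing scale (about half the
    ridge-spacing scale); ``sigma_fine_px`` the step-4 scale, small enough
    to preserve the weak links.  Under the default ``otsu`` strategy the
    mid threshold is Otsu's threshold of the coarse-smoothed image, the
    low threshold is ``low_otsu_factor`` times Otsu's threshold of the
    fine-smoothed image, and the high threshold is ``high_otsu_factor``
    times the mid threshold.  Under ``quantile`` the three thresholds are
    intensity quantiles; under ``fixed`` they are absolute intensities.
    """

    sigma_coarse_px: float = 4.0
    sigma_fine_px: float = 1.5
    threshold_strategy: str = "otsu"  # {"otsu", "quantile", "fixed"}
    low_threshold: float | None = None
    mid_threshold: float | None = None
    high_threshold: float | None = None
    low_otsu_factor: float = 0.35
    high_otsu_factor: float = 1.8
    close_radius_px: int = 2
    dilate_radius_px: int = 2
    min_link_length_px: int = 10
    prune_spurs: bool = True
    drop_disconnected_links: bool = True
    #: require fine-scale ridge evidence for strong-network walls; without
    #: this, the coarse-smoothing halos of two nearby junctions can bridge
    #: a short failed furrow and wrongly split its merged cell in two
    refine_strong_with_fine: bool = True
    #: margin on that evidence threshold (otsu strategy): intact walls sit
    #: well above Otsu's split of the fine image while weak residual links
    #: and junction halos sit below ~1.2x of it
    strong_otsu_factor: float = 1.2

    def __post_init__(self) -> None:
        if self.sigma_coarse_px <= 0 or self.sigma_fine_px <= 0:
            raise ValueError("Gaussian sigmas must be positive")
        if self.sigma_fine_px >= self.sigma_coarse_px:
            raise ValueError("sigma_fine_px must be smaller than sigma_coarse_px")
        if self.threshold_strategy not in ("otsu", "quantile", "fixed"):
            raise ValueError(f"unknown threshold strategy {self.threshold_strategy!r}")
        if self.threshold_strategy in ("quantile", "fixed"):
            vals = (self.low_threshold, self.mid_threshold, self.high_threshold)
            if any(v is None for v in vals):
                raise ValueError(
                    f"strategy {self.threshold_strategy!r} requires explicit "
                    "low/mid/high thresholds"
                )
            if not (vals[0] < vals[1] < vals[2]):  # type: ignore[operator]
                raise ValueError("thresholds must satisfy low < mid < high")
        if self.close_radius_px < 1 or self.dilate_radius_px < 1:
            raise ValueError("morphological radii must be positive")
        if self.min_link_length_px < 1:
            raise ValueError("min_link_length_px must be positive")


@dataclass
class SegmentationResult:
    """Output of a full :func:`segment` run."""

    network: NetworkMask
    cells: CompartmentLabels
    compartments: CompartmentLabels
    cell_of_compartment: dict[int, int]
    nuclei_per_cell: dict[int, int]
    unassigned_compartments: list[int]
    provenance: dict

    @property
    def n_cells(self) -> int:
        return self.cells.n_labels

    @property
    def n_compartments(self) -> int:
        return self.compartments.n_labels


# --------------------------------------------------------------------------
# thresholds
# --------------------------------------------------------------------------


def _otsu(values: np.ndarray, context: str) -> float:
    if float(values.max()) == float(values.min()):
        raise DegenerateImageError(
            f"cannot compute an Otsu threshold for {context}: constant image"
        )
    return float(threshold_otsu(values))


def resolve_mid_threshold(smoothed: IntensityImage, params: SegmentationParams) -> float:
    """Step-2 threshold on the coarse-smoothed image, per strategy."""
    px = smoothed.pixels
    if params.threshold_strategy == "otsu":
        return _otsu(px, "the coarse-smoothed image")
    if params.threshold_strategy == "quantile":
        return float(np.quantile(px, params.mid_threshold))
    return float(params.mid_threshold)  # fixed


def resolve_low_threshold(
    fine: IntensityImage, params: SegmentationParams, mid: float | None = None
) -> float:
    """Step-4 low threshold on the fine-smoothed image, per strategy."""
    px = fine.pixels
    if params.threshold_strategy == "otsu":
        low = params.low_otsu_factor * _otsu(px, "the fine-smoothed image")
        if mid is not None and low >= mid:
            logger.warning(
                "low threshold %.3g not below mid %.3g; clamping to 0.5*mid", low, mid
            )
            low = 0.5 * mid
        return float(low)
    if params.threshold_strategy == "quantile":
        return float(np.quantile(px, params.low_threshold))
    return float(params.low_threshold)


def resolve_high_threshold(
    smoothed: IntensityImage, params: SegmentationParams, mid: float | None = None
) -> float:
    """Step-6 high threshold on the coarse-smoothed image, per strategy."""
    if params.threshold_strategy == "otsu":
        base = mid if mid is not None else _otsu(smoothed.pixels, "the coarse-smoothed image")
        return float(params.high_otsu_factor * base)
    if params.threshold_strategy == "quantile":
        return float(np.quantile(smoothed.pixels, params.high_threshold))
    return float(params.high_threshold)


# --------------------------------------------------------------------------
# steps 1-3: strong network
# --------------------------------------------------------------------------


def smooth_coarse(image: IntensityImage, params: SegmentationParams) -> IntensityImage:
    """Step 1: Gaussian smoothing retaining only coarse furrow-canal features.

    Reflective border handling keeps the mean intensity essentially
    unchanged (within 1%).
    """
    if params.sigma_coarse_px <= 0:
        raise ValueError("sigma_coarse_px must be positive")
    out = ndi.gaussian_filter(np.asarray(image.pixels, dtype=float),
                              params.sigma_coarse_px, mode="reflect")
    return IntensityImage(np.clip(out, 0.0, None), image.pixel_size_um)


def smooth_fine(image: IntensityImage, params: SegmentationParams) -> IntensityImage:
    """Step-4 smoothing: suppress noise while retaining fine features."""
    out = ndi.gaussian_filter(np.asarray(image.pixels, dtype=float),
                              params.sigma_fine_px, mode="reflect")
    return IntensityImage(np.clip(out, 0.0, None), image.pixel_size_um)


def preliminary_network_mask(
    smoothed: IntensityImage,
    params: SegmentationParams,
    threshold: float | None = None,
) -> np.ndarray:
    """Step 2: threshold the smoothed image into a preliminary network mask."""
    thr = resolve_mid_threshold(smoothed, params) if threshold is None else threshold
    logger.info("preliminary network mask: mid threshold = %.4g", thr)
    return smoothed.pixels >= thr


def skeletonize_network(mask: np.ndarray) -> NetworkMask:
    """Step 3: thin the mask iteratively to a 1-pixel-wide network.

    Thinning is topology preserving: connected components and holes of the
    input survive in the skeleton, and the skeleton is a subset of the
    input foreground.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise NoNetworkError("cannot skeletonize an empty mask")
    return NetworkMask(thin(mask))


# --------------------------------------------------------------------------
# step 4: weak links
# --------------------------------------------------------------------------

_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=np.uint8)


def _neighbor_counts(skel: np.ndarray) -> np.ndarray:
    return ndi.convolve(skel.astype(np.uint8), _NEIGHBOR_KERNEL, mode="constant")


def prune_spurs(skel: np.ndarray, max_length_px: int) -> np.ndarray:
    """Remove short skeleton branches ending in a free endpoint.

    Endpoint pixels (<=1 neighbour, 8-connectivity) are peeled off
    ``max_length_px`` times, which deletes spurs shorter than that length
    and shortens longer dead-end branches by the same amount.
    """
    out = np.asarray(skel, dtype=bool).copy()
    for _ in range(int(max_length_px)):
        if not out.any():
            break
        endpoints = out & (_neighbor_counts(out) <= 1)
        if not endpoints.any():
            break
        out &= ~endpoints
    return out


def drop_disconnected_components(skel: np.ndarray) -> np.ndarray:
    """Keep only the largest 8-connected component of the skeleton."""
    lbl, n = ndi.label(skel, structure=np.ones((3, 3), dtype=int))
    if n <= 1:
        return np.asarray(skel, dtype=bool)
    sizes = np.bincount(lbl.ravel())
    sizes[0] = 0
    return lbl == int(np.argmax(sizes))


def nuclei_link_mask(
    image: IntensityImage,
    params: SegmentationParams,
    low_threshold: float | None = None,
) -> np.ndarray:
    """Step 4: capture weak furrow-canal links that separate nuclei.

    Fine smoothing, a low threshold (so that weak residual links of failed
    furrows are kept), morphological closing to join broken links,
    thinning, then pruning: spurs shorter than ``min_link_length_px`` and
    components disconnected from the main network are removed (each
    independently switchable).
    """
    fine = smooth_fine(image, params)
    thr = resolve_low_threshold(fine, params) if low_threshold is None else low_threshold
    logger.info("nuclei link mask: low threshold = %.4g", thr)
    mask = fine.pixels >= thr
    if not mask.any():
        return mask
    mask = closing(mask, disk(params.close_radius_px))
    skel = thin(mask)
    if params.prune_spurs:
        skel = prune_spurs(skel, params.min_link_length_px)
    if params.drop_disconnected_links and skel.any():
        skel = drop_disconnected_components(skel)
    return skel


# --------------------------------------------------------------------------
# steps 5-6: compartments
# --------------------------------------------------------------------------


def compartment_mask(
    prelim_network: np.ndarray,
    link_mask: np.ndarray,
    params: SegmentationParams,
) -> np.ndarray:
    """Step 5: invert the dilated full network into candidate compartments.

    The thinned step-2 mask is united with the step-4 mask, dilated by
    ``dilate_radius_px``, and inverted; holes inside the resulting
    foreground (noise specks enclosed within compartments) are filled.
    """
    prelim_network = np.asarray(prelim_network, dtype=bool)
    link_mask = np.asarray(link_mask, dtype=bool)
    if prelim_network.shape != link_mask.shape:
        raise ValueError(
            f"mask shapes differ: {prelim_network.shape} vs {link_mask.shape}"
        )
    network = thin(prelim_network) | link_mask if prelim_network.any() else link_mask
    network = dilation(network, disk(params.dilate_radius_px))
    compartments = ~network
    # fill speck holes: dilated noise dots enclosed inside compartments are
    # background components distinct from the main network (which must not
    # itself be filled even when it lies fully inside the image)
    bg_lbl, n = ndi.label(network, structure=np.ones((3, 3), dtype=int))
    if n > 1:
        sizes = np.bincount(bg_lbl.ravel())
        sizes[0] = 0
        keep = {int(np.argmax(sizes))}
        keep |= {
            int(v)
            for v in np.unique(
                np.concatenate(
                    [bg_lbl[0, :], bg_lbl[-1, :], bg_lbl[:, 0], bg_lbl[:, -1]]
                )
            )
            if v != 0
        }
        specks = network & ~np.isin(bg_lbl, sorted(keep))
        compartments = compartments | specks
    return compartments


def remove_boundary_artifacts(
    compartments: np.ndarray,
    smoothed: IntensityImage,
    params: SegmentationParams,
    high_threshold: float | None = None,
) -> np.ndarray:
    """Step 6: clean thinning artifacts and drop border-touching regions.

    A high threshold on the coarse-smoothed image marks saturated ridge
    cores; its complement is intersected with the compartment mask.
    Compartments touching the image border are additionally discarded
    because partially imaged cells cannot be scored.
    """
    compartments = np.asarray(compartments, dtype=bool)
    thr = (
        resolve_high_threshold(smoothed, params)
        if high_threshold is None
        else high_threshold
    )
    logger.info("boundary artifact removal: high threshold = %.4g", thr)
    out = compartments & ~(smoothed.pixels >= thr)
    return _clear_border_regions(out)


def _clear_border_regions(mask: np.ndarray) -> np.ndarray:
    lbl, _ = ndi.label(mask)  # 4-connectivity
    border = np.unique(
        np.concatenate([lbl[0, :], lbl[-1, :], lbl[:, 0], lbl[:, -1]])
    )
    border = border[border != 0]
    if border.size == 0:
        return mask
    return mask & ~np.isin(lbl, border)


def _consecutive_labels(mask: np.ndarray, kind: str) -> CompartmentLabels:
    lbl = sk_label(mask, connectivity=1)
    return CompartmentLabels(lbl.astype(np.int32), kind=kind)


# --------------------------------------------------------------------------
# full pipeline
# --------------------------------------------------------------------------


def _majority_overlap(
    compartments: np.ndarray, cells: np.ndarray
) -> tuple[dict[int, int], list[int]]:
    """Assign each compartment label to the cell label covering most of it."""
    comp = compartments.ravel()
    cell = cells.ravel()
    sel = comp > 0
    if not sel.any():
        return {}, []
    pairs = comp[sel].astype(np.int64) * (cell.max() + 1) + cell[sel]
    uniq, counts = np.unique(pairs, return_counts=True)
    comp_ids = uniq // (cell.max() + 1)
    cell_ids = uniq % (cell.max() + 1)
    assignment: dict[int, int] = {}
    best: dict[int, int] = {}
    for cid, lid, cnt in zip(comp_ids, cell_ids, counts):
        if cnt > best.get(int(cid), 0):
            best[int(cid)] = int(cnt)
            assignment[int(cid)] = int(lid)
    unassigned = sorted(c for c, a in assignment.items() if a == 0)
    assignment = {c: a for c, a in assignment.items() if a != 0}
    return assignment, unassigned


def segment(image: IntensityImage, params: SegmentationParams | None = None) -> SegmentationResult:
    """Run the full six-step procedure on one furrow-marker image.

    Returns the strong furrow-canal skeleton, cell labels (regions
    enclosed by the strong network), nucleus-compartment labels (regions
    enclosed by the full network including weak links), the
    compartment-to-cell assignment, and per-cell nucleus counts.  The
    final cell label image is rebuilt as the union of each cell's member
    compartments, so every compartment is contained in exactly one cell.

    Raises
    ------
    NoNetworkError
        If no plausible furrow-canal network is present (e.g. a blank or
        noise-only image).
    """
    params = params or SegmentationParams()
    smoothed = smooth_coarse(image, params)
    mid = resolve_mid_threshold(smoothed, params)
    m2 = preliminary_network_mask(smoothed, params, threshold=mid)
    if not m2.any():
        raise NoNetworkError("no network found: preliminary mask is empty")
    if m2.mean() > MAX_NETWORK_FRACTION:
        raise NoNetworkError(
            f"no network found: thresholded foreground covers "
            f"{100 * m2.mean():.0f}% of the image (noise-like)"
        )
    skeleton = skeletonize_network(m2)

    fine = smooth_fine(image, params)
    low = resolve_low_threshold(fine, params, mid=mid)
    m4 = nuclei_link_mask(image, params, low_threshold=low)

    high = resolve_high_threshold(smoothed, params, mid=mid)
    comp_mask = compartment_mask(m2, m4, params)
    comp_mask = remove_boundary_artifacts(comp_mask, smoothed, params, high_threshold=high)
    # cell regions keep their border-touching members here: a cell is
    # dropped as a whole when its strong-network region touches the image
    # border, otherwise a partially imaged multinucleate cell would
    # masquerade as mononucleate after its border compartment is cleared
    m2_strong = m2
    if params.refine_strong_with_fine:
        strong_mid = resolve_mid_threshold(fine, params)
        if params.threshold_strategy == "otsu":
            strong_mid *= params.strong_otsu_factor
        m2_strong = m2 & (fine.pixels >= strong_mid)
        if not m2_strong.any():
            m2_strong = m2
    cell_mask = compartment_mask(m2_strong, np.zeros_like(m4), params)
    cell_mask &= ~(smoothed.pixels >= high)

    compartments = _consecutive_labels(comp_mask, "nucleus_compartment")
    if compartments.n_labels == 0:
        raise NoNetworkError("no network found: no enclosed compartments detected")
    cell_regions = sk_label(cell_mask, connectivity=1)
    border_regions = set(
        int(v)
        for v in np.unique(
            np.concatenate(
                [cell_regions[0, :], cell_regions[-1, :],
                 cell_regions[:, 0], cell_regions[:, -1]]
            )
        )
        if v != 0
    )

    assignment, _ = _majority_overlap(compartments.labels, cell_regions)
    unassigned = sorted(
        set(range(1, compartments.n_labels + 1)) - set(assignment)
    )
    if unassigned:
        logger.warning(
            "%d compartment(s) overlap no cell region and were left unassigned: %s",
            len(unassigned), unassigned,
        )
    border_excluded = sorted(
        c for c, region in assignment.items() if region in border_regions
    )
    assignment = {c: r for c, r in assignment.items() if r not in border_regions}

    # renumber cells consecutively and rebuild the cell image as the union
    # of member compartments (containment exact by construction)
    region_to_cell: dict[int, int] = {}
    cell_of_compartment: dict[int, int] = {}
    for comp_id in sorted(assignment):
        region = assignment[comp_id]
        if region not in region_to_cell:
            region_to_cell[region] = len(region_to_cell) + 1
        cell_of_compartment[comp_id] = region_to_cell[region]

    # compartments of border-truncated cells are dropped alongside their cell
    keep = np.zeros(compartments.n_labels + 1, dtype=bool)
    keep[sorted(cell_of_compartment)] = True
    comp_relabel = np.cumsum(keep).astype(np.int32) * keep
    comp_labels = comp_relabel[compartments.labels]
    cell_of_compartment = {
        int(comp_relabel[c]): cell for c, cell in cell_of_compartment.items()
    }
    compartments = CompartmentLabels(comp_labels, kind="nucleus_compartment")

    lut = np.zeros(compartments.n_labels + 1, dtype=np.int32)
    for comp_id, cell_id in cell_of_compartment.items():
        lut[comp_id] = cell_id
    cell_labels = lut[compartments.labels]
    cells = CompartmentLabels(cell_labels, kind="cell")

    nuclei_per_cell: dict[int, int] = {}
    for cell_id in cell_of_compartment.values():
        nuclei_per_cell[cell_id] = nuclei_per_cell.get(cell_id, 0) + 1

    provenance = {
        "params": asdict(params),
        "thresholds": {"low": low, "mid": mid, "high": high},
        "n_cells": len(region_to_cell),
        "n_compartments": compartments.n_labels,
        "unassigned_compartments": unassigned,
        "n_border_excluded_compartments": len(border_excluded),
    }
    return SegmentationResult(
        network=skeleton,
        cells=cells,
        compartments=compartments,
        cell_of_compartment=cell_of_compartment,
        nuclei_per_cell=nuclei_per_cell,
        unassigned_compartments=unassigned,
        provenance=provenance,
    )


# --------------------------------------------------------------------------
# optional nucleus-channel mode
# --------------------------------------------------------------------------


def detect_nuclei_centroids(
    nucleus_image: IntensityImage, min_area_px: int = 9
) -> np.ndarray:
    """Detect nucleus blobs in a nuclear-marker channel; return centroids.

    Simple Otsu thresholding plus connected-component centroids; intended
    for well-separated cortical nuclei in a surface view.
    """
    thr = _otsu(nucleus_image.pixels, "the nucleus channel")
    mask = nucleus_image.pixels >= thr
    lbl, n = ndi.label(mask)
    if n == 0:
        return np.empty((0, 2))
    sizes = ndi.sum_labels(np.ones_like(lbl), lbl, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= min_area_px) + 1
    centroids = ndi.center_of_mass(mask, lbl, index=keep)
    return np.asarray(centroids, dtype=float).reshape(-1, 2)


def assign_nuclei_to_cells(
    centroids: np.ndarray, cells: CompartmentLabels
) -> dict[int, int]:
    """Count detected nuclei per cell by centroid containment."""
    counts: dict[int, int] = {}
    h, w = cells.labels.shape
    for r, c in np.asarray(centroids).reshape(-1, 2):
        ri, ci = int(round(r)), int(round(c))
        if 0 <= ri < h and 0 <= ci < w:
            cell = int(cells.labels[ri, ci])
            if cell > 0:
                counts[cell] = counts.get(cell, 0) + 1
    return counts
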