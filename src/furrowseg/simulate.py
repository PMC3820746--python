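"""Synthetic surface-view embryo images with planted ground truth.

During cellularization, plasma-membrane furrows ingress between the
cortical nuclei of the syncytial fly embryo, so that in a surface view the
F-actin/Myosin-rich furrow canals form a bright, near-hexagonal network
outlining one nascent cell per nucleus.  When a furrow fails or regresses,
the corresponding network edge drops to a weak residual intensity and the
two flanking compartments merge into one multinucleate cell.

This module builds that geometry explicitly — a jittered-hexagonal Voronoi
tessellation with one nucleus per tile — plants furrow failures on a known
set of edges, and renders the result into a noisy intensity image.  The
planted truth (which nuclei share a cell, which edges failed, the exact
mononucleate-cells-to-nuclei ratio) is emitted alongside, so segmentation
and quantification can be scored against it.

A companion renderer produces 3-D RNA-FISH stacks in which each nucleus
carries 0, 1 or 2 diffraction-limited transcription spots according to a
planted genotype (null / heterozygous / wild-type), each spot independently
visible with a detection probability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import Voronoi
from shapely.geometry import LineString, box
from skimage.draw import line as draw_line
from skimage.morphology import dilation, disk

from .core import DEFAULT_PIXEL_SIZE_UM, FishStack, LatticeSizingError

# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

#: minimal acceptable mean cell diameter, px; below this the ridge raster
#: would merge neighbouring edges and the geometry is meaningless
MIN_CELL_DIAMETER_PX = 10.0

VALID_GENOTYPES = ("null", "het", "wt")
_SPOTS_PER_GENOTYPE = {"null": 0, "het": 1, "wt": 2}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated surface-view acquisition.

    ``failure_fraction`` is the per-edge probability that an interior
    furrow fails; failed edges are rendered at ``weak_link_contrast``
    times the intact ridge amplitude (residual weak links).  Default
    noise gives a ridge signal-to-noise ratio of ~10.
    """

    image_size_px: tuple[int, int] = (512, 512)  # (rows, cols)
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    n_nuclei: int = 100
    failure_fraction: float = 0.0
    weak_link_contrast: float = 0.3
    ridge_width_px: int = 3
    ridge_amplitude: float = 100.0
    blur_sigma_px: float = 1.0
    noise_sd: float = 10.0
    shot_noise: bool = False
    jitter_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.failure_fraction <= 1.0):
            raise ValueError("failure_fraction must lie in [0, 1]")
        if not (0.0 <= self.weak_link_contrast < 1.0):
            raise ValueError("weak_link_contrast must lie in [0, 1)")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.n_nuclei < 1 or self.ridge_width_px < 1:
            raise ValueError("n_nuclei and ridge_width_px must be positive")
        if self.blur_sigma_px < 0 or self.noise_sd < 0:
            raise ValueError("blur_sigma_px and noise_sd must be non-negative")
        if not (0.0 <= self.jitter_fraction <= 0.25):
            raise ValueError("jitter_fraction must lie in [0, 0.25]")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


# --------------------------------------------------------------------------
# lattice
# --------------------------------------------------------------------------


@dataclass
class LatticeEdge:
    """A furrow-canal segment between two Voronoi tiles.

    ``tile_b`` is -1 when the neighbouring site is a padding ("ghost")
    point outside the image; such rim edges close the network around
    boundary tiles but are never failable.
    """

    tile_a: int
    tile_b: int
    p0: tuple[float, float]  # (row, col)
    p1: tuple[float, float]

    @property
    def interior(self) -> bool:
        return self.tile_b >= 0

    @property
    def length(self) -> float:
        return math.hypot(self.p1[0] - self.p0[0], self.p1[1] - self.p0[1])


@dataclass
class CellLattice:
    """Voronoi tessellation of jittered hexagonal seeds: one tile per nucleus."""

    shape: tuple[int, int]
    nucleus_centers: np.ndarray  # (n, 2) float, (row, col)
    edges: list[LatticeEdge]
    boundary_tile: np.ndarray  # (n,) bool — tile touches/exceeds the image border
    spacing_px: float
    failed: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.failed is None:
            self.failed = np.zeros(len(self.edges), dtype=bool)

    @property
    def n_tiles(self) -> int:
        return len(self.nucleus_centers)

    def failable_edge_ids(self) -> list[int]:
        """Edges eligible for planted failure.

        An edge can fail when it separates two real tiles and at least one
        of them is interior: failures then have homogeneous statistics
        across the scored (interior) region, while every planted failure
        still affects at least one scored nucleus.  Rim edges against the
        padding and edges between two boundary tiles never fail.
        """
        return [
            i
            for i, e in enumerate(self.edges)
            if e.interior
            and not (self.boundary_tile[e.tile_a] and self.boundary_tile[e.tile_b])
        ]


@dataclass
class GroundTruth:
    """Planted truth emitted by the simulator, consumed only by tests.

    ``cell_of_nucleus`` maps every nucleus (tile) id to its cell id after
    merging tiles across failed edges; ``true_ratio`` is the exact
    mononucleate-cells-to-nuclei ratio over interior tiles (boundary tiles
    are excluded, mirroring the boundary-artifact removal of the
    segmentation pipeline).
    """

    nucleus_centers: np.ndarray
    cell_of_nucleus: dict[int, int]
    failed_edges: frozenset[int]
    true_ratio: float
    boundary_tiles: frozenset[int]
    genotype: str | None = None

    def multinucleate_cells(self) -> dict[int, list[int]]:
        """cell id -> nucleus ids, restricted to cells with >=2 nuclei."""
        members: dict[int, list[int]] = {}
        for nuc, cell in self.cell_of_nucleus.items():
            members.setdefault(cell, []).append(nuc)
        return {c: ns for c, ns in members.items() if len(ns) >= 2}

    def to_dict(self) -> dict:
        return {
            "nucleus_centers": np.asarray(self.nucleus_centers).tolist(),
            "cell_of_nucleus": {str(k): int(v) for k, v in self.cell_of_nucleus.items()},
            "failed_edges": sorted(self.failed_edges),
            "true_ratio": self.true_ratio,
            "boundary_tiles": sorted(self.boundary_tiles),
            "genotype": self.genotype,
        }


def _hex_grid(shape: tuple[int, int], spacing: float, pad: float) -> np.ndarray:
    """Hexagonal lattice points covering the padded image rectangle."""
    h, w = shape
    dy = spacing * math.sqrt(3.0) / 2.0
    rows = np.arange(-pad, h + pad, dy)
    pts = []
    for i, r in enumerate(rows):
        offset = (spacing / 2.0) if (i % 2) else 0.0
        cols = np.arange(-pad + offset, w + pad, spacing)
        pts.extend((r, c) for c in cols)
    return np.asarray(pts, dtype=float)


def make_lattice(config: SimulationConfig) -> CellLattice:
    """Build the Voronoi-like tessellation of jittered hexagonal seeds.

    Exactly ``config.n_nuclei`` tiles are created, each containing its own
    nucleus centre (a Voronoi cell always contains its site).  Seeds are
    the ``n_nuclei`` jittered lattice points nearest the image centre; the
    remaining lattice points act as padding sites so that every tile is a
    finite polygon.  Edges are Voronoi ridges clipped to the image bounds.

    Raises
    ------
    LatticeSizingError
        If the image cannot host ``n_nuclei`` cells of >=10 px diameter.
    """
    if config.n_nuclei < 4:
        raise LatticeSizingError("need at least 4 nuclei for a meaningful tessellation")
    h, w = config.image_size_px
    # spacing such that n_nuclei hexagons of side-to-side distance `spacing`
    # tile the image area
    spacing = math.sqrt(2.0 * h * w / (math.sqrt(3.0) * config.n_nuclei))
    if spacing < MIN_CELL_DIAMETER_PX:
        raise LatticeSizingError(
            f"{config.n_nuclei} nuclei in a {h}x{w} px image gives mean cell "
            f"diameter {spacing:.1f} px < {MIN_CELL_DIAMETER_PX} px"
        )
    # the grid is laid slightly denser than the exact tiling so that, after
    # jitter, at least n_nuclei points still fall inside the image
    spacing *= 0.96
    rng = np.random.default_rng(config.seed)
    pts = _hex_grid((h, w), spacing, pad=2.5 * spacing)
    jitter = config.jitter_fraction * spacing
    pts = pts + rng.uniform(-jitter, jitter, size=pts.shape)

    inside = (
        (pts[:, 0] >= 0) & (pts[:, 0] < h) & (pts[:, 1] >= 0) & (pts[:, 1] < w)
    )
    inside_idx = np.flatnonzero(inside)
    if len(inside_idx) < config.n_nuclei:
        raise LatticeSizingError(
            f"only {len(inside_idx)} lattice points fit inside the image, "
            f"need {config.n_nuclei}"
        )
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    d2 = np.sum((pts[inside_idx] - center) ** 2, axis=1)
    order = inside_idx[np.argsort(d2, kind="stable")]
    seed_idx = np.sort(order[: config.n_nuclei])
    ghost_idx = np.setdiff1d(np.arange(len(pts)), seed_idx)

    seeds = pts[seed_idx]
    all_pts = np.vstack([seeds, pts[ghost_idx]])
    vor = Voronoi(all_pts)

    n = config.n_nuclei
    boundary = np.zeros(n, dtype=bool)
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region:
            boundary[i] = True
            continue
        verts = vor.vertices[region]
        if (
            (verts[:, 0] < 0).any()
            or (verts[:, 0] > h - 1).any()
            or (verts[:, 1] < 0).any()
            or (verts[:, 1] > w - 1).any()
        ):
            boundary[i] = True

    clip_box = box(0.0, 0.0, h - 1.0, w - 1.0)  # shapely x=row, y=col here
    edges: list[LatticeEdge] = []
    ridge_order = sorted(
        range(len(vor.ridge_points)),
        key=lambda k: (min(vor.ridge_points[k]), max(vor.ridge_points[k])),
    )
    for k in ridge_order:
        p, q = (int(v) for v in vor.ridge_points[k])
        v1, v2 = vor.ridge_vertices[k]
        if v1 == -1 or v2 == -1:
            continue  # unbounded ridge: only possible between ghost points
        if p >= n and q >= n:
            continue  # ghost-ghost ridge, outside the tissue
        a, b = sorted((p, q))
        seg = LineString([tuple(vor.vertices[v1]), tuple(vor.vertices[v2])])
        clipped = seg.intersection(clip_box)
        if clipped.is_empty or clipped.length < 1.0:
            continue
        coords = list(clipped.coords)
        edges.append(
            LatticeEdge(
                tile_a=a,
                tile_b=b if b < n else -1,
                p0=(coords[0][0], coords[0][1]),
                p1=(coords[-1][0], coords[-1][1]),
            )
        )
        if edges[-1].tile_b == -1 and a < n:
            boundary[a] = True  # tile abuts the padding rim

    return CellLattice(
        shape=(h, w),
        nucleus_centers=seeds,
        edges=edges,
        boundary_tile=boundary,
        spacing_px=spacing,
    )


# --------------------------------------------------------------------------
# failure planting
# --------------------------------------------------------------------------


def plant_failures(
    lattice: CellLattice, failure_fraction: float, seed: int
) -> tuple[CellLattice, GroundTruth]:
    """Flag a random subset of interior edges as failed and derive the truth.

    Each edge between two interior tiles fails independently with
    probability ``failure_fraction``.  Nuclei are then merged into cells by
    taking connected components of the tile-adjacency graph restricted to
    failed edges, and the exact mononucleate-cells-to-nuclei ratio over
    interior tiles is recorded.
    """
    if not (0.0 <= failure_fraction <= 1.0):
        raise ValueError("failure_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    failed = np.zeros(len(lattice.edges), dtype=bool)
    for i in lattice.failable_edge_ids():
        if rng.random() < failure_fraction:
            failed[i] = True

    g = nx.Graph()
    interior = set(int(t) for t in np.flatnonzero(~lattice.boundary_tile))
    g.add_nodes_from(range(lattice.n_tiles))
    for i in np.flatnonzero(failed):
        e = lattice.edges[i]
        g.add_edge(e.tile_a, e.tile_b)

    # the ratio counts interior nuclei only: a mononucleate cell is a
    # singleton component, and it enters the numerator when its nucleus
    # is interior
    cell_of_nucleus: dict[int, int] = {}
    n_mono = 0
    for comp in nx.connected_components(g):
        cell_id = min(comp)
        for t in comp:
            cell_of_nucleus[int(t)] = int(cell_id)
        if len(comp) == 1 and next(iter(comp)) in interior:
            n_mono += 1

    n_interior = len(interior)
    true_ratio = n_mono / n_interior if n_interior else float("nan")
    out = replace(lattice, failed=failed)
    gt = GroundTruth(
        nucleus_centers=lattice.nucleus_centers,
        cell_of_nucleus=cell_of_nucleus,
        failed_edges=frozenset(int(i) for i in np.flatnonzero(failed)),
        true_ratio=true_ratio,
        boundary_tiles=frozenset(int(t) for t in np.flatnonzero(lattice.boundary_tile)),
    )
    return out, gt


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------


def rasterize_edges(
    lattice: CellLattice, edge_ids, shape: tuple[int, int] | None = None
) -> np.ndarray:
    """Boolean raster of the 1-px centerlines of the given edges."""
    shape = shape or lattice.shape
    mask = np.zeros(shape, dtype=bool)
    h, w = shape
    for i in edge_ids:
        e = lattice.edges[i]
        r0, c0 = (int(round(v)) for v in e.p0)
        r1, c1 = (int(round(v)) for v in e.p1)
        rr, cc = draw_line(
            np.clip(r0, 0, h - 1),
            np.clip(c0, 0, w - 1),
            np.clip(r1, 0, h - 1),
            np.clip(c1, 0, w - 1),
        )
        mask[rr, cc] = True
    return mask


def render_furrow_image(
    lattice: CellLattice, gt: GroundTruth, config: SimulationConfig
) -> np.ndarray:
    """Render the furrow-canal network into a noisy intensity image.

    Intact edges are drawn as ridges of ``ridge_width_px`` at full
    amplitude; failed edges at ``weak_link_contrast`` times that — the weak
    residual links that the low-threshold segmentation step is designed to
    capture.  The raster is blurred (``blur_sigma_px``), optionally passed
    through a Poisson shot-noise stage, corrupted with additive Gaussian
    read noise (``noise_sd``) and clipped at zero.
    """
    failed = set(gt.failed_edges)
    all_ids = range(len(lattice.edges))
    intact = rasterize_edges(lattice, [i for i in all_ids if i not in failed])
    weak = rasterize_edges(lattice, sorted(failed))
    radius = config.ridge_width_px // 2
    if radius > 0:
        selem = disk(radius)
        intact = dilation(intact, selem)
        weak = dilation(weak, selem)
    img = np.where(
        intact,
        config.ridge_amplitude,
        np.where(weak, config.ridge_amplitude * config.weak_link_contrast, 0.0),
    )
    if config.blur_sigma_px > 0:
        img = gaussian_filter(img, config.blur_sigma_px, mode="reflect")
    rng = np.random.default_rng(config.seed + 1)  # decoupled from lattice jitter
    if config.shot_noise:
        img = rng.poisson(np.clip(img, 0, None)).astype(float)
    if config.noise_sd > 0:
        img = img + rng.normal(0.0, config.noise_sd, size=img.shape)
    return np.clip(img, 0.0, None)


def render_nucleus_image(
    lattice: CellLattice,
    config: SimulationConfig,
    nucleus_sigma_px: float | None = None,
    amplitude: float = 100.0,
) -> np.ndarray:
    """Optional nucleus channel: one bright Gaussian blob per compartment."""
    sigma = nucleus_sigma_px or max(2.0, lattice.spacing_px / 6.0)
    img = np.zeros(lattice.shape, dtype=float)
    for r, c in lattice.nucleus_centers:
        _add_gaussian_blob(img, r, c, sigma, amplitude)
    rng = np.random.default_rng(config.seed + 2)
    if config.noise_sd > 0:
        img = img + rng.normal(0.0, config.noise_sd, size=img.shape)
    return np.clip(img, 0.0, None)


def simulate_embryo(
    config: SimulationConfig,
) -> tuple[np.ndarray, CellLattice, GroundTruth]:
    """Convenience composition: lattice -> failures -> rendered image."""
    lattice = make_lattice(config)
    lattice, gt = plant_failures(lattice, config.failure_fraction, config.seed)
    img = render_furrow_image(lattice, gt, config)
    return img, lattice, gt


# --------------------------------------------------------------------------
# FISH stacks
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class FishRenderParams:
    """Geometry and photometry of the simulated FISH acquisition.

    Transcription spots are diffraction-limited: ~300 nm across, i.e. a
    Gaussian of sigma ~1.2 px at 104 nm/px.  Nuclei sit on a jittered grid
    far enough apart that their blobs do not merge; two sister spots in a
    wild-type nucleus are kept >=3.6 px apart so a spot detector at the
    diffraction scale can resolve them.
    """

    nucleus_spacing_px: float = 11.0
    nucleus_sigma_px: float = 2.2
    nucleus_amplitude: float = 60.0
    spot_sigma_px: float = 1.2
    spot_amplitude: float = 120.0
    max_spot_offset_px: float = 2.5
    min_spot_separation_px: float = 3.6
    noise_sd: float = 2.0
    depth_um: float = 4.0
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM


@dataclass
class FishGroundTruth:
    """Planted truth of one FISH simulation."""

    genotype: str
    nucleus_centers: np.ndarray  # (n, 2)
    spot_positions: list[list[tuple[float, float]]]  # per nucleus, planted spots
    spot_visible: list[list[bool]]  # per nucleus, detection outcome
    spot_slice: list[list[int]]  # per nucleus, z-slice of each spot

    def visible_counts(self) -> np.ndarray:
        return np.array([sum(v) for v in self.spot_visible], dtype=int)


def _add_gaussian_blob(
    img: np.ndarray, r: float, c: float, sigma: float, amplitude: float
) -> None:
    """Add a small Gaussian patch in place (4-sigma support)."""
    h, w = img.shape
    rad = int(math.ceil(4.0 * sigma))
    r0, r1 = max(0, int(r) - rad), min(h, int(r) + rad + 1)
    c0, c1 = max(0, int(c) - rad), min(w, int(c) + rad + 1)
    if r0 >= r1 or c0 >= c1:
        return
    rr = np.arange(r0, r1)[:, None] - r
    cc = np.arange(c0, c1)[None, :] - c
    img[r0:r1, c0:c1] += amplitude * np.exp(-(rr**2 + cc**2) / (2.0 * sigma**2))


def render_fish_stack(
    genotype: str,
    n_nuclei: int = 150,
    n_slices: int = 4,
    p_detect: float = 1.0,
    seed: int = 0,
    params: FishRenderParams | None = None,
) -> tuple[FishStack, FishGroundTruth]:
    """Render a FISH z-stack for one embryo of the given genotype.

    Per nucleus, k spot candidates are planted (k = 0/1/2 for
    null/het/wt); each is independently visible with probability
    ``p_detect`` and placed at one random z slice.  Stack metadata is set
    so that ``params.depth_um`` (~4 um) spans ``n_slices``.
    """
    if genotype not in VALID_GENOTYPES:
        raise ValueError(f"unknown genotype {genotype!r}; expected one of {VALID_GENOTYPES}")
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    p = params or FishRenderParams()
    k = _SPOTS_PER_GENOTYPE[genotype]
    rng = np.random.default_rng(seed)

    ncols = int(math.ceil(math.sqrt(n_nuclei)))
    nrows = int(math.ceil(n_nuclei / ncols))
    s = p.nucleus_spacing_px
    h = int(round((nrows + 1) * s))
    w = int(round((ncols + 1) * s))
    centers = []
    for i in range(n_nuclei):
        gr, gc = divmod(i, ncols)
        jr, jc = rng.uniform(-0.15 * s, 0.15 * s, size=2)
        centers.append(((gr + 1) * s + jr, (gc + 1) * s + jc))
    centers = np.asarray(centers)

    nucleus = np.zeros((h, w), dtype=float)
    for r, c in centers:
        _add_gaussian_blob(nucleus, r, c, p.nucleus_sigma_px, p.nucleus_amplitude)

    stack = np.zeros((n_slices, h, w), dtype=float)
    positions: list[list[tuple[float, float]]] = []
    visible: list[list[bool]] = []
    slices: list[list[int]] = []
    for r, c in centers:
        pos_i: list[tuple[float, float]] = []
        if k == 2:
            theta = rng.uniform(0.0, 2.0 * math.pi)
            d = rng.uniform(p.min_spot_separation_px, 2.0 * p.max_spot_offset_px)
            dr, dc = (d / 2.0) * math.cos(theta), (d / 2.0) * math.sin(theta)
            pos_i = [(r + dr, c + dc), (r - dr, c - dc)]
        elif k == 1:
            rho = p.max_spot_offset_px * math.sqrt(rng.uniform())
            theta = rng.uniform(0.0, 2.0 * math.pi)
            pos_i = [(r + rho * math.cos(theta), c + rho * math.sin(theta))]
        vis_i = [bool(rng.random() < p_detect) for _ in pos_i]
        sl_i = [int(rng.integers(n_slices)) for _ in pos_i]
        for (sr, sc), v, z in zip(pos_i, vis_i, sl_i):
            if v:
                _add_gaussian_blob(stack[z], sr, sc, p.spot_sigma_px, p.spot_amplitude)
        positions.append(pos_i)
        visible.append(vis_i)
        slices.append(sl_i)

    if p.noise_sd > 0:
        stack = stack + rng.normal(0.0, p.noise_sd, size=stack.shape)
        nucleus = nucleus + rng.normal(0.0, p.noise_sd, size=nucleus.shape)
    stack = np.clip(stack, 0.0, None)
    nucleus = np.clip(nucleus, 0.0, None)

    fish = FishStack(
        spot_channel=stack,
        nucleus_channel=nucleus,
        z_step_um=p.depth_um / n_slices,
        pixel_size_um=p.pixel_size_um,
    )
    gt = FishGroundTruth(
        genotype=genotype,
        nucleus_centers=centers,
        spot_positions=positions,
        spot_visible=visible,
        spot_slice=slices,
    )
    return fish, gt
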