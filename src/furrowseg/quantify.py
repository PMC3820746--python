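"""Fidelity metrics for cellularization and their group statistics.

The central readout is the mononucleate-cells-to-nuclei ratio: the number
of cells enclosing exactly one nucleus divided by the number of nuclei
assayed, estimated by quadrat sampling — two fixed-area windows (default
2835 um^2 each) placed on the surface view, with the per-embryo value the
mean over windows.  An intact embryo has ratio 1; furrow failures merge
compartments into multinucleate cells and push the ratio below 1.

Also provided: the percent of embryos displaying any multinucleation
(with the binomial standard error of the proportion), background-
subtracted furrow-canal intensity (an F-actin level readout), and the
group-comparison statistics used for per-embryo values — two-sample
Student's t tests and two-way ANOVA with the embryo as the unit of
analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats
from skimage.morphology import dilation, disk

from .core import CompartmentLabels, EmbryoSummary, IntensityImage, NetworkMask

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QuantConfig:
    """Sampling and sufficiency parameters for the fidelity metrics.

    Defaults follow the conventional assay: two 2835-um^2 quadrats per
    embryo for the ratio, >=150 nuclei per embryo for per-embryo scoring,
    >=1500 nuclei when scoring whole-embryo multinucleation frequency,
    and >=75 furrow canals for an intensity measurement.
    """

    quadrant_area_um2: float = 2835.0
    quadrants_per_embryo: int = 2
    min_nuclei_ratio: int = 150
    min_nuclei_freq: int = 1500
    min_furrow_canals_factin: int = 75
    #: quadrats are inset from the field edge by about one cell diameter,
    #: as partially imaged border cells cannot be scored anyway; shrunk
    #: automatically when the image is too small for the full inset
    window_margin_um: float = 10.0

    def __post_init__(self) -> None:
        if self.quadrant_area_um2 <= 0 or self.quadrants_per_embryo < 1:
            raise ValueError("quadrant area and count must be positive")
        if min(self.min_nuclei_ratio, self.min_nuclei_freq, self.min_furrow_canals_factin) < 1:
            raise ValueError("sufficiency minima must be positive")


# --------------------------------------------------------------------------
# nucleus counts per cell
# --------------------------------------------------------------------------


def count_nuclei_per_cell(
    cells: CompartmentLabels, compartments: CompartmentLabels
) -> tuple[dict[int, int], dict[int, int], list[int]]:
    """Count nucleus compartments per cell by majority-overlap assignment.

    Returns ``(counts, cell_of_compartment, unassigned)`` where ``counts``
    maps every cell label (including zero-count cells) to the number of
    compartments whose majority-overlap cell it is; compartments
    overlapping no cell are listed in ``unassigned`` and logged.
    """
    if cells.labels.shape != compartments.labels.shape:
        raise ValueError("cells and compartments must share a shape")
    comp = compartments.labels.ravel().astype(np.int64)
    cell = cells.labels.ravel().astype(np.int64)
    sel = comp > 0
    n_cell_vals = int(cell.max()) + 1
    cell_of_compartment: dict[int, int] = {}
    unassigned: list[int] = []
    if sel.any():
        pairs = comp[sel] * n_cell_vals + cell[sel]
        uniq, cnts = np.unique(pairs, return_counts=True)
        best: dict[int, int] = {}
        for u, n in zip(uniq, cnts):
            cid, lid = int(u // n_cell_vals), int(u % n_cell_vals)
            if n > best.get(cid, 0):
                best[cid] = int(n)
                cell_of_compartment[cid] = lid
    for cid in range(1, int(comp.max()) + 1):
        if cell_of_compartment.get(cid, 0) == 0:
            cell_of_compartment.pop(cid, None)
            unassigned.append(cid)
    if unassigned:
        logger.warning("%d compartment(s) overlap no cell: %s", len(unassigned), unassigned)

    counts = {c: 0 for c in range(1, int(cell.max()) + 1)}
    for lid in cell_of_compartment.values():
        counts[lid] = counts.get(lid, 0) + 1
    return counts, cell_of_compartment, unassigned


# --------------------------------------------------------------------------
# mononucleate-cells-to-nuclei ratio by quadrat sampling
# --------------------------------------------------------------------------


def default_windows(
    shape: tuple[int, int],
    pixel_size_um: float,
    config: QuantConfig,
    rng: np.random.Generator | None = None,
) -> list[tuple[int, int, int, int]]:
    """Place ``quadrants_per_embryo`` square sampling windows in the image.

    Each window has area ``quadrant_area_um2``.  Default placement is
    deterministic: window centres are spread evenly along the longer image
    axis at mid-height of the shorter axis.  Pass ``rng`` for seedable
    random non-overlapping placement instead.

    Returns windows as ``(r0, c0, r1, c1)`` half-open pixel bounds.
    """
    h, w = shape
    side = int(round(math.sqrt(config.quadrant_area_um2) / pixel_size_um))
    if side > min(h, w):
        raise ValueError(
            f"a {side}x{side} px quadrat (={config.quadrant_area_um2} um^2 at "
            f"{pixel_size_um} um/px) does not fit in a {h}x{w} image"
        )
    k = config.quadrants_per_embryo
    margin = int(round(config.window_margin_um / pixel_size_um))
    # shrink the inset when the image cannot afford it
    m_r = max(0, min(margin, (h - side) // 2))
    m_c = max(0, min(margin, (w - k * side) // 2 if w >= h else (w - side) // 2))
    windows: list[tuple[int, int, int, int]] = []
    if rng is not None:
        taken: list[tuple[int, int]] = []
        for _ in range(1000):
            if len(windows) == k:
                break
            r0 = int(rng.integers(m_r, h - side - m_r + 1))
            c0 = int(rng.integers(m_c, w - side - m_c + 1))
            if all(abs(r0 - tr) >= side or abs(c0 - tc) >= side for tr, tc in taken):
                taken.append((r0, c0))
                windows.append((r0, c0, r0 + side, c0 + side))
        if len(windows) < k:
            raise ValueError("could not place non-overlapping random quadrats")
        return windows
    # deterministic: windows spread evenly along the longer axis within the
    # inset field, centred on the shorter axis
    long_axis = 1 if w >= h else 0
    L = w if long_axis == 1 else h
    S = h if long_axis == 1 else w
    m_long = m_c if long_axis == 1 else m_r
    m_short = m_r if long_axis == 1 else m_c
    span = L - 2 * m_long - side
    if span < 0:
        m_long, span = 0, L - side
    for i in range(k):
        start_long = m_long + ((i * span) // max(k - 1, 1) if k > 1 else span // 2)
        start_short = max((S - side) // 2, m_short if S - 2 * m_short >= side else 0)
        start_short = min(start_short, S - side)
        if long_axis == 1:
            windows.append((start_short, start_long, start_short + side, start_long + side))
        else:
            windows.append((start_long, start_short, start_long + side, start_short + side))
    for (a, b) in zip(windows, windows[1:]):
        if not (a[3] <= b[1] or a[2] <= b[0]):
            raise ValueError(
                f"image too small for {k} non-overlapping {side}x{side} px quadrats"
            )
    return windows


def _labels_fully_inside(
    labels: np.ndarray, window: tuple[int, int, int, int]
) -> set[int]:
    """Labels whose every pixel lies inside the half-open window."""
    r0, c0, r1, c1 = window
    inside = set(np.unique(labels[r0:r1, c0:c1])) - {0}
    if not inside:
        return inside
    outside_mask = np.ones(labels.shape, dtype=bool)
    outside_mask[r0:r1, c0:c1] = False
    outside = set(np.unique(labels[outside_mask]))
    return inside - outside


def mono_ratio(
    cells: CompartmentLabels,
    compartments: CompartmentLabels,
    nuclei_per_cell: dict[int, int],
    cell_of_compartment: dict[int, int],
    pixel_size_um: float,
    config: QuantConfig | None = None,
    windows: list[tuple[int, int, int, int]] | None = None,
    embryo_id: str = "embryo",
) -> EmbryoSummary:
    """Mononucleate-cells-to-nuclei ratio by quadrat sampling.

    Per window: ratio = (# cells fully inside the window with exactly one
    nucleus compartment) / (# nucleus compartments fully inside the
    window); cells and compartments crossing the window edge are excluded
    to avoid double counting.  The embryo ratio is the mean over windows;
    windows containing no nuclei are skipped with a warning, and an
    insufficiency flag is raised when fewer than ``min_nuclei_ratio``
    nuclei were assayed in total.
    """
    config = config or QuantConfig()
    if windows is None:
        windows = default_windows(cells.labels.shape, pixel_size_um, config)
    ratios: list[float] = []
    n_nuclei_assayed = 0
    n_mono = 0
    flags: list[str] = []
    any_multi = any(v >= 2 for v in nuclei_per_cell.values())
    for win in windows:
        comps_in = _labels_fully_inside(compartments.labels, win)
        if not comps_in:
            logger.warning("quadrat %s contains no nuclei; skipped", win)
            flags.append(f"empty_window:{win}")
            continue
        cells_in = _labels_fully_inside(cells.labels, win)
        mono_in = {c for c in cells_in if nuclei_per_cell.get(c, 0) == 1}
        ratios.append(len(mono_in) / len(comps_in))
        n_nuclei_assayed += len(comps_in)
        n_mono += len(mono_in)
    if not ratios:
        raise ValueError("all sampling quadrats were empty of nuclei")
    if n_nuclei_assayed < config.min_nuclei_ratio:
        flags.append(f"n_nuclei_assayed<{config.min_nuclei_ratio}")
        logger.warning(
            "only %d nuclei assayed (recommended >=%d)",
            n_nuclei_assayed, config.min_nuclei_ratio,
        )
    return EmbryoSummary(
        embryo_id=embryo_id,
        n_nuclei_assayed=n_nuclei_assayed,
        n_mononucleate_cells=n_mono,
        ratio=float(np.mean(ratios)),
        is_multinucleate=bool(any_multi),
        flags=flags,
    )


# --------------------------------------------------------------------------
# multinucleation frequency
# --------------------------------------------------------------------------


def multinucleation_frequency(
    summaries: list[EmbryoSummary], config: QuantConfig | None = None
) -> dict:
    """Percent of embryos displaying multinucleation, with binomial s.e.m.

    Embryos with fewer than ``min_nuclei_freq`` nuclei assayed are still
    counted but flagged in the output.
    """
    config = config or QuantConfig()
    if not summaries:
        raise ValueError("no embryo summaries given")
    n = len(summaries)
    k = sum(1 for s in summaries if s.is_multinucleate)
    p = k / n
    sem = 100.0 * math.sqrt(p * (1.0 - p) / n)
    underpowered = [
        s.embryo_id for s in summaries if s.n_nuclei_assayed < config.min_nuclei_freq
    ]
    return {
        "percent_multinucleate": 100.0 * p,
        "sem_percent": sem,
        "n_embryos": n,
        "n_multinucleate": k,
        "underpowered_embryos": underpowered,
    }


# --------------------------------------------------------------------------
# furrow-canal intensity (F-actin readout)
# --------------------------------------------------------------------------


def _canal_segments(network: NetworkMask) -> np.ndarray:
    """Label individual canal segments: skeleton arcs between junctions."""
    skel = network.mask
    neighbors = ndi.convolve(
        skel.astype(np.uint8), np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]]), mode="constant"
    )
    junctions = skel & (neighbors >= 3)
    arcs = skel & ~junctions
    lbl, _ = ndi.label(arcs, structure=np.ones((3, 3), dtype=int))
    return lbl


def factin_intensity(
    image: IntensityImage,
    network: NetworkMask,
    config: QuantConfig | None = None,
    canal_width_px: int = 3,
    compartments: CompartmentLabels | None = None,
) -> dict:
    """Background-subtracted mean intensity of furrow canals.

    The skeleton is split into canal segments (arcs between junctions) and
    dilated to ``canal_width_px``; per-canal intensity is the mean over the
    dilated segment minus the background (median of pixels belonging to
    neither the dilated network nor, when given, any compartment).  The
    embryo value is the mean over canals, with the standard deviation; an
    ``insufficient`` flag marks embryos with fewer than
    ``min_furrow_canals_factin`` canals.
    """
    config = config or QuantConfig()
    if image.pixels.shape != network.mask.shape:
        raise ValueError("image and network must share a shape")
    arcs = _canal_segments(network)
    radius = max(canal_width_px // 2, 1)
    selem = disk(radius)
    canal_mask = dilation(network.mask, selem)
    background_mask = ~canal_mask
    if compartments is not None:
        background_mask &= compartments.labels == 0
    if not background_mask.any():
        background_mask = ~canal_mask
    background = float(np.median(image.pixels[background_mask]))

    # per-arc means over the dilated arc: spread labels by nearest arc pixel
    n_arcs = int(arcs.max())
    per_canal: list[float] = []
    if n_arcs:
        _, (ir, ic) = ndi.distance_transform_edt(arcs == 0, return_indices=True)
        spread = arcs[ir, ic]
        spread = np.where(canal_mask, spread, 0)
        means = ndi.mean(image.pixels, labels=spread, index=np.arange(1, n_arcs + 1))
        per_canal = [float(m) - background for m in np.atleast_1d(means)]
    insufficient = len(per_canal) < config.min_furrow_canals_factin
    if insufficient:
        logger.warning(
            "%d canals measured (recommended >=%d)",
            len(per_canal), config.min_furrow_canals_factin,
        )
    return {
        "per_canal": per_canal,
        "mean": float(np.mean(per_canal)) if per_canal else float("nan"),
        "sd": float(np.std(per_canal, ddof=1)) if len(per_canal) > 1 else float("nan"),
        "background": background,
        "n_canals": len(per_canal),
        "insufficient": insufficient,
    }


# --------------------------------------------------------------------------
# group statistics (embryo = unit of analysis)
# --------------------------------------------------------------------------


def students_t(
    group_a, group_b, equal_var: bool = True
) -> dict:
    """Two-sided two-sample t test on per-embryo values.

    Pooled-variance Student's t by default; set ``equal_var=False`` for
    Welch's variant.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 embryos per group")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    df = len(a) + len(b) - 2 if equal_var else None
    return {"t": float(t), "p": float(p), "df": df, "equal_var": equal_var}


def two_way_anova(
    table: pd.DataFrame,
    value: str,
    factor_a: str,
    factor_b: str,
) -> pd.DataFrame:
    """Two-way ANOVA with interaction on a per-embryo table.

    ``table`` must contain one row per embryo with columns ``value``,
    ``factor_a`` and ``factor_b`` (e.g. genotype and temperature), and the
    design must be fully crossed with every cell occupied.  Returns the
    ANOVA table (F and P for both main effects and the interaction).
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    for col in (value, factor_a, factor_b):
        if col not in table.columns:
            raise ValueError(f"missing column {col!r}")
    cells = table.groupby([factor_a, factor_b], observed=True).size()
    n_a = table[factor_a].nunique()
    n_b = table[factor_b].nunique()
    if len(cells) < n_a * n_b or (cells < 2).any():
        raise ValueError("two-way design must be fully crossed with >=2 embryos per cell")
    model = ols(
        f"Q('{value}') ~ C(Q('{factor_a}')) * C(Q('{factor_b}'))", data=table
    ).fit()
    return sm.stats.anova_lm(model, typ=2)


def compare_groups(
    table: pd.DataFrame,
    value: str,
    design: str,
    equal_var: bool = True,
) -> dict:
    """Dispatch the figure-legend statistics on a per-embryo table.

    ``design`` is either a single factor name (pairwise Student's t tests
    between all levels) or ``"a*b"`` for a two-way ANOVA of factors a and
    b with interaction.  No multiple-testing correction is applied; this
    is recorded in the output metadata.
    """
    out: dict = {"design": design, "correction": "none"}
    if "*" in design:
        fa, fb = (s.strip() for s in design.split("*", 1))
        anova = two_way_anova(table, value, fa, fb)
        out["anova"] = anova
        out["p_values"] = {str(idx): float(row["PR(>F)"])
                          for idx, row in anova.iterrows()
                          if np.isfinite(row["PR(>F)"])}
        return out
    factor = design.strip()
    if factor not in table.columns:
        raise ValueError(f"missing column {factor!r}")
    levels = sorted(table[factor].unique())
    tests = {}
    for i, la in enumerate(levels):
        for lb in levels[i + 1:]:
            ga = table.loc[table[factor] == la, value]
            gb = table.loc[table[factor] == lb, value]
            tests[f"{la} vs {lb}"] = students_t(ga, gb, equal_var=equal_var)
    out["t_tests"] = tests
    return out


def summaries_to_frame(summaries: list[EmbryoSummary]) -> pd.DataFrame:
    """One row per embryo, ready for CSV export and group statistics."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "embryo_id": s.embryo_id,
                "n_nuclei_assayed": s.n_nuclei_assayed,
                "n_mononucleate_cells": s.n_mononucleate_cells,
                "ratio": s.ratio,
                "is_multinucleate": s.is_multinucleate,
                "factin_mean": s.factin_mean,
                "genotype": s.genotype,
                "temperature": s.temperature,
                "flags": ";".join(s.flags),
            }
        )
    return pd.DataFrame(rows)
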