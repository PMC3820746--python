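"""End-to-end compositions: simulate -> segment -> quantify / genotype.

These are the entry points for validation experiments on synthetic
embryos: measuring a simulated embryo exactly as a real one would be
measured, scoring the segmentation's cell-to-nucleus assignment against
the planted truth, sweeping the furrow failure rate to check ratio
recovery, and running replicate Mendelian-cross genotyping cohorts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import EmbryoSummary, IntensityImage
from .fish import SpotDetectionParams, GenotypeCall, genotype_distribution, genotype_embryo
from .quantify import QuantConfig, mono_ratio
from .segmentation import SegmentationParams, SegmentationResult, segment
from .simulate import (
    CellLattice,
    FishRenderParams,
    GroundTruth,
    SimulationConfig,
    render_fish_stack,
    simulate_embryo,
)

logger = logging.getLogger(__name__)

MENDELIAN_P = {"null": 0.25, "het": 0.50, "wt": 0.25}


@dataclass
class EmbryoMeasurement:
    """Everything produced for one simulated embryo."""

    image: np.ndarray
    lattice: CellLattice
    ground_truth: GroundTruth
    segmentation: SegmentationResult
    summary: EmbryoSummary


def measure_simulated_embryo(
    config: SimulationConfig,
    seg_params: SegmentationParams | None = None,
    quant_config: QuantConfig | None = None,
    embryo_id: str = "embryo",
) -> EmbryoMeasurement:
    """Simulate one embryo and measure it like a real acquisition."""
    img, lattice, gt = simulate_embryo(config)
    image = IntensityImage(img, config.pixel_size_um)
    seg = segment(image, seg_params)
    summary = mono_ratio(
        seg.cells,
        seg.compartments,
        seg.nuclei_per_cell,
        seg.cell_of_compartment,
        config.pixel_size_um,
        config=quant_config,
        embryo_id=embryo_id,
    )
    return EmbryoMeasurement(img, lattice, gt, seg, summary)


# --------------------------------------------------------------------------
# segmentation scoring against ground truth
# --------------------------------------------------------------------------


def assignment_accuracy(
    seg: SegmentationResult, lattice: CellLattice, gt: GroundTruth
) -> float:
    """Fraction of interior nuclei whose cell grouping matches the truth.

    Each interior nucleus is located in the compartment containing its
    planted centre; nuclei are grouped by the cell their compartment was
    assigned to, and a nucleus counts as correct when its predicted
    co-cell nucleus set equals the planted one.  A scored nucleus whose
    centre falls in no surviving compartment counts as incorrect.  Nuclei
    whose *true* cell includes a boundary tile are excluded from scoring:
    such cells extend beyond the imaged field and the pipeline rightly
    refuses to score them.
    """
    interior = [t for t in range(lattice.n_tiles) if t not in gt.boundary_tiles]
    # drop nuclei merged (by a planted failure) with an out-of-frame tile
    members: dict[int, set[int]] = {}
    for t, cell in gt.cell_of_nucleus.items():
        members.setdefault(cell, set()).add(t)
    interior = [
        t
        for t in interior
        if not (members[gt.cell_of_nucleus[t]] & gt.boundary_tiles)
    ]
    if not interior:
        return float("nan")
    h, w = seg.compartments.labels.shape
    comp_of_nucleus: dict[int, int] = {}
    for t in interior:
        r, c = gt.nucleus_centers[t]
        ri, ci = int(round(r)), int(round(c))
        if 0 <= ri < h and 0 <= ci < w:
            comp = int(seg.compartments.labels[ri, ci])
            if comp > 0:
                comp_of_nucleus[t] = comp

    pred_cell: dict[int, int] = {}
    for t, comp in comp_of_nucleus.items():
        cell = seg.cell_of_compartment.get(comp)
        if cell is not None:
            pred_cell[t] = cell

    pred_groups: dict[int, set[int]] = {}
    true_groups: dict[int, set[int]] = {}
    for t in interior:
        true_groups.setdefault(gt.cell_of_nucleus[t], set()).add(t)
        if t in pred_cell:
            pred_groups.setdefault(pred_cell[t], set()).add(t)

    n_correct = 0
    for t in interior:
        if t not in pred_cell:
            continue
        if pred_groups[pred_cell[t]] == true_groups[gt.cell_of_nucleus[t]]:
            n_correct += 1
    return n_correct / len(interior)


def segmentation_accuracy_sweep(
    failure_fraction: float,
    n_seeds: int = 20,
    base_config: SimulationConfig | None = None,
    seg_params: SegmentationParams | None = None,
    seed0: int = 0,
) -> list[float]:
    """Per-seed assignment accuracy at one planted failure rate."""
    base = base_config or SimulationConfig()
    accs = []
    for s in range(n_seeds):
        cfg = base.with_(failure_fraction=failure_fraction, seed=seed0 + s)
        img, lattice, gt = simulate_embryo(cfg)
        seg = segment(IntensityImage(img, cfg.pixel_size_um), seg_params)
        accs.append(assignment_accuracy(seg, lattice, gt))
    return accs


# --------------------------------------------------------------------------
# ratio recovery sweep
# --------------------------------------------------------------------------


def ratio_recovery(
    failure_fractions=(0.0, 0.02, 0.05, 0.1),
    n_seeds: int = 20,
    base_config: SimulationConfig | None = None,
    seg_params: SegmentationParams | None = None,
    quant_config: QuantConfig | None = None,
    seed0: int = 0,
) -> pd.DataFrame:
    """Estimated vs planted ratio across furrow failure rates.

    Returns one row per failure fraction with the seed-averaged estimated
    per-embryo ratio, the seed-averaged planted true ratio, and their
    difference.
    """
    base = base_config or SimulationConfig()
    rows = []
    for ff in failure_fractions:
        est, true = [], []
        for s in range(n_seeds):
            cfg = base.with_(failure_fraction=ff, seed=seed0 + s)
            m = measure_simulated_embryo(cfg, seg_params, quant_config,
                                         embryo_id=f"ff{ff}-s{s}")
            est.append(m.summary.ratio)
            true.append(m.ground_truth.true_ratio)
        rows.append(
            {
                "failure_fraction": ff,
                "mean_estimated_ratio": float(np.mean(est)),
                "mean_true_ratio": float(np.mean(true)),
                "bias": float(np.mean(est) - np.mean(true)),
                "n_seeds": n_seeds,
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Mendelian genotyping cohorts
# --------------------------------------------------------------------------


def genotype_cohort(
    n_embryos: int = 148,
    seed: int = 0,
    p_detect: float = 0.9,
    n_nuclei: int = 150,
    n_slices: int = 4,
    render_params: FishRenderParams | None = None,
    detect_params: SpotDetectionParams | None = None,
) -> tuple[list[GenotypeCall], list[str]]:
    """Simulate and genotype one het x het cohort.

    True genotypes are drawn with Mendelian probabilities (1/4 null,
    1/2 het, 1/4 wt); each embryo's FISH stack is rendered and pushed
    through projection, nucleus segmentation, spot detection and genotype
    calling.  Returns the calls and the planted genotypes.
    """
    rng = np.random.default_rng(seed)
    genos = list(
        rng.choice(list(MENDELIAN_P), size=n_embryos, p=list(MENDELIAN_P.values()))
    )
    calls = []
    for i, g in enumerate(genos):
        stack, _ = render_fish_stack(
            g,
            n_nuclei=n_nuclei,
            n_slices=n_slices,
            p_detect=p_detect,
            seed=int(rng.integers(2**31 - 1)),
            params=render_params,
        )
        calls.append(
            genotype_embryo(stack, embryo_id=f"e{i}", min_nuclei=min(n_nuclei, 150),
                            detect_params=detect_params)
        )
    return calls, genos


def genotyping_experiment(
    n_cohorts: int = 200,
    n_embryos: int = 148,
    seed: int = 0,
    p_detect: float = 0.9,
    n_nuclei: int = 150,
) -> pd.DataFrame:
    """Replicate het x het cohorts; one row of called percentages per cohort."""
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(n_cohorts):
        calls, _ = genotype_cohort(
            n_embryos=n_embryos,
            seed=int(rng.integers(2**31 - 1)),
            p_detect=p_detect,
            n_nuclei=n_nuclei,
        )
        dist = genotype_distribution(calls)
        rows.append(
            {
                "cohort": k,
                "percent_null": dist["observed_percent"]["null"],
                "percent_het": dist["observed_percent"]["het"],
                "percent_wt": dist["observed_percent"]["wt"],
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# end-to-end run (config-driven)
# --------------------------------------------------------------------------


def run_pipeline(config: dict, out_dir, seed: int | None = None,
                 save_images: bool = True) -> pd.DataFrame:
    """Config-driven end-to-end run: simulate -> segment -> quantify -> stats.

    ``config`` holds a ``simulate`` block (SimulationConfig fields plus
    ``n_embryos``), an optional list of ``conditions`` overriding fields
    per experimental group, optional ``segmentation`` / ``quantify``
    parameter blocks, and an optional ``stats`` block
    (``{"value": "ratio", "design": "genotype"}``).  Everything is written
    under ``out_dir``: per-embryo CSV, group statistics JSON, provenance
    JSON and (optionally) the per-embryo mask/label TIFFs.  A fixed seed
    reproduces the outputs exactly.
    """
    from .io import RunProvenance, write_intensity, write_labels, write_mask
    from .quantify import compare_groups, summaries_to_frame

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0)) if seed is None else int(seed)
    sim_block = dict(config.get("simulate", {}))
    n_embryos = int(sim_block.pop("n_embryos", 1))
    if "image_size_px" in sim_block:
        sim_block["image_size_px"] = tuple(sim_block["image_size_px"])
    conditions = config.get("conditions") or [{"name": "default"}]
    seg_params = SegmentationParams(**config.get("segmentation", {}))
    quant_config = QuantConfig(**config.get("quantify", {}))

    rng = np.random.default_rng(seed)
    summaries = []
    thresholds = {}
    cell_rows = []
    for cond in conditions:
        cond = dict(cond)
        name = str(cond.pop("name", "default"))
        labels = {
            "genotype": cond.pop("genotype", name),
            "temperature": cond.pop("temperature", None),
        }
        block = {**sim_block, **cond}
        for i in range(n_embryos):
            cfg = SimulationConfig(**{**block, "seed": int(rng.integers(2**31 - 1))})
            embryo_id = f"{name}-{i:03d}"
            m = measure_simulated_embryo(cfg, seg_params, quant_config, embryo_id)
            m.summary.genotype = labels["genotype"]
            m.summary.temperature = labels["temperature"]
            summaries.append(m.summary)
            thresholds[embryo_id] = m.segmentation.provenance["thresholds"]
            cell_rows.extend(
                {"embryo_id": embryo_id, "cell_id": cid, "n_nuclei": n}
                for cid, n in sorted(m.segmentation.nuclei_per_cell.items())
            )
            if save_images:
                edir = out_dir / embryo_id
                edir.mkdir(exist_ok=True)
                write_intensity(edir / "image.tif", m.image)
                write_mask(edir / "network.tif", m.segmentation.network.mask)
                write_labels(edir / "cells.tif", m.segmentation.cells.labels)
                write_labels(edir / "compartments.tif",
                             m.segmentation.compartments.labels)

    table = summaries_to_frame(summaries)
    table.to_csv(out_dir / "embryos.csv", index=False)
    pd.DataFrame(cell_rows).to_csv(out_dir / "cells.csv", index=False)

    stats_block = config.get("stats")
    if stats_block and table["genotype"].nunique() > 1:
        res = compare_groups(
            table,
            value=stats_block.get("value", "ratio"),
            design=stats_block.get("design", "genotype"),
        )
        res.pop("anova", None)  # frame not JSON-serializable; p_values kept
        (out_dir / "group_stats.json").write_text(json.dumps(res, indent=2, default=str))

    RunProvenance(
        config=config, seeds={"seed": seed}, thresholds=thresholds
    ).to_json(out_dir / "provenance.json")
    return table
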