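# furrowseg

Quantifying the fidelity of *Drosophila* cellularization from surface-view
fluorescence micrographs.

During cellularization — the first tissue-building event of the fly embryo —
plasma-membrane furrows ingress between ~6000 cortical nuclei and package
each nucleus into its own cell. In a surface view the F-actin/Myosin-rich
furrow canals form a bright, near-hexagonal network outlining the nascent
cells. When a furrow fails or regresses, its network edge decays to a weak
residual link and the two flanking compartments merge into one
**multinucleate cell**. Because hundreds of packaging events are visible per
image, fidelity can be scored as the **mononucleate-cells-to-nuclei ratio**

```
ratio = (# cells containing exactly one nucleus) / (# nuclei assayed)
```

which equals 1 in an intact (wild-type) embryo and falls below 1 as furrows
fail. `furrowseg` is a library for scientists who need that readout (and its
companions) from single-channel furrow-marker images, plus an RNA-FISH
genotyping assay, with a synthetic-embryo simulator to validate every step
against planted ground truth.

## What it does

- **`furrowseg.segmentation`** — the six-step morphological procedure:
  coarse Gaussian smoothing, intensity threshold, iterative thinning to a
  1-pixel network; then fine smoothing with a *low* threshold to capture the
  weak residual links of failed furrows, closing, thinning and spur/fragment
  pruning; the union is dilated and inverted into nucleus compartments, and
  a high threshold plus border clearing removes thinning artifacts.
  Cells are regions enclosed by the strong network, nucleus compartments by
  the full network; each compartment is assigned to its majority-overlap
  cell. Thresholds are a strategy parameter (Otsu default, quantile/fixed
  overrides) and every resolved value is logged.
- **`furrowseg.quantify`** — the ratio via quadrat sampling (two
  2835-µm² windows per embryo by default), percent of embryos displaying
  multinucleation (± binomial s.e.m.), background-subtracted furrow-canal
  intensity (an F-actin readout), Student's *t* and two-way ANOVA with the
  embryo as the unit of analysis.
- **`furrowseg.fish`** — RNA-FISH genotyping: maximum-intensity projection
  of a ~4 µm stack, per-nucleus transcription-spot counting
  (Laplacian-of-Gaussian at the ~300 nm diffraction scale), genotype from
  the maximum count (0 → null, 1 → het, ≥2 → wild type; ≥150 nuclei per
  embryo), and chi-square comparison of a cohort against the Mendelian
  25/50/25 expectation.
- **`furrowseg.simulate`** — jittered-hexagonal Voronoi tissue with one
  nucleus per tile, planted furrow failures with exact ground truth
  (merged-cell map, true ratio), image formation with blur and noise, and
  FISH stacks with 0/1/2 spots per nucleus at a given detection probability.
- **`furrowseg.io` / `furrowseg.cli`** — TIFF/CSV/JSON/YAML plumbing,
  run provenance, and a thin `furrowseg` command
  (`simulate`, `simulate-fish`, `segment`, `quantify`, `genotype`, `stats`,
  `run`).

## Worked example

```python
from furrowseg import IntensityImage, SimulationConfig, segment
from furrowseg.pipeline import measure_simulated_embryo

cfg = SimulationConfig(image_size_px=(768, 1280), n_nuclei=150,
                       failure_fraction=0.05, seed=7)
m = measure_simulated_embryo(cfg, embryo_id="demo")
print(m.summary.ratio, m.ground_truth.true_ratio, m.summary.is_multinucleate)
```

prints

```
0.7041156840934372 0.6857142857142857 True
```

— the pipeline estimates a ratio of 0.70 for this embryo from two sampling
quadrats while the planted truth over all interior nuclei is 0.69 (the gap
is quadrat sampling noise; seed-averaged estimates track the truth to
within ±0.02), and at least one multinucleate cell was observed. The
`examples/` directory holds short narrative scripts for each capability:

- `01_segment_embryo.py` — segmentation and per-cell nucleus counts,
- `02_multinucleation_metrics.py` — cohort metrics and the *t* test,
- `03_fish_genotyping.py` — genotype calls and the Mendelian comparison,
- `04_furrow_intensity.py` — linearity of the furrow-canal intensity readout.

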