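# Methods

This note documents the models, algorithms and numerical choices behind
`furrowseg`: what the synthetic embryos emulate and deliberately omit, how
the segmentation procedure works and where its defaults come from, how the
fidelity metrics and the FISH genotyping assay are defined, and the known
limits of each.

## The measurement problem

A cellularizing fly embryo packages its cortical nuclei into a monolayer of
cells; the furrow canals between nascent cells carry bright F-actin/Myosin
signal, so a surface-view micrograph shows a near-hexagonal network of
ridges enclosing one dark compartment per nucleus. Furrow failure leaves a
weak residual link where an edge used to be, merging two compartments into
one multinucleate cell. The analysis must (a) segment the strong network
(cell outlines) and the full network including weak links (nucleus
separations), (b) count nucleus compartments per cell, (c) convert counts
into per-embryo fidelity metrics, and (d) for genetics experiments, read an
embryo's genotype off nascent-transcription FISH spots.

## Synthetic embryos

The simulator exists so every stage can be validated against planted truth;
its defaults define the reference conditions used throughout the tests.

**Geometry.** Seed points on a hexagonal lattice are jittered by a uniform
offset of up to 25% of the lattice spacing and tessellated with a Voronoi
diagram; each tile holds one nucleus (a Voronoi cell always contains its
site). The spacing is set by the image area and `n_nuclei`; a sizing error
is raised when the implied cell diameter falls below 10 px. A ring of
padding sites keeps all tiles finite; tiles whose polygon crosses the image
border are flagged `boundary` and excluded from the planted ratio, matching
the pipeline's own border exclusion.

**Failures.** Each edge between two tiles fails independently with
probability `failure_fraction`, provided at least one of the two tiles is
interior: failure statistics are then homogeneous across the scored region,
while every planted failure affects at least one scored nucleus (so the
planted ratio is 1 exactly when no edge failed). Edges between two
boundary tiles and rim edges never fail. Cells are connected components of
the tile graph restricted to failed edges; the planted
`true_ratio` counts singleton interior tiles over all interior tiles.

**Image formation.** Intact edges are drawn as ridges of width 3 px at
amplitude 100; failed edges at `weak_link_contrast = 0.3` of that — bright
enough for a low threshold to catch, dim enough that it reads as a failed
furrow. The raster is blurred (σ = 1 px), optionally passed through a
Poisson stage, and corrupted with additive Gaussian read noise of s.d. 10
(ridge SNR ≈ 10); all randomness flows from one `numpy` generator per call,
so a config + seed reproduces images bit for bit. Deliberately *not*
modelled: a realistic PSF, 3-D structure, furrow-ingression dynamics,
intensity inhomogeneity across the field. Passing tests on these images
therefore demonstrate the correctness of the algorithms under the stated
image model, not performance on any particular microscope's data — on real
images the threshold strategy and sigmas are the knobs to revisit.

**FISH stacks.** Nuclei (Gaussian blobs, σ 2.2 px, one per grid site at
11 px spacing) sit in a separate channel; the spot channel is a stack of
`n_slices` planes spanning 4 µm. A genotype plants 0, 1 or 2 spot
candidates per nucleus (σ 1.2 px ≈ 300 nm at 104 nm/px); each candidate is
visible with probability `p_detect` and lives in one random slice. Two
sister spots are kept ≥ 3.6 px apart so that a detector at the diffraction
scale can resolve them; real sister-chromatid doublets can sit closer and
would merge — the detector's merge behaviour is documented by test, not
claimed to match manual counting.

## Segmentation

The procedure is six morphological steps on a single furrow-marker image:

1. **Coarse smoothing** (`sigma_coarse_px = 4`, reflective borders — mean
   preserved to <1%) retains only coarse furrow-canal features.
2. **Mid threshold** on the smoothed image → preliminary network mask.
3. **Thinning** (topology-preserving, 8-connected) to a 1-px network.
4. **Fine smoothing** (`sigma_fine_px = 1.5`) with a **low threshold**
   captures the weak residual links; the mask is closed (disk r = 2),
   thinned, and pruned: spurs shorter than `min_link_length_px = 10` are
   peeled endpoint-by-endpoint, and components disconnected from the
   largest network component are dropped. Both prunings are independently
   switchable because "remove disconnected links" admits either reading.
5. The thinned step-2 mask united with the step-4 mask is **dilated**
   (disk r = 2, independent of the closing radius) and **inverted**;
   speck holes inside compartments are filled. Filling identifies
   background components other than the main network (largest component or
   any touching the border) — a plain flood-fill would erase an enclosed
   network wholesale.
6. A **high threshold** on the step-1 image marks saturated ridge cores;
   its complement is intersected with the compartment mask, and regions
   touching the image border are dropped (partially imaged cells cannot be
   scored).

**Cells vs compartments.** Nucleus compartments are regions enclosed by the
full network (steps 4+5+6). Cell regions come from the strong network
alone, with one refinement: a candidate cell wall must also show
fine-scale ridge evidence (fine-smoothed intensity above the strong-wall
threshold). Without this, the coarse-smoothing halos of two junctions
less than ~2σ apart bridge a short failed furrow and wrongly split its
merged cell. Walls of intact furrows sit far above this threshold
(≈60 vs ≈30 for weak links under the default image model), so the
refinement only removes spurious walls; it is switchable
(`refine_strong_with_fine`).

Each compartment is assigned to the cell region covering the majority of
its area; compartments overlapping no cell are logged and excluded. Cells
whose strong-network region touches the image border are dropped *as a
whole*, together with their compartments — clearing only the
border-touching compartment would leave the rest of a truncated
multinucleate cell masquerading as mononucleate. The final cell label
image is rebuilt as the union of each cell's member compartments, which
makes compartment⊂cell containment exact by construction and keeps
labels consecutive.

**Thresholds.** The original workflow chose thresholds manually per image;
automation replaces that with a strategy parameter, and every resolved
value is logged and stored in the run provenance:

| threshold | otsu strategy (default) | role |
|---|---|---|
| mid | Otsu of the coarse-smoothed image | strong network (step 2) |
| low | 0.35 × Otsu of the fine-smoothed image | weak links (step 4) |
| high | 1.8 × mid | artifact removal (step 6) |
| strong wall | 1.2 × Otsu of the fine-smoothed image | cell-wall evidence |

The low factor puts the threshold ≈5 noise s.d. above background under the
default image model while staying below the weak-link ridge; the high
factor selects only ridge cores/junctions. `quantile` and `fixed`
strategies take the three values verbatim (and must satisfy
low < mid < high). A blank or noise-only image fails loudly: Otsu on a
constant image raises a degenerate-image error, a thresholded foreground
covering >45% of pixels or yielding zero enclosed compartments raises a
no-network error.

**Connectivity and coordinates.** Skeletons/network: 8-connectivity;
compartments: 4-connectivity (the standard duality that prevents label
leakage across diagonal skeleton pixels). Pixels are (row, col), 0-based;
physical lengths come from `pixel_size_um` (default 0.104 µm — a typical
confocal surface-view sampling).

**Optional nucleus channel.** When a nuclear-marker image is available,
`detect_nuclei_centroids` + `assign_nuclei_to_cells` count detected nuclei
per cell by centroid containment instead of furrow-derived compartments.

## Fidelity metrics

**Ratio.** Two square quadrats of 2835 µm² each (side ≈ 512 px at
104 nm/px) are placed deterministically along the longer image axis, inset
from the field edge by 10 µm (≈ one cell diameter; shrunk automatically on
small images) — as with a human scorer, quadrats avoid the image edge where
cells are partially imaged. Within a window,
ratio = (# cells fully inside with exactly one compartment) /
(# compartments fully inside); objects crossing the window edge are
excluded to prevent double counting, and because cells are unions of their
compartments the two "fully inside" judgements are consistent. The embryo
value is the mean over windows; empty windows are skipped with a warning,
and an insufficiency flag fires below 150 assayed nuclei. Seedable random
window placement is available. Unassigned compartments are excluded from
the denominator and logged rather than guessed.

**Multinucleation frequency.** Percent of embryos whose segmentation shows
any cell with ≥2 compartments, with the binomial s.e. of the proportion;
embryos with fewer than 1500 assayed nuclei are flagged, not dropped.

**Furrow-canal intensity.** The network skeleton is cut at junction pixels
into canal segments, dilated to the canal width; per-canal intensity is the
mean over the dilated segment minus the background (median over pixels in
neither the dilated network nor any compartment). The embryo value is the
mean ± s.d. over canals, flagged when fewer than 75 canals are available.
The measurement is linear in ridge amplitude and invariant to constant
offsets by construction.

**Statistics.** Per-embryo values are compared with a two-sided
pooled-variance Student's *t* (Welch optional) or a two-way ANOVA with
interaction (type-II sums of squares via `statsmodels`), requiring a fully
crossed design with ≥2 embryos per cell. No multiple-testing correction is
applied (none is conventional for these figure-level comparisons); the
output metadata says so explicitly.

## FISH genotyping

Maximum-intensity projection over z (warning when the stack depth strays
>50% from the conventional ~4 µm), nucleus labels from the nucleus channel
(Otsu + fill + size filter, distance-transform watershed to split touching
blobs), then single-scale Laplacian-of-Gaussian detection at σ = 300 nm /
2.355 with peaks above median + 8·1.4826·MAD of the response — spots are
sparse, so median/MAD estimate the noise floor robustly, and the 8-MAD
margin keeps the false-positive rate negligible on spot-free (null)
embryos. Peaks are assigned to the nucleus label under them; raw counts
are preserved and collapse to 0/1/2 only at genotype assignment
(max 0 → null, 1 → het, ≥2 → wild type), with an insufficiency flag below
150 scored nuclei. Cohort distributions are reported as percentages ±
binomial s.e.m. with a chi-square goodness-of-fit against 25/50/25.
Lowering `p_detect` can only shift calls toward fewer alleles — an
invariant the tests assert with coupled seeds.

## Validation experiments and problem sizes

All validation runs on synthetic embryos with planted truth:

- **Wild-type exactness** — one 768×1280 px embryo, 150 nuclei (~105
  interior), default noise: the measured ratio must be exactly 1.
- **Assignment accuracy** — noiseless 512×512 px embryos, 100 nuclei,
  20 seeds: per-nucleus cell grouping must match the planted truth for
  100% of scored nuclei with no failures and ≥95% at a 10% failure rate.
  Nuclei whose true cell extends out of frame are excluded from scoring
  (the pipeline rightly refuses to score partially imaged cells);
  remaining errors are failed furrows shorter than ~8 px, whose flanking
  junctions physically merge at this resolution.
- **Ratio recovery** — 768×1280 px, failure rates {0, 0.02, 0.05, 0.1},
  20 seeds each: seed-averaged estimates track the planted ratio within
  ±0.03 and decrease monotonically.
- **Mendelian cohorts** — 200 replicate 148-embryo het × het cohorts,
  150 nuclei/embryo, `p_detect = 0.9`: mean called fractions within 2
  points of 25/50/25. FISH frames are ~143×132 px, sized to hold 150
  nuclei at 11 px spacing.
- **ANOVA calibration** — 1000 simulated null replicates of a 2×2 design:
  interaction type-I error 0.05 ± 0.02.

These sizes keep the full suite comfortably within a desktop run while
leaving each check statistically meaningful.

## Known limitations

- The image model is 2-D with idealized Gaussian optics and
  spatially-uniform noise; real surface views curve out of focus toward
  the embryo edge and carry structured background.
- Furrow failures shorter than the smoothing scale (~8 px ≈ 0.8 µm) cannot
  be distinguished from intact junction clusters; they are rare under the
  Voronoi geometry but account for the residual assignment errors.
- The genotype caller trusts the nucleus channel; with only a furrow
  channel, compartments can stand in for nuclei, but touching-nucleus
  splitting is then unavailable.
- Amphiphysin-tubule scoring and 3-D furrow-length staging are out of
  scope; furrow length is accepted as user-supplied metadata only.
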