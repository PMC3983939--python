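# Methods

This note documents the models, algorithms and numerical choices behind
`ratiokd`, in the order the pipeline runs.

## Synthetic scene model

Each simulated field is a set of non-overlapping, randomly rotated ellipses
(nuclei) on a constant background, rendered into three registered channels
(DNA, green, red) at 16-bit range.

**Cells.** Per nucleus, the area is uniform in `nucleus_area_range`
(default 1.3–2.5 µm² at 0.1 µm/pixel, sitting inside the default 1.1–2.7 µm²
segmentation filter), eccentricity uniform in [0, 0.85], orientation uniform.
Placement is rejection sampling with a bounding-circle separation test;
clearly infeasible densities are refused up front and placement failure after
200 attempts per nucleus raises a "field too crowded" error.

**Expression.** Each cell draws an expression level `E` from
lognormal(meanlog = 5.5, sdlog = 1.0), spanning roughly two decades — wide
enough to probe ratio stability across the expression range. A cell is
transfected with probability `transfected_fraction` (default 0.7).
Transfected cells emit green `f·a·E` and red `b·E·(1−k_eff)`;
untransfected cells emit only DNA stain. Here `a`, `b` are channel gains
(default 1), `k` the knockdown efficiency, and `f` the green-expression bias
of the shRNA-bearing plasmid (both applied only in the test condition;
control fields always use `k = 0`, `f = 1`). With probability
`outlier_fraction` (default 0.02) a transfected cell is RNAi-insensitive:
`k_eff = 0`, reproducing the bright-red outlier tail. The 2% default and the
bias magnitude are free parameters of the simulation, not measured
constants.

**Rendering.** Green and red are spatially flat inside each nucleus, so a
noise-free ROI mean equals the per-cell truth exactly. The DNA channel has a
radial brightness profile (centre ≈ 1.3×, rim ≈ 0.85× of the per-cell level,
cell-to-cell spread lognormal sdlog 0.15), mimicking chromatin-dense nuclear
centres; this is what makes the pixel-quantile threshold rule cut dim rim
pixels rather than whole nuclei. Noise is optional Poisson shot noise on the
signal, plus a constant per-channel offset (default 100 counts) and Gaussian
read noise (default sd 5), clipped at the 16-bit ceiling.

**What the generator does not emulate:** optics (PSF blur, chromatic shift),
cytoplasmic fluorescence, bleed-through between channels, illumination
gradients, touching or overlapping nuclei, mitotic figures, partial-efficacy
outliers. Tests passing on this model therefore demonstrate the correctness
and statistical behaviour of the analysis, not robustness to those real-data
artifacts.

Determinism: a scene is a pure function of its parameters and seed;
experiments derive one independent substream per field from the experiment
seed (`numpy` `SeedSequence` spawning).

## Segmentation

Nuclei are the 8-connected components of pixels *strictly above* a global
DNA threshold, labeled consecutively in raster order of each component's
first pixel. The threshold is either manual or automatic: Otsu's two-class
criterion separates stained from background pixels, and the returned value
sits just below the (1 − q) quantile of the stained pixels (q = 0.95 by
default), so that at least ~95% of stained pixels survive the strict
comparison. The one-ULP nudge below the quantile handles quantized images,
where the quantile value itself would otherwise be excluded. A constant
image has no detectable foreground and raises an error.

ROIs are filtered by area (closed interval, default 1.1–2.7 µm²; area =
pixel count × pixel_size²) and by eccentricity (≤ 0.95 by default) as the
shape criterion. 8-connectivity merges diagonal speckle; no hole-filling or
watershed splitting is attempted — touching nuclei merge and are then
usually removed by the area ceiling. The default area window is a
configuration value inherited from the assay's Rat2 protocol, not a claim
about mammalian nuclear size in general; adapt it to your magnification.

## Quantification

Background is a per-channel scalar: the mean of per-ROI mean intensities
over the filtered nuclei of an untransfected sample (nuclear regions, the
same compartment that is measured). The SD of those per-ROI means is kept
for gating. Per cell, the mean intensity over the ROI mask is background-
subtracted and clamped at 0 (intensities are physical).

Transfectants are gated by `mean_green > threshold` (strict; a cell exactly
at the threshold is out). The threshold is either preset or derived as
`k_sd` × the untransfected green SD (default 3 SD), an operationalization of
"preset from background analysis". Cells below the gate have no R/G ratio
and are excluded from every downstream statistic, never zero-filled.

For immunofluorescence re-analysis, per-cell stain intensities of
transfectants are expressed as percent of the untransfected-cell average and
summarized by their median.

## Ratiometry

Each arm pools cells across its fields (rather than averaging per-field
medians) and is summarized by n, median, mean and SD of the R/G ratios, with
a warning below 300 transfectants. The share of ratios above
median + 3·IQR is reported as the outlier fraction; outliers stay in.

δ = m_scramble_control / m_scramble_test. KD is computed in the factored
form `100 · ((m_test · m_scr_control) / (m_control · m_scr_test))`, the
ratio taken before the multiplication by 100, so that when the same scramble
pair supplies both δ and the arms the numerator and denominator are
identical floats and KD is exactly 100.0 (IEEE multiplication is
commutative). KD above 100% is reported unclipped.

Uncertainty: a percentile bootstrap (default 2000 replicates, seeded)
resamples cells independently within each arm and recomputes the median
ratio; δ is held fixed, since its scramble arms come from a separate
experiment. The interval is widened, if necessary, to bracket the point
estimate. For repeat-level reporting, `repeat_summary` gives the mean ± SD
of KD over independent experiments. A `linearity_qc` helper fits red vs
green over transfectants (Pearson r, least squares); control arms should
show r close to 1.

Whether δ should be reused across targets sharing a vector is left to the
user: `estimate_delta` takes whichever scramble pair the experimenter deems
matched.

## Oligo design

The four-oligo shRNA scheme substitutes the 19-nt target x and its reverse
complement y into fixed templates (`GATCCCCxGC`, `ACAGGAAGCyGGG`,
`TTCCTGTCACyTTTT`, `xGTG`; lengths 28/31/33/22), assembling a 61-nt top
strand `GATCCCC + x + GCTTCCTGTCAC + y + TTTT` — sense, miR23 loop,
antisense, pol III poly-T terminator. "Complementary sequence" is
implemented as *reverse* complement throughout: duplexes can only anneal
antiparallel. The reporter scheme is `x + TTCG` / `y + TTGC` (23 nt each,
19-bp annealing core, 4-nt single-stranded tails). The negative-control
pair is emitted verbatim; it embeds the classical TTCAAGAGA loop rather
than the miR23 loop, which the validator reports as a note.

`validate_hairpin` audits, per set: duplex complementarity (failures name
the mismatched positions), the sense–loop–antisense architecture, terminal-
extension compatibility, and the ≥4-T terminator. The end check asserts that
the two terminal extensions cannot cross-anneal (which is what prevents
head-to-tail tandem inserts); an individually palindromic end — the
upstream BglII-type GATC overhang of the printed designs is one — is
reported as a note rather than a failure, because single-copy directionality
there is enforced by the vector side of the ligation, which a sequence-level
check of the insert cannot see. Restriction digestion and ligation
chemistry are otherwise out of scope. Designers are pure functions; no
randomness anywhere in this module.

## File formats and determinism

Fields are 3-page 16-bit grayscale TIFFs (DNA, green, red) or
`_dna`/`_gfp`/`_rfp` triplets; pixel values become float64 on load and the
configured pixel size overrides any TIFF resolution tag. Per-cell and ROI
tables are CSV, results JSON, configuration and manifests YAML; all carry a
schema version and loaders reject unknown major versions. Saturated pixels
are logged but not excluded. All pipeline randomness (the bootstrap) flows
from the single configured seed; reruns are byte-identical.

## Problem sizes

The test suite and the acceptance script run experiments of five 512×512
fields per arm at ~150 nuclei per field (~500 transfectants per arm after
gating, matching the assay's >300-cells-per-sample practice), 10–20
independent seeds for bias estimates, and scaled-down Monte-Carlo checks
(200 repetitions, 400–500 bootstrap replicates) for CI coverage. These sizes
give sub-minute runs while keeping binomial/Monte-Carlo error well inside
the asserted tolerances.

## Known limitations

* Segmentation is global-threshold + connected components; it will merge
  touching nuclei and has no learned or watershed fallback.
* The δ correction assumes the scramble pair is representative of the
  construct pair it corrects; the package does not test that assumption.
* The bootstrap CI reflects cell-sampling noise only, not field-to-field or
  experiment-to-experiment variance (use `repeat_summary` across repeats
  for the latter).
* The generator's noise model is per-pixel and channel-independent; real
  bleed-through or focus drift would require flat-field/unmixing steps that
  are deliberately out of scope.
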