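# Methods

## Setting

`phenochip` implements an automated 3D high-content image-analysis and
pharmacophenomics workflow for neuronal cultures grown in microfluidic
plates (OrganoPlate-style bioreactors). One bioreactor chamber is the unit
of analysis: a multi-channel 3D confocal stack is segmented into device
structures and cellular masks, scalar features are extracted per chamber,
and chambers are then compared across genotype / treatment groups with
nonparametric statistics, a bootstrap rescue-size estimate, and an SVM-RBF
classifier benchmark. Because no raw imaging data accompanies the published
study design, a synthetic-fixture generator with voxel-level ground truth
stands in for the microscope; it is first-class, tested code.

Volumes are numpy arrays indexed `(z, y, x)`, z = 0 being the bottom-most
acquired plane; gray levels are raw, dimensionless camera counts, which is
the scale on which all fixed thresholds below are defined.

## Image-processing conventions

* **Gaussian filters.** "Size N, standard deviation s" means an N x N
  truncated Gaussian sampled on the centred grid `-(N-1)/2 .. (N-1)/2`,
  normalised to sum 1 (the Matlab `fspecial` convention); borders are
  replicate-padded. The 2D kernel is exactly separable, so filtering is two
  1D passes. Filters act plane-wise by default (matching per-plane
  acquisition); a 3D variant is available via `three_d=True`. For
  even-sized kernels the array centre sits half a pixel off the kernel's
  analytic centre; the package is internally consistent about this and it
  cannot affect counts.
* **Difference of Gaussians (DoG).** Foreground blur minus background blur,
  signed values retained; constants map to exactly zero.
* **Connectivity.** 26-connected in 3D, 8-connected in 2D (the Matlab
  `bwconncomp` default), exposed as a parameter (`"minimal"` gives 6/4).
* **Component size gates are inclusive**: "less than 5 or more than 500
  removed" keeps components of exactly 5 and exactly 500 voxels.
* **Erosion borders.** The 6-connected surface/body split
  (`erode_with_surface`) treats out-of-volume neighbours as background, so
  volume-border voxels always erode — stated explicitly because it changes
  surface counts. The *chip refinement* erosions instead use the Matlab
  `imerode` convention (out-of-image = foreground) so that full-height
  walls survive the tall-rod erosion.
* **Structuring elements larger than the image** (the 501- and 3001-px
  rods on desk-scale fixtures) are clipped to the image extent with a
  logged warning.
* **Stitching.** Mosaic fields are placed by integer translation only;
  each field's offset from nominal is the argmax of normalized
  cross-correlation over the overlap strips, searched within +-25% of the
  nominal overlap. Overlapping voxels take the maximum of contributing
  tiles (preserves puncta); linear feathering is available. Zero-variance
  strips fall back to the nominal offset with a warning.

## Chip segmentation

A rough 2D mask from size-5 average-filtered maximum projections is
refined by a fixed chain: erode disk r=5, drop components < 1000 px, dilate
disk r=20, dilate vertical rod 101x1 (close gaps), erode vertical rod 501x1
(keep only full-height structures), drop components < 100 000 px. The
refined mask must split into exactly three blocks left-to-right; the middle
block is the phase guide. The Matrigel channel (MC) is reconstructed in the
complement of the device mask from a seed extending the phase guide one
pixel leftward; the perfusion channel (PC) likewise rightward. The 2D
device mask is projected to all planes and the phase guide clipped to the
lowest eight planes.

Per-assay rough rules:

* morphometric: OR over the four channels of per-channel thresholds. The
  published text gives no numeric thresholds ("based on fluorescence
  intensities"), so they are explicit configuration; the fixture default is
  500 against walls rendered at 800.
* mitochondrial: `(10 < TMRM_max < 30) OR ((30 < Hoechst_max < 200) AND
  (MitoTracker_max > 15))`. The printed formula is ambiguous about
  precedence; the OR-of-(range, AND) grouping is the default (TMRM-bright
  walls or nuclear+mito tissue) and the alternative grouping is selectable.
* cell death: `50 < Calcein_max < 300`, with rod heights 201/3001 and an
  extra disk opening r=20 plus dilation r=22.

The published component-size gates (1000 / 100 000 px) assume full-width
stitched mosaics (~4000 px); `synthetic.chip_params_for` rescales them to a
fixture's wall footprint while keeping every structuring element at its
published size.

## Assay mask recipes (fixed thresholds)

| mask | recipe |
|---|---|
| nuclei (morpho) | DoG(10/2 − 60/20) > 10, minus device, components ≥ 200 px |
| pyknotic | nuclei voxels with size-5 average-filtered raw Hoechst > 400 |
| neuron | lowpass(10/3) > 150 OR DoG(10/3 − 20/6) > 3, minus device, ≥ 200 px |
| TH | lowpass(10/1) > 100, minus device |
| nucleus (mito) | raw Hoechst > 100, minus device |
| cell (mito) | raw CellMask > 400 OR DoG(100/5 − 100/30) > 10, minus device |
| mitochondria | DoG(10/1 − 10/3) > 30, sizes in [5, 500] px, minus device |
| nuclei (death) | DoG(10/2 − 60/20) > 50, minus device, ≥ 200 px |
| EH | lowpass(10/3) > 500, minus device |
| CC3 | lowpass(10/3) > 250, minus device and nuclei, then ≥ 20 px |
| Calcein | lowpass(10/1) > 50 OR DoG(20/1 − 20/5) > 10, minus device and nuclei |
| live | Calcein minus nuclei, ≥ 200 px |
| CC3-live | Calcein AND (NOT nuclei) AND CC3 |

CC3's exclusions run before its size filter (the literal recipe order).
Fragmentation readouts use the 6-connected erosion split: fragmented
objects expose more surface per unit volume than compact ones.

## Skeleton graphs

Masks are thinned by topology-preserving 3D thinning
(`skimage.morphology.skeletonize`, Lee's method; algorithm name recorded in
the output). Nodes are skeleton voxels with ≥ 3 skeleton neighbours under
26-connectivity, merged when adjacent; links are the maximal skeleton paths
between nodes and/or endpoints, plus direct adjacencies between distinct
node clusters. A simple path is (0 nodes, 1 link); a Y is (1, 3); an H is
(2, 5). Node/link counts proxy neurite arborisation and mitochondrial
network complexity.

## Feature records

Each chamber yields one row: metadata (line, genotype, background,
treatment, timepoint) plus voxel counts, component counts, surface/body
splits, skeleton statistics, and ratio features (TH/Tuj1, neuron
volume / nuclear volume, pyknotic fraction, dead fraction EH/(EH+live)).
Counts are in voxels, computed chip-wide outside the device mask by
default (MC-only is an option). The pyknotic count is the number of
nucleus components containing at least one pyknotic voxel. Ratio features
with zero denominators are emitted as NaN. "Dead fraction" is a
convenience feature beyond the published list.

## Statistics

* **Outliers**: the interquartile rule with factor 1 — values strictly
  above Q3 + IQR or strictly below Q1 − IQR are removed, per group, once.
  Quartiles use linear (type-7) interpolation by default; a Matlab-like
  type-5 variant is selectable. The rule is *not* idempotent (trimming
  shrinks the IQR), and it is anti-conservative: on null Gaussian data the
  downstream Mann-Whitney test rejects at ≈ 0.11 instead of 0.05
  (measured over 1000 null features at n = 25/group; the testing layer
  without trimming is calibrated at 0.048). This bias is inherent to the
  published procedure; `compare_groups(remove_outliers=False)` gives the
  calibrated path, and both rates are reported by the acceptance script.
* **Tests**: two-sided Mann-Whitney for two groups (exact for small
  samples without ties), Kruskal-Wallis above two, with Dunn's rank-based
  z tests (tie-corrected, two-sided) on explicitly listed pairs.
* **Benjamini-Hochberg** runs over an explicit family size m (features x
  comparisons); m is never inferred. Adjusted p-values are monotone, ≥ raw,
  capped at 1.
* **Bootstrap rescue**: per iteration, k = 10 values drawn with replacement
  from each of wild-type, mutant and treated groups; rescue = 100 ·
  (mean_treated − mean_mut)/(mean_wt − mean_mut), so 0% = mutant level and
  100% = wild-type level. Default 10^5 iterations; percentile CI; a single
  explicit seed; aborts if > 1% of iterations have a degenerate
  denominator. Outlier removal precedes resampling by default.

## Classification

Correlation selection iteratively removes one member of the most-correlated
feature pair until all pairwise |Pearson r| are below the threshold; the
dropped member is the one with the larger mean |r| against the remaining
features (ties → later column). Constant features count as r = 0.

The SVM-RBF benchmark runs `repeats` (default 200) random stratified
5-fold partitions. Inside each training split, features are z-scored on
the training data only and the (C, γ) grid point — 21 log-spaced C in
[1e−5, 1e5] × 10 log-spaced γ in [1e−3, 10] by default — is chosen by inner
3-fold cross-validated AUC, so the held-out fold never informs model
selection. Per repeat, held-out decision values are pooled into one AUC;
the report gives mean ± std over repeats plus accuracy, sensitivity (TPR of
the explicit positive class) and specificity from pooled hard predictions.
Pooling decision values across folds with independent scalings biases AUC
slightly toward 0.5 (≈ 0.01–0.02 at n = 400); the calibration tests budget
for this. Feature selection is performed once on the full table before CV
(the published order); a leakage-safe per-fold variant is the recommended
alternative when sample sizes allow. No class reweighting by default.
Everything is deterministic under the seed.

## Synthetic fixtures

The generator renders the chip (two full-height walls, a central phase
guide confined to the lowest 8 of 20 planes), then assay-specific objects
in the channel interiors: ellipsoidal nuclei (normal 250 / pyknotic 600
counts on Hoechst), binary neurite trees (soma 400, thin neurites 120 on
Tuj1, a tapered 400→300→200 proximal segment bridging the soma's DoG
shadow so each tree is one connected detection), TH-positive subsets at
300, compact mitochondrial puncta (drawn sizes 5–80 voxels — the DoG
band-pass hollows large plateaus, so compact puncta are the regime the
detector is defined for), and live/dead/apoptotic cells (Calcein 400, EH
800, CC3 400 offset into the cytoplasm so it survives nucleus exclusion).
Default canvas 256×256×20 (460×400×20 for the cell-death assay, whose
opening/dilation radii need wider structures). Every rendered intensity
keeps ≥ 20% margin to its governing threshold, so noise-free recovery is
exact by design.

Noise is additive Gaussian per channel, σ = `noise_frac` × that channel's
cellular-signal dynamic range (device autofluorescence excluded — it is
not part of the quantified signal), clipped at zero like camera counts. At
the 5% level used in tests, all object counts remain within 5% of truth.
The published local neuron threshold of 3 counts tolerates only a few
counts of background noise, which constrains any honest noise model; this
is a genuine fragility of the recipe on low-SNR data.

The generator does **not** emulate optics (PSF, depth attenuation),
illumination gradients, cell-to-cell intensity variation, or touching
objects. Passing tests therefore demonstrate correctness of the mask
recipes, feature bookkeeping and statistical machinery — not robustness to
real acquisition artefacts.

A separate feature-table simulator draws multivariate Gaussian features
with planted genotype deficits (in SD units), a planted treatment rescue
fraction, and block correlation structure, for testing the statistics and
classification layers at scale.

## Problem sizes used

Tests and the acceptance script scale the published compute down to
desk/CI scale as the package's own defaults: bootstrap 10^4 iterations in
the replication study (10^5 elsewhere), classifier checks at 10–50 repeats
with small fixed grids (the full 21×10 grid and 200 repeats remain the
API defaults), fixtures at the canvas sizes above. Calibration checks
average several independent datasets because a single cross-validated AUC
at these sample sizes has Monte-Carlo spread ~0.04–0.07.

## Known limitations

* The 1×IQR trim inflates type-I error (quantified above).
* Full-table feature selection before CV leaks selection information; kept
  as the default for fidelity, with the per-fold option recommended.
* Chip segmentation assumes upright, unrotated chips with exactly three
  vertical device blocks; no multi-chip images.
* Counts are voxel-based; physical units require voxel-size metadata.
* Sub-pixel registration, deconvolution and illumination correction are
  out of scope.
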