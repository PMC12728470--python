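# Methods

## The measurement model

A tumor-forebrain organoid is imaged as a multi-channel confocal stack
(default 29 planes): one channel for a tumor marker and one for a neuronal
(microenvironment) marker. The per-organoid readout is the *summed
brightness*: the arithmetic sum of tumor-channel intensity over segmented
tumor areas and of neuronal-channel intensity over the whole organoid,
accumulated over all planes, together with the tumor area (voxel count) and
the TME area (organoid minus tumor voxels). Sums are accumulated in float64
and match a naive voxel loop to machine precision; per-plane values always
add up to the stack totals.

Segmentation is deliberately parameter-light: the organoid mask is a
per-plane Otsu threshold on the channel sum followed by hole filling and
retention of the largest connected component; tumor areas are a single Otsu
threshold on the tumor channel pooled over all in-organoid voxels (per-plane
thresholds would fail on planes without tumor), intersected with the
organoid mask. Both thresholds can be overridden by fixed values. Whether
the original acquisition thresholded per plane or in 3D is not published;
both are available and the defaults are stated here. All-zero stacks yield
an empty mask with a warning; saturated voxels are counted as a QC metric
but never excluded.

### Background subtraction

Summed brightness contains an autofluorescence pedestal that biases
treated/control ratios toward 1 (by `b·k/(s+b)` for signal `s`, pedestal
`b` and kill fraction `k`). Subtraction is off by default. When enabled the
pedestal is estimated per channel as the median over in-organoid voxels
where that channel's specific signal is absent ("compartment" mode): the
organoid-minus-tumor region for the tumor channel, and the tumor mask for
the neuronal channel. Two robustness guards apply to the neuronal estimate,
because it inherits the tumor mask's quality: (i) it uses only the most
tumor-confident half of the mask (voxels at or above the mask's median
tumor intensity — channel noise is independent, so this does not bias the
median); (ii) when the mask has no significant contrast over its complement
(median difference ≤ 3 robust SDs), the mask is a noise artifact — e.g. a
fully ablated tumor — and the tumor channel's complement estimate is reused
under a shared-pedestal assumption. An "outside" mode (median over
out-of-organoid voxels) exists for data with a camera offset; in phantom
data the outside is dark noise clipped at zero, so that mode estimates ~0
and is not the default.

## Screen statistics

Effects are ratios of group means, normalized to the plate's DMSO control;
the reported SEM is the treated group's SEM divided by the control mean
(the control level is treated as a fixed reference; its own uncertainty is
not propagated). Group differences use the two-sided Wilcoxon rank-sum
test: the exact null distribution for combined n ≤ 20 without ties, the
normal approximation with tie correction (and continuity correction)
otherwise; two groups with all values identical return p = 1. P-values are
Benjamini–Hochberg adjusted across drugs within each compartment; a hit is
adjusted tumor p < α (default 0.05) with a tumor effect < 1. Selectivity is
the TME effect minus the tumor effect. The screen table orders drugs by
anti-tumor effect with the strongest last (the figure convention;
configurable). Tumor effects can be computed on summed brightness or on
areas; area is the screen-overview default, brightness the dose-response
default. Note that the exact test is discrete: at n = 4 vs 4 the only
attainable p below 0.05 is 2/70 ≈ 0.029, so its true size is 1/35, slightly
below the nominal 5%.

## Dose-response and the therapeutic window

Curves normalize each dose to the dose-0 control per compartment and test
each dose against the control. The *first significant dose* of a
compartment is the lowest dose with p < α **and** a normalized mean below 1
(a reduction — significant increases do not count). The therapeutic window
runs from the first significant tumor dose to the largest tested dose
strictly below the first significant neuronal dose (or the top dose when
the neuronal compartment never responds); it exists when both bounds are
defined and ordered. Per-dose tests are unadjusted by default, mirroring
per-dose significance reporting; BH within the curve is available. An
optional Hill fit (top pinned at 1) reports EC50 for description only and
never gates the window. In the recovery benchmark the window is called at
per-dose α = 0.01: with the phantom's small measurement noise true onsets
test at p ~ 1e-4, so the stricter α suppresses false onsets at unaffected
doses at no cost in sensitivity.

## Cell-state classification and fidelity readouts

Counts are library-normalized to 10,000 per cell and log1p-transformed
(zero-count cells are dropped with a warning). The module score of a gene
set is the mean normalized expression of its genes minus the mean of
control genes sampled without replacement from expression-matched bins:
genes are ranked by mean expression and cut into 25 equal-size bins; each
signature gene draws up to 50 controls from its bin, seeded. Control pools
exclude the union of *all* scored signatures, not just the scored set —
rival programs' genes are repressed in the scored cells and would bias
every score upward if allowed as controls.

A cell's label is the argmax signature when the top score exceeds the
threshold (default 0: any positive enrichment wins), otherwise
*undifferentiated*; ties break by signature order. Cycle phase is S or G2M
when either score is positive (argmax), else G1; cycling = non-G1. The
default threshold works because programs are specific — in cells not
running a program its genes sit below their expression-matched controls, so
null scores are reliably negative. For data where that repression is weak,
raise the threshold (a value near 3 times the null-score SD, roughly 0.3–
0.5 at 30-gene signatures, separates cleanly at fold-change 4).

Pseudobulk profiles are per-condition means of *normalized* expression
(removing library-size confounding between conditions); fidelity is the
pairwise Pearson correlation over shared genes (optionally top-k variable).
Differential expression is per-gene two-sided rank-sum on normalized
expression with the tie-corrected normal approximation (count data are
tie-heavy), log2 fold change of group means with a pseudocount of 1, and BH
across tested genes; genes all-zero in both groups are excluded and
counted. Marker presence is the fraction of cells with expression > 0 per
(condition, state) subset; empty subsets report NaN, not 0. The signature
lists are user-supplied inputs (GMT or two-column text); the bundled
defaults are synthetic stand-ins used by the generators and tests, not
curated fetal-forebrain signatures.

## Synthetic generators

**Image phantoms.** The organoid is a sphere sampled anisotropically in z —
a circle per plane whose radius varies with depth, spanning all planes —
with spherical tumor foci placed entirely inside it (bounded rejection
sampling; an explicit geometry error when infeasible). When a target
`tumor_fraction` is set (default 0.12, 12 foci) a common focus radius is
derived from it, which keeps tumor volume nearly constant across organoids;
otherwise radii are drawn from a range. The tumor channel is
`tumor_intensity·(1-k_T)` inside foci plus a constant background inside the
organoid; the neuronal channel is `neuronal_intensity·(1-k_N)` in the
organoid outside foci plus the same background; outside the organoid the
noiseless image is zero. Noise is additive Gaussian clipped at zero — the
simplest model whose effect on summed brightness has closed-form variance
for tolerance setting. Defaults: 29 planes, 96×96, radius 36, intensities
200/150, background 10, noise SD 10, 4 organoids per group. Per-well seeds
derive from the master seed by stable hashing of the well id, so generation
is order-independent. Not modeled: point-spread function, clearing
artifacts, bleaching, multi-lineage TME — the phantom validates the
measurement mathematics, not optics.

**Count matrices.** Three conditions by default — primary tumor, the
organoid model (TBO) and tumorspheres — with 1000 cells each. Primary and
TBO share a balanced mix of RG-like/NProg-like/Nb-like/undifferentiated
(0.25 each); spheres are skewed to NProg-like (0.7) and accumulate cycling
cells (0.6 vs 0.2). Counts are negative-binomial (dispersion θ = 2) with
per-gene log-normal baselines around `baseline_mean` = 2 (σ_log = 0.6) and
a fixed expected library size of 5000, so empirical library sizes
concentrate around the target. Signature and cycle genes get a 3× baseline
boost (curated markers are chosen for robust detection) and programs are
specific: the running cell multiplies its program's genes by
`signature_fold_change` (default 4) while every other cell divides by it —
at fold change 1 all states collapse to an exact null. Cycling cells are
assigned S or G2M with equal probability and up-regulate that list.
Per-(condition, state) knockouts silence chosen genes, emulating marker
dropout in a model system. Not modeled: batch effects, ambient RNA,
doublets, continuous differentiation trajectories — so recovery results
bound what the classifier can do on clean data, not on real integration
problems.

## Problem sizes and numerical choices

Single-screen accuracy checks run on the default 29-plane phantom; the
large repeated campaigns (1000-drug type-I error, 200-run power, 100-run
window recovery) use a reduced geometry (15 planes, 64×64, radius 24) with
identical intensities, noise and tumor fraction, and the fidelity-ordering
campaign uses 300 cells per condition — sizes chosen so the full validation
runs in a few minutes on one CPU. Aggregate statistics use the n−1
denominator; a single-organoid group reports SD = SEM = 0 by policy. Mask
containment (tumor ⊆ organoid) is enforced structurally. All stochastic
steps are seeded; derived seeds are 31-bit hashes of (master seed,
identifier).

## Known limitations

* Thresholding assumes a tumor-positive intensity mode; with a fully
  ablated tumor the "tumor mask" is a noise split and only the shared-
  pedestal guard keeps the neuronal readout sane. Tumor-compartment ratios
  at kill fractions ≳ 0.9 are qualitative.
* The normalization SEM ignores control uncertainty; with very small
  control groups, effect error bars are optimistic.
* The exact rank-sum test's discreteness makes tiny-n type-I rates land on
  attainable levels (1/35 at n = 4 vs 4), not the nominal α.
* Signature scoring assumes signatures are broadly comparable in size and
  expression range; very small gene sets (< 10 genes) give noisy scores and
  deserve a positive assignment threshold.
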