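# Methods

`vncstudy` evaluates whether coronary calcium can be quantified on virtual
non-contrast (VNC) series derived from contrast-enhanced cardiac CT, using a
fully synthetic paired-series phantom in place of patient data. This note
records the model, its assumptions, the defaults, and what the results do and
do not show about real data.

## The paired-series model

Every synthetic patient is built from three additive Hounsfield-unit basis
maps on a fine base grid (default 0.5 mm in-plane, 0.2 mm along z over a
96 × 96 × 48 mm field of view):

* **water-equivalent tissue** — soft-tissue background (40 HU) and the
  unenhanced heart compartments (45 HU);
* **iodine** — the contrast enhancement added to the myocardium (+45 HU),
  right-ventricular pool (+205 HU) and left-ventricular pool (+405 HU);
* **calcium** — spherical coronary calcifications with a configurable core
  HU and a thin linear edge ramp.

The reconstructed series are linear views of sums of these maps:

| series | composition | thickness / increment |
|---|---|---|
| CTA | water + iodine + calcium | 0.4 / 0.2 mm |
| TNC | water + calcium | 3.0 / 1.5 mm |
| VNC_Conv_1..4 | water + *ρ* · calcium | 0.4/0.2, 0.4/0.2, 1.0/0.4, 1.0/0.4 mm |
| VNC_PC_1..4 | water + calcium + specks | same four settings |

with independent per-voxel Gaussian noise added per series (TNC 26 HU;
thin-slice VNC settings 1–2: 29 HU conventional / 32 HU calcium-preserving;
1.0 mm settings 3–4: 20 / 22 HU; CTA 15 HU). Slab reconstruction averages
the base maps over the slice thickness (a fixed interpolated-midpoint kernel
along z) before sampling at the increment, so overlapping slices such as the
3.0/1.5 mm reference behave like real thick-slice reconstructions,
including partial-volume dilution of small lesions.

**Heart geometry.** The heart mask is a left-ventricular sphere
(r ≈ 16 mm) with a thin myocardial shell (12.5 % of the cavity radius) and
a right-ventricular sphere (r ≈ 13 mm). The blood pools make up ≈ 78 % of
the mask, so the contrast series shows the expected trimodal histogram
(LV > RV > myocardium) and a supra-130-HU fraction near 0.8, while all
non-contrast series stay near zero. Coronary territories are four disjoint
boxes *outside* the heart mask, one per vessel (LM/LAD/CX/RCA); at this
phantom scale (heart ≈ 37 cm³ vs ≈ 600 cm³ in adults) in-heart lesions
would otherwise dominate the whole-heart histogram fraction, which in
patients they do not.

**Calcifications.** Hard spheres with a centered linear edge ramp whose
width defaults to the smallest base-grid spacing (0.2 mm). The width
matters: for a 400 HU lesion the 130 HU threshold sits at one quarter of
the edge ramp's height, so a ramp of width *h* moves the effective
thresholding radius to ≈ r + h/4. At h = 0.2 mm a radius-2 mm sphere
recovers its analytic 33.5 mm³ volume to within ≈ +10 % (thresholding
bloom); a full in-plane-voxel ramp (0.5 mm) would inflate it by ≈ +20 %.
Partial-volume voxels still arise in every direction because the ramp is
sampled on all three axes.

**The two VNC flavors.** Iodine is removed exactly in both (its
contribution to a VNC voxel is zero before noise). The conventional flavor
retains only a fraction *ρ* of the calcium excess; the template default is
ρ = 0.7, consistent with the ≈ 0.68 score ratio between derived and
reference medians that motivates the study. Crucially, the cohort sampler
draws *ρ* per patient from a clipped normal (SD 0.15, range 0.35–0.95):
in real reconstructions the conventional algorithm's calcium loss depends
on lesion composition and contrast timing and varies between patients, and
it is exactly this variability — not the systematic bias, which a
regression calibrates away — that limits the conventional flavor's
predictive accuracy. The calcium-preserving flavor keeps calcium intact
but adds a Poisson number (default rate 1 per series) of small spurious
specks (radius 0.7–1.2 mm, 160–300 HU) inside the vessel territories,
reproducing its tendency toward false-positive scores in calcium-free
patients.

**Cohort.** Default 20 patients: 15 % calcium-free, 25 % with a stented
vessel (the distal half of that territory is excluded from scoring on every
series), 2–14 lesions each with log-normal radii (median 1.5 mm, capped by
territory size) and uniform 160–800 HU peaks. Everything derives from one
master seed through named `SeedSequence` streams, so identical configs give
bit-identical volumes and byte-identical report tables.

## Image characterization

Series are resampled to an isotropic 1 mm frame (trilinear for images,
nearest-neighbor for masks; all series share one origin, so registration is
the identity) and cropped to the common overlap. Two measurements follow:

* **Iodine-removal efficacy** — the fraction of whole-heart-mask voxels
  strictly above 130 HU, computed on raw voxels so it is independent of the
  histogram binning (1 HU bins over −200…1500 HU by default).
* **Noise** — the HU standard deviation inside three 15-mm circular ROIs
  placed on distinct slices in the deepest part of the left-ventricular
  cavity (per-slice distance transform; seeded choice among the deepest
  positions) and copied unchanged to every registered series. The pooled
  value is the arithmetic mean of the three per-ROI SDs. Note that
  trilinear resampling attenuates the noise of coarse-z series somewhat
  (interpolated slices average neighbors), so recovered values sit slightly
  below the injected SDs; comparisons across series remain valid because
  all series pass through the same frame.

## Calcium scoring

Classical slice-wise Agatston scoring: voxels ≥ 130 HU (inclusive, the
Agatston convention — deliberately different from the strict `>` of the
histogram fraction; the two differ only on exactly-130 voxels) are grouped
into in-plane 8-connected lesions per slice; lesions below 1 mm² are
discarded; each lesion contributes area × weight (1–4 keyed to peak HU at
200/300/400). Because the phantom's series are not 3-mm reconstructions,
per-volume totals are multiplied by `z_increment / 3.0 mm`: overlapping
slices are not double-counted and thin slices are not over-counted, and the
factor reduces to 1 for a classical 3.0/3.0 mm series. The volume score is
qualifying-voxel count × in-plane area × increment. Vessels are assigned
by majority territory label with ties broken at the peak voxel.

The pipeline scores only inside the vessel territories dilated by 2 mm
(plus the stent exclusion). This emulates the reader-guided lesion
selection of semi-manual clinical software; without it, independent voxel
noise on ultra-thin slices would occasionally form supra-threshold clusters
anywhere in the volume, which no reader would click. Residual in-territory
noise clusters are rare and tiny, and they produce the occasional
false-positive classification that real VNC series also show.

## Statistics

* **Paired differences** — Shapiro–Wilk on the differences gates (α = 0.05)
  between the paired t-test and the Wilcoxon signed-rank test (zeros
  dropped). All-zero differences are reported as degenerate with p = 1.
* **Correlation** — Pearson and Spearman.
* **Regression** — ordinary least squares on square-root-transformed
  scores (variance-stabilizing for these right-skewed quantities), with r²
  reported on the transformed scale.
* **ICC(3,1)** — two-way mixed, consistency, single rater, from the ANOVA
  decomposition `(MS_subjects − MS_error) / (MS_subjects + (k−1) MS_error)`;
  a constant table is undefined and raises.
* **Bootstrap predictive accuracy** — per replicate: resample patients with
  replacement, fit OLS on (√VNC, √TNC), predict √TNC for *all original*
  patients, clip negative predictions to zero before squaring (scores are
  nonnegative; squaring a negative would silently inflate the error), and
  average |prediction − TNC|. 10,000 replicates; the distribution is
  summarized as median and quartiles (linear interpolation), matching a
  median-(IQR) reporting convention. Degenerate resamples (constant √VNC)
  are redrawn and counted. The conventional-vs-calcium-preserving
  comparison pairs replicates by index — both flavors of a setting use the
  same resample seed — and applies the Wilcoxon signed-rank test across
  replicates. Fitting on the resample and predicting the full original
  sample (rather than out-of-bag) keeps the prediction target fixed and
  deterministic.

## Problem sizes and defaults

The study runs at 20 patients on the 0.5 / 0.2 mm base grid with 10,000
bootstrap replicates; one full run takes a couple of minutes on one CPU and
stays under 1 GB by generating patients one at a time. These sizes are the
package defaults and what `scripts/acceptance.py` and the acceptance tests
use. Tests of individual operations use a ~48 mm phantom with the same
structure.

## What the phantom does and does not show

The generator reproduces the *statistical structure* the analysis relies
on: paired registered series, trimodal contrast histograms, near-complete
iodine removal, series-dependent noise, systematic and patient-variable
calcium loss in the conventional algorithm, spurious specks in the
calcium-preserving one, thick-slice partial volume in the reference. It
deliberately omits projection physics (beam hardening, motion, gating,
spectral noise correlations), realistic coronary geometry, and the vendor
algorithms themselves — the two VNC flavors are *emulations* whose
parameters were set so the known qualitative findings (underestimation,
excellent sqrt-scale correlation, better predictive accuracy of the
calcium-preserving flavor) are exercised by the pipeline rather than
assumed. Passing tests therefore validate the measurement pipeline and the
statistical machinery, and show that the emulated mechanisms are sufficient
to produce the reported behavior; they are not evidence about any
particular scanner.

Absolute scores depend on the declared thin-slice normalization and
minimum-lesion rule; vendor software does not document its conventions, so
cross-implementation comparisons should be made on quantities computed
under a single declared convention, as done here. Printed effective doses
in the source clinical protocol are inconsistent with their own stated
DLP × coefficient arithmetic; the package implements the stated formula
only.
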