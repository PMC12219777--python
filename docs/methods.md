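# Methods

## The measurement model

`deshvol` quantifies the DESH pattern on an ACPC-aligned, bias-corrected
T1-weighted volume in two steps: (1) construct anatomically defined search
volumes, (2) segment CSF within them by a global intensity threshold.
qDESH is the ratio of the segmented Sylvian-fissure CSF volume to the
segmented high-convexity CSF volume. The method assumes:

* the input is aligned to the AC–PC line and mid-sagittal plane, so that a
  coronal slice is a fixed `y` index and "superior" is a fixed axis
  direction (all arrays are held in RAS voxel order; non-canonical NIfTI
  orientations are permuted/flipped on load, never resampled);
* intensities are bias-corrected well enough that one global threshold
  separates CSF from gray matter everywhere inside the search volumes;
* landmarks (posterior commissure, Sylvian-fissure center height, medial
  limits, ventricle seed) are supplied by the user — the workflow is
  semiautomatic and deliberately avoids atlas registration or learned
  segmentation.

## Geometry rules and their numerical conventions

* **Coronal band.** Voxels whose y-center lies in `[y_PC, y_PC + L)` with
  `L = 20 mm` by default. The half-open convention includes the PC slice
  and excludes the far edge, so at 1 mm spacing the band is exactly 20
  slices. Both the high-convexity and Sylvian search volumes are confined
  to this band; confining the high-convexity volume to the band (rather
  than the whole head) keeps both ratio terms on the same anatomical slab.
* **High convexities.** Inside `intracranial ∩ band`, whole axial layers
  are accumulated from the most superior layer downward while the running
  volume is below the 30 cm³ target; the layer that reaches the target is
  included iff that leaves the achieved volume closer to the target.
  Layer granularity (rather than picking part of a layer) keeps the
  construction anatomically meaningful; the achieved volume — within one
  layer of the target by construction — is always reported.
* **Sylvian fissures.** Per hemisphere: `band ∩ head`, z within ±10 mm
  (inclusive) of the fissure center height (21 axial layers at 1 mm), and
  x lateral-of-or-equal to the medial limit. The head mask's border (the
  dura) is the outer limit. The left limit must lie medial-ward of the
  right one, which makes the two hemispheric regions disjoint without an
  explicit midline.
* **Lateral ventricle.** 6-connected flood fill of
  `{intensity < threshold}` from the seed; face connectivity prevents
  diagonal leakage through thin walls. Its volume is reported for
  correlation-style analyses but never enters the ratio.

## Thresholding

The histogram is built with 256 equal-width bins spanning `[min, max]` of
the intensities inside the union of all three search volumes (the
ventricle's pure CSF pool stabilizes the CSF peak), then smoothed with a
5-bin moving average. The CSF and GM modes are the two most prominent
local maxima of the smoothed histogram (topographic prominence; ties
broken toward the more extreme intensity; edge bins may be peaks). The
threshold is the arithmetic mean of the two peak bin centers, and a voxel
is CSF iff its intensity is *strictly below* it (the comparison direction
at the boundary is a convention; with float intensities it is almost
surely irrelevant). Bin count and window are configurable and echoed into
the result JSON. Every step is affinely equivariant, so the threshold of
`a·I + b` equals `a·T + b` to within one bin width and qDESH is invariant
under positive affine intensity rescaling.

The ventricle flood fill needs a threshold before the final one (defined
over all three volumes) exists. The pipeline therefore computes a
provisional threshold from the Sylvian + high-convexity union, grows the
ventricle with it, and then recomputes the definitive threshold over the
full union for all reported segmentations. On well-separated histograms
the two thresholds classify identically.

## Per-slice profile

For each coronal slice of the band the pipeline reports the slice's SF and
HC CSF volumes and their ratio `qDESH_slice`; a slice with zero HC CSF is
flagged undefined (JSON `null`), never imputed, and excluded from the
mean/SD summary. Slice volumes sum exactly to the global volumes (integer
voxel-count conservation).

## The phantom generator

The phantom emulates exactly the image features the pipeline consumes: an
intracranial envelope (prism in the presets; ellipsoid supported) filled
with a bright GM-like class, dark CSF compartments — paired Sylvian slabs
reaching the lateral dura, thin vertical convexity sheets reaching the
vertex, an interior ventricle blob — a dark background, and seeded i.i.d.
Gaussian noise. Two tissue classes suffice because the threshold uses only
the CSF and GM peaks. There is no cortical folding, white matter,
partial-volume blur, bias field, or scanner artifact; consequently,
passing tests demonstrate the correctness of the geometric construction,
thresholding, and accounting — not robustness to real-MRI confounds such
as partial-volume CSF underestimation at low resolution.

Presets share a 96×64×80 grid at 1 mm isotropic spacing with PC at voxel
(48, 20, 30); inside the band every axial layer holds exactly 1500 mm² of
intracranial cross-section, so the 30 cm³ rule selects exactly 20 layers
and noiseless oracles are exact. `control` (true qDESH ≈ 0.61) and `inph`
(true qDESH = 2.5) reproduce the clinical ordering (below vs above the
conventional cutoff of 1.0), not any cohort's values. Default intensities
are CSF 100 / GM 300 / background 0; noisy experiments use noise SD 20,
i.e. 10% of the CSF–GM gap, as the standard stress condition. The ground
truth `true_qdesh` is the compartment ratio after restriction to the
rule-based search geometry built from the noiseless head mask — what a
perfect segmentation would measure.

Rater variability is simulated by dilating/eroding each connected region
of the SF and HC search masks by a random whole-voxel amount bounded by a
magnitude in mm (the dura stays the outer limit); cohort simulation draws
per-subject slab/sheet dimensions from fixed ranges around the presets.

## Validation statistics

* **ICC(A,1)** — two-way model, absolute agreement, single measures, from
  the ANOVA mean squares
  `(MSR − MSE) / (MSR + (k−1)MSE + (k/n)(MSC − MSE))`, with the F-based
  confidence interval of McGraw & Wong and the F = MSR/MSE significance
  test. Perfect agreement returns a degenerate interval at 1.
* **Bland–Altman** — mean difference, mean ± 1.96·SD (n−1 denominator)
  limits of agreement, and the least-squares slope of difference on
  average as a proportional-bias check.
* **AUC** — the normalized Mann–Whitney U; ties count ½ (so the AUC
  equals exhaustive pair counting exactly). **DeLong** variance comes from
  the structural components (per-positive and per-negative mean placement
  values); the CI is normal-approximate and clipped to [0, 1]; the paired
  test uses the structural-component covariance, returning p = 1 when the
  AUC difference and its variance are both zero (identical or monotonically
  related scores).
* **Cutoff statistics** — sensitivity counts positives at or above the
  cutoff (high qDESH indicates iNPH), specificity negatives strictly
  below it.

Standard omnibus/correlation tests (Mann–Whitney as a test,
Kruskal–Wallis, Shapiro–Wilk, Pearson/Spearman) are left to scipy/pandas
and not wrapped.

## Problem sizes and degenerate inputs

Test and acceptance runs use the 96×64×80 presets (≈0.5 M voxels), 20
noisy phantoms per preset for recovery, 30 subjects for the rater study,
20 + 20 for the cohort, 500 null replicates for the DeLong test size and
200 for CI coverage — sizes at which every Monte-Carlo check is stable
across seeds while the whole suite runs in seconds. Degenerate inputs
fail loudly with specific messages: empty or constant-intensity masks,
unimodal histograms, a non-CSF flood-fill seed, a head too small for the
requested high-convexity volume, zero high-convexity CSF in the ratio
(an explicit error, never a silent infinity), and constant rating
matrices.

## Known limitations

* The histogram peak-finding parameters (bin count, smoothing window) are
  reasonable defaults, not a bit-for-bit match of any particular clinical
  implementation; results on real data may differ at the one-bin level.
* Whether the high-convexity 30 cm³ region should span the whole head
  rather than the 20 mm band is an open interpretation; the band-confined
  choice is implemented and documented above.
* The phantom's two-class model cannot exercise partial-volume effects,
  which in real low-resolution data bias V_CSF-HC downward (and hence
  qDESH upward) in tight convexities.
* Flood fill relies on the ventricle being separated from other CSF by at
  least one supra-threshold voxel wall; severe noise or pathology could
  merge compartments.
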