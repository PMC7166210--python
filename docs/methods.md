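# Methods

This note documents the models behind each stage, the parameters that
matter, the numerical choices, and what the synthetic phantom does and
does not establish about real histological material.

## The phantom

The generator emulates the inputs of a multimodal post-mortem mapping
study: per-subject 3-D label volumes of ten contiguous hippocampal
regions, the serial-section contours an anatomist would trace on a
sampled subset of sections, and film autoradiographs with co-exposed
radioactivity standards.

**Geometry.** In every section plane the phantom shows two interlocking
C-shaped band stacks around a common centre: the inner C carries the
hippocampus proper (FD innermost, then CA4, CA3, CA2, CA1) and the outer
C the subicular complex (ProS, Sub, PreS, PaS, TrS outermost); the two
Cs open towards opposite poles. The pattern is swept along the
sectioning axis with an ellipsoidal in-plane taper (half-length 12 mm),
so cross-section areas vary smoothly and close at the poles. Radial band
thicknesses (default 1.2, 0.5, 0.6, 0.5, 1.8, 0.7, 0.9, 0.7, 0.5,
0.5 mm, FD → TrS) were chosen so regional volumes span the relative
sizes seen in human material — CA1 and FD large, CA4 and the small
subicular fields an order of magnitude smaller — and so every band spans
at least two voxels at the default 0.25 mm grid. A 13 mm-radius
ellipsoid around the structure serves as the whole-"brain" mask for
volume normalization; it is a miniature stand-in, so normalized
fractions are larger than in real brains but behave identically under
scaling.

**Inter-subject variability.** Each subject applies a random similarity
transform to the canonical geometry: rotation up to ±5° about a random
axis, isotropic scale within ±5%, translation up to ±2 mm. No published
quantitative deformation magnitudes exist for this kind of material, so
these jitter defaults are free parameters chosen small enough that
template overlap without elastic registration remains meaningful (the
point of the probabilistic maps), yet large enough that overlap
fractions are graded rather than binary. Elastic registration is
deliberately out of scope; the known inverse similarity transform plays
the role of spatial normalization.

**Shrinkage.** Each brain draws a volume shrinkage factor s uniformly
from (0.7, 0.9) — the range typical of formalin fixation plus paraffin
embedding — and the whole geometry is scaled by s^(1/3). Ground-truth
volumes are recorded both as generated ("histological", by voxel count ×
voxel volume) and with the factor divided out ("fresh").

**Film model.** Gray value = g0 + g_max·(1 − exp(−gain·activity)), with
g0 = 10, g_max = 200, gain = 0.002 per fmol/mg: monotone, saturating and
invertible, the qualitative behaviour any calibration must handle.
Activity is taken proportional to binding-site density with unit
proportionality, so standards are expressed directly in density units.
Eight standards (0–800 fmol/mg) are rendered through the same response
into a margin strip; Gaussian gray noise (default sd 2, i.e. 1% of
g_max) is added everywhere. Real film physics (tritium quenching,
exposure-time effects) is not modelled.

**What passing tests show.** Recovery on the phantom establishes the
correctness of the estimators — Cavalieri summation, overlap counting,
argmax tie rules, calibration inversion — under known geometry and
noise. It does not establish robustness to the failure modes of real
histology: section tears and folds, delineation error, staining
inhomogeneity, non-rigid distortion beyond a similarity transform, or
film artifacts. All generators are pure functions of (spec, seed).

## Volumetry

Cavalieri estimate: V(r) = d · Σ A(r, k) over mapped sections, d =
section thickness × mapping interval (default 0.020 mm × 60 = 1.2 mm).
Only mapped sections enter the sum — borders exist only there.
Per-section area uses even-odd containment parity over the region's
closed contours, so a ring nested inside another counts as a hole; with
no nesting this is the plain polygon-area sum. Contours are extracted by
marching squares at the 0.5 iso-level of the binary region mask, giving
sub-voxel boundary interpolation; degenerate slivers (< 3 distinct
points or zero area) are dropped.

Accuracy: against the analytic sphere, the estimate at d = 0.3 mm is
within 0.1%; against voxel-count ground truth on the phantom at
d = 1.2 mm, within the Riemann bound d × TV(A) (TV = total variation of
the area profile) and empirically within ~2.5% per region. The
section-sampling error decreases monotonically with d once the
in-plane discretization bias (common to all spacings) is factored out.

Shrinkage correction multiplies every volume — regional and total brain —
by f = V_fresh/V_histological, so correction commutes with
normalization; a table can be corrected only once. The summary table
reports mean ± sd (n−1 denominator) in total, per hemisphere and per
sex, where the total and sex groupings use each subject's mean of left
and right; with equal-sized sex groups the grand mean therefore equals
the average of the sex-group means. Display rounds to integer mm³; full
precision is retained internally.

## Atlas maps

Nearest-neighbour pull-back is the only label interpolation: any
fractional scheme would invent labels and destroy the exact k/N
quantization of overlap fractions. Probability maps store k/N as
floating point with N recorded.

The MPM assigns every voxel with positive maximal probability (and, if a
threshold is configured, max ≥ threshold; default 0, optionally 0.4) to
the argmax region. Tie rule: (1) larger mean probability over the
26-neighbourhood, computed as the integer sum of subject counts over the
26 neighbours (centre excluded, zero-padded at grid edges, fixed divisor
26) — integer counts make the comparison immune to float summation
order; (2) lower region code. Both the threshold and the tie rule are
package conventions, logged with every run; whether the original
mapping applied an assignment threshold is not documented, so both
behaviours are exposed and neither claimed as original.

Overlap statistics at cut q summarize {v : p(v) ≥ q, p(v) > 0}: voxel
count, volume, and probability-weighted centre of gravity in template mm
(restricting to positive support keeps the q = 0 count meaningful).

## Permutation statistics

Tests operate on volumes normalized to fractions of total brain volume.
Between-subject design (sex): statistic = difference of group means;
null draws re-split the pooled values into groups of the original sizes,
independently with replacement over the permutation group (matching a
randomized — not exhaustive — procedure). Within-subject design
(hemispheres): statistic = mean paired difference; null draws flip each
pair's sign independently. Defaults: 10⁶ draws, Bonferroni over the 10
regions at family α = 0.05.

p uses the add-one estimator (1 + b)/(1 + B), which can never return 0
and is slightly conservative. Tied statistics count as "as extreme",
with a 10⁻⁹ relative tolerance on the comparison so that ties are not
lost to summation-order rounding — essential when inputs are small
fractions and the permutation distribution is highly discrete.
The significance criterion "observed exceeds 95% of the null" reads as
one-sided; the default here is two-sided (direction not known a priori)
with `alternative="one_sided_greater"` / `--one-sided` as the literal
rule. Exhaustive enumeration (all splits, or all 2ⁿ sign patterns) is
provided for n ≤ 16 and is the oracle the Monte-Carlo path is tested
against.

Calibration: with 5/5 groups the two-sided permutation distribution has
at most 126 distinct magnitudes, so the smallest attainable two-sided p
(~0.008) exceeds the Bonferroni threshold 0.005 — the corrected suite is
strongly conservative at this sample size, and the measured family-wise
error rate over 500 simulated null cohorts (2,000 permutations each) is
far below 0.05. These replicate counts are the package's standard
verification sizes; they complete in seconds.

An interaction test between hemisphere and region is not implemented:
no defensible test statistic is documented for it, and guessing one was
rejected.

## Receptor densitometry

Calibration fits gray = g0 + g_max·(1 − exp(−k·density)) to the
standards by least squares (either film polarity accepted); if the
parametric fit fails or is non-monotone, a shape-preserving monotone
(PCHIP) interpolation through the standards is used, after enforcing
monotonicity and collapsing duplicate knots. Standards that reverse
direction by more than 2% of the gray range (configurable) are rejected
with diagnostics rather than silently smoothed. Linearization clips
image grays to the calibrated range with a warning — extrapolating a
saturating response is unreliable — then applies the inverse transform
pixelwise. With 2% gray noise and 8 standards, per-region recovered
densities are within 5% median absolute relative error on synthetic
sections.

Specific binding = total − non-specific (floored at 0). When the
non-specific image is absent, total is used as specific: the shortcut is
justified only when non-specific binding is below 5% of total, so when
both images are present the mean-level fraction is computed and flagged
at ≥ 5%.

Regional means are pixel-count-weighted over all of a region's layers
(equivalent to direct averaging over the region's pixels); an unweighted
layer-mean option exists since the original averaging convention is not
documented. Fingerprints aggregate per-subject regional means over the
15-receptor panel: mean and SEM (sample sd / √n; n = 1 gives SEM 0 by
convention, flagged by the recorded n). Fingerprint comparison metrics —
size = difference of panel means, shape = Euclidean distance between
unit-mean-scaled vectors — are explicit package conventions, not
reconstructions of any published metric.

## Degenerate inputs and tie-breaks (summary)

- Label 0 is background everywhere; codebook validation reports stray codes.
- Regions absent from all mapped planes are omitted with a warning;
  regions with zero contours report 0 mm³ with a warning.
- Double shrinkage correction raises; missing total brain volume raises
  naming the subject; missing summary cells raise listing them.
- MPM ties: neighbourhood count sum, then lower code; empty pmap set raises.
- Empty suprathreshold sets return count 0 with an undefined-centroid flag.
- Calibration requires ≥ 4 distinct standards; saturated densities set a
  warning flag in the simulation truth record.

## Verification problem sizes

The test suite and acceptance script run entirely on generated data:
one full-resolution phantom (128³ voxels at 0.25 mm) for volumetry, a
6-subject coarse cohort (64³ at 0.5 mm) for atlas maps, 500 null cohorts
× 2,000 permutations for test calibration, 200 replicates for SEM
convergence, and 5×5×5 random grids for the brute-force map oracles.
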