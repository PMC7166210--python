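# hippomap

Quantitative workflow for multimodal mapping of the human hippocampal
formation: Cavalieri volumetry of serially sectioned, expert-delineated
regions; continuous probabilistic maps and maximum probability maps
(MPMs) in a common template space; Monte-Carlo permutation tests for
hemisphere and sex effects; and receptor-autoradiography densitometry
culminating in 15-receptor regional fingerprints.

It is aimed at neuroanatomists and imaging scientists who work with
post-mortem histology pipelines: delineations traced on a sampled subset
of serial sections, per-brain shrinkage correction, multi-subject
aggregation into a stereotaxic atlas, and radioligand film densitometry.
Because real material of this kind cannot be redistributed, the package
ships a first-class phantom generator so that every stage is testable
end-to-end against known ground truth.

## Methods at a glance

**Cavalieri volumetry.** For a region r traced on mapped sections with
spacing d = (section thickness) × (mapping interval),

&nbsp;&nbsp;&nbsp;&nbsp;V(r) = d · Σₖ A(r, k),

where A(r, k) is the region's profile area on mapped section k
(planimetric area of its closed contours, with nested rings counted as
holes). With 20 µm sections and every 60th section mapped, d = 1.2 mm.
Volumes are corrected per brain by f = V_fresh / V_histological and, for
statistics, expressed as fractions of that brain's total volume.

**Probabilistic maps and MPM.** After nearest-neighbour resampling of
each subject's label volume onto the template grid, the continuous map
of region r is p_r(v) = (# subjects whose region r covers voxel v) / N —
exactly quantized to multiples of 1/N. The MPM assigns each voxel to
argmax_r p_r(v) (ties: larger 26-neighbourhood mean probability, then
lower region code), producing a contiguous non-overlapping parcellation.

**Permutation tests.** Sex effects: difference of group means with the
null built by randomly re-splitting the pooled subjects (10⁶ draws by
default). Hemisphere effects: mean paired difference with per-subject
random sign flips. Monte-Carlo p = (1 + b)/(1 + B); Bonferroni across
the 10 regions.

**Receptor densitometry.** Co-exposed plastic standards of known
activity define a monotone transformation curve between film gray values
and binding-site density (fmol/mg protein; saturating-exponential fit
with a monotone-interpolation fallback). Linearized images yield
pixel-count-weighted regional means; a region's *fingerprint* is its
vector of mean densities over the 15-receptor panel (AMPA … D1) with
SEM, comparable by overall size and unit-mean-scaled shape.

## Worked example

```python
import numpy as np
from hippomap import synthetic_data as sd, volumetry, stats
from hippomap.core_io import RegionCodebook

# one phantom brain: 10 interlocking curved regions, known ground truth
spec = sd.PhantomSpec(seed=42)
volume, record, truth = sd.make_phantom_subject(spec, "B01", "female")

# 20 µm sections, every 60th mapped -> d = 1.2 mm
stack = sd.slice_to_contours(volume, thickness=0.020,
                             mounting_interval=15, mapping_interval=60)
est = volumetry.cavalieri_volume(stack)

cb = RegionCodebook.canonical()
print(f"mapped-section spacing: {stack.section_spacing_mm:.1f} mm")
print(f"shrinkage factor: {truth.shrinkage_factor:.3f}")
for code in (5, 1, 2):
    corrected = est[code] / truth.shrinkage_factor
    print(f"{cb.name_for(code):4s} Cavalieri {est[code]:7.1f} mm^3   "
          f"corrected {corrected:7.1f}   fresh truth {truth.fresh_volumes_mm3[code]:7.1f}")

# sex comparison on normalized volume fractions
male   = [4.1e-4, 3.6e-4, 3.9e-4, 3.3e-4, 4.0e-4]
female = [4.6e-4, 4.3e-4, 4.8e-4, 4.1e-4, 4.4e-4]
res = stats.permutation_test_between(male, female, n_perm=100_000, seed=1)
print(f"observed male-female difference: {res.observed_stat:+.2e}  p = {res.p_value:.4f}")
```

prints

```
mapped-section spacing: 1.2 mm
shrinkage factor: 0.821
CA1  Cavalieri   811.3 mm^3   corrected   988.7   fresh truth   990.8
FD   Cavalieri   247.0 mm^3   corrected   301.0   fresh truth   302.4
CA4  Cavalieri   135.6 mm^3   corrected   165.3   fresh truth   166.7
observed male-female difference: -6.60e-05  p = 0.0162
```

The Cavalieri estimates at 1.2 mm spacing sit within ~1% of the
generator's fresh-tissue ground truth once the known shrinkage factor is
divided out; the permutation p-value is the add-one Monte-Carlo estimate
of how often a random re-split of the ten subjects produces a mean
difference at least as extreme as the observed one.

The same stages are scriptable from the shell:

```sh
hippomap simulate --n-subjects 10 --seed 3 --out cohort/
hippomap volumes --contours cohort/P01_contours.json --out volumes.csv
hippomap stats --volumes volumes.csv --design sex --subjects subjects.csv \
               --n-perm 1000000 --seed 5 --out decisions.csv
hippomap pmap --volumes t1.nii.gz --volumes t2.nii.gz --out pmaps/
hippomap mpm --pmaps pmaps/pmap_region05.nii.gz --n-subjects 10 --out mpm.nii.gz
hippomap receptors fingerprint --densities densities.csv --region 5 \
               --out fp.csv --plot fp.png
```

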