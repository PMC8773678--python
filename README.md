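# ctinfarct

Automated detection of cerebral infarcts on non-contrast head CT.

Ischemic stroke shows up on CT as a subtle *hypodensity* — a small drop in
Hounsfield units (HU) inside brain tissue whose normal contrast is already
tiny (CSF ≈ 0 HU, white matter ≈ 25 HU, gray matter ≈ 35 HU). `ctinfarct`
implements a statistical detection pipeline for volumes that have been
spatially normalized onto a common template grid (181×217×181, 1 mm):

1. **Contrast-enhancing intensity transformation.** A continuous,
   invertible piecewise-linear map sends HU ∈ [−1000, 1000] onto
   [0, 4000], magnifying the soft-tissue band 11-fold:
   `HU+1000` on [−1000,−100] → [0,900], `11·HU+2000` on (−100,100] →
   (900,3100], `HU+3000` on (100,1000] → (3100,4000].
2. **Statistical skull/CSF elimination.** Whole-brain mean and SD of the
   positive voxels define thresholds at mean ± 2·SD; voxels below are
   tagged ventricle/CSF, above skull, and both are zeroed, leaving the
   parenchyma.
3. **Mask-aware Gaussian smoothing** (5-mm FWHM).
4. **Normative t-score map.** A lesion-free control cohort gives
   voxel-wise mean X̄_C and sample SD s_C maps; a patient voxel p becomes
   the Crawford–Howell single-case statistic

       t = (p − X̄_C) / ( √((n+1)/n) · s_C )

   so infarcts appear as strongly negative t.
5. **Patch CNN.** Each axial slice is tiled into non-overlapping 16×16
   t-score patches (tiles leaving the parenchyma or entering the
   ventricles are discarded); a 17-layer CNN (3× conv–batchnorm–ReLU–maxpool,
   fully connected → dropout → softmax) classifies every tile as infarcted
   or not. Training data are augmented by shifting each patch along the 8
   compass directions, rejecting shifts that flip the label or leave the
   parenchyma, then class-balanced and split 80/20.
6. **Reporting.** Detected tiles are drawn as red rectangles on the
   t-score map and can be named anatomically by pure coordinate lookup in
   an atlas label volume.

No clinical imaging data are shipped; a seeded **digital phantom module**
generates control cohorts and lesioned patients (nested ellipsoid head
geometry, tissue-specific HU, planted hypodense sphere-union lesions with
ground-truth masks) so the whole pipeline runs end to end out of the box.

## Worked example

```python
import ctinfarct as ci
from ctinfarct import pipeline

spec = ci.PhantomSpec(shape=(48, 56, 48), voxel_size_mm=(4.0, 4.0, 4.0), seed=7)
lesions = ci.LesionSpec(count=1, radius_range_mm=(16.0, 16.0),
                        decrement_range_hu=(15.0, 15.0), seed=8)

controls = [ci.generate_control(spec, 1000 + i) for i in range(10)]
model = pipeline.build_model_from_controls(controls)

patient, lesion = ci.generate_patient(spec, lesions, 2000)
tmap = pipeline.patient_tscore_map(patient, model)
```

prints, for the bundled seeds:

```
normative model: n=10, valid voxels=36840
lesion voxels: 372
mean t inside lesion:  -7.78
mean t outside lesion: -0.05
adopted 16x16 tiles: 46 (8 overlap the lesion)
```

A 15-HU hypodense lesion, invisible to the eye at this noise level, sits
almost 8 control standard deviations below the normative mean after the
11× contrast magnification and smoothing, while healthy parenchyma stays
near t = 0 — this separation is what the patch CNN learns. The full
pipeline is also scriptable from the shell:

```sh
ctinfarct simulate-cohort --out cohort --seed 1
ctinfarct build-normative --cohort cohort --out nm
ctinfarct extract-patches --cohort cohort --model nm --out ds --seed 1
ctinfarct train --patches ds --out cnn.npz --seed 1
ctinfarct detect --patient cohort/patient_000.nii.gz \
    --model cnn.npz --normative nm --out detections.csv
ctinfarct report --patient cohort/patient_000.nii.gz \
    --model cnn.npz --normative nm --out report/
```

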