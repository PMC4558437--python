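# srrquant

Automated quantification of the **striatal-to-reference ratio (SRR)** in
dopamine-transporter SPECT (e.g. [99mTc]-TRODAT), for researchers evaluating
Parkinson's disease (PD) imaging biomarkers.

Striatal DAT loss is the imaging hallmark of PD.  Because absolute activity
concentration is hard to calibrate in SPECT, uptake is expressed as the ratio
of mean striatal intensity to mean intensity in a cortical reference region:

```
SRR = mean(I, striatal VOI) / mean(I, reference VOI)        (SUR = SRR − 1)
```

The package implements a fully automatic pipeline built around an
**inverse-transformed VOI** strategy:

1. **Normal template** — healthy-control scans are spatially normalized and
   averaged into a template; striatal VOIs are segmented at 60% of the
   template maximum (caudate + putamen merged per side) and a cortical
   reference VOI is taken from an integer label volume.
2. **Spatial normalization** — a 12-parameter affine plus a low-frequency
   3-D cosine-basis (DCT) displacement field, minimizing SSD with a
   bending-energy penalty (16 Gauss–Newton iterations, unit regularization,
   8-mm FWHM source smoothing, no template smoothing).
3. **Inverse VOI mapping** — the transform is inverted (closed-form affine,
   fixed-point warp inversion) and the template VOIs are pulled back onto the
   *untouched native image*, where the SRR is computed.  The symptomatic
   side selects the contralateral striatum; bilateral or absent symptoms use
   both sides.  A conventional pipeline (VOIs applied to the spatially
   normalized image) is provided for paired comparison.
4. **Diagnostics** — Mann–Whitney ROC analysis (low SRR = diseased), Youden
   optimal cutoff, sensitivity/specificity/accuracy, McNemar's paired χ²,
   Welch's t-test.
5. **Duration model** — PD subjects binned by whole years of clinical
   duration (bins with < 10 subjects dropped), a quadratic fit
   `y = a·x² + b·x + c` of mean SRR on duration, and extrapolation to the
   healthy-control mean SRR to estimate the preclinical period.

No patient data ship with the package: a digital phantom generator (brain
ellipsoid, cortical ribbon, bilateral striatal foci, scalp shell, Gaussian
PSF, intensity-proportional noise, rigid/affine pose and smooth warp
perturbations) and a Gaussian cohort simulator provide fully synthetic,
seeded test data.

## Worked example

```python
import numpy as np
from scipy import ndimage
import srrquant as sq
from srrquant.volumes import VOIMask

# a synthetic subject with known striatum/cortex contrast 2.0, off-pose
spec = sq.PhantomSpec(psf_fwhm_mm=0.0, contrast_left=2.0, contrast_right=2.0,
                      translation_mm=(4, -3, 2), rotation_deg=(2, -3, 4),
                      warp_amplitude_mm=3.0, seed=11)
subject = sq.make_phantom(spec)

# template + VOIs from the generator's ground truth (eroded to the core)
canonical = sq.make_phantom(sq.PhantomSpec(psf_fwhm_mm=8.0))
template = sq.gaussian_smooth(canonical.volume, 8.0).copy_with(space="template")

def core(mask):
    return ndimage.binary_erosion(mask.data, np.ones((3, 3, 3)))

aff = template.affine
bundle = sq.TemplateBundle(
    template=template,
    striatum_left=VOIMask(core(canonical.masks_template["striatum_left"]), aff,
                          "template", "striatum_left"),
    striatum_right=VOIMask(core(canonical.masks_template["striatum_right"]), aff,
                           "template", "striatum_right"),
    reference=VOIMask(core(canonical.masks_template["reference"]), aff,
                      "template", "reference"))

rec = sq.run_subject_pipeline(subject.volume, bundle, side="none")
print(f"SRR = {rec.srr:.3f}")
```

prints `SRR = 2.000` — the pipeline recovers the true anatomical contrast of
the noiseless phantom despite the pose and warp perturbation.  The
statistical layer works the same way:

```python
df = sq.draw_srr_cohort(sq.default_cohort_spec(seed=0))
roc = sq.roc_analysis(df[df.group == "PD"].srr_true,
                      df[df.group != "PD"].srr_true)
print(f"AUC = {roc.auc:.3f}, cutoff = {roc.optimal_cutoff:.2f}")
```

prints `AUC = 0.976, cutoff = 1.73` for that single cohort draw; averaging
over 200 cohort replicates gives AUC ≈ 0.949 (the replicate average is what
the acceptance script reports).

A command-line interface mirrors the library:
`srrquant simulate | build-template | quantify | evaluate | duration`.

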