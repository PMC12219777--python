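# deshvol — quantitative DESH (qDESH) volumetry

Disproportionately enlarged subarachnoid space hydrocephalus (DESH) —
tight CSF spaces at the cerebral high convexities combined with dilated
Sylvian fissures — is a key radiological sign of idiopathic normal
pressure hydrocephalus (iNPH). Radiologists usually grade DESH visually,
which limits reproducibility. `deshvol` implements a quantitative,
landmark-based alternative for researchers working with ACPC-aligned,
bias-corrected 3D T1-weighted MRI:

```
qDESH = V_CSF-SF / V_CSF-HC
```

where `V_CSF-SF` is the CSF volume segmented inside the Sylvian-fissure
search volume and `V_CSF-HC` the CSF volume inside the high-convexity
search volume. The search volumes follow fixed geometric rules relative to
the posterior commissure (PC):

* a **coronal band** from the PC to 20 mm anterior of it (half-open; the
  PC slice is included) confines both search volumes;
* the **high-convexity** search volume is the topmost cranial 30 cm³ of
  combined CSF + brain within the band, accumulated whole axial layers at
  a time from the vertex down;
* the **Sylvian-fissure** search volume spans ±10 mm (the opercular
  margin) around the fissure's center height per hemisphere, lateral to a
  medial limit at the lateral-most cerebellar convexity, with the dura as
  outer limit;
* a **lateral-ventricle** volume is grown by 6-connected flood fill from a
  seed voxel (reported, but not part of the ratio).

CSF is segmented with a single subject-specific global threshold: the
intensity midway between the CSF and gray-matter peaks of the
moving-average-smoothed histogram over the union of all three search
volumes; voxels strictly below the threshold count as CSF. qDESH > 1
indicates Sylvian CSF out of proportion to convexity CSF — the DESH
pattern. A per-slice profile (`qDESH_slice` per coronal mm) quantifies how
strongly a single-slice assessment depends on slice position.

The package also ships the statistics used to validate such a biomarker —
ICC(A,1) with F-based confidence interval, Bland–Altman limits of
agreement, AUC in its Mann–Whitney form with DeLong confidence intervals
and the DeLong test for correlated ROC curves, and cutoff
sensitivity/specificity — plus a synthetic head-phantom generator with
exact ground truth (known compartment volumes and true qDESH) and
simulators for rater variability and labeled cohorts.

## Worked example

```python
import deshvol as dv

spec = dv.preset("inph", noise_sd=20.0, seed=42)   # iNPH-like phantom
image, truth = dv.generate_phantom(spec)
result = dv.run_pipeline(image, spec.search_spec(),
                         intracranial_mask=truth.masks["head"])
print(result.v_csf_sf, result.v_csf_hc, result.qdesh)
```

Running `python examples/01_phantom_qdesh.py` (the same computation with
commentary) prints:

```
global CSF threshold :   199.27 (CSF peak 99.1, GM peak 299.4)
V_CSF-SF             :    1.200 cm^3 (truth in search volume 1.200)
V_CSF-HC             :    0.480 cm^3 (truth in search volume 0.480)
V_LV                 :    9.072 cm^3 (true ventricle 9.072)
HC search volume     :   30.000 cm^3 (target 30)
qDESH                :   2.5000 (true 2.5000)
```

The threshold lands midway between the phantom's CSF (100) and GM (300)
intensities despite 10% noise; every measured volume matches the ground
truth, and the measured qDESH of 2.5 (Sylvian CSF 2.5× the convexity CSF)
equals the phantom's true ratio. The other examples cover the per-slice
profile (`02`), interrater reliability (`03`) and ROC analysis (`04`).

The same pipeline is available from the shell:

```bash
deshvol phantom --preset inph --seed 42 --noise-sd 20 \
    --out img.nii.gz --truth-dir truth/ --truth-json truth.json
deshvol compute --t1 img.nii.gz --pc 48,20,30 \
    --intracranial truth/head.nii.gz \
    --sf-center-z L:30,R:30 --medial-x L:38,R:57 --lv-seed 47,30,16 \
    --out result.json --profile-csv profile.csv
```

For real data, supply the PC voxel coordinate, an intracranial
(CSF + brain) mask, the per-hemisphere Sylvian center heights and medial
limits (or pass manually drawn NIfTI ROIs via `--roi-dir`), and a
ventricle seed — the workflow is semiautomatic by design.

## Scope

Bias-field correction and ACPC alignment are assumed done upstream;
automatic landmark detection, visual DESH grading, and linear indices
(Evans index, callosal angle, etc.) are out of scope. Phantom presets
reproduce the qualitative ordering (control < 1 < iNPH-like), not any
clinical cohort's values — see `docs/methods.md` for what the phantom does
and does not emulate.
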