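# autoidif

Fully automated **image-derived arterial input functions** (IDIF) for
dynamic PET from simultaneous PET/MR angiography.

Quantitative PET kinetic modeling (e.g. cerebral blood flow with
¹⁵O-water) needs the arterial input function — the tracer concentration in
arterial blood over time — which is classically measured by invasive
arterial blood sampling.  When a high-resolution time-of-flight MR
angiography (TOF-MRA) of the neck arteries is acquired on the same hybrid
scanner, the input function can instead be read out of the PET images
themselves.  `autoidif` implements that workflow end to end:

1. **Vessel enhancement** — multiscale inertia-tensor filter: per voxel and
   sphere radius *r*, the eigenvalues λ₁ ≤ λ₂ ≤ λ₃ of the local inertia
   tensor give the prolateness *p* = (λ₂ − λ₁)/(λ₁ + λ₂ + λ₃) ∈ [0, ½],
   large for tubular structures; scales combine as *P* = √Σ p(rᵢ)².
2. **Artery segmentation** — histogram threshold at the first minimum
   above zero (100 bins), 26-connected components, the two largest clusters
   (bilateral carotids), and the cluster farthest from the PET center of
   gravity (contralateral to the injection catheter).
3. **Alignment** — per-slice in-plane shift between mask centroid and PET
   maximum, smoothed by quadratic fits dx(z), dy(z), applied by cubic
   splines; projection to fractional partial-volume coefficients on the
   PET grid.
4. **PSF calibration** — disk ⊛ Gaussian fits to a syringe phantom
   (diameter 4.7 mm) by downhill simplex yield the system FWHM.
5. **GTM extraction** — the PSF-blurred partial-volume map *w* models each
   PET voxel as *w*·C_art + (1 − *w*)·C_ext inside a 2×FWHM region; the
   overdetermined system is inverted per frame, giving the IDIF and the
   extraarterial curve.
6. **Cross-calibration** — steady-state (150–300 s) comparison against
   blood samples: per subject ccᵢ = AIF/IDIF with linearly propagated
   error σ(ccᵢ), group cc = Σwᵢccᵢ/Σwᵢ with wᵢ = 1/σ(ccᵢ) and
   σ(cc) = n/Σ(1/σ(ccᵢ)); plus whole-scan AUC ratio and the
   intra-/extraarterial activity ratio.

A first-class synthetic-phantom module (`autoidif.phantom`) renders
TOF-MRA volumes, dynamic PET series and blood-sample tables with full
ground truth, so the entire pipeline is testable without scanner data.
See `docs/methods.md` for the model details and assumptions.

## Worked example

Generate a phantom subject and run the whole pipeline on it:

```bash
autoidif phantom --seed 17 --out-dir phantoms/s01
autoidif run --mra phantoms/s01/mra.nii.gz --pet phantoms/s01/pet.nii.gz \
             --frames phantoms/s01/frames.tsv --blood phantoms/s01/blood.tsv \
             --out-dir results/s01
python -c "import json; print(json.load(open('results/s01/report.json'))['calibration'])"
```

which prints (seed 17):

```
{'cc_i': 0.9865743477794151, 'sigma_cc_i': 0.02267516661532797,
 'mean_aif': 9.481334534772921, 'mean_idif': 9.610359884294114,
 'ia_ea_ratio': 3.0260910834998533, 'auc_ratio': 1.0148146145555836}
```

`cc_i` is the blood-sample/IDIF activity ratio in steady state — near 1.0
means the geometric deconvolution recovered absolute arterial activity
from the images; `ia_ea_ratio` is the steady-state intra- to extraarterial
concentration ratio (the phantom's true value is 3.0); `auc_ratio`
compares the whole-scan areas under IDIF and blood curve.  The IDIF itself
is written to `results/s01/idif.tsv` (46 frames over 300 s).

Library use mirrors the CLI:

```python
from autoidif import phantom, vessel_filter, mask_alignment, gtm_extraction
from autoidif.artery_segmentation import segment_arteries
from autoidif.psf_calibration import PSFModel

mra, pet, blood, truth = phantom.generate_subject(phantom.PhantomConfig(), seed=17)
pmap = vessel_filter.multiscale_prolateness(mra, vessel_filter.default_scales(mra.spacing))
mask = segment_arteries(vessel_filter.enhance(mra, pmap), pet.max_over_time())
pv, _, _ = mask_alignment.align_mask(mask, pet.max_over_time(), pet.frame(0))
idif = gtm_extraction.extract_idif(pet, pv, PSFModel(fwhm=6.86))
```

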