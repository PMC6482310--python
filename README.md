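# ocapdt

**OCT angiography processing and perfused-vessel-density metrics for early
prediction of photodynamic-therapy outcome.**

Vascular-targeted photodynamic therapy (PDT) succeeds or fails largely
through its effect on the microvasculature — not only inside the tumour,
but in the peri-tumour tissue that feeds it. Optical coherence angiography
(OCA) can image perfused vessels label-free within hours of treatment,
which makes an *early* (24 h) responder/non-responder call possible long
before histology at day 7. This package implements the complete analysis
chain for that call, aimed at researchers evaluating PDT regimes or
photosensitizers in small-animal tumour models:

1. **Angiographic reconstruction** — bulk-motion phase compensation
   followed by high-pass FIR filtering of the complex OCT signal along the
   densely oversampled slow scan axis. Static tissue is correlated across
   overlapping beam positions and is rejected; flow-decorrelated vessel
   voxels pass.
2. **Tumour segmentation** — per-pixel classification of structural OCT
   from the decomposition coefficients of local depth reflectivity
   profiles onto two class-specific PCA bases, with a random-forest
   classifier, collapsed to a filled en-face tumour region.
3. **Vessel quantification** — en-face maximum intensity projection,
   total-variation denoising, thresholding at 3× the background noise SD,
   skeletonisation, and the **perfused vessel density**
   `PVD = 100 · |skeleton ∩ region| / |region|` (%), evaluated in the
   tumour and in the ≤2 mm peri-tumour annulus.
4. **Outcome prediction** — per-scenario optimal threshold by midpoint
   search (maximising correctly predicted outcomes, CPO), Wilson score
   intervals for the binomial accuracy, and the two-stage decision rule:

   > any perfused vessels inside the tumour at 24 h ⇒ non-responder;
   > otherwise responder iff peri-tumour PVD ≤ 1 %.

5. **Synthetic data** — a phantom generator producing complex OCT volumes
   with known vessel ground truth (flow decorrelation, bulk-motion phase
   drift, speckle) and a cohort generator reproducing the published group
   structure (18 responders / 13 non-responders; 8 of 13 non-responders
   with zero tumour PVD at 24 h; peri-tumour 24 h statistics
   0.38 ± 0.22 % vs 2.21 ± 0.86 % with complete separation at 0.8 %/1.2 %),
   so every stage is testable without access to animal data.

## Worked example

```python
from ocapdt import (CohortSpec, generate_cohort, optimal_threshold,
                    wilson_interval, PredictionCriterion, predict_cohort)

cohort = generate_cohort(CohortSpec(seed=1))            # 31 synthetic animals
values, labels = cohort.values("peri-tumour", "24h")
search = optimal_threshold(values, labels)
print(f"derived peri-tumour threshold: {search.threshold_pvd:.2f} %")
print(f"threshold-only CPO: {search.cpo}/{search.n}")
lo, hi = wilson_interval(search.cpo, search.n).as_percent()
print(f"95% Wilson interval: {lo}-{hi} %")
preds = predict_cohort(cohort, PredictionCriterion(0.0, search.threshold_pvd))
print(f"combined-rule CPO: {int(preds['correct'].sum())}/{len(preds)}")
```

```
derived peri-tumour threshold: 1.00 %
threshold-only CPO: 31/31
95% Wilson interval: 89-100 %
combined-rule CPO: 31/31
```

The midpoint search lands exactly between the highest responder (0.8 %)
and lowest non-responder (1.2 %) peri-tumour PVD, classifies every animal
correctly, and the Wilson interval for 31/31 is 89–100 %. The imaging half
works the same way on a phantom:

```python
from ocapdt import (PhantomSpec, generate_oct_volume, reconstruct, project_mip,
                    make_region_masks, quantify_regions)

vol, truth = generate_oct_volume(PhantomSpec(seed=1))   # one 0.05 mm vessel
img = project_mip(reconstruct(vol))                     # motion comp + FIR + MIP
regions = make_region_masks(truth.mask2d, margin_mm=0.3, pixel_size=img.pixel_size)
res = quantify_regions(img, regions)
print(f"phantom tumour-region PVD: {res.pvd_percent('tumour'):.2f} %")
print(f"phantom peri-region PVD:   {res.pvd_percent('peri-tumour'):.2f} %")
```

```
phantom tumour-region PVD: 9.30 %
phantom peri-region PVD:   0.00 %
```

The vessel skeleton is confined to the region containing the phantom's
vessel; the surrounding annulus is clean.

## Command line

```bash
oca-pdt synth cohort --seed 1 --out cohort.csv
oca-pdt predict table --cohort cohort.csv --out summary.csv
oca-pdt synth volume --seed 1 --out volume.h5
oca-pdt reconstruct --in volume.h5 --out oca.h5
oca-pdt quantify --oca mip.tif --tumour-mask mask.png --margin-mm 2.0 --out pvd.csv
oca-pdt predict classify --tumour-pvd 0 --peri-pvd 0.4
oca-pdt run --config config.yaml --seed 1 --out-dir run/
oca-pdt validate run/cohort.csv run/volume.h5
```

`run` executes the full pipeline (phantom → OCA → masks → PVD → cohort →
prediction) and writes a manifest with every parameter used and a content
checksum per artifact; a fixed seed reproduces the manifest bit for bit.
Exit codes: 0 success, 2 validation failure, 3 stage failure.

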