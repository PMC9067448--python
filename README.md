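# arterymap

Mapping the superficial arteries of the face from bright-blood MR
angiography, for augmented-reality guidance during dermal filler
injections.

The arterial anatomy of the face varies enough between individuals that
"standard" danger-zone knowledge cannot guarantee an injection avoids an
artery; intravascular filler can cause skin necrosis or blindness.  One
proposed workflow maps each patient's own arteries with a non-invasive
time-of-flight MRA, segments the superficial subcutaneous arterial network
into a 3-D model, and projects that model back onto the patient's face
through a smartphone AR view anchored on tracked facial landmarks.
`arterymap` implements that processing chain and its accuracy evaluation as
a reproducible Python library:

1. **Vessel enhancement** — multiscale Jerman vesselness from scale-normalized
   Hessian eigenvalues.  With eigenvalues |λ₁| ≤ |λ₂| ≤ |λ₃| (sign-flipped for
   bright vessels) and the regularized eigenvalue
   λ<sub>ρ</sub> (λ₃ clamped below a fraction τ of its per-scale global
   maximum), the response is

       V = 0                                   if λ₂ ≤ 0 or λρ ≤ 0
       V = 1                                   if λ₂ ≥ λρ/2 > 0
       V = λ₂²(λρ − λ₂)·(3/(λ₂ + λρ))³         otherwise

   maximized over Gaussian scales (default 0.5–2 mm, matching facial-artery
   radii).
2. **Segmentation** — thresholding of the response, restriction to the
   subcutaneous skin-to-skull band (spacing-aware distance transform of an
   automatic head mask), small-component removal, marching-cubes meshing to
   STL, and 3-D thinning to labeled centerlines.
3. **Anatomy labeling** — assignment of centerlines to the 18 named arteries
   (facial, inferior/superior labial, angular, lateral/dorsal nasal,
   supratrochlear, supraorbital, superficial temporal; both sides) via a
   deterministic landmark-anchored region atlas.
4. **Registration & projection** — closed-form (Umeyama) similarity fit of
   68-point facial landmark sets, and Gauss–Newton camera-pose recovery
   from 2-D tracked landmarks, projecting the arterial model into the view
   through a pinhole camera.
5. **Accuracy statistics** — per-artery and overall millimetre deviations
   between projected arteries and ultrasound-verified positions,
   visualization-rate tables, and sensitivity recomputation excluding
   patients whose dental braces wipe out the labial arteries on MRA.
6. **Synthetic phantoms** — seeded, ground-truthed head phantoms (ellipsoid
   head, Gaussian-profile tubular arteries, 68 surface landmarks, camera
   views) so the whole chain is testable without patient data.

## Worked example

`examples/02_reproduce_accuracy_tables.py` recomputes every accuracy
statistic from the packaged 20-patient deviation table:

```
$ python examples/02_reproduce_accuracy_tables.py
Visualization rates (of 40 artery-sides in 20 patients):
artery  left  right  total  percentage
    Fa    15     15     30        75.0
    IL     5      2      7        17.5
    ...
    ST    20     20     40       100.0
 Total   113    103    216        60.0

overall mean deviation: 0.31 mm (SD 0.66 mm), maximum 5 mm
labial sensitivity excluding the 7 brace wearers: IL 26.9%, SL 69.2%
```

The superficial temporal artery is visualized in all 40 cases and the
inferior labial in only 7 (metal artifacts from dental braces); the overall
mean projection error of 0.31 mm — the unweighted mean of the 18 per-artery
group means — is well below the ~1 mm scale relevant for injection
guidance.

`examples/01_phantom_to_arteries.py` runs the full imaging chain on a
synthetic head and verifies each of the 18 planted arteries is recovered to
sub-voxel accuracy; `examples/03_register_and_project.py` recovers a camera
pose from noisy tracked landmarks and scores the projected artery overlay
in millimetres.

A thin CLI mirrors the library (`arterymap simulate | vesselness | segment |
label | register | report | run | mip`), e.g.:

```
arterymap vesselness --in vol.nii.gz --scales 0.5,0.75,1.0,1.5,2.0 --tau 0.5 --out vness.nii.gz
arterymap report --out-summary summary.json
```

## Layout

- `src/arterymap/` — library modules (`volume_io`, `vesselness`,
  `segmentation`, `anatomy_labeling`, `registration`, `accuracy`,
  `synthetic`, `pipeline`, `cli`) and packaged data
  (`data/table2_deviations.csv`, `data/atlas_regions.json`)
- `docs/methods.md` — models, parameters, numerical choices, limitations
- `examples/` — one narrative script per capability
- `tests/` — pytest suite with independent brute-force oracles
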