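# shadowcyte

Three-part white-blood-cell (WBC) differentials from **lens-free shadow
images**. A stained blood smear placed directly on a CMOS sensor (pixel
pitch 1.67 µm, sample–sensor gap ≈ 200 µm) casts dark cell shadows on a
bright field; `shadowcyte` turns such an image into the percentages of
neutrophils (Neu), monocytes (Mon) and lymphocytes (Lym) — the basic
differential used in routine blood work — with no lenses and no flow
cell. The intended users are developers of low-cost point-of-care
hematology instruments and anyone studying classification from
low-resolution contact microscopy.

## Method

1. **Segmentation.** Stained WBC shadows are darker than everything
   else in the field; pixels with intensity `< 95` are foreground. A
   marker-controlled watershed on the Euclidean distance transform
   splits touching shadows, components outside the plausible WBC area
   window are dropped, and each cell's padded bounding box is resized
   bilinearly to a 64×64 patch. The raw mask area gives the equivalent
   circular diameter `d = 2·√(area/π)·pitch` in µm.

2. **PPED features.** Each patch is summarized by its Projected
   Principal-Edge Distribution: four zero-sum 5×5 kernels detect
   horizontal, ±45° and vertical edges,

       I*_d(x, y) = | Σ_{p,q∈[−2,2]} K_d(p,q) · I(x+p, y+q) | ,

   a pixel gets a binary flag for its strongest direction when
   `max_d I*_d ≥ TH(x, y)`, each flag map is projected along its own
   orientation (column sums, row sums, diagonal sums over `i+j = m` and
   `i−j+63 = m`), the 127-bin diagonal projections are folded to 64 bins
   with a ½–1–½ stencil, and every projection is merged 4-to-1 into 16
   bins. Concatenating the blocks (H, +45°, V, −45°) gives a
   64-dimensional vector whose component sum equals the flag count.

3. **Classification.** With one standard vector `V_m` per class
   (trained as the per-class mean of labeled exemplars), distances
   `D_p(i) = ‖P − V_i‖₂` are normalized to `D_m(i) = D_p(i)/max D_p`,
   converted to probabilities `P_m(i) = 1 − D_m(i)`, and fused with a
   size prior `P_s` — the indicator of the diameter bin Lym 5–10 µm,
   Neu 10–14 µm, Mon 14–25 µm:

       T(i) = 0.9 · P_m(i) + 0.1 · P_s(i) ,

   the cell taking the arg-max class. Percentages over all cells give
   the differential.

4. **Evaluation.** Two differentials for the same sample are compared
   by the three-point Pearson correlation and per-class absolute error;
   a study is summarized by the mean correlation across samples.

A seeded synthetic-smear generator (`shadowcyte.synthetic`) renders
ground-truthed images matching the instrument's qualitative properties
(bright field ≈ 180, cell shadows ≈ 60, Gaussian diffraction blur,
sensor noise), with class-specific nuclear cartoons — three lobes,
kidney, round — so the whole pipeline is testable without real data.

## Worked example

```python
from shadowcyte import SynthParams, end_to_end_recovery

summary = end_to_end_recovery(SynthParams(seed=0))
for k, v in summary.items():
    print(f"{k}: {v}")
```

prints

```
n_generated: 60
n_recovered: 60
n_test: 30
label_accuracy: 0.9333333333333333
predicted_differential: {'Neu': 40.0, 'Mon': 30.0, 'Lym': 30.0}
true_differential: {'Neu': 33.333333333333336, 'Mon': 33.333333333333336, 'Lym': 33.333333333333336}
max_differential_error: 6.666666666666664
mean_diameter_rel_error: 0.024118007384993027
max_diameter_rel_error: 0.14495599441743176
```

i.e. a 60-cell smear (20 per class) was generated, all 60 shadows were
re-segmented, standards were trained on a stratified half, and 28 of
the 30 held-out cells were labeled correctly; measured shadow diameters
track the generated ones to 2.4 % on average.

The same flow is available from the shell:

```sh
shadowcyte simulate --n-per-class 20 --seed 0 --out smear.tiff --truth truth.json
shadowcyte segment smear.tiff --out-dir crops/
shadowcyte features --crop-dir crops/ --out features.csv
shadowcyte train --features features.csv --labels labels.csv --out standards.json
shadowcyte classify --features features.csv --standards standards.json \
    --scores-out scores.csv --counts-out counts.csv
shadowcyte evaluate --pred pairs.csv
```

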