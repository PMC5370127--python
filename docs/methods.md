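# Methods

## Imaging model and scope

The pipeline assumes contact ("shadow") imaging: a stained smear sits
~200 µm above a monochrome-equivalent CMOS array with 1.67 µm pixels,
so one leukocyte spans roughly 3–15 pixels and its image is a blurred
dark disk rather than a resolved cell. Color from such a system is
unreliable, so all processing starts from 8-bit luma (BT.601 weights,
configurable). Nothing in the package models the optics beyond a
configurable Gaussian blur; Fresnel diffraction, RBC morphology and
staining chemistry are out of scope.

## Segmentation

Foreground is `intensity < wbc_threshold` with the strict default 95:
Wright-Giemsa-stained WBC shadows fall below it while background and
red cells stay above. Touching shadows are split by a
marker-controlled watershed on the Euclidean distance transform (EDT).
Markers are local maxima of the EDT *smoothed with a 1 px Gaussian*
(`marker_smooth_sigma`), at a minimum separation equal to the radius
implied by `min_area_px`. The smoothing matters: on a noise-roughened
mask the raw EDT of a single convex cell carries spurious secondary
maxima, and without it large monocytes are occasionally split in two.
With it, masks with no touching cells reduce exactly to connected
components, while two disks overlapping by less than a radius are still
separated into near-equal halves.

Components are kept when their area lies in `[min_area_px,
max_area_px]`; the defaults are 9 px (≈ the smallest credible
lymphocyte shadow) and the area of a 25 µm disk at the image's pixel
pitch (no single WBC is wider). The padded bounding box (margin 2 px,
clipped to the frame; border-touching cells kept unless
`drop_border`) is resized bilinearly to 64×64. The physical diameter is
measured on the **raw** mask as the equivalent circular diameter, not
on the resized patch, because the size prior's bins are in µm. No
correction is applied for the diffraction enlargement of shadows; the
synthetic generator instead defines truth on the apparent-diameter
scale (below), and for real data the bins should be recalibrated per
instrument.

## PPED descriptor

Kernels: the four 5×5 direction kernels are ±1 step kernels — two rows
(or diagonals) of +1 facing two of −1 across the oriented edge, zero on
the center line — so each sums to zero, the vertical kernel is the
transpose of the horizontal one, and the diagonal pair are mirror
images. Responses are magnitudes of the correlation; the 2-px frame
where the window leaves the patch is defined as zero. Kernels are
loadable from JSON (`KernelSet.from_json`) so alternative weightings
can be swapped in without code changes.

Flag assignment is **arg-max only**: at most one direction is flagged
per pixel, ties resolving in the fixed order H, +45°, V, −45°. Setting
a flag for *every* direction whose shared maximum clears the threshold
would make the four feature maps identical and the descriptor
orientation-blind, which contradicts the point of separating four
principal edges.

Threshold policy. The edge threshold `TH(x, y)` is the one genuinely
open choice in the chain, and the package treats it as a named,
configurable policy:

* `global-fraction` (default, fraction 0.3): `TH = 0.3 · max I*` over
  the patch. A flag then marks an edge commensurate with the strongest
  structure in the crop; the rule is invariant to patch contrast and
  well suited to crops that were bilinearly upsampled from a handful of
  sensor pixels, where absolute gradient scales are arbitrary.
* `local-median` (floor 1): per-pixel median of the 40 adjacent-pair
  absolute differences inside the 5×5 window. This adapts to local
  texture, but its scale is that of a *single* pixel difference while
  the response of a zero-sum 5×5 kernel to the same gradient is ~30×
  larger, so on smooth interpolated crops it flags nearly every
  interior pixel and the descriptor saturates (measured vector sums ≈
  3600 = all interior pixels, for every class). It is retained for
  sensitivity analysis, not as the default.

The two projection reductions (½–1–½ folding of the 127 diagonal bins,
then 4-to-1 merging to 16) each conserve the total: in the folding,
every input index receives weight 1 across its one or two targets
(P(−1) and P(127) are defined as 0, and index 126 is even, so no mass
leaks at the ends). Hence `Σ vector = number of flags`, which the test
suite checks on random patches, and all components are non-negative
multiples of ½.

## Classifier

Standard vectors are per-class means of labeled exemplar descriptors
(median available); with one exemplar per class the standard is that
exemplar. Distances are normalized by the *maximum* of the three (the
normalization makes `P_m = 1 − D_m` a bounded pseudo-probability with
exactly one zero), so the decision is scale-invariant: multiplying all
distances by a positive constant changes nothing. Degenerate cases are
kept explicit rather than patched: all-equal distances give
`P_m = (0,0,0)` and the size prior alone decides; all-zero distances
give `P_m = (1,1,1)`.

The size bins are lower-inclusive half-open — [5,10) µm lymphocyte,
[10,14) neutrophil, [14,25] monocyte — because the open intervals of
the classic rule would leave 10 and 14 µm unassigned; 25 µm is included
as the largest admissible monocyte, and diameters outside [5,25] µm
contribute a zero prior instead of rejecting the cell. The fusion
weights default to 0.9 (features) / 0.1 (size); they are exposed as
parameters but treated as fixed constants of the method, not tuned
here. Exact score ties resolve to the smaller raw distance, then to the
fixed class order (Neu, Mon, Lym).

## Agreement metrics

Per-sample agreement between two differentials is the Pearson
correlation of the two (Neu, Mon, Lym) triples; a study is summarized
by the mean correlation and by per-class mean absolute errors in
percentage points. A three-point correlation is fragile — one dominant
class can pin it near 1 — so it is reported as a concordance index
only. Constant triples raise an error rather than returning NaN. The
bundled six-patient prototype-vs-analyzer table reproduces, at each
cell's printed precision, correlations 0.97 / 0.89 / 1 / 1 / 0.927 /
0.95, mean 0.96, and mean errors 3.45 / 6.04 / 6.7 points, which the
acceptance script recomputes at run time.

## Synthetic smears

The generator emulates the features of the instrument's output that the
pipeline actually exploits: a bright field (default 180) carrying dark
cell shadows (body 60, nuclear structure 25), diffraction approximated
by a Gaussian blur (σ = 1.5 px for the ~200 µm gap; the kernel is a
parameter, not a physical model), additive Gaussian sensor noise
(σ = 5), and a minimum center spacing (default 32 px ≈ twice the
largest cell) because real smears must be dilute enough that shadows do
not merge. Class morphology is a parametric cartoon of Wright-stained
nuclei — three lobes (Neu), kidney (Mon), near-full round nucleus
(Lym) — randomly oriented per cell; it gives the classes distinct
edge-distribution signatures the way real morphology does, with no
claim of biological fidelity.

Two calibration decisions make the generator self-consistent with the
segmenter:

* **Apparent-diameter ground truth.** Blur plus a fixed threshold
  shifts the measured boundary of a dark disk, so each cell's drawn
  radius is solved by bisection against the blur + threshold forward
  model until the *measured* equivalent diameter equals the requested
  one. Ground-truth diameter therefore means "apparent shadow diameter
  under the stated imaging model" — the quantity the size prior bins
  and the instrument itself operate on. Measured diameters then track
  truth to ~2–3 % mean error (the test bound is 15 %).
* **Detectable diameter ranges.** Diameters are drawn uniformly per
  class from the size bins clipped to the segmenter's detection
  window: the 9 px minimum area resolves nothing below 5.66 µm and a
  25 µm shadow sits exactly on the maximum-area cutoff, so the defaults
  are Lym 5.7–10, Neu 10–14, Mon 14–24.5 µm. Without the clipping, a
  cell drawn at the extreme edge of a bin is undetectable by
  construction and exact count recovery is impossible.

All randomness flows through one `numpy` generator seeded from
`SynthParams.seed`; identical parameters give byte-identical images.
What passing the synthetic benchmark shows is that the implementation
is internally consistent and that the descriptor + size fusion can
separate classes whose differences resemble the real cues; it does
**not** show performance on real smears, whose texture, staining
variability, debris and RBC background the cartoons do not contain.

## Benchmark sizes and numerical notes

The end-to-end benchmark uses a 512×512 canvas with 60 cells
(20/class), standards trained on a stratified half (even-indexed crops
per class in scan order) and evaluated on the other 30 cells; across
seeds this recovers 60/60 crops and 90–100 % of held-out labels. The
brute-force PPED oracle in the test suite is literal quadruple loops
over the defining sums and is compared exactly (floating-point halves
are exact in binary). Bilinear resizing uses `skimage.transform.resize`
with `preserve_range` and rounding back to uint8; 16-bit images are
rescaled by the fixed 65535→255 ratio rather than per-image min/max so
that reading is deterministic across frames.

## Known limitations

* No real shadow-image data ships with the package; thresholds (95),
  intensities and blur are plausible defaults, not fitted to an
  instrument.
* The diameter is not corrected for diffraction enlargement; on real
  hardware the size bins and the area window should be calibrated
  jointly with the optics.
* Three-class differential only; eosinophils and basophils (a few
  percent of WBCs) are not modeled and would be absorbed into the
  nearest class.
* The three-point correlation metric saturates easily and should not
  be the sole acceptance measure for a real instrument.
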