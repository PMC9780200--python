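# Methods

This note documents the models, conventions and design choices behind
`moequant`. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## 1. Imaging quantification

### Background threshold from negative controls

Negative-control fields are cells fed the natural sugar (ManNAc): after
the click reaction their streptavidin channel carries only nonspecific
binding. The reporter pixels of all control fields of a condition are
pooled and a single cutoff is computed:

* `percentile` (default, p = 99.5): the pooled order statistic at
  `ceil(q·(n−1))` (numpy's `higher` convention). This choice guarantees
  by construction that at most (100 − p)% of control pixels exceed the
  cutoff — the self-consistency property a background threshold should
  have. Linear interpolation between order statistics can leave
  marginally more than (100 − p)% strictly above the interpolated
  value, which is why the order-statistic convention is used.
* `mean_plus_ksd` (k = 3 by default): pooled mean + k·SD (population
  SD). Suitable when the control background is close to Gaussian.

Pooling is per condition, not per image: the original analysis applied
one threshold per condition's control, and a pooled estimate is more
stable for small control sets. Per-image thresholding is deliberately
not offered.

### Whole-cell ROIs

Cell ROIs are built from the thresholded *reporter* channel (the same
order of operations as the macro-style analysis this package
re-implements), not from the nuclei channel:
`reporter > cutoff` → morphological closing (disk, radius 2 px) →
hole filling → removal of 4-connected components < 500 px → labeling.
Hole filling matters: labeled cells can carry most of their reporter on
the membrane annulus and in the Golgi, leaving a dim nuclear "hole"
that must still count as cell area. Nuclei can optionally seed a
watershed split of touching cells (`use_nuclei_seeds`); the default
geometry keeps cells non-overlapping so the flag is off by default.
Cells touching the image border are kept (configurable upstream by
cropping; the measurement itself does not exclude them).

Defaults (closing 2 px, min cell 500 px, min Golgi component 20 px)
are tuned for 512×512 fields with 25–40 px cell radii — the geometry
the synthetic generator produces — and are all configurable.

### Golgi ROIs and the in/out partition

The Golgi-marker (TGN46-like) channel is thresholded by Otsu's method
*restricted to pixels inside cell ROIs*, so extracellular background
cannot shift the split; components < 20 px are dropped. An upper-
percentile rule is available as an alternative. Per cell:

    in_golgi  = cell ∧ golgi
    out_golgi = cell ∧ ¬golgi

disjoint and jointly exhaustive by construction, which makes integrated
density exactly additive: `IntDen(in) + IntDen(out) = IntDen(cell)`.

### Measurement and aggregation

IntDen is the raw sum of grey values over a region (mean × area at
pixel calibration 1, i.e. RawIntDen; no spatial calibration is
supported). Measurements are always taken on the raw, unthresholded
reporter channel — the threshold defines geometry only; thresholding
values as well would bias min/mean and break additivity.

Aggregation treats the image as the replication unit: image-level value
= mean of per-cell IntDen in that image; condition value = mean over
images; SD = sample SD (ddof = 1) over images, reported only from two
images up. Per-cell values remain available in `measurements.csv` for
anyone preferring cell-level aggregation. A condition with zero
measurable cells is reported as NaN with `n_cells = 0`, never as a
silent zero. Inside the pipeline's t-tests, however, an *image* in
which no cell survives the background threshold contributes an
image-level IntDen of 0 — the operational meaning of "no signal above
control background". This is what makes the null experiment (labeled
images identical to controls) well-defined: both groups are all zeros,
the pooled variance is zero, the t statistic is undefined, and the
comparison is recorded with p = NaN and label `ns` — identical data
cannot show a difference.

### In-Golgi fraction recovery

For validation against planted truth the pipeline reports

    f̂ = B_in / (B_in + B_out),   B_r = max(0, mean IntDen_r − b·Ā_r)

with `b` the per-pixel background and `Ā_r` the mean region area. In
the pipeline `b` is estimated as the pooled mean of the control
reporter channel; this slightly over-corrects (it mixes extracellular
background with in-cell nonspecific signal, inflating `b` by the
nonspecific excess times the cell area fraction, ≈ 0.15 counts/px at
defaults) but the resulting bias on f̂ is far below the 0.05 recovery
tolerance at default budgets. When the true background is known (as in
the synthetic validation), it is passed directly.

## 2. Flow cytometry

The original scatter gate was drawn by hand; a hand gate cannot be
reproduced, so the implemented gate is an explicit two-step rule whose
parameters are recorded in every result:

1. drop events with FSC-A below the 2nd sample percentile (debris);
2. on the survivors, compute median/MAD robust z-scores for FSC-A and
   SSC-A (MAD × 1.4826 for normal consistency) and drop events with
   |z| > 2.5 on either axis (doublets, outliers). MAD = 0 defines
   z = 0, so a degenerate, perfectly tight cluster is fully kept.

MFI is the arithmetic mean of the fluorescence channel over kept events
(no log transform — the statistic is a plain mean of intensities), and
`relative MFI = MFI(analog)/MFI(control)`. FCS 3.0/3.1 files (list
mode, linear area parameters) and CSV tables with `FSC-A`/`SSC-A`/
`FL1-A`/`FL2-A` headers are read; compensation, log-amplified
parameters and display transforms are out of scope.

## 3. Blot densitometry

Lane densities enter as numbers (band extraction from gel scans is out
of scope): `Rel. Int. = (biotin/Ponceau)_lane ÷ (biotin/Ponceau)_ref`,
with exactly one reference lane per blot group. The reference is set to
1 exactly (not recomputed through floating point), and the statistic is
invariant to rescaling all biotin densities by one constant and all
Ponceau densities by another.

## 4. Statistics

Unpaired two-tailed t-test; the classical Student equal-variance
variant is the default (df = n_a + n_b − 2) since the analysis this
mirrors specifies only "unpaired, two-tailed"; Welch (Satterthwaite df)
is available by flag and the variant used is carried in every output
row. Zero pooled variance raises a dedicated error rather than
returning a fabricated p. No multiple-testing correction is applied —
outputs carry the raw p plus the tier label
(`***` ≤ 0.005, `**` ≤ 0.01, `*` ≤ 0.05, `ns`; boundaries inclusive).

## 5. Synthetic scenes: what they emulate, and what they do not

Each field is 512×512 by default with 6 non-overlapping round cells
(radius 25–40 px, rejection-sampled placement), each carrying a nucleus
(0.4 of the cell radius, slightly offset), a 2-px plasma-membrane
annulus, and a perinuclear Golgi blob seated on the nucleus boundary
and sized to ~5% of the free cytoplasm. Channels:

* nuclei: +150 counts/px on nuclei;
* Golgi marker: +200 counts/px on Golgi;
* reporter: each cell receives an expected photon budget of 10⁵ counts
  split `f_golgi : membrane_frac : nuclear_frac : remainder` over
  Golgi / membrane / nucleus / cytoplasm, uniform within each set
  (defaults 0.5 : 0.1 : 0 : 0.4) — by construction the expected
  budget is conserved to machine precision, which is what makes planted
  fractions exactly recoverable in expectation.

All channels sit on a flat background of 2 counts/px and are observed
as `Poisson(expected) + N(0, 1)` clipped at zero — shot noise plus
camera read noise, the standard two-knob fluorescence forward model.
Matched control fields share the geometry stream of their seed and
replace the reporter by a uniform nonspecific level of 4 counts/px
inside cells. These levels put the cytoplasmic signal ~10× above the
control cutoff (the regime the recovery guarantees are stated for); an
`ac4_like_params()` preset (low `f_golgi`, strong nuclear+cytosolic
component) mimics a diffusely localising peracetylated reporter for
qualitative demos only.

What the scenes do **not** emulate — hence what passing tests do not
show about real data: optics (no PSF convolution, so segmentation
boundaries are unrealistically crisp), touching/overlapping cells,
intensity gradients and vignetting, autofluorescence structure,
out-of-focus light, 3D effects, photobleaching. Recovery results
should be read as "the arithmetic and geometry of the pipeline are
correct", not as an accuracy claim for any particular microscope.

Cytometry event tables: main population with Gaussian FSC/SSC clusters
(5·10⁴ ± 5·10³ and 3·10⁴ ± 4·10³) and lognormal fluorescence
(σ = 0.5); a planted fold shifts the log-mean by ln(fold) so the
population mean scales exactly by the fold. Debris sits near zero
scatter; doublets at 2× scatter and fluorescence. Lane tables apply
mean-one multiplicative lognormal noise of a given CV to planted
biotin/Ponceau ratios.

## 6. Numerical and reproducibility choices

* Grey values are float64 internally; loaders never rescale.
* Pixel coordinates are 0-based (row, column); masks share the image
  shape; connectivity is 4 for all labeling.
* Every generator is a pure function of (params, seed); geometry and
  noise use separate `SeedSequence` child streams so a scene and its
  control share geometry. Pipeline sub-seeds are derived from the run
  seed by a CRC-based mix and stay below 2³¹.
* Stage outputs are plain CSV with fixed headers; manifests echo every
  effective parameter (including defaults) so parameter drift between
  versions is detectable; no timestamps are written, making reruns
  byte-identical.
* Validation problem sizes (chosen once, as the package's own trade-off
  between statistical resolution and turnaround): 20 seeds per planted
  fraction at the default 512×512 geometry for fraction recovery;
  256×256 four-cell scenes where only geometry/arithmetic is under
  test; 10⁴ events per cytometry table; 10⁴ replicates for t-test null
  calibration.

## 7. Known limitations

* Whether the original macro-style analysis used per-cell or merged
  whole-image ROIs, and per-cell or per-image averaging, is ambiguous;
  per-cell ROIs with image-level averaging are implemented and the
  per-cell table is exported so other aggregations remain possible.
* The FCS reader covers the common list-mode/linear subset only.
* `estimate_golgi_fraction` assumes the background is spatially flat;
  structured background would bias the correction.
* No attempt is made to reproduce instrument-specific absolute values
  (raw MFIs, grey-level calibrations); all reported statistics are
  ratios or background-corrected contrasts by design.
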