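# Methods

## The labelling model

Fatty-acid synthesis polymerizes two-carbon acetyl units drawn at random
from the cytosolic acetyl-CoA pool. At isotopic steady state under a
U-¹³C-glucose tracer, a fraction *p* of that pool carries two ¹³C atoms,
so the number of labelled units in a chain of n = C/2 units is
Binom(n, p) and the fatty acid appears at even mass shifts M+2i. A second
process — direct uptake of the unlabelled fatty acid from the medium —
adds mass only at M+0. The C16-type model is therefore

    I₀ = uptake + (1 − uptake)·P(0),    Iᵢ = (1 − uptake)·P(i)  (i ≥ 1),

with P the binomial pmf. It sums to one identically. Interpretation
caveats: *p* is a *relative* contribution of the labelled substrate (the
pool size itself is not measurable this way), and `uptake` is relative to
the lipid classes that ionize in negative mode.

For C18 fatty acids a third route exists: elongation of an unlabelled C16
precursor by one (labelled) acetyl unit, which contributes exactly at
acetyl index 1 (M+2). With `uptake_C16` the unlabelled-precursor fraction
of the synthesized pool:

    I₁ = (1 − uptake)·(uptake_C16 + (1 − uptake_C16)·P(1))
    Iᵢ = (1 − uptake)·(1 − uptake_C16)·P(i)   (i ≥ 2),

I₀ as above. **Normalization**: these equations as written sum to
1 + (1 − uptake)·uptake_C16·P(0) ≥ 1, because the elongation branch does
not remove the precursor's own P(0) mass from the I₀ term. Observed
profiles are sum-normalized, so the implementation evaluates the
equations verbatim and then renormalizes the prediction to unit sum
before comparing with data; `renormalize=False` exposes the verbatim
values for audit. Whether the I₀ term should instead carry a
(1 − uptake_C16) factor (which would restore normalization analytically)
is an open modelling question; we do not assume it. Likewise the model
treats the elongating acetyl unit as always labelled — a factor *p* on
the elongation term would be an alternative reading; we implement the
equations as stated.

## Fitting

Parameters are estimated by box-constrained least squares on the
normalized acetyl-indexed profile: minimize Σᵢ (Iᵢ − Î ᵢ)² over
[0, 1]² (C16) or [0, 1]³ (C18), via trust-region-reflective `least_squares`
with an analytic Jacobian for the C16 model. Because the objective can
have local minima near the box corners, the optimizer is started from the
four corners of [0.1, 0.9]² (eight corners in 3-D); the lowest residual
wins, ties broken by lower *p*. This is deterministic — no random
restarts. Noiseless profiles invert to ~1e-6; agreement with an
exhaustive 0.002-step grid search is within 0.004 on noisy profiles.

**Identifiability.** When almost nothing is labelled, I ≈ (1, 0, …, 0)
for a continuum of (p, uptake) combinations, so *p* is meaningless. Fits
are flagged unidentifiable when the labelled mass fraction 1 − I₀ of the
input profile falls below a floor (default 0.05, configurable). Flagged
fits are excluded from uptake correlations and masked in tissue p-maps.

**Approximate uncertainties.** The Model/Results layer reports
Gauss–Newton standard errors, cov = s²(JᵀJ)⁻¹ with s² = SSE/(m − k).
These are indicative only in the interior of the box; parameters pinned
at 0 or 1 get NaN.

## Natural-abundance correction

Raw ladder intensities M+0…M+C mix tracer enrichment with natural heavy
isotopes (¹³C 1.07%, ²H 0.0115%, ¹⁷O 0.038%, ¹⁸O 0.205%). The correction
matrix A has as column j the theoretical mass-shift pattern of the
species with j tracer-¹³C atoms: a Binom(j, purity) term for the tracer
positions (tracer purity default 1.0, configurable) convolved with the
natural patterns of the remaining carbons and all H and O. Correction
solves A·x = raw (triangular at purity 1); if noise drives components
negative beyond 1e-12 the solution is replaced by non-negative least
squares. Two numerical choices worth noting:

* Columns of A are renormalized to unit sum. The measured ladder ends at
  M+C, and the natural-isotope mass that would fall beyond it (< 1% even
  for the fully labelled species) is folded back so that convolution
  conserves total intensity exactly and correction is the exact inverse
  of the simulated forward convolution.
* An ill-conditioned matrix (condition number > 1e12) raises rather than
  silently amplifying noise; in practice cond(A) ≈ 1.6 for C16.

After correction, odd mass shifts carry no tracer signal under the
two-carbon model; profiles are reduced to even shifts (M+2i → index i)
and renormalized. The discarded odd-mass fraction is kept as a QC metric
and flags the profile above a bound (default 0.05). Whether odd shifts
were meant to enter the fit at all is ambiguous; even-reduction with QC
is the implemented reading.

## Pixel-to-cell assignment

Ablation marks are circles on the microscopy raster, either rasterized
from a grid (origin, pitch, rotation, radius) or fitted to annotated
centres by a linear similarity model (least squares on
centre = origin + R(θ)·pitch·(col, row); ≥ 3 non-collinear points).
Overlap between a mark and a cell is the fraction of raster pixel centres
inside the circle that carry the cell's label — pure pixel counting at
microscopy resolution, no sub-pixel weighting; the discretization error
is bounded and tested against an exact counting oracle. Overlap is
normalized by mark area (not cell area).

The single-cell chain follows a fixed order: extract ladder intensities
(±5 ppm windows, checked for overlap; 5 ppm matches Orbitrap-class
resolution) → correct → sum-normalize per mark → drop marks whose raw
ladder total for this fatty acid is below 200 (strict `<`; the filter is
per fatty acid, so a mark can survive for C16:0 and drop for C14:0) →
assign marks with ≥ 30% overlap to the argmax-overlap cell (ties to the
lower cell id) → entrywise median across the cell's marks → renormalize.
Cells with zero surviving marks carry *missing* profiles, never zeros.

## Tissue pixels

Tissue sections have no segmentation; each MALDI pixel runs the same
correct → normalize → even-reduce → fit chain independently. Pixels whose
raw ladder total is below the limit of detection (default 1000; the
boundary is inclusive — exactly-at-limit pixels are kept) are masked, and
masked or unidentifiable pixels stay NaN in every map. Region-level
distributions average the normalized per-pixel profiles with the
arithmetic mean by default (means preserve linear mixing of subregions);
`statistic="median"` matches the single-cell convention. Runs at
different pitches (e.g. a 10 µm tumour window and a 50 µm whole-section
scan) are processed separately and carry their pitch in the output maps.

## Fluorescence features and classification

Reporter signal per cell is log10 of the background-subtracted maximum
channel intensity inside the mask; background is the median outside all
masks; the subtracted maximum is floored at 1 intensity unit before the
log so the feature is always defined. Cells are called
reporter-positive above the empirical 95th percentile of the
negative-control wells. Condition prediction from profiles uses
L2-regularized logistic regression (C = 1.0, fixed — determinism over
tuning, since the separations of interest are large) with stratified
5-fold cross-validated predictions; a resubstitution mode reproduces
apparent accuracy for audit. In the two-population analysis, accuracy is
scored against the true condition, with the classifier trained on the
(contaminated) reporter labels: reporter silencing creates false
negatives, and the point of the profile classifier is that it recovers
the true state despite them.

## The synthetic-data generator

The generator inverts the measurement chain: per-cell (p, uptake,
uptake_C16) → binomial forward model on even shifts → convolution with
the natural-abundance matrix → scaling by a per-cell fatty-acid pool size
(lognormal, mean 5e4 intensity units, CV 0.3) → unit-mean lognormal
multiplicative noise per peak (MALDI shot-to-shot variability; CV 0.2
default for cells, 0.1 for tissue) → uniform m/z jitter within ±2 ppm →
centroid spectra on the mark raster. Cells are non-overlapping ellipses,
mean area 550 µm² (gamma, CV 0.3) at 1 µm microscopy resolution; the mark
raster is 10 µm pitch with 5 µm radius. Mark spectra mix overlapping
cells by area fraction plus a weak unlabelled background pool (50 units,
below the 200 filter). Fluorescence images use two lognormal populations
with an optional "silenced" contamination fraction of the positives.
Tissue fields evaluate p/uptake maps per pixel (the default gradient
spans 0.45–0.70, the range observed in glioma tissue; the default
tissue uptake is constant 0.10 — tumour palmitate is predominantly
synthesized de novo); an optional low-intensity stripe exercises LOD
masking.

What the generator does *not* emulate: chemical matrix noise and
isobaric interferences, isotope fine structure, detector saturation,
lipid-class-dependent uptake differences, partial isotopic steady state,
and registration error between microscopy and MALDI frames (mark
positions are exact by construction). Passing tests therefore demonstrate
correctness of the computational chain under the stated noise model, not
robustness to every artefact of real acquisitions.

## Problem sizes in the verification suite

The end-to-end checks run at 600 cells (~13k marks) with CV 20% noise, a
128×128-pixel tissue field with CV 10%, and 300+300 cells for the
two-population analysis — sizes chosen so each check completes in minutes
on one CPU while leaving the medians and mean absolute errors they assert
well-resolved.

## Known limitations

* The C18 model's normalization ambiguity (above) means `uptake_C16` is
  interpretable only relative to the verbatim equations.
* Peak extraction assumes centroided spectra; profile-mode data must be
  centroided upstream.
* Overlapping ppm windows (very wide tolerance or very heavy fragments)
  are rejected rather than resolved.
* Uptake estimates inherit the negative-ion AIF lipid-class bias; see the
  model section.
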