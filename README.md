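# lipotrace

Single-cell and spatial stable-isotope tracing of fatty acids from MALDI
imaging mass spectrometry.

## What problem this solves

Feeding cells or animals U-¹³C-glucose labels the cytosolic (lipogenic)
acetyl-CoA pool, and fatty acids synthesized de novo inherit that label in
two-carbon steps. Negative-ion all-ion-fragmentation (AIF) MALDI imaging
releases fatty-acyl fragments (RCOO⁻) from esterified lipids at every
raster position, so the isotopologue pattern of each fatty acid — measured
per 10 µm ablation mark and assigned to segmented cells, or per tissue
pixel — reports how actively each cell synthesizes fatty acids, how
labelled its acetyl-CoA pool is, and how much of each fatty-acid pool it
imports unlabelled from the medium.

`lipotrace` turns raw pixel spectra (imzML) plus a cell-segmentation mask
into natural-abundance-corrected single-cell isotopologue profiles, fits a
binomial labelling model per cell or per pixel, and renders spatial maps
and single-cell tables. It is aimed at imaging-MS groups doing spatial
isotope tracing and at computational biologists who want a tested,
scriptable reference for isotopologue-model fitting.

## The model

A fatty acid with C carbons is built from n = C/2 acetyl units. If a
fraction *p* of the acetyl-CoA pool is fully labelled (M+2 units), the
number of labelled units is binomial, and a fraction `uptake` of the
fatty-acid pool arrives unlabelled from the medium:

    P(k) = C(n, k) · p^k · (1 − p)^(n−k)
    I₀   = uptake + (1 − uptake) · P(0)
    Iᵢ   = (1 − uptake) · P(i),   i = 1 … n

For C18 species, elongation of unlabelled C16 precursors adds one acetyl
unit (an M+2 signature), governed by a third parameter `uptake_C16`:

    I₁ = (1 − uptake) · (uptake_C16 + (1 − uptake_C16) · P(1))
    Iᵢ = (1 − uptake) · (1 − uptake_C16) · P(i),   i ≥ 2

Observed profiles are corrected for natural isotope abundance (matrix
inversion over the fragment's elemental formula), reduced to even mass
shifts M+2i, sum-normalized, and fitted by box-constrained least squares.
The de-novo fraction 1 − (M+0)/Σ(M+n) summarizes total labelling per
pixel.

## Worked example

```python
import numpy as np
from lipotrace import (FattyAcidDefinition, BinomialLabellingModel,
                       forward_model_c16)
from lipotrace.synthetic_fixtures import simulate_cell_field, simulate_spectra
from lipotrace.spatial_mapping import build_cell_records

c16 = FattyAcidDefinition.from_name("C16:0")
labels, grid, truth = simulate_cell_field(40, seed=11)
pixels, marks = simulate_spectra(truth, labels, grid, [c16],
                                 noise_cv=0.15, seed=12)
records = build_cell_records(pixels, marks, labels, [c16])
fit = records[0].fits["C16:0"]
print(f"cell 1: p = {fit.p:.3f}, uptake = {fit.uptake:.3f}")
print("truth :", truth.cells.iloc[0][["p", "uptake"]].round(3).to_dict())
```

prints

```
cell 1: p = 0.369, uptake = 0.796
truth : {'p': 0.361, 'uptake': 0.809}
```

i.e. from the 7 noisy ablation-mark spectra assigned to the first cell,
the median-aggregated profile recovers the true acetyl-CoA labelling
degree (0.361) and unlabelled-uptake fraction (0.809) to about one
percentage point. The
Model/Results interface gives the same fit with uncertainties and a
summary table:

```python
profile = np.asarray(
    forward_model_c16(0.61, 0.30).intensities)  # a noiseless example
res = BinomialLabellingModel(profile, variant="c16").fit()
print(res.summary())
```

```
Binomial labelling model results
================================================
variant: c16   acetyl units n: 8   profiles: 1
param           estimate   approx se
------------------------------------
p                 0.6100      0.0000
uptake            0.3000      0.0000
SSE: 0.000e+00   identifiable: True
```

(the standard errors are zero because the example profile is noiseless).

A command-line interface covers the same pipeline for people working from
the shell: `lipotrace simulate | extract | correct | single-cell | fit |
tissue-map | classify` (each writes its artifact plus a JSON run log).

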