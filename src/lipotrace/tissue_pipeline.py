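"""Per-pixel tissue analysis: ion images, LOD masking, and parameter maps.

Tissue sections carry no cell segmentation; every MALDI pixel is processed
independently with the same chain as single cells (extract → natural-
abundance correction → sum-normalization → even reduction → binomial fit).
Pixels whose summed raw fatty-acid ladder intensity falls below the limit
of detection (default 1,000; at-limit pixels are kept) are masked, and
masked pixels stay missing — never zero — in every downstream map.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io_formats import PixelSpectrumSet
from .isotope_model import (
    FattyAcidDefinition,
    IsotopologueProfile,
    correct_natural_abundance,
    de_novo_fraction,
    extract_isotopologue_intensities,
    fit_labelling,
    reduce_to_even,
)

__all__ = [
    "PixelMap",
    "DEFAULT_LOD",
    "ion_image",
    "lod_mask",
    "per_pixel_fit",
    "fraction_labelled_map",
    "isotopologue_distribution_of_region",
    "write_pixel_map",
]

DEFAULT_LOD = 1000.0


@dataclasses.dataclass
class PixelMap:
    """A per-pixel statistic aligned to the MALDI grid; invalid pixels are NaN."""

    values: np.ndarray
    mask: np.ndarray  # True where valid
    pitch: float
    statistic: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask must share a shape")
        # enforce the invariant: invalid pixels carry NaN, never numbers
        self.values = np.where(self.mask, self.values, np.nan)


def _grid_arrays(pixels: PixelSpectrumSet, per_pixel: np.ndarray) -> np.ndarray:
    """Scatter a per-spectrum vector onto the (n_rows, n_cols) grid (NaN holes)."""
    out = np.full(pixels.grid_shape, np.nan)
    out[pixels.pixel_index[:, 0], pixels.pixel_index[:, 1]] = per_pixel
    return out


def ion_image(
    pixels: PixelSpectrumSet,
    fa: FattyAcidDefinition,
    isotopologue: int | None = None,
    tic_normalize: bool = False,
    tol_ppm: float = 5.0,
) -> PixelMap:
    """Image of M+j intensity (or Σ over the ladder when ``isotopologue=None``).

    With ``tic_normalize`` each pixel is divided by its total ion count
    (sum of all centroid intensities in the spectrum); zero-TIC pixels are
    masked.
    """
    raw = extract_isotopologue_intensities(pixels, fa, tol_ppm=tol_ppm)
    vals = raw.sum(axis=1) if isotopologue is None else raw[:, isotopologue]
    valid = np.ones(vals.shape, dtype=bool)
    if tic_normalize:
        tic = pixels.tic()
        valid = tic > 0
        vals = np.divide(vals, tic, out=np.full_like(vals, np.nan), where=valid)
    grid_vals = _grid_arrays(pixels, vals)
    grid_mask = _grid_arrays(pixels, valid.astype(float)) == 1.0
    name = f"{fa.name} " + ("sum" if isotopologue is None else f"M+{isotopologue}")
    if tic_normalize:
        name += " / TIC"
    return PixelMap(values=grid_vals, mask=grid_mask, pitch=pixels.pitch,
                    statistic=name)


def lod_mask(
    pixels: PixelSpectrumSet,
    fa: FattyAcidDefinition,
    min_total: float = DEFAULT_LOD,
    tol_ppm: float = 5.0,
) -> np.ndarray:
    """Validity mask: pixel kept iff Σⱼ raw ladder intensity ≥ ``min_total``.

    The boundary is inclusive — only pixels *below* the limit of detection
    are discarded.
    """
    raw = extract_isotopologue_intensities(pixels, fa, tol_ppm=tol_ppm)
    totals = raw.sum(axis=1)
    grid_totals = _grid_arrays(pixels, totals)
    with np.errstate(invalid="ignore"):
        return np.nan_to_num(grid_totals, nan=-np.inf) >= min_total


def _per_pixel_profiles(
    pixels: PixelSpectrumSet,
    fa: FattyAcidDefinition,
    tol_ppm: float,
    tracer_purity: float,
) -> tuple[np.ndarray, np.ndarray]:
    """(normalized corrected ladder per pixel, raw totals per pixel)."""
    raw = extract_isotopologue_intensities(pixels, fa, tol_ppm=tol_ppm)
    totals = raw.sum(axis=1)
    out = np.full_like(raw, np.nan)
    for k in range(raw.shape[0]):
        if totals[k] <= 0:
            continue
        prof = IsotopologueProfile(fa, raw[k])
        corr = correct_natural_abundance(prof, tracer_purity=tracer_purity)
        out[k] = corr.normalized().intensities
    return out, totals


def per_pixel_fit(
    pixels: PixelSpectrumSet,
    fa: FattyAcidDefinition,
    variant: str = "c16",
    min_total: float = DEFAULT_LOD,
    tol_ppm: float = 5.0,
    tracer_purity: float = 1.0,
    identifiability_floor: float = 0.05,
) -> tuple[PixelMap, PixelMap]:
    """Binomial-model maps of p and uptake, fitted independently per pixel.

    Pixels below the LOD or with an unidentifiable fit are masked in the
    ``p`` map; the uptake map keeps LOD-masked pixels missing as well.
    """
    profiles, totals = _per_pixel_profiles(pixels, fa, tol_ppm, tracer_purity)
    n_pix = profiles.shape[0]
    p_vals = np.full(n_pix, np.nan)
    u_vals = np.full(n_pix, np.nan)
    ident = np.zeros(n_pix, dtype=bool)
    for k in range(n_pix):
        if totals[k] < min_total or not np.isfinite(profiles[k]).all():
            continue
        prof = IsotopologueProfile(fa, profiles[k], state="normalized",
                                   axis="mass_shift")
        even = reduce_to_even(prof)
        fit = fit_labelling(even, variant=variant,
                            identifiability_floor=identifiability_floor)
        p_vals[k] = fit.p
        u_vals[k] = fit.uptake
        ident[k] = fit.identifiable
    grid_p = _grid_arrays(pixels, np.where(ident, p_vals, np.nan))
    grid_u = _grid_arrays(pixels, np.where(np.isfinite(u_vals), u_vals, np.nan))
    p_map = PixelMap(values=grid_p, mask=np.isfinite(grid_p),
                     pitch=pixels.pitch, statistic=f"{fa.name} p")
    u_map = PixelMap(values=grid_u, mask=np.isfinite(grid_u),
                     pitch=pixels.pitch, statistic=f"{fa.name} uptake")
    return p_map, u_map


def fraction_labelled_map(
    pixels: PixelSpectrumSet,
    fa: FattyAcidDefinition,
    min_total: float = DEFAULT_LOD,
    tol_ppm: float = 5.0,
    tracer_purity: float = 1.0,
) -> PixelMap:
    """Map of the de-novo fraction 1 − (M+0)/Σ(M+n) per valid pixel."""
    profiles, totals = _per_pixel_profiles(pixels, fa, tol_ppm, tracer_purity)
    vals = np.full(profiles.shape[0], np.nan)
    for k in range(profiles.shape[0]):
        if totals[k] >= min_total and np.isfinite(profiles[k]).all():
            vals[k] = de_novo_fraction(profiles[k])
    grid = _grid_arrays(pixels, vals)
    return PixelMap(values=grid, mask=np.isfinite(grid), pitch=pixels.pitch,
                    statistic=f"{fa.name} fraction labelled")


def isotopologue_distribution_of_region(
    pixels: PixelSpectrumSet,
    fa: FattyAcidDefinition,
    region_mask: np.ndarray,
    min_total: float = DEFAULT_LOD,
    tol_ppm: float = 5.0,
    tracer_purity: float = 1.0,
    statistic: str = "mean",
) -> IsotopologueProfile:
    """Aggregate normalized per-pixel ladders over a region of the grid.

    Default aggregation is the arithmetic mean (it preserves linear mixing
    of subregions); ``statistic="median"`` matches the single-cell
    convention instead. The result is renormalized to unit sum.
    """
    region_mask = np.asarray(region_mask, dtype=bool)
    if region_mask.shape != pixels.grid_shape:
        raise ValueError("region mask shape must match the pixel grid")
    profiles, totals = _per_pixel_profiles(pixels, fa, tol_ppm, tracer_purity)
    rows, cols = pixels.pixel_index[:, 0], pixels.pixel_index[:, 1]
    keep = region_mask[rows, cols] & (totals >= min_total)
    keep &= np.isfinite(profiles).all(axis=1)
    if not keep.any():
        raise ValueError("region is empty after LOD masking")
    stack = profiles[keep]
    agg = np.median(stack, axis=0) if statistic == "median" else stack.mean(axis=0)
    agg = agg / agg.sum()
    return IsotopologueProfile(fa, agg, state="normalized", axis="mass_shift")


def write_pixel_map(pmap: PixelMap, tiff_path=None, csv_path=None) -> None:
    """Export a map as 32-bit float TIFF and/or a long-format CSV table."""
    if tiff_path is not None:
        import tifffile

        tifffile.imwrite(str(tiff_path), pmap.values.astype(np.float32))
    if csv_path is not None:
        import pandas as pd

        rows, cols = np.nonzero(pmap.mask)
        pd.DataFrame({
            "row": rows, "col": cols,
            "statistic": pmap.statistic,
            "value": pmap.values[rows, cols],
        }).to_csv(csv_path, index=False)
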