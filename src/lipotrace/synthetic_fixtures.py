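"""Ground-truthed synthetic datasets for every pipeline stage.

The generator emulates the measurement chain in reverse: per-cell (or
per-pixel) labelling parameters → binomial forward model on even mass
shifts → convolution with natural isotope abundance → scaling by a
fatty-acid pool size → multiplicative lognormal peak noise and ppm m/z
jitter → centroided pixel spectra on a raster of circular ablation marks
over a synthetic segmentation mask. All bookkeeping (true p, uptake, pool
sizes, per-mark composition) is retained so recovery can be scored exactly.

Geometry defaults mirror the experimental regime this pipeline targets:
10 µm raster pitch over adherent cells of ~550 µm² mean area, microscopy
resolution finer than the raster.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import skimage.draw

from .io_formats import LabelImage, PixelSpectrumSet
from .isotope_model import (
    FattyAcidDefinition,
    forward_model_c16,
    forward_model_c18,
    natural_abundance_matrix,
)
from .spatial_mapping import AblationMark, MarkGrid, compute_overlap, rasterize_grid

__all__ = [
    "GroundTruth",
    "simulate_cell_field",
    "simulate_spectra",
    "simulate_fluorescence",
    "simulate_tissue",
]

DistSpec = tuple | float | Callable[[np.random.Generator, int], np.ndarray]


def _draw(spec: DistSpec, size: int, rng: np.random.Generator) -> np.ndarray:
    """Sample from a distribution spec.

    Specs: a number (constant); ``("uniform", lo, hi)``;
    ``("mixture", [(weight, value_or_spec), ...])``; ``("normal", mu, sd)``;
    or a callable ``f(rng, size)``.
    """
    if callable(spec):
        return np.asarray(spec(rng, size), dtype=float)
    if np.isscalar(spec):
        return np.full(size, float(spec))
    kind = spec[0]
    if kind == "uniform":
        return rng.uniform(spec[1], spec[2], size)
    if kind == "normal":
        return rng.normal(spec[1], spec[2], size)
    if kind == "mixture":
        weights = np.array([w for w, _ in spec[1]], dtype=float)
        weights /= weights.sum()
        which = rng.choice(len(weights), size=size, p=weights)
        out = np.empty(size)
        for i, (_, sub) in enumerate(spec[1]):
            idx = np.flatnonzero(which == i)
            if idx.size:
                out[idx] = _draw(sub, idx.size, rng)
        return out
    raise ValueError(f"unknown distribution spec {spec!r}")


def _lognormal_factors(rng: np.random.Generator, size, cv: float) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with coefficient of variation cv."""
    if cv <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=size)


@dataclasses.dataclass
class GroundTruth:
    """Everything needed to score recovery of a synthetic dataset."""

    seed: int
    cells: pd.DataFrame | None = None  # cell_id, p, uptake, uptake_c16, pool_<fa>
    marks: pd.DataFrame | None = None  # mark_id, composition bookkeeping
    p_map: np.ndarray | None = None
    uptake_map: np.ndarray | None = None
    lod_stripe: np.ndarray | None = None  # boolean map of low-TIC pixels
    noise_cv: float | None = None
    mz_jitter_ppm: float | None = None


def simulate_cell_field(
    n_cells: int,
    mean_area_um2: float = 550.0,
    area_cv: float = 0.3,
    pitch: float = 10.0,
    pixel_size: float = 1.0,
    mark_radius: float = 5.0,
    fill_factor: float = 0.25,
    p_dist: DistSpec = ("uniform", 0.3, 0.7),
    uptake_dist: DistSpec = ("uniform", 0.4, 0.9),
    uptake_c16_dist: DistSpec = 0.2,
    seed: int = 0,
    max_tries_per_cell: int = 200,
) -> tuple[LabelImage, MarkGrid, GroundTruth]:
    """Random non-overlapping elliptical cells with an ablation-mark raster.

    The image side is sized so cells occupy about ``fill_factor`` of the
    area. Per-cell labelling parameters are drawn from the given specs
    (mixtures allow bimodal populations). Fails after bounded retries when
    the packing is infeasible.
    """
    rng = np.random.default_rng(seed)
    side_um = np.sqrt(n_cells * mean_area_um2 / fill_factor)
    side_px = int(np.ceil(side_um / pixel_size))
    labels = np.zeros((side_px, side_px), dtype=np.int32)

    areas = rng.gamma(shape=1.0 / area_cv**2,
                      scale=mean_area_um2 * area_cv**2, size=n_cells)
    areas = np.clip(areas, mean_area_um2 * 0.2, None)
    for cell_id in range(1, n_cells + 1):
        area_px = areas[cell_id - 1] / pixel_size**2
        aspect = rng.uniform(0.55, 1.0)
        a = np.sqrt(area_px / (np.pi * aspect))
        b = aspect * a
        theta = rng.uniform(0, np.pi)
        placed = False
        for _ in range(max_tries_per_cell):
            cy = rng.uniform(a + 1, side_px - a - 1)
            cx = rng.uniform(a + 1, side_px - a - 1)
            rr, cc = skimage.draw.ellipse(cy, cx, a, b, shape=labels.shape,
                                          rotation=theta)
            if rr.size == 0:
                continue
            if np.all(labels[rr, cc] == 0):
                labels[rr, cc] = cell_id
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place cell {cell_id} after {max_tries_per_cell} "
                "tries; reduce fill_factor or n_cells")

    n_nodes = int(side_um // pitch)
    grid = MarkGrid(origin=(pitch / 2.0, pitch / 2.0), pitch=pitch,
                    rotation=0.0, radius=mark_radius,
                    shape=(n_nodes, n_nodes))
    cells = pd.DataFrame({
        "cell_id": np.arange(1, n_cells + 1),
        "p": _draw(p_dist, n_cells, rng),
        "uptake": _draw(uptake_dist, n_cells, rng),
        "uptake_c16": _draw(uptake_c16_dist, n_cells, rng),
        "area_um2": [float(np.count_nonzero(labels == i)) * pixel_size**2
                     for i in range(1, n_cells + 1)],
    })
    truth = GroundTruth(seed=seed, cells=cells)
    return LabelImage(labels=labels, pixel_size=pixel_size), grid, truth


def _even_forward(fa: FattyAcidDefinition, p: float, uptake: float,
                  uptake_c16: float) -> np.ndarray:
    """Ground-truth even-isotopologue distribution for one cell and FA."""
    if fa.n_carbons >= 18:
        return forward_model_c18(p, uptake, uptake_c16,
                                 n=fa.acetyl_units).intensities
    return forward_model_c16(p, uptake, n=fa.acetyl_units).intensities


def simulate_spectra(
    truth: GroundTruth,
    labels: LabelImage,
    grid: MarkGrid,
    panel: Sequence[FattyAcidDefinition],
    noise_cv: float = 0.2,
    mz_jitter_ppm: float = 2.0,
    pool_mean: float = 5e4,
    pool_cv: float = 0.3,
    background_pool: float = 50.0,
    tracer_purity: float = 1.0,
    seed: int | None = None,
) -> tuple[PixelSpectrumSet, list[AblationMark]]:
    """Forward-simulate centroided mark spectra from per-cell ground truth.

    Each mark's spectrum mixes the contributions of the cells it overlaps
    (weighted by overlap fraction) plus a weak unlabelled background pool.
    Even-isotopologue distributions from the binomial model are convolved
    with the natural-abundance matrix, scaled by per-cell pool sizes, and
    degraded with unit-mean lognormal peak noise and uniform ppm m/z jitter.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    marks = rasterize_grid(grid)
    compute_overlap(marks, labels, overlap_threshold=0.0)
    cells = truth.cells
    assert cells is not None
    by_id = cells.set_index("cell_id")

    matrices = {fa.name: natural_abundance_matrix(fa.formula, fa.n_carbons,
                                                  tracer_purity)
                for fa in panel}
    # per-cell per-FA pool sizes (arbitrary intensity units per mark)
    pools = {fa.name: pd.Series(
        pool_mean * _lognormal_factors(rng, len(cells), pool_cv),
        index=by_id.index) for fa in panel}
    # per-cell corrected-space mass-shift vectors
    cell_vectors: dict[str, dict[int, np.ndarray]] = {}
    for fa in panel:
        vecs = {}
        for cell_id, row in by_id.iterrows():
            even = _even_forward(fa, row["p"], row["uptake"], row["uptake_c16"])
            full = np.zeros(fa.n_carbons + 1)
            full[::2] = even
            vecs[int(cell_id)] = matrices[fa.name] @ full
        # background: pure unlabelled pool
        bg = np.zeros(fa.n_carbons + 1)
        bg[0] = 1.0
        vecs[0] = matrices[fa.name] @ bg
        cell_vectors[fa.name] = vecs

    mzs: list[np.ndarray] = []
    intens: list[np.ndarray] = []
    index = []
    mark_rows = []
    for mark in marks:
        peaks_mz: list[np.ndarray] = []
        peaks_int: list[np.ndarray] = []
        composition = dict(mark.overlap)
        bg_frac = max(0.0, 1.0 - sum(composition.values()))
        totals = {}
        for fa in panel:
            expected = bg_frac * background_pool * cell_vectors[fa.name][0]
            for cell_id, frac in composition.items():
                expected = expected + (frac * pools[fa.name].loc[cell_id]
                                       * cell_vectors[fa.name][cell_id])
            noisy = expected * _lognormal_factors(rng, expected.size, noise_cv)
            ladder = fa.mz_ladder
            jitter = rng.uniform(-mz_jitter_ppm, mz_jitter_ppm, ladder.size)
            peaks_mz.append(ladder * (1.0 + jitter * 1e-6))
            peaks_int.append(noisy)
            totals[fa.name] = float(noisy.sum())
        mz = np.concatenate(peaks_mz)
        ii = np.concatenate(peaks_int)
        order = np.argsort(mz)
        mzs.append(mz[order])
        intens.append(ii[order])
        index.append(mark.grid_index)
        mark_rows.append({"mark_id": mark.mark_id,
                          "grid_row": mark.grid_index[0],
                          "grid_col": mark.grid_index[1],
                          "background_fraction": bg_frac,
                          **{f"total_{k}": v for k, v in totals.items()}})
    truth.marks = pd.DataFrame(mark_rows)
    truth.noise_cv = noise_cv
    truth.mz_jitter_ppm = mz_jitter_ppm
    pixels = PixelSpectrumSet(
        pixel_index=np.array(index, dtype=int),
        mz=mzs, intensity=intens, pitch=grid.pitch, grid_shape=grid.shape)
    return pixels, marks


def simulate_fluorescence(
    labels: LabelImage,
    positive_cells: Sequence[int],
    contamination: float = 0.0,
    neg_log_mean: float = 1.5,
    pos_log_mean: float = 3.0,
    log_sd: float = 0.25,
    background_level: float = 100.0,
    background_sd: float = 5.0,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Reporter-channel image with two lognormal cell populations.

    A ``contamination`` fraction of the truly positive cells is drawn from
    the negative distribution (emulating reporter silencing, which produces
    false negatives). Returns the image and a table with the true condition
    and the reporter state actually simulated.
    """
    rng = np.random.default_rng(seed)
    img = rng.normal(background_level, background_sd, labels.labels.shape)
    positive_cells = set(int(c) for c in positive_cells)
    rows = []
    for cell_id in labels.cell_ids:
        cell_id = int(cell_id)
        is_positive = cell_id in positive_cells
        silenced = is_positive and rng.random() < contamination
        log_mean = neg_log_mean if (not is_positive or silenced) else pos_log_mean
        peak = 10.0 ** rng.normal(log_mean, log_sd)
        mask = labels.labels == cell_id
        shape = rng.uniform(0.3, 1.0, mask.sum())
        img[mask] += peak * shape
        rows.append({"cell_id": cell_id, "condition_positive": is_positive,
                     "reporter_silenced": silenced})
    return img, pd.DataFrame(rows)


def simulate_two_conditions(
    n_per_condition: int,
    condition_a: tuple[float, float] = (0.55, 0.6),
    condition_b: tuple[float, float] = (0.05, 0.95),
    contamination: float = 0.1,
    panel: Sequence[FattyAcidDefinition] | None = None,
    noise_cv: float = 0.2,
    seed: int = 0,
    **field_kwargs,
) -> tuple[PixelSpectrumSet, list[AblationMark], LabelImage, GroundTruth]:
    """Co-plated two-population experiment with a fluorescent reporter.

    Half the cells get the ``condition_a`` (p, uptake) parameters, half
    ``condition_b``; condition-B cells carry the reporter, of which a
    ``contamination`` fraction is silenced (reporter-negative despite the
    B condition). The truth table gains ``condition``, ``reporter_positive``
    and fluorescence-feature bookkeeping columns.
    """
    if panel is None:
        from .isotope_model import default_panel

        panel = default_panel()
    n_cells = 2 * n_per_condition
    labels, grid, truth = simulate_cell_field(n_cells=n_cells, seed=seed,
                                              **field_kwargs)
    rng = np.random.default_rng(seed + 1)
    order = rng.permutation(n_cells)
    cells = truth.cells
    is_b = np.zeros(n_cells, dtype=bool)
    is_b[order[:n_per_condition]] = True
    cells["condition"] = np.where(is_b, "B", "A")
    cells.loc[~is_b, "p"], cells.loc[~is_b, "uptake"] = condition_a
    cells.loc[is_b, "p"], cells.loc[is_b, "uptake"] = condition_b
    silenced = is_b & (rng.random(n_cells) < contamination)
    cells["reporter_positive"] = is_b & ~silenced
    pixels, marks = simulate_spectra(truth, labels, grid, panel,
                                     noise_cv=noise_cv, seed=seed + 2)
    return pixels, marks, labels, truth


def _field(spec, shape: tuple[int, int]) -> np.ndarray:
    """Evaluate a 2-D field spec: constant, ("linear-x", lo, hi), or array."""
    if isinstance(spec, np.ndarray):
        if spec.shape != shape:
            raise ValueError("field array shape mismatch")
        return spec.astype(float)
    if np.isscalar(spec):
        return np.full(shape, float(spec))
    kind = spec[0]
    if kind == "linear-x":
        cols = np.linspace(spec[1], spec[2], shape[1])
        return np.tile(cols, (shape[0], 1))
    if kind == "linear-y":
        rows = np.linspace(spec[1], spec[2], shape[0])
        return np.tile(rows[:, None], (1, shape[1]))
    raise ValueError(f"unknown field spec {spec!r}")


def simulate_tissue(
    shape: tuple[int, int] = (128, 128),
    p_field=("linear-x", 0.45, 0.70),
    uptake_field=0.10,
    fa: FattyAcidDefinition | None = None,
    noise_cv: float = 0.1,
    mz_jitter_ppm: float = 2.0,
    pool_mean: float = 5e4,
    lod_stripe: tuple[int, int] | None = None,
    stripe_pool: float = 100.0,
    pitch: float = 10.0,
    tracer_purity: float = 1.0,
    seed: int = 0,
) -> tuple[PixelSpectrumSet, GroundTruth]:
    """Per-pixel tissue field with spatially varying labelling parameters.

    ``p_field`` defaults to the linear anterior–posterior style gradient
    0.45 → 0.70 across columns; ``lod_stripe=(c0, c1)`` rescales that column
    band to a total intensity far below the limit of detection so the
    masking stage has known-truth pixels to remove.
    """
    if fa is None:
        fa = FattyAcidDefinition.from_name("C16:0")
    rng = np.random.default_rng(seed)
    p_map = _field(p_field, shape)
    u_map = _field(uptake_field, shape)
    A = natural_abundance_matrix(fa.formula, fa.n_carbons, tracer_purity)
    stripe = np.zeros(shape, dtype=bool)
    if lod_stripe is not None:
        stripe[:, lod_stripe[0]:lod_stripe[1]] = True

    mzs, intens, index = [], [], []
    ladder = fa.mz_ladder
    n_units = fa.acetyl_units
    for r in range(shape[0]):
        for c in range(shape[1]):
            even = forward_model_c16(p_map[r, c], u_map[r, c],
                                     n=n_units).intensities
            full = np.zeros(fa.n_carbons + 1)
            full[::2] = even
            scale = stripe_pool if stripe[r, c] else pool_mean
            expected = scale * (A @ full)
            noisy = expected * _lognormal_factors(rng, expected.size, noise_cv)
            jitter = rng.uniform(-mz_jitter_ppm, mz_jitter_ppm, ladder.size)
            mz = ladder * (1.0 + jitter * 1e-6)
            order = np.argsort(mz)
            mzs.append(mz[order])
            intens.append(noisy[order])
            index.append((r, c))
    pixels = PixelSpectrumSet(pixel_index=np.array(index), mz=mzs,
                              intensity=intens, pitch=pitch, grid_shape=shape)
    truth = GroundTruth(seed=seed, p_map=p_map, uptake_map=u_map,
                        lod_stripe=stripe, noise_cv=noise_cv,
                        mz_jitter_ppm=mz_jitter_ppm)
    return pixels, truth
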