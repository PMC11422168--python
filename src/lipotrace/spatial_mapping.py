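"""Relating ablation marks to segmented cells and building single-cell profiles.

Each MALDI ablation mark is a circular crater on the microscopy raster. A
mark is *intracellular* for a cell when at least 30% of its area (by
pixel-centre count) lies inside that cell's mask; marks whose total raw
intensity for a fatty acid falls below 200 are discarded for that fatty
acid. Surviving marks are assigned to the cell of maximal overlap, and the
single-cell readout per isotopologue is the entrywise median over the
cell's marks, renormalized to unit sum.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import LabelImage, PixelSpectrumSet
from .isotope_model import (
    FattyAcidDefinition,
    IsotopologueProfile,
    LabellingFit,
    correct_natural_abundance,
    extract_isotopologue_intensities,
    fit_labelling,
    reduce_to_even,
)

__all__ = [
    "MarkGrid",
    "AblationMark",
    "CellRecord",
    "rasterize_grid",
    "fit_mark_grid",
    "compute_overlap",
    "filter_and_assign",
    "aggregate_cell_profile",
    "build_cell_records",
]

DEFAULT_MIN_TOTAL_INTENSITY = 200.0
DEFAULT_OVERLAP_THRESHOLD = 0.30


@dataclasses.dataclass
class MarkGrid:
    """Regular raster of circular ablation marks in the microscopy frame (µm)."""

    origin: tuple[float, float]  # (x, y) of grid node (row 0, col 0)
    pitch: float
    rotation: float  # radians, counter-clockwise
    radius: float
    shape: tuple[int, int]  # (n_rows, n_cols)

    def __post_init__(self) -> None:
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")

    @property
    def overlapping_marks(self) -> bool:
        """True when circles of adjacent nodes can intersect."""
        return self.radius > self.pitch / 2.0


@dataclasses.dataclass
class AblationMark:
    """One laser crater: its geometry and per-cell overlap fractions."""

    mark_id: int
    grid_index: tuple[int, int]
    centre: tuple[float, float]  # (x, y) µm
    radius: float
    overlap: dict[int, float] = dataclasses.field(default_factory=dict)
    intracellular_cell: int | None = None


@dataclasses.dataclass
class CellRecord:
    """One segmented cell with its aggregated profiles and model fits."""

    cell_id: int
    area_um2: float
    mark_ids: list[int]
    profiles: dict[str, IsotopologueProfile | None]
    fits: dict[str, LabellingFit | None] = dataclasses.field(default_factory=dict)
    fluorescence: dict[str, float] = dataclasses.field(default_factory=dict)
    condition: str | None = None

    def to_row(self) -> dict:
        """Flatten into one cell-table row (CSV-ready)."""
        row: dict = {
            "cell_id": self.cell_id,
            "area_um2": self.area_um2,
            "n_marks": len(self.mark_ids),
        }
        for fa_name, prof in sorted(self.profiles.items()):
            if prof is not None:
                for i, v in enumerate(prof.intensities):
                    row[f"{fa_name}_M+{2 * i if prof.axis == 'acetyl' else i}"] = v
        for fa_name, fit in sorted(self.fits.items()):
            if fit is None:
                continue
            row[f"{fa_name}_p"] = fit.p
            row[f"{fa_name}_uptake"] = fit.uptake
            if fit.uptake_c16 is not None:
                row[f"{fa_name}_uptake_C16"] = fit.uptake_c16
            row[f"{fa_name}_residual"] = fit.residual
            row[f"{fa_name}_identifiable"] = fit.identifiable
        for k, v in sorted(self.fluorescence.items()):
            row[f"fluo_{k}"] = v
        row["condition"] = self.condition
        return row


def rasterize_grid(grid: MarkGrid) -> list[AblationMark]:
    """One mark per grid node: centre = origin + R(rotation)·(col·pitch, row·pitch)."""
    cos_t, sin_t = np.cos(grid.rotation), np.sin(grid.rotation)
    marks = []
    mark_id = 0
    for row in range(grid.shape[0]):
        for col in range(grid.shape[1]):
            gx, gy = col * grid.pitch, row * grid.pitch
            x = grid.origin[0] + cos_t * gx - sin_t * gy
            y = grid.origin[1] + sin_t * gx + cos_t * gy
            marks.append(AblationMark(
                mark_id=mark_id, grid_index=(row, col),
                centre=(float(x), float(y)), radius=grid.radius))
            mark_id += 1
    return marks


def fit_mark_grid(
    annotated_centres: Sequence[tuple[float, float]],
    grid_indices: Sequence[tuple[int, int]],
    radius: float = 5.0,
    shape: tuple[int, int] | None = None,
) -> tuple[MarkGrid, float]:
    """Least-squares similarity fit of a grid to annotated mark centres.

    Solves for origin, pitch and rotation of the linear model
    ``centre = origin + R(θ)·pitch·(col, row)`` from ≥ 3 annotated centres
    with known grid indices. Returns the grid and the RMS residual (µm).
    """
    pts = np.asarray(annotated_centres, dtype=float)
    idx = np.asarray(grid_indices, dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 annotated centres")
    if np.linalg.matrix_rank(idx - idx.mean(axis=0)) < 2:
        raise ValueError("annotated grid indices are collinear/degenerate")
    # x = x0 + a·col − b·row ; y = y0 + b·col + a·row with a=pitch·cosθ, b=pitch·sinθ
    rows, cols = idx[:, 0], idx[:, 1]
    zeros, ones = np.zeros_like(rows), np.ones_like(rows)
    Ax = np.column_stack([ones, zeros, cols, -rows])
    Ay = np.column_stack([zeros, ones, rows, cols])
    A = np.vstack([Ax, Ay])
    b = np.concatenate([pts[:, 0], pts[:, 1]])
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    x0, y0, a, bb = sol
    pitch = float(np.hypot(a, bb))
    rotation = float(np.arctan2(bb, a))
    resid = (A @ sol - b).reshape(2, -1)  # (dx…, dy…)
    rms = float(np.sqrt(np.mean(resid[0] ** 2 + resid[1] ** 2)))
    if shape is None:
        shape = (int(rows.max()) + 1, int(cols.max()) + 1)
    grid = MarkGrid(origin=(float(x0), float(y0)), pitch=pitch,
                    rotation=rotation, radius=radius, shape=shape)
    return grid, rms


def compute_overlap(
    marks: Iterable[AblationMark],
    labels: LabelImage,
    overlap_threshold: float = DEFAULT_OVERLAP_THRESHOLD,
) -> list[AblationMark]:
    """Fill each mark's per-cell overlap map by pixel-centre-in-circle counting.

    ``overlap[cell] = (#raster pixels inside the circle with that label) /
    (#raster pixels inside the circle)``, at microscopy resolution. Marks
    entirely outside the image get an empty map. ``intracellular_cell`` is
    the argmax cell when its overlap reaches the threshold (ties broken by
    lower cell id).
    """
    px = labels.pixel_size
    img = labels.labels
    h, w = img.shape
    for mark in marks:
        cx, cy = mark.centre
        r = mark.radius
        c0 = max(int(np.floor((cx - r) / px)), 0)
        c1 = min(int(np.ceil((cx + r) / px)) + 1, w)
        r0 = max(int(np.floor((cy - r) / px)), 0)
        r1 = min(int(np.ceil((cy + r) / px)) + 1, h)
        mark.overlap = {}
        mark.intracellular_cell = None
        if c1 <= c0 or r1 <= r0:
            continue
        rows = (np.arange(r0, r1) + 0.5) * px
        cols = (np.arange(c0, c1) + 0.5) * px
        inside = ((cols[None, :] - cx) ** 2 + (rows[:, None] - cy) ** 2) <= r * r
        n_inside = int(inside.sum())
        if n_inside == 0:
            continue
        patch = img[r0:r1, c0:c1][inside]
        ids, counts = np.unique(patch[patch > 0], return_counts=True)
        mark.overlap = {int(i): float(c) / n_inside for i, c in zip(ids, counts)}
        if mark.overlap:
            best = max(mark.overlap.items(), key=lambda kv: (kv[1], -kv[0]))
            if best[1] >= overlap_threshold:
                mark.intracellular_cell = best[0]
    return list(marks)


def filter_and_assign(
    marks: Sequence[AblationMark],
    totals_by_mark: Mapping[int, float] | np.ndarray,
    min_total_intensity: float = DEFAULT_MIN_TOTAL_INTENSITY,
    overlap_threshold: float = DEFAULT_OVERLAP_THRESHOLD,
) -> dict[int, list[int]]:
    """Per-fatty-acid mark filtering and cell assignment.

    Drops marks whose total raw intensity for this fatty acid is below
    ``min_total_intensity`` (strict <, matching "less than 200"); of the
    rest, a mark is assigned to its argmax-overlap cell when that overlap is
    at least ``overlap_threshold``. Returns ``{cell_id: [mark_id, ...]}``.
    """
    assigned: dict[int, list[int]] = {}
    for mark in marks:
        total = float(totals_by_mark[mark.mark_id])
        if total < min_total_intensity:
            continue
        if not mark.overlap:
            continue
        best_cell, best_frac = max(mark.overlap.items(),
                                   key=lambda kv: (kv[1], -kv[0]))
        if best_frac >= overlap_threshold:
            assigned.setdefault(best_cell, []).append(mark.mark_id)
    return assigned


def aggregate_cell_profile(
    normalized_profiles: Sequence[np.ndarray],
) -> np.ndarray | None:
    """Entrywise median of the marks' normalized profiles, renormalized.

    Returns ``None`` for zero marks (a missing profile, never a zero one).
    """
    if len(normalized_profiles) == 0:
        return None
    stacked = np.vstack([np.asarray(p, dtype=float) for p in normalized_profiles])
    med = np.median(stacked, axis=0)
    total = med.sum()
    if total <= 0:
        return None
    return med / total


def build_cell_records(
    pixels: PixelSpectrumSet,
    marks: Sequence[AblationMark],
    labels: LabelImage,
    panel: Sequence[FattyAcidDefinition],
    model_variants: Mapping[str, str] | None = None,
    min_total_intensity: float = DEFAULT_MIN_TOTAL_INTENSITY,
    overlap_threshold: float = DEFAULT_OVERLAP_THRESHOLD,
    tol_ppm: float = 5.0,
    tracer_purity: float = 1.0,
    fit: bool = True,
) -> list[CellRecord]:
    """Full single-cell chain: extract → correct → normalize → filter →
    median-aggregate → renormalize → (even-reduce → fit).

    Marks are matched to spectra through the raster grid index, which must
    coincide with the pixel grid of ``pixels``. Cells with no surviving mark
    for a fatty acid carry a missing profile for it.
    """
    if model_variants is None:
        model_variants = {}
    # map grid index -> spectrum position
    index_of: dict[tuple[int, int], int] = {
        (int(r), int(c)): k for k, (r, c) in enumerate(pixels.pixel_index)}
    compute_overlap(marks, labels, overlap_threshold)

    per_fa_profiles: dict[str, dict[int, list[np.ndarray]]] = {}
    per_fa_assigned: dict[str, dict[int, list[int]]] = {}
    for fa in panel:
        raw = extract_isotopologue_intensities(pixels, fa, tol_ppm=tol_ppm)
        totals = {}
        normalized: dict[int, np.ndarray] = {}
        for mark in marks:
            k = index_of.get(mark.grid_index)
            if k is None:
                totals[mark.mark_id] = 0.0
                continue
            vec = raw[k]
            totals[mark.mark_id] = float(vec.sum())
            if vec.sum() > 0:
                prof = IsotopologueProfile(fa, vec)
                corr = correct_natural_abundance(prof, tracer_purity=tracer_purity)
                normalized[mark.mark_id] = corr.normalized().intensities
        assigned = filter_and_assign(
            marks, totals, min_total_intensity, overlap_threshold)
        per_fa_assigned[fa.name] = assigned
        per_fa_profiles[fa.name] = {
            cell: [normalized[m] for m in mk_ids if m in normalized]
            for cell, mk_ids in assigned.items()}

    records: list[CellRecord] = []
    for cell_id in labels.cell_ids:
        cell_id = int(cell_id)
        profiles: dict[str, IsotopologueProfile | None] = {}
        fits: dict[str, LabellingFit | None] = {}
        mark_ids: set[int] = set()
        for fa in panel:
            mk = per_fa_assigned[fa.name].get(cell_id, [])
            mark_ids.update(mk)
            agg = aggregate_cell_profile(per_fa_profiles[fa.name].get(cell_id, []))
            if agg is None:
                profiles[fa.name] = None
                fits[fa.name] = None
                continue
            prof = IsotopologueProfile(
                fa, agg, state="normalized", axis="mass_shift")
            profiles[fa.name] = prof
            if fit:
                variant = model_variants.get(
                    fa.name, "c18" if fa.n_carbons >= 18 else "c16")
                even = reduce_to_even(prof)
                fits[fa.name] = fit_labelling(even, variant=variant)
        records.append(CellRecord(
            cell_id=cell_id,
            area_um2=labels.cell_area(cell_id),
            mark_ids=sorted(mark_ids),
            profiles=profiles,
            fits=fits if fit else {},
        ))
    return records
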