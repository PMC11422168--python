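"""File formats and in-memory containers for imaging MS pixel data.

Everything here is plumbing: imzML spectra, integer label images from cell
segmentation, and the CSV single-cell table. No science lives in this module.

Internal conventions
--------------------
* Pixel grids are row-major and 0-based.  imzML stores 1-based ``(x, y)``
  coordinates; they are converted on read so that imzML pixel ``(1, 1)``
  becomes internal ``(row=0, col=0)``.
* Intensities are held as 64-bit floats regardless of the on-disk dtype,
  because natural-abundance correction produces signed intermediates.
* Spectra are stored processed-mode style (one m/z axis per pixel);
  continuous-mode files are expanded on read.
"""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PixelSpectrumSet",
    "LabelImage",
    "read_imzml",
    "write_imzml",
    "read_label_image",
    "write_cell_table",
    "read_cell_table",
]


@dataclasses.dataclass
class PixelSpectrumSet:
    """Centroided spectra on a rectangular raster.

    Parameters
    ----------
    pixel_index
        ``(n_pixels, 2)`` integer array of 0-based ``(row, col)`` grid
        coordinates, one per spectrum.
    mz
        List of 1-D arrays of centroid m/z values (Da), strictly increasing
        within each spectrum.
    intensity
        List of 1-D arrays of non-negative abundances, congruent with ``mz``.
    pitch
        Raster pitch in µm (spacing between adjacent ablation marks).
    grid_shape
        ``(n_rows, n_cols)`` of the acquisition raster.
    """

    pixel_index: np.ndarray
    mz: list[np.ndarray]
    intensity: list[np.ndarray]
    pitch: float
    grid_shape: tuple[int, int]

    def __post_init__(self) -> None:
        self.pixel_index = np.asarray(self.pixel_index, dtype=np.intp).reshape(-1, 2)
        if len(self.mz) != len(self.intensity) or len(self.mz) != len(self.pixel_index):
            raise ValueError("pixel_index, mz and intensity must have equal length")
        self.mz = [np.asarray(m, dtype=np.float64) for m in self.mz]
        self.intensity = [np.asarray(i, dtype=np.float64) for i in self.intensity]
        nr, nc = self.grid_shape
        for k, (m, i) in enumerate(zip(self.mz, self.intensity)):
            if m.shape != i.shape:
                raise ValueError(f"spectrum {k}: mz and intensity differ in length")
            if m.size > 1 and not np.all(np.diff(m) > 0):
                raise ValueError(f"spectrum {k}: m/z values must be strictly increasing")
            if np.any(i < 0):
                raise ValueError(f"spectrum {k}: negative intensity")
        r, c = self.pixel_index[:, 0], self.pixel_index[:, 1]
        if self.pixel_index.size and (
            r.min() < 0 or c.min() < 0 or r.max() >= nr or c.max() >= nc
        ):
            raise ValueError("pixel_index outside grid_shape")

    @property
    def n_pixels(self) -> int:
        return len(self.mz)

    def tic(self) -> np.ndarray:
        """Total ion count (sum of all centroid intensities) per pixel."""
        return np.array([i.sum() for i in self.intensity], dtype=np.float64)

    def spectrum_at(self, row: int, col: int) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(mz, intensity)`` of the pixel at grid position (row, col)."""
        hits = np.flatnonzero((self.pixel_index[:, 0] == row) & (self.pixel_index[:, 1] == col))
        if hits.size == 0:
            raise KeyError(f"no spectrum at ({row}, {col})")
        k = int(hits[0])
        return self.mz[k], self.intensity[k]


@dataclasses.dataclass
class LabelImage:
    """Integer cell-segmentation mask; 0 is background, k>0 a cell id."""

    labels: np.ndarray
    pixel_size: float = 1.0  # µm per microscopy pixel

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if not np.issubdtype(labels.dtype, np.integer):
            raise TypeError(
                "label image must be integer-valued; cast explicitly if the "
                "segmentation was saved as float"
            )
        if labels.ndim != 2:
            raise ValueError("label image must be 2-D single-channel")
        if labels.min() < 0:
            raise ValueError("labels must be non-negative")
        # widen so downstream arithmetic cannot overflow small dtypes
        self.labels = labels.astype(np.int64, copy=False)

    @property
    def cell_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def cell_area(self, cell_id: int) -> float:
        """Cell area in µm²."""
        return float(np.count_nonzero(self.labels == cell_id)) * self.pixel_size**2


def _to_zero_based(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """imzML 1-based (x, y) -> internal 0-based (row, col)."""
    return np.stack([np.asarray(y) - 1, np.asarray(x) - 1], axis=1)


def read_imzml(path: str | Path) -> PixelSpectrumSet:
    """Read an imzML/ibd pair (processed or continuous mode).

    The raster pitch is taken from the scan-settings metadata (``pixel size
    x``); 1-based imzML coordinates become 0-based (row, col).
    """
    from pyimzml.ImzMLParser import ImzMLParser

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        parser = ImzMLParser(str(path))
    except Exception as exc:  # noqa: BLE001 - surface as a format error
        raise ValueError(f"not a readable imzML file: {path}: {exc}") from exc

    mzs: list[np.ndarray] = []
    intensities: list[np.ndarray] = []
    xs: list[int] = []
    ys: list[int] = []
    for k, (x, y, _z) in enumerate(parser.coordinates):
        mz, inten = parser.getspectrum(k)
        mz = np.asarray(mz, dtype=np.float64)
        inten = np.asarray(inten, dtype=np.float64)
        if np.any(inten < 0):
            raise ValueError(f"pixel ({x},{y}): negative intensities in file")
        mzs.append(mz)
        intensities.append(inten)
        xs.append(int(x))
        ys.append(int(y))

    meta = parser.imzmldict
    pitch = float(meta.get("pixel size x", meta.get("pixel size y", 1.0)) or 1.0)
    n_cols = int(meta.get("max count of pixels x", max(xs) if xs else 1))
    n_rows = int(meta.get("max count of pixels y", max(ys) if ys else 1))
    index = _to_zero_based(np.array(xs), np.array(ys)) if xs else np.empty((0, 2), int)
    return PixelSpectrumSet(
        pixel_index=index,
        mz=mzs,
        intensity=intensities,
        pitch=pitch,
        grid_shape=(n_rows, n_cols),
    )


def write_imzml(pixels: PixelSpectrumSet, path: str | Path, mode: str = "processed") -> None:
    """Write a :class:`PixelSpectrumSet` as an imzML/ibd pair.

    Intensities are stored as 64-bit floats so write→read round-trips are
    lossless. The raster pitch is recorded as the ``pixel size x``/``y``
    scan settings (pyimzml does not emit them itself, so the XML is
    amended after writing).
    """
    from pyimzml.ImzMLWriter import ImzMLWriter

    path = Path(path)
    empty_indices = []
    with ImzMLWriter(
        str(path),
        mode=mode,
        intensity_dtype=np.float64,
    ) as writer:
        for k, ((row, col), mz, inten) in enumerate(
                zip(pixels.pixel_index, pixels.mz, pixels.intensity)):
            if mz.size == 0:
                # pyimzml cannot encode zero-length arrays: write a one-point
                # placeholder, then zero the declared lengths below so the
                # pixel reads back as an empty spectrum
                empty_indices.append(k)
                mz, inten = np.array([0.0]), np.array([0.0])
            writer.addSpectrum(mz, inten, (int(col) + 1, int(row) + 1, 1))
    text = path.read_text()
    for k in empty_indices:
        start = text.index(f'id="spectrum={k + 1}"')
        end = text.index("</spectrum>", start)
        block = text[start:end]
        for name in ("external array length", "external encoded length"):
            block = re.sub(
                rf'(name="{name}" value=")\d+(")', r"\g<1>0\g<2>", block)
        text = text[:start] + block + text[end:]
    path.write_text(text)
    anchor = 'name="max count of pixels y"'
    text = path.read_text()
    k = text.find(anchor)
    if k >= 0:
        eol = text.index("/>", k) + 2
        extra = (
            f'\n      <cvParam cvRef="IMS" accession="IMS:1000046" '
            f'name="pixel size x" value="{pixels.pitch:g}"/>'
            f'\n      <cvParam cvRef="IMS" accession="IMS:1000047" '
            f'name="pixel size y" value="{pixels.pitch:g}"/>'
        )
        path.write_text(text[:eol] + extra + text[eol:])


def read_label_image(path: str | Path) -> LabelImage:
    """Read a single-channel integer TIFF/PNG segmentation mask."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        arr = tifffile.imread(str(path))
    else:
        import imageio.v3 as iio

        arr = iio.imread(str(path))
    arr = np.asarray(arr)
    if np.issubdtype(arr.dtype, np.floating):
        raise TypeError(
            f"{path.name} is float-valued; label images must be integer — "
            "cast the segmentation explicitly before saving"
        )
    return LabelImage(labels=arr)


# ---------------------------------------------------------------------------
# single-cell table

_FLOAT_FMT = "%.17g"


def write_cell_table(records: Sequence, path: str | Path) -> None:
    """Write one CSV row per cell: profiles, fits, features, condition.

    All records must share a common fatty-acid panel; floats are written at
    17 significant digits so the table round-trips exactly.
    """
    rows = [r.to_row() for r in records]
    if rows:
        panel_cols = [tuple(sorted(k for k in row if "M+" in k)) for row in rows]
        if len(set(panel_cols)) > 1:
            ref = panel_cols[0]
            bad = [rows[i].get("cell_id") for i, pc in enumerate(panel_cols) if pc != ref]
            raise ValueError(f"inconsistent fatty-acid panels for cells {bad}")
        df = pd.DataFrame(rows)
    else:
        df = pd.DataFrame(
            columns=["cell_id", "area_um2", "n_marks", "condition"]
        )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_cell_table(path: str | Path) -> pd.DataFrame:
    """Read a cell table written by :func:`write_cell_table`.

    Uses round-trip float parsing so the table is numerically identical to
    what was written.
    """
    return pd.read_csv(path, float_precision="round_trip")
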