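"""Fatty-acid isotopologue models for single-cell stable-isotope tracing.

The scientific core of the package. Cells fed U-¹³C-glucose build fatty
acids by polymerizing two-carbon acetyl units drawn from the cytosolic
(lipogenic) acetyl-CoA pool. If a fraction *p* of that pool is fully
labelled (two ¹³C atoms per unit), the number of labelled units in a fatty
acid of C carbons (n = C/2 units) is binomial, so the even-mass-shift
isotopologue distribution M+0, M+2, …, M+2n carries *p* directly. A
fraction ``uptake`` of the fatty-acid pool is taken unlabelled from the
medium and contributes only at M+0. For C18 species, elongation of
unlabelled C16 precursors adds one (labelled) acetyl unit and contributes
at M+2, controlled by a third parameter ``uptake_C16``.

This module provides:

* :class:`FattyAcidDefinition` — formula, acetyl-unit count, theoretical
  [M−H]⁻ isotopologue m/z ladder;
* the binomial forward models (:func:`forward_model_c16`,
  :func:`forward_model_c18`) and the constrained least-squares inversion
  (:func:`fit_labelling`);
* natural-isotope-abundance correction of raw isotopologue intensities
  (:func:`correct_natural_abundance`), matrix-based in the style of IsoCor;
* the de-novo (fraction-labelled) statistic 1 − M+0/ΣM+n;
* extraction of isotopologue ladders from centroided pixel spectra.
"""

from __future__ import annotations

import dataclasses
import functools
import math
from typing import Sequence

import numpy as np
import scipy.linalg
import scipy.optimize

from .io_formats import PixelSpectrumSet

__all__ = [
    "DELTA_M_13C",
    "FattyAcidDefinition",
    "IsotopologueProfile",
    "ModelPrediction",
    "LabellingFit",
    "binomial_pmf",
    "forward_model_c16",
    "forward_model_c18",
    "forward_model",
    "fit_labelling",
    "natural_abundance_matrix",
    "correct_natural_abundance",
    "reduce_to_even",
    "de_novo_fraction",
    "extract_isotopologue_intensities",
    "default_panel",
]

#: mass difference ¹³C − ¹²C in Da
DELTA_M_13C = 1.0033548

# monoisotopic masses (Da)
_MASS = {"C": 12.0, "H": 1.00782503207, "O": 15.99491461956}
_ELECTRON = 0.00054857990907

# natural isotope abundances (fractions); heavy isotopes listed as
# (mass shift in integer units, abundance)
_NATURAL = {
    "C": [(1, 0.0107)],
    "H": [(1, 0.000115)],
    "O": [(1, 0.00038), (2, 0.00205)],
}


def _single_atom_pattern(element: str) -> np.ndarray:
    """Mass-shift distribution of one natural atom of ``element``."""
    heavies = _NATURAL[element]
    length = max(s for s, _ in heavies) + 1
    pat = np.zeros(length)
    pat[0] = 1.0 - sum(a for _, a in heavies)
    for shift, ab in heavies:
        pat[shift] = ab
    return pat


def _element_pattern(element: str, count: int) -> np.ndarray:
    """Mass-shift distribution of ``count`` natural atoms (iterated convolution)."""
    pat = np.array([1.0])
    single = _single_atom_pattern(element)
    for _ in range(count):
        pat = np.convolve(pat, single)
    return pat


@dataclasses.dataclass(frozen=True)
class FattyAcidDefinition:
    """A fatty acid observed as its RCOO⁻ fragment in negative-ion AIF-MS.

    Parameters
    ----------
    name
        Lipid shorthand, e.g. ``"C16:0"`` for palmitate.
    n_carbons
        Total carbons C; must be even and ≥ 4.
    n_double_bonds
        Number of C=C double bonds.

    Attributes
    ----------
    acetyl_units
        n = C/2, the number of acetyl-CoA units polymerized.
    formula
        Elemental composition of the carboxylate anion, C_c H_{2c−1−2d} O₂.
    mz_ladder
        Theoretical m/z of M+0 … M+C, spaced by the ¹³C−¹²C mass defect.
    """

    name: str
    n_carbons: int
    n_double_bonds: int = 0

    def __post_init__(self) -> None:
        if self.n_carbons < 4 or self.n_carbons % 2:
            raise ValueError("n_carbons must be even and >= 4")
        if self.n_double_bonds < 0:
            raise ValueError("n_double_bonds must be >= 0")

    @classmethod
    def from_name(cls, name: str) -> "FattyAcidDefinition":
        """Parse shorthand like ``"C16:0"`` or ``"18:1"``."""
        body = name.removeprefix("C").removeprefix("c")
        carbons, _, dbs = body.partition(":")
        return cls(name=name if name.startswith("C") else f"C{body}",
                   n_carbons=int(carbons), n_double_bonds=int(dbs or 0))

    @property
    def acetyl_units(self) -> int:
        return self.n_carbons // 2

    @property
    def formula(self) -> dict[str, int]:
        c, d = self.n_carbons, self.n_double_bonds
        return {"C": c, "H": 2 * c - 1 - 2 * d, "O": 2}

    @property
    def monoisotopic_mz(self) -> float:
        f = self.formula
        return sum(_MASS[el] * n for el, n in f.items()) + _ELECTRON

    @property
    def mz_ladder(self) -> np.ndarray:
        return self.monoisotopic_mz + DELTA_M_13C * np.arange(self.n_carbons + 1)


def default_panel() -> list[FattyAcidDefinition]:
    """The fatty acids routinely detected in negative-ion AIF imaging."""
    return [FattyAcidDefinition.from_name(n) for n in
            ("C14:0", "C16:0", "C16:1", "C18:0", "C18:1")]


@dataclasses.dataclass
class IsotopologueProfile:
    """Per-object (pixel or cell) intensity vector over one fatty acid's ladder.

    ``axis`` is ``"mass_shift"`` (length C+1, index j for M+j) or ``"acetyl"``
    (length n+1, index i for M+2i after even reduction). ``state`` tracks the
    processing stage: raw → corrected → normalized.
    """

    fatty_acid: FattyAcidDefinition
    intensities: np.ndarray
    state: str = "raw"
    axis: str = "mass_shift"
    total_raw: float | None = None
    qc_odd_fraction: float | None = None
    qc_flag: bool = False

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        expected = (self.fatty_acid.n_carbons if self.axis == "mass_shift"
                    else self.fatty_acid.acetyl_units) + 1
        if self.intensities.shape != (expected,):
            raise ValueError(
                f"profile length {self.intensities.size} != {expected} for "
                f"{self.fatty_acid.name} on axis {self.axis!r}")
        if self.state not in {"raw", "corrected", "normalized"}:
            raise ValueError(f"unknown state {self.state!r}")
        if self.state == "normalized" and abs(self.intensities.sum() - 1.0) > 1e-9:
            raise ValueError("normalized profile must sum to 1")

    def normalized(self) -> "IsotopologueProfile":
        """Return a copy normalized to unit sum (small negatives clipped to 0)."""
        v = np.clip(self.intensities, 0.0, None)
        total = v.sum()
        if total <= 0:
            raise ValueError("cannot normalize an all-zero profile")
        return dataclasses.replace(
            self, intensities=v / total, state="normalized",
            total_raw=self.total_raw if self.total_raw is not None
            else float(self.intensities.sum()))


@dataclasses.dataclass(frozen=True)
class ModelPrediction:
    """Expected normalized intensity over acetyl-unit index i = 0…n."""

    intensities: np.ndarray
    components: np.ndarray  # the binomial terms P_binom(i)

    def __iter__(self):
        return iter(self.intensities)


@dataclasses.dataclass
class LabellingFit:
    """Fitted binomial labelling parameters for one profile.

    ``p`` is the acetyl-CoA pool labelling degree, ``uptake`` the fraction of
    the fatty-acid pool taken unlabelled from the medium, ``uptake_c16`` the
    unlabelled-C16-precursor fraction (C18 model only). ``identifiable`` is
    False when the labelled mass fraction 1 − I₀ falls below a floor: with
    almost no labelling the binomial shape cannot be resolved and ``p`` is
    not meaningful.
    """

    p: float
    uptake: float
    uptake_c16: float | None
    residual: float
    identifiable: bool
    model_variant: str
    n: int


def binomial_pmf(p: float, n: int) -> np.ndarray:
    """Probability of k labelled acetyl units out of n at pool labelling p."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if n < 1:
        raise ValueError("n must be >= 1")
    k = np.arange(n + 1)
    coeff = np.array([math.comb(n, int(kk)) for kk in k], dtype=np.float64)
    with np.errstate(divide="ignore"):
        # evaluate in log space only where both bases are positive
        pk = np.where(k == 0, 1.0, p ** k.astype(float))
        qk = np.where(n - k == 0, 1.0, (1.0 - p) ** (n - k).astype(float))
    return coeff * pk * qk


def forward_model_c16(p: float, uptake: float, n: int = 8) -> ModelPrediction:
    """Binomial synthesis-plus-uptake model for a directly synthesized FA.

    I₀ = uptake + (1−uptake)·P(0);  Iᵢ = (1−uptake)·P(i) for i ≥ 1.
    Sums to 1 exactly for all parameters.
    """
    if not 0.0 <= uptake <= 1.0:
        raise ValueError(f"uptake must be in [0, 1], got {uptake}")
    pb = binomial_pmf(p, n)
    out = (1.0 - uptake) * pb
    out[0] += uptake
    return ModelPrediction(intensities=out, components=pb)


def forward_model_c18(
    p: float,
    uptake: float,
    uptake_c16: float,
    n: int = 9,
    renormalize: bool = True,
) -> ModelPrediction:
    """Elongation-aware model for C18 fatty acids (stearate, oleate).

    An unlabelled C16 precursor (fraction ``uptake_c16`` of the synthesized
    pool) elongated by one acetyl unit contributes at M+2 (acetyl index 1):

        I₀ = uptake + (1−uptake)·P(0)
        I₁ = (1−uptake)·(uptake_C16 + (1−uptake_C16)·P(1))
        Iᵢ = (1−uptake)·(1−uptake_C16)·P(i),  i ≥ 2

    As written these sum to 1 + (1−uptake)·uptake_C16·P(0) ≥ 1; since
    observed profiles are sum-normalized, the prediction is renormalized to
    unit sum by default. Pass ``renormalize=False`` to audit the equations
    verbatim.
    """
    for name, v in (("uptake", uptake), ("uptake_c16", uptake_c16)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    pb = binomial_pmf(p, n)
    out = (1.0 - uptake) * (1.0 - uptake_c16) * pb
    out[0] = uptake + (1.0 - uptake) * pb[0]
    out[1] = (1.0 - uptake) * (uptake_c16 + (1.0 - uptake_c16) * pb[1])
    if renormalize:
        out = out / out.sum()
    return ModelPrediction(intensities=out, components=pb)


def forward_model(params: Sequence[float], n: int, variant: str) -> np.ndarray:
    """Dispatch to the C16- or C18-type forward model; returns the vector."""
    if variant == "c16":
        return forward_model_c16(params[0], params[1], n=n).intensities
    if variant == "c18":
        return forward_model_c18(params[0], params[1], params[2], n=n).intensities
    raise ValueError(f"unknown model variant {variant!r}")


_STARTS_2D = [(0.1, 0.1), (0.1, 0.9), (0.9, 0.1), (0.9, 0.9)]
_STARTS_3D = [(p0, u0, c0) for p0 in (0.1, 0.9) for u0 in (0.1, 0.9)
              for c0 in (0.1, 0.9)]


def fit_labelling(
    profile: IsotopologueProfile | np.ndarray,
    variant: str = "c16",
    n: int | None = None,
    identifiability_floor: float = 0.05,
) -> LabellingFit:
    """Fit the binomial labelling model to a normalized acetyl-indexed profile.

    Box-constrained least squares (all parameters in [0, 1]) from four
    (C16) or eight (C18) deterministic corner starts at 0.1/0.9; the start
    with the lowest residual wins, ties broken by lower ``p``.

    Raises on a non-normalized :class:`IsotopologueProfile` or an all-zero
    vector. Plain arrays are accepted and normalized defensively if they sum
    to within 1e-6 of 1, else rejected.
    """
    if isinstance(profile, IsotopologueProfile):
        if profile.state != "normalized":
            raise ValueError("fit_labelling requires a normalized profile")
        if profile.axis != "acetyl":
            raise ValueError("fit_labelling requires an acetyl-unit-indexed "
                             "profile (apply reduce_to_even first)")
        y = profile.intensities
        n = profile.fatty_acid.acetyl_units
    else:
        y = np.asarray(profile, dtype=np.float64)
        if n is None:
            n = y.size - 1
    if y.size != n + 1:
        raise ValueError(f"profile length {y.size} != n+1 = {n + 1}")
    total = y.sum()
    if total <= 0:
        raise ValueError("cannot fit an all-zero profile")
    if abs(total - 1.0) > 1e-6:
        raise ValueError("profile must be normalized to unit sum")
    y = y / total

    if variant == "c16":
        starts = _STARTS_2D
    elif variant == "c18":
        starts = _STARTS_3D
    else:
        raise ValueError(f"unknown model variant {variant!r}")

    def residuals(theta: np.ndarray) -> np.ndarray:
        return forward_model(theta, n, variant) - y

    if variant == "c16":
        def jac(theta: np.ndarray) -> np.ndarray:
            p, u = theta
            pb = binomial_pmf(p, n)
            pb1 = binomial_pmf(p, n - 1)
            # d Binom(n,p)[k] / dp = n·(P_{n-1}[k-1] − P_{n-1}[k])
            dpb = n * (np.concatenate([[0.0], pb1])
                       - np.concatenate([pb1, [0.0]]))
            dp_col = (1.0 - u) * dpb
            du_col = -pb
            du_col = du_col.copy()
            du_col[0] += 1.0
            return np.column_stack([dp_col, du_col])
    else:
        jac = "2-point"

    best: tuple[float, float, np.ndarray] | None = None  # (sse, p, theta)
    for x0 in starts:
        sol = scipy.optimize.least_squares(
            residuals, x0=np.array(x0), bounds=(0.0, 1.0), jac=jac,
            xtol=1e-15, ftol=1e-15, gtol=1e-15, method="trf")
        sse = float(np.sum(sol.fun**2))
        key = (sse, float(sol.x[0]))
        if best is None or key < (best[0], best[1]):
            best = (sse, float(sol.x[0]), sol.x)
    assert best is not None
    sse, _, theta = best
    labelled_fraction = 1.0 - y[0]
    return LabellingFit(
        p=float(theta[0]),
        uptake=float(theta[1]),
        uptake_c16=float(theta[2]) if variant == "c18" else None,
        residual=sse,
        identifiable=bool(labelled_fraction >= identifiability_floor),
        model_variant=variant,
        n=n,
    )


# ---------------------------------------------------------------------------
# natural-abundance correction


@functools.lru_cache(maxsize=64)
def _natural_abundance_matrix_cached(
    formula_items: tuple[tuple[str, int], ...],
    n_tracer_positions: int,
    tracer_purity: float,
) -> np.ndarray:
    formula = dict(formula_items)
    c = n_tracer_positions
    size = c + 1
    A = np.zeros((size, size))
    for j in range(size):
        # tracer positions: Binom(j, purity) ¹³C atoms → shifts 0…j
        # (a delta at shift j when purity is 1)
        pattern = binomial_pmf(tracer_purity, j) if j > 0 else np.array([1.0])
        for el, count in formula.items():
            natural_count = count - j if el == "C" else count
            pattern = np.convolve(pattern, _element_pattern(el, natural_count))
        m = min(size, pattern.size)
        A[:m, j] = pattern[:m]
    # renormalize columns: natural-isotope mass falling beyond the measured
    # M+C window (< 1% even for the fully labelled species) is folded back
    # so that convolution conserves total intensity exactly
    A /= A.sum(axis=0, keepdims=True)
    A.setflags(write=False)
    return A


def natural_abundance_matrix(
    formula: dict[str, int],
    n_tracer_positions: int,
    tracer_purity: float = 1.0,
) -> np.ndarray:
    """Correction matrix A mapping tracer-labelled species to observed shifts.

    Column j is the theoretical mass-shift distribution of the species with j
    tracer-¹³C atoms: a binomial purity term over the j tracer positions
    convolved with the natural-abundance patterns of the remaining carbons
    and of all H and O atoms, truncated to shifts 0…C with the far-tail
    mass folded back (columns sum to 1, so convolution conserves total
    intensity). Observed raw intensities M_raw relate to tracer enrichments
    M_corr via ``M_raw = A @ M_corr``. Results are memoized per formula.
    """
    if formula.get("C", 0) < n_tracer_positions:
        raise ValueError("formula has fewer carbons than tracer positions")
    return _natural_abundance_matrix_cached(
        tuple(sorted(formula.items())), n_tracer_positions, float(tracer_purity))


def correct_natural_abundance(
    raw: IsotopologueProfile,
    tracer_purity: float = 1.0,
    negative_tolerance: float = 1e-12,
    max_condition: float = 1e12,
) -> IsotopologueProfile:
    """Remove natural heavy-isotope contributions from a raw ladder.

    Solves ``A @ x = raw`` with the correction matrix of the fragment's
    formula. If the direct solution carries negative components beyond
    ``negative_tolerance`` (noise pushing below zero), it is replaced by the
    non-negativity-constrained least-squares solution.
    """
    if raw.axis != "mass_shift":
        raise ValueError("correction applies to the mass-shift-indexed ladder")
    v = raw.intensities
    if v.sum() <= 0:
        raise ValueError("cannot correct an all-zero profile")
    fa = raw.fatty_acid
    A = natural_abundance_matrix(fa.formula, fa.n_carbons, tracer_purity)
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > max_condition:
        raise np.linalg.LinAlgError(
            f"correction matrix ill-conditioned (cond={cond:.3g})")
    if tracer_purity >= 1.0:
        x = scipy.linalg.solve_triangular(A, v, lower=True)
    else:
        x = np.linalg.solve(A, v)
    scale = max(v.max(), 1.0)
    if x.min() < -negative_tolerance * scale:
        x, _ = scipy.optimize.nnls(A, v)
    return dataclasses.replace(
        raw, intensities=x, state="corrected", total_raw=float(v.sum()))


def reduce_to_even(
    corrected: IsotopologueProfile,
    qc_bound: float = 0.05,
) -> IsotopologueProfile:
    """Collapse a corrected M+0…M+C ladder to acetyl-unit index (M+2i).

    Odd-shift intensities are tracer-impossible under the two-carbon-unit
    model; their mass fraction is reported as a QC metric (``qc_odd_fraction``)
    and flags the profile when it exceeds ``qc_bound``. The even entries are
    renormalized to unit sum.
    """
    if corrected.axis != "mass_shift":
        raise ValueError("reduce_to_even expects a mass-shift-indexed profile")
    v = np.clip(corrected.intensities, 0.0, None)
    total = v.sum()
    if total <= 0:
        raise ValueError("cannot reduce an all-zero profile")
    even = v[::2]
    odd_fraction = float(v[1::2].sum() / total)
    even_sum = even.sum()
    if even_sum <= 0:
        raise ValueError("no mass at even shifts")
    return dataclasses.replace(
        corrected,
        intensities=even / even_sum,
        state="normalized",
        axis="acetyl",
        qc_odd_fraction=odd_fraction,
        qc_flag=odd_fraction > qc_bound,
        total_raw=corrected.total_raw,
    )


def de_novo_fraction(profile: IsotopologueProfile | np.ndarray) -> float:
    """Fraction of the pool carrying any tracer carbon: 1 − M+0 / Σ M+n."""
    v = profile.intensities if isinstance(profile, IsotopologueProfile) else np.asarray(profile, float)
    total = v.sum()
    if total <= 0:
        return float("nan")
    return float(1.0 - v[0] / total)


# ---------------------------------------------------------------------------
# peak extraction


def extract_isotopologue_intensities(
    pixels: PixelSpectrumSet,
    fa: FattyAcidDefinition,
    tol_ppm: float = 5.0,
) -> np.ndarray:
    """Sum centroid intensities within ±tol_ppm of each ladder mass, per pixel.

    Returns an ``(n_pixels, C+1)`` array aligned with ``pixels.pixel_index``;
    absent peaks contribute 0. Raises if the ppm windows of adjacent ladder
    masses would overlap (ambiguous assignment).
    """
    ladder = fa.mz_ladder
    half = ladder * tol_ppm * 1e-6
    lo, hi = ladder - half, ladder + half
    if np.any(hi[:-1] >= lo[1:]):
        raise ValueError(
            f"tol_ppm={tol_ppm} makes adjacent isotopologue windows overlap "
            f"for {fa.name}")
    out = np.zeros((pixels.n_pixels, ladder.size))
    for k, (mz, inten) in enumerate(zip(pixels.mz, pixels.intensity)):
        if mz.size == 0:
            continue
        i0 = np.searchsorted(mz, lo)
        i1 = np.searchsorted(mz, hi, side="right")
        for j in range(ladder.size):
            if i1[j] > i0[j]:
                out[k, j] = inten[i0[j]:i1[j]].sum()
    return out
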