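"""Forward models, natural-abundance correction and profile arithmetic."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from lipotrace.io_formats import PixelSpectrumSet
from lipotrace.isotope_model import (
    DELTA_M_13C,
    FattyAcidDefinition,
    IsotopologueProfile,
    binomial_pmf,
    correct_natural_abundance,
    de_novo_fraction,
    extract_isotopologue_intensities,
    forward_model_c16,
    forward_model_c18,
    natural_abundance_matrix,
    reduce_to_even,
)

unit = st.floats(0.0, 1.0, allow_nan=False)


class TestFattyAcidDefinition:
    def test_palmitate_fragment_mass(self, c16):
        # C16H31O2⁻, reference monoisotopic [M−H]⁻ value
        assert c16.monoisotopic_mz == pytest.approx(255.2330, abs=1e-3)
        assert c16.acetyl_units == 8
        assert c16.formula == {"C": 16, "H": 31, "O": 2}

    def test_ladder_spacing_is_carbon_mass_defect(self, c16):
        ladder = c16.mz_ladder
        assert ladder.size == 17
        assert np.allclose(np.diff(ladder), DELTA_M_13C, atol=1e-9)
        assert np.all(np.diff(ladder) > 0)

    def test_oleate_formula_accounts_for_double_bond(self):
        fa = FattyAcidDefinition.from_name("C18:1")
        assert fa.formula == {"C": 18, "H": 33, "O": 2}
        assert fa.acetyl_units == 9

    @pytest.mark.parametrize("carbons", [3, 5, 2])
    def test_odd_or_short_chains_rejected(self, carbons):
        with pytest.raises(ValueError):
            FattyAcidDefinition(name="bad", n_carbons=carbons)


class TestBinomialPmf:
    def test_degenerate_unlabelled(self):
        assert np.array_equal(binomial_pmf(0.0, 8),
                              np.eye(9)[0])

    def test_symmetric_half(self):
        assert np.allclose(binomial_pmf(0.5, 2), [0.25, 0.5, 0.25])

    def test_closed_form_entry(self):
        # k=4 of Binom(8, 0.6)
        expected = math.comb(8, 4) * 0.6**4 * 0.4**4
        assert binomial_pmf(0.6, 8)[4] == pytest.approx(expected, rel=1e-12)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            binomial_pmf(1.2, 8)


class TestForwardModels:
    def test_pure_uptake_is_all_m0(self):
        out = forward_model_c16(0.37, 1.0).intensities
        assert np.allclose(out, np.eye(9)[0])

    def test_fully_labelled_is_delta_at_n(self):
        out = forward_model_c16(1.0, 0.0).intensities
        assert np.allclose(out, np.eye(9)[8])

    def test_i0_closed_form(self):
        out = forward_model_c16(0.61, 0.30).intensities
        assert out[0] == pytest.approx(0.30 + 0.70 * 0.39**8, rel=1e-12)

    def test_monte_carlo_cross_check(self):
        # sample molecules: with prob uptake all-unlabelled, else n Bernoulli units
        rng = np.random.default_rng(5)
        p, u, n, m = 0.61, 0.30, 8, 10**6
        taken_up = rng.random(m) < u
        labelled_units = rng.binomial(n, p, size=m)
        labelled_units[taken_up] = 0
        counts = np.bincount(labelled_units, minlength=n + 1) / m
        model = forward_model_c16(p, u, n).intensities
        assert np.allclose(counts, model, atol=4 / np.sqrt(m))

    @given(p=unit, u=unit)
    def test_c16_sums_to_one(self, p, u):
        assert forward_model_c16(p, u).intensities.sum() == pytest.approx(1.0, abs=1e-12)

    @given(p=unit, u=unit, uc=unit)
    def test_c18_sums_to_one_after_renormalization(self, p, u, uc):
        assert forward_model_c18(p, u, uc).intensities.sum() == pytest.approx(1.0, abs=1e-12)

    def test_c18_as_printed_excess_mass(self):
        # verbatim equations carry an extra (1-u)·uc·P(0) of mass
        p, u, uc = 0.3, 0.2, 0.5
        raw = forward_model_c18(p, u, uc, renormalize=False).intensities
        assert raw.sum() == pytest.approx(
            1.0 + (1 - u) * uc * binomial_pmf(p, 9)[0], rel=1e-12)

    def test_c18_degenerate_elongation_case(self):
        # uptake=0, uptake_C16=1, p=0: printed equations put unit mass at both
        # i=0 (P(0)=1) and i=1 (elongation); renormalized → (0.5, 0.5, 0, …)
        out = forward_model_c18(0.0, 0.0, 1.0).intensities
        assert np.allclose(out[:2], [0.5, 0.5])
        assert np.allclose(out[2:], 0.0)

    def test_c18_reduces_to_c16_without_elongation(self):
        a = forward_model_c18(0.4, 0.3, 0.0).intensities
        b = forward_model_c16(0.4, 0.3, n=9).intensities
        assert np.allclose(a, b, atol=1e-14)

    def test_c16_uptake_one_dominates_any_p(self):
        out = forward_model_c18(0.9, 1.0, 0.7).intensities
        assert np.allclose(out, np.eye(10)[0])

    def test_m0_monotone_in_p_and_uptake(self):
        ps = np.linspace(0.01, 0.99, 25)
        i0_p = [forward_model_c16(p, 0.3).intensities[0] for p in ps]
        assert np.all(np.diff(i0_p) < 0)
        i0_u = [forward_model_c16(0.4, u).intensities[0] for u in ps]
        assert np.all(np.diff(i0_u) > 0)


class TestNaturalAbundanceCorrection:
    def test_unlabelled_natural_pattern_corrects_to_delta(self, c16):
        A = natural_abundance_matrix(c16.formula, 16)
        raw = IsotopologueProfile(c16, A[:, 0] * 1e5)
        corrected = correct_natural_abundance(raw)
        expected = np.zeros(17)
        expected[0] = 1e5
        assert np.allclose(corrected.intensities, expected, atol=1e-6)

    @given(st.integers(0, 2**31 - 1))
    def test_convolve_then_correct_is_identity(self, seed):
        fa = FattyAcidDefinition.from_name("C16:0")
        A = natural_abundance_matrix(fa.formula, 16)
        x = np.random.default_rng(seed).random(17)
        raw = IsotopologueProfile(fa, A @ x)
        back = correct_natural_abundance(raw).intensities
        assert np.max(np.abs(back - x)) <= 1e-10 * max(1.0, np.abs(x).max())

    def test_all_zero_raw_rejected(self, c16):
        with pytest.raises(ValueError):
            correct_natural_abundance(IsotopologueProfile(c16, np.zeros(17)))

    def test_columns_conserve_intensity(self, c16):
        # truncated far-tail mass is folded back: columns sum to exactly 1
        A = natural_abundance_matrix(c16.formula, 16)
        assert np.allclose(A.sum(axis=0), 1.0, atol=1e-12)

    def test_purity_below_one_shifts_mass_down(self, c16):
        A = natural_abundance_matrix(c16.formula, 16, tracer_purity=0.99)
        # the fully labelled species now has mass below shift 16
        assert A[15, 16] > 0
        col_16 = A[:, 16]
        assert col_16[16] < natural_abundance_matrix(c16.formula, 16)[16, 16]

    def test_negative_noise_resolved_nonnegatively(self, c16):
        A = natural_abundance_matrix(c16.formula, 16)
        x = np.zeros(17)
        x[0] = 1e4
        raw_v = A @ x
        raw_v[1] *= 0.2  # deplete M+1 below its natural share
        out = correct_natural_abundance(IsotopologueProfile(c16, raw_v))
        assert out.intensities.min() >= -1e-9


class TestReduceAndDeNovo:
    def test_even_reduction_arithmetic(self, c16):
        v = np.zeros(17)
        v[0], v[1], v[2] = 0.5, 0.1, 0.4
        prof = IsotopologueProfile(c16, v, state="corrected")
        even = reduce_to_even(prof)
        assert np.allclose(even.intensities[:2], [0.5 / 0.9, 0.4 / 0.9])
        assert even.qc_odd_fraction == pytest.approx(0.1)
        assert even.qc_flag  # 10% odd mass exceeds the default 5% QC bound

    def test_zero_odd_mass_passes_qc(self, c16):
        v = np.zeros(17)
        v[::2] = 1.0
        even = reduce_to_even(IsotopologueProfile(c16, v, state="corrected"))
        assert even.qc_odd_fraction == 0.0
        assert even.intensities.sum() == pytest.approx(1.0)

    def test_large_odd_mass_flags(self, c16):
        v = np.zeros(17)
        v[0], v[1] = 0.5, 0.5
        even = reduce_to_even(IsotopologueProfile(c16, v, state="corrected"))
        assert even.qc_flag

    def test_corrected_synthetic_spectrum_has_low_odd_mass(self, c16):
        rng = np.random.default_rng(3)
        A = natural_abundance_matrix(c16.formula, 16)
        even = forward_model_c16(0.5, 0.3).intensities
        full = np.zeros(17)
        full[::2] = even
        raw_v = (A @ full) * rng.lognormal(0, 0.1, 17) * 1e4
        corrected = correct_natural_abundance(IsotopologueProfile(c16, raw_v))
        assert reduce_to_even(corrected).qc_odd_fraction < 0.02

    @pytest.mark.parametrize("vec,expected", [
        (np.eye(9)[0], 0.0),
        (np.eye(9)[8], 1.0),
    ])
    def test_de_novo_extremes(self, vec, expected):
        assert de_novo_fraction(vec) == expected

    @given(p=st.floats(0.01, 0.99), u=st.floats(0.0, 0.99))
    def test_de_novo_closed_form_identity(self, p, u):
        frac = de_novo_fraction(forward_model_c16(p, u).intensities)
        assert frac == pytest.approx((1 - u) * (1 - (1 - p) ** 8), rel=1e-9)

    def test_de_novo_of_empty_is_nan(self):
        assert math.isnan(de_novo_fraction(np.zeros(9)))


class TestExtraction:
    def _pixelset(self, mz, inten):
        return PixelSpectrumSet(pixel_index=[(0, 0)], mz=[np.asarray(mz, float)],
                                intensity=[np.asarray(inten, float)],
                                pitch=10.0, grid_shape=(1, 1))

    def test_no_nearby_peaks_gives_zero_vector(self, c16):
        px = self._pixelset([300.0, 400.0], [5.0, 5.0])
        out = extract_isotopologue_intensities(px, c16)
        assert np.array_equal(out, np.zeros((1, 17)))

    def test_single_centroid_at_m2(self, c16):
        px = self._pixelset([c16.mz_ladder[2]], [42.0])
        out = extract_isotopologue_intensities(px, c16)[0]
        assert out[2] == 42.0
        assert out.sum() == 42.0

    def test_jittered_peaks_recovered_exactly(self, c16):
        rng = np.random.default_rng(7)
        truth = rng.random(17) * 100
        jitter = rng.uniform(-2e-6, 2e-6, 17)
        mz = c16.mz_ladder * (1 + jitter)
        order = np.argsort(mz)
        px = self._pixelset(mz[order], truth[order])
        out = extract_isotopologue_intensities(px, c16, tol_ppm=5.0)[0]
        assert np.allclose(out, truth)

    def test_overlapping_windows_rejected(self, c16):
        with pytest.raises(ValueError):
            extract_isotopologue_intensities(
                self._pixelset([255.0], [1.0]), c16, tol_ppm=3000.0)
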