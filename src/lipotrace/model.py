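"""Model/Results interface over the binomial labelling fit.

:class:`BinomialLabellingModel` wraps :func:`lipotrace.isotope_model.
fit_labelling` in the familiar endog-model-fit-results idiom: build the
model from one or many normalized acetyl-indexed isotopologue profiles,
call :meth:`~BinomialLabellingModel.fit`, and read estimates, approximate
standard errors, diagnostics and a ``summary()`` table off the results
object.

Standard errors are Gauss–Newton approximations, ``cov = s²·(JᵀJ)⁻¹`` with
``s² = SSE/(m−k)`` and a forward-difference Jacobian at the solution; they
are indicative only near the interior of the parameter box and are reported
as NaN for parameters pinned at a bound.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .isotope_model import (
    IsotopologueProfile,
    LabellingFit,
    fit_labelling,
    forward_model,
)

__all__ = ["BinomialLabellingModel", "LabellingResults"]

_PARAM_NAMES = {"c16": ["p", "uptake"], "c18": ["p", "uptake", "uptake_c16"]}


class BinomialLabellingModel:
    """Binomial synthesis-plus-uptake model for isotopologue profiles.

    Parameters
    ----------
    profiles
        A single normalized acetyl-indexed profile (1-D array of length
        n+1 or :class:`IsotopologueProfile`) or a stack of them (2-D array,
        list, or DataFrame rows).
    variant
        ``"c16"`` (two parameters) or ``"c18"`` (adds the unlabelled-C16
        elongation fraction).
    """

    def __init__(self, profiles, variant: str = "c16",
                 identifiability_floor: float = 0.05):
        if isinstance(profiles, IsotopologueProfile):
            profiles = [profiles]
        if isinstance(profiles, pd.DataFrame):
            self._index = profiles.index
            data = profiles.to_numpy(dtype=float)
        elif isinstance(profiles, (list, tuple)) and profiles and isinstance(
                profiles[0], IsotopologueProfile):
            self._index = pd.RangeIndex(len(profiles))
            data = np.vstack([p.intensities for p in profiles])
            for p in profiles:
                if p.state != "normalized" or p.axis != "acetyl":
                    raise ValueError(
                        "profiles must be normalized and acetyl-indexed")
        else:
            data = np.asarray(profiles, dtype=float)
            if data.ndim == 1:
                data = data[None, :]
            self._index = pd.RangeIndex(data.shape[0])
        self.endog = data
        self.variant = variant
        self.n = data.shape[1] - 1
        self.identifiability_floor = identifiability_floor

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, fatty_acid: str,
                       variant: str | None = None,
                       **kwargs) -> "BinomialLabellingModel":
        """Build from cell-table columns named ``<fa>_M+0, <fa>_M+2, …``."""
        cols = sorted(
            (c for c in df.columns if c.startswith(f"{fatty_acid}_M+")),
            key=lambda c: int(c.rsplit("+", 1)[1]))
        if not cols:
            raise KeyError(f"no isotopologue columns for {fatty_acid!r}")
        sub = df[cols].dropna()
        if variant is None:
            n_carbons = int(cols[-1].rsplit("+", 1)[1])
            variant = "c18" if n_carbons >= 18 else "c16"
        model = cls(sub, variant=variant, **kwargs)
        return model

    def fit(self) -> "LabellingResults":
        fits = [fit_labelling(row / row.sum(), variant=self.variant,
                              n=self.n,
                              identifiability_floor=self.identifiability_floor)
                for row in self.endog]
        return LabellingResults(self, fits)

    def predict(self, params: Sequence[float]) -> np.ndarray:
        """Model-implied normalized profile for explicit parameter values."""
        return forward_model(params, self.n, self.variant)


class LabellingResults:
    """Fit results: per-profile estimates, diagnostics and summaries."""

    def __init__(self, model: BinomialLabellingModel, fits: list[LabellingFit]):
        self.model = model
        self.fits = fits
        names = _PARAM_NAMES[model.variant]
        rows = []
        for f in fits:
            row = {"p": f.p, "uptake": f.uptake}
            if model.variant == "c18":
                row["uptake_c16"] = f.uptake_c16
            row["residual"] = f.residual
            row["identifiable"] = f.identifiable
            rows.append(row)
        self.params = pd.DataFrame(rows, index=model._index)[
            names + ["residual", "identifiable"]]
        self._names = names

    @property
    def identifiable(self) -> pd.Series:
        return self.params["identifiable"]

    def predict(self) -> np.ndarray:
        """Fitted normalized profiles, one row per observation."""
        return np.vstack([self.model.predict(
            [f.p, f.uptake] + ([f.uptake_c16] if f.uptake_c16 is not None else []))
            for f in self.fits])

    def resid(self) -> np.ndarray:
        return self.model.endog / self.model.endog.sum(
            axis=1, keepdims=True) - self.predict()

    def bse(self) -> pd.DataFrame:
        """Gauss–Newton standard errors (NaN at parameter bounds)."""
        out = []
        m = self.model.n + 1
        k = len(self._names)
        for f, y in zip(self.fits, self.model.endog):
            theta = np.array([f.p, f.uptake] +
                             ([f.uptake_c16] if f.uptake_c16 is not None else []))
            eps = 1e-6
            J = np.empty((m, k))
            for j in range(k):
                hi = np.minimum(theta[j] + eps, 1.0)
                lo = np.maximum(theta[j] - eps, 0.0)
                th_hi, th_lo = theta.copy(), theta.copy()
                th_hi[j], th_lo[j] = hi, lo
                J[:, j] = (self.model.predict(th_hi)
                           - self.model.predict(th_lo)) / (hi - lo)
            dof = max(m - k, 1)
            s2 = f.residual / dof
            try:
                cov = s2 * np.linalg.inv(J.T @ J)
                se = np.sqrt(np.clip(np.diag(cov), 0, None))
            except np.linalg.LinAlgError:
                se = np.full(k, np.nan)
            at_bound = (theta <= 1e-9) | (theta >= 1 - 1e-9)
            se[at_bound] = np.nan
            out.append(se)
        return pd.DataFrame(out, index=self.model._index, columns=self._names)

    def summary(self) -> str:
        """Readable fit report: per-profile for one observation, population
        quantiles otherwise."""
        lines = [
            "Binomial labelling model results",
            "=" * 48,
            f"variant: {self.model.variant}   acetyl units n: {self.model.n}"
            f"   profiles: {len(self.fits)}",
        ]
        if len(self.fits) == 1:
            f = self.fits[0]
            se = self.bse().iloc[0]
            lines.append(f"{'param':<12}{'estimate':>12}{'approx se':>12}")
            lines.append("-" * 36)
            values = {"p": f.p, "uptake": f.uptake, "uptake_c16": f.uptake_c16}
            for name in self._names:
                se_txt = f"{se[name]:.4f}" if np.isfinite(se[name]) else "--"
                lines.append(f"{name:<12}{values[name]:>12.4f}{se_txt:>12}")
            lines.append(f"SSE: {f.residual:.3e}   "
                         f"identifiable: {f.identifiable}")
        else:
            q = self.params[self._names].quantile([0.25, 0.5, 0.75])
            lines.append(f"{'param':<12}{'median':>10}{'q25':>10}{'q75':>10}")
            lines.append("-" * 42)
            for name in self._names:
                lines.append(f"{name:<12}{q.loc[0.5, name]:>10.4f}"
                             f"{q.loc[0.25, name]:>10.4f}"
                             f"{q.loc[0.75, name]:>10.4f}")
            n_id = int(self.params['identifiable'].sum())
            lines.append(f"identifiable fits: {n_id}/{len(self.fits)}")
        return "\n".join(lines)

    def plot_profile(self, idx: int = 0, ax=None):
        """Observed vs fitted isotopologue distribution for one profile."""
        from . import viz

        y = self.model.endog[idx] / self.model.endog[idx].sum()
        return viz.plot_profile_fit(y, self.predict()[idx], ax=ax)
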