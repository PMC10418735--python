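"""Linear retention model shared by the RP-HPLC and RP-TLC stages.

Isocratic reversed-phase retention is, to good approximation, linear in the
volume fraction Φ of the organic modifier:

    log k = log kw + S·Φ        (HPLC)
    R_M   = R_M0  + S·Φ        (TLC)

with a negative slope S. The intercept — the retention extrapolated to pure
water (Φ = 0) — is the chromatographic lipophilicity index (log kw or R_M0),
and Φ0 = −intercept/S is the modifier fraction at which log k (or R_M)
vanishes. :class:`RetentionLineModel` fits this line by ordinary least
squares and returns a :class:`LipophilicityFit` results object.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .core import (
    DegenerateDesignError,
    InvalidInputError,
    RetentionPoint,
    RetentionSeries,
)

__all__ = ["RetentionLineModel", "LipophilicityFit", "extrapolate_phi0"]


def extrapolate_phi0(intercept: float, slope: float) -> float:
    """Modifier fraction at which the fitted retention line crosses zero.

    Returns ``-intercept/slope``; NaN when the slope is zero (a flat
    retention line never crosses zero, so Φ0 is undefined).
    """
    if slope == 0.0:
        return math.nan
    return -intercept / slope


@dataclass(frozen=True)
class LipophilicityFit:
    """Results of a retention-line fit.

    Attributes
    ----------
    intercept : float
        log kw (RP-HPLC) or R_M0 (RP-TLC): retention extrapolated to Φ = 0,
        on the logP scale.
    slope : float
        S, retention units per unit volume fraction; negative for
        reversed-phase behaviour.
    abs_correlation : float
        |Pearson r| between Φ and the measurements, in [0, 1]. Reported as a
        magnitude because the underlying slope is negative.
    phi0 : float
        −intercept/slope; NaN when the slope is zero.
    n_points : int
        Number of (Φ, value) pairs used.
    residual_sd : float
        Residual standard deviation, sqrt(SSR/(n−2)); NaN for n ≤ 2.
    intercept_se, slope_se : float
        OLS standard errors of the estimates; NaN for n ≤ 2.
    compound_id, technique : str, optional
        Provenance labels carried through from the series.
    """

    intercept: float
    slope: float
    abs_correlation: float
    n_points: int
    residual_sd: float
    intercept_se: float = math.nan
    slope_se: float = math.nan
    compound_id: Optional[str] = None
    technique: Optional[str] = None

    @property
    def phi0(self) -> float:
        return extrapolate_phi0(self.intercept, self.slope)

    @property
    def intercept_label(self) -> str:
        return "R_M0" if self.technique == "RP-TLC" else "log kw"

    def predict(self, phi):
        """Fitted retention value(s) at modifier fraction(s) ``phi``."""
        return self.intercept + self.slope * np.asarray(phi, dtype=float)

    def conf_int(self, alpha: float = 0.05) -> dict[str, tuple[float, float]]:
        """Two-sided (1−alpha) confidence intervals for intercept and slope."""
        if self.n_points <= 2 or math.isnan(self.slope_se):
            nan = (math.nan, math.nan)
            return {"intercept": nan, "slope": nan}
        t = stats.t.ppf(1.0 - alpha / 2.0, self.n_points - 2)
        return {
            "intercept": (
                self.intercept - t * self.intercept_se,
                self.intercept + t * self.intercept_se,
            ),
            "slope": (self.slope - t * self.slope_se, self.slope + t * self.slope_se),
        }

    def summary(self) -> str:
        """Human-readable fit report (intercept/slope to 2 dp, Φ0 and |r| to 3 dp)."""
        who = self.compound_id or "?"
        tech = self.technique or "?"
        lines = [
            f"Retention line fit — compound {who} ({tech})",
            f"  {self.intercept_label:8s} {self.intercept:8.2f}  (SE {self.intercept_se:.3g})",
            f"  {'S':8s} {self.slope:8.2f}  (SE {self.slope_se:.3g})",
            f"  {'phi0':8s} {self.phi0:8.3f}",
            f"  {'|r|':8s} {self.abs_correlation:8.3f}",
            f"  {'n':8s} {self.n_points:8d}",
            f"  {'resid sd':8s} {self.residual_sd:8.4f}",
        ]
        return "\n".join(lines)

    def plot(self, series: Optional[RetentionSeries] = None, ax=None):
        """Plot the fitted line (and the data, if a series is given)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if series is not None:
            ax.plot(series.phis, series.values, "o", label="measured")
            lo, hi = min(series.phis), max(series.phis)
        else:
            lo, hi = 0.0, 1.0
        grid = np.linspace(min(0.0, lo), hi, 50)
        ax.plot(grid, self.predict(grid), "-", label="OLS fit")
        ax.axhline(0.0, color="grey", lw=0.5)
        ax.set_xlabel("methanol volume fraction $\\Phi$")
        ax.set_ylabel("$\\log k$" if self.technique != "RP-TLC" else "$R_M$")
        ax.set_title(f"compound {self.compound_id or '?'}: "
                     f"{self.intercept_label} = {self.intercept:.2f}, "
                     f"$\\Phi_0$ = {self.phi0:.3f}")
        ax.legend()
        return ax


class RetentionLineModel:
    """Ordinary least-squares line through one compound's retention series.

    Parameters
    ----------
    series : RetentionSeries
        Measurements from one technique on a gradient of ≥ 3 distinct
        modifier fractions.

    Examples
    --------
    >>> from chromlip.core import RetentionPoint, RetentionSeries
    >>> pts = [RetentionPoint(phi, 2.0 - 3.0 * phi) for phi in (0.55, 0.65, 0.75)]
    >>> fit = RetentionLineModel(RetentionSeries("x", "RP-HPLC", pts)).fit()
    >>> round(fit.intercept, 10), round(fit.slope, 10)
    (2.0, -3.0)
    """

    def __init__(self, series: RetentionSeries):
        self.series = series
        values = np.asarray(series.values, dtype=float)
        if not np.all(np.isfinite(values)):
            raise InvalidInputError(
                f"compound {series.compound_id!r}: non-finite retention value"
            )
        self._phi = np.asarray(series.phis, dtype=float)
        self._y = values

    @classmethod
    def from_points(cls, phi, values, compound_id: str = "?",
                    technique: str = "RP-HPLC") -> "RetentionLineModel":
        """Build a model directly from arrays, without the ≥3-level gate.

        Intended for diagnostics and estimator studies on minimal designs;
        regular pipelines should go through :class:`RetentionSeries`, which
        enforces the three-level minimum.
        """
        self = cls.__new__(cls)
        phi = np.asarray(phi, dtype=float)
        values = np.asarray(values, dtype=float)
        if phi.shape != values.shape or phi.ndim != 1 or phi.size < 2:
            raise InvalidInputError("phi and values must be equal-length 1-D, n >= 2")
        if not (np.all(np.isfinite(phi)) and np.all(np.isfinite(values))):
            raise InvalidInputError("non-finite phi or retention value")
        pts = tuple(RetentionPoint(p, v) for p, v in zip(phi, values))
        series = object.__new__(RetentionSeries)
        object.__setattr__(series, "compound_id", compound_id)
        object.__setattr__(series, "technique", technique)
        object.__setattr__(series, "points", pts)
        self.series = series
        self._phi = phi
        self._y = values
        return self

    @classmethod
    def from_dataframe(cls, df, compound_id: str, technique: str,
                       phi_col: str = "phi", value_col: str = "value"):
        """Build a model from a tidy DataFrame with Φ and value columns."""
        pts = [
            RetentionPoint(float(r[phi_col]), float(r[value_col]))
            for _, r in df.iterrows()
        ]
        return cls(RetentionSeries(compound_id, technique, tuple(pts)))

    def fit(self) -> LipophilicityFit:
        """Fit the line; raises :class:`DegenerateDesignError` if Φ has no spread."""
        phi, y = self._phi, self._y
        if np.ptp(phi) == 0.0:
            raise DegenerateDesignError(
                f"compound {self.series.compound_id!r}: zero variance in phi"
            )
        res = stats.linregress(phi, y)
        n = len(phi)
        resid = y - (res.intercept + res.slope * phi)
        if n > 2:
            residual_sd = float(np.sqrt(np.sum(resid**2) / (n - 2)))
        else:
            residual_sd = math.nan
        return LipophilicityFit(
            intercept=float(res.intercept),
            slope=float(res.slope),
            abs_correlation=float(abs(res.rvalue)),
            n_points=n,
            residual_sd=residual_sd,
            intercept_se=float(res.intercept_stderr) if n > 2 else math.nan,
            slope_se=float(res.stderr) if n > 2 else math.nan,
            compound_id=self.series.compound_id,
            technique=self.series.technique,
        )
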