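"""RP-HPLC lipophilicity stage.

From isocratic runs at several methanol fractions Φ, the retention factor
k = t_r/t_m − 1 is computed against an unretained marker (uracil), log k is
regressed on Φ, and the intercept log kw — the retention extrapolated to
pure water — is the lipophilicity index. Φ0 = −log kw / S is the methanol
fraction at which the analyte shows unit retention (log k = 0).
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional

from .core import (
    HPLC,
    InsufficientGradientError,
    InvalidInputError,
    RetentionPoint,
    RetentionSeries,
)
from .model import LipophilicityFit, RetentionLineModel, extrapolate_phi0

__all__ = [
    "HplcRun",
    "retention_factor",
    "build_log_k_series",
    "fit_retention_line",
    "extrapolate_phi0",
]


@dataclass(frozen=True)
class HplcRun:
    """One isocratic injection: modifier fraction, retention and dead time.

    Times are in minutes; the analyte must elute after the dead volume
    (``t_r > t_m > 0``), otherwise log k is undefined downstream.
    """

    compound_id: str
    phi: float
    t_r: float
    t_m: float
    replicate: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.phi < 1.0:
            raise InvalidInputError(
                f"compound {self.compound_id!r}: phi={self.phi} outside (0, 1)"
            )
        if self.t_m <= 0.0:
            raise InvalidInputError(
                f"compound {self.compound_id!r}: dead time t_m={self.t_m} must be > 0"
            )
        if self.t_r <= self.t_m:
            raise InvalidInputError(
                f"compound {self.compound_id!r}: t_r={self.t_r} must exceed "
                f"t_m={self.t_m} (unretained or co-eluting analyte)"
            )


def retention_factor(t_r: float, t_m: float) -> float:
    """Dimensionless retention factor k = t_r/t_m − 1.

    Parameters are in minutes; ``t_m`` is the dead time of an unretained
    marker. Raises :class:`InvalidInputError` when ``t_m ≤ 0`` or
    ``t_r ≤ t_m`` (k would be ≤ 0 and log k undefined).
    """
    if t_m <= 0.0:
        raise InvalidInputError(f"dead time t_m={t_m} must be > 0")
    if t_r <= t_m:
        raise InvalidInputError(
            f"t_r={t_r} must exceed t_m={t_m}: k <= 0 has no log k"
        )
    return t_r / t_m - 1.0


def build_log_k_series(runs: Iterable[HplcRun]) -> RetentionSeries:
    """Reduce one compound's runs to a (Φ, log10 k) series.

    Replicates at the same Φ are averaged on retention time before the
    retention-factor transform; points come out sorted by Φ. Requires all
    runs to share a compound id and at least three distinct Φ levels.
    """
    runs = list(runs)
    if not runs:
        raise InvalidInputError("no HPLC runs supplied")
    ids = {r.compound_id for r in runs}
    if len(ids) != 1:
        raise InvalidInputError(f"runs mix compound ids {sorted(ids)}")
    t_ms = {r.t_m for r in runs}
    by_phi: dict[float, list[HplcRun]] = defaultdict(list)
    for r in runs:
        by_phi[r.phi].append(r)
    if len(by_phi) < 3:
        raise InsufficientGradientError(
            f"compound {runs[0].compound_id!r}: {len(by_phi)} distinct phi "
            "levels; need >= 3"
        )
    points = []
    for phi in sorted(by_phi):
        grp = by_phi[phi]
        t_r = sum(g.t_r for g in grp) / len(grp)
        t_m = sum(g.t_m for g in grp) / len(grp)
        points.append(RetentionPoint(phi, math.log10(retention_factor(t_r, t_m))))
    return RetentionSeries(runs[0].compound_id, HPLC, tuple(points))


def fit_retention_line(series: RetentionSeries) -> LipophilicityFit:
    """OLS fit of log k = log kw + S·Φ; see :class:`RetentionLineModel`."""
    return RetentionLineModel(series).fit()
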