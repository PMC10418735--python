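"""RP-TLC lipophilicity stage.

Retardation factors R_F read from reversed-phase plates are linearised with
R_M = log10((1 − R_F)/R_F), regressed on the methanol fraction Φ, and the
intercept R_M0 is the TLC lipophilicity index; Φ0 = −R_M0/S as in the HPLC
stage. The regression core is shared with :mod:`chromlip.hplc` — only the
transform and the interpretation of the intercept differ.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional

from .core import (
    TLC,
    InsufficientGradientError,
    InvalidInputError,
    RetentionPoint,
    RetentionSeries,
)
from .model import LipophilicityFit, RetentionLineModel

__all__ = ["TlcRun", "rm_from_rf", "rf_from_rm", "build_rm_series", "fit_rm_line"]


@dataclass(frozen=True)
class TlcRun:
    """One plate reading: modifier fraction and retardation factor R_F ∈ (0, 1)."""

    compound_id: str
    phi: float
    r_f: float
    replicate: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.phi < 1.0:
            raise InvalidInputError(
                f"compound {self.compound_id!r}: phi={self.phi} outside (0, 1)"
            )
        if not 0.0 < self.r_f < 1.0:
            raise InvalidInputError(
                f"compound {self.compound_id!r}: r_f={self.r_f} outside the open "
                "interval (0, 1); R_M is undefined at the boundaries"
            )


def rm_from_rf(r_f: float) -> float:
    """R_M = log10((1 − R_F)/R_F); strictly decreasing, antisymmetric about 0.5.

    Out-of-range inputs raise rather than clip: silently clipping plate
    readings would bias the extrapolated R_M0.
    """
    if not 0.0 < r_f < 1.0:
        raise InvalidInputError(f"r_f={r_f} outside (0, 1)")
    # evaluated as a difference of logs so that R_M(x) = -R_M(1-x) exactly
    return math.log10(1.0 - r_f) - math.log10(r_f)


def rf_from_rm(r_m: float) -> float:
    """Inverse transform, R_F = 1/(1 + 10^R_M); used by the simulator."""
    return 1.0 / (1.0 + 10.0**r_m)


def build_rm_series(runs: Iterable[TlcRun]) -> RetentionSeries:
    """Reduce one compound's plate readings to a (Φ, R_M) series.

    Replicates at the same Φ are averaged on R_F before the R_M transform;
    requires a shared compound id and ≥ 3 distinct Φ levels.
    """
    runs = list(runs)
    if not runs:
        raise InvalidInputError("no TLC runs supplied")
    ids = {r.compound_id for r in runs}
    if len(ids) != 1:
        raise InvalidInputError(f"runs mix compound ids {sorted(ids)}")
    by_phi: dict[float, list[TlcRun]] = defaultdict(list)
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
        mean_rf = sum(g.r_f for g in grp) / len(grp)
        points.append(RetentionPoint(phi, rm_from_rf(mean_rf)))
    return RetentionSeries(runs[0].compound_id, TLC, tuple(points))


def fit_rm_line(series: RetentionSeries) -> LipophilicityFit:
    """OLS fit of R_M = R_M0 + S·Φ; same contract as the HPLC line fit."""
    return RetentionLineModel(series).fit()
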