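"""Shared domain types for chromatographic lipophilicity analysis.

The package works on three kinds of records: compound identities
(:class:`CompoundRecord`), per-compound retention measurements collected on a
gradient of organic-modifier volume fractions (:class:`RetentionSeries`), and
tabulated in-silico predictions (:class:`CalcLogPSet`, :class:`ADMEProfile`).
All logarithms throughout the package are base 10, matching the log k, R_M
and logP conventions of the field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

__all__ = [
    "HPLC",
    "TLC",
    "SERIES_CATEGORIES",
    "CALCULATORS",
    "CYP_ISOFORMS",
    "ChromlipError",
    "InvalidInputError",
    "InsufficientGradientError",
    "DegenerateDesignError",
    "ParseError",
    "CompoundRecord",
    "RetentionPoint",
    "RetentionSeries",
    "CalcLogPSet",
    "ADMEProfile",
]

HPLC = "RP-HPLC"
TLC = "RP-TLC"

#: Substituent series at the 2-amino position of the thiazol-4(5H)-one scaffold.
SERIES_CATEGORIES = ("isopropylamino", "tert-butylamino", "adamantylamino")

#: The seven logP calculators whose predictions are compared with experiment.
CALCULATORS = ("milogP", "AlogPs", "AClogP", "ALOGP", "MLOGP", "XLOGP2", "XLOGP3")

#: Cytochrome P450 isoforms with inhibition flags in the ADME profile.
CYP_ISOFORMS = ("CYP2D6", "CYP3A4", "CYP1A2", "CYP2C19", "CYP2C9")


class ChromlipError(Exception):
    """Base class for all package errors."""


class InvalidInputError(ChromlipError, ValueError):
    """A value violates a physical or contract precondition."""


class InsufficientGradientError(InvalidInputError):
    """Fewer than the minimum number of distinct modifier fractions."""


class DegenerateDesignError(InvalidInputError):
    """The regression design has no variance in the modifier fraction."""


class ParseError(ChromlipError, ValueError):
    """A CSV input failed validation; message names the row and column."""


@dataclass(frozen=True)
class CompoundRecord:
    """Identity and C-5 substitution of one 2-aminothiazol-4(5H)-one derivative.

    Parameters
    ----------
    compound_id : str
        Label unique within a dataset ("1".."28" for the bundled set).
    series : str
        Amino substituent series, one of :data:`SERIES_CATEGORIES`.
    r1, r2 : str
        Substituent labels at C-5; empty when C-5 carries a spiro ring.
    spiro : str, optional
        Ring-size label (e.g. "C5H10") when C-5 is spiro-fused.
    """

    compound_id: str
    series: str
    r1: str = "H"
    r2: str = "H"
    spiro: Optional[str] = None

    def __post_init__(self) -> None:
        if self.series not in SERIES_CATEGORIES:
            raise InvalidInputError(
                f"compound {self.compound_id!r}: unknown series {self.series!r}; "
                f"expected one of {SERIES_CATEGORIES}"
            )


@dataclass(frozen=True)
class RetentionPoint:
    """One (Φ, measurement) pair: log k for RP-HPLC, R_M for RP-TLC."""

    phi: float
    value: float
    replicate: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.phi < 1.0:
            raise InvalidInputError(
                f"phi={self.phi!r} outside (0, 1); modifier concentration is a "
                "volume fraction"
            )


@dataclass(frozen=True)
class RetentionSeries:
    """Per-compound retention measurements from one technique.

    Points are kept in ascending-Φ order; a meaningful line fit requires at
    least three distinct modifier fractions.
    """

    compound_id: str
    technique: str
    points: tuple[RetentionPoint, ...]

    def __post_init__(self) -> None:
        if self.technique not in (HPLC, TLC):
            raise InvalidInputError(
                f"technique must be {HPLC!r} or {TLC!r}, got {self.technique!r}"
            )
        object.__setattr__(self, "points", tuple(self.points))
        if self.n_distinct_phi < 3:
            raise InsufficientGradientError(
                f"compound {self.compound_id!r}: {self.n_distinct_phi} distinct "
                "modifier fractions; need >= 3 for a line fit"
            )

    @property
    def phis(self) -> tuple[float, ...]:
        return tuple(p.phi for p in self.points)

    @property
    def values(self) -> tuple[float, ...]:
        return tuple(p.value for p in self.points)

    @property
    def n_distinct_phi(self) -> int:
        return len(set(self.phis))


@dataclass(frozen=True)
class CalcLogPSet:
    """The seven calculated logP values for one compound.

    ``values`` must contain exactly the keys in :data:`CALCULATORS`.
    """

    compound_id: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = [c for c in CALCULATORS if c not in self.values]
        extra = [c for c in self.values if c not in CALCULATORS]
        if missing or extra:
            raise InvalidInputError(
                f"compound {self.compound_id!r}: calculator set mismatch "
                f"(missing {missing}, unexpected {extra})"
            )
        for name, v in self.values.items():
            if v != v or v in (float("inf"), float("-inf")):
                raise InvalidInputError(
                    f"compound {self.compound_id!r}: non-finite value for {name}"
                )
        object.__setattr__(self, "values", dict(self.values))

    def __getitem__(self, calculator: str) -> float:
        try:
            return self.values[calculator]
        except KeyError:
            raise InvalidInputError(f"unknown calculator {calculator!r}") from None


@dataclass(frozen=True)
class ADMEProfile:
    """One compound's predicted ADME descriptors (pkCSM-style outputs).

    Units: ``log_s`` log mol/L; ``caco2_log_papp`` log(Papp in 1e-6 cm/s);
    ``hia_pct`` percent absorbed; ``vdss_log`` log L/kg; ``bbb_log_bb``
    log(brain/plasma); ``fu`` unbound fraction in [0, 1]; ``cl_tot``
    log(mL/min/kg).
    """

    compound_id: str
    log_s: float
    caco2_log_papp: float
    hia_pct: float
    vdss_log: float
    bbb_log_bb: float
    fu: float
    cyp_inhibition: Mapping[str, bool] = field(default_factory=dict)
    cl_tot: float = float("nan")

    def __post_init__(self) -> None:
        if not 0.0 <= self.fu <= 1.0:
            raise InvalidInputError(
                f"compound {self.compound_id!r}: fu={self.fu} outside [0, 1]"
            )
        if not 0.0 <= self.hia_pct <= 100.0:
            raise InvalidInputError(
                f"compound {self.compound_id!r}: hia_pct={self.hia_pct} "
                "outside [0, 100]"
            )
        unknown = [e for e in self.cyp_inhibition if e not in CYP_ISOFORMS]
        if unknown:
            raise InvalidInputError(
                f"compound {self.compound_id!r}: unknown CYP isoform(s) {unknown}"
            )
        object.__setattr__(self, "cyp_inhibition", dict(self.cyp_inhibition))


def check_unique_ids(ids: Sequence[str], context: str) -> None:
    """Raise :class:`ParseError` naming the first duplicated compound id."""
    seen: set[str] = set()
    for i, cid in enumerate(ids):
        if cid in seen:
            raise ParseError(f"{context}: duplicated compound_id {cid!r} (row {i + 1})")
        seen.add(cid)
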