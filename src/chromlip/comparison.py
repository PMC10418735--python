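"""Concordance of experimental lipophilicity indices with calculated logP.

log kw and R_M0 are compared compound-by-compound against seven calculated
logP scales; per compound the calculators with the smallest absolute
deviation are identified, with exact ties credited to every member of the
tie set (the printed 2-decimal tables contain genuine ties). The module also
carries the Lipinski lipophilicity screen (logP ≤ 5) and the simple range
and paired-difference summaries used to describe the dataset.
"""

from __future__ import annotations

from typing import Iterable, Mapping

from .core import CALCULATORS, CalcLogPSet, InvalidInputError

__all__ = [
    "closest_calculators",
    "concordance_counts",
    "lipinski_lipophilicity_flag",
    "summarize_range",
    "paired_difference_report",
]

LIPINSKI_LOGP_MAX = 5.0


def closest_calculators(experimental: float, calc: CalcLogPSet) -> frozenset[str]:
    """All calculators attaining min |experimental − calculated|.

    Values are compared as given (the bundled tables print 2 decimals; no
    re-rounding is applied). The result is never empty; exact ties return
    the whole tie set.
    """
    missing = [c for c in CALCULATORS if c not in calc.values]
    if missing:
        raise InvalidInputError(
            f"compound {calc.compound_id!r}: missing calculator value(s) {missing}"
        )
    deltas = {name: abs(experimental - calc.values[name]) for name in CALCULATORS}
    best = min(deltas.values())
    return frozenset(name for name, d in deltas.items() if d == best)


def concordance_counts(
    experimental_column: Mapping[str, float],
    calc_sets: Mapping[str, CalcLogPSet],
) -> dict[str, int]:
    """Per-calculator count of compounds whose tie set contains it.

    Ties are credited to every member, so the counts may sum to more than
    the number of compounds; equality holds iff no compound ties.
    """
    if set(experimental_column) != set(calc_sets):
        only_exp = sorted(set(experimental_column) - set(calc_sets))
        only_calc = sorted(set(calc_sets) - set(experimental_column))
        raise InvalidInputError(
            f"compound key mismatch (experimental-only {only_exp}, "
            f"calculated-only {only_calc})"
        )
    counts = {name: 0 for name in CALCULATORS}
    for cid, exp_value in experimental_column.items():
        for name in closest_calculators(exp_value, calc_sets[cid]):
            counts[name] += 1
    return counts


def lipinski_lipophilicity_flag(value: float) -> bool:
    """True iff the lipophilicity criterion of Lipinski's rule holds (logP ≤ 5)."""
    return value <= LIPINSKI_LOGP_MAX


def summarize_range(values: Iterable[float]) -> tuple[float, float]:
    """Exact (min, max) of a non-empty collection of lipophilicity values."""
    values = list(values)
    if not values:
        raise InvalidInputError("cannot summarize an empty collection")
    return (min(values), max(values))


def paired_difference_report(
    hplc: Mapping[str, float], tlc: Mapping[str, float]
) -> tuple[dict[str, float], int]:
    """Per-compound log kw − R_M0 differences and the count of positive ones.

    Both mappings must cover the same compounds. Returns ``(differences,
    n_positive)`` where ``n_positive`` counts strictly positive differences
    (compounds whose HPLC index exceeds the TLC index).
    """
    if set(hplc) != set(tlc):
        raise InvalidInputError(
            f"compound key mismatch: {sorted(set(hplc) ^ set(tlc))}"
        )
    diffs = {cid: hplc[cid] - tlc[cid] for cid in hplc}
    return diffs, sum(1 for d in diffs.values() if d > 0)
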