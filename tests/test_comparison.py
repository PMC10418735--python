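"""Concordance with calculated logP, Lipinski screen and range summaries."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from chromlip import (
    CalcLogPSet,
    InvalidInputError,
    closest_calculators,
    concordance_counts,
    lipinski_lipophilicity_flag,
    paired_difference_report,
    summarize_range,
)
from chromlip.core import CALCULATORS


def brute_force_closest(experimental, calc_set):
    """Independent linear scan over the seven values."""
    deltas = [(abs(experimental - calc_set.values[c]), c) for c in CALCULATORS]
    best = min(d for d, _ in deltas)
    return frozenset(c for d, c in deltas if d == best)


def make_set(cid="x", **overrides):
    base = dict.fromkeys(CALCULATORS, 1.0)
    base.update(overrides)
    return CalcLogPSet(cid, base)


def test_closest_calculator_compound_7_is_mlogp(dataset):
    tie = closest_calculators(3.22, dataset.calc_logp["7"])
    assert tie == frozenset({"MLOGP"})


def test_closest_calculator_compound_20_ties(dataset):
    tie = closest_calculators(3.60, dataset.calc_logp["20"])
    assert tie == frozenset({"AlogPs", "MLOGP"})


def test_exact_match_gives_singleton():
    calc = make_set(XLOGP3=2.50)
    assert closest_calculators(2.50, calc) == frozenset({"XLOGP3"})


def test_closest_matches_brute_force_on_every_fixture_row(dataset):
    for cid, calc in dataset.calc_logp.items():
        for exp in (dataset.log_kw[cid], dataset.rm0[cid]):
            assert closest_calculators(exp, calc) == brute_force_closest(exp, calc)


def test_incomplete_calculator_set_is_rejected():
    values = dict.fromkeys(CALCULATORS, 1.0)
    values.pop("MLOGP")
    with pytest.raises(InvalidInputError, match="MLOGP"):
        CalcLogPSet("x", values)


def test_concordance_counts_hplc(dataset):
    counts = concordance_counts(dataset.log_kw, dataset.calc_logp)
    assert counts["MLOGP"] == 9
    # ties are credited to every member, so totals can exceed 28
    assert sum(counts.values()) >= 28


def test_concordance_counts_tlc_aclogp_max(dataset):
    counts = concordance_counts(dataset.rm0, dataset.calc_logp)
    assert counts["AClogP"] == max(counts.values())


def test_concordance_tie_increments_both():
    calc = {"a": make_set("a", AlogPs=2.1, MLOGP=2.1)}
    counts = concordance_counts({"a": 2.05}, calc)
    assert counts["AlogPs"] == 1 and counts["MLOGP"] == 1


def test_concordance_key_mismatch():
    with pytest.raises(InvalidInputError):
        concordance_counts({"a": 1.0}, {"b": make_set("b")})


@pytest.mark.parametrize(
    "value,expected", [(5.63, False), (5.0, True), (0.94, True)]
)
def test_lipinski_lipophilicity_flag(value, expected):
    assert lipinski_lipophilicity_flag(value) is expected


def test_summarize_range_fixture_columns(dataset):
    assert summarize_range(dataset.log_kw.values()) == (1.35, 5.63)
    assert summarize_range(dataset.rm0.values()) == (0.94, 3.56)
    assert summarize_range([2.0]) == (2.0, 2.0)


def test_summarize_range_empty_rejected():
    with pytest.raises(InvalidInputError):
        summarize_range([])


@given(st.lists(st.floats(-10, 10), min_size=1, max_size=30))
def test_summarize_range_brackets_every_element(values):
    lo, hi = summarize_range(values)
    assert all(lo <= v <= hi for v in values)


def test_paired_difference_all_positive_on_fixture(dataset):
    diffs, n_pos = paired_difference_report(dataset.log_kw, dataset.rm0)
    assert n_pos == 28
    assert all(d > 0 for d in diffs.values())


def test_paired_difference_identical_columns():
    col = {"a": 1.0, "b": 2.0}
    _, n_pos = paired_difference_report(col, dict(col))
    assert n_pos == 0


def test_compounds_3_and_4_share_log_kw(dataset):
    assert dataset.log_kw["3"] == dataset.log_kw["4"] == 2.28


def test_paired_difference_key_mismatch():
    with pytest.raises(InvalidInputError):
        paired_difference_report({"a": 1.0}, {"b": 1.0})
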