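"""Rule-based screening of predicted ADME descriptors.

Classifies pkCSM-style absorption/distribution descriptors against the
thresholds used in medicinal-chemistry practice — Caco-2 permeability high
when log Papp > 0.9 (in 1e-6 cm/s), steady-state volume of distribution
optimal within [−0.15, 0.45] log L/kg — counts cytochrome P450 inhibition
flags per isoform, and summarises descriptor ranges over a compound set.

HIA and blood–brain-barrier cut-offs are conventions (no single published
threshold governs them); they default to the pkCSM guidance values and are
user-configurable.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

from .core import CYP_ISOFORMS, ADMEProfile, InvalidInputError

__all__ = [
    "classify_caco2",
    "classify_vdss",
    "classify_hia",
    "classify_bbb",
    "count_cyp_inhibitors",
    "adme_summary",
]

CACO2_HIGH_THRESHOLD = 0.9        # log Papp in 1e-6 cm/s
VDSS_LOW_THRESHOLD = -0.15        # log L/kg, closed interval for "optimal"
VDSS_HIGH_THRESHOLD = 0.45
HIA_POOR_THRESHOLD = 30.0         # % absorbed — convention, not study-specific
BBB_READY_THRESHOLD = 0.3         # log BB — convention
BBB_POOR_THRESHOLD = -1.0

#: Numeric descriptors summarised by :func:`adme_summary`.
NUMERIC_DESCRIPTORS = (
    "log_s", "caco2_log_papp", "hia_pct", "vdss_log", "bbb_log_bb", "fu", "cl_tot",
)


def classify_caco2(log_papp: float) -> str:
    """'high' iff log Papp strictly exceeds 0.9, else 'low'."""
    return "high" if log_papp > CACO2_HIGH_THRESHOLD else "low"


def classify_vdss(vdss_log: float) -> str:
    """'low' below −0.15, 'optimal' in [−0.15, 0.45], 'high' above 0.45.

    A high VDss means the compound partitions predominantly into tissues
    rather than plasma; boundaries are treated as inclusive for 'optimal'.
    """
    if vdss_log < VDSS_LOW_THRESHOLD:
        return "low"
    if vdss_log > VDSS_HIGH_THRESHOLD:
        return "high"
    return "optimal"


def classify_hia(hia_pct: float, poor_below: float = HIA_POOR_THRESHOLD) -> str:
    """'poor' below the (configurable) percent-absorbed cut-off, else 'good'."""
    return "poor" if hia_pct < poor_below else "good"


def classify_bbb(log_bb: float,
                 ready_above: float = BBB_READY_THRESHOLD,
                 poor_below: float = BBB_POOR_THRESHOLD) -> str:
    """'ready' above 0.3 log BB, 'poor' below −1, 'intermediate' between."""
    if log_bb > ready_above:
        return "ready"
    if log_bb < poor_below:
        return "poor"
    return "intermediate"


def count_cyp_inhibitors(
    profiles: Iterable[ADMEProfile], enzyme: str
) -> tuple[int, list[str]]:
    """Number and identity of compounds flagged as inhibitors of ``enzyme``."""
    if enzyme not in CYP_ISOFORMS:
        raise InvalidInputError(
            f"unknown CYP isoform {enzyme!r}; expected one of {CYP_ISOFORMS}"
        )
    hits = [p.compound_id for p in profiles if p.cyp_inhibition.get(enzyme, False)]
    return len(hits), hits


def adme_summary(profiles: Sequence[ADMEProfile]) -> dict[str, dict]:
    """Per-descriptor min/max with the compound ids attaining them.

    Returns ``{descriptor: {"min": v, "min_compound": id, "max": v,
    "max_compound": id}}`` over all finite values; raises on an empty input.
    """
    profiles = list(profiles)
    if not profiles:
        raise InvalidInputError("cannot summarize an empty profile collection")
    out: dict[str, dict] = {}
    for desc in NUMERIC_DESCRIPTORS:
        pairs = [
            (getattr(p, desc), p.compound_id)
            for p in profiles
            if not math.isnan(getattr(p, desc))
        ]
        if not pairs:
            continue
        mn = min(pairs)
        mx = max(pairs)
        out[desc] = {
            "min": mn[0], "min_compound": mn[1],
            "max": mx[0], "max_compound": mx[1],
        }
    return out
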