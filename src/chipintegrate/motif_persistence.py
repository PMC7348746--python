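"""Classify motif-enrichment changes between groups and their persistence.

Motif enrichment p-values (HOMER-style) are compared between growth-
restricted (IUGR) and control islets for one mark and age. A motif has
*gained* enrichment in IUGR when it is strongly enriched there
(p <= ``sig_alpha``) while clearly not enriched in controls
(p >= ``ns_floor``); *lost* is the mirror image; motifs enriched in both
groups are ``both_enriched`` and everything else is ``neither``. A change
is *persistent* when the same non-neutral call holds at both ages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .io_formats import MARKS, MotifEnrichmentRecord

__all__ = [
    "MotifChangeCall",
    "classify_motif_change",
    "persistent_motifs",
]

GAINED = "gained_in_IUGR"
LOST = "lost_in_IUGR"
BOTH = "both_enriched"
NEITHER = "neither"


@dataclass(frozen=True, slots=True)
class MotifChangeCall:
    motif_name: str
    consensus: str
    mark: str
    age: str
    change: str
    p_iugr: float
    p_control: float


def classify_motif_change(
    rec_iugr: MotifEnrichmentRecord,
    rec_control: MotifEnrichmentRecord,
    sig_alpha: float = 1e-4,
    ns_floor: float = 0.05,
) -> MotifChangeCall:
    """Classify one motif's enrichment change between IUGR and control.

    Both records must describe the same motif, mark and age, one per group.
    The call is a pure function of the two p-values and the thresholds, and
    is monotone: lowering ``p_iugr`` never turns a gain into a non-gain.
    """
    if rec_iugr.motif_name.casefold() != rec_control.motif_name.casefold():
        raise ValueError(
            f"motif name mismatch: {rec_iugr.motif_name!r} vs "
            f"{rec_control.motif_name!r}"
        )
    if rec_iugr.mark != rec_control.mark:
        raise ValueError("mark mismatch between motif records")
    if rec_iugr.condition.age != rec_control.condition.age:
        raise ValueError("age mismatch between motif records")
    if rec_iugr.condition.group != "IUGR" or rec_control.condition.group != "control":
        raise ValueError("records must be (IUGR, control) in that order")
    p_i, p_c = rec_iugr.pvalue, rec_control.pvalue
    if p_i <= sig_alpha and p_c >= ns_floor:
        change = GAINED
    elif p_c <= sig_alpha and p_i >= ns_floor:
        change = LOST
    elif p_i <= sig_alpha and p_c <= sig_alpha:
        change = BOTH
    else:
        change = NEITHER
    return MotifChangeCall(
        rec_iugr.motif_name,
        rec_iugr.consensus,
        rec_iugr.mark,
        rec_iugr.condition.age,
        change,
        p_i,
        p_c,
    )


def persistent_motifs(
    calls_2wk: Iterable[MotifChangeCall],
    calls_10wk: Iterable[MotifChangeCall],
    mark: str,
) -> list[MotifChangeCall]:
    """Motifs of ``mark`` with the same non-neutral change at both ages.

    Returns the 2-wk calls (name-sorted) of motifs whose change class is
    identical at 2 and 10 weeks and is not ``neither``. Matching is
    case-insensitive on the motif name.
    """
    if mark not in MARKS:
        raise ValueError(f"mark must be one of {MARKS}")
    later = {
        c.motif_name.casefold(): c for c in calls_10wk if c.mark == mark
    }
    persistent = []
    for call in calls_2wk:
        if call.mark != mark or call.change == NEITHER:
            continue
        other = later.get(call.motif_name.casefold())
        if other is not None and other.change == call.change:
            persistent.append(call)
    return sorted(persistent, key=lambda c: c.motif_name.casefold())
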