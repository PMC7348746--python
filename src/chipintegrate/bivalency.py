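"""Bivalent (poised) promoter calling and poised-state transition labels.

A promoter is called bivalent in a condition when an H3K4me3 peak and an
H3K27me3 peak overlap by at least ``min_overlap`` bp (default 5) and the
midpoint of their overlap lies within ``promoter_window`` bp (default 5000)
of the gene's TSS. Bivalent promoters carry both the activating and the
repressive mark and are typically silent but activation-ready ("poised");
low expression of the gene is consistent with that state and is checked by
:func:`filter_poised_by_expression`.

Across the 2 age x 2 group design each gene gets a 4-bit state vector
(2wk control, 2wk IUGR, 10wk control, 10wk IUGR); :func:`classify_transition`
maps each of the 16 vectors to a deterministic label, with named aliases for
the biologically salient patterns (bivalency gained or lost in growth-
restricted animals, poised states resolved with age in controls only, etc.).
"""

from __future__ import annotations

import dataclasses
from bisect import bisect_left, bisect_right
from collections import Counter
from dataclasses import dataclass
from itertools import product
from typing import Iterable, Mapping, Sequence

from .genomic_intervals import GenomeAnnotation, overlap_length
from .io_formats import CONDITIONS, Condition, Peak

__all__ = [
    "BivalencyCall",
    "BivalencyStateMatrix",
    "TRANSITION_LABELS",
    "call_bivalent_promoters",
    "filter_poised_by_expression",
    "build_state_matrix",
    "classify_transition",
    "summarize_transitions",
]


@dataclass(frozen=True)
class BivalencyCall:
    """Bivalency status of one gene's promoter in one condition."""

    gene_id: str
    condition: Condition
    bivalent: bool
    k4_peak: Peak | None = None
    k27_peak: Peak | None = None
    overlap_bp: int = 0
    poised_expression_consistent: bool | None = None


@dataclass(frozen=True)
class BivalencyStateMatrix:
    """Per-gene poised/not-poised states in canonical condition order."""

    gene_id: str
    states: tuple[bool, bool, bool, bool]

    @property
    def pattern(self) -> str:
        return "".join("T" if s else "F" for s in self.states)


def _transition_labels() -> dict[tuple[bool, bool, bool, bool], str]:
    labels: dict[tuple[bool, bool, bool, bool], str] = {}
    for bits in product((False, True), repeat=4):
        if bits == (True, True, True, True):
            label = "stable_poised"
        elif bits == (False, False, False, False):
            label = "never_poised"
        elif bits == (True, True, False, True):
            # poised early in both groups, resolved in adult controls but
            # poised again in adult growth-restricted animals
            label = "control_resolved_IUGR_repoised"
        elif bits == (False, False, True, False):
            # de novo poised only in adult controls
            label = "control_de_novo_IUGR_resolved"
        elif bits[:2] == (False, True):
            label = "gained_in_IUGR_2wk"
        elif bits[:2] == (True, False):
            label = "lost_in_IUGR_2wk"
        else:
            label = "state_" + "".join("1" if b else "0" for b in bits)
        labels[bits] = label
    return labels


#: Label for each of the 16 possible state vectors.
TRANSITION_LABELS = _transition_labels()


def call_bivalent_promoters(
    k4: Sequence[Peak],
    k27: Sequence[Peak],
    annotation: GenomeAnnotation,
    min_overlap: int = 5,
    promoter_window: int = 5000,
) -> list[BivalencyCall]:
    """Call bivalent promoters for one condition from its two peak sets.

    Returns one call per gene (bivalent or not). A gene is bivalent iff some
    H3K4me3/H3K27me3 peak pair overlaps by >= ``min_overlap`` bp with the
    overlap midpoint within ``promoter_window`` of the TSS; the qualifying
    pair with the largest overlap is recorded.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    conditions = {p.condition for p in k4} | {p.condition for p in k27}
    if len(conditions) > 1:
        raise ValueError(
            "peaks from mixed conditions passed to call_bivalent_promoters: "
            + ", ".join(sorted(c.label for c in conditions))
        )
    condition = next(iter(conditions)) if conditions else None

    # enumerate overlapping K4/K27 pairs per chromosome with a sweep
    pairs_by_chrom: dict[str, list[tuple[int, int, Peak, Peak]]] = {}
    k27_by_chrom: dict[str, list[Peak]] = {}
    for p in k27:
        k27_by_chrom.setdefault(p.interval.chrom, []).append(p)
    for chrom_peaks in k27_by_chrom.values():
        chrom_peaks.sort(key=lambda p: p.interval.start)
    for a in k4:
        chrom = a.interval.chrom
        others = k27_by_chrom.get(chrom, [])
        starts = [p.interval.start for p in others]
        # K27 peaks starting before a.end can overlap a
        hi = bisect_left(starts, a.interval.end)
        for b in others[:hi]:
            if b.interval.end <= a.interval.start:
                continue
            ov = overlap_length(a.interval, b.interval)
            if ov >= min_overlap:
                mid = (
                    max(a.interval.start, b.interval.start)
                    + min(a.interval.end, b.interval.end)
                ) // 2
                pairs_by_chrom.setdefault(chrom, []).append((mid, ov, a, b))
    for pairs in pairs_by_chrom.values():
        pairs.sort(key=lambda item: item[0])

    calls = []
    for gene in sorted(annotation.genes, key=lambda g: g.gene_id):
        pairs = pairs_by_chrom.get(gene.chrom, [])
        mids = [item[0] for item in pairs]
        lo = bisect_left(mids, gene.tss - promoter_window)
        hi = bisect_right(mids, gene.tss + promoter_window)
        best = None
        for mid, ov, a, b in pairs[lo:hi]:
            key = (ov, -a.interval.start, -b.interval.start)
            if best is None or key > best[0]:
                best = (key, ov, a, b)
        if best is None:
            calls.append(BivalencyCall(gene.gene_id, condition, False))
        else:
            _, ov, a, b = best
            calls.append(
                BivalencyCall(gene.gene_id, condition, True, a, b, ov)
            )
    return calls


def filter_poised_by_expression(
    calls: Iterable[BivalencyCall],
    abundance: Mapping[str, Mapping[str, float]],
    max_abundance: float = 1.0,
) -> list[BivalencyCall]:
    """Flag bivalent calls whose gene is lowly expressed in that condition.

    ``abundance`` maps gene_id -> group -> mean normalised expression. The
    flag is True when abundance < ``max_abundance`` in the call's group,
    False when expressed above it, and None (unknown) when no abundance is
    available. Calls are returned flagged, never removed.
    """
    flagged = []
    for call in calls:
        value = None
        if call.condition is not None:
            value = abundance.get(call.gene_id, {}).get(call.condition.group)
        consistent = None if value is None else bool(value < max_abundance)
        flagged.append(
            dataclasses.replace(call, poised_expression_consistent=consistent)
        )
    return flagged


def build_state_matrix(
    calls: Iterable[BivalencyCall],
) -> list[BivalencyStateMatrix]:
    """Collect per-condition calls into 4-bit state vectors per gene.

    A missing gene x condition call counts as not-bivalent; genes bivalent in
    no condition are omitted. Duplicate gene x condition calls are an error.
    """
    states: dict[str, dict[Condition, bool]] = {}
    for call in calls:
        per_gene = states.setdefault(call.gene_id, {})
        if call.condition in per_gene:
            raise ValueError(
                f"duplicate call for gene {call.gene_id} in condition "
                f"{call.condition.label}"
            )
        per_gene[call.condition] = call.bivalent
    matrices = []
    for gene_id in sorted(states):
        vector = tuple(states[gene_id].get(c, False) for c in CONDITIONS)
        if any(vector):
            matrices.append(BivalencyStateMatrix(gene_id, vector))
    return matrices


def classify_transition(matrix: BivalencyStateMatrix) -> str:
    """Label the gene's poised-state trajectory across the four conditions."""
    return TRANSITION_LABELS[matrix.states]


def summarize_transitions(
    matrices: Iterable[BivalencyStateMatrix],
) -> dict[str, object]:
    """Count transition labels and 10-wk control/IUGR discordant genes.

    Returns ``{"label_counts": {label: n}, "n_10wk_discordant": n}``; label
    counts sum to the number of matrices.
    """
    matrices = list(matrices)
    counts = Counter(classify_transition(m) for m in matrices)
    discordant = sum(1 for m in matrices if m.states[2] != m.states[3])
    return {
        "label_counts": dict(sorted(counts.items())),
        "n_10wk_discordant": discordant,
    }
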