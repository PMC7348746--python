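"""Assign differential histone sites to genes and classify concordance.

A differential site is credited to a gene when its midpoint lies within a
window (default 5 kb) of the gene's TSS; each gene keeps at most one site per
mark and age, the one nearest the TSS. A mark is *concordant* with the
gene's expression change when the direction of the enrichment change
predicts the direction of the expression change: same sign for the
activating marks H3K4me3 and H3K27Ac, opposite sign for the repressive mark
H3K27me3. Genes concordant for all three marks are the strongest candidates
for histone-mediated regulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .genomic_intervals import GenomeAnnotation, distance_to_nearest_tss
from .io_formats import MARKS, DiffSite, ExpressionRecord

logger = logging.getLogger(__name__)

__all__ = [
    "MarkGeneAssignment",
    "ConcordanceCall",
    "assign_diff_sites",
    "classify_concordance",
    "count_regulated_genes",
    "persistent_mark_genes",
]

CONCORDANT = "concordant"
DISCORDANT = "discordant"
ABSENT = "absent"


@dataclass(frozen=True, slots=True)
class MarkGeneAssignment:
    """The differential site chosen to represent one gene x mark x age."""

    gene_id: str
    mark: str
    age: str
    log2fc: float
    fdr: float
    distance: float  # signed bp from TSS, + = downstream


@dataclass(frozen=True)
class ConcordanceCall:
    """Per-mark concordance of histone changes with expression at one gene."""

    gene_id: str
    age: str
    statuses: Mapping[str, str]  # mark -> concordant/discordant/absent
    rna_log2fc: float
    rna_direction: str  # "up" or "down"

    @property
    def n_concordant_marks(self) -> int:
        return sum(1 for s in self.statuses.values() if s == CONCORDANT)


def assign_diff_sites(
    diff: Iterable[DiffSite],
    annotation: GenomeAnnotation,
    window: int = 5000,
    fdr_max: float = 0.05,
) -> list[MarkGeneAssignment]:
    """Assign significant differential sites to genes within ``window`` of a TSS.

    Sites with FDR above ``fdr_max`` are dropped. The site's midpoint must be
    within ``window`` bp (absolute, strand-aware sign retained) of the
    nearest TSS. Among several candidate sites for one gene x mark x age the
    nearest wins; ties go to the larger |log2FC|, then the smaller start.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    candidates: dict[tuple[str, str, str], list[tuple, ]] = {}
    for site in diff:
        if site.fdr > fdr_max:
            continue
        gene_id, d = distance_to_nearest_tss(
            site.interval.chrom, site.interval.midpoint, annotation
        )
        if gene_id is None or abs(d) > window:
            continue
        key = (gene_id, site.mark, site.age)
        candidates.setdefault(key, []).append((d, site))
    assignments = []
    for (gene_id, mark, age), sites in candidates.items():
        d, site = min(
            sites,
            key=lambda item: (
                abs(item[0]),
                -abs(item[1].log2fc),
                item[1].interval.start,
            ),
        )
        assignments.append(
            MarkGeneAssignment(gene_id, mark, age, site.log2fc, site.fdr, d)
        )
    assignments.sort(key=lambda a: (a.age, a.gene_id, a.mark))
    return assignments


def _mark_concordant(mark: str, mark_fc: float, rna_fc: float) -> bool:
    # a zero change cannot correlate in either direction
    if mark_fc == 0 or rna_fc == 0:
        return False
    same_sign = (mark_fc > 0) == (rna_fc > 0)
    return not same_sign if mark == "H3K27me3" else same_sign


def classify_concordance(
    assignments: Iterable[MarkGeneAssignment],
    expression: Iterable[ExpressionRecord],
    rna_fdr_max: float = 0.05,
) -> list[ConcordanceCall]:
    """Classify mark-expression concordance for every expressed gene.

    Only genes with a differential-expression record at FDR <=
    ``rna_fdr_max`` are classified; assignments to other genes are dropped
    (counted in the log). Marks without an assigned site are ``absent``.
    """
    expr_by_key: dict[tuple[str, str], ExpressionRecord] = {}
    for rec in expression:
        if rec.fdr <= rna_fdr_max:
            expr_by_key[(rec.gene_id, rec.age)] = rec
    assigned: dict[tuple[str, str], dict[str, MarkGeneAssignment]] = {}
    dropped = 0
    for a in assignments:
        if (a.gene_id, a.age) not in expr_by_key:
            dropped += 1
            continue
        assigned.setdefault((a.gene_id, a.age), {})[a.mark] = a
    if dropped:
        logger.info(
            "dropped %d assignments at genes without significant expression",
            dropped,
        )
    calls = []
    for (gene_id, age), marks in sorted(assigned.items()):
        rec = expr_by_key[(gene_id, age)]
        statuses = {}
        for mark in MARKS:
            if mark not in marks:
                statuses[mark] = ABSENT
            elif _mark_concordant(mark, marks[mark].log2fc, rec.log2fc):
                statuses[mark] = CONCORDANT
            else:
                statuses[mark] = DISCORDANT
        calls.append(
            ConcordanceCall(
                gene_id,
                age,
                statuses,
                rec.log2fc,
                "up" if rec.log2fc > 0 else "down",
            )
        )
    return calls


def count_regulated_genes(calls: Iterable[ConcordanceCall]) -> pd.DataFrame:
    """Tabulate genes concordant per mark and for all three marks, by age.

    Returns a DataFrame indexed by (age, row) where row is each mark plus
    ``all_3_marks``, with ``total``/``up``/``down`` gene counts. Up/down is
    the direction of the RNA change. Order-invariant in its input.
    """
    calls = list(calls)
    ages = sorted({c.age for c in calls}) or []
    rows = []
    for age in ages:
        age_calls = [c for c in calls if c.age == age]
        for mark in MARKS:
            hits = [c for c in age_calls if c.statuses.get(mark) == CONCORDANT]
            rows.append(
                {
                    "age": age,
                    "set": mark,
                    "total": len(hits),
                    "up": sum(1 for c in hits if c.rna_direction == "up"),
                    "down": sum(1 for c in hits if c.rna_direction == "down"),
                }
            )
        all3 = [c for c in age_calls if c.n_concordant_marks == len(MARKS)]
        rows.append(
            {
                "age": age,
                "set": "all_3_marks",
                "total": len(all3),
                "up": sum(1 for c in all3 if c.rna_direction == "up"),
                "down": sum(1 for c in all3 if c.rna_direction == "down"),
            }
        )
    df = pd.DataFrame(rows, columns=["age", "set", "total", "up", "down"])
    return df.set_index(["age", "set"])


def persistent_mark_genes(
    calls_2wk: Iterable[ConcordanceCall],
    calls_10wk: Iterable[ConcordanceCall],
    mark: str,
    direction: str,
) -> list[str]:
    """Genes concordant for ``mark`` with RNA moving ``direction`` at both ages.

    This is the persistence filter behind e.g. the set of genes with
    decreased H3K27Ac and decreased expression at both 2 and 10 weeks.
    """
    if mark not in MARKS:
        raise ValueError(f"mark must be one of {MARKS}")
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")

    def hits(calls: Iterable[ConcordanceCall]) -> set[str]:
        return {
            c.gene_id
            for c in calls
            if c.statuses.get(mark) == CONCORDANT
            and c.rna_direction == direction
        }

    return sorted(hits(calls_2wk) & hits(calls_10wk))
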