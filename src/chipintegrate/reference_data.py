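"""Bundled reference tables from the rat IUGR islet histone-mark experiment.

Four small transcribed summary tables ship with the package and serve as
worked-example inputs: the six genes with concordant changes of all three
histone marks at 10 weeks, the twenty genes with persistently decreased
H3K27Ac and expression at both ages, the motif-enrichment p-values with
persistent changes, and the poised-state (+/-) matrix of the six bivalent
genes whose 10-week state differs between control and growth-restricted
islets. Loader helpers convert them into the pipeline's domain objects.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

from .bivalency import BivalencyStateMatrix
from .diff_integration import MarkGeneAssignment
from .io_formats import (
    AGES,
    Condition,
    ExpressionRecord,
    MotifEnrichmentRecord,
    parse_pvalue,
)

__all__ = [
    "all3_marks_table",
    "k27ac_persistent_table",
    "motif_persistence_table",
    "bivalency_state_table",
    "all3_marks_inputs",
    "k27ac_persistent_inputs",
    "motif_persistence_records",
    "bivalency_state_matrices",
]

_MARK_COLUMNS = {
    "H3K4me3": "h3k4me3_log2fc",
    "H3K27me3": "h3k27me3_log2fc",
    "H3K27Ac": "h3k27ac_log2fc",
}


def _load(name: str) -> pd.DataFrame:
    path = files("chipintegrate").joinpath("data", name)
    return pd.read_csv(path, sep="\t")


def all3_marks_table() -> pd.DataFrame:
    """Per-gene log2FCs of all three marks plus RNA log2FC/FDR (10 wk)."""
    return _load("islet_all3_marks_10wk.tsv")


def k27ac_persistent_table() -> pd.DataFrame:
    """Genes with decreased H3K27Ac and expression at both 2 and 10 wk."""
    return _load("islet_k27ac_persistent.tsv")


def motif_persistence_table() -> pd.DataFrame:
    """Motif enrichment p-values per mark for both groups at both ages."""
    return _load("islet_motif_persistence.tsv")


def bivalency_state_table() -> pd.DataFrame:
    """Poised-state (+/-) calls across the four conditions for six genes."""
    return _load("islet_bivalency_states.tsv")


def all3_marks_inputs() -> tuple[list[MarkGeneAssignment], list[ExpressionRecord]]:
    """The all-three-marks table as integration inputs (age 10wk).

    Each gene yields one assignment per mark (distance 0, significant FDR)
    and one expression record, ready for ``classify_concordance``.
    """
    df = all3_marks_table()
    assignments, expression = [], []
    for row in df.itertuples(index=False):
        for mark, col in _MARK_COLUMNS.items():
            assignments.append(
                MarkGeneAssignment(row.gene, mark, "10wk",
                                   float(getattr(row, col)), 1e-3, 0.0)
            )
        expression.append(
            ExpressionRecord(row.gene, "10wk",
                             float(row.rna_log2fc), float(row.rna_fdr))
        )
    return assignments, expression


def k27ac_persistent_inputs() -> tuple[
    dict[str, list[MarkGeneAssignment]], dict[str, list[ExpressionRecord]]
]:
    """The H3K27Ac persistence table as per-age integration inputs."""
    df = k27ac_persistent_table()
    assignments: dict[str, list[MarkGeneAssignment]] = {a: [] for a in AGES}
    expression: dict[str, list[ExpressionRecord]] = {a: [] for a in AGES}
    for row in df.itertuples(index=False):
        for age in AGES:
            assignments[age].append(
                MarkGeneAssignment(
                    row.gene, "H3K27Ac", age,
                    float(getattr(row, f"h3k27ac_log2fc_{age}")), 1e-3, 0.0,
                )
            )
            expression[age].append(
                ExpressionRecord(
                    row.gene, age,
                    float(getattr(row, f"rna_log2fc_{age}")),
                    float(getattr(row, f"rna_fdr_{age}")),
                )
            )
    return assignments, expression


def motif_persistence_records() -> dict[
    tuple[str, Condition], list[MotifEnrichmentRecord]
]:
    """The motif table as per-mark, per-condition enrichment records."""
    df = motif_persistence_table()
    records: dict[tuple[str, Condition], list[MotifEnrichmentRecord]] = {}
    for row in df.itertuples(index=False):
        for age in AGES:
            for group in ("IUGR", "control"):
                cond = Condition(age, group)
                records.setdefault((row.mark, cond), []).append(
                    MotifEnrichmentRecord(
                        row.motif_name,
                        row.consensus,
                        row.mark,
                        cond,
                        parse_pvalue(getattr(row, f"p_{age}_{group}")),
                    )
                )
    return records


def bivalency_state_matrices() -> list[BivalencyStateMatrix]:
    """The +/- poised-state table as 4-bit state matrices."""
    df = bivalency_state_table()
    matrices = []
    for row in df.itertuples(index=False):
        states = tuple(
            getattr(row, f"biv_{age}_{group}") == "+"
            for age, group in (
                ("2wk", "control"),
                ("2wk", "IUGR"),
                ("10wk", "control"),
                ("10wk", "IUGR"),
            )
        )
        matrices.append(BivalencyStateMatrix(row.gene, states))
    return matrices
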