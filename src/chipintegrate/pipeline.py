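"""Config-driven orchestration of the analysis stages.

A run is described by a flat YAML config (the ``simulate`` bundle writes one)
naming the annotation, the peak/differential/expression/motif files per mark,
condition and age, and the tunable parameters. The helpers here load those
inputs into domain objects and run each analysis stage end to end; the CLI
subcommands are thin wrappers around them.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import bivalency as biv
from . import diff_integration as integ
from . import motif_persistence as motifs
from .genomic_intervals import GenomeAnnotation
from .io_formats import (
    AGES,
    CONDITIONS,
    MARKS,
    Condition,
    DiffSite,
    ExpressionRecord,
    MotifEnrichmentRecord,
    Peak,
    read_chrom_sizes,
    read_diff_table,
    read_expression,
    read_gtf,
    read_motif_table,
    read_peaks,
    read_refflat,
)

__all__ = ["Bundle", "load_bundle", "run_integration", "run_bivalency",
           "run_motifs"]


class Bundle:
    """Parsed inputs of one run."""

    def __init__(
        self,
        annotation: GenomeAnnotation,
        peaks: Mapping[tuple[str, Condition], list[Peak]],
        diff: Mapping[tuple[str, str], list[DiffSite]],
        expression: Mapping[str, list[ExpressionRecord]],
        motif_records: Mapping[tuple[str, Condition], list[MotifEnrichmentRecord]],
        params: dict,
    ) -> None:
        self.annotation = annotation
        self.peaks = dict(peaks)
        self.diff = dict(diff)
        self.expression = dict(expression)
        self.motif_records = dict(motif_records)
        self.params = dict(params)


def load_bundle(config_path: str | Path) -> Bundle:
    """Load every input named by a run config into domain objects."""
    config_path = Path(config_path)
    root = config_path.parent
    config = yaml.safe_load(config_path.read_text())
    chrom_sizes = read_chrom_sizes(root / config["chrom_sizes"])
    annotation_path = root / config["annotation"]
    if annotation_path.suffix in (".gtf", ".gff"):
        annotation = read_gtf(annotation_path, chrom_sizes)
    else:
        annotation = read_refflat(annotation_path, chrom_sizes)
    peaks = {}
    for mark, by_cond in config.get("peaks", {}).items():
        for label, rel in by_cond.items():
            cond = Condition.from_label(label)
            peaks[(mark, cond)] = read_peaks(root / rel, mark, cond)
    diff = {}
    for mark, by_age in config.get("diff", {}).items():
        for age, rel in by_age.items():
            diff[(mark, age)] = read_diff_table(root / rel, mark, age)
    expression = {}
    for age, rel in config.get("expression", {}).items():
        expression[age] = read_expression(root / rel, age)
    motif_records = {}
    for mark, by_cond in config.get("motifs", {}).items():
        for label, rel in by_cond.items():
            cond = Condition.from_label(label)
            motif_records[(mark, cond)] = read_motif_table(
                root / rel, mark, cond
            )
    return Bundle(annotation, peaks, diff, expression, motif_records,
                  config.get("params", {}))


def run_integration(
    bundle: Bundle,
    window: int = 5000,
    diff_fdr_max: float = 0.05,
    rna_fdr_max: float = 0.05,
) -> dict[str, object]:
    """Site assignment + concordance + counts + the persistence gene list.

    Returns the per-age concordance calls, the regulated-gene count table,
    and the genes with persistently decreased H3K27Ac and expression.
    """
    calls_by_age: dict[str, list[integ.ConcordanceCall]] = {}
    for age in AGES:
        sites = [
            s for (mark, a), sites in bundle.diff.items() if a == age
            for s in sites
        ]
        assignments = integ.assign_diff_sites(
            sites, bundle.annotation, window=window, fdr_max=diff_fdr_max
        )
        calls_by_age[age] = integ.classify_concordance(
            assignments, bundle.expression.get(age, []),
            rna_fdr_max=rna_fdr_max,
        )
    counts = integ.count_regulated_genes(
        [c for calls in calls_by_age.values() for c in calls]
    )
    persistent = integ.persistent_mark_genes(
        calls_by_age["2wk"], calls_by_age["10wk"], "H3K27Ac", "down"
    )
    return {
        "calls": calls_by_age,
        "counts": counts,
        "persistent_k27ac_down": persistent,
    }


def run_bivalency(
    bundle: Bundle,
    min_overlap: int = 5,
    promoter_window: int = 5000,
    max_abundance: float = 1.0,
) -> dict[str, object]:
    """Bivalent-promoter calls, state matrices and transition summary."""
    abundance: dict[str, dict[str, float]] = {}
    for records in bundle.expression.values():
        for rec in records:
            for group, value in rec.mean_abundance.items():
                abundance.setdefault(rec.gene_id, {})[group] = value
    all_calls: list[biv.BivalencyCall] = []
    for cond in CONDITIONS:
        k4 = bundle.peaks.get(("H3K4me3", cond), [])
        k27 = bundle.peaks.get(("H3K27me3", cond), [])
        calls = biv.call_bivalent_promoters(
            k4, k27, bundle.annotation,
            min_overlap=min_overlap, promoter_window=promoter_window,
        )
        all_calls.extend(
            biv.filter_poised_by_expression(calls, abundance, max_abundance)
        )
    matrices = biv.build_state_matrix(all_calls)
    summary = biv.summarize_transitions(matrices)
    table = pd.DataFrame(
        {
            "gene": [m.gene_id for m in matrices],
            "2wk_control": [m.states[0] for m in matrices],
            "2wk_IUGR": [m.states[1] for m in matrices],
            "10wk_control": [m.states[2] for m in matrices],
            "10wk_IUGR": [m.states[3] for m in matrices],
            "label": [biv.classify_transition(m) for m in matrices],
        }
    )
    return {"calls": all_calls, "matrices": matrices, "summary": summary,
            "table": table}


def run_motifs(
    bundle: Bundle,
    sig_alpha: float = 1e-4,
    ns_floor: float = 0.05,
) -> dict[str, object]:
    """Motif change calls per mark x age and the persistent sets."""
    by_key: dict[tuple[str, str], list[motifs.MotifChangeCall]] = {}
    for mark in MARKS:
        for age in AGES:
            iugr = {
                r.motif_name.casefold(): r
                for r in bundle.motif_records.get(
                    (mark, Condition(age, "IUGR")), []
                )
            }
            control = {
                r.motif_name.casefold(): r
                for r in bundle.motif_records.get(
                    (mark, Condition(age, "control")), []
                )
            }
            calls = [
                motifs.classify_motif_change(
                    iugr[name], control[name], sig_alpha, ns_floor
                )
                for name in sorted(iugr)
                if name in control
            ]
            if calls:
                by_key[(mark, age)] = calls
    persistent = {
        mark: motifs.persistent_motifs(
            by_key.get((mark, "2wk"), []), by_key.get((mark, "10wk"), []), mark
        )
        for mark in MARKS
        if (mark, "2wk") in by_key or (mark, "10wk") in by_key
    }
    return {"calls": by_key, "persistent": persistent}
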