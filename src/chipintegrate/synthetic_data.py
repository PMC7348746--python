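"""Synthetic toy genome, peak sets, differential and motif tables.

The generator emulates the *structure* of a four-condition (2 age x 2 group)
histone ChIP-seq + RNA-seq experiment rather than its read-level physics:
condition-level peak calls with planted bivalent promoters and poised-state
transitions, diffReps-style differential tables with planted sign structure
near TSSs, gene-level expression tables with planted mark-expression
concordance, and HOMER-style motif tables with planted persistence classes.
Every planted effect is recorded in a :class:`TruthManifest`, which recovery
tests use as the oracle.

Default scale is 2 chromosomes x 500 genes, which runs in seconds. Each
artifact type draws from its own named pseudorandom stream derived from the
single integer seed, so e.g. adding genes does not reshuffle motif tables.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .bivalency import TRANSITION_LABELS
from .genomic_intervals import GeneModel, GenomeAnnotation, GenomicInterval
from .io_formats import (
    AGES,
    CONDITIONS,
    MARKS,
    Condition,
    DiffSite,
    ExpressionRecord,
    MotifEnrichmentRecord,
    Peak,
    write_peaks,
    write_refflat,
)

__all__ = [
    "TruthManifest",
    "DEFAULT_STATE_FRACTIONS",
    "DEFAULT_CONCORDANCE_FRACTIONS",
    "DEFAULT_MOTIF_SPECS",
    "generate_annotation",
    "generate_condition_peaks",
    "generate_diff_and_expression",
    "generate_motif_tables",
    "simulate",
]


def _rng(seed: int, stream: str) -> np.random.Generator:
    """One named pseudorandom stream per artifact type."""
    return np.random.default_rng([int(seed), zlib.crc32(stream.encode())])


#: Fractions of genes planted with each bivalency state vector
#: (2wk control, 2wk IUGR, 10wk control, 10wk IUGR; T = poised). The mix
#: mirrors the study design: a stable poised background, small groups whose
#: poised state resolves with age in controls but not in growth-restricted
#: animals (TTFT) or appears de novo in adult controls only (FFTF), and rare
#: early gains/losses in the growth-restricted group.
DEFAULT_STATE_FRACTIONS: dict[str, float] = {
    "TTTT": 0.10,
    "TTFT": 0.01,
    "FFTF": 0.01,
    "FTTT": 0.006,
    "TFFF": 0.006,
    "FFFT": 0.01,
}

#: Fractions of (non-poised) genes planted per concordance class. The
#: all-three-marks classes exist only at 10 weeks (3 up + 3 down at the
#: default 500-gene scale), and the persistent H3K27Ac-down class spans both
#: ages (20 genes at default scale).
DEFAULT_CONCORDANCE_FRACTIONS: dict[str, float] = {
    "all3_up": 0.006,
    "all3_down": 0.006,
    "k27ac_down_persistent": 0.04,
    "k4me3_up_persistent": 0.02,
    "k27me3_up_persistent": 0.02,
    "discordant_all3": 0.01,
}

#: Planted motif persistence classes: 9 persistent H3K4me3 gains and 3
#: persistent H3K27me3 losses (the cardinalities of the motivating study),
#: plus transient and unchanged decoys.
DEFAULT_MOTIF_SPECS: tuple[tuple[str, str, str], ...] = tuple(
    [(f"GAIN{i:02d}", "H3K4me3", "persistent_gain") for i in range(1, 10)]
    + [(f"LOSS{i:02d}", "H3K27me3", "persistent_loss") for i in range(1, 4)]
    + [(f"TRANS{i:02d}", "H3K4me3", "transient_gain") for i in range(1, 4)]
    + [(f"NULL{i:02d}", "H3K4me3", "neither") for i in range(1, 4)]
    + [(f"NULL{i:02d}", "H3K27me3", "neither") for i in range(4, 7)]
    + [(f"BOTH{i:02d}", "H3K4me3", "both_enriched") for i in range(1, 3)]
)


@dataclass
class TruthManifest:
    """Ground-truth ledger of every planted effect plus generator parameters."""

    genes: pd.DataFrame
    motifs: pd.DataFrame
    params: dict

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.genes.to_csv(out_dir / "genes.tsv", sep="\t", index=False)
        self.motifs.to_csv(out_dir / "motifs.tsv", sep="\t", index=False)
        (out_dir / "params.json").write_text(
            json.dumps(self.params, indent=2, sort_keys=True) + "\n"
        )

    @classmethod
    def read(cls, out_dir: str | Path) -> "TruthManifest":
        out_dir = Path(out_dir)
        genes = pd.read_csv(out_dir / "genes.tsv", sep="\t")
        motifs = pd.read_csv(out_dir / "motifs.tsv", sep="\t")
        params = json.loads((out_dir / "params.json").read_text())
        return cls(genes, motifs, params)


# ---------------------------------------------------------------------------
# annotation


def generate_annotation(
    n_genes: int = 500,
    n_chroms: int = 2,
    gene_length_range: tuple[int, int] = (2000, 10000),
    spacing_range: tuple[int, int] = (12000, 20000),
    seed: int = 0,
    chrom_size_limit: int | None = None,
) -> GenomeAnnotation:
    """Lay out non-overlapping genes on a toy genome.

    Genes are distributed round-robin over chromosomes with intergenic
    spacing drawn from ``spacing_range`` (the default minimum of 12 kb keeps
    every TSS more than 5 kb from neighbouring gene bodies). Both strands
    occur; ~80% of genes are coding with 1-4 exons.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = _rng(seed, "annotation")
    cursors = {f"chr{i + 1}": 10000 for i in range(n_chroms)}
    chrom_names = list(cursors)
    genes: list[GeneModel] = []
    for i in range(n_genes):
        chrom = chrom_names[i % n_chroms]
        start = cursors[chrom] + int(rng.integers(*spacing_range))
        length = int(rng.integers(*gene_length_range))
        end = start + length
        if chrom_size_limit is not None and end + 10000 > chrom_size_limit:
            raise ValueError(
                f"chromosome capacity exceeded on {chrom} at gene {i}"
            )
        strand = "+" if rng.random() < 0.5 else "-"
        interval = GenomicInterval(chrom, start, end, strand)
        n_exons = int(rng.integers(1, 5))
        # alternate exon/intron segments with random weights
        weights = rng.random(2 * n_exons - 1) + 0.2
        seg_lengths = np.maximum(
            1, (weights / weights.sum() * length).astype(int)
        )
        seg_lengths[-1] += length - seg_lengths.sum()
        bounds = np.concatenate([[0], np.cumsum(seg_lengths)]) + start
        exons = tuple(
            GenomicInterval(chrom, int(bounds[j]), int(bounds[j + 1]), strand)
            for j in range(0, 2 * n_exons - 1, 2)
        )
        if rng.random() < 0.8:
            first, last = exons[0], exons[-1]
            cds_start = min(first.start + max(1, len(first) // 4), end - 2)
            cds_end = max(last.end - max(1, len(last) // 4), cds_start + 1)
        else:
            cds_start = cds_end = None
        genes.append(GeneModel(f"G{i:04d}", interval, exons, cds_start, cds_end))
        cursors[chrom] = end
    chrom_sizes = {chrom: cursor + 20000 for chrom, cursor in cursors.items()}
    return GenomeAnnotation(genes, chrom_sizes)


# ---------------------------------------------------------------------------
# peaks with planted bivalency


def _jitter(rng: np.random.Generator, sd: float) -> int:
    return int(round(rng.normal(0.0, sd))) if sd > 0 else 0


def _make_peak(
    chrom: str,
    start: int,
    end: int,
    mark: str,
    condition: Condition,
    rng: np.random.Generator,
    jitter_sd: float,
) -> Peak:
    start += _jitter(rng, jitter_sd)
    end += _jitter(rng, jitter_sd)
    start = max(0, start)
    end = max(start + 1, end)
    return Peak(GenomicInterval(chrom, start, end), mark, condition,
                score=float(rng.uniform(20, 200)))


def generate_condition_peaks(
    annotation: GenomeAnnotation,
    state_fractions: Mapping[str, float] | None = None,
    peak_width_range: tuple[int, int] = (400, 1200),
    jitter_sd: float = 0.0,
    min_overlap: int = 5,
    overlap_margin: int = 45,
    seed: int = 0,
) -> tuple[dict[tuple[str, Condition], list[Peak]], pd.DataFrame]:
    """Generate per-mark, per-condition peak sets with planted bivalency.

    Each gene is assigned a 4-bit poised-state vector according to
    ``state_fractions`` (patterns over {T,F}, remaining genes never poised).
    In a poised condition the gene receives an H3K4me3/H3K27me3 peak pair
    overlapping by ``min_overlap + overlap_margin`` bp centred on the TSS; in
    a non-poised condition only the H3K4me3 peak. H3K27Ac peaks cover every
    TSS in every condition. With ``jitter_sd`` 0 the geometry is exact;
    boundary jitter degrades overlaps and erodes planted bivalency.

    Returns the peak sets keyed by (mark, condition) and the per-gene truth
    table (pattern and transition label).
    """
    fractions = dict(
        DEFAULT_STATE_FRACTIONS if state_fractions is None else state_fractions
    )
    for pattern in fractions:
        if len(pattern) != 4 or set(pattern) - {"T", "F"}:
            raise ValueError(f"invalid state pattern {pattern!r}")
    if sum(fractions.values()) > 1 + 1e-9:
        raise ValueError("state fractions must sum to <= 1")

    rng = _rng(seed, "bivalency_peaks")
    genes = sorted(annotation.genes, key=lambda g: g.gene_id)
    order = rng.permutation(len(genes))
    pattern_of = {g.gene_id: "FFFF" for g in genes}
    cursor = 0
    for pattern, fraction in fractions.items():
        count = int(round(fraction * len(genes)))
        for idx in order[cursor:cursor + count]:
            pattern_of[genes[idx].gene_id] = pattern
        cursor += count

    half = (min_overlap + overlap_margin + 1) // 2
    peaks: dict[tuple[str, Condition], list[Peak]] = {
        (mark, cond): [] for mark in MARKS for cond in CONDITIONS
    }
    for gene in genes:
        tss = gene.tss
        pattern = pattern_of[gene.gene_id]
        for cond, poised in zip(CONDITIONS, pattern):
            w4 = int(rng.integers(*peak_width_range))
            w27 = int(rng.integers(*peak_width_range))
            wac = int(rng.integers(*peak_width_range))
            if poised == "T":
                # K4 ends just downstream of the TSS, K27 starts just
                # upstream: overlap [tss-half, tss+half) centred on the TSS
                peaks[("H3K4me3", cond)].append(_make_peak(
                    gene.chrom, tss + half - w4, tss + half,
                    "H3K4me3", cond, rng, jitter_sd))
                peaks[("H3K27me3", cond)].append(_make_peak(
                    gene.chrom, tss - half, tss - half + w27,
                    "H3K27me3", cond, rng, jitter_sd))
            else:
                peaks[("H3K4me3", cond)].append(_make_peak(
                    gene.chrom, tss - w4 // 2, tss + w4 // 2 + 1,
                    "H3K4me3", cond, rng, jitter_sd))
            peaks[("H3K27Ac", cond)].append(_make_peak(
                gene.chrom, tss - wac // 2, tss + wac // 2 + 1,
                "H3K27Ac", cond, rng, jitter_sd))

    truth = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "bivalency_pattern": [pattern_of[g.gene_id] for g in genes],
            "transition_label": [
                TRANSITION_LABELS[
                    tuple(c == "T" for c in pattern_of[g.gene_id])
                ]
                for g in genes
            ],
        }
    )
    return peaks, truth


# ---------------------------------------------------------------------------
# differential tables and expression


def _site(
    rng: np.random.Generator,
    gene: GeneModel,
    mark: str,
    age: str,
    log2fc: float,
    fdr: float,
    offset_range: tuple[int, int] = (-4000, 4000),
    noise_sd: float = 0.0,
) -> DiffSite:
    offset = int(rng.integers(offset_range[0], offset_range[1] + 1))
    width = int(rng.integers(200, 1000))
    center = max(width, gene.tss + offset)
    if noise_sd > 0:
        log2fc += float(rng.normal(0.0, noise_sd))
    if log2fc == 0:
        log2fc = 1e-6
    return DiffSite(
        GenomicInterval(gene.chrom, center - width // 2, center + width // 2),
        mark,
        age,
        log2fc,
        fdr / 2,
        fdr,
    )


# per class: {age: {mark: sign relative to the RNA direction}}; sign -1 for
# H3K27me3 encodes the repressive concordance convention
_CLASS_STRUCTURE: dict[str, dict[str, dict[str, int]]] = {
    "all3_up": {"10wk": {"H3K4me3": 1, "H3K27Ac": 1, "H3K27me3": -1}},
    "all3_down": {"10wk": {"H3K4me3": 1, "H3K27Ac": 1, "H3K27me3": -1}},
    "k27ac_down_persistent": {
        "2wk": {"H3K27Ac": 1},
        "10wk": {"H3K27Ac": 1},
    },
    "k4me3_up_persistent": {
        "2wk": {"H3K4me3": 1},
        "10wk": {"H3K4me3": 1},
    },
    "k27me3_up_persistent": {
        "2wk": {"H3K27me3": -1},
        "10wk": {"H3K27me3": -1},
    },
    # all three marks present but H3K27me3 moving WITH the RNA: the
    # repressive mark is discordant, so the gene never counts as all-3
    "discordant_all3": {
        "10wk": {"H3K4me3": 1, "H3K27Ac": 1, "H3K27me3": 1},
    },
}

_CLASS_RNA_DIRECTION = {
    "all3_up": 1,
    "all3_down": -1,
    "k27ac_down_persistent": -1,
    "k4me3_up_persistent": 1,
    "k27me3_up_persistent": -1,
    "discordant_all3": 1,
}


def generate_diff_and_expression(
    annotation: GenomeAnnotation,
    class_fractions: Mapping[str, float] | None = None,
    effect_size_range: tuple[float, float] = (0.5, 2.5),
    noise_sd: float = 0.0,
    fdr_sig: float = 1e-3,
    fdr_null: float = 0.9,
    seed: int = 0,
    exclude_genes: Iterable[str] = (),
    low_expression_genes: Iterable[str] = (),
) -> tuple[
    dict[tuple[str, str], list[DiffSite]],
    dict[str, list[ExpressionRecord]],
    pd.DataFrame,
]:
    """Generate differential-enrichment and expression tables with planted truth.

    Genes are assigned concordance classes per ``class_fractions`` (excluding
    ``exclude_genes``, typically planted-poised genes). Planted genes receive
    differential sites within 5 kb of their TSS with log2FC signs matching
    their class and FDR ``fdr_sig``; all other genes get null expression
    (FDR ``fdr_null``) and decoy sites that the pipeline must ignore (either
    non-significant or >5 kb from any TSS). ``low_expression_genes`` get
    mean abundance below 1 in both groups, emulating poised genes.
    """
    if effect_size_range[0] <= 0:
        raise ValueError("effect sizes must be > 0")
    fractions = dict(
        DEFAULT_CONCORDANCE_FRACTIONS
        if class_fractions is None
        else class_fractions
    )
    unknown = set(fractions) - set(_CLASS_STRUCTURE)
    if unknown:
        raise ValueError(f"unknown concordance classes {sorted(unknown)}")
    if sum(fractions.values()) > 1 + 1e-9:
        raise ValueError("class fractions must sum to <= 1")

    rng = _rng(seed, "diff_expression")
    genes = sorted(annotation.genes, key=lambda g: g.gene_id)
    excluded = set(exclude_genes)
    lowexpr = set(low_expression_genes)
    eligible = [g for g in genes if g.gene_id not in excluded]
    order = rng.permutation(len(eligible))
    class_of = {g.gene_id: "background" for g in genes}
    cursor = 0
    for cls, fraction in fractions.items():
        count = int(round(fraction * len(genes)))
        for idx in order[cursor:cursor + count]:
            class_of[eligible[idx].gene_id] = cls
        cursor += count

    diff: dict[tuple[str, str], list[DiffSite]] = {
        (mark, age): [] for mark in MARKS for age in AGES
    }
    expression: dict[str, list[ExpressionRecord]] = {age: [] for age in AGES}
    rows = []
    for gene in genes:
        cls = class_of[gene.gene_id]
        rna_fc: dict[str, float] = {}
        for age in AGES:
            planted = cls != "background" and age in _CLASS_STRUCTURE[cls]
            if planted:
                direction = _CLASS_RNA_DIRECTION[cls]
                fc = direction * float(rng.uniform(*effect_size_range))
                if noise_sd > 0:
                    fc += float(rng.normal(0.0, noise_sd))
                fdr = fdr_sig
                for mark, rel_sign in _CLASS_STRUCTURE[cls][age].items():
                    diff[(mark, age)].append(
                        _site(rng, gene, mark, age,
                              rel_sign * direction
                              * float(rng.uniform(*effect_size_range)),
                              fdr_sig, noise_sd=noise_sd)
                    )
            else:
                fc = float(rng.normal(0.0, 0.1))
                fdr = fdr_null
            rna_fc[age] = fc
            if gene.gene_id in lowexpr:
                abundance = {
                    "control": float(rng.uniform(0.0, 0.5)),
                    "IUGR": float(rng.uniform(0.0, 0.5)),
                }
            else:
                abundance = {
                    "control": float(rng.uniform(5, 200)),
                    "IUGR": float(rng.uniform(5, 200)),
                }
            expression[age].append(
                ExpressionRecord(gene.gene_id, age, fc, fdr, abundance)
            )
            # decoys: a non-significant site near the TSS and, occasionally,
            # a significant site beyond the 5 kb window
            if rng.random() < 0.10:
                mark = str(rng.choice(MARKS))
                diff[(mark, age)].append(
                    _site(rng, gene, mark, age,
                          float(rng.normal(0.0, 0.5)) or 0.1, fdr_null)
                )
            if rng.random() < 0.05:
                mark = str(rng.choice(MARKS))
                diff[(mark, age)].append(
                    _site(rng, gene, mark, age,
                          float(rng.uniform(*effect_size_range)), fdr_sig,
                          offset_range=(5501, 6900))
                )
        rows.append(
            {
                "gene_id": gene.gene_id,
                "concordance_class": cls,
                "rna_log2fc_2wk": rna_fc["2wk"],
                "rna_log2fc_10wk": rna_fc["10wk"],
                "low_expression": gene.gene_id in lowexpr,
            }
        )
    truth = pd.DataFrame(rows)
    return diff, expression, truth


# ---------------------------------------------------------------------------
# motif tables


_IUPAC = "ACGT"


def generate_motif_tables(
    motif_specs: Sequence[tuple[str, str, str]] | None = None,
    seed: int = 0,
) -> tuple[dict[tuple[str, Condition], list[MotifEnrichmentRecord]], pd.DataFrame]:
    """Generate per-mark, per-condition motif-enrichment tables.

    ``motif_specs`` is a sequence of (name, mark, class) with class one of
    ``persistent_gain``, ``persistent_loss``, ``transient_gain``,
    ``both_enriched`` or ``neither``. Gains plant p <= 1e-6 in IUGR and
    p >= 0.1 in control (losses mirrored); persistent classes hold at both
    ages, transient ones only at 2 weeks.
    """
    specs = DEFAULT_MOTIF_SPECS if motif_specs is None else tuple(motif_specs)
    valid = {"persistent_gain", "persistent_loss", "transient_gain",
             "both_enriched", "neither"}
    rng = _rng(seed, "motifs")
    records: dict[tuple[str, Condition], list[MotifEnrichmentRecord]] = {
        (mark, cond): [] for mark in MARKS for cond in CONDITIONS
    }
    rows = []
    for name, mark, cls in specs:
        if cls not in valid:
            raise ValueError(f"unknown motif class {cls!r}")
        consensus = "".join(rng.choice(list(_IUPAC), size=10))
        rows.append(
            {"motif_name": name, "consensus": consensus, "mark": mark,
             "planted_class": cls}
        )

        def enriched() -> float:
            return float(10.0 ** -rng.uniform(6, 60))

        def flat() -> float:
            return float(rng.choice([0.1, 0.5, 1.0]))

        for age in AGES:
            if cls == "persistent_gain" or (cls == "transient_gain"
                                            and age == "2wk"):
                p_iugr, p_control = enriched(), float(rng.choice([0.1, 1.0]))
            elif cls == "persistent_loss":
                p_iugr, p_control = float(rng.choice([0.1, 1.0])), enriched()
            elif cls == "both_enriched":
                p_iugr, p_control = enriched(), enriched()
            else:  # neither, or transient gain at 10 weeks
                p_iugr, p_control = flat(), flat()
            for group, p in (("IUGR", p_iugr), ("control", p_control)):
                cond = Condition(age, group)
                records[(mark, cond)].append(
                    MotifEnrichmentRecord(name, consensus, mark, cond, p)
                )
    return records, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# the full input bundle


def simulate(
    out_dir: str | Path,
    seed: int = 0,
    n_genes: int = 500,
    n_chroms: int = 2,
    jitter_sd: float = 0.0,
    noise_sd: float = 0.0,
    state_fractions: Mapping[str, float] | None = None,
    class_fractions: Mapping[str, float] | None = None,
    min_overlap: int = 5,
) -> TruthManifest:
    """Write a complete, self-describing input bundle plus truth manifest.

    The bundle contains the annotation (refFlat TSV + chrom sizes), BED peak
    files per mark x condition, differential TSVs per mark x age, expression
    TSVs per age, motif TSVs per mark x condition, the manifest directory,
    and a ``config.yaml`` naming every file so the analysis commands can run
    directly against it.
    """
    out_dir = Path(out_dir)
    annotation = generate_annotation(n_genes, n_chroms, seed=seed)
    peaks, biv_truth = generate_condition_peaks(
        annotation,
        state_fractions=state_fractions,
        jitter_sd=jitter_sd,
        min_overlap=min_overlap,
        seed=seed,
    )
    poised = set(
        biv_truth.loc[biv_truth.bivalency_pattern != "FFFF", "gene_id"]
    )
    diff, expression, expr_truth = generate_diff_and_expression(
        annotation,
        class_fractions=class_fractions,
        noise_sd=noise_sd,
        seed=seed,
        exclude_genes=poised,
        low_expression_genes=poised,
    )
    motif_records, motif_truth = generate_motif_tables(seed=seed)

    out_dir.mkdir(parents=True, exist_ok=True)
    write_refflat(annotation, out_dir / "annotation.refflat.tsv")
    with open(out_dir / "chrom.sizes", "w") as fh:
        for chrom, size in sorted(annotation.chrom_sizes.items()):
            fh.write(f"{chrom}\t{size}\n")

    config: dict = {
        "annotation": "annotation.refflat.tsv",
        "chrom_sizes": "chrom.sizes",
        "peaks": {},
        "diff": {},
        "expression": {},
        "motifs": {},
        "params": {
            "seed": seed,
            "n_genes": n_genes,
            "n_chroms": n_chroms,
            "jitter_sd": jitter_sd,
            "noise_sd": noise_sd,
            "min_overlap": min_overlap,
        },
    }

    (out_dir / "peaks").mkdir(exist_ok=True)
    for (mark, cond), peak_list in peaks.items():
        rel = f"peaks/{mark}_{cond.label}.bed"
        write_peaks(peak_list, out_dir / rel)
        config["peaks"].setdefault(mark, {})[cond.label] = rel

    (out_dir / "diff").mkdir(exist_ok=True)
    for (mark, age), sites in diff.items():
        rel = f"diff/{mark}_{age}.tsv"
        pd.DataFrame(
            {
                "chrom": [s.interval.chrom for s in sites],
                "start": [s.interval.start for s in sites],
                "end": [s.interval.end for s in sites],
                "log2fc": [s.log2fc for s in sites],
                "pvalue": [s.pvalue for s in sites],
                "fdr": [s.fdr for s in sites],
            }
        ).to_csv(out_dir / rel, sep="\t", index=False)
        config["diff"].setdefault(mark, {})[age] = rel

    for age, records in expression.items():
        rel = f"expression_{age}.tsv"
        pd.DataFrame(
            {
                "gene": [r.gene_id for r in records],
                "log2fc": [r.log2fc for r in records],
                "fdr": [r.fdr for r in records],
                "mean_control": [r.mean_abundance["control"] for r in records],
                "mean_iugr": [r.mean_abundance["IUGR"] for r in records],
            }
        ).to_csv(out_dir / rel, sep="\t", index=False)
        config["expression"][age] = rel

    (out_dir / "motifs").mkdir(exist_ok=True)
    for (mark, cond), records in motif_records.items():
        if not records:
            continue
        rel = f"motifs/{mark}_{cond.label}.tsv"
        pd.DataFrame(
            {
                "motif_name": [r.motif_name for r in records],
                "consensus": [r.consensus for r in records],
                "pvalue": [r.pvalue for r in records],
            }
        ).to_csv(out_dir / rel, sep="\t", index=False)
        config["motifs"].setdefault(mark, {})[cond.label] = rel

    genes_truth = biv_truth.merge(expr_truth, on="gene_id", how="outer")
    manifest = TruthManifest(genes_truth, motif_truth, config["params"])
    manifest.write(out_dir / "manifest")
    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return manifest
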