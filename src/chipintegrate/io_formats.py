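"""Readers and writers for every tabular interface of the pipeline.

Input dialects are modelled on the tools whose outputs the pipeline consumes:
MACS2-style BED/narrowPeak for peaks, diffReps-style TSV for differential
enrichment, edgeR-style gene tables for expression, and HOMER
knownResults-style tables for motif enrichment. Parsers never silently drop
rows: malformed coordinates abort with the offending line number, and rows
rejected for non-coordinate reasons are counted in the log.

The experimental design is fixed to the 2x2 layout the transition classifier
is defined on: ages ``2wk``/``10wk`` x groups ``control``/``IUGR``.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genomic_intervals import (
    GeneModel,
    GenomeAnnotation,
    GenomicInterval,
    SignalTrack,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MARKS",
    "AGES",
    "GROUPS",
    "Condition",
    "CONDITIONS",
    "Peak",
    "DiffSite",
    "ExpressionRecord",
    "MotifEnrichmentRecord",
    "parse_pvalue",
    "read_chrom_sizes",
    "read_refflat",
    "write_refflat",
    "read_gtf",
    "read_peaks",
    "write_peaks",
    "read_diff_table",
    "read_expression",
    "read_motif_table",
    "read_bedgraph",
    "write_results",
]

MARKS = ("H3K4me3", "H3K27me3", "H3K27Ac")
AGES = ("2wk", "10wk")
GROUPS = ("control", "IUGR")

IUPAC_ALPHABET = frozenset("ACGTRYSWKMBDHVN")


@dataclass(frozen=True, slots=True)
class Condition:
    """One cell of the 2x2 design: age x group."""

    age: str
    group: str

    def __post_init__(self) -> None:
        if self.age not in AGES:
            raise ValueError(f"age must be one of {AGES}, got {self.age!r}")
        if self.group not in GROUPS:
            raise ValueError(
                f"group must be one of {GROUPS}, got {self.group!r}"
            )

    @property
    def label(self) -> str:
        return f"{self.age}_{self.group}"

    @classmethod
    def from_label(cls, label: str) -> "Condition":
        age, _, group = label.partition("_")
        return cls(age, group)


#: The four conditions in canonical order (2wk control, 2wk IUGR,
#: 10wk control, 10wk IUGR) — the order of bivalency state vectors.
CONDITIONS = (
    Condition("2wk", "control"),
    Condition("2wk", "IUGR"),
    Condition("10wk", "control"),
    Condition("10wk", "IUGR"),
)


@dataclass(frozen=True, slots=True)
class Peak:
    """A condition-level (replicate-merged) peak call for one histone mark.

    ``qvalue_neglog10`` flags whether ``qvalue`` is on the -log10 scale
    (narrowPeak convention) or linear.
    """

    interval: GenomicInterval
    mark: str
    condition: Condition
    score: float = 0.0
    qvalue: float = 0.0
    qvalue_neglog10: bool = False

    def __post_init__(self) -> None:
        if self.mark not in MARKS:
            raise ValueError(f"mark must be one of {MARKS}, got {self.mark!r}")
        if self.qvalue < 0:
            raise ValueError("qvalue must be >= 0")


@dataclass(frozen=True, slots=True)
class DiffSite:
    """A differential-enrichment interval (IUGR vs control) for one mark."""

    interval: GenomicInterval
    mark: str
    age: str
    log2fc: float
    pvalue: float
    fdr: float

    def __post_init__(self) -> None:
        if self.mark not in MARKS:
            raise ValueError(f"mark must be one of {MARKS}")
        if self.age not in AGES:
            raise ValueError(f"age must be one of {AGES}")
        if not np.isfinite(self.log2fc):
            raise ValueError("log2fc must be finite")
        if not (0 < self.pvalue <= 1):
            raise ValueError("pvalue must be in (0, 1]")
        if not (0 < self.fdr <= 1):
            raise ValueError("fdr must be in (0, 1]")


@dataclass(frozen=True)
class ExpressionRecord:
    """Gene-level differential expression (IUGR vs control) at one age.

    ``mean_abundance`` maps group -> normalised mean expression (CPM-scale);
    it may be empty when the source table carries no abundance columns.
    """

    gene_id: str
    age: str
    log2fc: float
    fdr: float
    mean_abundance: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.age not in AGES:
            raise ValueError(f"age must be one of {AGES}")
        if not (0 < self.fdr <= 1):
            raise ValueError("fdr must be in (0, 1]")
        for group, value in self.mean_abundance.items():
            if value < 0:
                raise ValueError(f"mean abundance for {group} must be >= 0")


@dataclass(frozen=True, slots=True)
class MotifEnrichmentRecord:
    """One motif-enrichment result (HOMER-style) for one mark x condition."""

    motif_name: str
    consensus: str
    mark: str
    condition: Condition
    pvalue: float

    def __post_init__(self) -> None:
        if self.mark not in MARKS:
            raise ValueError(f"mark must be one of {MARKS}")
        bad = set(self.consensus.upper()) - IUPAC_ALPHABET
        if bad:
            raise ValueError(
                f"consensus {self.consensus!r} has non-IUPAC symbols {bad}"
            )
        if not (0 < self.pvalue <= 1):
            raise ValueError("pvalue must be in (0, 1]")


_SCI_RE = re.compile(r"^([0-9.]+)\s*[x×]\s*10\s*\^?\s*(-?[0-9]+)\s*\^?$")


def parse_pvalue(text: str | float) -> float:
    """Parse a p-value that may use typeset scientific notation.

    Accepts plain floats ("0.1", "1e-5") as well as strings like
    ``1.00 × 10^−43^`` (unicode multiplication sign, unicode minus, optional
    caret markers) as they appear in publication tables.
    """
    if isinstance(text, (int, float)):
        return float(text)
    s = str(text).strip()
    s = s.replace("−", "-").replace("–", "-")
    m = _SCI_RE.match(s.replace("^", " ").strip()) or _SCI_RE.match(s)
    if m:
        return float(m.group(1)) * 10.0 ** int(m.group(2))
    return float(s)


# ---------------------------------------------------------------------------
# annotation


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column TSV: chromosome name, length in bp."""
    sizes: dict[str, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: expected two columns")
        sizes[fields[0]] = int(fields[1])
    return sizes


_REFFLAT_COLUMNS = [
    "gene_id",
    "chrom",
    "strand",
    "tx_start",
    "tx_end",
    "cds_start",
    "cds_end",
    "exon_count",
    "exon_starts",
    "exon_ends",
]


def read_refflat(
    path: str | Path, chrom_sizes: Mapping[str, int]
) -> GenomeAnnotation:
    """Read gene models from a refFlat-style TSV.

    Columns: gene_id, chrom, strand, tx_start, tx_end, cds_start, cds_end,
    exon_count, exon_starts (comma-separated), exon_ends. A CDS with
    ``cds_start == cds_end`` marks a non-coding gene (UCSC convention).
    """
    df = pd.read_csv(path, sep="\t")
    missing = set(_REFFLAT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    genes = []
    for row in df.itertuples(index=False):
        interval = GenomicInterval(
            row.chrom, int(row.tx_start), int(row.tx_end), row.strand
        )
        starts = [int(x) for x in str(row.exon_starts).rstrip(",").split(",")]
        ends = [int(x) for x in str(row.exon_ends).rstrip(",").split(",")]
        exons = tuple(
            GenomicInterval(row.chrom, s, e, row.strand)
            for s, e in zip(starts, ends)
        )
        cds_start: int | None = int(row.cds_start)
        cds_end: int | None = int(row.cds_end)
        if cds_start == cds_end:
            cds_start = cds_end = None
        genes.append(
            GeneModel(str(row.gene_id), interval, exons, cds_start, cds_end)
        )
    return GenomeAnnotation(genes, chrom_sizes)


def write_refflat(annotation: GenomeAnnotation, path: str | Path) -> None:
    rows = []
    for g in sorted(annotation.genes, key=lambda g: g.gene_id):
        rows.append(
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "strand": g.strand,
                "tx_start": g.interval.start,
                "tx_end": g.interval.end,
                "cds_start": g.cds_start if g.is_coding else g.interval.start,
                "cds_end": g.cds_end if g.is_coding else g.interval.start,
                "exon_count": len(g.exons),
                "exon_starts": ",".join(str(e.start) for e in g.exons),
                "exon_ends": ",".join(str(e.end) for e in g.exons),
            }
        )
    pd.DataFrame(rows, columns=_REFFLAT_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def read_gtf(
    path: str | Path, chrom_sizes: Mapping[str, int]
) -> GenomeAnnotation:
    """Read gene models from a GTF file (gene_id attribute required).

    GTF is 1-based inclusive; coordinates are converted to 0-based half-open
    on read. Exon structure comes from ``exon`` features and the CDS span
    from ``CDS`` features; a transcript without CDS features is non-coding.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes = []
    for feature in db.features_of_type(("gene",)):
        gene_id = feature.attributes["gene_id"][0]
        interval = GenomicInterval(
            feature.seqid, feature.start - 1, feature.end, feature.strand
        )
        exons = sorted(
            db.children(feature, featuretype="exon"), key=lambda f: f.start
        )
        exon_ivs = tuple(
            GenomicInterval(e.seqid, e.start - 1, e.end, e.strand)
            for e in exons
        )
        cds = list(db.children(feature, featuretype="CDS"))
        cds_start = min(c.start for c in cds) - 1 if cds else None
        cds_end = max(c.end for c in cds) if cds else None
        genes.append(GeneModel(gene_id, interval, exon_ivs, cds_start, cds_end))
    return GenomeAnnotation(genes, chrom_sizes)


# ---------------------------------------------------------------------------
# peaks


def read_peaks(
    path: str | Path, mark: str, condition: Condition
) -> list[Peak]:
    """Read peaks from a BED3+ or narrowPeak file.

    narrowPeak rows (10 columns) carry their q-value on the -log10 scale;
    plainer BED rows get score/qvalue defaults. Malformed coordinates abort
    with the offending line number.
    """
    peaks: list[Peak] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: expected at least 3 columns")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ValueError(
                f"{path}:{lineno}: non-integer coordinate"
            ) from exc
        try:
            interval = GenomicInterval(chrom, start, end)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
        score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
        if len(fields) >= 10:  # narrowPeak
            qvalue = float(fields[8])
            neglog10 = True
        else:
            qvalue = 0.0
            neglog10 = False
        peaks.append(Peak(interval, mark, condition, score, qvalue, neglog10))
    logger.info("read %d %s peaks (%s) from %s",
                len(peaks), mark, condition.label, path)
    return peaks


def write_peaks(peaks: Sequence[Peak], path: str | Path) -> None:
    """Write peaks as BED5 (name column ``mark:condition``)."""
    with open(path, "w") as fh:
        for i, p in enumerate(
            sorted(peaks, key=lambda p: (p.interval.chrom, p.interval.start))
        ):
            fh.write(
                f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}"
                f"\t{p.mark}:{p.condition.label}:{i}\t{p.score:g}\n"
            )


# ---------------------------------------------------------------------------
# tabular inputs


def _resolve_columns(
    df: pd.DataFrame, aliases: Mapping[str, Sequence[str]], path: str | Path
) -> dict[str, str]:
    lower = {
        c.lower().replace(" ", "").replace("-", "").replace("_", ""): c
        for c in df.columns
    }
    resolved = {}
    for canonical, names in aliases.items():
        for name in names:
            if name in lower:
                resolved[canonical] = lower[name]
                break
        else:
            raise ValueError(
                f"{path}: missing required column {canonical!r} "
                f"(accepted names: {list(names)})"
            )
    return resolved


_DIFF_ALIASES = {
    "chrom": ("chrom", "chr", "chromosome"),
    "start": ("start",),
    "end": ("end",),
    "log2fc": ("log2fc", "logfc", "log2foldchange"),
    "pvalue": ("pvalue", "pval", "p"),
    "fdr": ("fdr", "padj", "qvalue"),
}


def read_diff_table(path: str | Path, mark: str, age: str) -> list[DiffSite]:
    """Read a diffReps-style differential-enrichment TSV."""
    df = pd.read_csv(path, sep="\t")
    cols = _resolve_columns(df, _DIFF_ALIASES, path)
    sites: list[DiffSite] = []
    rejected = 0
    for row in df.to_dict("records"):
        try:
            site = DiffSite(
                GenomicInterval(
                    str(row[cols["chrom"]]),
                    int(row[cols["start"]]),
                    int(row[cols["end"]]),
                ),
                mark,
                age,
                float(row[cols["log2fc"]]),
                parse_pvalue(row[cols["pvalue"]]),
                parse_pvalue(row[cols["fdr"]]),
            )
        except (ValueError, TypeError):
            rejected += 1
            continue
        sites.append(site)
    if rejected:
        logger.warning("%s: rejected %d malformed rows", path, rejected)
    if not sites and rejected == 0:
        logger.warning("%s: empty differential table", path)
    return sites


_EXPR_ALIASES = {
    "gene_id": ("gene", "geneid", "gene_id", "symbol"),
    "log2fc": ("log2fc", "logfc", "rnaseqlogfc"),
    "fdr": ("fdr", "padj", "rnaseqfdr"),
}


def read_expression(path: str | Path, age: str) -> list[ExpressionRecord]:
    """Read a gene-level differential-expression TSV.

    Optional ``mean_control``/``mean_iugr`` columns populate per-group mean
    abundance, used by the poised-gene low-expression filter.
    """
    df = pd.read_csv(path, sep="\t")
    cols = _resolve_columns(df, _EXPR_ALIASES, path)
    lower = {c.lower(): c for c in df.columns}
    records: list[ExpressionRecord] = []
    rejected = 0
    for row in df.to_dict("records"):
        abundance = {}
        for group, col in (("control", "mean_control"), ("IUGR", "mean_iugr")):
            if col in lower:
                abundance[group] = float(row[lower[col]])
        try:
            rec = ExpressionRecord(
                str(row[cols["gene_id"]]),
                age,
                float(row[cols["log2fc"]]),
                parse_pvalue(row[cols["fdr"]]),
                abundance,
            )
        except (ValueError, TypeError):
            rejected += 1
            continue
        records.append(rec)
    if rejected:
        logger.warning("%s: rejected %d malformed rows", path, rejected)
    if not records and rejected == 0:
        logger.warning("%s: empty expression table", path)
    return records


_MOTIF_ALIASES = {
    "motif_name": ("motifname", "motif", "name"),
    "consensus": ("consensus",),
    "pvalue": ("pvalue", "pval", "p"),
}


def read_motif_table(
    path: str | Path, mark: str, condition: Condition
) -> list[MotifEnrichmentRecord]:
    """Read a HOMER knownResults-style motif-enrichment TSV.

    Scientific notation in any publication-typeset form (``1.00 × 10^−43^``)
    is normalised to plain floats on read.
    """
    df = pd.read_csv(path, sep="\t")
    cols = _resolve_columns(df, _MOTIF_ALIASES, path)
    records: list[MotifEnrichmentRecord] = []
    rejected = 0
    for row in df.to_dict("records"):
        try:
            rec = MotifEnrichmentRecord(
                str(row[cols["motif_name"]]),
                str(row[cols["consensus"]]),
                mark,
                condition,
                parse_pvalue(row[cols["pvalue"]]),
            )
        except (ValueError, TypeError):
            rejected += 1
            continue
        records.append(rec)
    if rejected:
        logger.warning("%s: rejected %d malformed rows", path, rejected)
    if not records and rejected == 0:
        logger.warning("%s: empty motif table", path)
    return records


def read_bedgraph(
    path: str | Path,
    chrom_sizes: Mapping[str, int],
    bin_size: int,
    total_depth: float,
) -> dict[str, SignalTrack]:
    """Read a fixed-bin bedGraph into one SignalTrack per chromosome.

    Every record must align to the bin grid (start multiple of ``bin_size``,
    span one bin except possibly a short final bin).
    """
    tracks = {
        chrom: np.zeros(-(-size // bin_size))
        for chrom, size in chrom_sizes.items()
    }
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track")):
            continue
        chrom, start, end, value = line.split("\t")[:4]
        start = int(start)
        if chrom not in tracks:
            raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
        if start % bin_size != 0:
            raise ValueError(
                f"{path}:{lineno}: record not aligned to {bin_size} bp bins"
            )
        tracks[chrom][start // bin_size] = float(value)
    return {
        chrom: SignalTrack(chrom, bin_size, values, total_depth)
        for chrom, values in tracks.items()
    }


# ---------------------------------------------------------------------------
# results


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    params: Mapping[str, object] | None = None,
    seed: int | None = None,
    force: bool = False,
) -> list[Path]:
    """Write result tables as TSVs plus a run-metadata JSON.

    Output is deterministic: rows are sorted by the first column, column
    order is preserved, and the metadata records parameters, seed and
    package version (no timestamps). Existing files abort unless ``force``.
    """
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, df in sorted(tables.items()):
        path = out_dir / f"{name}.tsv"
        if path.exists() and not force:
            raise FileExistsError(f"{path} exists; pass force=True to replace")
        out = df.copy()
        if len(out.columns):
            out = out.sort_values(list(out.columns[:1]), kind="mergesort")
        out.to_csv(path, sep="\t", index=False)
        written.append(path)
    meta = {
        "package_version": __version__,
        "seed": seed,
        "parameters": dict(params or {}),
        "tables": [p.name for p in written],
    }
    meta_path = out_dir / "run_metadata.json"
    if meta_path.exists() and not force:
        raise FileExistsError(f"{meta_path} exists; pass force=True to replace")
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    written.append(meta_path)
    return written
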