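"""Core genomic interval arithmetic, region taxonomy and TSS-centric queries.

Coordinates are 0-based, half-open (BED convention) throughout. A gene's
transcription start site (TSS) is its strand-aware 5' end: ``start`` for a
plus-strand gene and ``end - 1`` for a minus-strand gene. Signed distances to
a TSS are reported in the gene's orientation, so positive means downstream of
the TSS regardless of strand.

The region taxonomy classifies a genomic point into exactly one of eight
categories used when summarising where histone-modification peaks fall:

* ``promoter_tss`` -- 1 kb upstream to 100 bp downstream of a TSS;
* ``tss``          -- 100 bp upstream to 1 kb downstream of a TSS;
* ``utr5``/``utr3``-- exonic sequence 5' of the start codon / 3' of the stop;
* ``exon``/``intron`` -- remaining gene-body positions of coding genes;
* ``noncoding``    -- inside a gene without an annotated CDS;
* ``intergenic``   -- none of the above.

Where the windows of neighbouring genes overlap, the gene with the nearest
TSS claims the point; within a gene the fixed precedence
promoter_tss > tss > utr5 > utr3 > exon > intron > noncoding applies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "GenomeAnnotation",
    "RegionCategory",
    "SignalTrack",
    "LogRatioTrack",
    "overlap_length",
    "assign_region_category",
    "distance_to_nearest_tss",
    "distance_to_nearest_gene_body",
    "summarize_distance_bins",
    "normalize_log2_ratio",
    "tss_metaprofile",
]

VALID_STRANDS = ("+", "-", ".")

# Strand-aware annotation windows, in bp relative to the TSS (negative =
# upstream in the gene's orientation, half-open on the downstream side).
PROMOTER_TSS_WINDOW = (-1000, 100)
TSS_WINDOW = (-100, 1000)

DISTANCE_BINS = ("<=1kb", "1-5kb", ">5kb")


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must be > start, got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Length in bp of the overlap of two intervals (0 if disjoint).

    Intervals on different chromosomes never overlap. Symmetric in its
    arguments and never negative.
    """
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


@dataclass(frozen=True)
class GeneModel:
    """A gene with exon structure and optional CDS.

    ``cds_start``/``cds_end`` are genomic coordinates (``cds_start <
    cds_end`` independent of strand); both ``None`` marks a non-coding gene.
    """

    gene_id: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...] = ()
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if self.interval.strand not in ("+", "-"):
            raise ValueError("gene strand must be '+' or '-'")
        if not self.exons:
            object.__setattr__(self, "exons", (self.interval,))
        prev_end = None
        for exon in self.exons:
            if exon.chrom != self.interval.chrom:
                raise ValueError("exon on wrong chromosome")
            if exon.start < self.interval.start or exon.end > self.interval.end:
                raise ValueError("exon outside gene interval")
            if prev_end is not None and exon.start < prev_end:
                raise ValueError("exons must be sorted and non-overlapping")
            prev_end = exon.end
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError("cds_start and cds_end must both be set or unset")
        if self.cds_start is not None and self.cds_start >= self.cds_end:
            raise ValueError("cds_start must be < cds_end")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        """Strand-aware transcription start site (5' end)."""
        if self.strand == "+":
            return self.interval.start
        return self.interval.end - 1

    @property
    def tes(self) -> int:
        """Strand-aware transcription end site (3' end)."""
        if self.strand == "+":
            return self.interval.end - 1
        return self.interval.start

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None


class RegionCategory(str, Enum):
    PROMOTER_TSS = "promoter_tss"
    TSS = "tss"
    UTR5 = "utr5"
    UTR3 = "utr3"
    EXON = "exon"
    INTRON = "intron"
    NONCODING = "noncoding"
    INTERGENIC = "intergenic"


class GenomeAnnotation:
    """A set of gene models plus chromosome sizes, indexed for TSS queries."""

    def __init__(
        self,
        genes: Iterable[GeneModel],
        chrom_sizes: Mapping[str, int],
    ) -> None:
        self.genes: tuple[GeneModel, ...] = tuple(genes)
        self.chrom_sizes: dict[str, int] = dict(chrom_sizes)

        seen: set[str] = set()
        for gene in self.genes:
            if gene.gene_id in seen:
                raise ValueError(f"duplicate gene_id {gene.gene_id!r}")
            seen.add(gene.gene_id)
            size = self.chrom_sizes.get(gene.chrom)
            if size is None:
                raise ValueError(
                    f"gene {gene.gene_id} on unknown chromosome {gene.chrom}"
                )
            if gene.interval.end > size:
                raise ValueError(
                    f"gene {gene.gene_id} extends past end of {gene.chrom}"
                )

        # Per-chromosome indexes: TSS positions sorted, and candidate spans
        # (gene body plus both TSS windows) for point classification.
        self._by_chrom: dict[str, dict[str, np.ndarray | list[GeneModel]]] = {}
        by_chrom_genes: dict[str, list[GeneModel]] = {}
        for gene in self.genes:
            by_chrom_genes.setdefault(gene.chrom, []).append(gene)
        for chrom, chrom_genes in by_chrom_genes.items():
            order = sorted(range(len(chrom_genes)),
                           key=lambda i: (chrom_genes[i].tss,
                                          chrom_genes[i].gene_id))
            chrom_genes = [chrom_genes[i] for i in order]
            tss = np.array([g.tss for g in chrom_genes], dtype=np.int64)
            reach = max(-PROMOTER_TSS_WINDOW[0], TSS_WINDOW[1])
            span_lo = np.array(
                [min(g.interval.start, g.tss - reach) for g in chrom_genes],
                dtype=np.int64,
            )
            span_hi = np.array(
                [max(g.interval.end, g.tss + reach) for g in chrom_genes],
                dtype=np.int64,
            )
            self._by_chrom[chrom] = {
                "genes": chrom_genes,
                "tss": tss,
                "span_lo": span_lo,
                "span_hi": span_hi,
            }

    def __len__(self) -> int:
        return len(self.genes)

    def genes_on(self, chrom: str) -> Sequence[GeneModel]:
        entry = self._by_chrom.get(chrom)
        return entry["genes"] if entry else ()

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


def _tss_offset(gene: GeneModel, pos: int) -> int:
    """Signed distance from TSS in the gene's orientation (+ = downstream)."""
    if gene.strand == "+":
        return pos - gene.tss
    return gene.tss - pos


def _categorize_within_gene(gene: GeneModel, pos: int) -> RegionCategory | None:
    """Category of ``pos`` with respect to one gene, or None if outside.

    Applies the fixed precedence promoter_tss > tss > utr5 > utr3 > exon >
    intron > noncoding.
    """
    d = _tss_offset(gene, pos)
    if PROMOTER_TSS_WINDOW[0] <= d < PROMOTER_TSS_WINDOW[1]:
        return RegionCategory.PROMOTER_TSS
    if TSS_WINDOW[0] <= d < TSS_WINDOW[1]:
        return RegionCategory.TSS
    if not (gene.interval.start <= pos < gene.interval.end):
        return None
    if not gene.is_coding:
        return RegionCategory.NONCODING
    in_exon = any(e.start <= pos < e.end for e in gene.exons)
    if not in_exon:
        return RegionCategory.INTRON
    if gene.strand == "+":
        if pos < gene.cds_start:
            return RegionCategory.UTR5
        if pos >= gene.cds_end:
            return RegionCategory.UTR3
    else:
        if pos >= gene.cds_end:
            return RegionCategory.UTR5
        if pos < gene.cds_start:
            return RegionCategory.UTR3
    return RegionCategory.EXON


def assign_region_category(
    chrom: str,
    pos: int,
    annotation: GenomeAnnotation,
) -> tuple[RegionCategory, str | None]:
    """Classify a genomic point into exactly one region category.

    Returns ``(category, gene_id)``; ``gene_id`` is None for intergenic
    points. When several genes claim the point, the gene with the nearest TSS
    wins (ties by lexicographically smallest gene_id).
    """
    if chrom not in annotation.chrom_sizes:
        raise ValueError(
            f"point on chromosome {chrom!r} absent from annotation; "
            "peak and annotation assemblies likely mismatch"
        )
    entry = annotation._by_chrom.get(chrom)
    if entry is None:
        return RegionCategory.INTERGENIC, None
    mask = (entry["span_lo"] <= pos) & (pos < entry["span_hi"])
    best: tuple[int, str, RegionCategory] | None = None
    for i in np.flatnonzero(mask):
        gene = entry["genes"][i]
        cat = _categorize_within_gene(gene, pos)
        if cat is None:
            continue
        key = (abs(pos - gene.tss), gene.gene_id)
        if best is None or key < (best[0], best[1]):
            best = (key[0], key[1], cat)
    if best is None:
        return RegionCategory.INTERGENIC, None
    return best[2], best[1]


def distance_to_nearest_tss(
    chrom: str,
    pos: int,
    annotation: GenomeAnnotation,
) -> tuple[str | None, float]:
    """Nearest TSS on the chromosome and the signed, strand-aware distance.

    Positive distance = downstream of the TSS in the gene's orientation.
    Nearest is by absolute distance; exact ties go to the lexicographically
    smallest gene_id. A chromosome with no genes returns ``(None, inf)``.
    """
    if chrom not in annotation.chrom_sizes:
        raise ValueError(f"unknown chromosome {chrom!r}")
    entry = annotation._by_chrom.get(chrom)
    if entry is None:
        return None, math.inf
    tss = entry["tss"]
    absd = np.abs(tss - pos)
    best = int(absd.min())
    candidates = [entry["genes"][i] for i in np.flatnonzero(absd == best)]
    gene = min(candidates, key=lambda g: g.gene_id)
    return gene.gene_id, float(_tss_offset(gene, pos))


def distance_to_nearest_gene_body(
    chrom: str,
    pos: int,
    annotation: GenomeAnnotation,
) -> tuple[str | None, float]:
    """Unsigned distance to the nearest gene body (0 inside a gene).

    Alternative distance metric to :func:`distance_to_nearest_tss` for
    summaries of how far peaks lie from genes rather than from start sites.
    Ties go to the lexicographically smallest gene_id.
    """
    if chrom not in annotation.chrom_sizes:
        raise ValueError(f"unknown chromosome {chrom!r}")
    best: tuple[float, str] | None = None
    for gene in annotation.genes_on(chrom):
        if gene.interval.start <= pos < gene.interval.end:
            d = 0
        else:
            d = min(
                abs(pos - gene.interval.start),
                abs(pos - (gene.interval.end - 1)),
            )
        if best is None or (d, gene.gene_id) < best:
            best = (d, gene.gene_id)
    if best is None:
        return None, math.inf
    return best[1], float(best[0])


def summarize_distance_bins(
    points: Sequence[tuple[str, int]],
    annotation: GenomeAnnotation,
    metric: str = "tss",
) -> pd.DataFrame:
    """Bin points by absolute distance to the nearest TSS (or gene body).

    Bins: ``<=1kb`` (|d| <= 1000), ``1-5kb`` (1000 < |d| <= 5000) and
    ``>5kb``. Points on gene-free chromosomes fall in ``>5kb``. ``metric``
    is ``"tss"`` (default) or ``"gene_body"``. Returns a DataFrame indexed
    by bin with ``count`` and ``fraction`` columns.
    """
    if metric not in ("tss", "gene_body"):
        raise ValueError("metric must be 'tss' or 'gene_body'")
    points = list(points)
    if not points:
        raise ValueError("summarize_distance_bins requires at least one point")
    counts = dict.fromkeys(DISTANCE_BINS, 0)
    for chrom, pos in points:
        if metric == "tss":
            _, d = distance_to_nearest_tss(chrom, pos, annotation)
        else:
            _, d = distance_to_nearest_gene_body(chrom, pos, annotation)
        a = abs(d)
        if a <= 1000:
            counts["<=1kb"] += 1
        elif a <= 5000:
            counts["1-5kb"] += 1
        else:
            counts[">5kb"] += 1
    total = len(points)
    return pd.DataFrame(
        {
            "count": [counts[b] for b in DISTANCE_BINS],
            "fraction": [counts[b] / total for b in DISTANCE_BINS],
        },
        index=pd.Index(DISTANCE_BINS, name="distance_bin"),
    )


@dataclass
class SignalTrack:
    """Fixed-bin, non-negative coverage for one chromosome.

    ``total_depth`` is the total mapped-read count of the library the track
    came from; it is the denominator of depth normalisation.
    """

    chrom: str
    bin_size: int
    values: np.ndarray
    total_depth: float

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if np.any(self.values < 0):
            raise ValueError("coverage values must be non-negative")
        if self.total_depth <= 0:
            raise ValueError("total_depth must be positive")


@dataclass
class LogRatioTrack:
    """Per-bin log2(sample/input) values for one chromosome."""

    chrom: str
    bin_size: int
    values: np.ndarray


def normalize_log2_ratio(
    sample: SignalTrack,
    input_ctrl: SignalTrack,
    pseudocount: float = 1e-6,
) -> LogRatioTrack:
    """Depth- and input-normalised log2 ratio track.

    Each bin is ``log2((sample_i/sample_depth + p) / (input_i/input_depth +
    p))`` with pseudocount ``p`` keeping every bin finite.
    """
    if sample.chrom != input_ctrl.chrom:
        raise ValueError("sample and input tracks are on different chromosomes")
    if sample.bin_size != input_ctrl.bin_size:
        raise ValueError("sample and input tracks have different bin sizes")
    if len(sample.values) != len(input_ctrl.values):
        raise ValueError("sample and input tracks have different lengths")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    s = sample.values / sample.total_depth + pseudocount
    c = input_ctrl.values / input_ctrl.total_depth + pseudocount
    return LogRatioTrack(sample.chrom, sample.bin_size, np.log2(s / c))


def tss_metaprofile(
    tracks: Mapping[str, LogRatioTrack],
    annotation: GenomeAnnotation,
    window: int = 5000,
    bin_size: int = 100,
) -> np.ndarray:
    """Average strand-oriented signal around all TSS (a TSS metaplot).

    Returns a vector of length ``2 * window / bin_size``; index
    ``window/bin_size`` is the bin containing the TSS. Minus-strand genes are
    flipped before averaging so upstream is always on the left. Bins falling
    outside a chromosome are ignored (NaN-averaged).
    """
    if window % bin_size != 0:
        raise ValueError("window must be a multiple of bin_size")
    n = window // bin_size
    rows = []
    for chrom, track in tracks.items():
        if track.bin_size != bin_size:
            raise ValueError(
                f"track for {chrom} has bin_size {track.bin_size}, "
                f"expected {bin_size}"
            )
        values = np.asarray(track.values, dtype=float)
        for gene in annotation.genes_on(chrom):
            center = gene.tss // bin_size
            offsets = np.arange(-n, n)
            if gene.strand == "+":
                idx = center + offsets
            else:
                # mirror so gene-oriented downstream is to the right and the
                # offset-0 bin stays at index n
                idx = center - offsets
            row = np.full(2 * n, np.nan)
            valid = (idx >= 0) & (idx < len(values))
            row[valid] = values[idx[valid]]
            rows.append(row)
    if not rows:
        raise ValueError("no TSS on any chromosome covered by the tracks")
    stacked = np.vstack(rows)
    with np.errstate(invalid="ignore"):
        return np.nanmean(stacked, axis=0)
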