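"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results with the plainest possible loops so
they stay independent of the implementation they check.
"""

from chipintegrate.genomic_intervals import RegionCategory

_PRECEDENCE = [
    RegionCategory.PROMOTER_TSS,
    RegionCategory.TSS,
    RegionCategory.UTR5,
    RegionCategory.UTR3,
    RegionCategory.EXON,
    RegionCategory.INTRON,
    RegionCategory.NONCODING,
]


def brute_force_category(chrom, pos, annotation):
    """Scan every gene; nearest TSS wins, then the fixed precedence."""
    best = None
    for gene in annotation.genes:
        if gene.chrom != chrom:
            continue
        d = pos - gene.tss if gene.strand == "+" else gene.tss - pos
        cats = []
        if -1000 <= d < 100:
            cats.append(RegionCategory.PROMOTER_TSS)
        if -100 <= d < 1000:
            cats.append(RegionCategory.TSS)
        if gene.interval.start <= pos < gene.interval.end:
            if not gene.is_coding:
                cats.append(RegionCategory.NONCODING)
            elif any(e.start <= pos < e.end for e in gene.exons):
                if gene.strand == "+":
                    if pos < gene.cds_start:
                        cats.append(RegionCategory.UTR5)
                    elif pos >= gene.cds_end:
                        cats.append(RegionCategory.UTR3)
                    else:
                        cats.append(RegionCategory.EXON)
                else:
                    if pos >= gene.cds_end:
                        cats.append(RegionCategory.UTR5)
                    elif pos < gene.cds_start:
                        cats.append(RegionCategory.UTR3)
                    else:
                        cats.append(RegionCategory.EXON)
            else:
                cats.append(RegionCategory.INTRON)
        if not cats:
            continue
        cat = min(cats, key=_PRECEDENCE.index)
        key = (abs(pos - gene.tss), gene.gene_id)
        if best is None or key < best[:2]:
            best = (key[0], key[1], cat)
    if best is None:
        return RegionCategory.INTERGENIC, None
    return best[2], best[1]
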