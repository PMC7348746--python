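# Methods

## Scope and model of the data

`chipintegrate` operates strictly downstream of read processing: peak calling,
differential-enrichment testing and motif discovery are consumed as result
tables, never computed. The experimental design is fixed to a 2x2 layout —
ages {2wk, 10wk} x groups {control, IUGR} — because the poised-state
transition classifier is defined on exactly four conditions; other designs
are rejected at the input layer. Peak sets are condition-level
(replicate-merged); no replicate-reproducibility logic is applied.

Coordinates are 0-based half-open (BED convention) throughout; GTF input is
converted on read. A gene's TSS is its strand-aware 5' end (`start` for +,
`end - 1` for −), and signed TSS distances are reported in gene orientation
(positive = downstream).

## Region taxonomy

A genomic point receives exactly one of eight categories. Windows are
strand-aware around the TSS: promoter-TSS spans −1000..+100 bp, the TSS
window −100..+1000 bp. Inside the gene body, exonic positions 5' of the CDS
are 5' UTR, 3' of it 3' UTR, other exonic positions exon, the rest intron;
genes without CDS are non-coding throughout their body. When windows of
neighbouring genes overlap, the gene with the nearest TSS claims the point
(exact ties to the lexicographically smallest gene id); within one gene the
fixed precedence promoter-TSS > TSS > 5'UTR > 3'UTR > exon > intron >
non-coding applies. Peaks are classified by their midpoint
(`floor((start+end)/2)`) — how a peak spanning several categories should be
assigned is genuinely open, and midpoint classification matches common
annotator behaviour. The >5 kb summary uses TSS distance by default;
`summarize_distance_bins(..., metric="gene_body")` measures distance to the
nearest gene body instead, for summaries phrased as distance "from the
nearest gene".

## Track normalisation and TSS metaprofiles

Coverage tracks are fixed-bin, depth-normalised, and compared to input
chromatin as `log2((s_i/D_s + p)/(c_i/D_c + p))` with pseudocount `p = 1e-6`
(configurable); the pseudocount keeps every bin finite and biases ratios
toward 0 only where both tracks are near-empty. Metaprofiles average the
ratio over all TSSs in a ±5000 bp window at 100 bp resolution (defaults),
mirroring minus-strand genes so transcriptional downstream is always to the
right; the offset-0 bin sits at vector index `window/bin`. Bins falling off
a chromosome end are NaN-averaged rather than zero-filled.

## Mark-expression concordance

Differential sites are filtered to FDR ≤ 0.05 (the upstream differential
caller's significance is not restated in the source analysis; adjusted
p ≤ 0.05 is the package default and is configurable and logged). A site is
credited to the gene with the nearest TSS when its midpoint lies within
5 kb; each gene keeps one site per mark and age — the nearest, with ties
broken by larger |log2FC| then smaller start — because the reference results
report a single fold-change per gene x mark. Concordance is a pure sign
rule: activating marks (H3K4me3, H3K27Ac) must move with the RNA, the
repressive mark (H3K27me3) against it; a zero fold-change is discordant, on
the grounds that no change cannot "correlate" in either direction. Only
genes with expression FDR ≤ 0.05 are classified; assignments at other genes
are dropped and counted in the log. Persistence means the same concordant
call with the same RNA direction at both ages.

## Bivalent promoters and transitions

A promoter is bivalent in a condition iff some H3K4me3/H3K27me3 peak pair
overlaps by at least `min_overlap = 5` bp and the midpoint of the overlap
lies within `promoter_window = 5000` bp of the TSS; the qualifying pair with
the largest overlap is recorded. The 5 bp floor is the published operational
definition of bivalency adopted here; the promoter window reuses the 5 kb
TSS window used elsewhere in the analysis (the source describes bivalency at
"promoter regions" without a number) and is configurable. No peak q-value
threshold beyond the upstream caller's own cut-off is applied.

Each gene's four boolean calls form a state vector ordered (2wk control,
2wk IUGR, 10wk control, 10wk IUGR); all four cells are kept independent. The
transition label is a pure lookup over the 16 vectors, with named aliases
for the salient patterns: 1111 `stable_poised`, 0000 `never_poised`, 1101
`control_resolved_IUGR_repoised`, 0010 `control_de_novo_IUGR_resolved`,
01·· `gained_in_IUGR_2wk`, 10·· `lost_in_IUGR_2wk`, and `state_XXXX` for the
remainder. A separate count reports genes whose 10-week control and IUGR
states differ. Lack of expression is consistent with a poised state: calls
are flagged (never removed) when mean abundance in the call's group falls
below `max_abundance = 1.0` on the expression table's scale (CPM-like);
missing abundance yields an explicit unknown flag.

## Motif persistence

For one motif, mark and age, the IUGR/control enrichment p-values classify
to `gained_in_IUGR` (p_IUGR ≤ `sig_alpha`, p_control ≥ `ns_floor`),
`lost_in_IUGR` (mirrored), `both_enriched` (both ≤ `sig_alpha`) or
`neither`. The source tables print control-side values of 0.1 or 1 against
IUGR values ≤ 1e−6, so any `sig_alpha` in [1e−6, 1e−4] with `ns_floor` in
(1e−4, 0.1] separates them identically; the defaults are `sig_alpha = 1e−4`,
`ns_floor = 0.05`. A change persists when the identical non-neutral class
holds at both ages; this includes `both_enriched`, which cannot arise from
the bundled reference p-values but can in principle. Motif names match
case-insensitively.

## Synthetic data

The generator states a world and the tests measure recovery from it; its
defaults are not tuned to test outcomes. The toy genome holds 500 genes on
2 chromosomes, gene bodies 2–10 kb, intergenic spacing 12–20 kb (so every
TSS is >5 kb from neighbouring genes and planted effects cannot collide),
both strands, ~80% coding with 1–4 exons. Planted structure mirrors the
motivating study's design: a 10% stable-poised background with ~1% slices
for the age-resolving patterns (TTFT, FFTF) and rare 2-week gains/losses;
concordance classes planting 3 up + 3 down all-three-marks genes at 10 weeks
only (none at 2 weeks), 20 persistent H3K27Ac-down genes, per-mark-only and
deliberately discordant decoys; 9 persistent H3K4me3 motif gains and 3
persistent H3K27me3 losses plus transient/neutral decoys. Poised genes get
mean abundance < 1; planted effects get FDR 1e−3 and effect sizes uniform in
[0.5, 2.5]; background genes get FDR 0.9 plus decoy sites that are either
non-significant or >5.5 kb from any TSS. One named RNG stream per artifact
type derives from the single seed, so enlarging the genome does not
reshuffle motif tables.

With `jitter_sd = 0` and `noise_sd = 0` the geometry is exact (bivalent
pairs overlap by 50 bp centred on the TSS) and every stage recovers the
manifest exactly; boundary jitter erodes overlaps below the 5 bp floor and
recall degrades monotonically in expectation. What the generator does *not*
emulate: read-level sampling noise, peak-width/signal correlation, broad
H3K27me3 domains, overlapping genes, chromosome-scale covariates. A green
recovery test therefore establishes correctness of the decision rules and
plumbing, not robustness to realistic ChIP noise.

## Numerical and degenerate-input choices

* Half-open interval overlap: adjacent intervals overlap 0 bp; different
  chromosomes overlap 0 bp rather than erroring.
* Nearest-TSS ties break to the lexicographically smallest gene id; site
  ties to larger |log2FC| then smaller start; bivalent-pair ties to the
  largest overlap then smallest peak starts. All outputs are deterministic
  and input-order-invariant.
* Gene-free chromosomes yield a "no gene"/infinite-distance sentinel (binned
  as >5 kb); unknown chromosomes are an error, signalling an
  annotation/peak assembly mismatch.
* Parsers reject malformed coordinates with the offending line number and
  count (never silently drop) other malformed rows; publication-typeset
  scientific notation ("1.00 × 10^−43^") is normalised to floats on read.
* Result writers emit byte-deterministic TSVs (stable sort, no timestamps)
  plus a run-metadata JSON with parameters, seed and package version.

## Limitations

* Site-to-gene assignment is nearest-TSS only; a site within 5 kb of two
  TSSs is credited once. Fine for the generator's spaced genome; on dense
  real annotations a multi-assignment mode would be a reasonable extension.
* Bivalency uses peak co-occurrence, not signal-level co-enrichment, and
  cannot distinguish truly bivalent nucleosomes from mixed cell populations
  — the usual caveat of bulk chromatin data.
* Full-scale published counts (thousands of differential genes, >1000
  bivalent genes, ~80% distal-mark fractions) depend on the original
  sequencing data and are out of reach of the bundled tables; the test
  suite covers those claims by planted-truth recovery instead.
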