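# Methods

## Coordinate model

All internal coordinates are 0-based half-open intervals; BED files are read
natively and GTF (1-based closed) is shifted on read and unshifted on write.
Transcript offsets always run 5'→3' of the transcript: the offset of a
genomic position is the number of exonic bases strictly 5' of it in
transcript orientation, so minus-strand arithmetic is confined to the two
coordinate-conversion methods and all downstream math (metagene binning,
region classification, exon/intron ordinals) is strand-free. Biotype is
inferred from CDS presence — a transcript with at least one CDS feature is
mRNA, otherwise lncRNA — which is robust across GTF dialects. Overlapping
exons within one transcript are rejected rather than merged, surfacing
malformed annotations early. mRNA models must have non-empty 5'UTR, CDS and
3'UTR in transcript coordinates; models violating this are rejected at
construction.

## Peak calling and merging

The caller tiles each chromosome into non-overlapping windows (default 25 bp)
and scores each window by the library-normalized enrichment
`(ip_w / L_ip) / ((input_w + c) / L_input)` with pseudocount `c = 1` coverage
unit, which keeps zero-input windows finite. Maximal runs of adjacent windows
at or above `min_enrichment` (default 2) whose total span is at least
`min_length` (default 50 bp) become peaks; the score is the run's mean
enrichment and the summit is the center of the strongest window. "Signal"
throughout is summed coverage, not read count: the pipeline consumes coverage
tracks, which keeps the synthetic data free of a read model while exercising
every downstream computation identically.

Within a group, replicate peak sets are intersected base-wise — a base
survives only when every replicate covers it — which is the strictest
reading of a "common region" and is testable against a per-base boolean
oracle. Between groups, peaks are unioned base-wise, with each merged
interval recording which group(s) contributed and the maximum contributing
score. Both merges produce sorted, non-overlapping, idempotent output.

## E-score differential methylation

Each merged peak receives one enrichment score per group,
`E = ((s_IP + c) / L_IP) / ((s_input + c) / L_input)`, after pooling
replicate signals and library sizes within the group (pooling by summation
matches a one-replicate-per-condition design and is the natural extension
beyond it). The score is kept on the linear scale: the conventional
mean-E threshold of 6 is only plausible for a linear ratio. A peak is called
`up` (higher in the case group) when mean E across groups exceeds `t_mean`
(default 6) and the log2 E-score difference exceeds `t_diff` (default 1);
`down` symmetrically; otherwise `ns`. The difference is computed as
`log2(E_case) − log2(E_control)` — a difference of logs rather than the log
of the ratio — so exchanging the group labels negates every value exactly in
floating point. The rule is a threshold call, not a hypothesis test, so no
multiple-testing correction applies here. Raising either threshold can only
shrink the set of non-`ns` calls.

## Metagene profiles

Each peak is reduced to a single representative point: the summit when the
caller recorded one, otherwise the interval midpoint. Point mapping is exact
against an enumeration oracle, whereas smearing a peak's span across bins
would introduce an arbitrary interval-weighting convention. The point is
projected onto every overlapping transcript of the profile's biotype; on
mRNA it is classified into 5'UTR/CDS/3'UTR by the CDS bounds in transcript
coordinates and expressed as a fraction of that region's length, on lncRNA
as a fraction of the spliced body. Fractions fill region-local bins —
20/40/40 for 5'UTR/CDS/3'UTR (each region drawn at fixed width, not
length-proportional) and 100 for lncRNA — and a peak mapping onto k
transcripts contributes total weight 1/k, removing any dependence on
annotation order. Counts are normalized to a density summing to 1 whenever
any peak maps.

Flatness of a profile (e.g. uniformly placed lncRNA peaks) is checked with a
chi-square goodness-of-fit test against the uniform law rather than per-bin
z-bands: with 100 bins, a ±3 SE band per bin rejects a perfectly uniform
generator in roughly a quarter of runs from chance alone.

## Functional annotation

The peak's representative point is tested against every overlapping
transcript. A transcript offers all categories the point satisfies (a 3'UTR
base is also exonic), and the highest-priority category wins under the
default order 5'UTR > 3'UTR > 1st exon > other exon > 1st intron > other
intron > distal intergenic — UTRs first because the seven reported classes
are disjoint. Exon and intron ordinals are counted in transcript orientation
(the 1st exon is 5'-most). When several transcripts tie on the winning
category, the one whose TSS is nearest supplies the gene id. Points
overlapping no transcript are distal intergenic, with the nearest TSS's gene
and the signed distance (positive downstream in that gene's orientation)
recorded. Promoter/downstream classes are intentionally absent.

## Motif discovery

Sequences of the top-N peaks by caller score (default 5000) are widened by
100 bp on each side, clipped to chromosome bounds, and reverse-complemented
for minus-strand peaks. The candidate space is a fixed, enumerable set of
IUPAC patterns — all 256 ACGT 4-mers plus RRAC, DRAC, RRACH, DRACH — rather
than an EM-optimized position weight matrix: with a fixed candidate set the
entire discovery loop is exactly testable. Each round builds, per remaining
candidate, the 2×2 table of sequences with/without at least one unerased
match (positive vs background), computes the one-sided Fisher's exact P
(evaluated as the hypergeometric survival function, which is the identical
quantity and vectorizes), and the E-value P × |candidates|. The minimum-E
candidate is emitted, its matched sites are lowercase-masked ("erased") in
both sequence sets so subsequent motifs rest on independent sites, and the
loop repeats until `max_motifs` (default 5) or the best E-value reaches 1.
Each emitted motif also carries the unerased E-value computed on pristine
sequences; for the first motif it equals the E-value exactly. Counting is
sequence-level (≥1 match), not site-level. When no background is supplied,
one seeded Altschul–Erikson dinucleotide shuffle of each positive sequence
is used — the standard choice, which preserves dinucleotide composition
exactly. Note that with a planted GGACT consensus every 4-mer substring
(GGAC, GACT) occurs in all positive sequences; which one ranks first is
decided by background counts, and either is an instance of the planted word.

## Gene-set enrichment

Terms are flat gene sets from GMT files (no ontology-DAG propagation). The
universe defaults to all genes carrying at least one annotation, the
standard convention; term sets are intersected with the universe before
testing. Per term, the one-sided Fisher's exact P is the hypergeometric
tail P(X ≥ k) with N universe genes, K in the term, n in the study set.
FDR adjustment is Benjamini–Hochberg (the field default where only "FDR" is
specified), applied within each namespace (BP/MF/CC/pathway). The rich
factor is k/K. Top-N report tables (default 15 for bars with −log10 P, 20
for bubbles with rich factor and gene count) are selected per namespace by
smallest P with ties broken lexicographically by term id.

## Synthetic data

The generator defines the study conditions and plants ground truth for every
module. Defaults: one 2 Mb chromosome; 170 mRNAs and 80 lncRNAs packed
non-overlapping on both strands, 2–4 exons of 250–700 bp with 150–500 bp
introns; mRNA UTRs at 15%/30% of spliced length (floors of 80/150 bp);
uniform ACGT genome. Input coverage is Poisson noise around flat
per-transcript expression (uniform 5–20 coverage units) over a background of
1; IP coverage multiplies the input rate by `peak_enrichment` (default 8,
matching a strong antibody pulldown) inside one planted peak per transcript,
100–200 bp wide (fragments are ~100 nt), clipped to its host exon so planted
intervals are always exonic. mRNA peak centers are drawn normally around the
CDS/3'UTR junction with SD `250 / stop_codon_bias` bp (default bias 5 → SD
50 bp), emulating the stop-codon hotspot; lncRNA peaks are uniform over the
body. A planted fraction of peaks (default 20%) differs between groups by
`diff_fold` (default 4): the elevated group carries baseline × fold while
the other stays at baseline, alternating which group is elevated so both
call directions occur. Scaling the *elevated* side keeps the group-mean
E-score above the calling gate; scaling one group *down* from baseline would
make down-regulated peaks undetectable by construction under the standard
thresholds. The consensus word GGACT is written into the genome under every
peak center. Term maps contain 50 terms; one planted term of 20 genes
samples members with 10× weight on the genes hosting differential peaks
(fold 1 reduces it to an exchangeable null term). All randomness flows from
integer-seeded numpy Generators (no hash-order dependence), so identical
seeds give byte-identical FASTA/GTF/bedGraph/GMT output.

What the generator does not emulate: read-level sampling and alignment
artifacts, fragment-length and GC biases, overdispersed (negative-binomial)
counting noise, overlapping gene models, and expression differences between
conditions. Passing tests therefore demonstrate correctness of the
computations and recoverability of planted signal under idealized noise, not
performance on real libraries.

## Numerical and reporting choices

Fisher tails are computed by scipy's hypergeometric survival function and
cross-checked in the tests both against explicit integer-arithmetic
summation of the hypergeometric pmf and against `scipy.stats.fisher_exact`.
Tables are written with fixed column orders and 6-decimal floats so reruns
diff cleanly; the pipeline manifest records a sha256 checksum per output
file, and rerunning any stage on unchanged inputs reproduces identical
bytes. Degenerate inputs fail loudly: empty study sets or universes, groups
missing an IP or input sample, zero library sizes, malformed BED/GTF lines
(reported with line numbers), and non-finite scores all raise errors rather
than propagating NaNs. Ties are broken deterministically everywhere (peak
name, term id, lexicographic candidate pattern).

Problem sizes in the test suite and the reproduction script (250
transcripts, 2 Mb genome, 200+200 motif sequences, 50-term maps, 20-seed
replications) were chosen so the planted effects are comfortably above the
noise floor at the default folds while the full suite runs in well under a
minute of compute per scenario.
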