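# Methods

This note documents the models, conventions and numerical choices behind
pirnakit, and what the synthetic-data generator does and does not emulate.

## Coordinates, strands, formats

All in-memory coordinates are 0-based half-open; BED dialect on disk.
The 5' coordinate of an alignment is `start` on the plus strand and
`end − 1` on the minus strand. Sequences are DNA-space (a piRNA 5' U is a
T). FASTA I/O goes through Biopython; BED6, GFF3 (a deliberate two-feature
subset: `gene` and `three_prime_UTR`) and all TSV tables through pandas;
per-base tracks are run-length bedGraph.

## Read processing

**Trimming.** Library structure is `insert + N×4 + adapter`, the four
random nucleotides coming from the 5' end of the pre-adenylated DNA
linker. The trimmer locates the leftmost adapter occurrence (prefix match
of ≥ 8 nt with ≤ 1 mismatch), removes it together with the 4 preceding
random nucleotides, and length-filters the insert to 18–35 nt; reads with
no detectable adapter, or trimmed out of range, are dropped and tallied by
reason. The generator's raw mode produces exactly this structure so the
trimmer is testable end to end.

**Alignment.** The mapper reports, per read, *all* placements in the best
stratum — the minimum achievable mismatch count up to `max_mismatches`
(default 2) — on both strands of every reference searched; a read is
*unique* iff that stratum holds exactly one placement. Ties across strands
are both kept. N in a read mismatches every base. Indels are not modelled
(piRNA-scale reads on consensus/toy references). Exact placements come
from substring scans (k-mer-indexed for references ≥ 20 kb); inexact ones
from pigeonhole seeding (a placement with ≤ m mismatches contains one of
m+1 exact read segments), verified per candidate offset — complete, and
validated against a brute-force all-offsets oracle in the test suite. The
mismatch allowance for small-RNA reads is not dictated by the biology;
it is exposed as a parameter everywhere.

**Weighting.** Two disciplines, chosen per analysis: `fractional` spreads
a read's multiplicity 1/k over its k best-stratum placements and is the
default for consensus-level quantification; `unique_only` keeps only
unique placements at full multiplicity and is mandatory for insertion-level
attribution. Reads are therefore mapped twice — against the TE consensus
set, and against the genome — because pooling both into one search would
mark every TE-derived read a multi-mapper and void both analyses.

## Quantification

Levels are normalised to one million sequenced miRNAs (PPM); per-TE
summaries are thousand reads per kb per 1 M miRNAs, computed over
antisense reads of 23–32 nt by default (both bounds are flags). miRNA
reads are counted by strand-matched overlap with the annotated loci
(within 2 nt of the locus bounds). Density profiles support full-coverage
(default, figure-style) and 5'-end modes; antisense tracks are exported
with a negative sign.

The maternal-deposition index for TE *t* is
`(embryo_t / ovary_t) / median_r(embryo_r / ovary_r)` over the six
germline-exclusive reference TEs (Burdock, F-element, DOC, I-element,
mdg3, flea). The reference statistic is the *median* — robust to one noisy
reference TE; the aggregation choice (mean vs median) is not fixed by the
underlying method description, and the median is this package's choice.
At least three reference TEs must have nonzero levels in both tissues. An
index is missing when the TE has no ovarian piRNAs; ≈ 1 means deposition
typical of germline piRNAs, ≈ 0 a somatic-only source.

## Signature statistics

The 5'-overlap histogram counts sense/antisense 5'-end pairs at overlap
`d = q − p + 1` (plus 5' at p, minus 5' at q), d = 1..30. The phasing
histogram counts, per strand (minus-strand coordinates mirrored so
"downstream" follows transcription), the distance from each 3' end to the
*nearest* strictly downstream 5' end, d = 1..50, summed across strands.
Pair weights multiply per-position 5'-end multiplicities — positions, not
reads, are the unit; read-level weighting is available via the weighting
flag since the cited-style score definitions leave this open.

Both are scored as `Z = (c_focal − mean(bg)) / sd(bg)` with the sample
standard deviation over all non-focal bins (ping-pong focal d = 10,
background {1..9, 11..30}; phasing focal d = 1, background {2..50});
one-sided `P = 1 − Φ(Z)`; tiers ns / * / ** / *** at 0.05 / 0.01 / 0.001.
The result is reported missing ("NA", insufficient piRNAs) when the
background sd is zero or fewer than `min_pairs` (default 100) pairs
support the histogram. `pingpong_percent` is the percentage of read weight
whose 5' end has an opposite-strand partner at overlap exactly 10.

**Calibration caveat.** The nearest-downstream phasing distance is
density-sensitive: on saturated loci (≫ 0.1 5'-ends/nt) the nearest
neighbour is at d = 1 for almost every read and the Z is large regardless
of true phasing. Null calibration is therefore stated for sparse libraries
(~0.03 starts/nt, i.e. 10,000 reads on a ~300 kb locus or a single-pass
random-gap walk), where 100-seed runs keep |Z| < 3 in ≥ 99% of replicates
for both statistics. The positive calls in the insertion caller operate on
dense source loci, where sensitivity — not specificity — is the binding
constraint.

## Copy number

Genomic DNA reads are aligned (fractional weighting) to the TE consensus
set and to the genome; the estimate is
`median(per-base consensus coverage) / median(per-base coverage over
genome-unique regions)`. The consensus median includes zero-coverage
positions by default (toggleable): internally deleted or diverged copies
then lower the estimate proportionally instead of being ignored, which is
why a full-length plus an internally deleted copy score between 1 and 2.
Whether zero positions belonged in the original median is not stated in
the method descriptions this follows; inclusion is this package's default.
At 30× simulated coverage the estimator recovers 1, 5 and 20 planted
copies within ±15% per replicate.

## Insertion-level and TE-level classification

`call_insertion` uses **genome-unique reads of piRNA length (23–32 nt)
only** — the length filter excludes the abundant 22-nt miRNAs and 21-nt
siRNAs from strand-bias and level computations; multi-mappers are
discarded up front. Quantities: unique PPM inside the insertion and in
2-kb flanks ("downstream" follows the host gene's transcription, plus
strand for intergenic insertions), the strand bias, and phasing/ping-pong
Z over the insertion plus its downstream flank. `antisense_fraction` is
measured **relative to the inserted TE's genomic orientation** (reads
antisense to the TE are the silencing-competent species); the host-gene
annotation determines the insertion's own orientation label. At an
antisense 3'-UTR insertion the piRNAs are sense to the host gene and
antisense to the TE, so this convention makes the unistrand criterion
coherent.

Decision rules (all thresholds in one config block; they are package
policy, since the underlying biology is qualitative):
`unistrand_source` = antisense fraction ≥ 0.8 AND downstream unique
piRNAs present AND phasing tier ≥ *; `dualstrand_source` = ≥ 20% of read
weight on each strand; otherwise `silent`; everything below 20 read
counts is silent. The diagnostic handle for multi-copy TEs is exactly the
biology: deletion junctions and insertion-flank junctions are the only
genome-unique segments of a repeated element, and the synthetic strain
reproduces this (its source copy carries a 752-nt internal deletion; its
full-length second copy is called silent).

`classify_origin` per TE: *somatic* requires antisense-dominant (≥ 0.8),
phased (tier ≥ *), no ping-pong (ns/NA), and — when embryo data exist — a
deposition index < 0.2; *germline* requires significant ping-pong or a
deposition index in [0.5, 2]; both lines of evidence give *mixed*, neither
*undetermined*. Without embryo data the call is made from signatures alone
and flagged `no-embryo`.

## The synthetic-data generator

The generator is the package's study-conditions module, not a test
convenience. It emulates: i.i.d.-uniform ACGT background genomes (so
"genome-unique" is well defined at toy scale and repeats occur only where
planted); TE insertions spliced into cluster / 3'-UTR / intergenic
contexts with orientation resolved against the host gene and optional
internal deletions; phased unistrand piRNAs as a 5'→3' walk (next 5' is
1 nt past the previous 3' with probability `phasing_tightness`, else a
uniform [2, 30] gap — the gap law of imperfectly phased piRNAs is a
modelling choice, not an empirical distribution); ping-pong pairs with
exact 10-nt 5' overlap for `pingpong_pair_fraction` of pairs (else uniform
{1..9, 11..30}); a 5' U frequency forced exactly to `u1_bias` (default
0.75, typical of primary piRNAs; the substitution can cost one mismatch at
the 5' base, which the 2-mismatch mapper absorbs); exact-sequence miRNA
reads with Dirichlet abundances; 21-nt siRNAs from both strands; uniform
single-end DNA reads at a requested fold-coverage (single-end suffices for
a median-coverage estimator; read pairing would add nothing). Position-level
alignment-table builders mirror the walk/pair/null models without the
sequence round trip and are used for many-replicate statistic calibration.

Not modelled: sequencing errors, base-quality realism, PCR duplicates,
chimeric reads, nucleotide composition biases of real genomes, and
SNP-based assignment of piRNAs to individual insertions (only the
junction/unique-region logic is generalised). Passing tests therefore
demonstrate the correctness and calibration of the statistics and callers
under their stated assumptions — not robustness to alignment artefacts or
repeat structure of real genomes.

## Problem sizes and determinism

Default experiment sizes — 10,000-read signature libraries, 100-seed null
calibrations, 30× coverage on ~40–90 kb toy genomes, 20-replicate call
recovery — were chosen so each analysis answers its question with
comfortable statistical margin at desk scale. Every simulation consumes a
single integer seed; identical configuration (including seed) yields
byte-identical FASTQ and TSV output. Seeds for sub-simulations are derived
arithmetically from the master seed and kept below 2³¹.
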