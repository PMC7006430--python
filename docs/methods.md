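# Methods

This note documents the models, parameter choices and numerical conventions
behind `dsrnacensus`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Duplication detection

A putative intramolecular dsRNA stem is operationalized as an **inverted
duplicated sequence (IDS)**: a local alignment between a transcript region
and the reverse complement of another region of the same transcript. The
**tandem duplicated sequence (TDS)** — the same-strand analogue — is the
structural null: it reflects the same repeat-proliferation process but
cannot base-pair intramolecularly.

The scanner is a seed-and-extend local aligner:

* exact 11-mer seeds between the sequence and itself (off-diagonal only,
  which removes the trivial self-identity and same-strand mirror images at
  the source) and between the sequence and its reverse complement;
* gapped x-drop extension from each seed in both directions with
  match +1, mismatch −2, affine gaps (7 for a length-1 gap, +2 per extra
  base), x-drop 20;
* per-hit identity assigned by a global alignment of the two detected arm
  segments (Biopython `PairwiseAligner` with the same scoring), counting
  matching columns over all aligned columns including gap columns — the
  convention of the 12-column tabular alignment format;
* acceptance is decided purely by the post-filter: aligned length strictly
  > 40 bp and identity strictly > 70%. Engine internals (seed length,
  scoring, x-drop) affect only which maximal alignments are found, and the
  tabular-import path (`parse_tabular_hits`) allows any external aligner to
  drive the identical downstream census. Hits from opposite mirror
  orderings are collapsed on the unordered interval pair plus strand
  relation; canonical ordering puts the leftmost-starting (ties: shorter)
  interval first.

Opposite-strand hits with overlapping arms (palindromes) are retained; the
inter-arm gap is floored at zero for them, and the optional gap cap
(`max_gap`, e.g. 2000 bp) drops hits whose arms are further apart.

A maximal-scoring local alignment necessarily trims arm-terminal
mismatches (a trailing mismatch always lowers the score). Reported arm
windows can therefore be a few bases narrower than a planted repeat, and
the reported identity correspondingly a little higher than the whole-arm
identity. Tests that verify identity therefore compare the reported value
against the exact Hamming identity of the sequence over the reported
windows, which is the ground truth for the alignment actually claimed.

Sequences with more than 50% non-ACGT characters are rejected with a
diagnostic; N-containing seeds are skipped and N never matches in
extension.

## Census and binning

Per class and per transcript, both arm intervals of every accepted hit are
pooled, sorted, and merged; book-ended intervals merge, matching the
default behaviour of the standard interval-merge tools. Each covered
nucleotide is attributed to the **longest** hit covering it (ties: higher
identity, then leftmost hit start) and binned by that hit's aligned length
and identity. Region "length" for binning is thus the attributed hit's
alignment length, not the merged-region span: merged spans mix hits, and
the attribution rule exists precisely to resolve multi-hit nucleotides.
Default bins partition (40, ∞) bp into (40, 100], (100, 300], (300, ∞) and
(0, 100] percent into (0, 70], (70, 80], (80, 90], (90, 96], (96, 100], so
the top cells isolate the long (> 300 bp) and nearly perfect (> 96%)
structures. Hit counts per cell count each hit once in its own cell.

Structure selection keeps hits with length > 300 and identity > 96%
(strict), then removes footprint overlaps keeping the highest-identity
candidate (ties: longer, then leftmost). Repeat-annotation overlap reports
merged-footprint bases inside the annotation; a missing annotation is
reported as "not available" rather than a spurious zero.

Splicing concatenates exon intervals (0-based half-open, sorted,
non-overlapping) into the mature mRNA with an explicit bijective coordinate
map for exonic positions. Transcript loading discards pre-mRNAs longer
than 1 Mbp.

## Depletion statistic

With no selection, each observed duplication is IDS or TDS with probability
½, so the depletion p-value is the one-sided exact lower binomial tail
P(X ≤ n_IDS), X ~ Binomial(n_IDS + n_TDS, ½), evaluated as a log-space sum
of log-pmf terms (`gammaln` + `logsumexp`). This is exact for totals up to
10⁶; beyond that a normal approximation with continuity correction is used
(its relative error on log₁₀ p is below 1% at the crossover, which the
suite checks). The one-sided form is used because it reproduces the
published tail for the (4, 258) class to the printed precision; a
two-sided variant (doubled smaller tail, capped at 1) is available behind
``alternative="two-sided"``. p-values are displayed in scientific notation,
as "< 1e-100" below that bound, and `log10_p` is always carried exactly —
tails around 10⁻⁶⁵⁰⁰ arise at genome scale and must not underflow.

## Expression and editing

The input boundary is a per-adenosine pileup (contig, 0-based position,
reference base, A-count, G-count). Read alignment, duplicate removal,
hyper-edited-read recovery, end trimming and the random assignment of
reads ambiguous between two nearly identical arms are upstream concerns;
the upstream assignment of arm-ambiguous reads must use a seeded RNG for
the pipeline to be reproducible. Adenosines are taken on the annotated
transcript strand (minus-strand genes contribute their genomic T positions,
with T→C counted as A→G).

Definitions: arm coverage is the mean coverage over **all** adenosines of
the arm, zero-coverage adenosines averaged in as zeros (interpretive
choice; it makes coverage an unbiased per-base expression measure rather
than an expressed-sites-only one). The editing index is ΣG/Σ(A+G), i.e. the
coverage-weighted mean of per-site editing levels; it is undefined (NaN)
for arms with no covered adenosine. FPKM conversion uses
coverage = FPKM × mapped reads × effective length / 10⁹ with effective
length = read length − 2 × 5 bp trim (88.64 coverage per FPKM for the
1.343 × 10⁹-read, 76-bp reference pool). Average inosines per transcript
defaults to the per-arm mean of index × adenosine count; a pooled-index
variant is available (``inosine_mode="pooled"``), as the averaging
convention is genuinely ambiguous. Residual identity subtracts
100 × inosines / mean arm length from the genomic identity (floored at 0);
structures starting above 96% whose residual drops below 96% are flagged
unwound. The expression filter requires **both** arms strictly above the
FPKM cutoff (0.01 and 0.1 are the reference operating points); arm
expression is the arm's own coverage-derived FPKM, not the host gene's,
since intronic arms can sit far below their gene's expression.

## Synthetic transcriptomes

The generator emulates exactly the features the pipeline consumes:

* **Gene anatomy** — per gene, 2–6 exons of 150–400 bp alternating with
  introns of 200–1500 bp over uniform-random background sequence: a
  desk-scale caricature of vertebrate genes (real introns are longer; only
  the exon/intron partition matters downstream).
* **Repeat insertions** — pairs of copies of a repeat consensus (60–500 bp,
  bracketing the 300-bp long-structure boundary), each copy independently
  substituted per base with probability *d* (uniform over the three other
  bases, no indels), inserted at distinct interior points of exon or intron
  segments in inverted or tandem orientation (default 50/50). Two copies at
  divergence *d* match at (1−d)² + d²/3 per column, so *d* ≤ 0.08 spans
  arm identities from 100% down to ~85%. The substitution-only model keeps
  the true arm identity an exact Hamming identity, making identity
  recovery testable without alignment ambiguity.
* **Pileups** — per adenosine, coverage ~ Poisson(mean) and G-count ~
  Binomial(coverage, editing rate).

Every planted pair is recorded with final coordinates, orientation,
realized identity and compartment (both-arms-exonic iff both insertion
points lie in exons). One RNG substream per gene, derived from the run
seed and a CRC-32 of the gene id, makes outputs byte-identical for a fixed
seed and independent of generation order.

What passing synthetic tests does **not** show: behaviour on real repeat
families (indels, truncated copies, nested insertions), low-complexity
sequence (no masking is applied), G:U wobble pairing or folding energetics
(sequence identity is the only pairing proxy, as in the underlying
method), or inter-molecular duplexes (out of scope by design).

## Test and verification scale

The suite verifies: planted-duplex recovery on 200 duplexes across four
divergence levels (identities ~85–100%, lengths 60–500 bp) with zero false
hits on 20 repeat-free control genes; null symmetry of IDS/TDS counts over
100 seeded replicates of 40 single-insertion genes (pooled fraction within
3 binomial SD of ½, false rejections at α = 0.01 in at most 1 replicate);
agreement with an exhaustive DP local-alignment oracle on 50 two-kilobase
sequences; editing-index recovery over a coverage {1, 10, 100} × rate
{0, 0.01, 0.1} grid (calibrated checks at coverage ≥ 10, where the
binomial error model is meaningful); and the splice contract that
intronic-arm duplexes appear only in the pre-mRNA census while
both-arms-exonic duplexes appear in both with equal identity. These sizes
keep the whole suite to a few minutes on one CPU while leaving every
assertion statistically calibrated (3-SD bands against exact binomial or
Monte-Carlo error).

## Numerical and degenerate-input conventions

* Coordinates are 0-based half-open internally and in BED outputs; the
  tabular alignment dialect converts to/from 1-based inclusive with
  opposite strand encoded by descending subject coordinates.
* Strict inequalities at every published threshold (40 bp, 70%, 300 bp,
  96%, FPKM cutoffs); boundary values are excluded.
* Empty inputs: a zero-gene config yields empty outputs; empty hit lists
  yield all-zero census tables; a census cell with zero IDS and zero TDS is
  flagged "no data" and gets no p-value; both counts zero is an error for
  the proportion test.
* Bins must exactly partition (40, ∞) and (0, 100]; violations raise.
* Pipeline runs write a manifest (inputs, parameter hash, seed, SHA-256 of
  every output); stage failures abort with a stage tag and remove the
  failed stage's partial outputs; every text output declares its
  coordinate convention in a header comment.
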