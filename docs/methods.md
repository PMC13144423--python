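# Methods

## The windowed richness score

For position *k* the score examines the 7-bp window *k*−3..*k*+3 and computes
`max(t + Σ xᵢ(xᵢ−1)/2 − g, 0)` with *t* the matching-base count, *xᵢ* the
run lengths of consecutive matches and *g* the longest non-match run. The
run bonus is implemented in closed form (a run of length 1 contributes 0).
The statistic is deliberately asymmetric: isolated matches are nearly
neutral, uninterrupted runs are rewarded quadratically, and a long opposite
run cancels scattered matches. Two conventions are fixed here and exposed as
configuration:

- **N handling.** N (and any IUPAC ambiguity code, which I/O maps to N with
  a warning) is always non-matching and contributes to *g*. This is the
  conservative choice: ambiguous sequence can only lower a score, never
  fabricate richness.
- **Chromosome edges.** Positions within half-width of either end are not
  scored rather than scored on truncated windows, because truncation would
  change the score's range (0–28 for 7 bp); downstream consumers see NaN at
  these positions and exclude them from means (zero is a meaningful score
  and must not be conflated with "unscored").

The generalisation to arbitrary match sets and half-widths exists, but the
defaults (match {T} or {A,T}, half-width 3) reproduce the published
statistic exactly.

Two independent code paths compute the score: `score_window` enumerates runs
directly (the reference), while `score_strand` runs a vectorised
column-sweep over a sliding-window view. The test suite proves them equal on
all 16384 7-mers and on random genomes. The reverse-strand track uses the
identity score(revcomp(w)) = score of the forward window under the
complemented match set, which follows from the reversal invariance of
(t, run multiset, g); the same identity gives the tested duality
T-score(reverse) ≡ A-score(forward).

## Termination regions and 3'-end classification

Bound-transcript (RIP-seq-style) 3' ends approximate termination sites; the
region from 50 bp upstream to 200 bp downstream of each TES — both endpoints
inclusive, hence 251 bp — is a termination region, mirrored in genome
coordinates for minus-strand transcripts and clipped at chromosome bounds
with a warning. A nascent (NET-seq-style) transcript is **terminal** when
its TES falls inside a same-strand region (boundaries included), else
**body** when its interval is wholly inside a same-strand bound transcript,
else **unassigned**. Terminal takes precedence over body; when several
regions contain a TES the first in genome order is recorded, which affects
the reported match but never the label. Same-strand matching is required
throughout because the template/non-template logic is strand-specific.
Transcript filters use strict inequalities (TPM > threshold, length <
threshold) with defaults TPM > 5 / < 5000 bp for nascent and TPM > 1 /
< 5000 bp for bound cohorts.

The published remainder category (transcripts with 3'-end read signal but
insufficient assembly support) depends on read-level evidence this package
does not model; those transcripts land in "unassigned".

## Homopolymer track statistics

"Non-overlapping consecutive nucleotides" is counted greedily: disjoint
left-to-right ℓ-mer occurrences, equal to Σ floor(run_length/ℓ) over maximal
runs (proved equal to a literal greedy scan by exhaustive enumeration in the
tests). An alternative mode counting maximal runs of exactly ℓ is available
behind a flag, since collapsed counting folds a 16-mer into two 8-mers.
Frequencies are motif count / number of windows over equal-width,
strand-aware windows (minus-strand windows are reverse-complemented so all
sequences are in non-template orientation). TES windows are width 40
centred on the TES (transcription-direction offsets −20..+19); body windows
are sampled uniformly among starts that keep the window inside the
transcript with its centre at least width/2 from the TES — when no start
satisfies the distance rule (transcript barely longer than the window) the
rule is waived so such transcripts still contribute one window. One body
window per transcript is the default. Poly-tract anchors for metagene
profiling record maximal runs ≥ 3 and anchor on the start of the longest run
≥ 6, ties to the leftmost.

## Metagene profiling and the flank test

Anchor matrices carry one row per anchor over −L..+R; minus-strand rows are
reversed so columns always follow transcription direction. Profiles are
means over consecutive 5-column bins (NaN excluded). The flank test
compares, per anchor, the mean over [−flank, −1] against [+1, +flank] — the
anchor base itself is excluded from both sides so "upstream of the TES" and
"downstream of the TES" are unambiguous and no base is double-counted — and
applies a two-sided Welch (unequal-variance) two-sample *t* test to the two
per-anchor vectors. Per-anchor means, not pooled per-base values, are the
default unit so each transcript contributes equally regardless of coverage;
pooling is available behind a flag. Anchors with incomplete flanks are
dropped. The maximum-signal summary reports, per transcript, the position of
the per-base signal maximum normalised so the TES maps to 1.0; ties resolve
to the most-3' position, a deliberate bias *against* 3'-end enrichment
claims for 5'-heavy signal but one that maps uniform signal to 1.0 — the
all-zero case is skipped and counted instead.

## The synthetic generator

`SyntheticConfig` defaults define the study conditions used throughout the
tests: 4 chromosomes × 260 kb of i.i.d. background at GC 0.36 (a plant-like
composition), 500 transcripts of 300–1500 bp packed left-to-right with
≥ 300 bp gaps and alternating strands (so same-strand transcripts never
overlap and every TES has clean flanks), 80% of transcripts planted with a
poly-T tract of 6–12 nt on the non-template strand starting 0–10 nt
downstream of the TES (acceptance-style recovery checks pin the length to
8), and a single-base 3'-end signal with per-base counts ~
Poisson(30 · 0.8^d + 0.1) where d is the distance from the TES toward the 5'
end — two parameters suffice to reproduce a sharp TES-proximal peak over low
body noise. Planted tract boundaries are clamped to a non-matching base so
the recorded length is the exact maximal run length, making the truth table
re-extractable. The chromosome size is chosen so that even worst-case
transcript lengths always pack, keeping generation total (no rejection
loops) and byte-deterministic under a single seed.

What the generator does *not* emulate: dinucleotide or isochore structure,
transcript overlap across strands at the same locus, read-level artifacts
(PCR duplication, mappability), or abundance-dependent signal. Passing
recovery tests therefore show the pipeline detects the planted compositional
signature under a clean i.i.d. null — they do not certify performance on
real genomes, where background run statistics are heavier-tailed.

## Numerical and degenerate-input choices

Scores are small non-negative integers; all comparisons are exact. bedGraph
output merges adjacent equal values into maximal intervals and skips NaN
(uncovered) positions; a round-trip back to per-base values is exact and
tested. The Welch test returns t = 0, p = 1 for the fully degenerate case of
identical per-anchor vectors rather than NaN. Empty anchor sets, windows
off chromosome ends, transcripts shorter than a window, and infeasible
synthetic packing all raise or warn explicitly rather than silently
degrading.

## Problem sizes

The shipped tests run the full pipeline at 500 transcripts on ~1 Mb genomes
and the null comparison over 20 seeds; these sizes give the recovery
contrasts orders of magnitude beyond their thresholds (e.g. downstream vs
upstream flank p ≈ 1e-140 against a p < 0.01 criterion) while keeping the
whole suite fast enough to run on every commit.

## Known limitations

GTF support is transcript-granular (exons ignored); bigWig is not written
(bedGraph only); scores at truncated chromosome-edge windows are absent by
design, so very short contigs (< 7 bp) cannot be scored at all; the
classification reproduces labels, not the published cohort counts, which
depend on accession-restricted sequencing data.
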