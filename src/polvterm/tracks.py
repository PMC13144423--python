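"""Homopolymer run detection, fixed-window tract frequencies and poly-tract anchors.

These statistics compare the sequence content of transcript-end windows with
gene-body background: a maximal run of a single base is recorded with its
start and length; within fixed-width windows the number of non-overlapping
l-mer homopolymer occurrences is counted greedily; and for metagene anchoring
the longest qualifying tract in a window is located.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import groupby
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import GenomeSequence, StrandedInterval, Transcript, reverse_complement

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunAnnotation:
    """A maximal homopolymer run: base, 0-based start in the examined sequence, length."""

    base: str
    start: int
    length: int


def find_runs(seq: str, min_length: int = 1) -> list[RunAnnotation]:
    """All maximal runs of A/C/G/T with length >= min_length, in start order.

    N never forms a run and breaks runs of other bases.
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    runs: list[RunAnnotation] = []
    pos = 0
    for base, grp in groupby(seq.upper()):
        n = sum(1 for _ in grp)
        if base != "N" and n >= min_length:
            runs.append(RunAnnotation(base=base, start=pos, length=n))
        pos += n
    return runs


def count_nonoverlapping(seq: str, base: str, length: int, mode: str = "greedy") -> int:
    """Count homopolymer motifs of ``base`` with length ``length`` in ``seq``.

    mode="greedy" (default): disjoint left-to-right l-mer occurrences, i.e.
    sum over maximal runs of floor(run_length / l). mode="exact": number of
    maximal runs of exactly length l.
    """
    if length < 2:
        raise ValueError("motif length must be >= 2")
    runs = [r for r in find_runs(seq, min_length=1) if r.base == base.upper()]
    if mode == "greedy":
        return sum(r.length // length for r in runs)
    if mode == "exact":
        return sum(1 for r in runs if r.length == length)
    raise ValueError(f"unknown mode {mode!r}")


def extract_window_sequences(
    genome: GenomeSequence, windows: Iterable[StrandedInterval]
) -> tuple[list[str], int]:
    """Strand-aware window sequences (reverse complemented for '-' windows).

    Windows overrunning chromosome ends are dropped; the dropped count is
    logged and returned.
    """
    seqs: list[str] = []
    dropped = 0
    for w in windows:
        if w.start < 0 or w.end > genome.lengths[w.chrom]:
            dropped += 1
            continue
        seq = genome.fetch(w.chrom, w.start, w.end)
        seqs.append(seq if w.strand == "+" else reverse_complement(seq))
    if dropped:
        logger.warning("dropped %d windows overrunning chromosome ends", dropped)
    return seqs, dropped


def window_track_frequencies(
    genome: GenomeSequence,
    windows: Sequence[StrandedInterval],
    lengths: Iterable[int] = range(2, 11),
    bases: str = "ACGT",
    mode: str = "greedy",
) -> pd.DataFrame:
    """Homopolymer motif frequencies across a set of equal-width windows.

    Returns a table with one row per (base, motif length): total motif count
    over all windows, the number of windows examined and the frequency
    count / n_windows.
    """
    windows = list(windows)
    if not windows:
        raise ValueError("empty window set")
    widths = {w.length for w in windows}
    if len(widths) != 1:
        raise ValueError(f"windows must share one width, got {sorted(widths)}")
    seqs, _ = extract_window_sequences(genome, windows)
    if not seqs:
        raise ValueError("all windows fell off chromosome ends")
    rows = []
    for base in bases:
        for ell in lengths:
            count = sum(count_nonoverlapping(s, base, ell, mode=mode) for s in seqs)
            rows.append(
                {
                    "base": base,
                    "length": ell,
                    "count": count,
                    "n_windows": len(seqs),
                    "frequency": count / len(seqs),
                }
            )
    return pd.DataFrame(rows)


def tes_windows(transcripts: Iterable[Transcript], width: int = 40) -> list[StrandedInterval]:
    """Windows of ``width`` bases centred on each TES, in genome coordinates.

    For width 40 this is TES-20..TES+19 in transcription direction; strand is
    carried so extraction yields the transcript-sense (non-template) sequence.
    """
    half = width // 2
    out = []
    for tx in transcripts:
        if tx.strand == "+":
            start = tx.tes - half
        else:
            start = tx.tes - (width - half) + 1
        out.append(StrandedInterval(tx.chrom, start, start + width, tx.strand))
    return out


def sample_body_windows(
    transcripts: Iterable[Transcript],
    width: int = 40,
    n_per_transcript: int = 1,
    seed: int | np.random.Generator = 0,
) -> list[StrandedInterval]:
    """Uniformly sampled gene-body windows, avoiding the TES neighbourhood.

    Window starts (in transcription direction) are uniform over positions
    whose window lies fully inside the transcript with its centre at least
    width/2 from the TES; when no start satisfies the TES-distance rule (very
    short transcripts) every fully-inside start is allowed instead.
    Transcripts shorter than the window are skipped with a warning.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: list[StrandedInterval] = []
    skipped = 0
    for tx in transcripts:
        if tx.length < width:
            skipped += 1
            continue
        max_start = tx.length - width
        # keep the window centre >= width/2 away from the TES (at offset length-1)
        limit = tx.length - 1 - width
        valid_max = limit if limit >= 0 else max_start
        for _ in range(n_per_transcript):
            s = int(rng.integers(0, valid_max + 1))
            if tx.strand == "+":
                g = tx.start + s
            else:
                g = tx.end - s - width
            out.append(StrandedInterval(tx.chrom, g, g + width, tx.strand))
    if skipped:
        logger.warning("skipped %d transcripts shorter than the %d-bp window", skipped, width)
    return out


def locate_polytract_anchor(
    seq: str, base: str, report_min: int = 3, anchor_min: int = 6
) -> int | None:
    """Start of the longest homopolymer tract of ``base`` with length >= anchor_min.

    Runs of length >= report_min are recorded; among recorded runs of length
    >= anchor_min the longest wins, ties going to the leftmost. Returns None
    when no run qualifies.
    """
    runs = [r for r in find_runs(seq, min_length=report_min) if r.base == base.upper()]
    candidates = [r for r in runs if r.length >= anchor_min]
    if not candidates:
        return None
    best = max(candidates, key=lambda r: (r.length, -r.start))
    return best.start
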