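"""Windowed T-score / AT-score richness statistic, per strand, genome-wide.

For a genome position k the score looks at the 7-bp window k-3..k+3 and
rewards matching bases (T for the T-score, A or T for the AT-score) with a
run-length bonus while penalising the longest run of non-matching bases:

    score(window) = max( t + sum_i x_i*(x_i - 1)/2 - g , 0 )

where t is the number of matching bases in the window, x_i are the lengths of
the runs of consecutive matching bases, and g is the length of the longest
run of consecutive non-matching bases. N always counts as non-matching. The
reverse-strand score at position k is the score of the reverse complement of
the same window, reported in forward-genome coordinates; because every
component is reversal-invariant this equals scoring the forward sequence with
the complemented match set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import groupby
from typing import Iterator

import numpy as np

from .io import GenomeSequence, write_bedgraph

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

FORWARD = "forward"
REVERSE = "reverse"
_STRAND_ALIASES = {"+": FORWARD, "-": REVERSE, FORWARD: FORWARD, REVERSE: REVERSE}


@dataclass(frozen=True)
class ScoringConfig:
    """Which bases count as matches and the window half-width.

    Defaults give the published T-score (7-bp window, match base T);
    ``at_score()`` gives the AT variant.
    """

    match_set: frozenset[str] = frozenset("T")
    half_width: int = 3

    def __post_init__(self) -> None:
        object.__setattr__(self, "match_set", frozenset(self.match_set))
        if not self.match_set or not self.match_set < set("ACGT"):
            raise ValueError("match_set must be a nonempty proper subset of {A,C,G,T}")
        if self.half_width < 1:
            raise ValueError("half_width must be >= 1")

    @property
    def width(self) -> int:
        return 2 * self.half_width + 1

    @property
    def max_score(self) -> int:
        w = self.width
        return w + w * (w - 1) // 2

    def complemented(self) -> "ScoringConfig":
        return ScoringConfig(frozenset(_COMPLEMENT[b] for b in self.match_set), self.half_width)


def t_score_config(half_width: int = 3) -> ScoringConfig:
    return ScoringConfig(frozenset("T"), half_width)


def at_score_config(half_width: int = 3) -> ScoringConfig:
    return ScoringConfig(frozenset("AT"), half_width)


@dataclass(frozen=True)
class ScoreComponents:
    """Audit trail for one window: t, run lengths x_i, c = len(x_i), g."""

    t: int
    run_lengths: tuple[int, ...]
    g: int

    @property
    def c(self) -> int:
        return len(self.run_lengths)


def score_window(window: str, config: ScoringConfig = ScoringConfig()) -> tuple[int, ScoreComponents]:
    """Score one window by the direct run-decomposition formula.

    This is the reference path: it enumerates the runs explicitly and is used
    as the oracle against the vectorised genome scorer.
    """
    if len(window) != config.width:
        raise ValueError(f"window length {len(window)} != {config.width}")
    window = window.upper()
    if not set(window) <= set("ACGTN"):
        raise ValueError(f"window contains invalid characters: {window!r}")
    match = config.match_set
    run_lengths: list[int] = []
    g = 0
    t = 0
    for is_match, run in groupby(window, key=lambda b: b in match):
        n = sum(1 for _ in run)
        if is_match:
            run_lengths.append(n)
            t += n
        else:
            g = max(g, n)
    bonus = sum(x * (x - 1) // 2 for x in run_lengths)
    score = max(t + bonus - g, 0)
    return score, ScoreComponents(t=t, run_lengths=tuple(run_lengths), g=g)


@dataclass
class ScoreTrack:
    """Per-position scores for one chromosome and strand.

    ``values[i]`` is the score at forward-genome position ``offset + i``.
    Positions within half_width of either chromosome end are not scored and
    are absent from the track.
    """

    chrom: str
    strand: str
    offset: int
    values: np.ndarray = field(repr=False)

    @property
    def positions(self) -> np.ndarray:
        return np.arange(self.offset, self.offset + len(self.values))


def _window_scores(match_mask: np.ndarray, width: int) -> np.ndarray:
    """Vectorised score for every width-length window of a boolean match mask."""
    windows = np.lib.stride_tricks.sliding_window_view(match_mask, width)
    t = windows.sum(axis=1, dtype=np.int32)
    n_win = windows.shape[0]
    run = np.zeros(n_win, dtype=np.int32)
    bonus = np.zeros(n_win, dtype=np.int32)
    gap = np.zeros(n_win, dtype=np.int32)
    g = np.zeros(n_win, dtype=np.int32)
    for j in range(width):
        col = windows[:, j]
        run = np.where(col, run + 1, 0)
        bonus += np.maximum(run - 1, 0)  # run of length x contributes 0+1+..+(x-1)
        gap = np.where(col, 0, gap + 1)
        np.maximum(g, gap, out=g)
    return np.maximum(t + bonus - g, 0)


def score_strand(
    genome: GenomeSequence, chrom: str, strand: str, config: ScoringConfig = ScoringConfig()
) -> ScoreTrack:
    """Score every fully-covered window of one chromosome on one strand.

    The reverse-strand track scores the reverse complement of each window,
    which reduces to matching the complemented base set on the forward
    sequence.
    """
    strand = _STRAND_ALIASES[strand]
    seq = genome.sequences[chrom]
    if len(seq) < config.width:
        raise ValueError(f"chromosome {chrom!r} shorter than the {config.width}-bp window")
    effective = config if strand == FORWARD else config.complemented()
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    mask = np.zeros(arr.size, dtype=bool)
    for base in effective.match_set:
        mask |= arr == ord(base)
    values = _window_scores(mask, config.width)
    return ScoreTrack(chrom=chrom, strand=strand, offset=config.half_width, values=values)


class ScoreTrackSet:
    """Tracks for both strands of every chromosome, with NaN outside coverage."""

    def __init__(self, tracks: dict[tuple[str, str], ScoreTrack], lengths: dict[str, int]):
        self.tracks = tracks
        self.lengths = lengths

    def __iter__(self) -> Iterator[ScoreTrack]:
        return iter(self.tracks.values())

    def track(self, chrom: str, strand: str) -> ScoreTrack:
        return self.tracks[(chrom, _STRAND_ALIASES[strand])]

    def fetch(self, chrom: str, strand: str, start: int, end: int) -> np.ndarray:
        """Per-base scores for [start, end); unscored edge positions are NaN."""
        track = self.track(chrom, strand)
        n = self.lengths[chrom]
        if not (0 <= start <= end <= n):
            raise ValueError(f"{chrom}:{start}-{end} outside chromosome of length {n}")
        out = np.full(end - start, np.nan)
        lo = max(start, track.offset)
        hi = min(end, track.offset + len(track.values))
        if lo < hi:
            out[lo - start : hi - start] = track.values[lo - track.offset : hi - track.offset]
        return out

    def write_bedgraph(self, prefix: str) -> tuple[str, str]:
        """Write <prefix>.fwd.bedgraph and <prefix>.rev.bedgraph."""
        paths = []
        for strand, suffix in ((FORWARD, "fwd"), (REVERSE, "rev")):
            path = f"{prefix}.{suffix}.bedgraph"
            per_chrom = {
                chrom: (track.offset, track.values)
                for (chrom, s), track in self.tracks.items()
                if s == strand
            }
            write_bedgraph(per_chrom, path)
            paths.append(path)
        return tuple(paths)


def score_genome(genome: GenomeSequence, config: ScoringConfig = ScoringConfig()) -> ScoreTrackSet:
    """Score every chromosome on both strands."""
    tracks: dict[tuple[str, str], ScoreTrack] = {}
    for chrom in genome.chrom_names:
        for strand in (FORWARD, REVERSE):
            track = score_strand(genome, chrom, strand, config)
            tracks[(chrom, strand)] = track
            logger.info(
                "scored %s %s: %d positions, mean %.3f, max %d",
                chrom,
                strand,
                len(track.values),
                float(track.values.mean()) if len(track.values) else float("nan"),
                int(track.values.max()) if len(track.values) else 0,
            )
    return ScoreTrackSet(tracks, genome.lengths)
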