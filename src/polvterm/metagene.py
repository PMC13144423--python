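"""Strand-aware metagene profiling around anchors, with flank statistics.

Anchors (typically transcript end sites) carry a strand; rows for '-' strand
anchors are reversed so that column order always follows the transcription
direction (negative offsets = before termination). Any object exposing
``fetch(chrom, strand, start, end) -> per-base float array`` can serve as the
signal source; NaN marks positions without a defined value (e.g. score-track
chromosome edges) and is excluded from all means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Protocol, Sequence

import numpy as np
from scipy import stats

from .io import Transcript, write_bedgraph, read_bedgraph, expand_bedgraph

logger = logging.getLogger(__name__)

Anchor = tuple[str, int, str]  # chrom, 0-based position, strand


class TrackLike(Protocol):
    def fetch(self, chrom: str, strand: str, start: int, end: int) -> np.ndarray: ...


class SignalTrack:
    """Dense per-base, per-strand signal (e.g. nascent-RNA 3'-end counts)."""

    def __init__(self, lengths: dict[str, int]):
        self.lengths = dict(lengths)
        self.data: dict[tuple[str, str], np.ndarray] = {}

    def _array(self, chrom: str, strand: str) -> np.ndarray:
        key = (chrom, strand)
        if key not in self.data:
            self.data[key] = np.zeros(self.lengths[chrom], dtype=float)
        return self.data[key]

    def add(self, chrom: str, strand: str, start: int, values: np.ndarray) -> None:
        arr = self._array(chrom, strand)
        arr[start : start + len(values)] += values

    def fetch(self, chrom: str, strand: str, start: int, end: int) -> np.ndarray:
        n = self.lengths[chrom]
        if not (0 <= start <= end <= n):
            raise ValueError(f"{chrom}:{start}-{end} outside chromosome of length {n}")
        return self._array(chrom, strand)[start:end].astype(float)

    def write_bedgraph(self, prefix: str) -> tuple[str, str]:
        paths = []
        for strand, suffix in (("+", "fwd"), ("-", "rev")):
            path = f"{prefix}.{suffix}.bedgraph"
            per_chrom = {
                chrom: (0, self._array(chrom, strand)) for chrom in self.lengths
            }
            # zero runs are written too; drop them for compactness
            per_chrom = {
                c: (0, np.where(v == 0, np.nan, v)) for c, (_, v) in per_chrom.items()
            }
            write_bedgraph(per_chrom, path)
            paths.append(path)
        return tuple(paths)

    @classmethod
    def from_bedgraph(
        cls, fwd_path: str, rev_path: str, lengths: dict[str, int]
    ) -> "SignalTrack":
        track = cls(lengths)
        for path, strand in ((fwd_path, "+"), (rev_path, "-")):
            for chrom, entries in read_bedgraph(path).items():
                track.data[(chrom, strand)] = expand_bedgraph(entries, lengths[chrom])
        return track


def transcript_tes_anchors(transcripts: Iterable[Transcript]) -> list[Anchor]:
    return [(tx.chrom, tx.tes, tx.strand) for tx in transcripts]


def _anchor_track_strand(anchor_strand: str, track_strand: str) -> str:
    if track_strand == "sense":
        return anchor_strand
    if track_strand == "antisense":
        return "-" if anchor_strand == "+" else "+"
    if track_strand in ("+", "-"):
        return track_strand
    raise ValueError(f"track_strand must be sense/antisense/+/-, got {track_strand!r}")


def extract_matrix(
    track: TrackLike,
    anchors: Sequence[Anchor],
    left: int,
    right: int,
    track_strand: str = "sense",
    lengths: dict[str, int] | None = None,
) -> tuple[np.ndarray, list[int]]:
    """Per-anchor rows of track values from -left to +right around each anchor.

    Columns follow transcription direction (rows of '-' strand anchors are
    reversed). ``track_strand`` picks which strand of the track is read:
    "sense" (default; the anchor's own strand — the non-template strand for a
    TES anchor), "antisense", or a fixed "+"/"-". Anchors whose extended
    window leaves the chromosome are dropped with a warning; the indices of
    kept anchors are returned alongside the matrix.
    """
    if not anchors:
        raise ValueError("empty anchor list")
    lengths = lengths or getattr(track, "lengths", None)
    rows, kept = [], []
    dropped = 0
    for i, (chrom, pos, strand) in enumerate(anchors):
        lo = pos - left if strand == "+" else pos - right
        hi = pos + right + 1 if strand == "+" else pos + left + 1
        n = lengths[chrom] if lengths else None
        if lo < 0 or (n is not None and hi > n):
            dropped += 1
            continue
        values = track.fetch(chrom, _anchor_track_strand(strand, track_strand), lo, hi)
        rows.append(values if strand == "+" else values[::-1])
        kept.append(i)
    if dropped:
        logger.warning("dropped %d anchors with flanks outside chromosome bounds", dropped)
    if not rows:
        raise ValueError("no anchor had complete flanks")
    return np.vstack(rows), kept


@dataclass
class MetageneProfile:
    """Binned mean signal relative to the anchor, oriented by transcription."""

    rel_positions: np.ndarray  # bin centres, anchor = 0
    mean: np.ndarray
    n: np.ndarray  # anchors contributing at least one value per bin
    bin_width: int


def profile(matrix: np.ndarray, left: int, bin_width: int = 5) -> MetageneProfile:
    """Column means of an anchor matrix after binning into bin_width columns.

    NaN cells (undefined positions) are excluded from means; a trailing
    partial bin is kept and averaged over the columns it has.
    """
    if matrix.size == 0:
        raise ValueError("empty matrix")
    n_cols = matrix.shape[1]
    centres, means, ns = [], [], []
    for s in range(0, n_cols, bin_width):
        block = matrix[:, s : s + bin_width]
        with np.errstate(invalid="ignore"):
            means.append(np.nanmean(block))
        ns.append(int(np.any(~np.isnan(block), axis=1).sum()))
        centres.append(s - left + (block.shape[1] - 1) / 2)
    return MetageneProfile(
        rel_positions=np.array(centres),
        mean=np.array(means),
        n=np.array(ns),
        bin_width=bin_width,
    )


@dataclass
class FlankComparison:
    """Welch two-sample comparison of per-anchor flank means around the anchor."""

    upstream_values: np.ndarray
    downstream_values: np.ndarray
    t_statistic: float
    p_value: float
    n_anchors: int
    test: str = "Welch two-sample t, two-sided"


def flank_test(
    track: TrackLike,
    anchors: Sequence[Anchor],
    flank: int = 50,
    track_strand: str = "sense",
    units: str = "anchor_mean",
    lengths: dict[str, int] | None = None,
) -> FlankComparison:
    """Welch t test of upstream vs downstream flanks around each anchor.

    Each anchor contributes its mean over [-flank, -1] and over [+1, +flank]
    in transcription direction; the anchor base itself is excluded from both
    flanks. With units="pooled" the per-base values are pooled instead of
    averaged per anchor. Anchors with any undefined flank position are
    dropped; at least two usable anchors are required.
    """
    matrix, _ = extract_matrix(
        track, anchors, left=flank, right=flank, track_strand=track_strand, lengths=lengths
    )
    up = matrix[:, :flank]
    down = matrix[:, flank + 1 :]
    complete = ~np.isnan(up).any(axis=1) & ~np.isnan(down).any(axis=1)
    up, down = up[complete], down[complete]
    if up.shape[0] < 2:
        raise ValueError("fewer than 2 anchors with complete flanks")
    if units == "anchor_mean":
        a, b = up.mean(axis=1), down.mean(axis=1)
    elif units == "pooled":
        a, b = up.ravel(), down.ravel()
    else:
        raise ValueError(f"units must be 'anchor_mean' or 'pooled', got {units!r}")
    if np.array_equal(a, b):
        t_stat, p_val = 0.0, 1.0
    else:
        t_stat, p_val = stats.ttest_ind(a, b, equal_var=False)
    return FlankComparison(
        upstream_values=a,
        downstream_values=b,
        t_statistic=float(t_stat),
        p_value=float(p_val),
        n_anchors=int(up.shape[0]),
    )


def max_signal_positions(
    track: TrackLike,
    transcripts: Sequence[Transcript],
) -> np.ndarray:
    """Normalised position in (0, 1] of each transcript's signal maximum.

    Signal is read on the transcript's own strand; the position of the
    per-base maximum is expressed along the transcription direction and
    normalised so the TES maps to 1.0. Ties resolve to the most 3' position.
    Transcripts with all-zero signal are skipped (count logged).
    """
    out = []
    skipped = 0
    for tx in transcripts:
        values = track.fetch(tx.chrom, tx.strand, tx.start, tx.end)
        if tx.strand == "-":
            values = values[::-1]  # transcription direction
        if not np.any(values > 0):
            skipped += 1
            continue
        best = int(np.flatnonzero(values == np.nanmax(values))[-1])  # most 3'
        out.append((best + 1) / tx.length)
    if skipped:
        logger.info("skipped %d transcripts with all-zero signal", skipped)
    return np.array(out)
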