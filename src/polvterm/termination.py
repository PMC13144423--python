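"""Termination-region construction and 3'-end classification of transcripts.

The mapping strategy: 3' ends of polymerase-bound (RIP-seq-style) transcripts
approximate termination sites, so the window from 50 bp upstream to 200 bp
downstream of each such TES (in transcription direction) is declared a
termination region. Nascent-transcript (NET-seq-style) transcripts are then
classified by where their own precisely-mapped 3' end falls: inside a
same-strand termination region ("terminal"), wholly inside a same-strand
bound-transcript body ("body"), or neither ("unassigned").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io import GenomeSequence, StrandedInterval, Transcript

logger = logging.getLogger(__name__)

TERMINAL = "terminal"
BODY = "body"
UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class TranscriptFilter:
    """Abundance/length filter: keep tpm > min_tpm and length < max_length (strict)."""

    min_tpm: float
    max_length: int

    def __post_init__(self) -> None:
        if self.min_tpm < 0 or self.max_length <= 0:
            raise ValueError("filter thresholds must be positive")


NET_FILTER = TranscriptFilter(min_tpm=5.0, max_length=5000)
RIP_FILTER = TranscriptFilter(min_tpm=1.0, max_length=5000)


def filter_transcripts(
    transcripts: Iterable[Transcript], flt: TranscriptFilter
) -> list[Transcript]:
    """Retain transcripts with tpm strictly above and length strictly below the cutoffs."""
    kept = []
    for tx in transcripts:
        if tx.tpm is None:
            raise ValueError(f"transcript {tx.id!r} has no TPM; filtering requires it")
        if tx.tpm > flt.min_tpm and tx.length < flt.max_length:
            kept.append(tx)
    return kept


@dataclass(frozen=True)
class TerminationRegion:
    source_transcript_id: str
    interval: StrandedInterval


def make_termination_regions(
    rip_transcripts: Iterable[Transcript],
    upstream: int = 50,
    downstream: int = 200,
    genome: GenomeSequence | None = None,
) -> list[TerminationRegion]:
    """Region from ``upstream`` bp before to ``downstream`` bp after each TES.

    Both endpoints are inclusive relative to the TES base, so the default
    width is 251 bp. For '-' strand transcripts the window is mirrored in
    genome coordinates. Regions are clipped at chromosome bounds (position 0,
    or the chromosome length when a genome is supplied) with a warning.
    """
    regions: list[TerminationRegion] = []
    clipped = 0
    for tx in rip_transcripts:
        tes = tx.tes
        if tx.strand == "+":
            start, end = tes - upstream, tes + downstream + 1
        else:
            start, end = tes - downstream, tes + upstream + 1
        if start < 0:
            start, clipped = 0, clipped + 1
        if genome is not None:
            n = genome.lengths[tx.chrom]
            if end > n:
                end, clipped = n, clipped + 1
        regions.append(
            TerminationRegion(tx.id, StrandedInterval(tx.chrom, start, end, tx.strand))
        )
    if clipped:
        logger.warning("%d termination regions clipped at chromosome bounds", clipped)
    return regions


@dataclass
class TerminationClassification:
    """Per-transcript label (terminal/body/unassigned) plus matched ids."""

    labels: dict[str, str]
    matched: dict[str, str | None] = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        out = {TERMINAL: 0, BODY: 0, UNASSIGNED: 0}
        for label in self.labels.values():
            out[label] += 1
        return out


def classify_net_transcripts(
    net_transcripts: Sequence[Transcript],
    rip_transcripts: Sequence[Transcript],
    regions: Sequence[TerminationRegion],
) -> TerminationClassification:
    """Classify each nascent transcript by its 3'-end location.

    "terminal" (TES inside a same-strand termination region; boundary
    positions included) takes precedence over "body" (interval wholly
    contained in a same-strand bound-transcript body). When several regions
    contain a TES the first in genome order is recorded as the match.
    """
    by_key_regions: dict[tuple[str, str], list[TerminationRegion]] = {}
    for r in sorted(regions, key=lambda r: (r.interval.chrom, r.interval.start)):
        by_key_regions.setdefault((r.interval.chrom, r.interval.strand), []).append(r)
    by_key_rip: dict[tuple[str, str], list[Transcript]] = {}
    for tx in sorted(rip_transcripts, key=lambda t: (t.chrom, t.start)):
        by_key_rip.setdefault((tx.chrom, tx.strand), []).append(tx)

    labels: dict[str, str] = {}
    matched: dict[str, str | None] = {}
    for tx in net_transcripts:
        key = (tx.chrom, tx.strand)
        label, match = UNASSIGNED, None
        for region in by_key_regions.get(key, ()):  # genome order
            if region.interval.start <= tx.tes < region.interval.end:
                label, match = TERMINAL, region.source_transcript_id
                break
        if label == UNASSIGNED:
            for rip in by_key_rip.get(key, ()):
                if rip.start <= tx.start and tx.end <= rip.end:
                    label, match = BODY, rip.id
                    break
        labels[tx.id] = label
        matched[tx.id] = match
    result = TerminationClassification(labels=labels, matched=matched)
    logger.info("classification counts: %s", result.counts)
    return result
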