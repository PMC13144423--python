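"""Readers and writers for the plain-text genomics formats the pipeline touches.

All coordinates are 0-based half-open internally, matching BED/bedGraph on
disk. Human-facing log messages use 1-based inclusive coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeSequence:
    """Named chromosome sequences over the alphabet {A, C, G, T, N}.

    Sequences are stored uppercased; any IUPAC ambiguity code other than N is
    mapped to N at load time.
    """

    chrom_names: list[str]
    sequences: dict[str, str] = field(repr=False)

    def __post_init__(self) -> None:
        for name in self.chrom_names:
            bad = set(self.sequences[name]) - VALID_BASES
            if bad:
                raise ValueError(f"chromosome {name!r} contains invalid characters {sorted(bad)}")

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(self.sequences[c]) for c in self.chrom_names}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self.sequences:
            raise KeyError(f"unknown chromosome {chrom!r}")
        n = len(self.sequences[chrom])
        if not (0 <= start <= end <= n):
            raise ValueError(f"{chrom}:{start}-{end} outside chromosome of length {n}")
        return self.sequences[chrom][start:end]


def read_fasta(path: str | Path) -> GenomeSequence:
    """Load a FASTA file into memory, normalising case and ambiguity codes.

    Header text after the first whitespace is dropped. Duplicate identifiers
    are an error; non-ACGTN IUPAC codes are replaced by N with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    names: list[str] = []
    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seqs:
            raise ValueError(f"duplicate FASTA header {record.id!r}")
        seq = str(record.seq).upper()
        bad = set(seq) - VALID_BASES
        if bad:
            logger.warning(
                "chromosome %s: %d non-ACGTN IUPAC characters (%s) mapped to N",
                record.id,
                sum(seq.count(b) for b in bad),
                "".join(sorted(bad)),
            )
            seq = seq.translate(str.maketrans({b: "N" for b in bad}))
        names.append(record.id)
        seqs[record.id] = seq
    if not names:
        raise ValueError(f"{path}: no FASTA records found")
    return GenomeSequence(chrom_names=names, sequences=seqs)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(genome.sequences[c]), id=c, description="") for c in genome.chrom_names
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


@dataclass(frozen=True)
class StrandedInterval:
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Transcript:
    """A stranded transcript interval; the TES is the last transcribed base."""

    interval: StrandedInterval
    id: str
    tpm: float | None = None

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def length(self) -> int:
        return self.interval.length

    @property
    def tes(self) -> int:
        """0-based position of the 3'-most transcribed base."""
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


def read_bed6(
    path: str | Path,
    genome: GenomeSequence | None = None,
    score_is_tpm: bool = False,
) -> list[Transcript]:
    """Parse a 6-column BED file into transcripts.

    Column 5 is interpreted as TPM when ``score_is_tpm`` is set. Records with
    strand '.' are rejected: every analysis here is strand-specific.
    """
    path = Path(path)
    transcripts: list[Transcript] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 BED columns, got {len(fields)}")
            chrom, start_s, end_s, name, score_s, strand = fields[:6]
            start, end = int(start_s), int(end_s)
            if strand == ".":
                raise ValueError(f"{path}:{lineno}: unstranded record {name!r} not allowed")
            if genome is not None and chrom not in genome:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            interval = StrandedInterval(chrom, start, end, strand)
            if genome is not None and end > genome.lengths[chrom]:
                raise ValueError(f"{path}:{lineno}: interval exceeds chromosome {chrom!r}")
            tpm = float(score_s) if score_is_tpm else None
            transcripts.append(Transcript(interval=interval, id=name, tpm=tpm))
    return transcripts


def write_bed6(
    transcripts: Iterable[Transcript], path: str | Path, tpm_in_score: bool = False
) -> None:
    with open(path, "w") as fh:
        for tx in transcripts:
            score = f"{tx.tpm:g}" if (tpm_in_score and tx.tpm is not None) else "0"
            fh.write(f"{tx.chrom}\t{tx.start}\t{tx.end}\t{tx.id}\t{score}\t{tx.strand}\n")


def read_gtf_transcripts(path: str | Path, tpm_attribute: str = "TPM") -> list[Transcript]:
    """Minimal GTF reader: transcript-feature lines only, exons ignored.

    GTF coordinates are 1-based inclusive; they are converted to 0-based
    half-open. The ``transcript_id`` attribute is required; a TPM attribute is
    picked up when present.
    """
    transcripts: list[Transcript] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _, feature, start_s, end_s, _, strand, _, attrs = fields[:9]
            if feature != "transcript":
                continue
            attr_map: dict[str, str] = {}
            for item in attrs.rstrip(";").split(";"):
                item = item.strip()
                if not item:
                    continue
                key, _, value = item.partition(" ")
                attr_map[key] = value.strip().strip('"')
            if "transcript_id" not in attr_map:
                raise ValueError(f"{path}:{lineno}: transcript line lacks transcript_id")
            tpm = float(attr_map[tpm_attribute]) if tpm_attribute in attr_map else None
            interval = StrandedInterval(chrom, int(start_s) - 1, int(end_s), strand)
            transcripts.append(Transcript(interval=interval, id=attr_map["transcript_id"], tpm=tpm))
    return transcripts


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def write_bedgraph(
    per_chrom: Mapping[str, tuple[int, np.ndarray]], path: str | Path
) -> None:
    """Write per-base values as a run-length-merged bedGraph.

    ``per_chrom`` maps chromosome -> (offset, values); position ``offset + i``
    carries ``values[i]``. NaN values are treated as uncovered and skipped.
    Adjacent equal values are merged into maximal intervals.
    """
    with open(path, "w") as fh:
        for chrom, (offset, values) in per_chrom.items():
            values = np.asarray(values, dtype=float)
            if values.size == 0:
                continue
            covered = ~np.isnan(values)
            # breakpoints where value changes or coverage toggles
            change = np.empty(values.size, dtype=bool)
            change[0] = True
            same = (values[1:] == values[:-1]) & covered[1:] & covered[:-1]
            change[1:] = ~same
            starts = np.flatnonzero(change)
            ends = np.append(starts[1:], values.size)
            for s, e in zip(starts, ends):
                if not covered[s]:
                    continue
                v = values[s]
                text = f"{int(v)}" if float(v).is_integer() else f"{v:g}"
                fh.write(f"{chrom}\t{offset + s}\t{offset + e}\t{text}\n")


def read_bedgraph(path: str | Path) -> dict[str, list[tuple[int, int, float]]]:
    """Read a bedGraph into sorted, non-overlap-checked per-chromosome entries."""
    entries: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start_s, end_s, value_s = line.split("\t") if "\t" in line else line.split()
            start, end = int(start_s), int(end_s)
            if start >= end:
                raise ValueError(f"{path}:{lineno}: empty or inverted interval")
            entries.setdefault(chrom, []).append((start, end, float(value_s)))
    for chrom, items in entries.items():
        items.sort()
        for (s1, e1, _), (s2, _, _) in zip(items, items[1:]):
            if s2 < e1:
                raise ValueError(f"{path}: overlapping bedGraph intervals on {chrom}")
    return entries


def expand_bedgraph(
    entries: Sequence[tuple[int, int, float]], length: int, fill: float = 0.0
) -> np.ndarray:
    """Expand sorted bedGraph entries to a dense per-base array of ``length``."""
    values = np.full(length, fill, dtype=float)
    for start, end, value in entries:
        if end > length:
            raise ValueError("bedGraph interval exceeds stated chromosome length")
        values[start:end] = value
    return values
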