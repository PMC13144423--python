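"""Synthetic genomes, transcripts and nascent-transcript signal with ground truth.

The generator emulates the statistical structure the termination analysis
assumes: an i.i.d. background genome of controllable GC content, stranded
non-overlapping transcripts, an optional planted poly-T tract on the
non-template (transcript-sense) strand just downstream of each TES — i.e. an
A-rich template strand — and a single-base 3'-end signal whose Poisson mean
peaks at the TES and decays geometrically into the body. Every planted tract
is recorded in a truth table so each pipeline stage can be checked against
known structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    GenomeSequence,
    StrandedInterval,
    Transcript,
    write_fasta,
    write_bed6,
)
from .metagene import SignalTrack

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    Defaults model a compact plant-like setting: GC 0.36 background, 500
    transcripts of 0.3-1.5 kb packed into ~1 Mb of genome, 80% of them with a
    6-12 nt poly-T tract planted on the non-template strand 0-10 nt
    downstream of the TES, and a sharp TES-proximal Poisson signal
    (peak mean 30 decaying geometrically with q = 0.8, body noise 0.1).
    """

    seed: int = 0
    n_chromosomes: int = 4
    chromosome_length: int = 260_000
    gc_content: float = 0.36
    n_transcripts: int = 500
    transcript_length_range: tuple[int, int] = (300, 1500)
    planted_fraction: float = 0.8
    tract_length_range: tuple[int, int] = (6, 12)
    tract_offset_range: tuple[int, int] = (0, 10)
    signal_peak: float = 30.0
    signal_decay: float = 0.8
    body_noise_rate: float = 0.1
    min_gap: int = 300
    tpm_log_mean: float = 3.0
    tpm_log_sigma: float = 0.8

    def __post_init__(self) -> None:
        if not (0 < self.gc_content < 1):
            raise ValueError("gc_content must be in (0, 1)")
        if not (0 <= self.planted_fraction <= 1):
            raise ValueError("planted_fraction must be in [0, 1]")
        for lo, hi in (
            self.transcript_length_range,
            self.tract_length_range,
            self.tract_offset_range,
        ):
            if lo > hi or lo < 0:
                raise ValueError("ranges must satisfy 0 <= lo <= hi")
        if not (0 < self.signal_decay < 1):
            raise ValueError("signal_decay must be in (0, 1)")


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    genome: GenomeSequence
    transcripts: list[Transcript]
    truth: pd.DataFrame = field(repr=False)
    signal: SignalTrack = field(repr=False)


def _random_chromosome(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=probs)


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Build a dataset deterministically from the config seed.

    Transcripts are packed left-to-right per chromosome with random gaps of
    at least ``min_gap`` bases and alternating strands, so same-strand
    transcripts never overlap and every TES has clear flanks. Raises if the
    requested transcripts cannot be packed into the genome.
    """
    rng = np.random.default_rng(config.seed)
    chrom_arrays: dict[str, np.ndarray] = {}
    names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    for name in names:
        chrom_arrays[name] = _random_chromosome(rng, config.chromosome_length, config.gc_content)

    lo, hi = config.transcript_length_range
    placements: list[tuple[str, int, int, str]] = []
    chrom_iter = iter(names)
    chrom = next(chrom_iter)
    cursor = config.min_gap
    i = 0
    while i < config.n_transcripts:
        length = int(rng.integers(lo, hi + 1))
        if cursor + length + config.min_gap > config.chromosome_length:
            try:
                chrom = next(chrom_iter)
            except StopIteration:
                raise ValueError(
                    f"cannot pack {config.n_transcripts} transcripts into "
                    f"{config.n_chromosomes} x {config.chromosome_length} bp"
                ) from None
            cursor = config.min_gap
            continue
        strand = "+" if i % 2 == 0 else "-"
        placements.append((chrom, cursor, cursor + length, strand))
        cursor += length + int(rng.integers(config.min_gap, config.min_gap + 200))
        i += 1

    n_planted = int(round(config.planted_fraction * config.n_transcripts))
    planted_idx = set(
        rng.choice(config.n_transcripts, size=n_planted, replace=False).tolist()
    )
    tpms = rng.lognormal(config.tpm_log_mean, config.tpm_log_sigma, config.n_transcripts)

    transcripts: list[Transcript] = []
    truth_rows = []
    t_lo, t_hi = config.tract_length_range
    o_lo, o_hi = config.tract_offset_range
    for i, (chrom, start, end, strand) in enumerate(placements):
        tx = Transcript(
            interval=StrandedInterval(chrom, start, end, strand),
            id=f"tx{i + 1:04d}",
            tpm=float(tpms[i]),
        )
        transcripts.append(tx)
        row = {
            "transcript_id": tx.id,
            "chrom": chrom,
            "start": start,
            "end": end,
            "strand": strand,
            "tes": tx.tes,
            "tpm": tx.tpm,
            "planted": i in planted_idx,
            "tract_offset": pd.NA,
            "tract_length": pd.NA,
            "tract_start": pd.NA,
        }
        if i in planted_idx:
            tract_len = int(rng.integers(t_lo, t_hi + 1))
            offset = int(rng.integers(o_lo, o_hi + 1))
            arr = chrom_arrays[chrom]
            if strand == "+":
                # poly-T on the forward (non-template) strand downstream of TES
                a = tx.tes + 1 + offset
                arr[a : a + tract_len] = ord("T")
                if arr[a - 1] == ord("T"):
                    arr[a - 1] = ord("C")
                if arr[a + tract_len] == ord("T"):
                    arr[a + tract_len] = ord("C")
                tract_start = a
            else:
                # non-template strand is '-': poly-T there = poly-A on forward
                b = tx.tes - offset  # exclusive upper bound in forward coords
                a = b - tract_len
                arr[a:b] = ord("A")
                if arr[a - 1] == ord("A"):
                    arr[a - 1] = ord("G")
                if arr[b] == ord("A"):
                    arr[b] = ord("G")
                tract_start = a
            row.update(tract_offset=offset, tract_length=tract_len, tract_start=tract_start)
        truth_rows.append(row)

    genome = GenomeSequence(
        chrom_names=names,
        sequences={c: chrom_arrays[c].tobytes().decode("ascii") for c in names},
    )

    signal = SignalTrack(genome.lengths)
    for tx in transcripts:
        # distance from the TES, increasing toward the 5' end
        d = np.arange(tx.length)[::-1] if tx.strand == "+" else np.arange(tx.length)
        lam = config.signal_peak * config.signal_decay**d + config.body_noise_rate
        counts = rng.poisson(lam).astype(float)
        signal.add(tx.chrom, tx.strand, tx.start, counts)

    truth = pd.DataFrame(truth_rows)
    logger.info(
        "generated %d transcripts (%d planted) on %d chromosomes",
        len(transcripts),
        n_planted,
        config.n_chromosomes,
    )
    return SyntheticDataset(
        config=config, genome=genome, transcripts=transcripts, truth=truth, signal=signal
    )


def matched_rip_cohort(
    transcripts: Sequence[Transcript],
    seed: int = 0,
    delta_range: tuple[int, int] = (-40, 150),
) -> list[Transcript]:
    """Bound-transcript annotations whose termination regions contain each TES.

    Each output transcript shares its partner's start but has its TES shifted
    by -delta along the transcription direction, with delta drawn inside the
    termination-region window (default well within [-50, +200]), so
    classification against this cohort must label every partner "terminal".
    """
    rng = np.random.default_rng(seed)
    out = []
    d_lo, d_hi = delta_range
    for tx in transcripts:
        delta = int(rng.integers(d_lo, d_hi + 1))
        delta = min(delta, tx.length - 60)  # keep the shifted transcript non-empty
        if tx.strand == "+":
            interval = StrandedInterval(tx.chrom, tx.start, tx.tes - delta + 1, "+")
        else:
            interval = StrandedInterval(tx.chrom, tx.tes + delta, tx.end, "-")
        out.append(Transcript(interval=interval, id=f"rip_{tx.id}", tpm=tx.tpm))
    return out


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write genome.fa, transcripts.bed, signal bedGraphs and truth.tsv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": out_dir / "genome.fa",
        "transcripts": out_dir / "transcripts.bed",
        "truth": out_dir / "truth.tsv",
    }
    write_fasta(dataset.genome, paths["genome"])
    write_bed6(dataset.transcripts, paths["transcripts"], tpm_in_score=True)
    fwd, rev = dataset.signal.write_bedgraph(str(out_dir / "signal"))
    paths["signal_fwd"], paths["signal_rev"] = Path(fwd), Path(rev)
    dataset.truth.to_csv(paths["truth"], sep="\t", index=False)
    with open(out_dir / "config.json", "w") as fh:
        import json

        json.dump(asdict(dataset.config), fh, indent=1)
    paths["config"] = out_dir / "config.json"
    return paths
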