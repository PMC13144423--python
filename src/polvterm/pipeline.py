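"""End-to-end pipeline: filter -> termination regions -> classification ->
genome scoring -> TES metagene + flank test -> homopolymer track frequencies.

Results are written as TSV/JSON plus score bedGraphs, with a manifest
recording the package version, the full parameter set, the seed and
per-stage record counts; on failure the manifest still records the failing
stage. All randomness (body-window sampling) flows from the single seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import read_fasta, read_bed6
from .scoring import t_score_config, score_genome
from .termination import (
    TranscriptFilter,
    NET_FILTER,
    RIP_FILTER,
    filter_transcripts,
    make_termination_regions,
    classify_net_transcripts,
    TERMINAL,
)
from .metagene import transcript_tes_anchors, extract_matrix, profile, flank_test
from .tracks import tes_windows, sample_body_windows, window_track_frequencies

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    genome_fasta: str
    net_bed: str
    rip_bed: str
    out_dir: str
    seed: int = 0
    half_width: int = 3
    upstream: int = 50
    downstream: int = 200
    track_window: int = 40
    flank: int = 50
    metagene_left: int = 200
    metagene_right: int = 200
    bin_width: int = 5
    net_filter: TranscriptFilter = field(default_factory=lambda: NET_FILTER)
    rip_filter: TranscriptFilter = field(default_factory=lambda: RIP_FILTER)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the run directory. Writes manifest.json
    even on failure, with the failing stage named."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": asdict(config),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": {},
        "status": "running",
    }
    stage = "load"
    try:
        t0 = time.time()
        genome = read_fasta(config.genome_fasta)
        net = read_bed6(config.net_bed, genome=genome, score_is_tpm=True)
        rip = read_bed6(config.rip_bed, genome=genome, score_is_tpm=True)
        manifest["stages"][stage] = {
            "n_chromosomes": len(genome.chrom_names),
            "n_net": len(net),
            "n_rip": len(rip),
            "seconds": round(time.time() - t0, 3),
        }

        stage = "filter"
        t0 = time.time()
        net_kept = filter_transcripts(net, config.net_filter)
        rip_kept = filter_transcripts(rip, config.rip_filter)
        manifest["stages"][stage] = {
            "n_net_kept": len(net_kept),
            "n_rip_kept": len(rip_kept),
            "seconds": round(time.time() - t0, 3),
        }

        stage = "classification"
        t0 = time.time()
        if not net_kept:
            raise ValueError("no nascent transcripts survive filtering")
        regions = make_termination_regions(
            rip_kept, upstream=config.upstream, downstream=config.downstream, genome=genome
        )
        classification = classify_net_transcripts(net_kept, rip_kept, regions)
        labels_df = pd.DataFrame(
            {
                "transcript_id": list(classification.labels),
                "label": list(classification.labels.values()),
                "matched_rip_id": [classification.matched[i] for i in classification.labels],
            }
        )
        labels_df.to_csv(out / "labels.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {
            **classification.counts,
            "seconds": round(time.time() - t0, 3),
        }

        stage = "scoring"
        t0 = time.time()
        tracks = score_genome(genome, t_score_config(config.half_width))
        tracks.write_bedgraph(str(out / "tscore"))
        manifest["stages"][stage] = {
            "n_tracks": len(tracks.tracks),
            "seconds": round(time.time() - t0, 3),
        }

        stage = "metagene"
        t0 = time.time()
        terminal = [tx for tx in net_kept if classification.labels[tx.id] == TERMINAL]
        cohort = terminal if len(terminal) >= 2 else net_kept
        anchors = transcript_tes_anchors(cohort)
        matrix, _ = extract_matrix(
            tracks, anchors, config.metagene_left, config.metagene_right, track_strand="sense"
        )
        prof = profile(matrix, left=config.metagene_left, bin_width=config.bin_width)
        pd.DataFrame(
            {"rel_position": prof.rel_positions, "mean": prof.mean, "n": prof.n}
        ).to_csv(out / "tes_metagene.tsv", sep="\t", index=False)
        comparison = flank_test(tracks, anchors, flank=config.flank, track_strand="sense")
        with open(out / "flank_test.json", "w") as fh:
            json.dump(
                {
                    "test": comparison.test,
                    "t_statistic": comparison.t_statistic,
                    "p_value": comparison.p_value,
                    "n_anchors": comparison.n_anchors,
                    "upstream_mean": float(np.mean(comparison.upstream_values)),
                    "downstream_mean": float(np.mean(comparison.downstream_values)),
                },
                fh,
                indent=1,
            )
        manifest["stages"][stage] = {
            "n_anchors": comparison.n_anchors,
            "p_value": comparison.p_value,
            "seconds": round(time.time() - t0, 3),
        }

        stage = "track_frequencies"
        t0 = time.time()
        tes_freq = window_track_frequencies(
            genome, tes_windows(cohort, width=config.track_window)
        )
        body_freq = window_track_frequencies(
            genome,
            sample_body_windows(cohort, width=config.track_window, seed=config.seed),
        )
        tes_freq.assign(window_set="tes").to_csv(out / "freq_tes.tsv", sep="\t", index=False)
        body_freq.assign(window_set="body").to_csv(out / "freq_body.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {
            "n_tes_windows": int(tes_freq["n_windows"].iloc[0]),
            "n_body_windows": int(body_freq["n_windows"].iloc[0]),
            "seconds": round(time.time() - t0, 3),
        }

        manifest["status"] = "ok"
        return out
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        raise StageError(stage, exc) from exc
    finally:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
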