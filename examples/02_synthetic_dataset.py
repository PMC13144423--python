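"""Generate a synthetic genome with planted termination tracts.

Builds a small dataset (60 transcripts, 80% with a poly-T tract on the
non-template strand just downstream of the TES), writes it to disk, and
prints what was planted. The truth table is the ground truth every other
example checks against.
"""

from polvterm import SyntheticConfig, generate, write_dataset

config = SyntheticConfig(
    seed=7,
    n_chromosomes=2,
    chromosome_length=60_000,
    n_transcripts=60,
    transcript_length_range=(300, 800),
    tract_length_range=(8, 8),
)
dataset = generate(config)
paths = write_dataset(dataset, "scratch/example_dataset")

planted = dataset.truth[dataset.truth.planted]
print(f"genome: {len(dataset.genome.chrom_names)} chromosomes of {config.chromosome_length} bp")
print(f"transcripts: {len(dataset.transcripts)}, planted tracts: {len(planted)}")
print(planted[["transcript_id", "strand", "tes", "tract_offset", "tract_length"]].head().to_string(index=False))
print("files:", ", ".join(str(p) for p in paths.values()))
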