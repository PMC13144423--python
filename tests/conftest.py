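import numpy as np
import pytest

import polvterm as pv


@pytest.fixture(scope="session")
def planted_dataset() -> pv.SyntheticDataset:
    """Planted-tract study conditions: 500 transcripts, 80% with an 8-nt
    poly-T tract on the non-template strand just downstream of the TES."""
    config = pv.SyntheticConfig(seed=11, tract_length_range=(8, 8))
    return pv.generate(config)


@pytest.fixture(scope="session")
def planted_score_tracks(planted_dataset) -> pv.ScoreTrackSet:
    return pv.score_genome(planted_dataset.genome)


@pytest.fixture()
def toy_genome() -> pv.GenomeSequence:
    return pv.GenomeSequence(
        chrom_names=["c1", "c2"],
        sequences={"c1": "ACGTTTTTTTACGTACGTAC", "c2": "GGGGGGGGGG"},
    )


def random_genome(seed: int, length: int = 10_000, gc: float = 0.4) -> pv.GenomeSequence:
    rng = np.random.default_rng(seed)
    bases = rng.choice(list("ACGT"), size=length, p=[(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return pv.GenomeSequence(chrom_names=["chr1"], sequences={"chr1": "".join(bases)})
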