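from __future__ import annotations

import numpy as np
import pytest

from mitoforge.genome import CircularChromosome, GenomeConfiguration


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


def single_chrom_config(sequence: str, name: str = "cfg", chrom_id: str = "chr1",
                        **kwargs) -> GenomeConfiguration:
    return GenomeConfiguration(
        name=name, chromosomes=(CircularChromosome(chrom_id, sequence, **kwargs),)
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240501)
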