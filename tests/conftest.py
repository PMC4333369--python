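import numpy as np
import pytest

import bubblesnp as bs


@pytest.fixture(scope="session")
def toy_sets():
    """The classic two-sequence toy: one SNP (A/T) between two tiny genomes,
    each read four times in its own set (k=4 world)."""
    return [
        bs.ReadSet.from_sequences(["ACTGACCTG"] * 4, set_id=0),
        bs.ReadSet.from_sequences(["ACTGTCCTG"] * 4, set_id=1),
    ]


@pytest.fixture(scope="session")
def toy_graph(toy_sets):
    return bs.build_graph(bs.count_kmers(toy_sets, 4, per_set=True), 1)


def random_genome(length: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[b] for b in rng.integers(0, 4, size=length))


def plant_snp(genome: str, site: int, alt: str) -> str:
    assert genome[site] != alt
    return genome[:site] + alt + genome[site + 1 :]
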