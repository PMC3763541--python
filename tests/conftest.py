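import numpy as np
import pytest

from mist.reference import ExonTarget, GenomeRef

BASES = np.array(list("ACGT"))


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, n)])


@pytest.fixture
def rng():
    return np.random.default_rng(20130704)


@pytest.fixture
def small_genome(rng):
    return GenomeRef({"chr1": random_dna(rng, 2000), "chr2": random_dna(rng, 1500)})


def make_target(genome: GenomeRef, chrom="chr1", core=(500, 800), pad=70, tid="T"):
    start = max(0, core[0] - pad)
    end = min(len(genome.sequences[chrom]), core[1] + pad)
    return ExonTarget(
        target_id=tid,
        chrom=chrom,
        start=start,
        end=end,
        strand="+",
        core_start=core[0],
        core_end=core[1],
        extension=pad,
        sequence=genome.slice(chrom, start, end),
        source_ids=[tid],
    )
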