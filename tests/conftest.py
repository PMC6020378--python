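import numpy as np
import pytest

from guidenet.encoder import GUIDE_LEN, NUCLEOTIDES, GuideSequence


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


def random_guide_sequence(rng, chrom="chr1", start=0, strand="+",
                          cell_type="cellA") -> GuideSequence:
    bases = np.array(list(NUCLEOTIDES))
    seq = "".join(bases[rng.integers(0, 4, GUIDE_LEN)])
    seq = seq[:21] + "GG"
    return GuideSequence(seq, chrom, start, start + GUIDE_LEN, strand, cell_type)


@pytest.fixture(scope="session")
def small_genome():
    from guidenet.synth import gen_genome
    return gen_genome(3000, gc=0.5, seed=42)
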