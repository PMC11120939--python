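import numpy as np
import pytest

from aoskit import CodingSequence, surrogate_cds


@pytest.fixture(scope="session")
def arhgap31_cds() -> CodingSequence:
    """Synthetic surrogate CDS reproducing the published exon-12 variant
    consequences (1444-residue wild-type protein)."""
    return surrogate_cds()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240424)


@pytest.fixture
def toy_cds() -> CodingSequence:
    # M A Q stop
    return CodingSequence("toy", "ATGGCTCAGTAA")
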