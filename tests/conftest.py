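import numpy as np
import pytest

from pedqg.pedigree import Pedigree, PedigreeRecord


@pytest.fixture
def trio_pedigree() -> Pedigree:
    return Pedigree(
        [
            PedigreeRecord("mother", None, None, "F"),
            PedigreeRecord("father", None, None, "M"),
            PedigreeRecord("child", "mother", "father", "U"),
        ]
    )


@pytest.fixture
def sib_pedigree() -> Pedigree:
    """Two founder pairs, full sibs, half sibs, and a full-sib mating."""
    return Pedigree(
        [
            PedigreeRecord("d1", None, None, "F"),
            PedigreeRecord("s1", None, None, "M"),
            PedigreeRecord("d2", None, None, "F"),
            PedigreeRecord("s2", None, None, "M"),
            PedigreeRecord("fs_a", "d1", "s1", "F"),
            PedigreeRecord("fs_b", "d1", "s1", "M"),
            PedigreeRecord("hs_c", "d1", "s2", "U"),
            PedigreeRecord("inbred", "fs_a", "fs_b", "U"),
        ]
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
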