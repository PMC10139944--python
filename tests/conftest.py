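import numpy as np
import pytest

from modconserv.alignments import StrainAlignment, StrainTree


@pytest.fixture
def small_alignment() -> StrainAlignment:
    return StrainAlignment(
        orf_id="YTEST1",
        strain_ids=("S288C", "s1", "s2", "s3"),
        rows=("MKTAYS", "MKTAYS", "MRTAYS", "M-TAYS"),
        reference_strain="S288C",
    )


@pytest.fixture
def star_tree() -> StrainTree:
    return StrainTree.from_newick(
        "(S288C:0.5,s1:0.5,s2:0.5,s3:0.5);"
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_column(rng: np.random.Generator, size: int,
                  alphabet: str = "ACDEFGHIKLMNPQRSTVWY") -> list[str]:
    return list(rng.choice(list(alphabet), size=size))
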