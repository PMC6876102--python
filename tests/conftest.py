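import numpy as np
import pytest

from plexsig.model import ChromatinComplex, GenomicFragment


@pytest.fixture
def worked_example():
    """Three-fragment complex with gaps 500 and 4500 bp."""
    return ChromatinComplex.from_fragments(
        "OC8",
        [
            GenomicFragment("chr2L", 100, 500),
            GenomicFragment("chr2L", 1000, 1500),
            GenomicFragment("chr2L", 6000, 6500),
        ],
    )


def make_complex(cid, coords, chrom="chr2L", **kwargs):
    return ChromatinComplex.from_fragments(
        cid, [GenomicFragment(chrom, s, e) for s, e in coords], **kwargs
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
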