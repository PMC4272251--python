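import io

import numpy as np
import pytest

from mthet.calling import CallingThresholds
from mthet.refmodel import GenomeRegion, ReferenceModel, load_packaged_reference


@pytest.fixture(scope="session")
def rcrs() -> ReferenceModel:
    return load_packaged_reference()


@pytest.fixture
def thresholds() -> CallingThresholds:
    return CallingThresholds()


@pytest.fixture
def toy_reference() -> ReferenceModel:
    """100-base circular reference with one forward gene at 10-30."""
    rng = np.random.default_rng(7)
    seq = "".join(rng.choice(list("ACGT"), size=100))
    # gene 10-30: 21 bases, 7 codons, ATG + 6 non-stop codons
    seq = seq[:9] + "ATG" + "CTA CCC GGT ACT TTC CAA".replace(" ", "") + seq[30:]
    return ReferenceModel(
        name="toy",
        sequence=seq,
        genes=[
            GenomeRegion(10, 30, "G1", "protein-coding", "+"),
            GenomeRegion(90, 5, "CRtoy", "control", "+"),  # wraps the origin
        ],
        special_regions={"polyC": GenomeRegion(40, 49, "polyC")},
    )


def stream(text: str) -> io.StringIO:
    return io.StringIO(text)
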