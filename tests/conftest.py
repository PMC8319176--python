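import pytest

from salpipe.annotate import Peak, Spectrum, build_acyl_library

#: the wide CHNOPS search bounds used for head-group assignment
WIDE_BOUNDS = {
    "C": (0, 100),
    "H": (0, 100),
    "N": (0, 100),
    "O": (0, 100),
    "S": (0, 4),
    "P": (0, 1),
}


@pytest.fixture(scope="session")
def acyl_library():
    return build_acyl_library(range(10, 23), range(0, 4), (0, 1))


@pytest.fixture()
def sulfonate_spectrum():
    """MS3-style spectrum holding the four diagnostic sulfonate ions."""
    return Spectrum(
        level=3,
        peaks=tuple(Peak(mz) for mz in (79.9568, 80.9643, 63.9611, 64.9692)),
        precursor_mz=374.2364,
    )
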