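import numpy as np
import pytest

from physmap.fingerprint import Fingerprint

# Repeat unit that is clonable (contains a HindIII site) but invisible to
# the five fingerprinting enzymes: clones inside such a block have (near)
# zero bands and fail the quality filter.
LOWBAND_REPEAT_UNIT = "AAGCTT" + "AAT" * 40

# 510 bp of alternating AT: contains no recognition site of any
# fingerprinting enzyme nor HindIII, and is longer than the 500 bp band
# window, so it isolates the band content of flanking sequence.
NEUTRAL_SPACER = "AT" * 255


def make_fp(owner, bands):
    return Fingerprint(owner, np.sort(np.asarray(list(bands), dtype=np.int64)))


def positional_fp(owner, start_kb, length_kb, base=1500):
    """Abstract clone model: one band per kb of covered sequence, so the
    shared-band count of two clones equals their overlap in kb."""
    return make_fp(owner, range(base + start_kb, base + start_kb + length_kb))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
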