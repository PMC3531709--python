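import numpy as np
import pytest

from igclean import Read, human_heavy_config
from igclean.midtags import reverse_complement


@pytest.fixture
def config():
    """The standard human heavy-chain study configuration."""
    return human_heavy_config()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_read(rid, bases, qual=35):
    """A read with a flat quality profile."""
    return Read(rid, bases, [qual] * len(bases))


def assemble_read(config, fw_mid_idx, rv_mid_idx, fw_primer, rv_primer, gene,
                  adapter="TCACGA", flipped=False, qual=35):
    """Build an anatomically correct amplicon read from its parts.

    ``fw_primer``/``rv_primer`` must already be concrete (no degenerate
    codes).  ``flipped`` emits the reverse-complemented strand.
    """
    fw_mid = config.mids[fw_mid_idx - 1] if fw_mid_idx else ""
    rv_mid = config.mids[rv_mid_idx - 1] if rv_mid_idx else ""
    bases = (adapter + fw_mid + fw_primer + gene
             + reverse_complement(rv_primer) + reverse_complement(rv_mid) + adapter)
    if flipped:
        bases = reverse_complement(bases)
    return make_read("fixture", bases, qual)


def realize(primer, rng):
    """Resolve IUPAC degeneracies to concrete bases."""
    from igclean.primers import IUPAC_EXPANSION
    return "".join(
        sorted(IUPAC_EXPANSION[c] - {"N"})[int(rng.integers(len(IUPAC_EXPANSION[c] - {"N"})))]
        for c in primer)
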