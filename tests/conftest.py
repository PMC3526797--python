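import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from cracpipe.annotation import Feature
from cracpipe.genome import Genome


@pytest.fixture
def tiny_genome():
    """60 nt toy chromosome with a deterministic sequence."""
    g = Genome()
    g.add("chrT", "ACGTACGTAC" + "GGGGGGGGGG" + "TTCCGGAATT" + "CACACACACA"
                  "GTGTGTGTGT" + "AACCGGTTAA")
    return g


@pytest.fixture
def spliced_feature():
    """Single-intron plus-strand mRNA: exons [0,10) and [20,30)."""
    return Feature(
        id="G1", chrom="chrT", strand="+", exons=[(0, 10), (20, 30)], tx_class="mRNA"
    )


@pytest.fixture
def forged():
    """Small forged genome shared across tests (module-scope determinism)."""
    from cracpipe.simulate import ForgeSpec, forge_genome

    return forge_genome(ForgeSpec(), seed=7)
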