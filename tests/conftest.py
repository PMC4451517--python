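import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from lipidsite import synthetic as syn  # noqa: E402


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def toy_system():
    """Small protein/ligand/water topology plus base coordinates."""
    return syn.toy_complex()


@pytest.fixture
def toy_indices(toy_system):
    topo, _ = toy_system
    return {
        "donor": int(topo.select(resname="LYS", atom_name="N")[0]),
        "acceptor": int(topo.select(resname="PLM", atom_name="O1")[0]),
        "tail": int(topo.select(resname="PLM", atom_name="C16")[0]),
        "anchor": int(topo.select(resname="PLM", atom_name="C1")[0]),
    }
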