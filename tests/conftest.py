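import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose oracles.py

from netcascade import Network


@pytest.fixture
def triangle() -> Network:
    return Network.from_edges([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def path_abc() -> Network:
    return Network.from_edges([("A", "B"), ("B", "C")])


@pytest.fixture
def path_abcde() -> Network:
    return Network.from_edges([("A", "B"), ("B", "C"), ("C", "D"), ("D", "E")])


def k1n(n: int) -> Network:
    """Star with hub 'h' and leaves l01..l<n>."""
    return Network.from_edges(("h", f"l{i:02d}") for i in range(1, n + 1))


@pytest.fixture
def star4() -> Network:
    return k1n(4)
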