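import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from essmir.io import RnaSequence

BASES = "ACGU"


def random_residues(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_fasta(tmp_path):
    path = tmp_path / "tiny.fasta"
    path.write_text(">a first\nACGUACGU\n>b\nGGGGAAAACCCC\n>c\nacgtacgt\n")
    return path


@pytest.fixture
def seq_factory():
    def make(residues: str, sid: str = "s") -> RnaSequence:
        return RnaSequence(id=sid, residues=residues)

    return make
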