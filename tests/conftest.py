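import numpy as np
import pytest

from tepirna.records import SequenceRecord, TERecord
from tepirna.simulate import FamilySpec, simulate_te_library


@pytest.fixture(scope="session")
def tiny_library() -> list[TERecord]:
    """Three short consensus sequences, deterministic, total < 10 kb."""
    specs = [
        FamilySpec("TE_A", "LTR", "Ty3_gypsy", consensus_len=400, copy_number=0),
        FamilySpec("TE_B", "LINE", None, consensus_len=300, copy_number=0),
        FamilySpec("TE_C", "DNA", None, consensus_len=250, copy_number=0),
    ]
    return simulate_te_library(specs, seed=1234)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(99)


def make_read(rid: str, seq: str) -> SequenceRecord:
    return SequenceRecord(rid, seq)
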