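import numpy as np
import pytest

from keser import EmbeddingSet, EventTable, Vocabulary


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_events():
    return EventTable.from_records(
        [
            ("p1", "PheCode:714.1", 0),
            ("p1", "RXNORM:6851", 10),
            ("p1", "PheCode:714.1", 35),
            ("p2", "PheCode:714.1", 5),
            ("p2", "RXNORM:6851", 5),
            ("p2", "LAB:11039-5", 100),
            ("p3", "CCS:213", 2),
        ]
    )


@pytest.fixture
def toy_embeddings(rng):
    """12 codes of two types with generic (full-rank) random vectors."""
    codes = tuple(f"PheCode:{i:03d}" for i in range(8)) + tuple(
        f"RXNORM:{i}" for i in range(4)
    )
    V = rng.standard_normal((12, 6))
    return EmbeddingSet(Vocabulary(codes), V)


def events_file(tmp_path, text, name="events.tsv"):
    path = tmp_path / name
    path.write_text(text)
    return path
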