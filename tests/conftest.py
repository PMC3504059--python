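import pytest
from hypothesis import settings

from threeitem.matrix_io import CharacterMatrix, DataType

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_matrix(rows: dict[str, str], data_type: str) -> CharacterMatrix:
    """Build a matrix from {taxon: state-string} preserving insertion order."""
    return CharacterMatrix(
        tuple(rows),
        tuple(tuple(s) for s in rows.values()),
        DataType(data_type),
    )


@pytest.fixture
def binary_4x2() -> CharacterMatrix:
    return make_matrix({"A": "01", "B": "11", "C": "10", "D": "00"}, "binary")


@pytest.fixture
def umc_5taxa() -> CharacterMatrix:
    """The five-taxon worked column: states 0, 1, 1, 2, 2."""
    return make_matrix({"A": "0", "B": "1", "C": "1", "D": "2", "E": "2"}, "umc")
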