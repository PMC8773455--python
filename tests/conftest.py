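import numpy as np
import pytest

from mtlineage.haplotree import load_packaged_macro_table, load_packaged_tree
from mtlineage.io import load_reference
from mtlineage.popgen import AlignedMatrix


@pytest.fixture(scope="session")
def reference():
    return load_reference()


@pytest.fixture(scope="session")
def tree():
    return load_packaged_tree()


@pytest.fixture(scope="session")
def macro_table():
    return load_packaged_macro_table()


def make_matrix(rows: list[str], populations: list[str] | None = None) -> AlignedMatrix:
    """Build an AlignedMatrix directly from row strings (test helper)."""
    n = len(rows)
    L = len(rows[0])
    pops = populations or ["pop"] * n
    data = np.array([list(r) for r in rows], dtype="U1")
    return AlignedMatrix(
        [f"s{i}" for i in range(n)],
        pops,
        [(i + 1, 0) for i in range(L)],
        data,
    )


def random_matrix(rng, n, L, alphabet="ACGT", n_frac=0.0, populations=None):
    chars = list(alphabet)
    data = rng.choice(chars, size=(n, L))
    if n_frac:
        mask = rng.random((n, L)) < n_frac
        data[mask] = "N"
    rows = ["".join(r) for r in data]
    return make_matrix(rows, populations)
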