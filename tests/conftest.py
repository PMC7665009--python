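from __future__ import annotations

import random

import pytest

from ontochron import (
    CharacterMatrix,
    OTULabel,
    TimeFrame,
    load_fixture_table1,
    select_frame,
)
from ontochron.matrix_io import default_characters


@pytest.fixture(scope="session")
def table1() -> CharacterMatrix:
    return load_fixture_table1()


@pytest.fixture(scope="session")
def frame_25_50_75(table1):
    return select_frame(table1, TimeFrame((25, 50, 75)))


@pytest.fixture(scope="session")
def frame_5_10_50(table1):
    return select_frame(table1, TimeFrame((5, 10, 50)))


@pytest.fixture(scope="session")
def frame_5_10_20(table1):
    return select_frame(table1, TimeFrame((5, 10, 20)))


def make_matrix(rows, species_prefix="T") -> CharacterMatrix:
    """Build a matrix from raw state strings with synthetic OTU labels."""
    otus = tuple(
        OTULabel(f"{species_prefix}{i}", float(i)) for i in range(len(rows))
    )
    return CharacterMatrix(
        otus=otus,
        characters=default_characters(len(rows[0])),
        rows=tuple(rows),
    )


def random_rows(rng: random.Random, n: int, k: int, missing: float = 0.1,
                distinct: bool = True, allow_zero: bool = False):
    """Random state strings; by default pairwise distinct and never all-zero
    (so merged-row handling does not change the search space)."""
    rows: list[str] = []
    seen = set()
    guard = 0
    while len(rows) < n:
        guard += 1
        if guard > 10000:  # pragma: no cover - generator sanity
            raise RuntimeError("cannot draw enough distinct rows")
        row = "".join(
            "?" if rng.random() < missing else rng.choice("01") for _ in range(k)
        )
        if distinct and row in seen:
            continue
        if not allow_zero and set(row) <= {"0", "?"}:
            continue
        seen.add(row)
        rows.append(row)
    return rows
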