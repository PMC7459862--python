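from __future__ import annotations

import numpy as np
import pytest

from kmerprimer import SequenceRecord


def make_db(seqs: list[str], lineages: list[list[str]] | None = None):
    """Build a database of records with ids s1, s2, ..."""
    db = []
    for i, s in enumerate(seqs):
        lin = lineages[i] if lineages else None
        db.append(SequenceRecord(id=f"s{i + 1}", description="", seq=s, lineage=lin))
    return db


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def random_iupac(rng: np.random.Generator, length: int, max_degeneracy: int) -> str:
    """Random IUPAC string whose degeneracy stays within the cap."""
    letters = list("ACGT")
    twofold = list("RYSWKM")
    threefold = list("BDHV")
    out = []
    deg = 1
    for _ in range(length):
        roll = rng.random()
        if roll < 0.25 and deg * 2 <= max_degeneracy:
            c = twofold[rng.integers(0, len(twofold))]
            deg *= 2
        elif roll < 0.30 and deg * 3 <= max_degeneracy:
            c = threefold[rng.integers(0, len(threefold))]
            deg *= 3
        elif roll < 0.33 and deg * 4 <= max_degeneracy:
            c = "N"
            deg *= 4
        else:
            c = letters[rng.integers(0, 4)]
        out.append(c)
    return "".join(out)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
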