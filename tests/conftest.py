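"""Shared fixtures: tiny marker databases and deterministic RNG."""

from __future__ import annotations

import numpy as np
import pytest

from strainscope.ingest import Pileup
from strainscope.markerdb import Marker, MarkerDB


@pytest.fixture
def rng():
    return np.random.default_rng(20170401)


@pytest.fixture
def toy_db():
    """Three short markers for one species, one for another."""
    rng = np.random.default_rng(7)
    bases = np.frombuffer(b"ACGT", dtype="S1")

    def seq(n):
        return rng.choice(bases, size=n).tobytes().decode()

    return MarkerDB(
        [
            Marker("M1", "s__alpha", seq(300)),
            Marker("M2", "s__alpha", seq(400)),
            Marker("M3", "s__alpha", seq(350)),
            Marker("B1", "s__beta", seq(320)),
        ]
    )


def make_pileup(marker_id: str, columns: list[dict[str, int]], length: int | None = None) -> Pileup:
    """Build a pileup from per-position base->count dicts (rest zero)."""
    L = length if length is not None else len(columns)
    counts = np.zeros((4, L), dtype=np.int64)
    order = "ACGT"
    for pos, col in enumerate(columns):
        for base, k in col.items():
            counts[order.index(base), pos] = k
    return Pileup(marker_id=marker_id, counts=counts)


def sam_text(records: list[str], db: MarkerDB) -> str:
    """Minimal SAM with @SQ lines for every marker in the database."""
    header = ["@HD\tVN:1.6\tSO:unknown"]
    for m in db:
        header.append(f"@SQ\tSN:{m.marker_id}\tLN:{m.length}")
    return "\n".join(header + records) + "\n"
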