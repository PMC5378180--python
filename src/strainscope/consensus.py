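"""Dominant-strain consensus calling and per-sample quality control.

Each marker's consensus is the per-position majority base over the
quality-passing pileup; positions with no coverage (or an exact tie) are
called N, so ambiguity encodes both lack of signal and conflicting signal.
The QC cascade then (1) strips marker ends, whose coverage is depressed by
read-truncation at the boundaries, (2) discards markers whose ambiguous
fraction exceeds 20%, and (3) reports the species present in the sample
only when more than 80% of its database markers were reconstructed.

The cascade order here is call -> strip -> ambiguity filter -> species
gate: the ambiguous fraction is measured on the stripped sequence because
terminal positions are systematically low-coverage and would otherwise
dominate the N count.  ``filter_before_strip=True`` restores the
measure-then-strip order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .ingest import BASES, Pileup

__all__ = [
    "ConsensusMarker",
    "StrainProfile",
    "call_consensus",
    "strip_ends",
    "filter_markers",
    "species_gate",
    "qc_cascade",
]

_BASE_ARRAY = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class ConsensusMarker:
    """Majority-rule consensus of one marker in one sample."""

    marker_id: str
    species: str
    sequence: str
    mean_depth: float = float("nan")

    @property
    def ambiguous_fraction(self) -> float:
        if not self.sequence:
            return 1.0
        return self.sequence.count("N") / len(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class StrainProfile:
    """QC-passed consensus markers of one species in one sample."""

    sample_id: str
    species: str
    markers: dict[str, ConsensusMarker]
    markers_in_db: int
    source: str = "metagenome"  # or "reference"

    def __post_init__(self) -> None:
        if self.source not in ("metagenome", "reference"):
            raise ValueError(f"invalid source {self.source!r}")
        for cm in self.markers.values():
            if cm.species != self.species:
                raise ValueError(
                    f"marker {cm.marker_id!r} species {cm.species!r} != {self.species!r}"
                )

    @property
    def n_markers(self) -> int:
        return len(self.markers)


def call_consensus(pileup: Pileup, species: str, min_depth: int = 1) -> ConsensusMarker:
    """Majority-rule base call per position; N on ties or depth < min_depth."""
    counts = pileup.counts
    depth = counts.sum(axis=0)
    top = counts.max(axis=0)
    ties = (counts == top).sum(axis=0) > 1
    best = counts.argmax(axis=0)
    seq = _BASE_ARRAY[best].copy()
    seq[ties | (depth < max(min_depth, 1))] = b"N"
    return ConsensusMarker(
        marker_id=pileup.marker_id,
        species=species,
        sequence=seq.tobytes().decode(),
        mean_depth=float(depth.mean()) if depth.size else 0.0,
    )


def strip_ends(marker: ConsensusMarker, n: int = 50) -> ConsensusMarker:
    """Remove the first and last ``n`` bases of the consensus.

    A marker shorter than 2n becomes empty and is discarded downstream.
    """
    if n < 0:
        raise ValueError("strip length must be >= 0")
    if n == 0:
        return marker
    seq = marker.sequence[n:-n] if len(marker.sequence) > 2 * n else ""
    return replace(marker, sequence=seq)


def filter_markers(
    markers: list[ConsensusMarker], max_ambiguous_fraction: float = 0.20
) -> list[ConsensusMarker]:
    """Drop empty markers and those with ambiguous fraction strictly >threshold."""
    if not 0 <= max_ambiguous_fraction <= 1:
        raise ValueError("max_ambiguous_fraction must be in [0, 1]")
    return [
        m
        for m in markers
        if m.sequence and m.ambiguous_fraction <= max_ambiguous_fraction
    ]


def species_gate(
    profile: StrainProfile, min_marker_fraction: float = 0.80
) -> Optional[StrainProfile]:
    """Retain the profile only if reconstructed markers strictly exceed the
    given fraction of the species' database markers; else the species is
    reported absent (None) in this sample."""
    if profile.markers_in_db < 1:
        raise ValueError("markers_in_db must be >= 1")
    if profile.n_markers / profile.markers_in_db > min_marker_fraction:
        return profile
    return None


def qc_cascade(
    pileups: dict[str, Pileup],
    species: str,
    sample_id: str,
    markers_in_db: int,
    min_depth: int = 1,
    strip_length: int = 50,
    max_ambiguous_fraction: float = 0.20,
    min_marker_fraction: float = 0.80,
    filter_before_strip: bool = False,
) -> Optional[StrainProfile]:
    """Run call_consensus -> strip_ends -> filter_markers -> species_gate.

    Returns None when the species fails the gate (reported absent).
    """
    called = [call_consensus(p, species, min_depth) for p in pileups.values()]
    if filter_before_strip:
        called = filter_markers(called, max_ambiguous_fraction)
        called = [strip_ends(m, strip_length) for m in called]
        called = [m for m in called if m.sequence]
    else:
        called = [strip_ends(m, strip_length) for m in called]
        called = filter_markers(called, max_ambiguous_fraction)
    profile = StrainProfile(
        sample_id=sample_id,
        species=species,
        markers={m.marker_id: m for m in called},
        markers_in_db=markers_in_db,
    )
    return species_gate(profile, min_marker_fraction)
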