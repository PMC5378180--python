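"""Species-specific marker gene database.

A marker is a gene fragment that is unique to one species and conserved
within it, so that reads recruited by the marker can be attributed to the
species with high confidence.  The database maps each species to its set of
markers; strain reconstruction downstream operates marker by marker.

Markers can also be extracted from assembled reference genomes by local
alignment, so that isolate genomes can be placed in the same phylogenies as
metagenome-derived strains.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Marker",
    "MarkerDB",
    "load_marker_db",
    "write_marker_db",
    "extract_reference_markers",
    "clean_sequence",
]

_NON_ACGT = re.compile(r"[^ACGT]")


def clean_sequence(seq: str) -> str:
    """Uppercase a DNA string and collapse every non-ACGT code to N."""
    return _NON_ACGT.sub("N", str(seq).upper())


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class Marker:
    """One species-specific marker sequence."""

    marker_id: str
    species: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.marker_id:
            raise ValueError("marker_id must be non-empty")
        if not self.species:
            raise ValueError(f"marker {self.marker_id!r}: species must be non-empty")
        if not self.sequence:
            raise ValueError(f"marker {self.marker_id!r}: sequence must be non-empty")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(
                f"marker {self.marker_id!r}: invalid characters {sorted(bad)!r}; "
                "run clean_sequence() first"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


class MarkerDB:
    """Validated collection of markers indexed by species.

    Invariants enforced on construction: marker ids are unique, every
    species has at least one marker, and a marker belongs to exactly one
    species.
    """

    def __init__(self, markers: Iterable[Marker]):
        self._markers: dict[str, Marker] = {}
        self._species_index: dict[str, list[str]] = {}
        for m in markers:
            if m.marker_id in self._markers:
                raise ValueError(f"duplicate marker_id {m.marker_id!r}")
            self._markers[m.marker_id] = m
            self._species_index.setdefault(m.species, []).append(m.marker_id)
        if not self._markers:
            raise ValueError("marker database is empty")

    def __len__(self) -> int:
        return len(self._markers)

    def __contains__(self, marker_id: str) -> bool:
        return marker_id in self._markers

    def __getitem__(self, marker_id: str) -> Marker:
        return self._markers[marker_id]

    def __iter__(self):
        return iter(self._markers.values())

    @property
    def species(self) -> list[str]:
        return sorted(self._species_index)

    def markers_for(self, species: str) -> list[Marker]:
        if species not in self._species_index:
            raise KeyError(f"unknown species {species!r}")
        return [self._markers[mid] for mid in self._species_index[species]]

    def n_markers(self, species: str) -> int:
        return len(self.markers_for(species))


def load_marker_db(fasta_path: str | Path, mapping_path: str | Path) -> MarkerDB:
    """Load markers from a FASTA file plus a marker->species mapping TSV.

    The mapping file has two columns, ``marker_id<TAB>species``, with or
    without a header line.  Every FASTA record must appear in the mapping.
    """
    mapping: dict[str, str] = {}
    with open(mapping_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{mapping_path}:{lineno}: expected 2 tab-separated columns, got {len(parts)}"
                )
            mid, species = parts
            if mid == "marker_id" and species == "species":
                continue  # header
            if not species:
                raise ValueError(f"{mapping_path}:{lineno}: empty species for marker {mid!r}")
            if mid in mapping:
                raise ValueError(f"duplicate marker_id {mid!r} in mapping")
            mapping[mid] = species

    markers = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in mapping:
            raise ValueError(f"FASTA record {rec.id!r} has no species mapping row")
        markers.append(
            Marker(marker_id=rec.id, species=mapping[rec.id], sequence=clean_sequence(rec.seq))
        )
    return MarkerDB(markers)


def write_marker_db(db: MarkerDB, fasta_path: str | Path, mapping_path: str | Path) -> None:
    """Serialize a MarkerDB back to FASTA + mapping TSV (inverse of load)."""
    records = [
        SeqRecord(Seq(m.sequence), id=m.marker_id, description="") for m in db
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    with open(mapping_path, "w") as fh:
        fh.write("marker_id\tspecies\n")
        for m in db:
            fh.write(f"{m.marker_id}\t{m.species}\n")


# --- reference-genome marker extraction -------------------------------------

_SEED_K = 15


def _local_aligner() -> PairwiseAligner:
    mat = substitution_matrices.Array(alphabet="ACGTN", dims=2)
    for x in "ACGT":
        for y in "ACGT":
            mat[x, y] = 1.0 if x == y else -1.0
    for x in "ACGTN":
        mat["N", x] = 0.0
        mat[x, "N"] = 0.0
    aligner = PairwiseAligner()
    aligner.substitution_matrix = mat
    aligner.mode = "local"
    aligner.open_gap_score = -3.0
    aligner.extend_gap_score = -1.0
    return aligner


def _alignment_stats(alignment) -> tuple[int, int, int, int, int, int]:
    """Return (matches, mismatches, gap_columns, q_aligned, t_start, t_end)."""
    t_ranges, q_ranges = alignment.aligned
    target = alignment.target
    query = alignment.query
    matches = mismatches = 0
    t_aln = q_aln = 0
    for (ts, te), (qs, qe) in zip(t_ranges, q_ranges):
        t_aln += te - ts
        q_aln += qe - qs
        for a, b in zip(target[ts:te], query[qs:qe]):
            if a == b:
                matches += 1
            else:
                mismatches += 1
    t_span = t_ranges[-1][1] - t_ranges[0][0]
    q_span = q_ranges[-1][1] - q_ranges[0][0]
    gap_columns = (t_span - t_aln) + (q_span - q_aln)
    return matches, mismatches, gap_columns, q_aln, int(t_ranges[0][0]), int(t_ranges[-1][1])


def _seed_windows(genome: str, marker: str, pad: int) -> list[tuple[int, int]]:
    """Candidate genome windows sharing an exact 15-mer with the marker."""
    kmers: dict[str, list[int]] = {}
    for i in range(len(marker) - _SEED_K + 1):
        kmers.setdefault(marker[i : i + _SEED_K], []).append(i)
    diagonals: set[int] = set()
    for g in range(len(genome) - _SEED_K + 1):
        hits = kmers.get(genome[g : g + _SEED_K])
        if hits:
            for m in hits:
                diagonals.add(g - m)
    if not diagonals:
        return []
    # merge nearby diagonals into windows
    windows: list[tuple[int, int]] = []
    for d in sorted(diagonals):
        start = max(0, d - pad)
        end = min(len(genome), d + len(marker) + pad)
        if windows and start <= windows[-1][1]:
            windows[-1] = (windows[-1][0], max(windows[-1][1], end))
        else:
            windows.append((start, end))
    return windows


def extract_reference_markers(
    genome: str,
    db: MarkerDB,
    species: str,
    min_identity: float = 0.90,
    min_coverage_frac: float = 0.80,
    sample_id: str = "reference",
):
    """Extract the species' marker homologs from a reference genome.

    For every marker of ``species``, the best seeded local alignment of the
    marker against the genome (either strand) is computed; if its identity
    and aligned marker fraction pass the thresholds, the genome-side
    sequence becomes that marker's consensus in the returned profile.
    Markers without a qualifying hit are simply absent.

    ``genome`` may be a plain DNA string or an iterable of (name, sequence)
    records; records are scanned independently.
    """
    from .consensus import ConsensusMarker, StrainProfile

    if isinstance(genome, str):
        records = [("genome", clean_sequence(genome))]
    else:
        records = [(name, clean_sequence(seq)) for name, seq in genome]
    if not records or all(not seq for _, seq in records):
        raise ValueError("genome is empty")
    markers = db.markers_for(species)  # raises KeyError for unknown species

    aligner = _local_aligner()
    found: dict[str, ConsensusMarker] = {}
    for marker in markers:
        best = None  # (score, extracted_sequence)
        for _, gseq in records:
            for strand_seq in (gseq, reverse_complement(gseq)):
                for ws, we in _seed_windows(strand_seq, marker.sequence, pad=50):
                    window = strand_seq[ws:we]
                    alignments = aligner.align(window, marker.sequence)
                    try:
                        aln = alignments[0]
                    except IndexError:
                        continue
                    m, x, g, q_aln, ts, te = _alignment_stats(aln)
                    columns = m + x + g
                    if columns == 0:
                        continue
                    identity = m / columns
                    coverage = q_aln / marker.length
                    if identity < min_identity or coverage < min_coverage_frac:
                        continue
                    # a hit on the reverse-complemented record is already in
                    # marker orientation, so no re-complementing is needed
                    extracted = window[ts:te]
                    if best is None or aln.score > best[0]:
                        best = (aln.score, extracted)
        if best is not None:
            seq = best[1]
            found[marker.marker_id] = ConsensusMarker(
                marker_id=marker.marker_id,
                species=species,
                sequence=seq,
                mean_depth=float("nan"),
            )
    return StrainProfile(
        sample_id=sample_id,
        species=species,
        markers=found,
        markers_in_db=len(markers),
        source="reference",
    )
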