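"""Read ingestion: SAM alignments or raw reads to per-marker pileups.

The pileup is the per-position tally of quality-passing bases over the four
nucleotides; it carries everything the consensus caller and the polymorphism
test need (total covering reads N_s and dominant-allele support T_s per
site).  Bases below the Phred threshold (default 30) are excluded from both
counts and depth.

``naive_map`` is a deliberately simple exact-seed / ungapped-extension
mapper used for fixtures and simulations, so that the pipeline can be
exercised without an external aligner.  Any real aligner's SAM output is
accepted through ``parse_sam``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Iterator

import numpy as np
import pysam

if TYPE_CHECKING:  # avoid runtime import cycle
    from .markerdb import Marker, MarkerDB

__all__ = [
    "Read",
    "AlignedRead",
    "Pileup",
    "parse_sam",
    "build_pileup",
    "build_pileups",
    "naive_map",
]

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# CIGAR operations that consume the reference / the query
_REF_CONSUMING = set("MDN=X")
_QUERY_CONSUMING = set("MIS=X")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Read:
    """An unaligned sequencing read (FASTQ record in memory)."""

    name: str
    sequence: str
    qualities: list[int]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(f"read {self.name!r}: |bases| != |qualities|")


@dataclass
class AlignedRead:
    """A read placed on a marker, in marker (forward-strand) coordinates.

    ``cigar`` is a list of (op, length) with ops from MIDS=X; ``start`` is
    the 0-based offset of the first reference-consuming base.
    """

    marker_id: str
    start: int
    bases: str
    qualities: list[int]
    cigar: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.qualities):
            raise ValueError("|bases| != |qualities|")
        if self.start < 0:
            raise ValueError("start must be >= 0")
        if not self.cigar:
            self.cigar = [("M", len(self.bases))]

    def reference_span(self) -> int:
        return sum(n for op, n in self.cigar if op in _REF_CONSUMING)

    def aligned_bases(self) -> Iterator[tuple[int, str, int]]:
        """Yield (marker_position, base, quality) for every aligned base.

        Insertions and soft-clips consume query only and are dropped;
        deletions consume reference only and contribute no base.
        """
        rpos = self.start
        qpos = 0
        for op, n in self.cigar:
            if op in ("M", "=", "X"):
                for k in range(n):
                    yield rpos + k, self.bases[qpos + k], self.qualities[qpos + k]
                rpos += n
                qpos += n
            elif op in ("D", "N"):
                rpos += n
            elif op in ("I", "S"):
                qpos += n
            elif op == "H":
                pass
            else:
                raise ValueError(f"unsupported CIGAR op {op!r}")


@dataclass
class Pileup:
    """Per-position base tallies for one marker in one sample.

    ``counts`` is a (4, L) array in A,C,G,T row order of quality-passing
    bases; ``depth`` is its column sum.
    """

    marker_id: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError("counts must have shape (4, marker_length)")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("marker\tpos\tA\tC\tG\tT\n")
            for pos in range(self.length):
                a, c, g, t = self.counts[:, pos]
                fh.write(f"{self.marker_id}\t{pos}\t{a}\t{c}\t{g}\t{t}\n")


_CIGAR_OPS = "MIDNSHP=X"


def parse_sam(path: str | Path, db: "MarkerDB") -> Iterator[AlignedRead]:
    """Stream alignments from a SAM/BAM file as :class:`AlignedRead`.

    Unmapped, secondary and supplementary records are skipped.  Reference
    names must be marker ids present in ``db``.
    """
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            name = rec.reference_name
            if name not in db:
                raise ValueError(f"SAM reference {name!r} not found in marker database")
            if rec.cigartuples is None:
                raise ValueError(f"read {rec.query_name!r}: missing CIGAR")
            cigar = [(_CIGAR_OPS[op], n) for op, n in rec.cigartuples]
            quals = (
                list(rec.query_qualities)
                if rec.query_qualities is not None
                else [40] * len(rec.query_sequence)
            )
            read = AlignedRead(
                marker_id=name,
                start=rec.reference_start,
                bases=rec.query_sequence.upper(),
                qualities=quals,
                cigar=cigar,
            )
            if read.start + read.reference_span() > db[name].length:
                raise ValueError(
                    f"read {rec.query_name!r} extends past end of marker {name!r}"
                )
            yield read


def build_pileup(
    reads: Iterable[AlignedRead], marker: "Marker", min_base_quality: int = 30
) -> Pileup:
    """Tally quality-passing bases of ``reads`` over ``marker`` positions."""
    counts = np.zeros((4, marker.length), dtype=np.int64)
    for read in reads:
        if read.marker_id != marker.marker_id:
            raise ValueError(
                f"read targets {read.marker_id!r}, expected {marker.marker_id!r}"
            )
        for pos, base, qual in read.aligned_bases():
            if qual < min_base_quality:
                continue
            idx = BASE_INDEX.get(base)
            if idx is None:  # N or other ambiguity in the read
                continue
            counts[idx, pos] += 1
    return Pileup(marker_id=marker.marker_id, counts=counts)


def build_pileups(
    reads: Iterable[AlignedRead], db: "MarkerDB", min_base_quality: int = 30
) -> dict[str, Pileup]:
    """Group aligned reads by marker and build one pileup per marker hit."""
    grouped: dict[str, list[AlignedRead]] = {}
    for read in reads:
        grouped.setdefault(read.marker_id, []).append(read)
    return {
        mid: build_pileup(rs, db[mid], min_base_quality) for mid, rs in grouped.items()
    }


class _KmerIndex:
    """Exact k-mer index over all marker sequences of a database."""

    def __init__(self, db: "MarkerDB", k: int):
        self.k = k
        self.index: dict[str, list[tuple[str, int]]] = {}
        self.sequences = {m.marker_id: m.sequence for m in db}
        for m in db:
            seq = m.sequence
            for i in range(len(seq) - k + 1):
                self.index.setdefault(seq[i : i + k], []).append((m.marker_id, i))


def naive_map(
    reads: Iterable[Read],
    db: "MarkerDB",
    seed_k: int = 15,
    max_mismatch_frac: float = 0.10,
) -> Iterator[AlignedRead]:
    """Map reads to markers by exact k-mer seeding and ungapped extension.

    Both strands are tried; the hit with the fewest mismatches wins (ties
    broken toward the first candidate encountered).  Reads whose best
    ungapped placement exceeds ``max_mismatch_frac`` mismatches, or that
    share no seed with any marker, are dropped.  Output is in marker
    coordinates with forward-strand bases.
    """
    index = _KmerIndex(db, seed_k)
    for read in reads:
        L = len(read.sequence)
        if L < seed_k:
            continue
        max_mm = int(max_mismatch_frac * L)
        best = None  # (mismatches, marker_id, start, strand_seq, strand_quals)
        for strand_seq, quals in (
            (read.sequence, read.qualities),
            (_revcomp(read.sequence), read.qualities[::-1]),
        ):
            seen: set[tuple[str, int]] = set()
            for seed_start in range(0, L - seed_k + 1, seed_k):
                hits = index.index.get(strand_seq[seed_start : seed_start + seed_k])
                if not hits:
                    continue
                for mid, mpos in hits:
                    start = mpos - seed_start
                    if start < 0:
                        continue
                    mseq = index.sequences[mid]
                    if start + L > len(mseq):
                        continue
                    key = (mid, start)
                    if key in seen:
                        continue
                    seen.add(key)
                    ref = mseq[start : start + L]
                    if ref == strand_seq:
                        mm = 0
                    else:
                        mm = sum(a != b for a, b in zip(strand_seq, ref))
                    if mm > max_mm:
                        continue
                    if best is None or mm < best[0]:
                        best = (mm, mid, start, strand_seq, quals)
                if best is not None and best[0] == 0:
                    break
            if best is not None and best[0] == 0:
                break
        if best is not None:
            _, mid, start, seq, quals = best
            yield AlignedRead(
                marker_id=mid,
                start=start,
                bases=seq,
                qualities=list(quals),
                cigar=[("M", L)],
            )
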