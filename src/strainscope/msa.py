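"""Per-marker multiple alignment, gap/ambiguity trimming, concatenation.

Consensus sequences of the same marker across samples are near-identical
(within-species divergence is a few percent at most), so a center-star
progressive alignment — every sequence pairwise-aligned to the longest one
and merged under "once a gap, always a gap" — is adequate and fully
deterministic.  Pre-aligned FASTA from an external aligner can be
substituted via :func:`marker_alignment_from_rows`.

The trimming cascade mirrors the marker-gene QC conventions:

1. trailing columns are trimmed inward while their gap fraction is >=20%;
2. internal columns present in <30% of rows are removed;
3. columns containing any N are removed when such columns are <80% of the
   alignment (otherwise kept, as a guard against degenerate alignments),
   after which every surviving N becomes a gap;
4. after concatenating markers, columns inside long gap runs (>=3
   consecutive gaps in some row) are removed when they are <80% of the
   columns; finally rows with >20% gaps are dropped.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

__all__ = [
    "MarkerAlignment",
    "SpeciesAlignment",
    "align_marker",
    "marker_alignment_from_rows",
    "trim_trailing_gaps",
    "drop_sparse_columns",
    "resolve_ambiguous_columns",
    "concatenate",
    "drop_long_gap_columns",
    "drop_gappy_samples",
    "build_species_alignment",
]

GAP = "-"


def _check_rows(rows: Mapping[str, str]) -> int:
    lengths = {len(s) for s in rows.values()}
    if len(lengths) > 1:
        raise ValueError(f"alignment rows differ in length: {sorted(lengths)}")
    return lengths.pop() if lengths else 0


@dataclass
class MarkerAlignment:
    """Gapped alignment of one marker's consensus sequences across samples."""

    marker_id: str
    rows: dict[str, str]

    def __post_init__(self) -> None:
        self.n_columns = _check_rows(self.rows)

    def to_matrix(self) -> np.ndarray:
        return _to_matrix(self.rows)

    def replace_rows(self, matrix: np.ndarray, sample_ids: Sequence[str]) -> "MarkerAlignment":
        return MarkerAlignment(self.marker_id, _from_matrix(matrix, sample_ids))


@dataclass
class SpeciesAlignment:
    """Concatenated, trimmed marker alignments for one species.

    ``column_map`` maps each column to its (marker_id, marker_column) of
    origin, in fixed marker order.
    """

    species: str
    rows: dict[str, str]
    column_map: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.n_columns = _check_rows(self.rows)
        if self.column_map and len(self.column_map) != self.n_columns:
            raise ValueError("column_map length != n_columns")

    def to_matrix(self) -> np.ndarray:
        return _to_matrix(self.rows)


def _to_matrix(rows: Mapping[str, str]) -> np.ndarray:
    ids = list(rows)
    if not ids:
        return np.empty((0, 0), dtype="S1")
    return np.frombuffer("".join(rows[i] for i in ids).encode(), dtype="S1").reshape(
        len(ids), -1
    )


def _from_matrix(matrix: np.ndarray, sample_ids: Sequence[str]) -> dict[str, str]:
    return {
        sid: matrix[i].tobytes().decode() for i, sid in enumerate(sample_ids)
    }


# --- alignment --------------------------------------------------------------

def _global_aligner() -> PairwiseAligner:
    mat = substitution_matrices.Array(alphabet="ACGTN", dims=2)
    for x in "ACGT":
        for y in "ACGT":
            mat[x, y] = 1.0 if x == y else -1.0
    for x in "ACGTN":
        mat["N", x] = 0.0
        mat[x, "N"] = 0.0
    aligner = PairwiseAligner()
    aligner.substitution_matrix = mat
    aligner.mode = "global"
    aligner.open_gap_score = -3.0
    aligner.extend_gap_score = -1.0
    return aligner


def _merge_pair(
    master_center: str,
    merged_rows: dict[str, str],
    center_gapped: str,
    seq_gapped: str,
    new_id: str,
) -> tuple[str, dict[str, str]]:
    """Merge a (center, new sequence) pairwise alignment into the star MSA."""
    take_old: list[Optional[int]] = []  # column index into the old master, or None
    take_new: list[Optional[int]] = []  # column index into the pairwise aln, or None
    i = j = 0
    M, P = len(master_center), len(center_gapped)
    while i < M or j < P:
        old_gap = i < M and master_center[i] == GAP
        new_gap = j < P and center_gapped[j] == GAP
        if old_gap:
            # insertion column contributed by a previously merged sequence
            take_old.append(i)
            take_new.append(None)
            i += 1
        elif new_gap:
            # insertion column contributed by the new sequence
            take_old.append(None)
            take_new.append(j)
            j += 1
        else:
            # both hold the same (next) center character
            take_old.append(i)
            take_new.append(j)
            i += 1
            j += 1
    new_master = "".join(
        master_center[o] if o is not None else GAP for o in take_old
    )
    out: dict[str, str] = {}
    for sid, row in merged_rows.items():
        out[sid] = "".join(row[o] if o is not None else GAP for o in take_old)
    out[new_id] = "".join(
        seq_gapped[n] if n is not None else GAP for n in take_new
    )
    return new_master, out


def align_marker(
    sequences: Mapping[str, str], marker_id: str = ""
) -> MarkerAlignment:
    """Center-star progressive alignment of one marker across samples.

    The longest sequence (ties: lexicographically smallest sample id) is
    the center; every other sequence is globally aligned to it and merged.
    Ungapping any output row reproduces its input exactly.
    """
    if not sequences:
        raise ValueError("no sequences to align")
    if len(sequences) == 1:
        return MarkerAlignment(marker_id, dict(sequences))
    center_id = min(sequences, key=lambda s: (-len(sequences[s]), s))
    center_seq = sequences[center_id]
    aligner = _global_aligner()
    master = center_seq
    merged: dict[str, str] = {center_id: center_seq}
    for sid in sorted(sequences):
        if sid == center_id:
            continue
        seq = sequences[sid]
        if seq == center_seq:  # fast path for the dominant identical case
            cg, sg = center_seq, seq
        else:
            aln = aligner.align(center_seq, seq)[0]
            cg, sg = str(aln[0]), str(aln[1])
        master, merged = _merge_pair(master, merged, cg, sg, sid)
    return MarkerAlignment(marker_id, merged)


def marker_alignment_from_rows(
    rows: Mapping[str, str], marker_id: str = ""
) -> MarkerAlignment:
    """Wrap pre-aligned rows (e.g. from an external aligner) as a MarkerAlignment."""
    return MarkerAlignment(marker_id, dict(rows))


# --- trimming ---------------------------------------------------------------

def trim_trailing_gaps(
    aln: MarkerAlignment, max_gap_fraction: float = 0.20
) -> MarkerAlignment:
    """Trim columns inward from each end while their gap fraction is
    >= ``max_gap_fraction``; stop at the first compliant column per end."""
    ids = list(aln.rows)
    mat = aln.to_matrix()
    if mat.size == 0:
        return aln
    gap_frac = (mat == GAP.encode()).mean(axis=0)
    lo, hi = 0, mat.shape[1]
    while lo < hi and gap_frac[lo] >= max_gap_fraction:
        lo += 1
    while hi > lo and gap_frac[hi - 1] >= max_gap_fraction:
        hi -= 1
    return aln.replace_rows(mat[:, lo:hi], ids)


def drop_sparse_columns(
    aln: MarkerAlignment, min_present_fraction: float = 0.30
) -> MarkerAlignment:
    """Remove columns whose non-gap fraction is strictly below the threshold."""
    ids = list(aln.rows)
    mat = aln.to_matrix()
    if mat.size == 0:
        return aln
    present = (mat != GAP.encode()).mean(axis=0)
    return aln.replace_rows(mat[:, present >= min_present_fraction], ids)


def resolve_ambiguous_columns(
    aln: MarkerAlignment, max_N_col_fraction: float = 0.80
) -> MarkerAlignment:
    """Delete N-containing columns when they are < the threshold fraction of
    all columns; otherwise keep them.  Surviving Ns become gaps."""
    ids = list(aln.rows)
    mat = aln.to_matrix()
    if mat.size == 0:
        return aln
    has_n = (mat == b"N").any(axis=0)
    if has_n.sum() < max_N_col_fraction * mat.shape[1]:
        mat = mat[:, ~has_n]
    else:
        mat = mat.copy()
        mat[mat == b"N"] = GAP.encode()
    return aln.replace_rows(mat, ids)


def concatenate(
    alignments: Sequence[MarkerAlignment],
    samples: Sequence[str],
    species: str = "",
) -> SpeciesAlignment:
    """Join marker alignments in the given (fixed) order per sample.

    A sample missing a marker contributes an all-gap block of that
    marker's width.
    """
    if not alignments:
        raise ValueError("no marker alignments to concatenate")
    rows: dict[str, list[str]] = {sid: [] for sid in samples}
    column_map: list[tuple[str, int]] = []
    for aln in alignments:
        width = aln.n_columns
        blank = GAP * width
        for sid in samples:
            rows[sid].append(aln.rows.get(sid, blank))
        column_map.extend((aln.marker_id, c) for c in range(width))
    return SpeciesAlignment(
        species=species,
        rows={sid: "".join(parts) for sid, parts in rows.items()},
        column_map=column_map,
    )


def _long_gap_columns(rows: Mapping[str, str], min_run: int = 3) -> np.ndarray:
    """Boolean mask over columns lying inside a gap run of >= min_run in any row."""
    n_cols = _check_rows(rows)
    mask = np.zeros(n_cols, dtype=bool)
    pattern = re.compile(f"{GAP}{{{min_run},}}")
    for row in rows.values():
        for m in pattern.finditer(row):
            mask[m.start() : m.end()] = True
    return mask


def drop_long_gap_columns(
    aln: SpeciesAlignment, max_longgap_fraction: float = 0.80
) -> SpeciesAlignment:
    """Remove columns inside >=3-gap runs when they are < the threshold
    fraction of all columns; otherwise keep the alignment unchanged."""
    if aln.n_columns == 0:
        return aln
    mask = _long_gap_columns(aln.rows)
    if mask.sum() >= max_longgap_fraction * aln.n_columns:
        return aln
    keep = ~mask
    ids = list(aln.rows)
    mat = aln.to_matrix()[:, keep]
    cmap = [cm for cm, k in zip(aln.column_map, keep) if k] if aln.column_map else []
    return SpeciesAlignment(aln.species, _from_matrix(mat, ids), cmap)


def drop_gappy_samples(
    aln: SpeciesAlignment, max_sample_gap_fraction: float = 0.20
) -> SpeciesAlignment:
    """Remove rows with gaps in strictly more than the threshold fraction."""
    if aln.n_columns == 0:
        return aln
    rows = {
        sid: row
        for sid, row in aln.rows.items()
        if row.count(GAP) / len(row) <= max_sample_gap_fraction
    }
    return SpeciesAlignment(aln.species, rows, list(aln.column_map))


def build_species_alignment(
    marker_sequences: Mapping[str, Mapping[str, str]],
    species: str = "",
    gap_trailing: float = 0.20,
    gap_internal: float = 0.30,
    n_col: float = 0.80,
    long_gap: float = 0.80,
    gap_sample: float = 0.20,
) -> SpeciesAlignment:
    """Full cascade: align each marker, trim, concatenate, species-level trim.

    ``marker_sequences`` maps marker_id -> (sample_id -> consensus
    sequence).  Markers are concatenated in lexicographic marker_id order.
    """
    samples = sorted({s for seqs in marker_sequences.values() for s in seqs})
    if not samples:
        raise ValueError("no samples")
    trimmed: list[MarkerAlignment] = []
    for mid in sorted(marker_sequences):
        aln = align_marker(marker_sequences[mid], mid)
        aln = trim_trailing_gaps(aln, gap_trailing)
        aln = drop_sparse_columns(aln, gap_internal)
        aln = resolve_ambiguous_columns(aln, n_col)
        if aln.n_columns > 0:
            trimmed.append(aln)
    if not trimmed:
        raise ValueError(f"species {species!r}: every marker alignment was trimmed away")
    sp = concatenate(trimmed, samples, species)
    sp = drop_long_gap_columns(sp, long_gap)
    sp = drop_gappy_samples(sp, gap_sample)
    return sp
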