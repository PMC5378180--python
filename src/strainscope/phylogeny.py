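"""Strain distances and phylogenies from concatenated marker alignments.

The strain distance is the length-normalized SNV rate: for each pair of
rows, the fraction of mismatching columns among columns where both rows
carry an unambiguous nucleotide (A/C/G/T).  Trees are built by
neighbor-joining on that matrix — deterministic and adequate in the
near-clonal regime the method operates in — while ``export_alignment``
writes relaxed-PHYLIP/FASTA so that external maximum-likelihood software
can be used instead when desired.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .msa import GAP, SpeciesAlignment

__all__ = [
    "SnvDistanceMatrix",
    "PhyloTree",
    "snv_distance",
    "build_tree",
    "export_alignment",
]

#: pairs sharing fewer comparable columns than this are flagged low-confidence
LOW_CONFIDENCE_COLUMNS = 1000


@dataclass
class SnvDistanceMatrix:
    """Pairwise SNV rates between samples for one species."""

    species: str
    sample_ids: list[str]
    d: np.ndarray  # (n, n) symmetric, zero diagonal
    n_compared: np.ndarray  # (n, n) comparable-column counts

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        self.n_compared = np.asarray(self.n_compared, dtype=np.int64)
        n = len(self.sample_ids)
        if self.d.shape != (n, n) or self.n_compared.shape != (n, n):
            raise ValueError("matrix shapes must match sample_ids")
        if not np.allclose(self.d, self.d.T) or np.any(np.diag(self.d) != 0):
            raise ValueError("d must be symmetric with zero diagonal")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.sample_ids.index(pair[0])
        j = self.sample_ids.index(pair[1])
        return float(self.d[i, j])

    def low_confidence_pairs(self) -> list[tuple[str, str]]:
        """Pairs compared over fewer than LOW_CONFIDENCE_COLUMNS columns."""
        out = []
        n = len(self.sample_ids)
        for i in range(n):
            for j in range(i + 1, n):
                if self.n_compared[i, j] < LOW_CONFIDENCE_COLUMNS:
                    out.append((self.sample_ids[i], self.sample_ids[j]))
        return out

    def to_skbio(self) -> DistanceMatrix:
        return DistanceMatrix(self.d, ids=self.sample_ids)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.d, index=self.sample_ids, columns=self.sample_ids).to_csv(
            path, sep="\t"
        )

    @classmethod
    def from_tsv(cls, path: str | Path, species: str = "") -> "SnvDistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        ids = [str(c) for c in df.columns]
        d = df.to_numpy(dtype=float)
        n_compared = np.full_like(d, LOW_CONFIDENCE_COLUMNS, dtype=np.int64)
        np.fill_diagonal(n_compared, 0)
        return cls(species=species, sample_ids=ids, d=d, n_compared=n_compared)


@dataclass
class PhyloTree:
    """A strain tree plus optional per-leaf metadata."""

    tree: TreeNode
    metadata: Optional[pd.DataFrame] = None

    @property
    def leaf_names(self) -> list[str]:
        return [t.name for t in self.tree.tips()]

    def to_newick(self, path: Optional[str | Path] = None) -> str:
        s = str(self.tree)
        if path is not None:
            Path(path).write_text(s)
        return s


def snv_distance(aln: SpeciesAlignment, min_compared: int = 1) -> SnvDistanceMatrix:
    """Length-normalized SNV rate between every pair of alignment rows.

    Only columns where both rows have A/C/G/T are compared; a pair with no
    comparable column is an error naming the pair.
    """
    ids = sorted(aln.rows)
    if len(ids) < 2:
        raise ValueError("need >= 2 rows to compute distances")
    mat = np.frombuffer("".join(aln.rows[i] for i in ids).encode(), dtype="S1").reshape(
        len(ids), -1
    )
    valid = np.isin(mat, np.frombuffer(b"ACGT", dtype="S1"))
    n = len(ids)
    d = np.zeros((n, n))
    n_compared = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            m = int(both.sum())
            if m < max(min_compared, 1):
                raise ValueError(
                    f"pair ({ids[i]!r}, {ids[j]!r}) has no comparable columns"
                )
            mism = int((mat[i][both] != mat[j][both]).sum())
            d[i, j] = d[j, i] = mism / m
            n_compared[i, j] = n_compared[j, i] = m
    np.fill_diagonal(n_compared, 0)
    return SnvDistanceMatrix(species=aln.species, sample_ids=ids, d=d, n_compared=n_compared)


def build_tree(
    dist: SnvDistanceMatrix, metadata: Optional[pd.DataFrame] = None
) -> PhyloTree:
    """Neighbor-joining tree on the SNV distance matrix.

    Negative branch-length estimates (an artifact of NJ on noisy or
    non-additive matrices) are clamped to zero with a warning.
    """
    if len(dist.sample_ids) < 3:
        raise ValueError(
            "need >= 3 leaves for a tree; report pairwise distances instead"
        )
    tree = nj(dist.to_skbio(), neg_as_zero=False)
    clamped = 0
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clamped += 1
    if clamped:
        warnings.warn(f"clamped {clamped} negative NJ branch lengths to 0", stacklevel=2)
    return PhyloTree(tree=tree, metadata=metadata)


def export_alignment(aln: SpeciesAlignment, path: str | Path) -> tuple[Path, Path]:
    """Write the alignment as aligned FASTA and relaxed PHYLIP (N-free).

    Any residual N is replaced by a gap so the files are accepted by
    standard phylogenetics tools.  Returns the two file paths.
    """
    if not aln.rows or aln.n_columns == 0:
        raise ValueError("cannot export an empty alignment")
    base = Path(path)
    fasta = base.with_suffix(".fasta")
    phylip = base.with_suffix(".phy")
    ids = sorted(aln.rows)
    rows = {sid: aln.rows[sid].replace("N", GAP) for sid in ids}
    with open(fasta, "w") as fh:
        for sid in ids:
            fh.write(f">{sid}\n{rows[sid]}\n")
    with open(phylip, "w") as fh:
        fh.write(f" {len(ids)} {aln.n_columns}\n")
        for sid in ids:
            fh.write(f"{sid}  {rows[sid]}\n")
    return fasta, phylip
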