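"""Population structure of strains: retention, subclades, geography, ordination.

Strain retention.  Within-subject pairs of samples yield SNV distances that
are near zero when the dominant strain was retained and comparable to
unrelated-pair distances when it was replaced.  Distances are normalized by
the median over all pairs of the species (so 1.0 = typical unrelated
strains), a two-component Gaussian mixture is fitted to the normalized
values, and a pair is called ``same_strain`` when it falls within
mu + 3*sigma of the lower-mean component.

Subclades.  A subclade is a maximal subtree of the (midpoint-rooted) strain
phylogeny whose members' pairwise SNV rates all stay below a tight
threshold (default 0.1%), supported by at least two subjects or by a
reference genome plus a metagenome-derived strain.  Country-enriched
subtrees are maximal subtrees of a minimum size in which one country
accounts for at least 80% of the leaves.

Ordination is classical PCoA of the SNV matrix; subspecies-level clusters
are recovered by spectral clustering of the first two coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa
from sklearn.metrics import pairwise_distances
from sklearn.mixture import GaussianMixture
from sklearn.cluster import SpectralClustering

from .phylogeny import PhyloTree, SnvDistanceMatrix

__all__ = [
    "NormalizedDistance",
    "MixtureFit",
    "RetentionCall",
    "Subclade",
    "CountrySubtree",
    "normalize_distances",
    "fit_retention_mixture",
    "call_retention",
    "detect_subclades",
    "country_subtrees",
    "ordination",
    "cluster_ordination",
]


@dataclass
class NormalizedDistance:
    """One sample pair's SNV rate, normalized by the species-wide median."""

    species: str
    pair: tuple[str, str]
    raw: float
    normalized: float
    same_subject: bool
    subject: Optional[str] = None  # set when same_subject


@dataclass
class MixtureFit:
    """Two-component Gaussian mixture over normalized distances."""

    means: tuple[float, float]  # (mu_low, mu_high)
    sds: tuple[float, float]
    weights: tuple[float, float]
    threshold: float  # mu_low + 3 * sigma_low
    reliable: bool  # False when the components' 3-sigma ranges overlap


@dataclass
class RetentionCall:
    species: str
    subject: str
    pair: tuple[str, str]
    normalized: float
    verdict: str  # "same_strain" | "different_strain"
    reliable: bool


def normalize_distances(
    dist: SnvDistanceMatrix, metadata: pd.DataFrame
) -> list[NormalizedDistance]:
    """Annotate every pair with subject identity and normalize by the median
    raw distance over all pairs of the species.

    ``metadata`` is indexed by sample id with at least a ``subject`` column.
    """
    ids = dist.sample_ids
    subjects = {
        sid: metadata.loc[sid, "subject"] if sid in metadata.index else None
        for sid in ids
    }
    pairs = []
    raws = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            pairs.append((ids[i], ids[j]))
            raws.append(float(dist.d[i, j]))
    n_inter = sum(
        1
        for a, b in pairs
        if subjects[a] is None or subjects[b] is None or subjects[a] != subjects[b]
    )
    if n_inter < 3:
        raise ValueError("need >= 3 distinct-subject pairs for stable normalization")
    denom = float(np.median(raws))
    if denom <= 0:
        raise ValueError(
            f"degenerate species {dist.species!r}: median pairwise distance is 0"
        )
    out = []
    for (a, b), raw in zip(pairs, raws):
        same = (
            subjects[a] is not None
            and subjects[b] is not None
            and subjects[a] == subjects[b]
        )
        out.append(
            NormalizedDistance(
                species=dist.species,
                pair=(a, b),
                raw=raw,
                normalized=raw / denom,
                same_subject=same,
                subject=subjects[a] if same else None,
            )
        )
    return out


def fit_retention_mixture(
    values: Sequence[float], seed: int = 42, max_iter: int = 500
) -> MixtureFit:
    """Fit the two-component Gaussian mixture used for retention calling."""
    x = np.asarray(values, dtype=float).reshape(-1, 1)
    if x.shape[0] < 20:
        raise ValueError("need >= 20 values to fit the retention mixture")
    gm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        max_iter=max_iter,
        n_init=3,
        init_params="kmeans",
        random_state=seed,
        reg_covar=1e-10,
    ).fit(x)
    if not gm.converged_:
        raise RuntimeError(
            f"mixture EM did not converge in {max_iter} iterations "
            f"(lower bound {gm.lower_bound_:.4g})"
        )
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    order = np.argsort(means)
    mu = (float(means[order[0]]), float(means[order[1]]))
    sd = (float(sds[order[0]]), float(sds[order[1]]))
    w = (float(gm.weights_[order[0]]), float(gm.weights_[order[1]]))
    threshold = mu[0] + 3 * sd[0]
    reliable = threshold < mu[1] - 3 * sd[1]
    return MixtureFit(means=mu, sds=sd, weights=w, threshold=threshold, reliable=reliable)


def call_retention(
    normalized: Sequence[NormalizedDistance],
    fit: Optional[MixtureFit] = None,
    seed: int = 42,
) -> list[RetentionCall]:
    """Call retained vs replaced strains for every same-subject pair.

    The mixture is fitted to all normalized distances of the species unless
    a pre-fitted model is supplied.
    """
    if fit is None:
        fit = fit_retention_mixture([nd.normalized for nd in normalized], seed=seed)
    calls = []
    for nd in normalized:
        if not nd.same_subject:
            continue
        verdict = "same_strain" if nd.normalized <= fit.threshold else "different_strain"
        calls.append(
            RetentionCall(
                species=nd.species,
                subject=str(nd.subject),
                pair=nd.pair,
                normalized=nd.normalized,
                verdict=verdict,
                reliable=fit.reliable,
            )
        )
    return calls


# --- subclades and geography -------------------------------------------------

@dataclass
class Subclade:
    species: str
    id: str
    leaf_set: frozenset[str]
    n_subjects: int
    intra_snv_median: float
    intra_snv_max: float
    contains_reference: bool
    country_counts: dict[str, int] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.leaf_set)


def _meta_col(metadata: Optional[pd.DataFrame], sid: str, col: str):
    if metadata is None or sid not in metadata.index or col not in metadata.columns:
        return None
    val = metadata.loc[sid, col]
    return None if pd.isna(val) else val


def _rooted(tree: PhyloTree):
    t = tree.tree
    if len(t.children) > 2:  # unrooted NJ output: root at midpoint for
        t = t.root_at_midpoint()  # "subtree" to be well-defined
    return t


def _clades(root) -> list[frozenset]:
    """All candidate subtrees (clades) of a rooted tree, including the root."""
    out = []
    for node in root.postorder():
        if not node.is_tip():
            out.append(frozenset(t.name for t in node.tips()))
    return out


def detect_subclades(
    tree: PhyloTree,
    dist: SnvDistanceMatrix,
    max_intra_snv: float = 0.001,
    metadata: Optional[pd.DataFrame] = None,
) -> list[Subclade]:
    """Maximal disjoint subtrees with all pairwise SNV rates < max_intra_snv.

    A qualifying subtree must contain strains from at least two subjects,
    or at least one reference genome together with at least one
    metagenome-derived strain.  Disjointness is enforced greedily,
    largest subtree first.
    """
    root = _rooted(tree)
    index = {sid: k for k, sid in enumerate(dist.sample_ids)}
    meta = tree.metadata if metadata is None else metadata

    def qualifies(leaves: frozenset) -> Optional[tuple[float, float]]:
        idx = [index[l] for l in leaves]
        sub = dist.d[np.ix_(idx, idx)]
        pair_vals = sub[np.triu_indices(len(idx), k=1)]
        if pair_vals.size == 0 or float(pair_vals.max()) >= max_intra_snv:
            return None
        refs = sum(1 for l in leaves if _meta_col(meta, l, "source") == "reference")
        samples = len(leaves) - refs
        subjects = {
            s
            for l in leaves
            if _meta_col(meta, l, "source") != "reference"
            and (s := _meta_col(meta, l, "subject")) is not None
        }
        if len(subjects) >= 2 or (refs >= 1 and samples >= 1):
            return float(np.median(pair_vals)), float(pair_vals.max())
        return None

    candidates = []
    for leaves in _clades(root):
        if any(l not in index for l in leaves):
            raise ValueError("tree and distance matrix leaves differ")
        stats = qualifies(leaves)
        if stats is not None:
            candidates.append((leaves, stats))
    # greedy largest-first, ties broken lexicographically for determinism
    candidates.sort(key=lambda c: (-len(c[0]), tuple(sorted(c[0]))))
    chosen: list[Subclade] = []
    used: set[str] = set()
    for leaves, (med, mx) in candidates:
        if leaves & used:
            continue
        used |= leaves
        countries: dict[str, int] = {}
        for l in sorted(leaves):
            c = _meta_col(meta, l, "country")
            if c is not None:
                countries[str(c)] = countries.get(str(c), 0) + 1
        subjects = {
            s
            for l in leaves
            if _meta_col(meta, l, "source") != "reference"
            and (s := _meta_col(meta, l, "subject")) is not None
        }
        chosen.append(
            Subclade(
                species=dist.species,
                id=f"SC{len(chosen)}",
                leaf_set=leaves,
                n_subjects=len(subjects),
                intra_snv_median=med,
                intra_snv_max=mx,
                contains_reference=any(
                    _meta_col(meta, l, "source") == "reference" for l in leaves
                ),
                country_counts=countries,
            )
        )
    return chosen


@dataclass
class CountrySubtree:
    leaf_set: frozenset[str]
    country: str
    fraction: float

    @property
    def size(self) -> int:
        return len(self.leaf_set)


def country_subtrees(
    tree: PhyloTree,
    metadata: pd.DataFrame,
    min_fraction: float = 0.80,
    min_size: int = 5,
) -> list[CountrySubtree]:
    """Maximal subtrees of >= min_size leaves dominated by one country.

    A subtree is reported when its most common country accounts for at
    least ``min_fraction`` of its leaves and no qualifying ancestor
    contains it.
    """
    root = _rooted(tree)

    def top_country(leaves) -> Optional[tuple[str, float]]:
        counts: dict[str, int] = {}
        for l in leaves:
            c = _meta_col(metadata, l, "country")
            if c is not None:
                counts[str(c)] = counts.get(str(c), 0) + 1
        if not counts:
            return None
        country = max(sorted(counts), key=lambda c: counts[c])
        return country, counts[country] / len(leaves)

    candidates = []
    for leaves in _clades(root):
        if len(leaves) < min_size:
            continue
        tc = top_country(leaves)
        if tc is not None and tc[1] >= min_fraction:
            candidates.append(CountrySubtree(leaves, tc[0], tc[1]))
    candidates.sort(key=lambda c: (-c.size, tuple(sorted(c.leaf_set))))
    chosen: list[CountrySubtree] = []
    for cand in candidates:
        if any(cand.leaf_set <= kept.leaf_set for kept in chosen):
            continue  # nested inside an already-reported (larger) subtree
        chosen.append(cand)
    return chosen


# --- ordination --------------------------------------------------------------

def ordination(dist: SnvDistanceMatrix, k_components: int = 2) -> pd.DataFrame:
    """Classical multidimensional scaling (PCoA) of the SNV matrix.

    Components are ordered by eigenvalue; each component's sign is fixed by
    making its largest-magnitude coordinate positive.
    """
    if np.allclose(dist.d, 0):
        return pd.DataFrame(
            np.zeros((len(dist.sample_ids), k_components)),
            index=dist.sample_ids,
            columns=[f"PC{i + 1}" for i in range(k_components)],
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # negative-eigenvalue notice on noisy d
        res = pcoa(DistanceMatrix(dist.d, ids=dist.sample_ids), number_of_dimensions=0)
    coords = res.samples.to_numpy()
    k = min(k_components, coords.shape[1])
    coords = coords[:, :k]
    for c in range(coords.shape[1]):
        col = coords[:, c]
        if col[np.abs(col).argmax()] < 0:
            coords[:, c] = -col
    if k < k_components:  # pad degenerate embeddings with zero components
        coords = np.hstack([coords, np.zeros((coords.shape[0], k_components - k))])
    return pd.DataFrame(
        coords,
        index=dist.sample_ids,
        columns=[f"PC{i + 1}" for i in range(k_components)],
    )


def cluster_ordination(
    coords: pd.DataFrame, n_clusters: int, seed: int = 42
) -> np.ndarray:
    """Spectral clustering (RBF affinity) of the first two coordinates."""
    x = coords.to_numpy()[:, :2]
    if n_clusters < 2:
        return np.zeros(x.shape[0], dtype=int)
    # gamma scaled to the data spread so well-separated blobs stay separable
    med = np.median(pairwise_distances(x))
    gamma = 1.0 / (2 * med**2) if med > 0 else 1.0
    sc = SpectralClustering(
        n_clusters=n_clusters,
        affinity="rbf",
        gamma=gamma,
        assign_labels="kmeans",
        random_state=seed,
    )
    return sc.fit_predict(x)
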