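"""Retention mixture, subclade detection, geography, and ordination."""

import io
import itertools

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode
from sklearn.metrics import adjusted_rand_score

from strainscope.msa import SpeciesAlignment
from strainscope.phylogeny import PhyloTree, SnvDistanceMatrix, build_tree, snv_distance
from strainscope.popstructure import (
    call_retention,
    cluster_ordination,
    country_subtrees,
    detect_subclades,
    fit_retention_mixture,
    normalize_distances,
    ordination,
)
from strainscope.simulate import mutate_strain


def _dist(ids, d, species="s__x"):
    d = np.asarray(d, dtype=float)
    n_comp = np.full_like(d, 5000, dtype=np.int64)
    np.fill_diagonal(n_comp, 0)
    return SnvDistanceMatrix(species, list(ids), d, n_comp)


def _meta(**cols):
    samples = cols.pop("samples")
    return pd.DataFrame(cols, index=pd.Index(samples, name="sample"))


class TestNormalizeDistances:
    def test_all_equal_normalizes_to_one(self):
        d = np.full((4, 4), 0.02)
        np.fill_diagonal(d, 0)
        meta = _meta(samples=list("abcd"), subject=["u1", "u2", "u3", "u4"])
        nd = normalize_distances(_dist("abcd", d), meta)
        assert all(x.normalized == pytest.approx(1.0) for x in nd)

    def test_intra_subject_ratio(self):
        # intra pair 0.001 against an inter median of 0.01 -> normalized 0.1
        ids = ["u1a", "u1b", "x", "y"]
        d = np.full((4, 4), 0.01)
        np.fill_diagonal(d, 0)
        d[0, 1] = d[1, 0] = 0.001
        meta = _meta(samples=ids, subject=["u1", "u1", "u2", "u3"])
        nd = normalize_distances(_dist(ids, d), meta)
        intra = [x for x in nd if x.same_subject]
        assert len(intra) == 1
        assert intra[0].normalized == pytest.approx(0.1)
        assert intra[0].subject == "u1"

    def test_zero_median_degenerate(self):
        d = np.zeros((4, 4))
        meta = _meta(samples=list("abcd"), subject=["u1", "u2", "u3", "u4"])
        with pytest.raises(ValueError, match="degenerate"):
            normalize_distances(_dist("abcd", d), meta)

    def test_too_few_inter_pairs(self):
        d = np.full((3, 3), 0.01)
        np.fill_diagonal(d, 0)
        meta = _meta(samples=list("abc"), subject=["u1", "u1", "u1"])
        with pytest.raises(ValueError, match="distinct-subject"):
            normalize_distances(_dist("abc", d), meta)


class TestRetentionMixture:
    def test_parameter_recovery(self, rng):
        low = rng.normal(0.02, 0.01, size=100)
        high = rng.normal(1.0, 0.1, size=100)
        fit = fit_retention_mixture(np.concatenate([low, high]), seed=0)
        assert fit.means[0] == pytest.approx(0.02, abs=0.02)
        assert fit.means[1] == pytest.approx(1.0, abs=0.05)
        assert fit.reliable
        assert (low <= fit.threshold).mean() >= 0.97

    def test_unimodal_flagged_unreliable(self, rng):
        fit = fit_retention_mixture(rng.normal(1.0, 0.1, size=200), seed=0)
        assert not fit.reliable

    def test_separated_point_masses(self):
        values = [0.0] * 50 + [1.0] * 50
        fit = fit_retention_mixture(values, seed=0)
        assert fit.means[0] == pytest.approx(0.0, abs=1e-6)
        assert fit.means[1] == pytest.approx(1.0, abs=1e-6)
        assert all(v <= fit.threshold for v in values[:50])
        assert all(v > fit.threshold for v in values[50:])

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            fit_retention_mixture([0.1] * 10)

    def test_retention_pipeline_recovers_programmed_fraction(self, rng):
        """Sequence-level longitudinal cohort: 50 subjects, 70% retain."""
        bases = np.frombuffer(b"ACGT", dtype="S1")
        ancestor = {
            f"m{k}": rng.choice(bases, size=500).tobytes().decode() for k in range(20)
        }
        n_subjects, retain_frac = 50, 0.70
        retained = rng.random(n_subjects) < retain_frac
        rows = {}
        subjects = {}
        for s in range(n_subjects):
            strain, _ = mutate_strain(ancestor, 0.005, seed=1000 + s)
            rows[f"u{s}_t0"] = "".join(strain[m] for m in sorted(strain))
            if retained[s]:
                second = strain
            else:
                second, _ = mutate_strain(ancestor, 0.005, seed=5000 + s)
            rows[f"u{s}_t1"] = "".join(second[m] for m in sorted(second))
            subjects[f"u{s}_t0"] = subjects[f"u{s}_t1"] = f"u{s}"
        aln = SpeciesAlignment("s__x", rows)
        dist = snv_distance(aln)
        meta = pd.DataFrame({"subject": subjects})
        calls = call_retention(normalize_distances(dist, meta), seed=1)
        by_subject = {c.subject: c.verdict for c in calls}
        est = sum(v == "same_strain" for v in by_subject.values()) / n_subjects
        assert est == pytest.approx(retained.mean(), abs=0.05)


class TestSubclades:
    def _toy(self):
        newick = "(((a:0.0002,b:0.0002):0.0001,c:0.0003):0.01,(d:0.02,e:0.03):0.01,f:0.05);"
        tree = TreeNode.read(io.StringIO(newick))
        ids = list("abcdef")
        d = tree.tip_tip_distances(ids).data
        return PhyloTree(tree=tree), _dist(ids, d)

    def test_tight_clade_detected(self):
        tree, dist = self._toy()
        meta = _meta(samples=list("abcdef"),
                     subject=[f"u{i}" for i in range(6)],
                     country=["IT"] * 6)
        scs = detect_subclades(tree, dist, max_intra_snv=0.001, metadata=meta)
        assert len(scs) == 1
        assert scs[0].leaf_set == frozenset("abc")
        assert scs[0].n_subjects == 3
        assert scs[0].intra_snv_max < 0.001

    def test_single_subject_clade_rejected(self):
        tree, dist = self._toy()
        meta = _meta(samples=list("abcdef"), subject=["u0"] * 6, country=["IT"] * 6)
        assert detect_subclades(tree, dist, metadata=meta) == []

    def test_reference_plus_sample_qualifies(self):
        tree, dist = self._toy()
        meta = _meta(samples=list("abcdef"),
                     subject=["u0"] * 6,
                     country=["IT"] * 6,
                     source=["reference", "metagenome", "metagenome"] + ["metagenome"] * 3)
        scs = detect_subclades(tree, dist, metadata=meta)
        assert len(scs) == 1 and scs[0].contains_reference

    def test_divergent_star_empty(self):
        ids = list("abcd")
        d = np.full((4, 4), 0.02)
        np.fill_diagonal(d, 0)
        dist = _dist(ids, d)
        tree = build_tree(dist)
        meta = _meta(samples=ids, subject=[f"u{i}" for i in range(4)])
        assert detect_subclades(tree, dist, metadata=meta) == []

    def test_matches_bruteforce_and_leaf_order_invariant(self, rng):
        """Greedy subtree scan equals brute force over all clades (<=12 leaves)."""
        for rep in range(5):
            n = 10
            ids = [f"s{i}" for i in range(n)]
            # two planted tight clusters + background
            centers = {0: 0.0, 1: 3.0}
            assign = [0, 0, 0, 1, 1, 1, 1] + [None] * 3
            coords = []
            for i, a in enumerate(assign):
                if a is None:
                    coords.append(6.0 + 2 * rng.random())
                else:
                    coords.append(centers[a] + rng.normal(0, 0.0001))
            d = np.abs(np.subtract.outer(coords, coords)) * 0.001
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0)
            dist = _dist(ids, d)
            tree = build_tree(dist)
            meta = _meta(samples=ids, subject=[f"u{i}" for i in range(n)])
            scs = detect_subclades(tree, dist, max_intra_snv=0.001, metadata=meta)
            got = {sc.leaf_set for sc in scs}

            # brute force: enumerate clades of the midpoint-rooted tree
            rooted = tree.tree.root_at_midpoint()
            clades = []
            for node in rooted.postorder():
                if not node.is_tip():
                    clades.append(frozenset(t.name for t in node.tips()))
            idx = {s: k for k, s in enumerate(ids)}

            def ok(leaves):
                pairs = [
                    d[idx[a], idx[b]] for a, b in itertools.combinations(leaves, 2)
                ]
                return bool(pairs) and max(pairs) < 0.001 and len(leaves) >= 2

            qualifying = sorted(
                (c for c in clades if ok(c)), key=lambda c: (-len(c), tuple(sorted(c)))
            )
            expected, used = set(), set()
            for c in qualifying:
                if not (c & used):
                    expected.add(c)
                    used |= c
            assert got == expected

            # invariance to the order distance-matrix samples are listed in
            perm = list(rng.permutation(n))
            dist2 = _dist([ids[k] for k in perm], d[np.ix_(perm, perm)])
            tree2 = build_tree(dist2)
            scs2 = detect_subclades(tree2, dist2, max_intra_snv=0.001, metadata=meta)
            assert {sc.leaf_set for sc in scs2} == got


class TestCountrySubtrees:
    def _tree(self, newick):
        return PhyloTree(tree=TreeNode.read(io.StringIO(newick)))

    def test_dominant_country_reported(self):
        t = self._tree("((((a:1,b:1):1,(c:1,d:1):1):1,e:1):2,(x:1,(y:1,z:1):1):2);")
        meta = _meta(samples=list("abcdexyz"),
                     country=["China"] * 4 + ["China", "US", "US", "US"])
        subs = country_subtrees(t, meta, min_fraction=0.8, min_size=5)
        assert len(subs) == 1
        assert subs[0].country == "China"
        assert subs[0].leaf_set == frozenset("abcde")
        assert subs[0].fraction == pytest.approx(1.0)

    def test_below_fraction_not_reported(self):
        t = self._tree("(((a:1,b:1):1,(c:1,d:1):1):2,(e:1,f:4):2);")
        meta = _meta(samples=list("abcdef"),
                     country=["China", "China", "China", "US", "US", "US"])
        assert country_subtrees(t, meta, min_fraction=0.8, min_size=5) == []

    def test_whole_tree_single_country_reported_once(self):
        t = self._tree("(((a:1,b:1):1,(c:1,d:1):1):2,(e:1,f:4):2);")
        meta = _meta(samples=list("abcdef"), country=["Peru"] * 6)
        subs = country_subtrees(t, meta, min_fraction=0.8, min_size=5)
        assert len(subs) == 1
        assert subs[0].leaf_set == frozenset("abcdef")


class TestOrdination:
    def test_collinear_points(self):
        d = [[0, 1, 2], [1, 0, 1], [2, 1, 0]]
        coords = ordination(_dist("abc", d), k_components=2)
        pc1 = coords["PC1"].to_numpy()
        assert np.allclose(np.diff(np.sort(pc1)), [1, 1], atol=1e-9)
        assert np.allclose(coords["PC2"], 0, atol=1e-9)

    def test_all_zero_distances(self):
        d = np.zeros((3, 3))
        coords = ordination(_dist("abc", d), k_components=2)
        assert np.allclose(coords.to_numpy(), 0)

    def test_euclidean_exactness(self, rng):
        pts = rng.random((6, 3))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        coords = ordination(_dist([f"s{i}" for i in range(6)], d), k_components=6)
        emb = coords.to_numpy()
        d2 = np.sqrt(((emb[:, None, :] - emb[None, :, :]) ** 2).sum(-1))
        assert np.allclose(d2, d, atol=1e-9)

    def test_sign_convention(self, rng):
        d = [[0, 1, 2], [1, 0, 1], [2, 1, 0]]
        coords = ordination(_dist("abc", d), k_components=1)
        pc1 = coords["PC1"].to_numpy()
        assert pc1[np.abs(pc1).argmax()] > 0


class TestClusterOrdination:
    def test_separated_blobs_perfectly_recovered(self, rng):
        a = rng.normal(0, 0.1, size=(20, 2))
        b = rng.normal(10, 0.1, size=(20, 2))
        coords = pd.DataFrame(np.vstack([a, b]), columns=["PC1", "PC2"])
        labels = cluster_ordination(coords, n_clusters=2, seed=0)
        truth = [0] * 20 + [1] * 20
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_single_cluster(self, rng):
        coords = pd.DataFrame(rng.random((10, 2)), columns=["PC1", "PC2"])
        assert set(cluster_ordination(coords, n_clusters=1)) == {0}

    def test_duplicated_points_cluster_together(self, rng):
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0], [5.0, 5.0]])
        coords = pd.DataFrame(pts, columns=["PC1", "PC2"])
        labels = cluster_ordination(coords, n_clusters=2, seed=0)
        assert labels[0] == labels[1] and labels[2] == labels[3]
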