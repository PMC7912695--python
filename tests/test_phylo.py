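"""Phylogenetics: JC distances, neighbor joining, patristic distances,
mpd/comdist and ses.mpd null models."""

import itertools

import numpy as np
import pandas as pd
import pytest

from desertam.phylo import (JC_MAX, comdist, comdist_matrix,
                            exhaustive_mpd_null, jc_distance_matrix, mpd,
                            neighbor_joining, patristic_distances, ses_mpd)


def random_tree_matrix(rng, n, min_len=0.1, max_len=1.0):
    """Random binary tree -> (additive distance matrix, adjacency dict).

    Built by random sequential joins; distances from brute-force path walks
    over the weighted adjacency (independent of any NJ code).
    """
    labels = [f"T{i:02d}" for i in range(n)]
    adj: dict[str, list[tuple[str, float]]] = {l: [] for l in labels}
    clusters = list(labels)
    nxt = 0
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), 2, replace=False))
        a, b = clusters[i], clusters[j]
        new = f"I{nxt}"
        nxt += 1
        adj[new] = []
        for child in (a, b):
            w = float(rng.uniform(min_len, max_len))
            adj[new].append((child, w))
            adj[child].append((new, w))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(new)
    d = pd.DataFrame(0.0, index=labels, columns=labels)
    for src in labels:
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for dst in labels:
            d.loc[src, dst] = dist[dst]
    d = (d + d.T) / 2.0  # exact symmetry despite float summation order
    return d, adj


class TestJukesCantor:
    def test_identical_sequences_zero(self):
        d = jc_distance_matrix({"a": "ACGTACGT", "b": "ACGTACGT"})
        assert d.loc["a", "b"] == 0.0

    def test_closed_form_ten_percent(self, rng):
        s1 = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 100)])
        s2 = list(s1)
        for i in range(10):
            s2[i * 10] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s2[i * 10]]
        d = jc_distance_matrix({"a": s1, "b": "".join(s2)})
        expected = -0.75 * np.log(1 - 4 * 0.1 / 3)
        assert d.loc["a", "b"] == pytest.approx(expected, abs=1e-9)
        assert d.loc["a", "b"] == pytest.approx(0.10732, abs=1e-4)

    def test_gap_columns_excluded_pairwise(self):
        d = jc_distance_matrix({"a": "ACGT-CGT", "b": "ACGTAC-T"})
        # comparable columns: 0..3, 5 (b gap at 6, a gap at 4); all equal
        assert d.loc["a", "b"] == 0.0

    def test_saturation_capped(self):
        d = jc_distance_matrix({"a": "AAAA", "b": "CCCC"})
        assert d.loc["a", "b"] == JC_MAX

    def test_no_comparable_columns_errors(self):
        with pytest.raises(ValueError):
            jc_distance_matrix({"a": "AC--", "b": "--GT"})


class TestNeighborJoining:
    def test_two_taxa_single_edge(self):
        d = pd.DataFrame([[0, 0.4], [0.4, 0]], index=["a", "b"],
                         columns=["a", "b"])
        tree = neighbor_joining(d)
        pat = patristic_distances(tree)
        assert pat.loc["a", "b"] == pytest.approx(0.4)

    def test_single_taxon_errors(self):
        d = pd.DataFrame([[0.0]], index=["a"], columns=["a"])
        with pytest.raises(ValueError):
            neighbor_joining(d)

    def test_four_taxon_additive_round_trip(self, rng):
        d, _ = random_tree_matrix(rng, 4)
        pat = patristic_distances(neighbor_joining(d))
        pat = pat.loc[d.index, d.columns]
        assert np.allclose(pat.to_numpy(), d.to_numpy(), atol=1e-9)

    def test_round_trip_random_trees(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 13))
            d, _ = random_tree_matrix(rng, n)
            pat = patristic_distances(neighbor_joining(d))
            pat = pat.loc[d.index, d.columns]
            assert np.allclose(pat.to_numpy(), d.to_numpy(), atol=1e-9)

    def test_matches_scikit_bio_on_additive_matrix(self, rng):
        """Independent-implementation cross-check on an additive matrix."""
        import io

        from skbio import DistanceMatrix, TreeNode
        from skbio.tree import nj as skbio_nj

        d, _ = random_tree_matrix(rng, 8)
        ours = patristic_distances(neighbor_joining(d))
        sk_tree = skbio_nj(DistanceMatrix(d.to_numpy(), ids=list(d.index)))
        for a, b in itertools.combinations(d.index, 2):
            sk_dist = sk_tree.find(a).distance(sk_tree.find(b))
            assert ours.loc[a, b] == pytest.approx(sk_dist, abs=1e-8)

    def test_tie_break_is_deterministic(self):
        labels = list("dcba")
        d = pd.DataFrame(1.0, index=labels, columns=labels)
        np.fill_diagonal(d.values, 0.0)
        t1 = neighbor_joining(d).as_string(schema="newick")
        d2 = d.loc[list("abcd"), list("abcd")]
        t2 = neighbor_joining(d2).as_string(schema="newick")
        assert t1 == t2

    def test_star_tree_from_equidistant_taxa(self):
        labels = list("abcd")
        d = pd.DataFrame(1.0, index=labels, columns=labels)
        np.fill_diagonal(d.values, 0.0)
        pat = patristic_distances(neighbor_joining(d))
        for a, b in itertools.combinations(labels, 2):
            assert pat.loc[a, b] == pytest.approx(1.0)


class TestPatristic:
    def test_matches_brute_force_paths(self, rng):
        d, _ = random_tree_matrix(rng, 9)
        tree = neighbor_joining(d)
        pat = patristic_distances(tree)
        # oracle: walk the dendropy tree edges explicitly leaf-to-leaf
        leaves = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}

        def path_length(a, b):
            anc_a = {}
            node, acc = leaves[a], 0.0
            while node is not None:
                anc_a[id(node)] = acc
                acc += node.edge.length or 0.0
                node = node.parent_node
            node, acc = leaves[b], 0.0
            while id(node) not in anc_a:
                acc += node.edge.length or 0.0
                node = node.parent_node
            return acc + anc_a[id(node)]

        for a, b in itertools.combinations(pat.index, 2):
            assert pat.loc[a, b] == pytest.approx(path_length(a, b), abs=1e-10)

    def test_zero_diagonal_and_symmetry(self, rng):
        d, _ = random_tree_matrix(rng, 6)
        pat = patristic_distances(neighbor_joining(d))
        assert np.allclose(np.diag(pat.to_numpy()), 0.0)
        assert np.allclose(pat.to_numpy(), pat.to_numpy().T)


@pytest.fixture
def toy_distances(rng):
    d, _ = random_tree_matrix(rng, 8)
    return d


class TestMpdComdist:
    def test_pair_is_their_distance(self, toy_distances):
        d = toy_distances
        a, b = d.index[0], d.index[3]
        assert mpd({a, b}, d) == pytest.approx(d.loc[a, b])

    def test_singleton_sample_is_missing(self, toy_distances):
        assert mpd({toy_distances.index[0]}, toy_distances) is None

    def test_unknown_taxon_errors(self, toy_distances):
        with pytest.raises(KeyError):
            mpd({"nope", toy_distances.index[0]}, toy_distances)

    def test_mpd_matches_brute_force(self, toy_distances, rng):
        d = toy_distances
        taxa = list(rng.choice(d.index, 6, replace=False))
        pairs = list(itertools.combinations(taxa, 2))
        manual = np.mean([d.loc[a, b] for a, b in pairs])
        assert mpd(set(taxa), d) == pytest.approx(manual)
        assert len(pairs) == 15

    def test_comdist_cross_pairs_and_symmetry(self, toy_distances, rng):
        d = toy_distances
        a = set(rng.choice(d.index, 3, replace=False))
        b = set(rng.choice(d.index, 4, replace=False))
        manual = np.mean([d.loc[x, y] for x in sorted(a) for y in sorted(b)])
        assert comdist(a, b, d) == pytest.approx(manual)
        assert comdist(a, b, d) == pytest.approx(comdist(b, a, d))

    def test_comdist_self_single_taxon_zero(self, toy_distances):
        x = toy_distances.index[0]
        assert comdist({x}, {x}, toy_distances) == 0.0

    def test_comdist_matrix_shape(self, toy_distances):
        d = toy_distances
        m = comdist_matrix({"A": set(d.index[:3]), "B": set(d.index[3:6])}, d)
        assert np.allclose(np.diag(m.to_numpy()), 0.0)
        assert m.loc["A", "B"] == pytest.approx(m.loc["B", "A"])


class TestSesMpd:
    def test_sample_equals_pool_is_degenerate(self, toy_distances):
        pool = list(toy_distances.index)
        r = ses_mpd(set(pool), toy_distances, pool, n_reps=99, seed=0)
        assert r.degenerate and r.z is None and not r.significant

    def test_null_moments_match_exhaustive_enumeration(self, toy_distances):
        d = toy_distances
        pool = list(d.index[:4])
        sample = set(d.index[:2])
        r = ses_mpd(sample, d, pool, n_reps=999, seed=3)
        exact_mean, exact_sd = exhaustive_mpd_null(2, d, pool)
        mc_se = exact_sd / np.sqrt(r.n_reps)
        assert r.null_mean == pytest.approx(exact_mean, abs=3 * mc_se)
        # SD of SD estimate ~ sd/sqrt(2(n-1))
        assert r.null_sd == pytest.approx(
            exact_sd, abs=3 * exact_sd / np.sqrt(2 * (r.n_reps - 1)))

    def test_seeded_determinism(self, toy_distances):
        d = toy_distances
        pool = list(d.index)
        sample = set(d.index[:4])
        r1 = ses_mpd(sample, d, pool, n_reps=199, seed=11)
        r2 = ses_mpd(sample, d, pool, n_reps=199, seed=11)
        assert (r1.observed, r1.null_mean, r1.null_sd, r1.z) == \
               (r2.observed, r2.null_mean, r2.null_sd, r2.z)

    def test_null_rejection_rate_is_calibrated(self, rng):
        """Samples drawn from the null pool reject at ~the nominal 5% level."""
        d, _ = random_tree_matrix(rng, 24)
        pool = list(d.index)
        rejections = 0
        n_sim = 500
        for i in range(n_sim):
            k = int(rng.integers(3, 10))
            sample = set(rng.choice(pool, k, replace=False))
            r = ses_mpd(sample, d, pool, n_reps=999,
                        seed=int(rng.integers(2 ** 31)))
            rejections += bool(r.significant)
        assert 0.03 <= rejections / n_sim <= 0.08

    def test_pool_smaller_than_sample_errors(self, toy_distances):
        d = toy_distances
        with pytest.raises(ValueError):
            ses_mpd(set(d.index[:4]), d, list(d.index[:3]), n_reps=9, seed=0)
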