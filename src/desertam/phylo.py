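"""Phylogenetic community structure: Jukes-Cantor distances over aligned VT
type sequences, a deterministic neighbor-joining tree, patristic distances,
and presence-absence mpd / comdist with standardized effect sizes (ses.mpd)
against configurable taxon pools.

Negative ses.mpd Z values indicate phylogenetic clustering — member taxa are
more closely related than a uniform random draw of the same number of taxa
from the pool.
"""

from __future__ import annotations

import itertools
from typing import Mapping, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from .nullmodels import NullTestResult, random_subsets, summarize_null

#: finite stand-in distance when the observed p-distance saturates (p >= 0.75)
JC_MAX = 10.0


def jc_distance_matrix(seqs: Mapping[str, str]) -> pd.DataFrame:
    """Jukes-Cantor distance matrix from equal-length aligned sequences.

    Sites where either sequence has a gap or an uncalled base are excluded
    pairwise. d = -(3/4) ln(1 - (4/3) p); saturated pairs (p >= 0.75) are
    capped at ``JC_MAX``.
    """
    labels = list(seqs)
    arrs = {}
    length = None
    for lab in labels:
        s = seqs[lab].upper()
        if length is None:
            length = len(s)
        elif len(s) != length:
            raise ValueError(f"sequence {lab} length {len(s)} != {length}")
        arrs[lab] = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    valid = {lab: np.isin(arrs[lab], np.frombuffer(b"ACGT", dtype=np.uint8))
             for lab in labels}
    n = len(labels)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        a, b = labels[i], labels[j]
        ok = valid[a] & valid[b]
        m = int(ok.sum())
        if m == 0:
            raise ValueError(f"no comparable columns between {a} and {b}")
        p = float(np.mean(arrs[a][ok] != arrs[b][ok]))
        if p >= 0.75:
            dist = JC_MAX
        elif p == 0.0:
            dist = 0.0
        else:
            dist = -0.75 * np.log1p(-4.0 * p / 3.0)
        d[i, j] = d[j, i] = dist
    return pd.DataFrame(d, index=labels, columns=labels)


def neighbor_joining(d: pd.DataFrame) -> dendropy.Tree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q matrix are resolved by joining the pair whose
    (lexicographically smallest member label, then largest) sorts first,
    where a cluster is labelled by its smallest leaf label. Negative branch
    length estimates are clamped to zero with the deficit moved to the sister
    branch, preserving the joined pair's summed length.
    """
    labels = [str(x) for x in d.index]
    if list(d.columns.astype(str)) != labels:
        raise ValueError("distance matrix rows and columns must match")
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    D = d.to_numpy(dtype=float, copy=True)
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")

    tns = dendropy.TaxonNamespace(labels)
    nodes = []
    for lab in labels:
        node = dendropy.Node(taxon=tns.get_taxon(lab))
        nodes.append(node)
    reps = list(labels)  # representative (smallest) leaf label per cluster
    active = list(range(n))

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    if n == 2:
        root = dendropy.Node()
        for idx, half in ((0, D[0, 1] / 2.0), (1, D[0, 1] / 2.0)):
            root.add_child(nodes[idx])
            nodes[idx].edge.length = half
        tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
        tree.is_rooted = False
        return tree

    while len(active) > 3:
        r = len(active)
        sub = D[np.ix_(active, active)]
        rowsums = sub.sum(axis=1)
        q = (r - 2) * sub - rowsums[:, None] - rowsums[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        best: Optional[tuple[str, str, int, int]] = None
        for a, b in zip(*np.nonzero(np.isclose(q, qmin, rtol=0, atol=1e-12))):
            if a >= b:
                continue
            ra, rb = reps[active[a]], reps[active[b]]
            key = (min(ra, rb), max(ra, rb))
            if best is None or key < (best[0], best[1]):
                best = (*key, a, b)
        assert best is not None
        a, b = best[2], best[3]
        if reps[active[b]] < reps[active[a]]:  # children in label order
            a, b = b, a
        ia, ib = active[a], active[b]
        dij = sub[a, b]
        li = dij / 2.0 + (rowsums[a] - rowsums[b]) / (2.0 * (r - 2))
        lj = dij - li
        li, lj = clamp(li, lj)
        parent = dendropy.Node()
        parent.add_child(nodes[ia])
        nodes[ia].edge.length = li
        parent.add_child(nodes[ib])
        nodes[ib].edge.length = lj
        # distances from the new node to every other active cluster
        new_d = 0.5 * (D[ia, :] + D[ib, :] - dij)
        D = np.vstack([D, new_d])
        new_col = np.append(new_d, 0.0)
        D = np.hstack([D, new_col[:, None]])
        nodes.append(parent)
        reps.append(min(reps[ia], reps[ib]))
        k = len(nodes) - 1
        active = [x for x in active if x not in (ia, ib)] + [k]

    root = dendropy.Node()
    active.sort(key=lambda x: reps[x])
    if len(active) == 3:
        i, j, k = active
        li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
        lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
        lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        for idx, ln in ((i, li), (j, lj), (k, lk)):
            root.add_child(nodes[idx])
            nodes[idx].edge.length = max(ln, 0.0)
    else:  # two clusters left (possible when n == 3 never, guard anyway)
        i, j = active
        root.add_child(nodes[i])
        nodes[i].edge.length = D[i, j] / 2.0
        root.add_child(nodes[j])
        nodes[j].edge.length = D[i, j] / 2.0
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return tree


def patristic_distances(tree: dendropy.Tree) -> pd.DataFrame:
    """Leaf-to-leaf path-length (patristic) distance matrix."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return pd.DataFrame(d, index=labels, columns=labels)


def mpd(sample_taxa, d: pd.DataFrame) -> Optional[float]:
    """Unweighted mean pairwise distance among a sample's taxa.

    Returns None (missing) for samples with fewer than two taxa — a single
    taxon has no pairs, which is different from being at distance zero.
    """
    taxa = sorted(set(sample_taxa))
    missing = [t for t in taxa if t not in d.index]
    if missing:
        raise KeyError(f"taxa not in distance matrix: {missing}")
    if len(taxa) < 2:
        return None
    sub = d.loc[taxa, taxa].to_numpy()
    k = len(taxa)
    return float(sub.sum() / (k * (k - 1)))


def comdist(sample_a, sample_b, d: pd.DataFrame) -> float:
    """Mean patristic distance over all cross pairs of two samples."""
    a = sorted(set(sample_a))
    b = sorted(set(sample_b))
    if not a or not b:
        raise ValueError("comdist requires two non-empty samples")
    missing = [t for t in a + b if t not in d.index]
    if missing:
        raise KeyError(f"taxa not in distance matrix: {missing}")
    return float(d.loc[a, b].to_numpy().mean())


def comdist_matrix(site_taxa: Mapping[str, set], d: pd.DataFrame) -> pd.DataFrame:
    """Between-sample phylogenetic distance matrix (zero diagonal)."""
    sites = list(site_taxa)
    m = np.zeros((len(sites), len(sites)))
    for i, j in itertools.combinations(range(len(sites)), 2):
        m[i, j] = m[j, i] = comdist(site_taxa[sites[i]], site_taxa[sites[j]], d)
    return pd.DataFrame(m, index=sites, columns=sites)


def ses_mpd(sample_taxa, d: pd.DataFrame, pool: Sequence[str],
            n_reps: int = 999, seed: int | None = None,
            z_crit: float = 1.96, sample_name: str = "",
            pool_scale: str = "global") -> NullTestResult:
    """Standardized effect size of mpd vs uniform draws from a taxon pool.

    Null communities are uniform random subsets of the pool with the observed
    richness, drawn without replacement; negative Z indicates clustering.
    """
    taxa = sorted(set(sample_taxa))
    pool = sorted(set(pool))
    if len(pool) < len(taxa):
        raise ValueError(f"pool ({len(pool)}) smaller than sample ({len(taxa)})")
    obs = mpd(taxa, d)
    if obs is None:
        raise ValueError("mpd undefined for samples with < 2 taxa")
    rng = np.random.default_rng(seed)
    dpool = d.loc[pool, pool].to_numpy()
    k = len(taxa)
    idx = random_subsets(rng, len(pool), k, n_reps)
    sub = dpool[idx[:, :, None], idx[:, None, :]]  # (n_reps, k, k)
    null = sub.sum(axis=(1, 2)) / (k * (k - 1))
    return summarize_null(sample_name, "mpd", obs, null, pool_scale, z_crit)


def exhaustive_mpd_null(sample_size: int, d: pd.DataFrame,
                        pool: Sequence[str]) -> tuple[float, float]:
    """Exact null mean/SD of mpd over every subset of the pool (small pools)."""
    pool = sorted(set(pool))
    vals = [mpd(subset, d)
            for subset in itertools.combinations(pool, sample_size)]
    arr = np.array(vals, dtype=float)
    # the enumeration IS the null distribution: population SD (ddof=0)
    return float(arr.mean()), float(arr.std(ddof=0))


def results_table(results: Sequence[NullTestResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "sample": r.sample, "statistic": r.statistic_name,
        "observed": r.observed, "null_mean": r.null_mean,
        "null_sd": r.null_sd, "z": np.nan if r.z is None else r.z,
        "n_reps": r.n_reps, "pool_scale": r.pool_scale,
        "significant": r.significant, "degenerate": r.degenerate,
    } for r in results])
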