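"""Ordination of community dissimilarities: Jaccard distances, principal
coordinates analysis (PCoA), non-metric multidimensional scaling (NMDS), and
permutation-tested environmental vector fitting (envfit).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import MDS

from .assign import CommunityTable


@dataclass
class Ordination:
    samples: list[str]
    scores: np.ndarray  # samples x axes
    method: str  # "pcoa" | "nmds"
    eigenvalues: Optional[np.ndarray] = None  # pcoa
    stress: Optional[float] = None  # nmds (Kruskal stress-1)
    converged: bool = True

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"axis{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=self.samples, columns=cols)


@dataclass
class EnvFitResult:
    variable: str
    direction: np.ndarray  # unit-norm cosines per axis
    r2: float
    p: float


def _check_dissimilarity(d: pd.DataFrame) -> np.ndarray:
    m = d.to_numpy(dtype=float)
    if m.shape[0] != m.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError("dissimilarity matrix must be symmetric")
    return m


def jaccard_matrix(table: CommunityTable) -> pd.DataFrame:
    """Jaccard dissimilarity 1 - |A∩B|/|A∪B| on presence/absence.

    Two samples with no taxa at all are at distance 0 by convention.
    """
    if len(table.sites) < 2:
        raise ValueError("need at least 2 samples")
    x = table.presence().to_numpy(bool)
    d = squareform(pdist(x, metric="jaccard"))
    return pd.DataFrame(d, index=table.sites, columns=table.sites)


def pcoa(d: pd.DataFrame, k: int = 2) -> Ordination:
    """Classical (Gower) principal coordinates analysis.

    The squared dissimilarity matrix is double-centred and
    eigendecomposed; scores are eigenvectors scaled by the square root of
    their (non-negative) eigenvalues. All eigenvalues — including negative
    ones arising from non-Euclidean dissimilarities — are reported
    unmodified; axes with non-positive eigenvalues get zero scores.
    """
    m = _check_dissimilarity(d)
    n = m.shape[0]
    if k >= n:
        raise ValueError(f"k must be < number of samples ({n})")
    a = -0.5 * m ** 2
    centerer = np.eye(n) - np.ones((n, n)) / n
    g = centerer @ a @ centerer
    eigval, eigvec = np.linalg.eigh((g + g.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    lead = np.clip(eigval[:k], 0.0, None)
    lead[lead < np.abs(eigval).max() * 1e-12] = 0.0  # numerical-noise axes
    scale = np.sqrt(lead)
    scores = eigvec[:, :k] * scale
    return Ordination(samples=list(d.index), scores=scores, method="pcoa",
                      eigenvalues=eigval)


def nmds(d: pd.DataFrame, k: int = 2, n_starts: int = 4,
         seed: int | None = None, max_iter: int = 300) -> Ordination:
    """Non-metric MDS minimizing Kruskal stress-1.

    Configuration distances are monotonically (isotonic) regressed on the
    input dissimilarities; the best of a PCoA start plus ``n_starts - 1``
    seeded random starts is returned.
    """
    if k < 1 or n_starts < 1:
        raise ValueError("k and n_starts must be >= 1")
    m = _check_dissimilarity(d)
    n = m.shape[0]
    if n <= 2:
        scores = np.zeros((n, k))
        if n == 2:
            scores[0, 0], scores[1, 0] = -m[0, 1] / 2.0, m[0, 1] / 2.0
        return Ordination(samples=list(d.index), scores=scores,
                          method="nmds", stress=0.0)
    rng = np.random.default_rng(seed)
    inits: list[Optional[np.ndarray]] = [pcoa(d, k=min(k, n - 1)).scores]
    if inits[0].shape[1] < k:  # pad if k exceeded available axes
        pad = np.zeros((n, k - inits[0].shape[1]))
        inits[0] = np.hstack([inits[0], pad])
    for _ in range(n_starts - 1):
        inits.append(rng.normal(size=(n, k)))
    best_scores, best_stress = None, np.inf
    for init in inits:
        mds = MDS(n_components=k, metric_mds=False, metric="precomputed",
                  n_init=1, init="random", max_iter=max_iter, eps=1e-6,
                  normalized_stress=True,
                  random_state=int(rng.integers(2 ** 31)))
        scores = mds.fit_transform(m, init=init)
        if mds.stress_ < best_stress:
            best_stress = float(mds.stress_)
            best_scores = scores
            n_iter = mds.n_iter_
    return Ordination(samples=list(d.index), scores=best_scores,
                      method="nmds", stress=best_stress,
                      converged=n_iter < max_iter)


def envfit(ord: Ordination, env: pd.DataFrame, n_perm: int = 999,
           seed: int | None = None) -> list[EnvFitResult]:
    """Fit each numeric environmental variable onto the ordination axes.

    Per variable, an OLS fit of the (centred) variable on the score axes
    gives r2 = explained variance fraction and a unit direction vector; the
    permutation p-value uses the add-one convention
    p = (1 + #{permuted r2 >= observed}) / (n_perm + 1).
    """
    missing = [s for s in ord.samples if s not in env.index]
    if missing:
        raise KeyError(f"samples missing from env table: {missing}")
    x = ord.scores - ord.scores.mean(axis=0)
    q, _ = np.linalg.qr(x)
    rng = np.random.default_rng(seed)
    results = []
    n = x.shape[0]
    for var in env.columns:
        y = env.loc[ord.samples, var].to_numpy(dtype=float)
        yc = y - y.mean()
        ss_tot = float(yc @ yc)
        if ss_tot <= 0:
            results.append(EnvFitResult(var, np.zeros(x.shape[1]), 0.0, 1.0))
            continue
        coefs, *_ = np.linalg.lstsq(x, yc, rcond=None)
        norm = np.linalg.norm(coefs)
        direction = coefs / norm if norm > 0 else coefs
        r2 = float((q.T @ yc) @ (q.T @ yc) / ss_tot)
        count = 0
        for _ in range(n_perm):
            yp = yc[rng.permutation(n)]
            r2p = float((q.T @ yp) @ (q.T @ yp) / ss_tot)
            if r2p >= r2:
                count += 1
        p = (1.0 + count) / (n_perm + 1.0)
        results.append(EnvFitResult(var, direction, min(r2, 1.0), p))
    return results


def envfit_table(results: Sequence[EnvFitResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"variable": r.variable, "r2": r.r2, "p": r.p}
        for i, c in enumerate(r.direction):
            row[f"axis{i + 1}"] = c
        rows.append(row)
    return pd.DataFrame(rows)
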