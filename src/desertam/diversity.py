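"""Per-site diversity: analytic rarefaction, Hill numbers of order 0/1/2,
asymptotic (Chao1 and Chao-Jost) estimators, and a multinomial bootstrap for
standard errors and confidence limits.

Hill numbers are effective numbers of species: q=0 observed richness, q=1 the
exponential of Shannon entropy, q=2 the inverse Simpson concentration. The
asymptotic estimators extrapolate each to full sample coverage from the
sample's rare-species frequencies (singletons f1 and doubletons f2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .assign import CommunityTable


@dataclass
class AbundanceVector:
    site: str
    counts: np.ndarray  # positive integers, one per VT present

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.counts = self.counts[self.counts > 0]
        if self.counts.size == 0:
            raise ValueError(f"site {self.site!r} has no reads")

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass
class DiversityEstimate:
    site: str
    order_q: int
    observed: float
    estimated: float
    se: float
    lcl: float
    ucl: float


def abundance_vectors(table: CommunityTable) -> list[AbundanceVector]:
    return [AbundanceVector(site, table.counts.loc[site].to_numpy())
            for site in table.sites]


def rarefaction_curve(v: AbundanceVector, depths) -> np.ndarray:
    """Expected richness E[S_m] in a uniform subsample of m reads.

    Hypergeometric (without replacement) expectation:
    E[S_m] = sum_i [1 - C(n - n_i, m) / C(n, m)].
    """
    n = v.n
    counts = v.counts
    out = np.empty(len(depths), dtype=float)
    for k, m in enumerate(depths):
        m = int(m)
        if m < 0 or m > n:
            raise ValueError(f"depth {m} outside [0, {n}]")
        # log C(n-ni, m) - log C(n, m); zero probability when n-ni < m
        nm = n - counts
        with np.errstate(invalid="ignore"):
            logratio = (gammaln(nm + 1) - gammaln(nm - m + 1)
                        - gammaln(n + 1) + gammaln(n - m + 1))
        p_absent = np.where(nm >= m, np.exp(logratio), 0.0)
        out[k] = float(np.sum(1.0 - p_absent))
    return out


def hill_observed(v: AbundanceVector, q: int) -> float:
    """Observed Hill number of order q in {0, 1, 2}."""
    if q not in (0, 1, 2):
        raise ValueError("q must be 0, 1 or 2")
    p = v.counts / v.n
    if q == 0:
        return float(len(p))
    if q == 1:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(1.0 / np.sum(p ** 2))


def _f(v: AbundanceVector, k: int) -> int:
    return int(np.sum(v.counts == k))


def chao1(v: AbundanceVector) -> float:
    """Chao1 asymptotic richness: S_obs + f1^2/(2 f2), bias-corrected
    S_obs + f1(f1-1)/(2(f2+1)) when there are no doubletons."""
    s_obs = len(v.counts)
    f1, f2 = _f(v, 1), _f(v, 2)
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0 / (f2 + 1.0)


def _chao_jost_shannon(v: AbundanceVector) -> float:
    """Chao-Jost asymptotic estimator of exp(Shannon entropy)."""
    n = v.n
    x = v.counts
    # sum over observed species of (x/n) * sum_{k=x}^{n-1} 1/k
    harm = np.concatenate(([0.0], np.cumsum(1.0 / np.arange(1, n + 1))))
    # sum_{k=x}^{n-1} 1/k = H(n-1) - H(x-1)
    part1 = np.sum((x / n) * (harm[n - 1] - harm[x - 1]))
    f1, f2 = _f(v, 1), _f(v, 2)
    if f1 == 0:
        return float(np.exp(part1))
    if f2 > 0:
        A = 2.0 * f2 / ((n - 1.0) * f1 + 2.0 * f2)
    elif f1 > 1:
        A = 2.0 / ((n - 1.0) * (f1 - 1.0) + 2.0)
    else:
        A = 1.0
    if A < 1.0:
        r = np.arange(1, n)
        correction = (f1 / n) * (1.0 - A) ** (1 - n) * (
            -np.log(A) - np.sum((1.0 - A) ** r / r))
    else:
        correction = 0.0
    return float(np.exp(part1 + correction))


def _asymptotic_simpson(v: AbundanceVector) -> float:
    """Asymptotic inverse Simpson (minimum-variance unbiased concentration)."""
    n = v.n
    x = v.counts
    denom = np.sum(x * (x - 1.0)) / (n * (n - 1.0))
    if denom <= 0:  # all singletons: concentration estimate degenerates
        return hill_observed(v, 2)
    return float(1.0 / denom)


def hill_asymptotic(v: AbundanceVector, q: int) -> float:
    """Asymptotic Hill number of order q (Chao1 / Chao-Jost estimators)."""
    if q not in (0, 1, 2):
        raise ValueError("q must be 0, 1 or 2")
    if v.n < 2:
        raise ValueError("need at least 2 reads to extrapolate")
    if q == 0:
        return chao1(v)
    if q == 1:
        return _chao_jost_shannon(v)
    return _asymptotic_simpson(v)


def bootstrap_ci(v: AbundanceVector, q: int, B: int = 200,
                 seed: int | None = None, estimator: str = "asymptotic"
                 ) -> tuple[float, float, float]:
    """Multinomial bootstrap (se, lcl, ucl) for a Hill estimate.

    Resamples n reads from the observed relative abundances B times,
    recomputes the estimator, and reports the bootstrap SD with 95%
    normal-approximation limits. For q=0 the lower limit is floored at the
    observed richness (the estimand cannot fall below what was seen).
    """
    if B < 50:
        raise ValueError("B must be >= 50")
    if estimator not in ("asymptotic", "observed"):
        raise ValueError("estimator must be 'asymptotic' or 'observed'")
    fn = hill_asymptotic if estimator == "asymptotic" else hill_observed
    rng = np.random.default_rng(seed)
    p = v.counts / v.n
    draws = rng.multinomial(v.n, p, size=B)
    vals = np.empty(B)
    for b in range(B):
        counts = draws[b][draws[b] > 0]
        vals[b] = fn(AbundanceVector(v.site, counts), q)
    se = float(np.std(vals, ddof=1))
    center = fn(v, q)
    lcl = center - 1.96 * se
    ucl = center + 1.96 * se
    if q == 0:
        lcl = max(lcl, hill_observed(v, 0))
    return se, lcl, ucl


def diversity_table(table: CommunityTable, B: int = 200, seed: int = 0
                    ) -> list[DiversityEstimate]:
    """Observed and asymptotic Hill diversity with bootstrap CIs per site."""
    out = []
    for i, v in enumerate(abundance_vectors(table)):
        for q in (0, 1, 2):
            obs = hill_observed(v, q)
            if v.n >= 2:
                est = hill_asymptotic(v, q)
                se, lcl, ucl = bootstrap_ci(v, q, B=B, seed=seed + 7919 * i + q)
            else:
                est, se, lcl, ucl = obs, 0.0, obs, obs
            out.append(DiversityEstimate(v.site, q, obs, est, se, lcl, ucl))
    return out
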