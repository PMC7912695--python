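"""Shared machinery for randomization (null-model) tests.

A null community is a uniform random subset of the taxon pool with the same
richness as the observed community; the test statistic's null distribution is
summarized by its mean and SD, and the observed value is expressed as
Z = (observed - null mean) / null SD. |Z| beyond a critical value (1.96 by
default, the two-sided 5% normal point) is called significant. When the null
distribution has zero spread the test is degenerate and no Z is reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np


@dataclass
class NullTestResult:
    sample: str
    statistic_name: str
    observed: float
    null_mean: float
    null_sd: float
    z: Optional[float]
    n_reps: int
    pool_scale: str
    significant: bool
    degenerate: bool = False


def random_subsets(rng: np.random.Generator, pool_size: int, k: int,
                   n_reps: int) -> np.ndarray:
    """(n_reps, k) index matrix of uniform subsets without replacement."""
    if k > pool_size:
        raise ValueError(f"subset size {k} exceeds pool size {pool_size}")
    # argsort of uniforms = random permutation per row; take first k
    u = rng.random((n_reps, pool_size))
    return np.argpartition(u, k - 1, axis=1)[:, :k]


def summarize_null(sample: str, statistic_name: str, observed: float,
                   null_values: np.ndarray, pool_scale: str,
                   z_crit: float = 1.96) -> NullTestResult:
    """Build a NullTestResult from observed value + simulated null values.

    The null SD uses the sample SD of the replicate values (ddof=1); the
    observed community is not pooled into the null distribution.
    """
    null_values = np.asarray(null_values, dtype=float)
    mean = float(np.mean(null_values))
    sd = float(np.std(null_values, ddof=1))
    # an SD at floating-point-noise level means every null draw was
    # (numerically) identical: the test is degenerate, not astronomically
    # significant
    if sd <= max(1e-12, 1e-9 * abs(mean)) or not math.isfinite(sd):
        return NullTestResult(sample, statistic_name, observed, mean, sd,
                              None, len(null_values), pool_scale,
                              significant=False, degenerate=True)
    z = (observed - mean) / sd
    return NullTestResult(sample, statistic_name, observed, mean, sd, z,
                          len(null_values), pool_scale,
                          significant=abs(z) > z_crit)
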