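"""Habitat (desert) affiliation analysis.

Each virtual taxon gets an aridity index: the fraction of its reference
database records originating from the "deserts and xeric shrublands" biome.
A community's aridity is the unweighted mean index over its member taxa.
Whether a community holds more desert-affiliated taxa than expected is tested
by comparing the observed mean against uniform random communities of equal
richness drawn (without replacement) from a taxon pool — globally, or only
taxa previously recorded in the sample's continent or biogeographic realm.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .assign import VTReference
from .nullmodels import NullTestResult, random_subsets, summarize_null

#: biome label whose records define desert affiliation
DESERT_BIOME = "deserts and xeric shrublands"

SCALES = ("global", "continent", "realm")


@dataclass
class AridityIndex:
    vt_id: str
    value: Optional[float]  # None when the taxon has no records
    n_records: int

    @property
    def defined(self) -> bool:
        return self.value is not None


@dataclass
class CommunityAridity:
    sample: str
    value: float
    n_vt: int


@dataclass
class PoolSpec:
    scale: str  # global | continent | realm
    members: frozenset[str]

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown pool scale {self.scale!r}")
        self.members = frozenset(self.members)


def aridity_index(vt: VTReference,
                  desert_labels: frozenset[str] = frozenset({DESERT_BIOME})
                  ) -> AridityIndex:
    """Fraction of a taxon's biome records carrying a desert label."""
    if not desert_labels:
        raise ValueError("desert_labels must be non-empty")
    n = len(vt.biome_records)
    if n == 0:
        return AridityIndex(vt.vt_id, None, 0)
    hits = sum(1 for b in vt.biome_records if b in desert_labels)
    return AridityIndex(vt.vt_id, hits / n, n)


def aridity_indices(refs: Sequence[VTReference],
                    desert_labels: frozenset[str] = frozenset({DESERT_BIOME})
                    ) -> dict[str, AridityIndex]:
    return {r.vt_id: aridity_index(r, desert_labels) for r in refs}


def community_aridity(sample_taxa, indices: Mapping[str, AridityIndex],
                      sample_name: str = "") -> CommunityAridity:
    """Unweighted mean aridity index over member taxa with defined indices."""
    taxa = sorted(set(sample_taxa))
    if not taxa:
        raise ValueError("sample must be non-empty")
    vals = [indices[t].value for t in taxa
            if t in indices and indices[t].defined]
    if not vals:
        raise ValueError(
            f"no member of sample {sample_name!r} has a defined aridity index")
    return CommunityAridity(sample_name, float(np.mean(vals)), len(vals))


def aridity_null_test(sample_taxa, indices: Mapping[str, AridityIndex],
                      pool: PoolSpec, n_reps: int = 999,
                      seed: int | None = None, z_crit: float = 1.96,
                      sample_name: str = "") -> NullTestResult:
    """Randomization test of community aridity against a taxon pool.

    Null communities are uniform size-n subsets of the pool's taxa with
    defined indices, n being the number of scored members of the observed
    community. Sample taxa absent from a sub-global pool still contribute to
    the observed mean; the pool only shapes the null distribution.
    """
    obs = community_aridity(sample_taxa, indices, sample_name)
    pool_vals = np.array([indices[t].value for t in sorted(pool.members)
                          if t in indices and indices[t].defined])
    if len(pool_vals) < obs.n_vt:
        raise ValueError(
            f"pool {pool.scale!r} has {len(pool_vals)} scorable taxa, "
            f"fewer than sample size {obs.n_vt}")
    rng = np.random.default_rng(seed)
    idx = random_subsets(rng, len(pool_vals), obs.n_vt, n_reps)
    null = pool_vals[idx].mean(axis=1)
    return summarize_null(sample_name, "community_aridity", obs.value, null,
                          pool.scale, z_crit)


def exhaustive_aridity_null(sample_size: int, indices: Mapping[str, AridityIndex],
                            pool: PoolSpec) -> tuple[float, float]:
    """Exact null mean/SD by enumerating all pool subsets (small pools)."""
    vals = np.array([indices[t].value for t in sorted(pool.members)
                     if t in indices and indices[t].defined])
    means = [np.mean(c) for c in itertools.combinations(vals, sample_size)]
    arr = np.array(means)
    # the enumeration IS the null distribution: population SD (ddof=0)
    return float(arr.mean()), float(arr.std(ddof=0))


def multi_scale_test(site_taxa: Mapping[str, set],
                     indices: Mapping[str, AridityIndex],
                     pools: Mapping[str, Mapping[str, PoolSpec]],
                     n_reps: int = 999, seed: int | None = None,
                     z_crit: float = 1.96) -> list[NullTestResult]:
    """Run the aridity null test for every site at every pool scale.

    ``pools[scale][site]`` gives the pool for one site at one scale (the
    global pool is typically shared across sites).
    """
    rng = np.random.default_rng(seed)
    results = []
    for scale in SCALES:
        if scale not in pools:
            raise ValueError(f"missing pool scale {scale!r}")
        for site, taxa in site_taxa.items():
            pool = pools[scale][site]
            results.append(aridity_null_test(
                taxa, indices, pool, n_reps=n_reps,
                seed=int(rng.integers(2 ** 31)), z_crit=z_crit,
                sample_name=site))
    return results


def count_significant(results: Sequence[NullTestResult], scale: str,
                      z_crit: float = 1.96) -> int:
    """Number of sites with z strictly above +z_crit at one pool scale.

    This is the directional (over-representation) count; the two-sided call
    is carried on each result's ``significant`` flag.
    """
    if scale not in {r.pool_scale for r in results}:
        raise ValueError(f"no results at scale {scale!r}")
    return sum(1 for r in results
               if r.pool_scale == scale and r.z is not None and r.z > z_crit)


def zscore_table(results: Sequence[NullTestResult],
                 z_crit: float = 1.96) -> pd.DataFrame:
    """Wide scales-by-sites table of Z values with significance stars."""
    sites = list(dict.fromkeys(r.sample for r in results))
    rows = {}
    for scale in SCALES:
        row = {}
        for site in sites:
            match = [r for r in results
                     if r.pool_scale == scale and r.sample == site]
            if not match:
                row[site] = ""
                continue
            r = match[0]
            if r.z is None:
                row[site] = "degenerate"
            else:
                star = "*" if abs(r.z) > z_crit else ""
                row[site] = f"{r.z:.3f}{star}"
        rows[scale] = row
    return pd.DataFrame(rows).T[sites]
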