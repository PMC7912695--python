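"""Synthetic data generator with known ground truth.

Emulates every input the pipeline consumes: a MaarjAM-like virtual-taxon
catalogue (type sequences evolved under JC69 along a Yule phylogeny, biome
records with controllable desert fractions, continent/realm occurrences,
cultured flags), site communities assembled with a tunable desert-affiliation
filter and optional clade restriction, and paired 2x300 bp amplicon reads
with primers, substitution errors, Phred qualities and planted processing
defects.

Sequences are evolved without indels so the emitted type sequences are
already aligned; multiple sequence alignment stays out of scope.
"""

from __future__ import annotations

import dataclasses
import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import dendropy
import numpy as np
import pandas as pd

from ._seq import IUPAC, revcomp
from .assign import CommunityTable, VTReference, write_reference
from .habitat import DESERT_BIOME, PoolSpec

#: paired (continent, biogeographic realm) labels a site can be placed in
REGIONS = (
    ("Africa", "Afrotropic"),
    ("Asia", "Palearctic"),
    ("Australia", "Australasian"),
    ("North America", "Nearctic"),
    ("South America", "Neotropic"),
)

OTHER_BIOMES = (
    "temperate grasslands",
    "tropical moist forest",
    "mediterranean woodlands",
    "montane grasslands",
    "temperate broadleaf forest",
)

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Study-shaped defaults: 6 desert sites, 50 VT, ~5000 reads per site."""

    n_vt: int = 50
    tree_model: str = "yule"
    birth_rate: float = 1.0
    seq_length: int = 500
    substitution_model: str = "JC69"
    #: mean root-to-tip path length, substitutions/site
    mutation_scale: float = 0.15
    #: pendant-edge floor keeping sister taxa resolvable at 97% identity
    min_pendant: float = 0.05
    n_sites: int = 6
    site_richness_range: tuple[int, int] = (3, 36)
    reads_per_site: int = 5000
    read_length: int = 300
    read_error_rate: float = 0.01
    quality_mean: float = 35.0
    quality_sd: float = 3.0
    low_quality_mean: float = 20.0
    #: desert-affiliation selection strength (weight ~ exp(beta * index))
    affiliation_beta: float = 8.0
    clustering_mode: str = "none"  # none | clade
    desert_label_fraction_range: tuple[float, float] = (0.0, 0.8)
    records_range: tuple[int, int] = (5, 40)
    cultured_p: float = 0.42
    continent_occupancy: float = 0.8
    realm_occupancy: float = 0.8
    primer_fail_rate: float = 0.02
    low_quality_rate: float = 0.05
    merge_fail_rate: float = 0.02
    fwd_primer: str = "CAGCCGCGGTAATTCCAGCT"     # WANDA
    rev_primer: str = "GAACCCAAACACTTTGGTTTCC"   # AML2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_vt < 4:
            raise ValueError("n_vt must be >= 4")
        if self.tree_model != "yule" or self.substitution_model != "JC69":
            raise ValueError("supported models: yule tree, JC69 substitutions")
        for name in ("birth_rate", "mutation_scale", "read_error_rate",
                     "primer_fail_rate", "low_quality_rate", "merge_fail_rate",
                     "affiliation_beta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.clustering_mode not in ("none", "clade"):
            raise ValueError("clustering_mode must be 'none' or 'clade'")


@dataclass
class GroundTruth:
    """What the generator planted, for recovery tests."""

    membership: dict[str, list[str]]          # site -> member VT
    true_counts: dict[str, dict[str, int]]    # site -> vt -> planted reads
    read_source: dict[str, str]               # read id -> source VT
    read_category: dict[str, str]             # read id -> good/primer/quality/overlap
    aridity: dict[str, float]                 # vt -> planted record fraction
    affiliation_beta: float
    clustering_mode: str
    clades: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


def _decode(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def simulate_tree(cfg: SimulationConfig) -> dendropy.Tree:
    """Yule tree over n_vt leaves, scaled to the configured mean depth."""
    from dendropy.simulate import treesim

    tree = treesim.birth_death_tree(
        birth_rate=cfg.birth_rate, death_rate=0.0,
        num_extant_tips=cfg.n_vt, rng=random.Random(cfg.seed + 101))
    # deterministic VT labels in leaf-traversal order
    width = len(str(cfg.n_vt))
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"VT{i + 1:0{width}d}"
    depths = [leaf.distance_from_root() for leaf in tree.leaf_node_iter()]
    mean_depth = float(np.mean(depths))
    scale = cfg.mutation_scale / mean_depth if mean_depth > 0 else 1.0
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scale
    if cfg.mutation_scale > 0:  # floor is meaningless in a zero-change model
        for leaf in tree.leaf_node_iter():
            if leaf.edge.length is not None and leaf.edge.length < cfg.min_pendant:
                leaf.edge.length = cfg.min_pendant
    return tree


def evolve_sequences(tree: dendropy.Tree, cfg: SimulationConfig,
                     rng: np.random.Generator) -> dict[str, str]:
    """JC69 sequence evolution from a uniform-random root, no indels."""
    L = cfg.seq_length
    root_seq = BASES[rng.integers(0, 4, size=L)]
    seqs_at: dict[int, np.ndarray] = {id(tree.seed_node): root_seq}
    out: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            seq = root_seq
        else:
            parent_seq = seqs_at[id(node.parent_node)]
            d = node.edge.length or 0.0
            p_change = 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))
            seq = parent_seq.copy()
            hit = rng.random(L) < p_change
            n_hit = int(hit.sum())
            if n_hit:
                # draw a different base uniformly among the other three
                shift = rng.integers(1, 4, size=n_hit).astype(np.uint8)
                idx = (np.searchsorted(BASES, seq[hit]) + shift) % 4
                seq[hit] = BASES[idx]
            seqs_at[id(node)] = seq
        if node.is_leaf():
            out[node.taxon.label] = _decode(seq)
    return out


def simulate_reference(cfg: SimulationConfig
                       ) -> tuple[list[VTReference], dendropy.Tree, dict[str, str]]:
    """Reference catalogue + phylogeny + (already aligned) type sequences."""
    rng = np.random.default_rng(cfg.seed)
    tree = simulate_tree(cfg)
    seqs = evolve_sequences(tree, cfg, rng)
    lo, hi = cfg.desert_label_fraction_range
    refs = []
    for vt in sorted(seqs):
        n_rec = int(rng.integers(cfg.records_range[0], cfg.records_range[1] + 1))
        theta = float(rng.uniform(lo, hi))
        n_desert = int(rng.binomial(n_rec, theta))
        others = [OTHER_BIOMES[i]
                  for i in rng.integers(0, len(OTHER_BIOMES), n_rec - n_desert)]
        continents = {c for c, _ in REGIONS
                      if rng.random() < cfg.continent_occupancy}
        if not continents:
            continents = {REGIONS[rng.integers(len(REGIONS))][0]}
        realms = {r for _, r in REGIONS if rng.random() < cfg.realm_occupancy}
        if not realms:
            realms = {REGIONS[rng.integers(len(REGIONS))][1]}
        refs.append(VTReference(
            vt_id=vt, type_seq=seqs[vt],
            biome_records=[DESERT_BIOME] * n_desert + others,
            continents=continents, realms=realms,
            cultured=bool(rng.random() < cfg.cultured_p)))
    return refs, tree, seqs


def _clade_leaves(tree: dendropy.Tree, rng: np.random.Generator,
                  n_vt: int) -> list[str]:
    """Pick a lineage of moderate size (>= 5 leaves, <= half the tree)."""
    target = max(5, n_vt // 3)
    candidates = []
    for node in tree.preorder_internal_node_iter():
        leaves = [lf.taxon.label for lf in node.leaf_iter()]
        if 5 <= len(leaves) <= max(5, n_vt // 2):
            candidates.append(leaves)
    if not candidates:  # tiny trees: fall back to the smallest cherry-side
        candidates = [[lf.taxon.label for lf in tree.leaf_node_iter()]]
    # prefer sizes near the target, break ties at random
    sizes = np.array([abs(len(c) - target) for c in candidates])
    best = np.flatnonzero(sizes == sizes.min())
    return sorted(candidates[int(rng.choice(best))])


def site_metadata(cfg: SimulationConfig, rng: np.random.Generator
                  ) -> pd.DataFrame:
    """Site labels with continent/realm placement and climate/soil variables."""
    sites = [f"D{i + 1}" for i in range(cfg.n_sites)]
    region_idx = rng.integers(0, len(REGIONS), size=cfg.n_sites)
    rows = []
    for s, ri in zip(sites, region_idx):
        continent, realm = REGIONS[ri]
        rows.append({
            "site": s, "continent": continent, "realm": realm,
            "MAT": round(float(rng.uniform(10.0, 26.0)), 1),
            "MAP": round(float(rng.uniform(100.0, 320.0)), 0),
            "pH": round(float(rng.uniform(4.9, 8.5)), 2),
            "P": round(float(rng.uniform(0.4, 61.0)), 2),
            "N": round(float(rng.uniform(0.03, 0.10)), 3),
            "C": round(float(rng.uniform(0.29, 0.62)), 2),
        })
    return pd.DataFrame(rows).set_index("site")


def build_pools(refs: list[VTReference], sites: pd.DataFrame
                ) -> dict[str, dict[str, PoolSpec]]:
    """Global/continent/realm pools per site from catalogue occurrences."""
    all_vt = frozenset(r.vt_id for r in refs)
    pools: dict[str, dict[str, PoolSpec]] = {"global": {}, "continent": {}, "realm": {}}
    for site, row in sites.iterrows():
        pools["global"][site] = PoolSpec("global", all_vt)
        pools["continent"][site] = PoolSpec(
            "continent",
            frozenset(r.vt_id for r in refs if row["continent"] in r.continents))
        pools["realm"][site] = PoolSpec(
            "realm",
            frozenset(r.vt_id for r in refs if row["realm"] in r.realms))
    return pools


def simulate_communities(refs: list[VTReference], tree: dendropy.Tree,
                         cfg: SimulationConfig, rng: np.random.Generator,
                         sites: pd.DataFrame,
                         pools: dict[str, dict[str, PoolSpec]]
                         ) -> tuple[dict[str, list[str]], CommunityTable,
                                    dict[str, list[str]]]:
    """Assemble site communities under desert-affiliation/clade filtering.

    Members are drawn without replacement with weight exp(beta * aridity
    index); clade mode restricts the candidate pool to one lineage and caps
    richness at its size. Per-member read counts are log-normal, floored at 2
    so no planted member is lost to singleton filtering by construction.
    """
    from .habitat import aridity_indices

    idx = aridity_indices(refs)
    vt_ids = sorted(idx)
    values = np.array([idx[v].value if idx[v].defined else 0.0 for v in vt_ids])
    lo, hi = cfg.site_richness_range
    membership: dict[str, list[str]] = {}
    clades: dict[str, list[str]] = {}
    counts: dict[str, dict[str, int]] = {}
    for site in sites.index:
        if cfg.clustering_mode == "clade":
            cand = _clade_leaves(tree, rng, cfg.n_vt)
            clades[site] = cand
            n_min = min(5, len(cand))
        else:
            cand = vt_ids
            n_min = lo
        cap = min(hi, len(cand),
                  len(pools["continent"][site].members),
                  len(pools["realm"][site].members))
        n_i = int(rng.integers(n_min, max(n_min, cap) + 1))
        cvals = values[[vt_ids.index(v) for v in cand]]
        # Gumbel top-k = weighted sampling without replacement
        keys = cfg.affiliation_beta * cvals + rng.gumbel(size=len(cand))
        chosen = sorted(np.array(cand)[np.argsort(keys)[::-1][:n_i]].tolist())
        membership[site] = chosen
        w = rng.lognormal(mean=0.0, sigma=1.5, size=n_i)
        extra = rng.multinomial(max(cfg.reads_per_site - 2 * n_i, 0), w / w.sum())
        counts[site] = {v: int(2 + e) for v, e in zip(chosen, extra)}
    mat = pd.DataFrame(0, index=list(sites.index), columns=vt_ids, dtype=int)
    for s, row in counts.items():
        for v, c in row.items():
            mat.loc[s, v] = c
    mat = mat.loc[:, mat.sum(axis=0) > 0]
    return membership, CommunityTable(mat), clades


def _mutate_primer(primer: str, rng: np.random.Generator, n_sub: int = 3) -> str:
    """Substitute bases so the result has >= n_sub IUPAC mismatches."""
    out = list(primer)
    positions = rng.permutation(len(primer))
    done = 0
    for pos in positions:
        if done >= n_sub:
            break
        covered = IUPAC.get(out[pos].upper(), "ACGT")
        alternatives = [b for b in "ACGT" if b not in covered]
        if alternatives:
            out[pos] = alternatives[int(rng.integers(len(alternatives)))]
            done += 1
    return "".join(out)


def _qual_string(rng: np.random.Generator, n: int, mean: float, sd: float) -> str:
    q = np.clip(np.rint(rng.normal(mean, sd, size=n)), 2, 41).astype(int)
    return "".join(chr(33 + int(x)) for x in q)


def _with_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(len(arr)) < rate
    n_hit = int(hit.sum())
    if n_hit:
        shift = rng.integers(1, 4, size=n_hit).astype(np.uint8)
        idx = (np.searchsorted(BASES, arr[hit]) + shift) % 4
        arr[hit] = BASES[idx]
    return _decode(arr)


def simulate_reads(counts: CommunityTable, refs: list[VTReference],
                   cfg: SimulationConfig, rng: np.random.Generator,
                   outdir: str | Path) -> GroundTruth:
    """Write paired FASTQ per site; returns planted per-read bookkeeping.

    Read layout: forward read starts with the forward primer, reverse read
    with the reverse primer; the mates overlap in the amplicon middle.
    Defect categories (bad primer / low quality / no merge overlap) are
    mutually exclusive and drawn per read.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seq_by_vt = {r.vt_id: r.type_seq for r in refs}
    R = cfg.read_length
    gt_source: dict[str, str] = {}
    gt_cat: dict[str, str] = {}
    p_defect = [cfg.primer_fail_rate, cfg.low_quality_rate, cfg.merge_fail_rate]
    p_good = max(0.0, 1.0 - sum(p_defect))
    cats = ("primer", "quality", "overlap", "good")
    probs = np.array(p_defect + [p_good])
    for site in counts.sites:
        row = counts.counts.loc[site]
        vt_list = [v for v in row.index if row[v] > 0]
        reads = [(v, i) for v in vt_list for i in range(int(row[v]))]
        cat_draw = rng.choice(len(cats), size=len(reads), p=probs)
        f1 = (outdir / f"{site}_R1.fastq").open("w")
        f2 = (outdir / f"{site}_R2.fastq").open("w")
        try:
            for (vt, i), ci in zip(reads, cat_draw):
                cat = cats[ci]
                rid = f"{site}_{vt}_{i:05d}"
                fwd_primer = cfg.fwd_primer
                if cat == "primer":
                    fwd_primer = _mutate_primer(cfg.fwd_primer, rng)
                template = fwd_primer + seq_by_vt[vt] + revcomp(cfg.rev_primer)
                fwd = _with_errors(template[:R], cfg.read_error_rate, rng)
                if cat == "overlap":
                    fill = _decode(BASES[rng.integers(0, 4, R - len(cfg.rev_primer))])
                    rev = cfg.rev_primer + fill
                else:
                    rev = _with_errors(revcomp(template)[:R],
                                       cfg.read_error_rate, rng)
                if cat == "quality":
                    q_fwd = _qual_string(rng, len(fwd), cfg.low_quality_mean,
                                         cfg.quality_sd)
                else:
                    q_fwd = _qual_string(rng, len(fwd), cfg.quality_mean,
                                         cfg.quality_sd)
                q_rev = _qual_string(rng, len(rev), cfg.quality_mean,
                                     cfg.quality_sd)
                f1.write(f"@{rid}\n{fwd}\n+\n{q_fwd}\n")
                f2.write(f"@{rid}\n{rev}\n+\n{q_rev}\n")
                gt_source[rid] = vt
                gt_cat[rid] = cat
        finally:
            f1.close()
            f2.close()
    return GroundTruth(membership={}, true_counts={}, read_source=gt_source,
                       read_category=gt_cat, aridity={},
                       affiliation_beta=cfg.affiliation_beta,
                       clustering_mode=cfg.clustering_mode)


def write_pools(pools: dict[str, dict[str, PoolSpec]], path: str | Path) -> None:
    rows = []
    for scale, by_site in pools.items():
        for site, spec in by_site.items():
            for vt in sorted(spec.members):
                rows.append({"scale": scale, "site": site, "vt_id": vt})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_pools(path: str | Path) -> dict[str, dict[str, PoolSpec]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    pools: dict[str, dict[str, PoolSpec]] = {}
    for (scale, site), grp in df.groupby(["scale", "site"]):
        pools.setdefault(scale, {})[site] = PoolSpec(scale,
                                                     frozenset(grp["vt_id"]))
    return pools


@dataclass
class SimulatedDataset:
    """In-memory handles plus the on-disk layout consumed by the pipeline."""

    config: SimulationConfig
    refs: list[VTReference]
    tree: dendropy.Tree
    sites: pd.DataFrame
    pools: dict[str, dict[str, PoolSpec]]
    truth: GroundTruth
    true_table: CommunityTable
    outdir: Path


def simulate_dataset(cfg: SimulationConfig, outdir: str | Path
                     ) -> SimulatedDataset:
    """Generate the full input bundle for one pipeline run."""
    from .habitat import aridity_indices

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed + 7)
    refs, tree, seqs = simulate_reference(cfg)
    sites = site_metadata(cfg, rng)
    pools = build_pools(refs, sites)
    membership, table, clades = simulate_communities(refs, tree, cfg, rng,
                                                     sites, pools)
    truth = simulate_reads(table, refs, cfg, rng, outdir / "reads")
    truth.membership = membership
    truth.true_counts = {s: {v: int(c) for v, c in table.counts.loc[s].items()
                             if c > 0} for s in table.sites}
    idx = aridity_indices(refs)
    truth.aridity = {v: idx[v].value for v in sorted(idx) if idx[v].defined}
    truth.clades = clades

    write_reference(refs, str(outdir / "reference.fasta"),
                    str(outdir / "reference_meta.tsv"), aligned=seqs)
    tree.write(path=str(outdir / "reference_tree.nwk"), schema="newick")
    sites.to_csv(outdir / "sites.tsv", sep="\t")
    sites[["MAT", "MAP", "pH", "P", "N", "C"]].to_csv(outdir / "env.tsv", sep="\t")
    write_pools(pools, outdir / "pools.tsv")
    table.to_tsv(str(outdir / "true_community.tsv"))
    truth.to_json(outdir / "ground_truth.json")
    return SimulatedDataset(cfg, refs, tree, sites, pools, truth, table, outdir)
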