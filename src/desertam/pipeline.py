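"""Stage orchestration: each stage reads its inputs from disk and writes
plain-text outputs, so standalone stage runs are byte-identical to the
corresponding slice of a full run under the same global seed.

Expected input layout (as produced by :func:`desertam.simulate.simulate_dataset`):
``reads/{site}_R1.fastq`` + ``_R2.fastq``, ``reference.fasta`` (aligned type
sequences) + ``reference_meta.tsv``, ``sites.tsv``, ``env.tsv``, ``pools.tsv``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import assign as asn
from . import diversity as dv
from . import habitat as hb
from . import ordination as ordn
from . import phylo as ph
from .config import PipelineConfig, derive_seed
from .nullmodels import NullTestResult
from .readproc import (ReadProcessingConfig, process_site, read_merged_fasta,
                       write_merged_fasta)

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _sites(config: PipelineConfig) -> pd.DataFrame:
    path = Path(config.input_dir) / "sites.tsv"
    if not path.exists():
        raise StageError("setup", f"missing site table {path}")
    return pd.read_csv(path, sep="\t", index_col="site")


def _out(config: PipelineConfig) -> Path:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def stage_reads(config: PipelineConfig) -> list[Path]:
    """Primer-trim, quality-filter and merge every site's FASTQ pair."""
    out = _out(config)
    rp_cfg = ReadProcessingConfig(
        fwd_primer=config.fwd_primer, rev_primer=config.rev_primer,
        max_mismatch=config.max_mismatch, min_mean_q=config.min_mean_q,
        min_overlap=config.min_overlap, max_overlap=config.max_overlap,
        min_identity=config.min_identity)
    stats_rows = []
    outputs = []
    for site in _sites(config).index:
        f1 = Path(config.input_dir) / "reads" / f"{site}_R1.fastq"
        f2 = Path(config.input_dir) / "reads" / f"{site}_R2.fastq"
        if not f1.exists() or not f2.exists():
            raise StageError("reads", f"missing FASTQ pair for site {site}: "
                                      f"{f1}, {f2}")
        try:
            merged, stats = process_site(str(f1), str(f2), rp_cfg, site=site)
        except ValueError as exc:
            raise StageError("reads", str(exc)) from exc
        path = out / f"{site}_merged.fasta"
        write_merged_fasta(merged, str(path))
        outputs.append(path)
        stats_rows.append({"site": site, "n_input": stats.n_input,
                           "n_primer_fail": stats.n_primer_fail,
                           "n_quality_fail": stats.n_quality_fail,
                           "n_merge_fail": stats.n_merge_fail,
                           "n_merged": stats.n_merged})
    stats_path = out / "processing_stats.tsv"
    pd.DataFrame(stats_rows).to_csv(stats_path, sep="\t", index=False)
    outputs.append(stats_path)
    return outputs


def _load_refs(config: PipelineConfig) -> list[asn.VTReference]:
    base = Path(config.input_dir)
    try:
        return asn.load_reference(str(base / "reference.fasta"),
                                  str(base / "reference_meta.tsv"))
    except (OSError, KeyError, ValueError) as exc:
        raise StageError("assign", f"cannot load reference catalogue: {exc}")


def stage_assign(config: PipelineConfig) -> list[Path]:
    """Assign merged reads to VT; build and singleton-filter the table."""
    out = _out(config)
    refs = _load_refs(config)
    sites = list(_sites(config).index)
    assignments = []
    for site in sites:
        path = out / f"{site}_merged.fasta"
        if not path.exists():
            raise StageError("assign", f"missing merged reads {path} "
                                       "(run the reads stage first)")
        reads = read_merged_fasta(str(path), site=site)
        assignments.extend(asn.assign_reads(
            reads, refs, config.id_threshold, config.cov_threshold,
            prescreen=config.prescreen_top))
    asn.write_assignments(assignments, str(out / "assignments.tsv"))
    table = asn.build_community_table(assignments, sites=sites)
    table.to_tsv(str(out / "community_raw.tsv"))
    filtered = asn.remove_singletons(table)
    filtered.to_tsv(str(out / "community.tsv"))
    frac = asn.cultured_fraction(filtered, refs) if filtered.vt_ids else 0.0
    summary = pd.DataFrame([{
        "n_reads_assigned": int(table.counts.to_numpy().sum()),
        "n_vt_raw": len(table.vt_ids),
        "n_vt_retained": len(filtered.vt_ids),
        "cultured_fraction": round(frac, 4)}])
    summary.to_csv(out / "assignment_summary.tsv", sep="\t", index=False)
    return [out / "assignments.tsv", out / "community_raw.tsv",
            out / "community.tsv", out / "assignment_summary.tsv"]


def _community(config: PipelineConfig) -> asn.CommunityTable:
    path = Path(config.output_dir) / "community.tsv"
    if not path.exists():
        alt = Path(config.input_dir) / "community.tsv"
        if alt.exists():  # --skip-reads entry point: table provided as input
            return asn.CommunityTable.from_tsv(str(alt))
        raise StageError("community", f"no community table at {path}")
    return asn.CommunityTable.from_tsv(str(path))


def stage_diversity(config: PipelineConfig) -> list[Path]:
    """Rarefaction curves and observed/asymptotic Hill diversity per site."""
    out = _out(config)
    table = _community(config)
    seed = derive_seed(config.seed, "diversity")
    rows = [{"site": e.site, "q": e.order_q,
             "observed": round(e.observed, 4), "estimated": round(e.estimated, 4),
             "se": round(e.se, 4), "lcl": round(e.lcl, 4),
             "ucl": round(e.ucl, 4)}
            for e in dv.diversity_table(table, B=config.bootstrap_B, seed=seed)]
    div_path = out / "diversity.tsv"
    pd.DataFrame(rows).to_csv(div_path, sep="\t", index=False)
    rare_rows = []
    for v in dv.abundance_vectors(table):
        depths = np.unique(np.linspace(1, v.n, 25).astype(int))
        for m, s in zip(depths, dv.rarefaction_curve(v, depths)):
            rare_rows.append({"site": v.site, "depth": int(m),
                              "expected_richness": round(float(s), 4)})
    rare_path = out / "rarefaction.tsv"
    pd.DataFrame(rare_rows).to_csv(rare_path, sep="\t", index=False)
    return [div_path, rare_path]


def _aligned_seqs(config: PipelineConfig) -> dict[str, str]:
    path = Path(config.input_dir) / "reference.fasta"
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def stage_phylo(config: PipelineConfig) -> list[Path]:
    """NJ tree over type sequences, patristic distances, ses.mpd per site."""
    out = _out(config)
    table = _community(config)
    seqs = _aligned_seqs(config)
    try:
        dmat = ph.jc_distance_matrix(seqs)
    except ValueError as exc:
        raise StageError("phylo", str(exc)) from exc
    tree = ph.neighbor_joining(dmat)
    tree_path = out / "nj_tree.nwk"
    tree.write(path=str(tree_path), schema="newick")
    pat = ph.patristic_distances(tree)
    pat_path = out / "patristic.tsv"
    pat.round(6).to_csv(pat_path, sep="\t", index_label="vt_id")
    from .simulate import load_pools
    pools = load_pools(Path(config.input_dir) / "pools.tsv")
    rng = np.random.default_rng(derive_seed(config.seed, "phylo"))
    results = []
    for scale in hb.SCALES:
        for site in table.sites:
            taxa = table.site_taxa(site)
            pool = pools[scale][site].members & set(pat.index)
            if len(taxa) < 2 or len(pool) < len(taxa):
                results.append(NullTestResult(
                    site, "mpd", math.nan, math.nan, math.nan, None,
                    config.n_reps, scale, significant=False, degenerate=True))
                continue
            results.append(ph.ses_mpd(
                taxa, pat, sorted(pool), n_reps=config.n_reps,
                seed=int(rng.integers(2 ** 31)), z_crit=config.z_crit,
                sample_name=site, pool_scale=scale))
    res_path = out / "ses_mpd.tsv"
    ph.results_table(results).round(6).to_csv(res_path, sep="\t", index=False)
    return [tree_path, pat_path, res_path]


def stage_ordinate(config: PipelineConfig) -> list[Path]:
    """Jaccard PCoA, phylogenetic-comdist NMDS, and environmental fitting."""
    out = _out(config)
    table = _community(config)
    seed = derive_seed(config.seed, "ordinate")
    jac = ordn.jaccard_matrix(table)
    jac_path = out / "jaccard.tsv"
    jac.round(6).to_csv(jac_path, sep="\t", index_label="site")
    pco = ordn.pcoa(jac, k=min(config.axes, len(table.sites) - 1))
    pcoa_path = out / "pcoa_scores.tsv"
    pco.scores_frame().round(6).to_csv(pcoa_path, sep="\t", index_label="site")
    pat_path = Path(config.output_dir) / "patristic.tsv"
    if not pat_path.exists():
        raise StageError("ordinate", f"missing {pat_path} "
                                     "(run the phylo stage first)")
    pat = pd.read_csv(pat_path, sep="\t", index_col="vt_id")
    site_taxa = {s: table.site_taxa(s) for s in table.sites
                 if len(table.site_taxa(s)) > 0}
    cd = ph.comdist_matrix(site_taxa, pat)
    cd_path = out / "comdist.tsv"
    cd.round(6).to_csv(cd_path, sep="\t", index_label="site")
    nm = ordn.nmds(cd, k=config.axes, n_starts=config.nmds_starts, seed=seed)
    nmds_path = out / "nmds_scores.tsv"
    frame = nm.scores_frame().round(6)
    frame["stress"] = round(nm.stress, 6)
    frame.to_csv(nmds_path, sep="\t", index_label="site")
    env_file = Path(config.input_dir) / "env.tsv"
    outputs = [jac_path, pcoa_path, cd_path, nmds_path]
    if env_file.exists():
        env = pd.read_csv(env_file, sep="\t", index_col="site")
        env = env.loc[[s for s in nm.samples]]
        fits = ordn.envfit(nm, env, n_perm=config.n_perm, seed=seed + 1)
        env_path = out / "envfit.tsv"
        ordn.envfit_table(fits).round(6).to_csv(env_path, sep="\t", index=False)
        outputs.append(env_path)
    return outputs


def stage_habitat(config: PipelineConfig) -> list[Path]:
    """Aridity indices and the multi-scale randomization Z-table."""
    out = _out(config)
    table = _community(config)
    refs = _load_refs(config)
    from .simulate import load_pools
    pools = load_pools(Path(config.input_dir) / "pools.tsv")
    indices = hb.aridity_indices(refs)
    idx_rows = [{"vt_id": v,
                 "aridity_index": (round(indices[v].value, 6)
                                   if indices[v].defined else "NA"),
                 "n_records": indices[v].n_records}
                for v in sorted(indices)]
    idx_path = out / "aridity_index.tsv"
    pd.DataFrame(idx_rows).to_csv(idx_path, sep="\t", index=False)
    site_taxa = {s: table.site_taxa(s) for s in table.sites
                 if len(table.site_taxa(s)) > 0}
    if config.n_reps < 999:
        log.warning("habitat null model run with n_reps=%d (< 999): "
                    "low-precision Z values", config.n_reps)
    results = hb.multi_scale_test(
        site_taxa, indices, pools, n_reps=config.n_reps,
        seed=derive_seed(config.seed, "habitat"), z_crit=config.z_crit)
    long_path = out / "aridity_null_long.tsv"
    ph.results_table(results).round(6).to_csv(long_path, sep="\t", index=False)
    wide_path = out / "aridity_ztable.tsv"
    hb.zscore_table(results, z_crit=config.z_crit).to_csv(
        wide_path, sep="\t", index_label="scale")
    return [idx_path, long_path, wide_path]


STAGES = {
    "reads": stage_reads,
    "assign": stage_assign,
    "diversity": stage_diversity,
    "phylo": stage_phylo,
    "ordinate": stage_ordinate,
    "habitat": stage_habitat,
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: PipelineConfig) -> dict:
    """Run every stage in order; returns the output manifest (also written
    to ``manifest.json``: relative path -> sha256 of every artifact)."""
    out = _out(config)
    stage_names = list(STAGES)
    if config.skip_reads:
        stage_names = [s for s in stage_names if s not in ("reads", "assign")]
    outputs: list[Path] = []
    for name in stage_names:
        log.info("running stage %s", name)
        outputs.extend(STAGES[name](config))
    manifest = {str(p.relative_to(out)): _sha256(p) for p in sorted(outputs)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    return manifest
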