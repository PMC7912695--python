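"""Paired-end amplicon read processing: primer matching/trimming, mean-quality
filtering and overlap merging.

The stage mirrors a standard SSU metabarcoding workflow: primers are matched
at the 5' terminus of each mate allowing a configurable number of mismatches
(IUPAC-degenerate primer positions match any base they cover), pairs are kept
only when both mates have an arithmetic mean Phred score at or above the
threshold, and surviving pairs are merged over the best-identity 3' overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

from Bio import SeqIO

from ._seq import IUPAC, iupac_mismatches, revcomp

log = logging.getLogger(__name__)


@dataclass
class ReadPair:
    """A forward/reverse read pair with per-base Phred qualities."""

    id: str
    fwd_seq: str
    fwd_qual: list[int]
    rev_seq: str
    rev_qual: list[int]
    site: str = ""

    def __post_init__(self) -> None:
        if len(self.fwd_seq) != len(self.fwd_qual):
            raise ValueError(f"{self.id}: forward seq/qual length mismatch")
        if len(self.rev_seq) != len(self.rev_qual):
            raise ValueError(f"{self.id}: reverse seq/qual length mismatch")


@dataclass
class MergedRead:
    """A merged amplicon sequence and the overlap length used to build it."""

    id: str
    seq: str
    site: str
    overlap_len: int


@dataclass
class ProcessingStats:
    """Per-site read accounting; categories partition the input."""

    site: str = ""
    n_input: int = 0
    n_primer_fail: int = 0
    n_quality_fail: int = 0
    n_merge_fail: int = 0
    n_merged: int = 0

    def check(self) -> None:
        total = (self.n_primer_fail + self.n_quality_fail
                 + self.n_merge_fail + self.n_merged)
        if total != self.n_input:
            raise AssertionError(
                f"stats do not conserve counts for site {self.site!r}: "
                f"{self.n_input} input vs {total} categorized")


@dataclass
class ReadProcessingConfig:
    """Primer, quality and merge parameters for one processing run."""

    fwd_primer: str = "CAGCCGCGGTAATTCCAGCT"      # WANDA (SSU, AMF-inclusive)
    rev_primer: str = "GAACCCAAACACTTTGGTTTCC"    # AML2 (AMF-specific)
    max_mismatch: int = 1
    min_mean_q: float = 30.0
    min_overlap: int = 10
    max_overlap: int = 300
    min_identity: float = 0.75
    exclude_ids: frozenset[str] = field(default_factory=frozenset)


def match_and_trim_primers(pair: ReadPair, fwd_primer: str, rev_primer: str,
                           max_mismatch: int = 1) -> Optional[ReadPair]:
    """Trim 5'-anchored primers off both mates, or reject the pair.

    Returns the trimmed pair, or ``None`` when either mate's leading
    primer-length window has more than ``max_mismatch`` mismatches (a primer
    longer than its read is likewise a rejection). Primer IUPAC codes match
    every base they cover; ``N`` in the read matches nothing.
    """
    if not fwd_primer or not rev_primer:
        raise ValueError("primers must be non-empty")
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    for primer, seq in ((fwd_primer, pair.fwd_seq), (rev_primer, pair.rev_seq)):
        if len(primer) > len(seq):
            return None
        if iupac_mismatches(primer, seq[:len(primer)]) > max_mismatch:
            return None
    nf, nr = len(fwd_primer), len(rev_primer)
    return replace(pair,
                   fwd_seq=pair.fwd_seq[nf:], fwd_qual=pair.fwd_qual[nf:],
                   rev_seq=pair.rev_seq[nr:], rev_qual=pair.rev_qual[nr:])


def quality_filter(pair: ReadPair, min_mean_q: float = 30.0) -> bool:
    """Keep a pair iff both mates' arithmetic mean Phred score >= threshold."""
    for qual in (pair.fwd_qual, pair.rev_qual):
        if not qual:
            return False
        if sum(qual) / len(qual) < min_mean_q:
            return False
    return True


def _overlap_identity(fwd: str, rc_rev: str, ov: int) -> float:
    """Fraction of matching bases over an overlap of length ``ov``.

    ``N`` matches nothing. The overlap is the last ``ov`` bases of the forward
    mate against the first ``ov`` bases of the reverse-complemented reverse
    mate.
    """
    a = fwd[-ov:]
    b = rc_rev[:ov]
    matches = sum(1 for x, y in zip(a, b) if x == y and x in "ACGT")
    return matches / ov


def merge_pair(pair: ReadPair, min_overlap: int = 10, max_overlap: int = 300,
               min_identity: float = 0.75) -> Optional[MergedRead]:
    """Merge mates over their best-identity 3' overlap, or reject.

    Candidate overlap lengths in ``[min_overlap, max_overlap]`` (bounded by
    both read lengths) are scored by base identity; the best-identity overlap
    meeting ``min_identity`` wins, ties going to the longest overlap. In the
    overlap the consensus base is the one with the higher Phred score, ties
    going to the forward mate.
    """
    fwd = pair.fwd_seq
    rc_rev = revcomp(pair.rev_seq)
    rc_rev_qual = pair.rev_qual[::-1]
    hi = min(max_overlap, len(fwd), len(rc_rev))
    best_ov = 0
    best_ident = -1.0
    for ov in range(min_overlap, hi + 1):
        ident = _overlap_identity(fwd, rc_rev, ov)
        if ident >= min_identity and ident >= best_ident:
            # >= prefers the longest among equal scores (ov increases)
            best_ident = ident
            best_ov = ov
    if best_ov == 0:
        return None
    ov = best_ov
    head = fwd[:-ov] if ov < len(fwd) else ""
    tail = rc_rev[ov:]
    consensus = []
    fq = pair.fwd_qual
    for k in range(ov):
        fbase = fwd[len(fwd) - ov + k]
        rbase = rc_rev[k]
        if fbase == rbase:
            consensus.append(fbase)
        elif rc_rev_qual[k] > fq[len(fwd) - ov + k]:
            consensus.append(rbase)
        else:
            consensus.append(fbase)
    seq = head + "".join(consensus) + tail
    return MergedRead(id=pair.id, seq=seq, site=pair.site, overlap_len=ov)


def process_pairs(pairs: Iterable[ReadPair], config: ReadProcessingConfig,
                  site: str = "") -> tuple[list[MergedRead], ProcessingStats]:
    """Run primer trimming -> quality filter -> merging over read pairs."""
    stats = ProcessingStats(site=site)
    merged: list[MergedRead] = []
    for pair in pairs:
        if pair.id in config.exclude_ids:
            continue
        stats.n_input += 1
        trimmed = match_and_trim_primers(pair, config.fwd_primer,
                                         config.rev_primer,
                                         config.max_mismatch)
        if trimmed is None:
            stats.n_primer_fail += 1
            continue
        if not quality_filter(trimmed, config.min_mean_q):
            stats.n_quality_fail += 1
            continue
        m = merge_pair(trimmed, config.min_overlap, config.max_overlap,
                       config.min_identity)
        if m is None:
            stats.n_merge_fail += 1
            continue
        stats.n_merged += 1
        merged.append(m)
    stats.check()
    return merged, stats


def iter_fastq_pairs(fastq_fwd: str, fastq_rev: str,
                     site: str = "") -> Iterator[ReadPair]:
    """Iterate matched read pairs from two FASTQ (Phred+33) files."""
    it_f = SeqIO.parse(fastq_fwd, "fastq")
    it_r = SeqIO.parse(fastq_rev, "fastq")
    while True:
        rec_f = next(it_f, None)
        rec_r = next(it_r, None)
        if rec_f is None and rec_r is None:
            return
        if rec_f is None or rec_r is None:
            raise ValueError(
                f"unequal read counts between {fastq_fwd} and {fastq_rev}")
        yield ReadPair(
            id=rec_f.id,
            fwd_seq=str(rec_f.seq).upper(),
            fwd_qual=list(rec_f.letter_annotations["phred_quality"]),
            rev_seq=str(rec_r.seq).upper(),
            rev_qual=list(rec_r.letter_annotations["phred_quality"]),
            site=site,
        )


def process_site(fastq_fwd: str, fastq_rev: str, config: ReadProcessingConfig,
                 site: str = "") -> tuple[list[MergedRead], ProcessingStats]:
    """Process one site's FASTQ pair into merged reads plus accounting.

    The optional ``config.exclude_ids`` set is the hook for dropping reads
    flagged by an external chimera screen.
    """
    merged, stats = process_pairs(iter_fastq_pairs(fastq_fwd, fastq_rev, site),
                                  config, site=site)
    log.info("site %s: %d input, %d primer-fail, %d quality-fail, "
             "%d merge-fail, %d merged", site or "?", stats.n_input,
             stats.n_primer_fail, stats.n_quality_fail, stats.n_merge_fail,
             stats.n_merged)
    return merged, stats


def write_merged_fasta(merged: Iterable[MergedRead], path: str) -> None:
    with open(path, "w") as fh:
        for m in merged:
            fh.write(f">{m.id} site={m.site} overlap={m.overlap_len}\n{m.seq}\n")


def read_merged_fasta(path: str, site: str = "") -> list[MergedRead]:
    out = []
    for rec in SeqIO.parse(path, "fasta"):
        fields = dict(part.split("=", 1) for part in rec.description.split()[1:]
                      if "=" in part)
        out.append(MergedRead(id=rec.id, seq=str(rec.seq).upper(),
                              site=fields.get("site", site),
                              overlap_len=int(fields.get("overlap", 0))))
    return out
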