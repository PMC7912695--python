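"""Read processing: primer matching, quality filtering, merging."""

import itertools

import numpy as np
import pytest

from desertam._seq import IUPAC, revcomp
from desertam.readproc import (ReadPair, ReadProcessingConfig,
                               match_and_trim_primers, merge_pair,
                               process_pairs, quality_filter)

from conftest import make_pair, random_dna

PRIMER_F = "CAGCCGCGGTAATTCCAGCT"
PRIMER_R = "GAACCCAAACACTTTGGTTTCC"


def brute_force_primer_match(primer, window, max_mismatch):
    """Oracle: expand every IUPAC combination of the primer, accept if any
    expansion is within max_mismatch of the window."""
    options = [IUPAC[p.upper()] for p in primer]
    best = len(primer)
    for concrete in itertools.product(*options):
        mm = sum(1 for c, b in zip(concrete, window) if c != b)
        best = min(best, mm)
    return best <= max_mismatch


class TestPrimerMatching:
    def test_exact_primer_trimmed(self):
        pair = make_pair(PRIMER_F + "AAAA", PRIMER_R + "CCCC")
        out = match_and_trim_primers(pair, PRIMER_F, PRIMER_R, 1)
        assert out is not None
        assert out.fwd_seq == "AAAA" and out.rev_seq == "CCCC"
        assert len(out.fwd_qual) == 4 and len(out.rev_qual) == 4

    def test_two_mismatches_rejected_one_accepted(self):
        bad = "TT" + PRIMER_F[2:]  # 2 mismatches
        ok = "T" + PRIMER_F[1:]    # 1 mismatch
        assert match_and_trim_primers(
            make_pair(bad + "AA", PRIMER_R + "AA"), PRIMER_F, PRIMER_R, 1) is None
        assert match_and_trim_primers(
            make_pair(ok + "AA", PRIMER_R + "AA"), PRIMER_F, PRIMER_R, 1) is not None

    def test_ambiguity_code_is_free_match(self):
        # primer R covers A and G; one real mismatch elsewhere stays within 1
        primer = "RCGT"
        read = "ACGA"  # R~A free, T->A mismatch
        pair = make_pair(read + "AAAA", "TTTT" + "AAAA")
        out = match_and_trim_primers(pair, primer, "TTTT", 1)
        assert out is not None and out.fwd_seq == "AAAA"

    def test_primer_longer_than_read_rejects(self):
        pair = make_pair("ACG", "ACGT")
        assert match_and_trim_primers(pair, "ACGTA", "ACGT", 1) is None

    def test_n_in_read_counts_as_mismatch(self):
        read = "N" + PRIMER_F[1:]
        ok = match_and_trim_primers(
            make_pair(read + "AA", PRIMER_R + "AA"), PRIMER_F, PRIMER_R, 1)
        assert ok is not None  # 1 mismatch allowed
        read2 = "NN" + PRIMER_F[2:]
        assert match_and_trim_primers(
            make_pair(read2 + "AA", PRIMER_R + "AA"), PRIMER_F, PRIMER_R, 1) is None

    @pytest.mark.parametrize("primer", ["ACGT", "RYKM", "ANGT", "WSBD"])
    def test_matches_brute_force_iupac_expansion(self, primer, rng):
        for _ in range(60):
            window = random_dna(rng, len(primer))
            for mm in (0, 1, 2):
                pair = make_pair(window + "ACGT", "TTTT" + "ACGT")
                got = match_and_trim_primers(pair, primer, "TTTT", mm) is not None
                want = brute_force_primer_match(primer, window, mm)
                assert got == want, (primer, window, mm)


class TestQualityFilter:
    def test_boundary_inclusive(self):
        assert quality_filter(make_pair("ACGT", "ACGT", q=30), 30.0)

    def test_one_mate_below_threshold_drops(self):
        pair = ReadPair("r", "ACGT", [35] * 4, "ACGT", [29, 30, 30, 30], "S")
        assert not quality_filter(pair, 30.0)  # rev mean 29.75

    def test_uniformly_bad_drops(self):
        assert not quality_filter(make_pair("ACGT", "ACGT", q=2), 30.0)

    def test_empty_sequence_drops(self):
        assert not quality_filter(ReadPair("r", "", [], "ACGT", [40] * 4), 30.0)


def brute_force_merge(fwd, rc_rev, min_ov, max_ov, min_ident):
    """Oracle: score every overlap length, best identity then longest."""
    best = None
    for ov in range(min_ov, min(max_ov, len(fwd), len(rc_rev)) + 1):
        a, b = fwd[-ov:], rc_rev[:ov]
        matches = sum(1 for x, y in zip(a, b) if x == y and x in "ACGT")
        ident = matches / ov
        if ident >= min_ident and (best is None or ident > best[0]
                                   or (ident == best[0] and ov > best[1])):
            best = (ident, ov)
    return best


class TestMerging:
    def test_exact_overlap(self, rng):
        core = random_dna(rng, 280)
        fwd = core[:150]
        rev = revcomp(core[130:])  # 20 bp overlap
        m = merge_pair(make_pair(fwd, rev))
        assert m is not None
        assert m.overlap_len == 20
        assert m.seq == core
        assert len(m.seq) == len(fwd) + len(rev) - m.overlap_len

    def test_overlap_below_window_rejected(self, rng):
        core = random_dna(rng, 100)
        fwd = core[:54]
        rev = revcomp(core[46:])  # 8 bp overlap < 10
        assert merge_pair(make_pair(fwd, rev)) is None

    def test_identity_boundary_at_75_percent(self, rng):
        # 20 bp overlap with exactly 5 (accept, identity 0.75) vs 6 (reject,
        # 0.70) mismatches; the overlap window is pinned to 20 bp
        left = random_dna(rng, 50)
        overlap = random_dna(rng, 20)
        right = random_dna(rng, 50)
        fwd = left + overlap

        def rev_with_mm(k):
            ov = list(overlap)
            for i in range(k):
                ov[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[ov[i]]
            return revcomp("".join(ov) + right)

        ok = merge_pair(make_pair(fwd, rev_with_mm(5)),
                        min_overlap=20, max_overlap=20)
        bad = merge_pair(make_pair(fwd, rev_with_mm(6)),
                         min_overlap=20, max_overlap=20)
        assert ok is not None and ok.overlap_len == 20
        assert bad is None

    def test_consensus_takes_higher_phred(self):
        # 10 bp overlap disagreeing at its first position (A vs G)
        fwd = "AAAA" + "ACGTACGTAC"
        core_r = "GCGTACGTAC" + "TTTT"
        pair = ReadPair("r", fwd, [30] * 4 + [10] * 10,
                        revcomp(core_r), [35] * 14, "S")
        m = merge_pair(pair)
        assert m is not None and m.overlap_len == 10
        assert m.seq[4] == "G"  # reverse base wins (35 > 10)
        pair_tie = ReadPair("r", fwd, [30] * 4 + [35] * 10,
                            revcomp(core_r), [35] * 14, "S")
        m2 = merge_pair(pair_tie)
        assert m2.seq[4] == "A"  # tie -> forward base

    def test_matches_brute_force_on_random_pairs(self, rng):
        for _ in range(150):
            fwd = random_dna(rng, int(rng.integers(30, 90)))
            if rng.random() < 0.6:  # planted true overlap
                ov = int(rng.integers(5, 35))
                tail = random_dna(rng, int(rng.integers(5, 40)))
                rc_rev = fwd[-ov:] + tail
            else:
                rc_rev = random_dna(rng, int(rng.integers(30, 90)))
            pair = make_pair(fwd, revcomp(rc_rev))
            got = merge_pair(pair, 10, 300, 0.75)
            want = brute_force_merge(fwd, rc_rev, 10, 300, 0.75)
            if want is None:
                assert got is None
            else:
                assert got is not None and got.overlap_len == want[1]


class TestProcessPairs:
    def _planted(self, rng, n_bad_primer, n_low_q, n_short_ov, n_good):
        cfg = ReadProcessingConfig()
        pairs = []
        core = random_dna(rng, 200)
        fwd_core, rev_core = core[:120], revcomp(core[80:])  # 40 bp overlap
        i = 0
        for _ in range(n_bad_primer):
            pairs.append(make_pair("TTT" + PRIMER_F[3:] + fwd_core,
                                   PRIMER_R + rev_core, pair_id=f"p{i}")); i += 1
        for _ in range(n_low_q):
            pairs.append(make_pair(PRIMER_F + fwd_core, PRIMER_R + rev_core,
                                   q=20, pair_id=f"p{i}")); i += 1
        for _ in range(n_short_ov):
            pairs.append(make_pair(PRIMER_F + fwd_core,
                                   PRIMER_R + random_dna(rng, 120),
                                   pair_id=f"p{i}")); i += 1
        for _ in range(n_good):
            pairs.append(make_pair(PRIMER_F + fwd_core, PRIMER_R + rev_core,
                                   pair_id=f"p{i}")); i += 1
        return pairs, cfg

    def test_planted_defects_are_counted_per_category(self, rng):
        pairs, cfg = self._planted(rng, 10, 10, 10, 70)
        merged, stats = process_pairs(pairs, cfg, site="S")
        assert (stats.n_input, stats.n_primer_fail, stats.n_quality_fail,
                stats.n_merge_fail, stats.n_merged) == (100, 10, 10, 10, 70)
        assert len(merged) == 70

    def test_order_insensitivity(self, rng):
        pairs, cfg = self._planted(rng, 5, 4, 3, 20)
        _, s1 = process_pairs(pairs, cfg)
        perm = [pairs[i] for i in rng.permutation(len(pairs))]
        _, s2 = process_pairs(perm, cfg)
        assert (s1.n_primer_fail, s1.n_quality_fail, s1.n_merge_fail,
                s1.n_merged) == (s2.n_primer_fail, s2.n_quality_fail,
                                 s2.n_merge_fail, s2.n_merged)

    def test_empty_input(self):
        merged, stats = process_pairs([], ReadProcessingConfig())
        assert merged == [] and stats.n_input == 0

    def test_chimera_exclusion_hook(self, rng):
        pairs, cfg = self._planted(rng, 0, 0, 0, 10)
        cfg2 = ReadProcessingConfig(exclude_ids=frozenset({"p0", "p3"}))
        merged, stats = process_pairs(pairs, cfg2)
        assert stats.n_input == 8 and len(merged) == 8
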