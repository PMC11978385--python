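import re

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mafscan.maf_io import AlignedSequence, AlignmentBlock
from mafscan.motif_models import KmerSet, Pwm, RegexSet, reverse_complement
from mafscan.search_engine import (
    SearchOptions,
    build_gap_index,
    find_kmer_hits,
    find_pwm_hits,
    find_regex_hits,
    map_to_gapped,
    search_block,
    to_genomic,
)

from conftest import parse_text


def naive_kmer_scan(kmers, seq, rc=False):
    """O(n*m) oracle: every occurrence of every k-mer (and its RC)."""
    seq_u = seq.upper()
    found = set()
    for kid, kseq in kmers.kmers:
        targets = [(kseq.upper(), "+")]
        if rc:
            targets.append((reverse_complement(kseq).upper(), "-"))
        for pattern, strand in targets:
            for i in range(len(seq_u) - len(pattern) + 1):
                if seq_u[i : i + len(pattern)] == pattern:
                    found.add((i, i + len(pattern), kid, strand))
    return found


def naive_pwm_scan(pwm, seq):
    """Score every window directly with Pwm.score (oracle)."""
    found = set()
    L = pwm.length
    seq_u = seq.upper()
    for i in range(len(seq_u) - L + 1):
        window = seq_u[i : i + L]
        if any(c not in "ACGT" for c in window):
            continue
        if pwm.score(window) >= pwm.threshold:
            found.add((i, i + L))
    return found


class TestGapIndex:
    def test_hand_mapping(self):
        index = build_gap_index("AC-G-T")
        assert index.ungapped == "ACGT"
        assert index.u2g == (0, 1, 3, 5)

    def test_gap_free_identity(self):
        index = build_gap_index("ACGT")
        assert index.u2g == (0, 1, 2, 3)

    def test_all_gaps(self):
        index = build_gap_index("----")
        assert index.ungapped == ""
        assert index.u2g == ()

    def test_map_to_gapped_hand_case(self):
        index = build_gap_index("AC-G-T")
        assert map_to_gapped(index, 1, 3) == (1, 4)  # "CG" -> "C-G"

    def test_map_full_span(self):
        index = build_gap_index("AC-G-T")
        assert map_to_gapped(index, 0, 4) == (0, 6)

    def test_map_identity_on_gapfree(self):
        index = build_gap_index("ACGTAC")
        assert map_to_gapped(index, 2, 5) == (2, 5)

    def test_out_of_range(self):
        index = build_gap_index("ACGT")
        with pytest.raises(ValueError):
            map_to_gapped(index, 2, 5)

    @settings(max_examples=200, deadline=None)
    @given(st.text(alphabet="ACGT-", min_size=1, max_size=40), st.data())
    def test_round_trip_gapped_slice_ungaps_to_span(self, text, data):
        index = build_gap_index(text)
        n = len(index.ungapped)
        if n == 0:
            return
        u_start = data.draw(st.integers(0, n - 1))
        u_end = data.draw(st.integers(u_start + 1, n))
        g_start, g_end = map_to_gapped(index, u_start, u_end)
        sliced = text[g_start:g_end].replace("-", "")
        assert sliced == index.ungapped[u_start:u_end]
        assert not text[g_start] == "-" and not text[g_end - 1] == "-"


class TestKmerSearch:
    def test_overlapping_occurrences(self):
        ks = KmerSet(kmers=(("m", "ACA"),))
        hits = find_kmer_hits(ks, "ACACA")
        assert [(h.u_start, h.u_end) for h in hits] == [(0, 3), (2, 5)]

    def test_no_match(self):
        assert find_kmer_hits(KmerSet(kmers=(("m", "AAA"),)), "CCCC") == []

    def test_nested_patterns(self):
        ks = KmerSet(kmers=(("a", "AC"), ("b", "ACA")))
        hits = find_kmer_hits(ks, "ACA")
        assert {(h.motif_id, h.u_start, h.u_end) for h in hits} == {
            ("a", 0, 2),
            ("b", 0, 3),
        }

    def test_case_insensitive_match_preserves_case(self):
        hits = find_kmer_hits(KmerSet(kmers=(("m", "ACGT"),)), "aacgtt")
        assert hits[0].matched_sequence == "acgt"

    def test_reverse_complement_search(self):
        hits = find_kmer_hits(KmerSet(kmers=(("m", "CAT"),)), "ATGC", rc=True)
        assert len(hits) == 1
        assert hits[0].strand_of_match == "-"
        assert (hits[0].u_start, hits[0].u_end) == (0, 3)
        assert hits[0].matched_sequence == "ATG"

    def test_palindrome_reported_on_both_strands(self):
        hits = find_kmer_hits(KmerSet(kmers=(("m", "ACGT"),)), "ACGT", rc=True)
        assert sorted(h.strand_of_match for h in hits) == ["+", "-"]

    def test_sorted_by_start_then_id(self):
        ks = KmerSet(kmers=(("z", "AC"), ("a", "AC")))
        hits = find_kmer_hits(ks, "ACAC")
        assert [(h.u_start, h.motif_id) for h in hits] == [
            (0, "a"), (0, "z"), (2, "a"), (2, "z"),
        ]

    @settings(max_examples=300, deadline=None)
    @given(
        st.text(alphabet="ACGTacgt", min_size=0, max_size=60),
        st.lists(
            st.text(alphabet="ACGT", min_size=1, max_size=5),
            min_size=1, max_size=5, unique=True,
        ),
        st.booleans(),
    )
    def test_oracle_equivalence(self, seq, patterns, rc):
        ks = KmerSet(kmers=tuple((f"k{i}", p) for i, p in enumerate(patterns)))
        hits = find_kmer_hits(ks, seq, rc=rc)
        got = {(h.u_start, h.u_end, h.motif_id, h.strand_of_match) for h in hits}
        expected = {
            (s, e, kid, strand)
            for s, e, kid, strand in naive_kmer_scan(ks, seq, rc=rc)
        }
        assert got == expected


@pytest.fixture
def strong_ac_pwm():
    counts = np.array([[50.0, 0.0], [0.0, 50.0], [0.0, 0.0], [0.0, 0.0]])
    pwm = Pwm(name="consAC", counts=counts)
    return pwm.calibrated(p_value=0.05, n_samples=10_000, seed=0)


class TestPwmSearch:
    def test_single_strong_hit(self, strong_ac_pwm):
        hits = find_pwm_hits(strong_ac_pwm, "TTACTT")
        assert [(h.u_start, h.u_end) for h in hits] == [(2, 4)]
        assert hits[0].score == pytest.approx(strong_ac_pwm.score("AC"))
        assert 0 < hits[0].p_value < 1

    def test_ambiguous_windows_skipped(self, strong_ac_pwm):
        assert find_pwm_hits(strong_ac_pwm, "NNNN") == []
        # window straddling an N is skipped, flanking valid windows are not
        hits = find_pwm_hits(strong_ac_pwm, "ACNAC")
        assert [(h.u_start, h.u_end) for h in hits] == [(0, 2), (3, 5)]

    def test_p_value_one_hits_every_window(self):
        counts = np.array([[5.0, 1.0], [1.0, 5.0], [1.0, 1.0], [1.0, 1.0]])
        pwm = Pwm(name="m", counts=counts).calibrated(p_value=1.0, n_samples=5000, seed=0)
        hits = find_pwm_hits(pwm, "ACGTA")
        assert len(hits) == 4

    def test_short_sequence_empty(self, strong_ac_pwm):
        assert find_pwm_hits(strong_ac_pwm, "A") == []

    def test_uncalibrated_rejected(self):
        pwm = Pwm(name="m", counts=np.ones((4, 2)))
        with pytest.raises(ValueError, match="calibrated"):
            find_pwm_hits(pwm, "ACGT")

    def test_rc_scan_uses_reverse_complement_matrix(self, strong_ac_pwm):
        hits = find_pwm_hits(strong_ac_pwm, "TTGTTT", rc=True)
        minus = [h for h in hits if h.strand_of_match == "-"]
        assert [(h.u_start, h.u_end) for h in minus] == [(2, 4)]
        assert minus[0].matched_sequence == "GT"

    @settings(max_examples=200, deadline=None)
    @given(st.text(alphabet="ACGTN", min_size=0, max_size=50), st.data())
    def test_oracle_equivalence(self, seq, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31)))
        counts = rng.integers(0, 20, size=(4, 3)).astype(float)
        pwm = Pwm(name="r", counts=counts).calibrated(
            p_value=data.draw(st.sampled_from([0.01, 0.1, 0.5, 1.0])),
            n_samples=1000 + 1,
            seed=0,
        )
        hits = find_pwm_hits(pwm, seq)
        assert {(h.u_start, h.u_end) for h in hits} == naive_pwm_scan(pwm, seq)


class TestRegexSearch:
    def test_scan_and_resume(self):
        rs = RegexSet(patterns=(("r1", "GA+T"),))
        hits = find_regex_hits(rs, "GAATXGAT")
        assert [(h.u_start, h.u_end, h.matched_sequence) for h in hits] == [
            (0, 4, "GAAT"),
            (5, 8, "GAT"),
        ]

    def test_anchored_empty_pattern_no_match(self):
        assert find_regex_hits(RegexSet(patterns=(("r", "^$"),)), "ACGT") == []

    def test_zero_length_matches_discarded(self):
        assert find_regex_hits(RegexSet(patterns=(("r", "A*"),)), "CCC") == []

    def test_distinct_patterns_may_overlap(self):
        rs = RegexSet(patterns=(("a", "ACG"), ("b", "CGT")))
        hits = find_regex_hits(rs, "ACGT")
        assert {(h.motif_id, h.u_start) for h in hits} == {("a", 0), ("b", 1)}

    def test_case_insensitive(self):
        hits = find_regex_hits(RegexSet(patterns=(("r", "GAT"),)), "xgatx")
        assert hits[0].matched_sequence == "gat"

    def test_rc_coordinates_mapped_back(self):
        # "CAT" on the reverse complement of "GATG..." -> forward "ATG"
        hits = find_regex_hits(RegexSet(patterns=(("r", "CAT"),)), "ATGC", rc=True)
        assert [(h.u_start, h.u_end, h.strand_of_match) for h in hits] == [(0, 3, "-")]
        assert hits[0].matched_sequence == "ATG"

    @settings(max_examples=200, deadline=None)
    @given(
        st.text(alphabet="ACGT", min_size=0, max_size=60),
        st.sampled_from(["GA+T", "AC[GT]", "T{2,}", "A.G", "(?:AC)+"]),
    )
    def test_oracle_equivalence(self, seq, pattern):
        rs = RegexSet(patterns=(("r", pattern),))
        got = [(h.u_start, h.u_end) for h in find_regex_hits(rs, seq)]
        expected = [
            m.span()
            for m in re.finditer(pattern, seq, re.IGNORECASE)
            if m.start() != m.end()
        ]
        assert got == expected


class TestToGenomic:
    def test_plus_strand(self):
        seq = AlignedSequence("hg.chr1", 10, 20, "+", 100, "A" * 20)
        assert to_genomic(seq, 5, 9) == ("chr1", 15, 19)

    def test_minus_strand_hand_case(self):
        seq = AlignedSequence("hg.chr1", 10, 20, "-", 100, "A" * 20)
        assert to_genomic(seq, 5, 9) == ("chr1", 81, 85)

    def test_full_span_plus(self):
        seq = AlignedSequence("hg.chr1", 7, 4, "+", 100, "ACGT")
        assert to_genomic(seq, 0, 4) == ("chr1", 7, 11)

    def test_undotted_src_uses_src_as_chrom(self):
        seq = AlignedSequence("plasmid", 0, 4, "+", 10, "ACGT")
        assert to_genomic(seq, 0, 2) == ("plasmid", 0, 2)

    def test_out_of_range(self):
        seq = AlignedSequence("hg.chr1", 0, 4, "+", 10, "ACGT")
        with pytest.raises(ValueError):
            to_genomic(seq, 2, 6)

    def test_minus_strand_span_length_preserved(self):
        seq = AlignedSequence("hg.chr1", 3, 10, "-", 50, "A" * 10)
        chrom, s, e = to_genomic(seq, 2, 7)
        assert e - s == 5
        assert s == 50 - (3 + 7)


class TestSearchBlock:
    def test_spec_example_block(self):
        blocks = parse_text(
            "a\ns hg.chr1 0 4 + 100 AC-GT\ns mm.chr1 0 5 + 50 ACAGT\n"
        )
        hits = search_block(blocks[0], KmerSet(kmers=(("m", "ACGT"),)))
        assert len(hits) == 1
        hit = hits[0]
        assert (hit.u_start, hit.u_end) == (0, 4)
        assert (hit.g_start, hit.g_end) == (0, 5)
        assert hit.records[0].vector.symbols == "11–11"
        assert hit.records[0].percent == pytest.approx(80.0)
        assert hit.block_conservation == pytest.approx(80.0)

    def test_absent_motif_empty(self, two_blocks):
        assert search_block(two_blocks[0], KmerSet(kmers=(("m", "GGGGG"),))) == []

    def test_search_src_by_genome_prefix(self, two_blocks):
        hits = search_block(
            two_blocks[0],
            KmerSet(kmers=(("m", "ACAGT"),)),
            SearchOptions(search_src="mm"),
        )
        assert len(hits) == 1
        assert hits[0].genome == "mm"
        assert hits[0].records[0].compared_src == "hg.chr1"

    def test_missing_search_src_skips_block(self, two_blocks):
        assert (
            search_block(
                two_blocks[0],
                KmerSet(kmers=(("m", "AC"),)),
                SearchOptions(search_src="rn.chr2"),
            )
            == []
        )

    def test_genome_ids_restrict_comparisons(self, two_blocks):
        block = two_blocks[1]  # hg, mm, rn
        hits = search_block(
            block,
            KmerSet(kmers=(("m", "GATTAC"),)),
            SearchOptions(genome_ids=("rn",)),
        )
        assert [r.compared_src for r in hits[0].records] == ["rn.chr2"]

    def test_rc_hit_strand(self):
        blocks = parse_text("a\ns hg.chr1 0 4 + 100 ATGA\n")
        hits = search_block(
            blocks[0], KmerSet(kmers=(("m", "CAT"),)), SearchOptions(rc=True)
        )
        assert [(h.u_start, h.strand_of_match) for h in hits] == [(0, "-")]

    def test_block_independence_under_permutation(self, two_blocks):
        ks = KmerSet(kmers=(("m", "GATTAC"), ("n", "AC"),))
        forward = [search_block(b, ks, block_index=i) for i, b in enumerate(two_blocks)]
        reverse = [
            search_block(b, ks, block_index=i)
            for i, b in enumerate(reversed(two_blocks))
        ]
        strip = lambda hits: [
            (h.motif_id, h.u_start, h.u_end, h.g_start, h.g_end,
             tuple((r.compared_src, r.vector.symbols) for r in h.records))
            for h in hits
        ]
        assert [strip(h) for h in reverse] == [strip(h) for h in reversed(forward)]

    def test_pwm_hits_carry_score_and_p(self, strong_ac_pwm):
        blocks = parse_text("a\ns hg.chr1 0 6 + 100 TTACTT\ns mm.chr1 0 6 + 50 TTACTT\n")
        hits = search_block(blocks[0], [strong_ac_pwm])
        assert len(hits) == 1
        assert hits[0].motif_kind == "pwm"
        assert hits[0].score is not None and hits[0].p_value is not None
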