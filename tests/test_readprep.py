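"""Demultiplexing, trimming, merging, and the 80-bp length filter."""

import pytest

from ampsel.readprep import (
    MergedRead,
    ReadPair,
    demux_by_index,
    length_filter,
    merge_pair,
    prep_reads,
    quality_trim,
)
from ampsel.seq import revcomp
from ampsel.simulate import SimConfig, TruthGenotype, simulate_library
from conftest import make_panel


def pair(seq1, seq2, q1=None, q2=None, i5="AACCGGTT", i7="TTGGCCAA", rid="r1"):
    return ReadPair(rid, seq1, q1 or "?" * len(seq1), seq2, q2 or "?" * len(seq2), i5, i7)


class TestDemux:
    def test_exact_match_assigns(self, toy_panel):
        groups = demux_by_index([pair("ACGT", "ACGT")], toy_panel, 0)
        assert len(groups["s00"]) == 1
        assert not groups["unassigned"]

    def test_one_mismatch_with_tolerance(self, toy_panel):
        p = pair("ACGT", "ACGT", i5="AACCGGTA")  # 1 sub in i5
        assert demux_by_index([p], toy_panel, 0)["unassigned"] == [p]
        groups = demux_by_index([p], toy_panel, 1)
        assert len(groups["s00"]) == 1

    def test_equidistant_indexes_stay_unassigned(self):
        from ampsel.panel import MarkerPanel, SampleRecord

        panel = MarkerPanel(
            markers=make_panel().markers,
            samples=[
                SampleRecord("a", "AAAAAAAA", "CCCCCCCC"),
                SampleRecord("b", "AAAAAAAT", "CCCCCCCC"),
            ],
        )
        # observed i5 one substitution from both samples' i5
        p = pair("ACGT", "ACGT", i5="AAAAAAAG", i7="CCCCCCCC")
        groups = demux_by_index([p], panel, max_index_mismatch=1)
        assert groups["unassigned"] == [p]

    def test_strictly_closer_sample_wins(self):
        from ampsel.panel import MarkerPanel, SampleRecord

        panel = MarkerPanel(
            markers=make_panel().markers,
            samples=[
                SampleRecord("a", "AAAAAAAA", "CCCCCCCC"),
                SampleRecord("b", "AAAATTTT", "CCCCCCCC"),
            ],
        )
        p = pair("ACGT", "ACGT", i5="AAAAAAAT", i7="CCCCCCCC")
        groups = demux_by_index([p], panel, max_index_mismatch=1)
        assert len(groups["a"]) == 1

    def test_partition_exhaustive_and_disjoint(self, toy_panel):
        pairs = [
            pair("A", "A", i5=s.i5_index, i7=s.i7_index, rid=f"r{i}")
            for i, s in enumerate(toy_panel.samples)
        ] + [pair("A", "A", i5="GGGGGGGG", i7="CCCCCCCC", rid="junk")]
        groups = demux_by_index(pairs, toy_panel, 0)
        assert sum(len(v) for v in groups.values()) == len(pairs)
        assert len(groups["unassigned"]) == 1


class TestQualityTrim:
    def test_high_quality_read_unchanged(self):
        s, q = quality_trim("ACGTACGT", "?" * 8, q_threshold=20)
        assert (s, q) == ("ACGTACGT", "?" * 8)

    def test_trailing_low_quality_removed(self):
        qual = "?" * 5 + "+" * 5  # Q30 x5 then Q10 x5
        s, q = quality_trim("ACGTACGTAC", qual, q_threshold=20)
        assert s == "ACGTA" and q == "?" * 5

    def test_exact_adapter_suffix_removed(self):
        adapter = "GTGACTGGAGTTCAGACGTGT"
        read = "ACGTACGTACGTACGTACGT" + adapter
        s, _ = quality_trim(read, "?" * len(read), adapter=adapter)
        assert s == "ACGTACGTACGTACGTACGT"

    def test_partial_adapter_suffix_removed(self):
        adapter = "GTGACTGGAGTTCAGACGTGT"
        read = "ACGTACGTACGTACGTACGT" + adapter[:8]
        s, _ = quality_trim(read, "?" * len(read), adapter=adapter)
        assert s == "ACGTACGTACGTACGTACGT"

    def test_adapter_with_one_mismatch_per_10nt_removed(self):
        adapter = "GTGACTGGAGTTCAGACGTGT"
        mutated = "C" + adapter[1:11] + "A" + adapter[12:]
        read = "ACGTACGTACGTACGTACGT" + mutated
        s, _ = quality_trim(read, "?" * len(read), adapter=adapter)
        assert s == "ACGTACGTACGTACGTACGT"


class TestMerge:
    def test_exact_overlap_arithmetic(self, rng):
        """100-nt exact overlap: merged length is len1 + len2 - 100."""
        insert = "".join(rng.choice(list("ACGT"), size=200))
        s1, s2 = insert[:150], revcomp(insert[50:])
        m = merge_pair(pair(s1, s2))
        assert m is not None
        assert m.length == 200
        assert m.sequence == insert

    def test_no_admissible_overlap_fails(self, rng):
        a = "".join(rng.choice(list("AC"), size=60))
        b = "".join(rng.choice(list("GT"), size=60))
        assert merge_pair(pair(a, b)) is None

    def test_mismatch_resolved_to_higher_quality_base(self):
        insert = "ACGTACGTACGTACGTACGT"
        s1 = insert
        s2 = revcomp(insert)
        # corrupt one base of read 1 at low quality
        s1 = "T" + s1[1:]
        q1 = "0" + "?" * (len(s1) - 1)  # Q15 at the corrupted base
        m = merge_pair(ReadPair("r", s1, q1, s2, "?" * len(s2), "", ""))
        assert m.sequence == insert

    def test_outie_full_overlap_recovers_insert(self, rng):
        """Mates reading through a short amplicon merge to the insert only."""
        insert = "".join(rng.choice(list("ACGT"), size=127))
        ad1 = "GTGACTGGAGTTCAGACGTGTGCA"[:23]
        ad2 = "ACACTCTTTCCCTACACGACGCT"[:23]
        s1 = insert + ad1  # 150 nt
        s2 = revcomp(ad2 + insert)[:150]
        m = merge_pair(pair(s1, s2))
        assert m is not None
        assert m.length == 127
        assert m.sequence == insert

    def test_merge_symmetry(self, rng):
        """Swapping mates yields the reverse-complementary merged sequence."""
        insert = "".join(rng.choice(list("ACGT"), size=180))
        s1, s2 = insert[:150], revcomp(insert[30:])
        m_fwd = merge_pair(pair(s1, s2))
        m_rev = merge_pair(pair(s2, s1))
        assert m_fwd is not None and m_rev is not None
        assert m_rev.sequence == revcomp(m_fwd.sequence)


class TestLengthFilter:
    @pytest.mark.parametrize("length,kept", [(79, 0), (80, 1), (81, 1)])
    def test_boundary(self, length, kept):
        reads = [MergedRead("s", "A" * length, length, 30.0)]
        out, dropped = length_filter(reads)
        assert len(out) == kept and dropped == 1 - kept


@pytest.fixture(scope="module")
def prepped(tmp_path_factory):
    panel = make_panel(n_samples=3)
    truth = [
        TruthGenotype("s00", "SSR_A", [(127, 2)]),
        TruthGenotype("s01", "SSR_A", [(127, 1), (133, 1)]),
        TruthGenotype("s02", "SSR_B", [(108, 1), (114, 1)]),
    ]
    cfg = SimConfig(
        mean_depth_per_marker=400, stutter_prob=0, plus_one_prob=0,
        seq_error_rate=0, incomplete_frac=0.1, dimer_frac=0.2, seed=17,
    )
    out = tmp_path_factory.mktemp("sim")
    res = simulate_library(panel, truth, cfg, out)
    merged, stats = prep_reads(res.r1_path, res.r2_path, panel)
    return panel, truth, res, merged, stats


class TestSimulatorRoundTrip:
    def test_read_conservation_through_stages(self, prepped):
        _, _, res, merged, stats = prepped
        assert stats.n_input == sum(res.class_counts.values())
        assigned = sum(e["assigned"] for e in stats.per_sample.values())
        assert stats.n_input == assigned + stats.n_unassigned
        for sid, e in stats.per_sample.items():
            assert e["assigned"] == (
                e["kept"] + e["trim_dropped"] + e["merge_failed"] + e["length_filtered"]
            )
            assert e["kept"] == len(merged[sid])

    def test_noise_free_demux_and_lengths_perfect(self, prepped):
        """Without hopping/error, every kept read has its true allele length."""
        _, truth, res, merged, stats = prepped
        true_lengths = {t.sample_id: {a for a, _ in t.allele_copies} for t in truth}
        # incomplete products (blank indexes) are exactly the unassigned ones
        assert stats.n_unassigned == res.class_counts["incomplete"]
        for t in truth:
            lengths = {m.length for m in merged[t.sample_id]}
            assert lengths == true_lengths[t.sample_id]

    def test_dimers_all_filtered_no_on_target_lost(self, prepped):
        _, _, res, merged, stats = prepped
        filtered = sum(e["length_filtered"] for e in stats.per_sample.values())
        assert filtered == res.class_counts["dimer"]
        kept = sum(e["kept"] for e in stats.per_sample.values())
        assert kept == res.class_counts["on_target"]
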