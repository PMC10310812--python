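"""Genotype calling, dosage apportionment, and selection decisions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ampsel.assign_count import AlleleTable, TopAlleles
from ampsel.calling import (
    CallingParams,
    call_diploid,
    call_polyploid,
    evaluate_mas,
    exhaustive_dosage,
    largest_remainder_dosage,
    select_individuals,
)
from ampsel.errors import AmpselError
from ampsel.reference import (
    apple_demo_markers,
    load_apple_genotyping_table,
    load_pear_mas_table,
    pear_mas_markers,
)
from ampsel.report_io import top_alleles_to_table
from conftest import make_marker_ssr


def top(entries, sample="s", marker="m", total=1000):
    return TopAlleles(
        sample_id=sample,
        marker=marker,
        entries=[(a, int(round(f * total)), f) for a, f in entries],
        total_marker_reads=total,
    )


class TestDiploid:
    def test_clear_heterozygote(self):
        m = make_marker_ssr(unit=3)
        call = call_diploid(top([(108, 0.49), (114, 0.45), (111, 0.02), (107, 0.01)]), m)
        assert call.rendering == "108/114"

    def test_near_fixed_homozygote(self):
        m = make_marker_ssr(unit=2)
        call = call_diploid(top([(162, 0.99), (161, 0.01)]), m)
        assert call.rendering == "162/162"

    def test_stutter_folded_into_parent(self):
        """A one-unit-below entry within the stutter ratio joins its parent."""
        m = make_marker_ssr(unit=2)
        call = call_diploid(top([(127, 0.48), (125, 0.20), (123, 0.05)]), m)
        assert call.rendering == "127/127"

    def test_lone_weak_candidate_flagged(self):
        m = make_marker_ssr(unit=2)
        call = call_diploid(top([(127, 0.55), (120, 0.08)]), m)
        assert call.rendering == "127/127"
        assert "stutter-ambiguous" in call.flags

    def test_low_depth_flagged_but_called(self):
        m = make_marker_ssr(unit=2)
        call = call_diploid(top([(127, 0.5), (133, 0.45)], total=20), m)
        assert call.rendering == "127/133"
        assert "low-depth" in call.flags

    def test_empty_is_no_call(self):
        m = make_marker_ssr(unit=2)
        call = call_diploid(TopAlleles(sample_id="s", marker="m", no_data=True), m)
        assert call.rendering == "no-call"


class TestPolyploid:
    def test_duplex_simplex_triploid(self):
        m = make_marker_ssr(unit=3)
        call = call_polyploid(top([(108, 0.65), (114, 0.30), (105, 0.02), (107, 0.02)]), 3, m)
        assert call.rendering == "108/108/114"

    def test_balanced_triploid(self):
        m = make_marker_ssr(unit=3)
        call = call_polyploid(top([(108, 0.34), (105, 0.33), (114, 0.29), (111, 0.01)]), 3, m)
        assert call.rendering == "105/108/114"

    def test_indel_duplex(self):
        m = apple_demo_markers()[1]  # indel, no repeat unit
        call = call_polyploid(top([(162, 0.63), (159, 0.35)]), 3, m)
        assert call.rendering == "159/162/162"

    def test_single_allele_triplex(self):
        m = make_marker_ssr(unit=2)
        call = call_polyploid(top([(162, 0.99), (161, 0.01)]), 3, m)
        assert call.rendering == "162/162/162"

    def test_over_allelic_truncated_and_flagged(self):
        m = apple_demo_markers()[1]
        call = call_polyploid(
            top([(100, 0.30), (110, 0.25), (120, 0.24), (130, 0.21)]), 3, m
        )
        assert "over-allelic" in call.flags
        assert sum(d for _, d in call.alleles_with_dosage) == 3

    def test_dosage_conserved_property(self, rng):
        m = apple_demo_markers()[1]
        for _ in range(200):
            ploidy = int(rng.integers(2, 7))
            k = int(rng.integers(1, 5))
            raw = rng.dirichlet(np.ones(k) * 2)
            entries = sorted(
                [(int(100 + 3 * i), float(f)) for i, f in enumerate(raw)],
                key=lambda t: -t[1],
            )
            call = call_polyploid(top(entries), ploidy, m)
            if call.alleles_with_dosage:
                assert sum(d for _, d in call.alleles_with_dosage) == call.ploidy


class TestDosageApportionment:
    @given(
        st.integers(2, 6).flatmap(
            lambda p: st.tuples(
                st.just(p),
                st.lists(st.floats(0.01, 1.0), min_size=1, max_size=4).filter(
                    lambda fs: len(fs) <= p
                ),
            )
        )
    )
    @settings(max_examples=300, deadline=None)
    def test_largest_remainder_equals_exhaustive_search(self, case):
        """Apportionment matches brute-force L1-minimisation for k<=4, p<=6."""
        ploidy, raw = case
        total = sum(raw)
        freqs = sorted((f / total for f in raw), reverse=True)
        assert largest_remainder_dosage(freqs, ploidy) == exhaustive_dosage(freqs, ploidy)

    def test_every_allele_gets_a_copy(self):
        assert largest_remainder_dosage([0.97, 0.02, 0.01], 3) == [1, 1, 1]

    def test_too_many_alleles_raises(self):
        with pytest.raises(AmpselError):
            largest_remainder_dosage([0.4, 0.3, 0.3], 2)


class TestMAS:
    def test_threshold_is_strict(self):
        m = make_marker_ssr(target_alleles=[127], carrier_threshold=0.30)
        t = AlleleTable(sample_id="s", marker="SSR_A")
        t.add(127, 30)
        t.add(129, 70)
        d = evaluate_mas(t, m)
        assert d.target_frequency == pytest.approx(0.30)
        assert not d.carries  # exactly at threshold -> non-carrier

    def test_absent_target_is_zero(self):
        m = make_marker_ssr(target_alleles=[127], carrier_threshold=0.30)
        t = AlleleTable(sample_id="s", marker="SSR_A")
        t.add(129, 100)
        d = evaluate_mas(t, m)
        assert d.target_frequency == 0.0 and not d.carries

    def test_multiple_target_alleles_sum(self):
        m = make_marker_ssr(target_alleles=[127, 129], carrier_threshold=0.30)
        t = AlleleTable(sample_id="s", marker="SSR_A")
        t.add(127, 20)
        t.add(129, 15)
        t.add(133, 65)
        assert evaluate_mas(t, m).target_frequency == pytest.approx(0.35)

    def test_zero_reads_is_no_data(self):
        m = make_marker_ssr(target_alleles=[127], carrier_threshold=0.30)
        d = evaluate_mas(AlleleTable(sample_id="s", marker="SSR_A"), m)
        assert "no-data" in d.flags and not d.carries

    def test_monotonicity_in_target_reads(self):
        """Adding target-allele reads never flips a carrier to non-carrier."""
        m = make_marker_ssr(target_alleles=[127], carrier_threshold=0.30)
        previous = False
        for extra in range(0, 200, 10):
            t = AlleleTable(sample_id="s", marker="SSR_A")
            t.add(127, 50 + extra)
            t.add(129, 100)
            carries = evaluate_mas(t, m).carries
            assert carries or not previous
            previous = carries


class TestSelection:
    def test_vacuous_requirement_selects_all(self):
        m = make_marker_ssr(target_alleles=[127], carrier_threshold=0.30)
        t = AlleleTable(sample_id="s", marker="SSR_A")
        t.add(129, 100)
        report = select_individuals([evaluate_mas(t, m)], [])
        assert report.selected == {"s": True}

    def test_missing_decision_is_hard_error(self):
        m = make_marker_ssr(target_alleles=[127], carrier_threshold=0.30)
        t = AlleleTable(sample_id="s", marker="SSR_A")
        t.add(127, 100)
        with pytest.raises(AmpselError, match="other_marker"):
            select_individuals([evaluate_mas(t, m)], ["other_marker"])

    def test_single_marker_selection_equals_carrier_set(self):
        tops, _ = load_pear_mas_table()
        marker = pear_mas_markers()[0]
        decisions = [
            evaluate_mas(top_alleles_to_table(t), marker)
            for t in tops
            if t.marker == marker.name
        ]
        report = select_individuals(decisions, [marker.name])
        carriers = {d.sample_id for d in decisions if d.carries}
        assert set(report.selected_samples()) == carriers


class TestPublishedTables:
    def test_apple_genotypes_reproduced(self):
        """Every published apple genotype string is reproduced from frequencies."""
        tops, expected = load_apple_genotyping_table()
        markers = {m.name: m for m in apple_demo_markers()}
        for t in tops:
            ploidy, genotype = expected[(t.sample_id, t.marker)]
            if ploidy == 2:
                call = call_diploid(t, markers[t.marker])
            else:
                call = call_polyploid(t, ploidy, markers[t.marker])
            assert call.rendering == genotype, (t.sample_id, t.marker)

    def test_pear_mas_evaluations_reproduced(self):
        """Target frequencies and carrier labels match the published rows."""
        tops, expected = load_pear_mas_table()
        markers = {m.name: m for m in pear_mas_markers()}
        for t in tops:
            freq, label = expected[(t.sample_id, t.marker)]
            d = evaluate_mas(top_alleles_to_table(t), markers[t.marker])
            assert d.label == label, (t.sample_id, t.marker)
            assert d.target_frequency == pytest.approx(freq, abs=0.005)

    def test_unique_seedling_selected(self):
        tops, _ = load_pear_mas_table()
        markers = {m.name: m for m in pear_mas_markers()}
        decisions = [
            evaluate_mas(top_alleles_to_table(t), markers[t.marker])
            for t in tops
            if t.sample_id.startswith("Seedling")
        ]
        report = select_individuals(
            decisions, ["TsuENH157.mod", "PPACS2", "Psc07"]
        )
        assert report.selected_samples() == ["Seedling 7"]
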