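"""Site classification, block calling, midpoint expansion, and summaries."""

import itertools

import numpy as np
import pytest

from helpers import classify_oracle, expand_oracle, gt, make_table
from lagerpaint.painter import (
    QUERY_MISSING,
    REPS_MISSING,
    SHARED_BY_MULTIPLE,
    SHARED_BY_NONE,
    UNASSIGNED,
    AncestryBlock,
    Population,
    PopulationScheme,
    RawBlock,
    SiteAssignment,
    call_blocks,
    classify_site,
    expand_blocks,
    percentages_from_bp,
    summarize,
    summarize_across_strains,
)
from lagerpaint.vcf_io import GenomeIndex, GenotypeCall, VariantSite

GENOTYPES = [None, (0, 0), (0, 1), (1, 1)]
LABELS = ("Tibet", "Ireland", "NorthCarolina")


def single_rep_scheme():
    return PopulationScheme(
        "query",
        tuple(
            Population(lab, frozenset({f"rep_{lab}"}), frozenset({f"rep_{lab}"}))
            for lab in LABELS
        ),
    )


def site_for(genotypes):
    calls = tuple(GenotypeCall(g, 50, 99) for g in genotypes)
    return VariantSite("chr1", 100, "A", ("G",), calls)


ROSTER = ("query", "rep_Tibet", "rep_Ireland", "rep_NorthCarolina")


class TestClassifySite:
    def test_alt_uniquely_shared_with_one_population(self):
        # query and the Tibet rep carry ALT; other reps are hom REF
        a = classify_site(site_for([(0, 1), (1, 1), (0, 0), (0, 0)]), single_rep_scheme(), ROSTER)
        assert a.label == "Tibet" and a.reason is None

    def test_allele_shared_with_two_populations_is_ambiguous(self):
        # an allele carried by two populations' reps can never assign either one
        a = classify_site(site_for([(1, 1), (1, 1), (1, 1), (0, 0)]), single_rep_scheme(), ROSTER)
        assert a.label == UNASSIGNED and a.reason == SHARED_BY_NONE
        # a heterozygous query whose two alleles are each uniquely shared with a
        # different population is ambiguous
        two_pop = PopulationScheme(
            "query",
            (
                Population("Tibet", frozenset({"rep_Tibet"}), frozenset({"rep_Tibet"})),
                Population("Ireland", frozenset({"rep_Ireland"}), frozenset({"rep_Ireland"})),
            ),
        )
        site = VariantSite(
            "chr1", 100, "A", ("G",),
            tuple(GenotypeCall(g, 50, 99) for g in [(0, 1), (1, 1), (0, 0)]),
        )
        b = classify_site(site, two_pop, ("query", "rep_Tibet", "rep_Ireland"))
        assert b.label == UNASSIGNED and b.reason == SHARED_BY_MULTIPLE

    def test_ref_allele_can_be_the_diagnostic_allele(self):
        # query hom REF, Ireland rep hom REF, others hom ALT: REF is uniquely shared
        a = classify_site(site_for([(0, 0), (1, 1), (0, 0), (1, 1)]), single_rep_scheme(), ROSTER)
        assert a.label == "Ireland"

    def test_missing_query_and_missing_reps(self):
        scheme = single_rep_scheme()
        a = classify_site(site_for([None, (1, 1), (0, 0), (0, 0)]), scheme, ROSTER)
        assert a.reason == QUERY_MISSING
        b = classify_site(site_for([(0, 1), None, (0, 0), (0, 0)]), scheme, ROSTER)
        assert b.reason == REPS_MISSING

    def test_matches_set_algebra_oracle_on_all_configurations(self):
        """Exhaustive check over every 3-population x diploid-genotype layout."""
        scheme = single_rep_scheme()
        for combo in itertools.product(GENOTYPES, repeat=4):
            got = classify_site(site_for(list(combo)), scheme, ROSTER)
            expected = classify_oracle(
                frozenset(combo[0] or ()),
                {lab: frozenset(combo[i + 1] or ()) for i, lab in enumerate(LABELS)},
            )
            observed = got.label if got.is_assigned else got.reason
            assert observed == expected, f"genotypes {combo}"

    def test_population_order_does_not_matter(self):
        scheme = single_rep_scheme()
        flipped = PopulationScheme("query", tuple(reversed(scheme.populations)))
        for combo in itertools.product(GENOTYPES, repeat=4):
            a = classify_site(site_for(list(combo)), scheme, ROSTER)
            b = classify_site(site_for(list(combo)), flipped, ROSTER)
            assert (a.label, a.reason) == (b.label, b.reason)

    def test_alt_presence_only_mode_ignores_ref_sharing(self):
        a = classify_site(
            site_for([(0, 0), (1, 1), (0, 0), (1, 1)]),
            single_rep_scheme(),
            ROSTER,
            alt_presence_only=True,
        )
        assert a.reason == QUERY_MISSING  # query carries no ALT allele

    def test_scheme_roster_mismatch_raises(self):
        with pytest.raises(ValueError, match="not in roster"):
            classify_site(site_for([(0, 0), (0, 0)]), single_rep_scheme(), ("query", "rep_Tibet"))


def asg(pos, label, reason=None):
    return SiteAssignment("chr1", pos, label, reason)


class TestCallBlocks:
    def test_two_clean_runs(self):
        blocks = call_blocks([asg(100, "A"), asg(200, "A"), asg(500, "B"), asg(600, "B")])
        assert [(b.label, b.first_pos, b.last_pos, b.support) for b in blocks] == [
            ("A", 100, 200, 2), ("B", 500, 600, 2),
        ]

    def test_singleton_forms_no_block_but_breaks_runs(self):
        blocks = call_blocks([asg(100, "A"), asg(300, "B"), asg(400, "B")])
        assert [(b.label, b.first_pos, b.last_pos) for b in blocks] == [("B", 300, 400)]
        # a singleton of a different population splits an otherwise continuous run
        split = call_blocks([asg(10, "A"), asg(20, "A"), asg(30, "B"),
                             asg(40, "A"), asg(50, "A")])
        assert [(b.label, b.first_pos, b.last_pos) for b in split] == [
            ("A", 10, 20), ("A", 40, 50),
        ]

    def test_empty_input(self):
        assert call_blocks([]) == []

    def test_unassigned_sites_are_transparent_by_default(self):
        stream = [asg(10, "A"), asg(20, UNASSIGNED, SHARED_BY_NONE), asg(30, "A")]
        blocks = call_blocks(stream)
        assert [(b.label, b.first_pos, b.last_pos, b.support) for b in blocks] == [
            ("A", 10, 30, 2)
        ]
        assert call_blocks(stream, unassigned_breaks_runs=True) == []

    def test_min_support_threshold(self):
        stream = [asg(10, "A"), asg(20, "A"), asg(30, "A")]
        assert len(call_blocks(stream, min_support=3)) == 1
        assert len(call_blocks(stream, min_support=4)) == 0

    def test_query_missing_desert_breaks_and_becomes_unassigned(self):
        stream = (
            [asg(10, "A"), asg(20, "A")]
            + [asg(30 + i, UNASSIGNED, QUERY_MISSING) for i in range(10)]
            + [asg(100, "A"), asg(110, "A")]
        )
        blocks = call_blocks(stream, missing_run_cap=10)
        assert [(b.label, b.first_pos, b.last_pos) for b in blocks] == [
            ("A", 10, 20), (UNASSIGNED, 30, 39), ("A", 100, 110),
        ]
        # below the cap the missing run is transparent
        assert [
            (b.label, b.first_pos, b.last_pos)
            for b in call_blocks(stream, missing_run_cap=11)
        ] == [("A", 10, 110)]

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            call_blocks([asg(200, "A"), asg(100, "A")])


class TestExpandBlocks:
    def test_midpoint_border_worked_example(self):
        raw = [RawBlock("chr1", "A", 100, 200, 2), RawBlock("chr1", "B", 500, 600, 2)]
        out = expand_blocks(raw, 1000)
        assert [(b.start, b.end, b.label) for b in out] == [(0, 350, "A"), (350, 1000, "B")]
        assert [b.length for b in out] == [350, 650]

    def test_single_block_covers_chromosome(self):
        out = expand_blocks([RawBlock("chr1", "A", 400, 450, 3)], 1000)
        assert [(b.start, b.end, b.label) for b in out] == [(0, 1000, "A")]

    def test_no_blocks_yields_unassigned_chromosome(self):
        out = expand_blocks([], 1000, chrom="chr1")
        assert [(b.start, b.end, b.label) for b in out] == [(0, 1000, UNASSIGNED)]

    def test_same_label_neighbours_merge(self):
        raw = [
            RawBlock("chr1", "A", 10, 20, 2),
            RawBlock("chr1", "A", 50, 60, 2),
            RawBlock("chr1", "B", 90, 95, 2),
        ]
        out = expand_blocks(raw, 100)
        assert [(b.start, b.end, b.label) for b in out] == [(0, 75, "A"), (75, 100, "B")]
        assert out[0].support == 4 and out[0].outermost == (10, 60)

    def test_out_of_range_block_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            expand_blocks([RawBlock("chr1", "A", 10, 2000, 2)], 1000)
        with pytest.raises(ValueError, match="overlap"):
            expand_blocks(
                [RawBlock("chr1", "A", 10, 50, 2), RawBlock("chr1", "B", 40, 80, 2)], 100
            )

    def test_matches_per_base_nearest_site_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            length = int(rng.integers(50, 2000))
            n_blocks = int(rng.integers(1, 8))
            edges = np.sort(rng.choice(np.arange(1, length + 1), 2 * n_blocks, replace=False))
            raw = [
                RawBlock(
                    "chr1",
                    str(rng.choice(["A", "B", "C"])),
                    int(edges[2 * i]),
                    int(edges[2 * i + 1]),
                    2,
                )
                for i in range(n_blocks)
            ]
            got = [(b.start, b.end, b.label) for b in expand_blocks(raw, length)]
            assert got == expand_oracle(raw, length)

    def test_tiling_is_exact(self):
        rng = np.random.default_rng(7)
        length = 5000
        edges = np.sort(rng.choice(np.arange(1, length + 1), 12, replace=False))
        raw = [
            RawBlock("chr1", str(rng.choice(["A", "B"])), int(edges[2 * i]), int(edges[2 * i + 1]), 2)
            for i in range(6)
        ]
        out = expand_blocks(raw, length)
        assert out[0].start == 0 and out[-1].end == length
        for left, right in zip(out, out[1:]):
            assert left.end == right.start
        assert sum(b.length for b in out) == length


INDEX_1CHR = GenomeIndex((("chr1", 1000),))


class TestSummarize:
    def test_two_block_arithmetic(self):
        blocks = [
            AncestryBlock("chr1", 0, 350, "A"),
            AncestryBlock("chr1", 350, 1000, "B"),
        ]
        s = summarize(blocks, INDEX_1CHR)
        assert s.bp_by_pop == {"A": 350, "B": 650}
        assert s.percent("A") == 35.00 and s.percent("B") == 65.00
        assert s.unassigned_bp == 0 and s.genome_bp == 1000

    def test_unassigned_excluded_from_percentage_denominator(self):
        blocks = [
            AncestryBlock("chr1", 0, 200, "A"),
            AncestryBlock("chr1", 200, 800, UNASSIGNED),
            AncestryBlock("chr1", 800, 1000, "B"),
        ]
        s = summarize(blocks, INDEX_1CHR)
        assert s.percent("A") == s.percent("B") == 50.00
        assert s.assigned_bp + s.unassigned_bp == s.genome_bp == 1000

    def test_gap_or_overlap_rejected(self):
        with pytest.raises(ValueError, match="tiling"):
            summarize([AncestryBlock("chr1", 0, 900, "A")], INDEX_1CHR)
        with pytest.raises(ValueError, match="tiling"):
            summarize(
                [AncestryBlock("chr1", 0, 600, "A"), AncestryBlock("chr1", 500, 1000, "B")],
                INDEX_1CHR,
            )

    def test_percentages_sum_to_100(self):
        pct = percentages_from_bp({"A": 123456, "B": 7890, "C": 11111})
        assert sum(pct.values()) == pytest.approx(100.0)


class TestAcrossStrains:
    def test_mean_of_two_strains(self):
        from lagerpaint.painter import AncestrySummary

        a = AncestrySummary({"Tibet": 5600, "Ireland": 3800, "NC": 600}, 0, 10000)
        b = AncestrySummary({"Tibet": 5200, "Ireland": 4200, "NC": 600}, 0, 10000)
        means = summarize_across_strains([a, b])
        assert means["Tibet"] == pytest.approx(54.0)
        assert means["Ireland"] == pytest.approx(40.0)
        assert means["NC"] == pytest.approx(6.0)

    def test_single_summary_identity(self):
        from lagerpaint.painter import AncestrySummary

        a = AncestrySummary({"A": 300, "B": 700}, 0, 1000)
        means = summarize_across_strains([a])
        assert means == a.percentages

    def test_label_mismatch_rejected(self):
        from lagerpaint.painter import AncestrySummary

        a = AncestrySummary({"A": 1}, 0, 10)
        b = AncestrySummary({"B": 1}, 0, 10)
        with pytest.raises(ValueError, match="labels"):
            summarize_across_strains([a, b])
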