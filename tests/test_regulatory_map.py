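import numpy as np
import pandas as pd
import pytest

from liveraging.io_formats import GeneAnnotation, GenomicInterval
from liveraging.regulatory_map import (
    assign_peaks,
    build_anchors,
    classify_concordance,
    is_concordant,
    linked_enhancer_stats,
    promoter_windows,
)
from tests.conftest import random_intervals


def brute_force_merge(intervals, max_gap=0):
    """O(n^2) transitive-closure oracle for interval merging."""
    parent = list(range(len(intervals)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(intervals)):
        for j in range(i + 1, len(intervals)):
            a, b = intervals[i], intervals[j]
            if a.chrom == b.chrom and a.start <= b.end + max_gap and b.start <= a.end + max_gap:
                parent[find(i)] = find(j)
    groups = {}
    for i, iv in enumerate(intervals):
        groups.setdefault(find(i), []).append(iv)
    merged = sorted(
        (g[0].chrom, min(iv.start for iv in g), max(iv.end for iv in g), len(g))
        for g in groups.values()
    )
    return merged


class TestPromoterWindows:
    def test_plain_arithmetic(self):
        (win,) = promoter_windows([GeneAnnotation("g", "chr1", 10_000, "+")]).values()
        assert (win.start, win.end) == (7000, 13_000)

    def test_clipped_at_zero(self):
        (win,) = promoter_windows([GeneAnnotation("g", "chr1", 1000, "+")]).values()
        assert (win.start, win.end) == (0, 4000)

    def test_strand_symmetry(self):
        plus = promoter_windows([GeneAnnotation("g1", "chr1", 50_000, "+")])["g1"]
        minus = promoter_windows([GeneAnnotation("g2", "chr1", 50_000, "-")])["g2"]
        assert (plus.start, plus.end) == (minus.start, minus.end)
        assert len(plus) == 6000


class TestBuildAnchors:
    def test_book_ended_intervals_merge_at_gap_zero(self):
        anchors = build_anchors(
            [(GenomicInterval("c", 100, 200), {"g1"}), (GenomicInterval("c", 200, 300), {"g2"})]
        )
        assert len(anchors) == 1
        a = anchors[0]
        assert (a.interval.start, a.interval.end) == (100, 300)
        assert a.linked_genes == {"g1", "g2"} and a.n_source_enhancers == 2

    def test_separated_intervals_stay_apart(self):
        anchors = build_anchors(
            [(GenomicInterval("c", 100, 200), {"g1"}), (GenomicInterval("c", 250, 300), {"g2"})]
        )
        assert len(anchors) == 2

    def test_max_gap_bridges_separation(self):
        anchors = build_anchors(
            [(GenomicInterval("c", 100, 200), {"g1"}), (GenomicInterval("c", 250, 300), {"g2"})],
            max_gap=50,
        )
        assert len(anchors) == 1

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(77)
        for _ in range(25):
            ivs = random_intervals(rng, int(rng.integers(2, 120)), max_start=3000)
            anchors = build_anchors([(iv, {iv.name}) for iv in ivs])
            got = sorted(
                (a.interval.chrom, a.interval.start, a.interval.end, a.n_source_enhancers)
                for a in anchors
            )
            assert got == brute_force_merge(ivs)

    def test_idempotent_and_order_independent(self, rng):
        ivs = random_intervals(rng, 80, max_start=2000)
        enh = [(iv, {iv.name}) for iv in ivs]
        anchors = build_anchors(enh)
        again = build_anchors([(a.interval, a.linked_genes) for a in anchors])
        assert [(a.interval, a.linked_genes) for a in again] == [
            (a.interval, a.linked_genes) for a in anchors
        ]
        shuffled = list(enh)
        rng.shuffle(shuffled)
        assert build_anchors(shuffled) == anchors

    def test_base_preservation_at_gap_zero(self, rng):
        ivs = random_intervals(rng, 60, chroms=("chr1",), max_start=2000)
        anchors = build_anchors([(iv, set()) for iv in ivs])
        covered_in = set()
        for iv in ivs:
            covered_in.update(range(iv.start, iv.end))
        covered_out = set()
        for a in anchors:
            covered_out.update(range(a.interval.start, a.interval.end))
        assert covered_in == covered_out


def _deps(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "direction", "mark"])


class TestAssignPeaks:
    PROMOTERS = {"geneA": GenomicInterval("c", 7000, 13_000, name="geneA")}
    ANCHORS = build_anchors(
        [(GenomicInterval("c", 50_000, 51_000), {"g1", "g2", "g3"})]
    )

    def test_promoter_overlap_assigns(self):
        out = assign_peaks(_deps([("c", 7500, 7600, "up", "H3K27ac")]),
                           self.PROMOTERS, self.ANCHORS)
        assert out.to_dict(orient="records") == [
            {"gene_id": "geneA", "mark": "H3K27ac", "region_class": "promoter",
             "peak_direction": "up", "peak_id": "c:7500-7600"}
        ]

    def test_abutting_peak_not_assigned_half_open(self):
        out = assign_peaks(_deps([("c", 13_000, 13_100, "up", "H3K27ac")]),
                           self.PROMOTERS, [])
        assert len(out) == 0

    def test_multi_gene_anchor_yields_row_per_gene(self):
        out = assign_peaks(_deps([("c", 50_500, 50_600, "down", "H3K27me3")]),
                           {}, self.ANCHORS)
        assert len(out) == 3
        assert set(out["gene_id"]) == {"g1", "g2", "g3"}
        assert (out["region_class"] == "enhancer").all()


class TestConcordance:
    def _gene_diff(self, rows):
        return pd.DataFrame(rows, columns=["feature_id", "direction"])

    def test_active_mark_loss_with_decreased_expression_is_concordant(self):
        assignments = pd.DataFrame(
            [("gA", "H3K27ac", "promoter", "down", "p1")],
            columns=["gene_id", "mark", "region_class", "peak_direction", "peak_id"],
        )
        res = classify_concordance(assignments, self._gene_diff([("gA", "down")]))
        assert res.records["concordant"].all()
        assert res.categories["gA"] == "promoter_only"

    def test_repressive_mark_gain_with_increased_expression_is_discordant(self):
        assignments = pd.DataFrame(
            [("gA", "H3K27me3", "enhancer", "up", "p1")],
            columns=["gene_id", "mark", "region_class", "peak_direction", "peak_id"],
        )
        res = classify_concordance(assignments, self._gene_diff([("gA", "up")]))
        assert not res.records["concordant"].any()
        assert res.categories["gA"] == "neither"

    def test_both_category_and_counts_partition(self):
        assignments = pd.DataFrame(
            [
                ("gA", "H3K27ac", "promoter", "up", "p1"),
                ("gA", "H3K27ac", "enhancer", "up", "p2"),
                ("gB", "H3K27me3", "enhancer", "down", "p3"),
                ("gC", "H3K27ac", "promoter", "down", "p4"),
            ],
            columns=["gene_id", "mark", "region_class", "peak_direction", "peak_id"],
        )
        diff = self._gene_diff([("gA", "up"), ("gB", "up"), ("gC", "up"), ("gD", "down")])
        res = classify_concordance(assignments, diff)
        assert res.categories == {
            "gA": "both", "gB": "enhancer_only", "gC": "neither", "gD": "neither"
        }
        assert sum(res.category_counts.values()) == 4

    def test_h3k9me3_excluded_by_default_but_includable(self):
        assignments = pd.DataFrame(
            [("gA", "H3K9me3", "promoter", "down", "p1")],
            columns=["gene_id", "mark", "region_class", "peak_direction", "peak_id"],
        )
        diff = self._gene_diff([("gA", "up")])
        assert classify_concordance(assignments, diff).categories["gA"] == "neither"
        res = classify_concordance(assignments, diff, exclude_marks=())
        assert res.categories["gA"] == "promoter_only"  # repressive down vs expr up

    def test_unknown_mark_raises_naming_it(self):
        assignments = pd.DataFrame(
            [("gA", "H3K36me3", "promoter", "up", "p1")],
            columns=["gene_id", "mark", "region_class", "peak_direction", "peak_id"],
        )
        with pytest.raises(KeyError, match="H3K36me3"):
            classify_concordance(assignments, self._gene_diff([("gA", "up")]))

    def test_polarity_flip_symmetry_on_random_fixtures(self, rng):
        genes = [f"g{i}" for i in range(40)]
        diff = self._gene_diff(
            [(g, str(rng.choice(["up", "down"]))) for g in genes]
        )
        assignments = pd.DataFrame(
            [
                (
                    str(rng.choice(genes)),
                    str(rng.choice(["H3K27ac", "H3K27me3", "H3K4me3"])),
                    str(rng.choice(["promoter", "enhancer"])),
                    str(rng.choice(["up", "down"])),
                    f"p{i}",
                )
                for i in range(120)
            ],
            columns=["gene_id", "mark", "region_class", "peak_direction", "peak_id"],
        )
        res = classify_concordance(assignments, diff)
        assert sum(res.category_counts.values()) == len(diff)
        flipped = assignments.assign(
            peak_direction=assignments["peak_direction"].map({"up": "down", "down": "up"})
        )
        res_flipped = classify_concordance(flipped, diff)
        merged = res.records.merge(
            res_flipped.records, on=["gene_id", "mark", "region_class", "peak_id"],
            suffixes=("", "_flipped"),
        )
        assert (merged["concordant"] != merged["concordant_flipped"]).all()

    def test_is_concordant_truth_table(self):
        assert is_concordant("up", "up", "active")
        assert not is_concordant("up", "down", "active")
        assert is_concordant("down", "up", "repressive")
        assert not is_concordant("up", "up", "repressive")


class TestLinkedEnhancerStats:
    ANCHORS = build_anchors(
        [
            (GenomicInterval("c", 1000, 2000), {"g1"}),
            (GenomicInterval("c", 5000, 6000), {"g1", "g2"}),
            (GenomicInterval("c", 9000, 9500), {"g3"}),
        ]
    )

    def test_counts_anchors_carrying_peaks(self):
        deps = _deps([("c", 1500, 1600, "up", "H3K27ac"), ("c", 5100, 5200, "up", "H3K27ac")])
        stats = linked_enhancer_stats(self.ANCHORS, deps, ["g1", "g2", "g3", "g4"])
        assert stats.per_gene.to_dict() == {"g1": 2, "g2": 1, "g3": 0, "g4": 0}
        assert stats.mean_all == pytest.approx(0.75)
        assert stats.mean_hit == pytest.approx(1.5)

    def test_empty_deps_gives_zero_counts(self):
        stats = linked_enhancer_stats(self.ANCHORS, _deps([]), ["g1", "g2"])
        assert (stats.per_gene == 0).all() and stats.mean_all == 0.0
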