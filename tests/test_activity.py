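"""Merged regions, peak annotation, TSS profiles, and triple-mark calls."""

import numpy as np
import pytest

from nadkit.activity import (
    PeakSet,
    annotate_peaks,
    build_merged_regions,
    classify_active_nags,
    peak_overlap_fraction,
    promoter_interval,
    tss_profile,
)
from nadkit.genome_io import GeneModel, Interval
from nadkit.nag_annotation import NagSet
from nadkit.simulate import (
    SimulationConfig,
    simulate_peaks,
    simulate_truth,
)

import pandas as pd

from conftest import random_intervals


def peakset(sample, spans, assay="ATAC", chrom="chrA"):
    return PeakSet(assay, sample, [Interval(chrom, s, e) for s, e in spans])


def overlap_components(peaksets):
    """Brute-force oracle: connected components of the pairwise overlap graph."""
    peaks = [
        (ps.sample, i, iv)
        for ps in peaksets
        for i, iv in enumerate(ps.intervals)
    ]
    parent = list(range(len(peaks)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(peaks)):
        for j in range(i + 1, len(peaks)):
            if peaks[i][2].overlaps(peaks[j][2]):
                parent[find(i)] = find(j)
    comps = {}
    for i, (sample, idx, _) in enumerate(peaks):
        comps.setdefault(find(i), set()).add((sample, idx))
    return {frozenset(v) for v in comps.values()}


class TestMergedRegions:
    def test_overlapping_peaks_merge(self):
        regions = build_merged_regions(
            [peakset("s1", [(100, 200)]), peakset("s2", [(150, 250)])]
        )
        assert len(regions) == 1
        assert (regions[0].interval.start, regions[0].interval.end) == (100, 250)
        assert regions[0].presence == {"s1": True, "s2": True}

    def test_disjoint_peaks_stay_separate(self):
        regions = build_merged_regions(
            [peakset("s1", [(100, 200)]), peakset("s2", [(300, 400)])]
        )
        assert len(regions) == 2
        assert [r.presence for r in regions] == [
            {"s1": True, "s2": False},
            {"s1": False, "s2": True},
        ]

    def test_touching_peaks_do_not_merge(self):
        regions = build_merged_regions(
            [peakset("s1", [(100, 200)]), peakset("s2", [(200, 300)])]
        )
        assert len(regions) == 2

    def test_matches_union_find_oracle(self, rng):
        for _ in range(20):
            sets = [
                PeakSet("ATAC", f"s{k}", random_intervals(rng, 30, max_pos=3000))
                for k in range(3)
            ]
            regions = build_merged_regions(sets)
            assert {frozenset(r.members) for r in regions} == overlap_components(
                sets
            )
            # span rule: min start / max end over members
            lookup = {s.sample: s for s in sets}
            for r in regions:
                ivs = [lookup[s].intervals[i] for s, i in r.members]
                assert r.interval.start == min(iv.start for iv in ivs)
                assert r.interval.end == max(iv.end for iv in ivs)

    def test_duplicate_sample_labels_rejected(self):
        with pytest.raises(ValueError):
            build_merged_regions(
                [peakset("s", [(0, 10)]), peakset("s", [(20, 30)])]
            )


class TestPeakOverlapFraction:
    def test_identical_sets(self):
        a = peakset("a", [(0, 100), (200, 300)])
        assert peak_overlap_fraction(a, peakset("b", [(0, 100), (200, 300)])) == 1.0

    def test_disjoint_sets(self):
        a = peakset("a", [(0, 100)])
        assert peak_overlap_fraction(a, peakset("b", [(500, 600)])) == 0.0

    def test_matches_component_oracle(self, rng):
        for _ in range(10):
            a = PeakSet("ATAC", "a", random_intervals(rng, 40, max_pos=4000))
            b = PeakSet("ATAC", "b", random_intervals(rng, 40, max_pos=4000))
            comps = overlap_components(
                [PeakSet("ATAC", "__a__", a.intervals),
                 PeakSet("ATAC", "__b__", b.intervals)]
            )
            expected = sum(
                sum(1 for s, _ in comp if s == "__a__")
                for comp in comps
                if any(s == "__b__" for s, _ in comp)
            ) / len(a)
            assert peak_overlap_fraction(a, b) == pytest.approx(expected)

    def test_empty_first_set_errors(self):
        with pytest.raises(ValueError):
            peak_overlap_fraction(
                PeakSet("ATAC", "a", []), peakset("b", [(0, 10)])
            )


GENES = [
    GeneModel("gA", "GA", "chrA", 50_000, 70_000, "+"),
    GeneModel("gB", "GB", "chrA", 200_000, 240_000, "-"),
]


class TestPromoterWindow:
    def test_plus_strand(self):
        iv = promoter_interval(GENES[0])
        assert (iv.start, iv.end) == (48_000, 50_500)

    def test_minus_strand(self):
        # TSS at 239_999; upstream extends to higher coordinates
        iv = promoter_interval(GENES[1])
        assert (iv.start, iv.end) == (239_500, 242_000)

    def test_clipped_at_chromosome_start(self):
        g = GeneModel("g", "G", "chrA", 100, 5_000, "+")
        assert promoter_interval(g).start == 0


class TestAnnotatePeaks:
    def annotate(self, spans):
        return annotate_peaks(peakset("s", spans), GENES)

    def test_promoter_category(self):
        table = self.annotate([(49_400, 49_600)]).table  # TSS-500 of gA
        assert table.iloc[0]["category"] == "promoter"
        assert table.iloc[0]["gene_id"] == "gA"

    def test_gene_body_category(self):
        table = self.annotate([(60_000, 60_200)]).table  # 10 kb into gA
        assert table.iloc[0]["category"] == "gene_body"
        assert table.iloc[0]["gene_id"] == "gA"

    def test_intergenic_category(self):
        table = self.annotate([(150_000, 150_200)]).table
        assert table.iloc[0]["category"] == "intergenic"
        assert pd.isna(table.iloc[0]["gene_id"])

    def test_minus_strand_promoter(self):
        table = self.annotate([(241_000, 241_200)]).table  # upstream of gB
        assert table.iloc[0]["category"] == "promoter"
        assert table.iloc[0]["gene_id"] == "gB"

    def test_promoter_priority_over_gene_body(self):
        # peak covering both gA's promoter window and its body
        table = self.annotate([(49_900, 50_900)]).table
        assert table.iloc[0]["category"] == "promoter"


class TestTssProfile:
    def test_centered_peak_symmetric_maximum(self):
        g = GeneModel("g", "G", "chrA", 50_000, 60_000, "+")
        profile = tss_profile(
            [Interval("chrA", 49_800, 50_200)], [g], window=2000, n_bins=40
        )
        assert len(profile) == 40
        assert profile[19] == profile[20] == 1.0
        np.testing.assert_allclose(profile, profile[::-1])

    def test_no_peaks_all_zero(self):
        g = GeneModel("g", "G", "chrA", 50_000, 60_000, "+")
        assert not tss_profile([], [g]).any()

    def test_matches_per_bp_oracle(self, rng):
        g = GeneModel("g", "G", "chrA", 50_000, 60_000, "+")
        peaks = [
            Interval("chrA", int(s), int(s) + int(w))
            for s, w in zip(
                rng.integers(47_000, 53_000, 30), rng.integers(50, 600, 30)
            )
        ]
        occupancy = np.zeros(4000)
        for iv in peaks:
            s = max(iv.start, 48_000) - 48_000
            e = min(iv.end, 52_000) - 48_000
            if e > s:
                occupancy[s:e] = 1.0
        expected = occupancy.reshape(40, 100).mean(axis=1)
        np.testing.assert_allclose(
            tss_profile(peaks, [g], 2000, 40), expected
        )

    def test_strand_flip_mirrors_profile(self):
        plus = GeneModel("g", "G", "chrA", 5_000, 9_000, "+")  # TSS 5000
        minus = GeneModel("g", "G", "chrA", 1_000, 5_001, "-")  # TSS 5000
        peaks = [Interval("chrA", 4_000, 4_700), Interval("chrA", 5_600, 5_650)]
        p_plus = tss_profile(peaks, [plus], 2000, 40)
        p_minus = tss_profile(peaks, [minus], 2000, 40)
        np.testing.assert_allclose(p_minus, p_plus[::-1])

    def test_indivisible_window_errors(self):
        with pytest.raises(ValueError):
            tss_profile([], GENES, window=1000, n_bins=33)


def nagset(gene_ids):
    return NagSet(
        "sim",
        pd.DataFrame(
            {
                "gene_id": list(gene_ids),
                "gene_name": list(gene_ids),
                "biotype": "protein_coding",
                "overlap_bp": 1000,
                "fraction_of_gene_in_nad": 1.0,
            }
        ),
    )


class TestClassifyActiveNags:
    def setup_method(self):
        self.genes = GENES
        self.nags = nagset(["gA", "gB"])
        self.atac = annotate_peaks(
            peakset("s", [(49_400, 49_600), (241_000, 241_200)]), GENES
        )
        self.h3k4me3 = PeakSet(
            "H3K4me3", "s", [Interval("chrA", 49_000, 49_300)]
        )
        self.pol2 = PeakSet("POL2", "s", [Interval("chrA", 49_500, 49_700)])

    def test_triple_marked_gene_is_active(self):
        profile, summary = classify_active_nags(
            self.nags, self.genes, self.atac, self.h3k4me3, self.pol2
        )
        assert profile.active_gene_ids == {"gA"}
        assert summary.n_triple == 1
        assert summary.n_nag_promoter_accessible == 2
        summary.validate()

    def test_missing_pol2_peak_not_active(self):
        pol2 = PeakSet("POL2", "s", [])
        profile, summary = classify_active_nags(
            self.nags, self.genes, self.atac, self.h3k4me3, pol2
        )
        assert profile.active_gene_ids == set()
        assert summary.n_triple == 0
        assert summary.n_double == 0

    def test_missing_assay_reported(self):
        with pytest.warns(UserWarning, match="missing assay"):
            profile, summary = classify_active_nags(
                self.nags, self.genes, self.atac, self.h3k4me3, None
            )
        assert summary.n_triple == 0
        assert "POL2" not in profile.assays_used

    def test_conjunction_is_order_independent(self):
        _, s1 = classify_active_nags(
            self.nags, self.genes, self.atac, self.h3k4me3, self.pol2
        )
        _, s2 = classify_active_nags(
            self.nags, self.genes, self.atac, pol2=self.pol2,
            h3k4me3=self.h3k4me3,
        )
        assert s1.n_triple == s2.n_triple

    def test_recovers_planted_active_set_noise_free(self):
        config = SimulationConfig(
            seed=7, peak_fnr=0.0, peak_fpr=0.0, n_genes=300
        )
        truth = simulate_truth(config)
        peaks = simulate_peaks(truth, config)
        nags = nagset(sorted(truth.nag_ids))
        atac = annotate_peaks(peaks["ATAC"], truth.genes)
        profile, summary = classify_active_nags(
            nags, truth.genes, atac, peaks["H3K4me3"], peaks["POL2"]
        )
        assert profile.active_gene_ids == truth.active_ids
        assert summary.n_triple == len(truth.active_ids)
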