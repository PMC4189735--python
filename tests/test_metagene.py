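"""Metagene engine: anchors, window matrices, profiles, densities,
orderings — with brute-force per-base oracles and orientation checks."""

import numpy as np
import pandas as pd
import pytest

from anchorprof import (
    AnchorRegionSet,
    CoverageTrack,
    average_profile,
    build_anchors,
    cluster_and_order,
    compute_coverage,
    compute_window_matrix,
    make_fragments,
    region_density,
    strand_resolved_density,
)
from anchorprof.metagene import WindowMatrix


def constant_track(c, size=50_000):
    return CoverageTrack(values={"chr1": np.full(size, float(c))})


def random_track(seed, size=50_000):
    rng = np.random.default_rng(seed)
    return CoverageTrack(values={"chr1": rng.gamma(2.0, 1.0, size=size)})


def brute_force_matrix(track, entries, flank, window, slide):
    """Per-base oracle: relative coordinate r maps to genomic anchor+r on
    '+' regions and anchor-r on '-' regions."""
    rows = []
    for e in entries.itertuples(index=False):
        arr = track.values[e.chrom]
        v = np.array([
            arr[e.anchor + r if e.orientation == "+" else e.anchor - r]
            for r in range(-flank, flank)
        ])
        rows.append([v[s : s + window].mean() for s in range(0, 2 * flank - window + 1, slide)])
    return np.array(rows)


class TestAnchors:
    def test_plus_gene_convention(self, two_gene_annotation):
        tss = build_anchors(two_gene_annotation, "TSS", 500)
        tes = build_anchors(two_gene_annotation, "TES", 500)
        assert tss.entries.set_index("label").at["plus_gene", "anchor"] == 1000
        assert tes.entries.set_index("label").at["plus_gene", "anchor"] == 2999

    def test_minus_gene_orientation_flip(self, two_gene_annotation):
        tss = build_anchors(two_gene_annotation, "TSS", 500)
        row = tss.entries.set_index("label").loc["minus_gene"]
        assert row["anchor"] == 6999 and row["orientation"] == "-"
        # relative position +100 on a minus gene maps to genomic anchor - 100
        flank = 500
        track = CoverageTrack(values={"chr1": np.zeros(20_000)})
        track.values["chr1"][6999 - 100] = 123.0
        regions = AnchorRegionSet(tss.entries[tss.entries["label"] == "minus_gene"], flank)
        m = compute_window_matrix(track, regions, window=1, slide=1)
        assert m.values[0, flank + 100] == 123.0

    def test_anchors_inside_gene_bodies(self, tiny_annotation):
        for kind in ("TSS", "TES"):
            anchors = build_anchors(tiny_annotation, kind, 100)
            for e in anchors.entries.itertuples(index=False):
                g = tiny_annotation[e.label]
                assert g.start <= e.anchor < g.end

    def test_region_center_anchor(self):
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [300]})
        anchors = build_anchors(None, "region_center", 50, regions=regions)
        assert anchors.entries.at[0, "anchor"] == 200
        assert anchors.entries.at[0, "orientation"] == "+"

    def test_near_edge_regions_dropped(self):
        entries = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "anchor": [100, 25_000],
             "orientation": ["+", "+"], "label": ["edge", "ok"]}
        )
        usable = AnchorRegionSet(entries, 3_000).within_bounds({"chr1": 50_000})
        assert list(usable.entries["label"]) == ["ok"]


class TestWindowMatrix:
    def test_constant_field(self, tiny_annotation):
        anchors = build_anchors(tiny_annotation, "TSS", 3_000)
        track = CoverageTrack(values={"chr1": np.full(500_000, 7.5)})
        m = compute_window_matrix(track, anchors)
        assert np.allclose(m.values, 7.5)

    def test_column_count_296(self):
        entries = pd.DataFrame({"chrom": ["chr1"], "anchor": [25_000],
                                "orientation": ["+"], "label": ["r"]})
        m = compute_window_matrix(random_track(0), AnchorRegionSet(entries, 3_000))
        assert m.values.shape[1] == 296
        assert m.coords[0] == -3_000 and m.coords[-1] == 2_900

    def test_matches_brute_force(self):
        rng = np.random.default_rng(1)
        entries = pd.DataFrame(
            {"chrom": "chr1",
             "anchor": rng.integers(4_000, 46_000, size=10),
             "orientation": rng.choice(["+", "-"], size=10),
             "label": [f"r{i}" for i in range(10)]}
        )
        track = random_track(2)
        regions = AnchorRegionSet(entries, 3_000)
        m = compute_window_matrix(track, regions, 100, 20)
        bf = brute_force_matrix(track, entries, 3_000, 100, 20)
        assert np.allclose(m.values, bf, rtol=0, atol=1e-9)

    def test_mirrored_genome_mirrors_profiles(self):
        """Reverse-complementing the genome (mirrored fragments and strands)
        leaves oriented window matrices unchanged."""
        size = 20_000
        rng = np.random.default_rng(3)
        start = rng.integers(0, size - 200, size=2_000)
        fr = make_fragments("chr1", start, start + 150, "+")
        track = compute_coverage(fr, {"chr1": size})
        m_start = size - (start + 150)
        fr_m = make_fragments("chr1", m_start, m_start + 150, "-")
        track_m = compute_coverage(fr_m, {"chr1": size})
        anchor = 10_000
        entries = pd.DataFrame({"chrom": ["chr1"], "anchor": [anchor],
                                "orientation": ["+"], "label": ["r"]})
        entries_m = pd.DataFrame({"chrom": ["chr1"], "anchor": [size - 1 - anchor],
                                  "orientation": ["-"], "label": ["r"]})
        m = compute_window_matrix(track, AnchorRegionSet(entries, 2_000))
        mm = compute_window_matrix(track_m, AnchorRegionSet(entries_m, 2_000))
        assert np.allclose(m.values, mm.values)


class TestProfileAndDensity:
    def test_profile_single_region_is_that_row(self):
        m = WindowMatrix(np.array([[1.0, 2.0, 3.0]]), np.array([0, 1, 2]), ["a"], 1, 1)
        assert np.array_equal(average_profile(m).to_numpy(), [1.0, 2.0, 3.0])

    def test_profile_odd_count_median(self):
        vals = np.array([[0.0], [10.0], [20.0]])
        m = WindowMatrix(vals, np.array([0]), list("abc"), 1, 1)
        assert average_profile(m).iloc[0] == 10.0

    def test_profile_matches_sort_and_pick_oracle(self):
        rng = np.random.default_rng(4)
        vals = rng.random((101, 296))
        m = WindowMatrix(vals, np.arange(296), [str(i) for i in range(101)], 1, 1)
        prof = average_profile(m).to_numpy()
        oracle = np.sort(vals, axis=0)[50]  # middle of 101 sorted values
        assert np.array_equal(prof, oracle)

    def test_profile_empty_matrix_errors(self):
        m = WindowMatrix(np.empty((0, 3)), np.arange(3), [], 1, 1)
        with pytest.raises(ValueError):
            average_profile(m)

    def test_density_constant_and_linearity(self, tiny_annotation):
        anchors = build_anchors(tiny_annotation, "TSS", 1_000)
        d1 = region_density(constant_track(3.0, 500_000), anchors)
        assert np.allclose(d1["density"], 3.0)
        d2 = region_density(constant_track(6.0, 500_000), anchors)
        assert np.allclose(d2["density"].to_numpy(), 2 * d1["density"].to_numpy())

    def test_density_matches_per_base_oracle(self):
        track = random_track(5)
        entries = pd.DataFrame({"chrom": ["chr1"], "anchor": [20_000],
                                "orientation": ["-"], "label": ["r"]})
        d = region_density(track, AnchorRegionSet(entries, 3_000))
        oracle = track.values["chr1"][17_001:23_001].mean()  # (a-flank, a+flank] on '-'
        assert d["density"].iloc[0] == pytest.approx(oracle, rel=0, abs=1e-12)

    def test_strand_resolved_density_orientation(self):
        size = 20_000
        plus = CoverageTrack(values={"chr1": np.zeros(size)})
        minus = CoverageTrack(values={"chr1": np.zeros(size)})
        plus.values["chr1"][:] = 1.0  # uniform plus-strand signal
        entries = pd.DataFrame({"chrom": ["chr1", "chr1"], "anchor": [5_000, 15_000],
                                "orientation": ["+", "-"], "label": ["p", "m"]})
        d = strand_resolved_density(plus, minus, AnchorRegionSet(entries, 1_000))
        d = d.set_index(["label", "strandedness"])["density"]
        assert d[("p", "sense")] == 1.0 and d[("p", "antisense")] == 0.0
        assert d[("m", "sense")] == 0.0 and d[("m", "antisense")] == 1.0


class TestClusterOrdering:
    @staticmethod
    def planted_matrix(seed=0, n=200, p=50, separation=5.0):
        rng = np.random.default_rng(seed)
        labels = np.array([0] * (n // 2) + [1] * (n // 2))
        base = np.where(labels[:, None] == 0, 0.0, separation)
        return base + rng.normal(0, 1.0, size=(n, p)), labels

    def test_k1_is_descending_row_mean_sort(self):
        rng = np.random.default_rng(1)
        vals = rng.random((20, 5))
        m = WindowMatrix(vals, np.arange(5), [str(i) for i in range(20)], 1, 1)
        order = cluster_and_order(m, k=1, seed=0)
        means = vals.mean(axis=1)
        assert np.all(np.diff(means[order]) <= 1e-12)

    def test_deterministic_under_seed(self):
        vals, _ = self.planted_matrix()
        m = WindowMatrix(vals, np.arange(vals.shape[1]),
                         [str(i) for i in range(len(vals))], 1, 1)
        o1 = cluster_and_order(m, k=3, seed=42)
        o2 = cluster_and_order(m, k=3, seed=42)
        assert np.array_equal(o1, o2)

    def test_ordering_is_permutation(self):
        vals, _ = self.planted_matrix(seed=2)
        m = WindowMatrix(vals, np.arange(vals.shape[1]),
                         [str(i) for i in range(len(vals))], 1, 1)
        order = cluster_and_order(m, k=4, seed=0)
        assert sorted(order) == list(range(len(vals)))
        companion = m.reordered(order)
        assert sorted(companion.labels) == sorted(m.labels)

    def test_planted_two_populations_recovered(self):
        """k=2 on a 5-sigma separated two-population matrix: <= 2% of rows
        land on the wrong side of the ordering split."""
        vals, labels = self.planted_matrix(seed=3, separation=5.0)
        m = WindowMatrix(vals, np.arange(vals.shape[1]),
                         [str(i) for i in range(len(vals))], 1, 1)
        order = cluster_and_order(m, k=2, seed=7)
        n = len(labels)
        top_half = labels[order[: n // 2]]
        # high-amplitude population (label 1) should occupy the top block
        errors = (top_half == 0).sum() + (labels[order[n // 2 :]] == 1).sum()
        assert errors / n <= 0.02

    def test_k_bounds(self):
        vals, _ = self.planted_matrix()
        m = WindowMatrix(vals, np.arange(vals.shape[1]),
                         [str(i) for i in range(len(vals))], 1, 1)
        with pytest.raises(ValueError):
            cluster_and_order(m, k=len(vals) + 1, seed=0)
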