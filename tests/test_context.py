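"""TSS proximity, tallies, overlap fractions, distances, signal matrices."""

import numpy as np
import pandas as pd
import pytest

from tfiiic.context import (
    chromosome_tally,
    distance_to_regions,
    feature_overlap_fractions,
    signal_matrix,
    tss_proximity,
)
from tfiiic.genome import FETrack, FeatureSet
from tfiiic.permutation import ShuffleConstraint
from tfiiic.sites import TFIIICSite, TFIIICSiteSet

from conftest import track_from_dense


def make_sites(layout, specs):
    """specs: list of (chrom, center, site_class)."""
    return TFIIICSiteSet(
        layout=layout,
        sites=tuple(TFIIICSite(c, p, 8.0, 0.0, cls) for c, p, cls in specs),
    )


class TestTssProximity:
    def test_window_endpoints_inclusive(self, tiny_layout):
        sites = make_sites(tiny_layout, [("chrI", 500, "extra")])
        for pos, expected in [(600, 1), (601, 0), (400, 1), (399, 0)]:
            tss = FeatureSet("tss", [("chrI", pos, pos + 1, "tRNA", "+")], kind="point")
            out = tss_proximity(sites, tss, window=100)
            row = out[(out.site_class == "extra") & (out.tss_class == "any")]
            assert int(row["count"].iloc[0]) == expected, pos

    def test_multi_class_counting(self, tiny_layout):
        """A site with TSSs of two classes counts once per class, once in 'any'."""
        sites = make_sites(tiny_layout, [("chrI", 500, "polIII_bound")])
        tss = FeatureSet("tss", [("chrI", 450, 451, "tRNA", "+"),
                                 ("chrI", 550, 551, "snoRNA", "+")], kind="point")
        out = tss_proximity(sites, tss).set_index("tss_class")["count"]
        assert out["tRNA"] == 1 and out["snoRNA"] == 1 and out["any"] == 1

    def test_unlabeled_grouped_as_unknown(self, tiny_layout):
        sites = make_sites(tiny_layout, [("chrI", 500, "extra")])
        tss = FeatureSet("tss", [("chrI", 500, 501, ".", "+")], kind="point")
        out = tss_proximity(sites, tss)
        assert "unknown" in set(out["tss_class"])

    def test_matches_bruteforce_membership(self, tiny_layout, rng):
        for _ in range(100):
            centers = [("chrI", int(p), "extra") for p in rng.integers(0, 10_000, size=10)]
            sites = make_sites(tiny_layout, centers)
            tss_pos = rng.integers(0, 10_000, size=15)
            tss = FeatureSet("tss", [("chrI", int(p), int(p) + 1, "tRNA", "+")
                                     for p in tss_pos], kind="point")
            out = tss_proximity(sites, tss, window=100)
            brute = sum(
                any(c - 100 <= t <= c + 100 for t in tss_pos)
                for _, c, _ in centers
            )
            row = out[(out.site_class == "extra") & (out.tss_class == "any")]
            assert int(row["count"].iloc[0]) == brute


class TestChromosomeTally:
    def test_empty_set_all_zero(self, tiny_layout):
        out = chromosome_tally(make_sites(tiny_layout, []), tiny_layout)
        assert out.empty or (out["count"] == 0).all()

    def test_totals_conserved_and_match_groupby(self, tiny_layout, rng):
        specs = []
        for _ in range(60):
            chrom = str(rng.choice(["chrI", "chrII", "chrX"]))
            pos = int(rng.integers(0, tiny_layout.chromosomes[chrom]))
            cls = str(rng.choice(["extra", "polIII_bound"]))
            specs.append((chrom, pos, cls))
        sites = make_sites(tiny_layout, specs)
        for level in ("chromosome", "domain"):
            out = chromosome_tally(sites, tiny_layout, level=level)
            assert out["count"].sum() == len(sites)
            oracle = pd.DataFrame(specs, columns=["chrom", "pos", "cls"]).groupby(
                ["chrom", "cls"]).size()
            per_chrom = out.groupby(["chromosome", "site_class"])["count"].sum()
            for (chrom, cls), n in oracle.items():
                assert per_chrom[(chrom, cls)] == n


class TestFeatureOverlapFractions:
    def test_single_covering_label_saturates(self, tiny_layout):
        fs = FeatureSet("cov", [(c, 0, l, "all", ".")
                                for c, l in tiny_layout.chromosomes.items()])
        sites = make_sites(tiny_layout, [("chrI", 5, "extra"), ("chrII", 5, "extra")])
        constraint = ShuffleConstraint("within_chromosome", tiny_layout)
        out = feature_overlap_fractions(sites, fs, constraint, reps=100, seed=0)
        assert (out["fraction"] == 1.0).all()
        assert (out["p_greater"] == 1.0).all()

    def test_planted_membership_recovered(self, tiny_layout, rng):
        centers = sorted(rng.choice(np.arange(100, 9_900, 10), 30, replace=False))
        inside = set(rng.choice(30, size=9, replace=False))
        fs = FeatureSet("lab", [("chrI", int(centers[i]) - 2, int(centers[i]) + 3, "planted", ".")
                                for i in inside])
        sites = make_sites(tiny_layout, [("chrI", int(c), "extra") for c in centers])
        constraint = ShuffleConstraint("within_chromosome", tiny_layout)
        out = feature_overlap_fractions(sites, fs, constraint, reps=50, seed=0)
        row = out[out.label == "planted"].iloc[0]
        assert row["count"] == 9
        assert row["fraction"] == pytest.approx(0.3)


class TestDistanceToRegions:
    def test_center_inside_region_is_zero(self, tiny_layout):
        regions = FeatureSet("r", [("chrI", 400, 600, "x", ".")])
        sites = make_sites(tiny_layout, [("chrI", 500, "extra")])
        out = distance_to_regions(sites, regions)
        assert out.distances["distance"].iloc[0] == 0
        assert out.medians["extra"] == 0

    def test_matches_bruteforce_nearest_edge(self, tiny_layout, rng):
        for _ in range(50):
            n_r = int(rng.integers(1, 20))
            starts = rng.integers(0, 9_000, size=n_r)
            widths = rng.integers(1, 500, size=n_r)
            regions = FeatureSet("r", [("chrI", int(s), int(s + w), "x", ".")
                                       for s, w in zip(starts, widths)])
            specs = sorted(
                ("chrI", int(p), "extra") for p in rng.integers(0, 10_000, size=10))
            out = distance_to_regions(make_sites(tiny_layout, specs), regions)
            for (_, c, _), d in zip(specs, out.distances["distance"]):
                brute = min(
                    0 if s <= c < s + w else (s - c if c < s else c - (s + w) + 1)
                    for s, w in zip(starts, widths)
                )
                assert d == brute

    def test_reflection_symmetry(self, tiny_layout, rng):
        """Mirroring a chromosome leaves all nearest distances unchanged."""
        L = tiny_layout.chromosomes["chrI"]
        starts = rng.integers(0, 9_000, size=8)
        widths = rng.integers(1, 400, size=8)
        regions = FeatureSet("r", [("chrI", int(s), int(s + w), "x", ".")
                                   for s, w in zip(starts, widths)])
        mirrored = FeatureSet("r", [("chrI", L - int(s + w), L - int(s), "x", ".")
                                    for s, w in zip(starts, widths)])
        specs = [("chrI", int(p), "extra") for p in rng.integers(0, L, size=20)]
        specs_m = [("chrI", L - 1 - p, cls) for _, p, cls in specs]
        a = distance_to_regions(make_sites(tiny_layout, specs), regions)
        b = distance_to_regions(make_sites(tiny_layout, specs_m), mirrored)
        assert sorted(a.distances["distance"]) == sorted(b.distances["distance"])

    def test_classes_compared_by_rank_sum(self, tiny_layout):
        regions = FeatureSet("r", [("chrI", 0, 100, "x", ".")])
        specs = [("chrI", 100 + 10 * i, "extra") for i in range(10)]
        specs += [("chrI", 5_000 + 10 * i, "polIII_bound") for i in range(10)]
        out = distance_to_regions(make_sites(tiny_layout, specs), regions)
        assert out.medians["extra"] < out.medians["polIII_bound"]
        assert out.comparisons["extra_vs_polIII_bound"] < 0.01


class TestSignalMatrix:
    def test_constant_track_gives_constant_matrix(self, tiny_layout):
        track = FETrack("f", {"chrI": ([0], [10_000], [3.5])})
        sites = make_sites(tiny_layout, [("chrI", 5_000, "extra")])
        sm = signal_matrix(sites, track)
        assert sm.matrix.shape == (1, 199)
        np.testing.assert_allclose(sm.matrix, 3.5)

    def test_window_count_formula(self, tiny_layout):
        track = FETrack("f")
        sites = make_sites(tiny_layout, [("chrI", 5_000, "extra")])
        assert signal_matrix(sites, track, span=2000, window=20, offset=10).n_windows == 199
        assert signal_matrix(sites, track, span=1000, window=50, offset=25).n_windows == 39

    def test_entries_match_bruteforce_window_means(self, tiny_layout, rng):
        L = tiny_layout.chromosomes["chrI"]
        dense = rng.uniform(0, 5, size=L)
        track = track_from_dense("f", {"chrI": dense})
        centers = sorted(int(p) for p in rng.integers(1_000, L - 1_000, size=5))
        sites = make_sites(tiny_layout, [("chrI", c, "extra") for c in centers])
        sm = signal_matrix(sites, track)
        for _ in range(1000):
            i = int(rng.integers(0, len(centers)))
            j = int(rng.integers(0, 199))
            w_start = centers[i] - 1000 + 10 * j
            expected = dense[w_start:w_start + 20].mean()
            assert sm.matrix[i, j] == pytest.approx(expected)

    def test_edge_site_zero_padded_and_flagged(self, tiny_layout):
        track = FETrack("f", {"chrI": ([0], [10_000], [2.0])})
        sites = make_sites(tiny_layout, [("chrI", 100, "extra")])
        sm = signal_matrix(sites, track)
        assert sm.site_index["edge_padded"].iloc[0]
        assert sm.matrix[0, 0] == 0.0          # fully outside the chromosome
        assert sm.matrix[0, -1] == 2.0

    def test_translation_equivariance(self, tiny_layout, rng):
        dense = rng.uniform(0, 5, size=4_000)
        shift = 1_000
        base = np.zeros(10_000)
        base[2_000:6_000] = dense
        shifted = np.zeros(10_000)
        shifted[2_000 + shift:6_000 + shift] = dense
        t1 = track_from_dense("f", {"chrI": base})
        t2 = track_from_dense("f", {"chrI": shifted})
        s1 = make_sites(tiny_layout, [("chrI", 4_000, "extra")])
        s2 = make_sites(tiny_layout, [("chrI", 4_000 + shift, "extra")])
        np.testing.assert_allclose(signal_matrix(s1, t1).matrix,
                                   signal_matrix(s2, t2).matrix)
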