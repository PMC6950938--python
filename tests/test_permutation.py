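"""Constrained shuffling, empirical P-values, overlap/distance/interval nulls."""

import numpy as np
import pytest
from scipy import stats

from tfiiic.genome import Domain, FeatureSet, GenomeLayout
from tfiiic.permutation import (
    ConstraintError,
    ShuffleConstraint,
    distance_null_once,
    empirical_p,
    interval_null,
    nearest_distance,
    nearest_distances,
    neighbor_intervals,
    overlap_count,
    permutation_overlap_test,
    replicate_rng,
    shuffle_points,
)


class TestShufflePoints:
    def test_width_one_cell_is_deterministic(self):
        layout = GenomeLayout(chromosomes={"chrI": 1})
        constraint = ShuffleConstraint("within_chromosome", layout)
        for r in range(10):
            out = shuffle_points([("chrI", 0)], constraint, replicate_rng(0, r))
            assert out == [("chrI", 0)]

    def test_uniform_occupancy_by_decile(self):
        layout = GenomeLayout(chromosomes={"chrI": 1000})
        constraint = ShuffleConstraint("within_chromosome", layout)
        positions = [
            shuffle_points([("chrI", 500)], constraint, replicate_rng(3, r))[0][1]
            for r in range(2000)
        ]
        counts, _ = np.histogram(positions, bins=10, range=(0, 1000))
        p = stats.chisquare(counts).pvalue
        assert p > 0.01

    def test_within_domain_containment(self, tiny_layout):
        constraint = ShuffleConstraint("within_domain", tiny_layout)
        points = [("chrI", 100), ("chrI", 5000), ("chrII", 6000), ("chrX", 10)]
        for r in range(200):
            out = shuffle_points(points, constraint, replicate_rng(1, r))
            assert len(out) == len(points)
            for (c0, p0), (c1, p1) in zip(points, out):
                d0 = tiny_layout.domain_at(c0, p0)
                assert c1 == c0
                assert d0.start <= p1 < d0.end

    def test_genome_mode_moves_across_chromosomes(self, tiny_layout):
        constraint = ShuffleConstraint("genome", tiny_layout)
        seen = {
            shuffle_points([("chrI", 0)], constraint, replicate_rng(0, r))[0][0]
            for r in range(200)
        }
        assert seen == set(tiny_layout.chromosomes)

    def test_genome_mode_length_weighted(self, tiny_layout):
        constraint = ShuffleConstraint("genome", tiny_layout)
        hits = [
            shuffle_points([("chrI", 0)], constraint, replicate_rng(1, r))[0][0]
            for r in range(3000)
        ]
        total = sum(tiny_layout.chromosomes.values())
        expected = [3000 * l / total for l in tiny_layout.chromosomes.values()]
        observed = [hits.count(c) for c in tiny_layout.chromosomes]
        assert stats.chisquare(observed, expected).pvalue > 0.01

    def test_exclusion_respected_and_empty_cell_raises(self):
        layout = GenomeLayout(chromosomes={"chrI": 100, "chrII": 50})
        exclusion = FeatureSet("excl", [("chrI", 0, 50, "x", "."),
                                        ("chrII", 0, 50, "x", ".")])
        constraint = ShuffleConstraint("within_chromosome", layout, exclusion)
        for r in range(100):
            out = shuffle_points([("chrI", 10)], constraint, replicate_rng(0, r))
            assert out[0][1] >= 50
        with pytest.raises(ConstraintError):
            shuffle_points([("chrII", 10)], constraint, replicate_rng(0, 0))

    def test_fixed_seed_reproducible(self, tiny_layout):
        constraint = ShuffleConstraint("within_domain", tiny_layout)
        points = [("chrI", 100), ("chrII", 7000)]
        a = shuffle_points(points, constraint, replicate_rng(5, 7))
        b = shuffle_points(points, constraint, replicate_rng(5, 7))
        assert a == b


class TestEmpiricalP:
    def test_no_null_as_extreme_reports_bound(self):
        nulls = np.arange(2000)
        p, bound = empirical_p(5000, nulls, "greater")
        assert bound and p == pytest.approx(1 / 2000)

    def test_all_ties_give_p_one(self):
        p, bound = empirical_p(3.0, [3.0] * 100, "greater")
        assert p == 1.0 and not bound

    def test_direct_count(self):
        p, bound = empirical_p(3, [0, 1, 2, 3], "greater")
        assert p == 0.25 and not bound
        p_less, _ = empirical_p(0, [0, 1, 2, 3], "less")
        assert p_less == 0.25

    def test_two_sided_doubles_smaller_side(self):
        p, bound = empirical_p(3, [0, 1, 2, 3], "two_sided")
        assert p == 0.5 and not bound

    def test_monotone_in_observed(self, rng):
        nulls = rng.normal(size=500)
        ps = [empirical_p(x, nulls, "greater")[0] for x in np.linspace(-3, 3, 20)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_empty_nulls_rejected(self):
        with pytest.raises(ValueError):
            empirical_p(1.0, [], "greater")


class TestOverlapCount:
    def test_no_features_counts_zero(self):
        fs = FeatureSet("f", [])
        assert overlap_count([("chrI", 5)], fs) == 0

    def test_half_open_membership(self):
        fs = FeatureSet("f", [("chrI", 10, 20, "x", ".")])
        assert overlap_count([("chrI", 10)], fs) == 1
        assert overlap_count([("chrI", 19)], fs) == 1
        assert overlap_count([("chrI", 20)], fs) == 0

    def test_point_in_overlapping_features_counted_once(self):
        fs = FeatureSet("f", [("chrI", 0, 30, "a", "."), ("chrI", 10, 20, "b", ".")])
        assert overlap_count([("chrI", 15)], fs) == 1

    def test_matches_bruteforce_double_loop(self, rng):
        for _ in range(100):
            n_f = int(rng.integers(1, 50))
            starts = rng.integers(0, 900, size=n_f)
            widths = rng.integers(1, 60, size=n_f)
            fs = FeatureSet("f", [("chrI", int(s), int(s + w), "x", ".")
                                  for s, w in zip(starts, widths)])
            points = [("chrI", int(p)) for p in rng.integers(0, 1000, size=int(rng.integers(1, 50)))]
            brute = sum(
                any(s <= p < s + w for s, w in zip(starts, widths))
                for _, p in points
            )
            assert overlap_count(points, fs) == brute


class TestPermutationOverlapTest:
    def test_saturated_features_give_p_one(self, tiny_layout):
        fs = FeatureSet("f", [(c, 0, l, "x", ".")
                              for c, l in tiny_layout.chromosomes.items()])
        constraint = ShuffleConstraint("within_chromosome", tiny_layout)
        res = permutation_overlap_test([("chrI", 5), ("chrII", 5)], fs, constraint,
                                       reps=100, seed=0)
        assert res.observed == 2
        assert np.all(res.nulls == 2)
        assert res.p_greater == 1.0

    def test_null_mean_matches_binomial_expectation(self):
        # features cover fraction rho of a single constraint cell holding n sites
        layout = GenomeLayout(chromosomes={"chrI": 10_000})
        rho = 0.3
        fs = FeatureSet("f", [("chrI", 0, int(10_000 * rho), "x", ".")])
        constraint = ShuffleConstraint("within_chromosome", layout)
        n = 40
        points = [("chrI", 9_000 + 10 * i) for i in range(n)]
        res = permutation_overlap_test(points, fs, constraint, reps=2000, seed=11)
        se = np.sqrt(n * rho * (1 - rho) / 2000)
        assert abs(res.null_mean - n * rho) < 3 * se

    def test_planted_enrichment_yields_bound_p(self, tiny_layout, rng):
        fs = FeatureSet("f", [("chrI", 1000, 1100, "x", ".")])
        points = [("chrI", int(p)) for p in rng.integers(1000, 1100, size=30)]
        constraint = ShuffleConstraint("within_chromosome", tiny_layout)
        res = permutation_overlap_test(points, fs, constraint, reps=2000, seed=2)
        assert res.greater_is_bound
        assert res.p_greater == pytest.approx(1 / 2000)
        assert res.p_string() == "< 0.0005"

    def test_reproducible_with_seed(self, tiny_layout):
        fs = FeatureSet("f", [("chrI", 0, 2000, "x", ".")])
        constraint = ShuffleConstraint("within_domain", tiny_layout)
        points = [("chrI", 100), ("chrI", 4000)]
        a = permutation_overlap_test(points, fs, constraint, reps=50, seed=4)
        b = permutation_overlap_test(points, fs, constraint, reps=50, seed=4)
        np.testing.assert_array_equal(a.nulls, b.nulls)


class TestNearestDistance:
    def test_inside_is_zero(self):
        fs = FeatureSet("f", [("chrI", 10, 20, "x", ".")])
        assert nearest_distance("chrI", 15, fs) == 0

    def test_bookended_convention(self):
        fs = FeatureSet("f", [("chrI", 10, 20, "x", ".")])
        assert nearest_distance("chrI", 20, fs) == 1   # first base past the end
        assert nearest_distance("chrI", 9, fs) == 1    # base just before start
        assert nearest_distance("chrI", 0, fs) == 10

    def test_missing_chromosome_returns_none(self):
        fs = FeatureSet("f", [("chrI", 10, 20, "x", ".")])
        assert nearest_distance("chrII", 5, fs) is None

    def test_matches_bruteforce_scan(self, rng):
        for _ in range(50):
            n_f = int(rng.integers(1, 50))
            starts = rng.integers(0, 900, size=n_f)
            widths = rng.integers(1, 60, size=n_f)
            fs = FeatureSet("f", [("chrI", int(s), int(s + w), "x", ".")
                                  for s, w in zip(starts, widths)])
            for p in rng.integers(0, 1000, size=20):
                p = int(p)
                brute = min(
                    0 if s <= p < s + w else (s - p if p < s else p - (s + w) + 1)
                    for s, w in zip(starts, widths)
                )
                assert nearest_distance("chrI", p, fs) == brute


class TestDistanceNullOnce:
    def test_points_inside_features_observe_zero(self, tiny_layout):
        fs = FeatureSet("f", [("chrI", 0, 10_000, "x", ".")])
        constraint = ShuffleConstraint("within_chromosome", tiny_layout)
        obs, null, p = distance_null_once(
            [("chrI", 5), ("chrI", 500)], fs, constraint, seed=0)
        assert np.all(obs == 0)

    def test_all_points_dropped_raises(self, tiny_layout):
        fs = FeatureSet("f", [("chrII", 0, 100, "x", ".")])
        constraint = ShuffleConstraint("within_chromosome", tiny_layout)
        with pytest.raises(ValueError, match="dropped"):
            distance_null_once([("chrI", 5)], fs, constraint, seed=0)

    def test_calibration_under_null_placement(self):
        """Observed drawn from the null process -> rank-sum p roughly uniform."""
        layout = GenomeLayout(chromosomes={"chrI": 50_000})
        fs = FeatureSet("f", [("chrI", i * 5000, i * 5000 + 500, "x", ".")
                              for i in range(10)])
        constraint = ShuffleConstraint("within_chromosome", layout)
        master = np.random.default_rng(77)
        ps = []
        for i in range(200):
            points = [("chrI", int(p)) for p in master.integers(0, 50_000, size=30)]
            _, _, p = distance_null_once(points, fs, constraint, seed=1000 + i)
            ps.append(p)
        frac = np.mean(np.array(ps) <= 0.05)
        assert 0.02 <= frac <= 0.10


class TestIntervalNull:
    def test_observed_intervals_direct_subtraction(self):
        layout = GenomeLayout(chromosomes={"chrI": 10_000})
        obs = neighbor_intervals([("chrI", 100), ("chrI", 300), ("chrI", 1300)], layout)
        assert sorted(obs.tolist()) == [200, 1000]

    def test_no_cross_domain_pairs(self, tiny_layout):
        # one point per domain of chrI -> no intervals at all
        points = [("chrI", 100), ("chrI", 5000), ("chrI", 9000)]
        assert neighbor_intervals(points, tiny_layout).size == 0
        with pytest.raises(ValueError, match="2 points"):
            interval_null(points, tiny_layout, reps=10, seed=0)

    def test_null_means_match_simulation_oracle(self):
        """Mean neighbor interval of k uniform points agrees with resimulation."""
        layout = GenomeLayout(chromosomes={"chrI": 100_000})
        k = 12
        points = [("chrI", 1000 * (i + 1)) for i in range(k)]
        _, null_means, _ = interval_null(points, layout, reps=400, seed=5)
        oracle_rng = np.random.default_rng(99)
        oracle = [
            np.mean(np.diff(np.sort(oracle_rng.integers(0, 100_000, size=k))))
            for _ in range(10_000)
        ]
        se = np.std(oracle) / np.sqrt(400) + np.std(oracle) / np.sqrt(10_000)
        assert abs(np.mean(null_means) - np.mean(oracle)) < 4 * se

    def test_clustered_points_detected(self, tiny_layout, rng):
        centers = [("chrI", int(100 + 20 * i)) for i in range(30)]
        obs, null_means, p = interval_null(centers, tiny_layout, reps=200, seed=3)
        assert np.median(obs) < np.mean(null_means)
        assert p < 0.001
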