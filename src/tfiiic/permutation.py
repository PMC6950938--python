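"""Constrained randomization of site positions and empirical-P machinery.

Sites are shuffled as 1-bp centers, independently and uniformly over the
allowed bases of their constraint cell: the whole genome (length-weighted
across chromosomes), their own chromosome, or their own arm/center domain.
Optional exclusion regions are subtracted from the allowed universe before
sampling. Empirical P-values use the plug-in estimator #{as extreme}/reps,
reported as a bound "< 1/reps" when no permutation is as extreme.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .genome import FeatureSet, GenomeLayout

MODES = ("genome", "within_chromosome", "within_domain")


class ConstraintError(ValueError):
    """A site cannot be hosted by its constraint cell."""


def _subtract(starts, ends, ex_starts, ex_ends):
    """Subtract merged exclusion intervals from merged allowed intervals."""
    out_s, out_e = [], []
    j = 0
    for s, e in zip(starts, ends):
        pos = s
        while j < len(ex_starts) and ex_ends[j] <= pos:
            j += 1
        k = j
        while k < len(ex_starts) and ex_starts[k] < e:
            if ex_starts[k] > pos:
                out_s.append(pos)
                out_e.append(ex_starts[k])
            pos = max(pos, ex_ends[k])
            k += 1
        if pos < e:
            out_s.append(pos)
            out_e.append(e)
    return np.array(out_s, np.int64), np.array(out_e, np.int64)


@dataclass
class _Cell:
    key: str
    chroms: list[str]              # chromosome of each allowed interval
    starts: np.ndarray             # allowed interval starts
    ends: np.ndarray
    cum: np.ndarray = field(init=False)   # cumulative allowed length

    def __post_init__(self) -> None:
        lengths = self.ends - self.starts
        self.cum = np.concatenate(([0], np.cumsum(lengths)))

    @property
    def total(self) -> int:
        return int(self.cum[-1])

    def sample(self, n: int, rng: np.random.Generator):
        r = rng.integers(0, self.total, size=n)
        idx = np.searchsorted(self.cum, r, side="right") - 1
        pos = self.starts[idx] + (r - self.cum[idx])
        return [(self.chroms[i], int(p)) for i, p in zip(idx, pos)]


class ShuffleConstraint:
    """Allowed-placement universe for site shuffling.

    mode: "genome" (one cell spanning all chromosomes), "within_chromosome"
    (one cell per chromosome), or "within_domain" (one cell per arm/center
    domain). ``exclusion`` intervals are removed from the allowed bases.
    """

    def __init__(self, mode: str, layout: GenomeLayout,
                 exclusion: FeatureSet | None = None):
        if mode not in MODES:
            raise ValueError(f"unknown shuffle mode {mode!r}")
        self.mode = mode
        self.layout = layout
        self.exclusion = exclusion
        self._cells: dict[str, _Cell] = {}
        self._build()

    def _allowed(self, chrom: str, start: int, end: int):
        starts = np.array([start], np.int64)
        ends = np.array([end], np.int64)
        if self.exclusion is not None:
            ex_s, ex_e = self.exclusion.merged_intervals(chrom)
            starts, ends = _subtract(starts, ends, ex_s, ex_e)
        return starts, ends

    def _build(self) -> None:
        if self.mode == "genome":
            chroms, ss, es = [], [], []
            for chrom, length in self.layout.chromosomes.items():
                s, e = self._allowed(chrom, 0, length)
                chroms.extend([chrom] * len(s))
                ss.append(s)
                es.append(e)
            cell = _Cell("genome", chroms,
                         np.concatenate(ss) if ss else np.zeros(0, np.int64),
                         np.concatenate(es) if es else np.zeros(0, np.int64))
            self._cells["genome"] = cell
        elif self.mode == "within_chromosome":
            for chrom, length in self.layout.chromosomes.items():
                s, e = self._allowed(chrom, 0, length)
                self._cells[chrom] = _Cell(chrom, [chrom] * len(s), s, e)
        else:
            for d in self.layout.all_domains():
                key = f"{d.chromosome}:{d.start}-{d.end}"
                s, e = self._allowed(d.chromosome, d.start, d.end)
                self._cells[key] = _Cell(key, [d.chromosome] * len(s), s, e)

    def cell_of(self, chromosome: str, position: int) -> _Cell:
        if self.mode == "genome":
            return self._cells["genome"]
        if self.mode == "within_chromosome":
            if chromosome not in self._cells:
                raise ConstraintError(f"no cell for chromosome {chromosome!r}")
            return self._cells[chromosome]
        d = self.layout.domain_at(chromosome, position)
        return self._cells[f"{d.chromosome}:{d.start}-{d.end}"]


def shuffle_points(centers, constraint: ShuffleConstraint,
                   rng: np.random.Generator):
    """Redraw each center uniformly among allowed bases of its own cell.

    Collisions between shuffled points are permitted; output order matches
    grouping by cell, with length preserved.
    """
    groups: dict[str, list[int]] = {}
    cells: dict[str, _Cell] = {}
    for i, (chrom, pos) in enumerate(centers):
        cell = constraint.cell_of(chrom, pos)
        if cell.total == 0:
            raise ConstraintError(
                f"site {chrom}:{pos} lies in a cell with no allowed bases"
            )
        groups.setdefault(cell.key, []).append(i)
        cells[cell.key] = cell
    out: list[tuple[str, int] | None] = [None] * len(centers)
    for key in sorted(groups):
        idxs = groups[key]
        drawn = cells[key].sample(len(idxs), rng)
        for i, p in zip(idxs, drawn):
            out[i] = p
    return out


def replicate_rng(seed: int, replicate: int) -> np.random.Generator:
    """Deterministic substream for one permutation replicate."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(replicate)]))


def empirical_p(observed: float, nulls, direction: str) -> tuple[float, bool]:
    """Plug-in empirical P; (1/reps, bound=True) when no null is as extreme."""
    nulls = np.asarray(nulls, dtype=float)
    if nulls.size == 0:
        raise ValueError("empty null sample")
    n = nulls.size
    k_greater = int(np.sum(nulls >= observed))
    k_less = int(np.sum(nulls <= observed))
    if direction == "greater":
        k = k_greater
    elif direction == "less":
        k = k_less
    elif direction == "two_sided":
        k = min(k_greater, k_less)
        if k == 0:
            return 1.0 / n, True
        return min(1.0, 2.0 * k / n), False
    else:
        raise ValueError(f"unknown direction {direction!r}")
    if k == 0:
        return 1.0 / n, True
    return k / n, False


@dataclass
class PermutationResult:
    """Observed statistic, permutation null sample, and empirical P."""

    statistic: str
    observed: float
    nulls: np.ndarray
    direction: str
    empirical_p: float
    p_is_bound: bool
    p_greater: float
    greater_is_bound: bool
    p_less: float
    less_is_bound: bool
    seed: int | None = None

    @property
    def reps(self) -> int:
        return int(self.nulls.size)

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.nulls))

    def p_string(self) -> str:
        if self.p_is_bound:
            return f"< {1.0 / self.reps:g}"
        return f"{self.empirical_p:g}"

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "observed": self.observed,
            "null_mean": self.null_mean,
            "reps": self.reps,
            "direction": self.direction,
            "p": self.empirical_p,
            "p_is_bound": self.p_is_bound,
            "p_greater": self.p_greater,
            "p_less": self.p_less,
            "seed": self.seed,
        }


def _make_result(statistic, observed, nulls, direction, seed) -> PermutationResult:
    nulls = np.asarray(nulls, dtype=float)
    p, bound = empirical_p(observed, nulls, direction)
    pg, bg = empirical_p(observed, nulls, "greater")
    pl, bl = empirical_p(observed, nulls, "less")
    return PermutationResult(
        statistic=statistic, observed=float(observed), nulls=nulls,
        direction=direction, empirical_p=p, p_is_bound=bound,
        p_greater=pg, greater_is_bound=bg, p_less=pl, less_is_bound=bl,
        seed=seed,
    )


def overlap_count(points, features: FeatureSet) -> int:
    """Number of points whose base lies inside any feature interval.

    Half-open membership; each point counted at most once even when features
    overlap.
    """
    count = 0
    cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, pos in points:
        if chrom not in cache:
            cache[chrom] = features.merged_intervals(chrom)
        starts, ends = cache[chrom]
        if starts.size == 0:
            continue
        i = np.searchsorted(starts, pos, side="right") - 1
        if i >= 0 and pos < ends[i]:
            count += 1
    return count


def permutation_overlap_test(
    points, features: FeatureSet, constraint: ShuffleConstraint,
    reps: int = 2000, seed: int = 0, direction: str = "greater",
    statistic: str = "overlap_count",
) -> PermutationResult:
    """Compare observed point-in-feature overlap against shuffled placements."""
    points = list(points)
    observed = overlap_count(points, features)
    nulls = np.empty(reps, dtype=float)
    for r in range(reps):
        shuffled = shuffle_points(points, constraint, replicate_rng(seed, r))
        nulls[r] = overlap_count(shuffled, features)
    return _make_result(statistic, observed, nulls, direction, seed)


def nearest_distance(chromosome: str, position: int, features: FeatureSet) -> int | None:
    """Distance from a point to the nearest feature edge on its chromosome.

    0 when inside a feature; book-ended/past-the-end intervals are 1 away
    (bedtools-closest convention). None when the chromosome has no features.
    """
    starts, ends = features.merged_intervals(chromosome)
    if starts.size == 0:
        return None
    i = np.searchsorted(starts, position, side="right") - 1
    if i >= 0 and position < ends[i]:
        return 0
    best = None
    if i >= 0:
        best = position - int(ends[i]) + 1
    if i + 1 < starts.size:
        d = int(starts[i + 1]) - position
        best = d if best is None else min(best, d)
    return best


def nearest_distances(points, features: FeatureSet):
    """Per-point nearest distance; points on feature-free chromosomes dropped."""
    out, dropped = [], []
    for chrom, pos in points:
        d = nearest_distance(chrom, pos, features)
        if d is None:
            dropped.append((chrom, pos))
        else:
            out.append(d)
    return np.array(out, dtype=float), dropped


def rank_sum_p(a, b) -> float:
    """Two-sided Mann-Whitney U with normal approximation and tie correction."""
    return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                    method="asymptotic").pvalue)


def distance_null_once(points, features: FeatureSet,
                       constraint: ShuffleConstraint, seed: int = 0):
    """Observed nearest distances vs one shuffled replicate, with rank-sum P.

    Points on chromosomes lacking features are dropped from both sides.
    """
    points = list(points)
    observed, dropped = nearest_distances(points, features)
    if observed.size == 0:
        raise ValueError("all points dropped: no chromosome carries features")
    shuffled = shuffle_points(points, constraint, replicate_rng(seed, 0))
    null, _ = nearest_distances(shuffled, features)
    p = rank_sum_p(observed, null)
    return observed, null, p


def neighbor_intervals(points, layout: GenomeLayout) -> np.ndarray:
    """Center-to-center distances between neighbors within each domain.

    No cross-domain pairs: each arm/center domain contributes distances only
    between consecutive points it contains.
    """
    out = []
    by_domain: dict[tuple, list[int]] = {}
    for chrom, pos in points:
        d = layout.domain_at(chrom, pos)
        by_domain.setdefault((d.chromosome, d.start, d.end), []).append(pos)
    for key in sorted(by_domain):
        ps = np.sort(np.array(by_domain[key], dtype=np.int64))
        if ps.size >= 2:
            out.append(np.diff(ps))
    if not out:
        return np.zeros(0, dtype=np.int64)
    return np.concatenate(out)


def interval_null(points, layout: GenomeLayout, reps: int = 2000,
                  seed: int = 0):
    """Observed neighbor intervals vs permutation means (within domains).

    Each replicate shuffles points within their domain and records the mean
    neighbor interval; the distribution of ``reps`` means is compared with
    the observed interval distribution by rank-sum test.
    """
    points = list(points)
    observed = neighbor_intervals(points, layout)
    if observed.size == 0:
        raise ValueError("no domain holds >= 2 points")
    constraint = ShuffleConstraint("within_domain", layout)
    null_means = np.empty(reps, dtype=float)
    for r in range(reps):
        shuffled = shuffle_points(points, constraint, replicate_rng(seed, r))
        null_means[r] = float(np.mean(neighbor_intervals(shuffled, layout)))
    p = rank_sum_p(observed, null_means)
    return observed, null_means, p
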