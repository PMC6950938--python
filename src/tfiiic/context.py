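"""Genomic-context statistics for classified TFIIIC sites.

TSS proximity, per-chromosome/domain tallies, feature-overlap fractions with
permutation tests, distances to enriched regions, and windowed signal
matrices for heatmaps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import FETrack, FeatureSet, GenomeLayout
from .permutation import (
    PermutationResult,
    ShuffleConstraint,
    distance_null_once,
    nearest_distances,
    permutation_overlap_test,
    rank_sum_p,
)
from .sites import TFIIICSiteSet


def tss_proximity(sites: TFIIICSiteSet, tss: FeatureSet, window: int = 100) -> pd.DataFrame:
    """Fraction of sites with a TSS within +/- ``window`` bp of their center.

    TSS points carry gene-class labels (tRNA, snoRNA, ...); a site with TSSs
    of several classes counts once per class, and the "any" row counts each
    site once. Both window endpoints are inclusive. Unlabeled TSSs are
    grouped under "unknown".
    """
    df = tss.df.copy()
    df["label"] = df["label"].replace(".", "unknown").fillna("unknown")
    positions: dict[str, dict[str, np.ndarray]] = {}
    for (chrom, label), grp in df.groupby(["chrom", "label"]):
        positions.setdefault(chrom, {})[label] = np.sort(grp["start"].to_numpy(np.int64))

    classes = sorted({s.site_class for s in sites.sites})
    tss_labels = sorted(df["label"].unique())
    counts = {(cls, lab): 0 for cls in classes for lab in tss_labels + ["any"]}
    totals = {cls: 0 for cls in classes}
    for s in sites.sites:
        totals[s.site_class] += 1
        hit_any = False
        for lab, pos in positions.get(s.chromosome, {}).items():
            lo = np.searchsorted(pos, s.center - window, side="left")
            hi = np.searchsorted(pos, s.center + window, side="right")
            if hi > lo:
                counts[(s.site_class, lab)] += 1
                hit_any = True
        if hit_any:
            counts[(s.site_class, "any")] += 1
    rows = [
        {
            "site_class": cls,
            "tss_class": lab,
            "count": counts[(cls, lab)],
            "total": totals[cls],
            "fraction": counts[(cls, lab)] / totals[cls] if totals[cls] else float("nan"),
        }
        for cls in classes
        for lab in tss_labels + ["any"]
    ]
    return pd.DataFrame(rows)


def chromosome_tally(sites: TFIIICSiteSet, layout: GenomeLayout,
                     level: str = "chromosome") -> pd.DataFrame:
    """Integer site tallies per chromosome or per arm/center domain, by class."""
    rows = []
    classes = sorted({s.site_class for s in sites.sites})
    if level == "chromosome":
        units = [(chrom, None) for chrom in layout.chromosomes]
    elif level == "domain":
        units = [(d.chromosome, d) for d in layout.all_domains()]
    else:
        raise ValueError(f"unknown tally level {level!r}")
    for chrom, domain in units:
        for cls in classes:
            n = sum(
                1
                for s in sites.sites
                if s.chromosome == chrom
                and s.site_class == cls
                and (domain is None or domain.start <= s.center < domain.end)
            )
            rows.append(
                {
                    "chromosome": chrom,
                    "domain": domain.label if domain else "all",
                    "start": domain.start if domain else 0,
                    "end": domain.end if domain else layout.chromosomes[chrom],
                    "site_class": cls,
                    "count": n,
                }
            )
    return pd.DataFrame(rows)


def feature_overlap_fractions(
    sites: TFIIICSiteSet,
    features: FeatureSet,
    constraint: ShuffleConstraint,
    reps: int = 2000,
    seed: int = 0,
    per_label: bool = True,
) -> pd.DataFrame:
    """Observed per-label overlap fraction plus a permutation test per label.

    A site center inside intervals of two labels counts for both; the "any"
    row counts each site once.
    """
    centers = sites.centers()
    n = len(centers)
    labels = features.labels() if per_label else []
    rows = []
    for lab in labels + ["any"]:
        fs = features if lab == "any" else features.subset(lab)
        result = permutation_overlap_test(
            centers, fs, constraint, reps=reps, seed=seed,
            statistic=f"overlap:{features.name}:{lab}",
        )
        rows.append(
            {
                "label": lab,
                "count": int(result.observed),
                "total": n,
                "fraction": result.observed / n if n else float("nan"),
                "null_mean": result.null_mean,
                "p_greater": result.p_greater,
                "greater_is_bound": result.greater_is_bound,
                "p_less": result.p_less,
                "less_is_bound": result.less_is_bound,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class DistanceSummary:
    """Per-site nearest distances with class labels and group comparisons."""

    distances: pd.DataFrame            # columns: chromosome, center, site_class, distance
    medians: dict[str, float]          # per site class
    comparisons: dict[str, float]      # rank-sum p per named comparison
    null_distances: np.ndarray | None = None
    null_median: float | None = None


def distance_to_regions(
    sites: TFIIICSiteSet,
    regions: FeatureSet,
    null_constraint: ShuffleConstraint | None = None,
    seed: int = 0,
) -> DistanceSummary:
    """Nearest-edge distance from each site center to a region set.

    Distances are 0 inside a region. Medians are reported per site class,
    with rank-sum comparisons between every pair of classes; when
    ``null_constraint`` is given, a single-permutation null is added
    (optionally excluding the regions themselves via the constraint's
    exclusion set) and compared per class.
    """
    rows = []
    for s in sites.sites:
        d, dropped = nearest_distances([(s.chromosome, s.center)], regions)
        if d.size:
            rows.append(
                {"chromosome": s.chromosome, "center": s.center,
                 "site_class": s.site_class, "distance": float(d[0])}
            )
    df = pd.DataFrame(rows, columns=["chromosome", "center", "site_class", "distance"])
    classes = sorted(df["site_class"].unique()) if len(df) else []
    medians = {cls: float(df.loc[df["site_class"] == cls, "distance"].median())
               for cls in classes}
    comparisons: dict[str, float] = {}
    for i, a in enumerate(classes):
        for b in classes[i + 1:]:
            da = df.loc[df["site_class"] == a, "distance"]
            db = df.loc[df["site_class"] == b, "distance"]
            if len(da) and len(db):
                comparisons[f"{a}_vs_{b}"] = rank_sum_p(da, db)

    null = null_median = None
    if null_constraint is not None and len(df):
        points = list(zip(df["chromosome"], df["center"].astype(int)))
        _, null, _ = distance_null_once(points, regions, null_constraint, seed=seed)
        null_median = float(np.median(null))
        for cls in classes:
            da = df.loc[df["site_class"] == cls, "distance"]
            comparisons[f"{cls}_vs_null"] = rank_sum_p(da, null)
    return DistanceSummary(distances=df, medians=medians, comparisons=comparisons,
                           null_distances=null, null_median=null_median)


@dataclass
class SignalMatrix:
    """Sites x windows matrix of mean FE around site centers."""

    matrix: np.ndarray
    site_index: pd.DataFrame     # chromosome, center, site_class, edge_padded
    factor: str
    span: int
    window: int
    offset: int

    @property
    def n_windows(self) -> int:
        return self.matrix.shape[1]


def signal_matrix(
    sites: TFIIICSiteSet,
    track: FETrack,
    span: int = 2000,
    window: int = 20,
    offset: int = 10,
) -> SignalMatrix:
    """Mean FE in sliding windows across a span centered on each site.

    Defaults give 199 windows of 20 bp at 10-bp offsets over 2 kb. Sites too
    close to a chromosome edge are zero-padded and flagged.
    """
    n_win = (span - window) // offset + 1
    half = span // 2
    mat = np.zeros((len(sites), n_win), dtype=np.float64)
    rows = []
    for i, s in enumerate(sites.sites):
        lo, hi = s.center - half, s.center + half
        length = sites.layout.chromosomes[s.chromosome] if sites.layout else None
        padded = lo < 0 or (length is not None and hi > length)
        # dense() zero-fills negative coordinates and bases past the runs
        arr = track.dense(s.chromosome, lo, hi)
        csum = np.concatenate(([0.0], np.cumsum(arr)))
        starts = np.arange(n_win) * offset
        mat[i] = (csum[starts + window] - csum[starts]) / window
        rows.append(
            {"chromosome": s.chromosome, "center": s.center,
             "site_class": s.site_class, "edge_padded": bool(padded)}
        )
    return SignalMatrix(
        matrix=mat,
        site_index=pd.DataFrame(rows, columns=["chromosome", "center", "site_class", "edge_padded"]),
        factor=track.factor, span=span, window=window, offset=offset,
    )
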