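"""End-to-end orchestration: site calling, classification, context analyses,
segmentation and permutation tests, assembled into a report bundle.

Per-analysis shuffle constraints follow the study design: repeat overlap uses
within-chromosome shuffles; per-chromosome tallies use genome-wide shuffles;
exon/state-like features, H3K9 overlap and distance, nuclear-pore sites and
LEM-2 subdomains use within-domain shuffles; the H3K9me3 distance null
additionally excludes the enriched regions themselves from the allowed
placement universe.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .context import (
    chromosome_tally,
    distance_to_regions,
    feature_overlap_fractions,
    tss_proximity,
)
from .genome import (
    FeatureSet,
    attach_domains,
    read_bedgraph,
    read_chrom_sizes,
    read_features,
    read_sites_tsv,
    write_features,
    write_sites_tsv,
)
from .permutation import ShuffleConstraint, interval_null, permutation_overlap_test
from .segmentation import region_stats, segment_enriched_regions
from .sites import (
    CLASS_EXTRA,
    CLASS_POLIII,
    TFIIICSiteSet,
    call_high_confidence_sites,
    classify_sites,
    read_peaks_bed,
)

log = logging.getLogger("tfiiic")


@dataclass
class RunConfig:
    """Input paths, thresholds, and permutation settings for one run."""

    chrom_sizes: str = ""
    domains: str = ""
    tftc3_peaks: str = ""
    tftc5_peaks: str = ""
    tftc3_bedgraph: str = ""
    rpc1_bedgraph: str = ""
    h3k9me2_bedgraph: str = ""
    h3k9me3_bedgraph: str = ""
    ncrna_tss: str = ""
    coding_tss: str = ""
    repeats: str = ""
    lem2_subdomains: str = ""
    npp13: str = ""
    outdir: str = "tfiiic_out"

    fe_min: float = 5.0
    proximity: int = 100
    polIII_threshold: float = 20.0
    flank: int = 250
    tss_window: int = 100
    npp13_window: int = 500
    h3k9_window: int = 1000
    h3k9_threshold: float = 2.5
    heatmap_window: int = 20
    heatmap_offset: int = 10
    heatmap_span: int = 2000

    reps: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fe_min", "proximity", "polIII_threshold", "flank",
                     "tss_window", "npp13_window", "h3k9_window",
                     "h3k9_threshold", "heatmap_window", "heatmap_offset",
                     "heatmap_span"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _result_entry(result, constraint_mode: str) -> dict:
    d = result.to_dict()
    d["constraint"] = constraint_mode
    return d


def _expand_points(features: FeatureSet, flank: int) -> FeatureSet:
    rows = [
        (r.chrom, max(0, r.start - flank), r.end + flank, r.label, r.strand)
        for r in features.df.itertuples(index=False)
    ]
    return FeatureSet(f"{features.name}±{flank}", rows, kind="interval")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis per config; returns the statistics bundle.

    Writes into ``config.outdir``: the classified site TSV, enriched-region
    BEDs, a statistics JSON, and a run manifest echoing every parameter.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stats: dict = {}

    stage = "genome"
    try:
        layout = read_chrom_sizes(config.chrom_sizes)
        if config.domains:
            layout = attach_domains(layout, config.domains)

        stage = "site_calling"
        tftc3_peaks = read_peaks_bed(config.tftc3_peaks, layout)
        tftc5_peaks = read_peaks_bed(config.tftc5_peaks, layout)
        tftc3_track = read_bedgraph(config.tftc3_bedgraph, layout, "tftc3")
        log.info("site calling: fe_min=%g proximity=%d on %d TFTC-3 peaks",
                 config.fe_min, config.proximity, len(tftc3_peaks))
        sites = call_high_confidence_sites(
            tftc3_peaks, tftc3_track, tftc5_peaks, layout,
            fe_min=config.fe_min, proximity=config.proximity,
        )
        stats["n_tftc3_peaks"] = len(tftc3_peaks)
        stats["n_high_confidence_sites"] = len(sites)

        stage = "classification"
        rpc1_track = read_bedgraph(config.rpc1_bedgraph, layout, "rpc1")
        log.info("classification: polIII_threshold=%g flank=%d",
                 config.polIII_threshold, config.flank)
        sites = classify_sites(sites, rpc1_track,
                               polIII_threshold=config.polIII_threshold,
                               flank=config.flank)
        counts = sites.class_counts()
        stats["n_extra"] = counts.get(CLASS_EXTRA, 0)
        stats["n_polIII_bound"] = counts.get(CLASS_POLIII, 0)
        write_sites_tsv(sites, outdir / "sites.tsv")

        extra = sites.by_class(CLASS_EXTRA)
        polIII = sites.by_class(CLASS_POLIII)
        within_chrom = ShuffleConstraint("within_chromosome", layout)
        within_domain = ShuffleConstraint("within_domain", layout)
        genome_wide = ShuffleConstraint("genome", layout)

        stage = "tallies"
        tally = chromosome_tally(sites, layout, level="chromosome")
        tally.to_csv(outdir / "chromosome_tally.tsv", sep="\t", index=False)
        stats["chromosome_tally"] = tally.to_dict(orient="records")
        dtally = chromosome_tally(sites, layout, level="domain")
        dtally.to_csv(outdir / "domain_tally.tsv", sep="\t", index=False)
        arm_rows = dtally[dtally["domain"].isin(["left_arm", "right_arm"])]
        n_extra_arm = int(arm_rows[arm_rows["site_class"] == CLASS_EXTRA]["count"].sum())
        stats["n_extra_in_arms"] = n_extra_arm

        stage = "chromosome_distribution_tests"
        chrom_tests = {}
        for chrom, length in layout.chromosomes.items():
            chrom_fs = FeatureSet(chrom, [(chrom, 0, length, chrom, ".")])
            res = permutation_overlap_test(
                extra.centers(), chrom_fs, genome_wide,
                reps=config.reps, seed=config.seed,
                statistic=f"extra_on_{chrom}",
            )
            chrom_tests[chrom] = _result_entry(res, "genome")
        stats["extra_per_chromosome_tests"] = chrom_tests

        stage = "neighbor_intervals"
        if len(extra) >= 2:
            obs, null_means, p = interval_null(
                extra.centers(), layout, reps=config.reps, seed=config.seed,
            )
            np.savetxt(outdir / "interval_null_means.tsv", null_means,
                       header="null_mean_interval", comments="")
            stats["neighbor_intervals"] = {
                "median_observed": float(np.median(obs)),
                "mean_observed": float(np.mean(obs)),
                "n_intervals": int(obs.size),
                "null_mean_of_means": float(np.mean(null_means)),
                "rank_sum_p": p,
                "reps": config.reps,
                "constraint": "within_domain",
                "seed": config.seed,
            }

        stage = "tss_proximity"
        if config.ncrna_tss:
            tss = read_features(config.ncrna_tss, "bed", layout, kind="point")
            prox = tss_proximity(sites, tss, window=config.tss_window)
            prox.to_csv(outdir / "tss_proximity.tsv", sep="\t", index=False)
            stats["tss_proximity"] = prox.to_dict(orient="records")

        stage = "coding_tss_distance"
        if config.coding_tss:
            coding = read_features(config.coding_tss, "bed", layout, kind="point")
            summary = distance_to_regions(sites, coding,
                                          null_constraint=within_chrom,
                                          seed=config.seed)
            stats["coding_tss_distance"] = {
                "medians": summary.medians,
                "null_median": summary.null_median,
                "comparisons": summary.comparisons,
                "constraint": "within_chromosome",
            }

        stage = "repeats"
        if config.repeats:
            repeats = read_features(config.repeats, "bed", layout)
            for name, subset in (("extra", extra), ("polIII_bound", polIII)):
                fr = feature_overlap_fractions(
                    subset, repeats, within_chrom,
                    reps=config.reps, seed=config.seed,
                )
                fr.to_csv(outdir / f"repeat_overlap_{name}.tsv", sep="\t", index=False)
                stats[f"repeat_overlap_{name}"] = fr.to_dict(orient="records")

        stage = "segmentation"
        region_sets = {}
        for mark, path in (("h3k9me2", config.h3k9me2_bedgraph),
                           ("h3k9me3", config.h3k9me3_bedgraph)):
            if not path:
                continue
            track = read_bedgraph(path, layout, mark)
            regions = segment_enriched_regions(
                track, layout, window=config.h3k9_window,
                threshold=config.h3k9_threshold, mark=mark,
            )
            region_sets[mark] = regions
            write_features(regions.regions, outdir / f"{mark}_regions.bed")
            rs = region_stats(regions)
            stats[f"{mark}_regions"] = {k: rs[k] for k in ("mark", "count", "mean_size")}

        stage = "h3k9_context"
        for mark, regions in region_sets.items():
            fr = feature_overlap_fractions(
                extra, regions.regions, within_domain,
                reps=config.reps, seed=config.seed, per_label=False,
            )
            stats[f"{mark}_overlap_extra"] = fr.to_dict(orient="records")
            exclusion = regions.regions if mark == "h3k9me3" else None
            null_constraint = ShuffleConstraint("within_domain", layout,
                                                exclusion=exclusion)
            summary = distance_to_regions(sites, regions.regions,
                                          null_constraint=null_constraint,
                                          seed=config.seed)
            stats[f"{mark}_distance"] = {
                "medians": summary.medians,
                "null_median": summary.null_median,
                "comparisons": summary.comparisons,
                "constraint": "within_domain",
                "null_excludes_regions": mark == "h3k9me3",
            }

        stage = "npp13"
        if config.npp13:
            npp13 = read_features(config.npp13, "bed", layout, kind="point")
            windows = _expand_points(npp13, config.npp13_window)
            for name, subset in (("extra", extra), ("polIII_bound", polIII)):
                res = permutation_overlap_test(
                    subset.centers(), windows, within_domain,
                    reps=config.reps, seed=config.seed,
                    statistic=f"npp13_overlap_{name}",
                )
                entry = _result_entry(res, "within_domain")
                entry["fraction"] = res.observed / len(subset) if len(subset) else None
                stats[f"npp13_overlap_{name}"] = entry

        stage = "lem2"
        if config.lem2_subdomains:
            lem2 = read_features(config.lem2_subdomains, "bed", layout)
            for name, subset in (("extra", extra), ("polIII_bound", polIII)):
                res = permutation_overlap_test(
                    subset.centers(), lem2, within_domain,
                    reps=config.reps, seed=config.seed,
                    statistic=f"lem2_overlap_{name}",
                )
                entry = _result_entry(res, "within_domain")
                entry["fraction"] = res.observed / len(subset) if len(subset) else None
                stats[f"lem2_overlap_{name}"] = entry

        stage = "report"
        manifest = {
            "version": __version__,
            "config": config.to_dict(),
        }
        _dump_json(manifest, outdir / "manifest.json")
        _dump_json(stats, outdir / "stats.json")
    except Exception:
        log.error("pipeline failed at stage %r", stage)
        raise
    return stats


def _dump_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=default)
        fh.write("\n")


def summarize_supplementary(sites_path, layout, coords: str = "auto") -> dict:
    """Tally a supplementary-style site table for comparison with headline counts.

    Returns per-class totals, per-chromosome tallies and, when the layout
    carries a domain partition, neighbor-interval summaries for the extra
    class.
    """
    sites = read_sites_tsv(sites_path, layout=layout, coords=coords)
    counts = sites.class_counts()
    out = {
        "n_sites": len(sites),
        "class_counts": counts,
        "per_chromosome": {},
    }
    tally = chromosome_tally(sites, layout, level="chromosome") if len(sites) else None
    if tally is not None:
        for (chrom), grp in tally.groupby("chromosome"):
            out["per_chromosome"][chrom] = {
                row["site_class"]: int(row["count"]) for _, row in grp.iterrows()
            }
    extra = sites.by_class(CLASS_EXTRA)
    if len(extra) >= 2 and layout.domains:
        from .permutation import neighbor_intervals

        obs = neighbor_intervals(extra.centers(), layout)
        if obs.size:
            out["extra_neighbor_intervals"] = {
                "n": int(obs.size),
                "median": float(np.median(obs)),
                "mean": float(np.mean(obs)),
            }
    return out
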