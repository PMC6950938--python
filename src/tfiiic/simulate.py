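"""Synthetic genomes, FE tracks, site placements, and annotations.

The generator emulates the statistical structure the analysis assumes: two
co-binding TFIIIC subunit tracks with localized peaks over a noisy
background, a Pol III track co-occupying a subset of sites, extra sites
placed as dense clusters concentrated in designated autosome arms,
block-shaped H3K9-like enrichment placed adjacent to (but not over) the
clusters, and point/interval annotations (ncRNA TSSs, repeats, LEM-2-like
subdomains, nuclear-pore-like points) with known planted truth.

Everything is a deterministic function of (seed, parameters). Default
parameters are scaled so a full study-shaped dataset (about 10 Mb of
genome, 504 extra + 525 Pol III-bound sites) generates in seconds.
"""

from __future__ import annotations

import bisect
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import (
    Domain,
    FETrack,
    FeatureSet,
    GenomeLayout,
    write_bedgraph,
    write_features,
)
from .sites import PeakCall, write_peaks_bed

# Edge margin keeps signal windows, classification flanks and heatmap spans
# fully inside the chromosome for every planted site.
EDGE_MARGIN = 1100


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stage)]))


@dataclass
class SyntheticTruth:
    """Planted ground truth for one synthetic dataset."""

    seed: int
    layout: GenomeLayout
    sites: pd.DataFrame          # chrom, center, site_class, cluster (+ annotation flags)
    designated_arms: dict[str, str]
    params: dict = field(default_factory=dict)
    h3k9_blocks: dict[str, FeatureSet] = field(default_factory=dict)
    annotations: dict[str, FeatureSet] = field(default_factory=dict)

    def centers(self, site_class: str | None = None):
        df = self.sites
        if site_class is not None:
            df = df[df["site_class"] == site_class]
        return list(zip(df["chrom"], df["center"].astype(int)))


def make_layout(
    n_autosomes: int = 5,
    autosome_length: int = 1_600_000,
    x_length: int = 1_700_000,
    arm_fraction: float = 0.33,
    seed: int = 0,
) -> GenomeLayout:
    """Scaled-down nematode-style genome: partitioned autosomes plus one X.

    Each autosome splits into left arm / center / right arm with arms taking
    ``arm_fraction`` of the length each; the X chromosome is a single
    ``whole`` domain.
    """
    if not 0 < arm_fraction < 0.5:
        raise ValueError("arm_fraction must lie in (0, 0.5)")
    if autosome_length <= 0 or x_length <= 0:
        raise ValueError("chromosome lengths must be positive")
    roman = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX"]
    names = [f"chr{roman[i]}" for i in range(n_autosomes)]
    chroms = {name: autosome_length for name in names}
    chroms["chrX"] = x_length
    arm = int(round(autosome_length * arm_fraction))
    domains = []
    for name in names:
        domains.append(Domain(name, 0, arm, "left_arm"))
        domains.append(Domain(name, arm, autosome_length - arm, "center"))
        domains.append(Domain(name, autosome_length - arm, autosome_length, "right_arm"))
    domains.append(Domain("chrX", 0, x_length, "whole"))
    return GenomeLayout(
        chromosomes=chroms,
        domains=tuple(domains),
        autosomes=frozenset(names),
    )


def designated_arms(layout: GenomeLayout) -> dict[str, str]:
    """One heterochromatin-biased arm per autosome.

    The first and last autosomes take their right arm, the others their left
    arm — mirroring the one-arm asymmetry of extra-site placement.
    """
    autos = [c for c in layout.chromosomes if layout.is_autosome(c)]
    out = {}
    for i, chrom in enumerate(autos):
        out[chrom] = "right_arm" if i in (0, len(autos) - 1) else "left_arm"
    return out


class _Placer:
    """Tracks placed positions per chromosome and enforces a minimum gap."""

    def __init__(self, min_separation: int):
        self.min_separation = min_separation
        self.placed: dict[str, list[int]] = {}

    def ok(self, chrom: str, pos: int) -> bool:
        ps = self.placed.get(chrom, [])
        i = bisect.bisect_left(ps, pos)
        for j in (i - 1, i):
            if 0 <= j < len(ps) and abs(ps[j] - pos) < self.min_separation:
                return False
        return True

    def add(self, chrom: str, pos: int) -> None:
        bisect.insort(self.placed.setdefault(chrom, []), pos)


def _weighted_domain_choice(domains: list[Domain], rng: np.random.Generator) -> Domain:
    lengths = np.array([d.end - d.start for d in domains], dtype=float)
    return domains[rng.choice(len(domains), p=lengths / lengths.sum())]


def plant_sites(
    layout: GenomeLayout,
    n_extra: int = 504,
    n_polIII: int = 525,
    arm_bias: float = 0.96,
    cluster_geometric_p: float = 0.15,
    spacing_median: float = 1207.0,
    spacing_sigma: float = 0.8,
    polIII_x_bias: float = 0.38,
    min_separation: int = 400,
    seed: int = 0,
) -> SyntheticTruth:
    """Place extra sites as clusters in designated arms; Pol III sites uniformly.

    Extra-site clusters: cluster seeds fall in a designated arm with
    probability ``arm_bias`` (elsewhere otherwise), cluster sizes are
    geometric(``cluster_geometric_p``), and within-cluster spacing is
    log-normal with the given median. Pol III-bound sites fall on the X with
    probability ``polIII_x_bias`` and uniformly on autosomes otherwise.
    """
    rng = _rng(seed, 1)
    arms = designated_arms(layout)
    all_domains = layout.all_domains()
    biased = [d for d in all_domains if arms.get(d.chromosome) == d.label]
    other = [d for d in all_domains if d not in biased]
    if not biased:
        raise ValueError("layout has no designated arms (no partitioned autosomes)")

    placer = _Placer(min_separation)
    mu = np.log(spacing_median)
    rows = []
    cluster_id = 0
    guard = 0
    while len(rows) < n_extra:
        guard += 1
        if guard > 200_000:
            raise RuntimeError("infeasible packing: cannot place extra sites")
        pool = biased if rng.random() < arm_bias else other
        dom = _weighted_domain_choice(pool, rng)
        lo = dom.start + EDGE_MARGIN if dom.start == 0 else dom.start
        hi = dom.end - EDGE_MARGIN if dom.end == layout.chromosomes[dom.chromosome] else dom.end
        if hi - lo < min_separation:
            continue
        k = int(rng.geometric(cluster_geometric_p))
        start = int(rng.integers(lo, hi))
        spacings = np.maximum(
            rng.lognormal(mu, spacing_sigma, size=max(k - 1, 0)), min_separation
        ).astype(np.int64)
        positions = start + np.concatenate(([0], np.cumsum(spacings)))
        placed_any = False
        for pos in positions:
            if len(rows) >= n_extra:
                break
            pos = int(pos)
            if not lo <= pos < hi:
                break  # truncate cluster at the domain edge
            if not placer.ok(dom.chromosome, pos):
                continue
            placer.add(dom.chromosome, pos)
            rows.append((dom.chromosome, pos, "extra", cluster_id))
            placed_any = True
        if placed_any:
            cluster_id += 1

    autosome_domains = [d for d in all_domains if layout.is_autosome(d.chromosome)]
    x_domains = [d for d in all_domains if not layout.is_autosome(d.chromosome)]
    guard = 0
    n_placed = 0
    while n_placed < n_polIII:
        guard += 1
        if guard > 200_000:
            raise RuntimeError("infeasible packing: cannot place Pol III sites")
        if x_domains and rng.random() < polIII_x_bias:
            dom = _weighted_domain_choice(x_domains, rng)
        else:
            dom = _weighted_domain_choice(autosome_domains, rng)
        lo = dom.start + EDGE_MARGIN if dom.start == 0 else dom.start
        hi = dom.end - EDGE_MARGIN if dom.end == layout.chromosomes[dom.chromosome] else dom.end
        pos = int(rng.integers(lo, hi))
        if not placer.ok(dom.chromosome, pos):
            continue
        placer.add(dom.chromosome, pos)
        rows.append((dom.chromosome, pos, "polIII_bound", -1))
        n_placed += 1

    sites = pd.DataFrame(rows, columns=["chrom", "center", "site_class", "cluster"])
    sites = sites.sort_values(["chrom", "center"], kind="stable").reset_index(drop=True)
    params = {
        "n_extra": n_extra, "n_polIII": n_polIII, "arm_bias": arm_bias,
        "cluster_geometric_p": cluster_geometric_p,
        "spacing_median": spacing_median, "spacing_sigma": spacing_sigma,
        "polIII_x_bias": polIII_x_bias, "min_separation": min_separation,
    }
    return SyntheticTruth(seed=seed, layout=layout, sites=sites,
                          designated_arms=arms, params=params)


def _add_triangle(arr: np.ndarray, center: int, amp: float, half_width: int) -> None:
    lo = max(0, center - half_width)
    hi = min(arr.size, center + half_width + 1)
    x = np.arange(lo, hi)
    arr[lo:hi] += amp * (1.0 - np.abs(x - center) / half_width)


def _tile_noise(length: int, sd: float, tile: int, rng: np.random.Generator) -> np.ndarray:
    """Half-normal background FE, piecewise constant over short tiles."""
    if sd <= 0:
        return np.zeros(length)
    n_tiles = (length + tile - 1) // tile
    vals = np.abs(rng.normal(0.0, sd, size=n_tiles))
    return np.repeat(vals, tile)[:length]


@dataclass
class TrackBundle:
    tracks: dict[str, FETrack]
    peaks: dict[str, list[PeakCall]]


def synthesize_tracks(
    truth: SyntheticTruth,
    peak_fe_extra: float = 15.0,
    peak_fe_polIII_cobind: float = 40.0,
    tftc5_fe: float = 12.0,
    peak_width: int = 200,
    noise_sd: float = 0.5,
    noise_tile: int = 20,
    n_decoy_lowfe: int = 400,
    n_decoy_orphan: int = 229,
    decoy_lowfe_amp: float = 3.0,
    decoy_orphan_amp: float = 8.0,
    h3k9_fe: float = 10.0,
    h3k9_window: int = 1000,
    h3k9_fraction: float = 0.7,
    h3k9_me2_gap: int = 500,
    h3k9_me3_gap: int = 2000,
    h3k9_block_windows: tuple[int, int] = (2, 5),
    seed: int | None = None,
) -> TrackBundle:
    """Synthesize TFTC-3/TFTC-5/RPC-1 FE tracks plus H3K9-like mark tracks.

    All planted sites get triangular TFTC-3 and TFTC-5 peaks (maximum FE at
    the planted center, strictly above the site-calling cutoff); only Pol
    III-bound sites get RPC-1 peaks above the classification cutoff. Decoy
    TFTC-3 peaks emulate the raw peak list before high-confidence filtering:
    low-FE decoys fail the FE cutoff, orphan decoys lack a nearby TFTC-5
    peak. H3K9-like tracks carry window-aligned enriched blocks placed
    adjacent to — never over — a fraction of the extra-site clusters
    (me2-like blocks upstream with a short gap, me3-like blocks downstream
    with a longer gap).
    """
    if seed is None:
        seed = truth.seed
    if peak_fe_extra <= 5 or peak_fe_polIII_cobind <= 20:
        import warnings

        warnings.warn("peak amplitudes do not guarantee separable classes")
    rng = _rng(seed, 2)
    layout = truth.layout
    half = peak_width // 2

    placer = _Placer(3 * peak_width)
    for chrom, center in truth.centers():
        placer.add(chrom, center)

    decoys: list[tuple[str, int, str]] = []
    all_domains = layout.all_domains()
    guard = 0
    want = [("lowfe", n_decoy_lowfe), ("orphan", n_decoy_orphan)]
    for kind, n in want:
        placed = 0
        while placed < n:
            guard += 1
            if guard > 500_000:
                raise RuntimeError("infeasible packing: cannot place decoy peaks")
            dom = _weighted_domain_choice(all_domains, rng)
            lo = dom.start + EDGE_MARGIN if dom.start == 0 else dom.start
            hi = dom.end - EDGE_MARGIN if dom.end == layout.chromosomes[dom.chromosome] else dom.end
            if hi <= lo:
                continue
            pos = int(rng.integers(lo, hi))
            if not placer.ok(dom.chromosome, pos):
                continue
            placer.add(dom.chromosome, pos)
            decoys.append((dom.chromosome, pos, kind))
            placed += 1

    # H3K9-like blocks, window-aligned and kept clear of all peak signal
    block_placer = _Placer(1)
    blocks: dict[str, list[tuple[str, int, int]]] = {"h3k9me2": [], "h3k9me3": []}
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in layout.chromosomes}

    def _conflicts(chrom: str, s: int, e: int) -> bool:
        for a, b in occupied[chrom]:
            if s < b + h3k9_window and e + h3k9_window > a:
                return True
        ps = placer.placed.get(chrom, [])
        i = bisect.bisect_left(ps, s - 300)
        while i < len(ps) and ps[i] < e + 300:
            return True
        return False

    extra = truth.sites[truth.sites["site_class"] == "extra"]
    for cid, grp in extra.groupby("cluster"):
        if rng.random() >= h3k9_fraction:
            continue
        chrom = grp["chrom"].iloc[0]
        length = layout.chromosomes[chrom]
        c_lo, c_hi = int(grp["center"].min()), int(grp["center"].max())
        for mark, anchor, direction, gap in (
            ("h3k9me2", c_lo, -1, h3k9_me2_gap),
            ("h3k9me3", c_hi, +1, h3k9_me3_gap),
        ):
            n_win = int(rng.integers(h3k9_block_windows[0], h3k9_block_windows[1] + 1))
            size = n_win * h3k9_window
            # widen the gap, then flip sides, until a clear spot is found
            for sign, mult in ((direction, 1), (direction, 2), (direction, 4),
                               (-direction, 1), (-direction, 2)):
                a = c_hi if sign > 0 else c_lo
                if sign > 0:
                    s = ((a + peak_width + gap * mult) // h3k9_window + 1) * h3k9_window
                    e = s + size
                else:
                    e = ((a - peak_width - gap * mult) // h3k9_window) * h3k9_window
                    s = e - size
                if s < 0 or e > length or s >= e or _conflicts(chrom, s, e):
                    continue
                occupied[chrom].append((s, e))
                blocks[mark].append((chrom, s, e))
                break

    noise_rng = {name: _rng(seed, 10 + i) for i, name in enumerate(
        ["tftc3", "tftc5", "rpc1", "h3k9me2", "h3k9me3"])}

    tracks: dict[str, FETrack] = {}
    dense_acc: dict[str, dict[str, np.ndarray]] = {
        name: {} for name in ["tftc3", "tftc5", "rpc1", "h3k9me2", "h3k9me3"]
    }
    for chrom, length in layout.chromosomes.items():
        for name in dense_acc:
            dense_acc[name][chrom] = _tile_noise(length, noise_sd, noise_tile,
                                                 noise_rng[name])
    for row in truth.sites.itertuples(index=False):
        amp3 = peak_fe_extra
        _add_triangle(dense_acc["tftc3"][row.chrom], row.center, amp3, half)
        _add_triangle(dense_acc["tftc5"][row.chrom], row.center, tftc5_fe, half)
        if row.site_class == "polIII_bound":
            _add_triangle(dense_acc["rpc1"][row.chrom], row.center,
                          peak_fe_polIII_cobind, half)
    for chrom, pos, kind in decoys:
        amp = decoy_lowfe_amp if kind == "lowfe" else decoy_orphan_amp
        _add_triangle(dense_acc["tftc3"][chrom], pos, amp, half)
        if kind == "lowfe":
            _add_triangle(dense_acc["tftc5"][chrom], pos, tftc5_fe, half)
    for mark in ("h3k9me2", "h3k9me3"):
        for chrom, s, e in blocks[mark]:
            dense_acc[mark][chrom][s:e] += h3k9_fe

    for name, arrays in dense_acc.items():
        tracks[name] = FETrack.from_dense(name, arrays)

    tftc3_peaks = []
    tftc5_peaks = []
    for row in truth.sites.itertuples(index=False):
        tftc3_peaks.append(PeakCall(row.chrom, row.center - half, row.center + half,
                                    peak_fe_extra))
        tftc5_peaks.append(PeakCall(row.chrom, row.center - half, row.center + half,
                                    tftc5_fe))
    for chrom, pos, kind in decoys:
        amp = decoy_lowfe_amp if kind == "lowfe" else decoy_orphan_amp
        tftc3_peaks.append(PeakCall(chrom, pos - half, pos + half, amp))
        if kind == "lowfe":
            tftc5_peaks.append(PeakCall(chrom, pos - half, pos + half, tftc5_fe))

    truth.h3k9_blocks = {
        mark: FeatureSet(
            f"{mark}_planted",
            [(c, s, e, mark, ".") for c, s, e in blocks[mark]],
            layout=layout,
        )
        for mark in blocks
    }
    truth.params.update({
        "peak_fe_extra": peak_fe_extra,
        "peak_fe_polIII_cobind": peak_fe_polIII_cobind,
        "tftc5_fe": tftc5_fe, "peak_width": peak_width, "noise_sd": noise_sd,
        "n_decoy_lowfe": n_decoy_lowfe, "n_decoy_orphan": n_decoy_orphan,
        "h3k9_fe": h3k9_fe, "h3k9_fraction": h3k9_fraction,
    })
    return TrackBundle(tracks=tracks,
                       peaks={"tftc3": tftc3_peaks, "tftc5": tftc5_peaks})


def plant_annotations(
    truth: SyntheticTruth,
    tss_at_polIII_fraction: float = 0.88,
    tss_at_extra_fraction: float = 0.04,
    tss_class_probs: dict[str, float] | None = None,
    n_tss_coding: int = 2000,
    repeat_at_extra_fraction: float = 0.446,
    repeat_at_polIII_fraction: float = 0.082,
    cerep3_fraction: float = 0.951,
    n_background_repeats: int = 300,
    lem2_containment: float = 0.88,
    npp13_at_polIII_fraction: float = 0.41,
    n_background_npp13: int = 8,
    seed: int | None = None,
) -> dict[str, FeatureSet]:
    """Plant annotation features with recorded per-site memberships.

    ncRNA TSSs land within +/-100 bp of chosen site centers; repeats cover
    chosen site centers (mostly a CeRep3-like class at extra sites); LEM-2
    style subdomains are large arm blocks built to contain a chosen fraction
    of extra sites; nuclear-pore-like points sit at a fraction of Pol
    III-bound site centers. Membership flags are written back into
    ``truth.sites``.
    """
    if seed is None:
        seed = truth.seed
    if tss_class_probs is None:
        tss_class_probs = {"tRNA": 0.81, "snoRNA": 0.11, "other_ncRNA": 0.08}
    for frac in (tss_at_polIII_fraction, tss_at_extra_fraction,
                 repeat_at_extra_fraction, repeat_at_polIII_fraction,
                 lem2_containment, npp13_at_polIII_fraction):
        if not 0 <= frac <= 1:
            raise ValueError("fractions must lie in [0, 1]")
    rng = _rng(seed, 3)
    layout = truth.layout
    sites = truth.sites

    classes = list(tss_class_probs)
    probs = np.array([tss_class_probs[c] for c in classes], dtype=float)
    probs = probs / probs.sum()

    nc_tss_rows = []
    has_tss, tss_class = [], []
    for row in sites.itertuples(index=False):
        frac = (tss_at_polIII_fraction if row.site_class == "polIII_bound"
                else tss_at_extra_fraction)
        if rng.random() < frac:
            pos = row.center + int(rng.integers(-80, 81))
            cls = classes[rng.choice(len(classes), p=probs)]
            nc_tss_rows.append((row.chrom, pos, pos + 1, cls, "+"))
            has_tss.append(True)
            tss_class.append(cls)
        else:
            has_tss.append(False)
            tss_class.append("")
    sites["has_nc_tss"] = has_tss
    sites["nc_tss_class"] = tss_class

    all_domains = layout.all_domains()
    coding_rows = []
    for _ in range(n_tss_coding):
        dom = _weighted_domain_choice(all_domains, rng)
        pos = int(rng.integers(dom.start, dom.end))
        strand = "+" if rng.random() < 0.5 else "-"
        coding_rows.append((dom.chromosome, pos, pos + 1, "coding", strand))

    repeat_rows = []
    in_repeat, repeat_class = [], []
    for row in sites.itertuples(index=False):
        frac = (repeat_at_extra_fraction if row.site_class == "extra"
                else repeat_at_polIII_fraction)
        if rng.random() < frac:
            u1 = int(rng.integers(20, 101))
            u2 = int(rng.integers(20, 101))
            cls = "CeRep3" if rng.random() < cerep3_fraction else "other_repeat"
            repeat_rows.append((row.chrom, row.center - u1, row.center + u2, cls, "."))
            in_repeat.append(True)
            repeat_class.append(cls)
        else:
            in_repeat.append(False)
            repeat_class.append("")
    sites["in_repeat"] = in_repeat
    sites["repeat_class"] = repeat_class
    site_positions = {c: sorted(g["center"]) for c, g in sites.groupby("chrom")}
    placed_bg = 0
    guard = 0
    while placed_bg < n_background_repeats:
        guard += 1
        if guard > 200_000:
            break
        dom = _weighted_domain_choice(all_domains, rng)
        width = int(rng.integers(50, 401))
        if dom.end - dom.start <= width:
            continue
        s = int(rng.integers(dom.start, dom.end - width))
        ps = site_positions.get(dom.chromosome, [])
        i = bisect.bisect_left(ps, s - 300)
        if i < len(ps) and ps[i] < s + width + 300:
            continue
        cls = "other_repeat" if rng.random() < 0.7 else "CeRep3"
        repeat_rows.append((dom.chromosome, s, s + width, cls, "."))
        placed_bg += 1

    # LEM-2-like subdomains: cover a Bernoulli-chosen fraction of extra
    # sites; boundaries fall halfway between covered/uncovered neighbours.
    covered = {}
    for row in sites.itertuples(index=True):
        if row.site_class == "extra":
            covered[row.Index] = rng.random() < lem2_containment
    sites["in_lem2"] = [covered.get(i, False) for i in sites.index]
    lem2_rows = []
    for chrom, grp in sites.groupby("chrom"):
        length = layout.chromosomes[chrom]
        grp = grp.sort_values("center")
        centers = grp["center"].to_numpy()
        flags = grp["in_lem2"].to_numpy()
        i = 0
        n = len(grp)
        while i < n:
            if not flags[i]:
                i += 1
                continue
            j = i
            while j + 1 < n and flags[j + 1]:
                j += 1
            left = (centers[i] + centers[i - 1]) // 2 if i > 0 else max(0, centers[i] - 5000)
            right = (centers[j] + centers[j + 1]) // 2 if j + 1 < n else min(length, centers[j] + 5000)
            lem2_rows.append((chrom, int(left), int(right), "lem2_subdomain", "."))
            i = j + 1

    lem2 = FeatureSet("lem2_subdomains", lem2_rows, layout=layout)
    gap_rows = []
    for chrom, label in truth.designated_arms.items():
        dom = next(d for d in layout.domains_of(chrom) if d.label == label)
        ms, me = lem2.merged_intervals(chrom)
        pos = dom.start
        for s, e in zip(ms, me):
            if s > pos and s < dom.end:
                gap_rows.append((chrom, int(max(pos, dom.start)), int(min(s, dom.end)), "gap", "."))
            pos = max(pos, e)
        if pos < dom.end:
            gap_rows.append((chrom, int(pos), dom.end, "gap", "."))

    npp13_rows = []
    at_npp13 = []
    for row in sites.itertuples(index=False):
        hit = row.site_class == "polIII_bound" and rng.random() < npp13_at_polIII_fraction
        if hit:
            pos = row.center + int(rng.integers(-50, 51))
            npp13_rows.append((row.chrom, pos, pos + 1, "npp13", "."))
        at_npp13.append(hit)
    sites["at_npp13"] = at_npp13
    for _ in range(n_background_npp13):
        dom = _weighted_domain_choice(all_domains, rng)
        pos = int(rng.integers(dom.start, dom.end))
        npp13_rows.append((dom.chromosome, pos, pos + 1, "npp13", "."))

    annotations = {
        "ncrna_tss": FeatureSet("ncrna_tss", nc_tss_rows, kind="point", layout=layout),
        "coding_tss": FeatureSet("coding_tss", coding_rows, kind="point", layout=layout),
        "repeats": FeatureSet("repeats", repeat_rows, layout=layout),
        "lem2_subdomains": lem2,
        "lem2_gaps": FeatureSet("lem2_gaps", gap_rows, layout=layout),
        "npp13": FeatureSet("npp13", npp13_rows, kind="point", layout=layout),
    }
    truth.annotations = annotations
    truth.params.update({
        "tss_at_polIII_fraction": tss_at_polIII_fraction,
        "tss_at_extra_fraction": tss_at_extra_fraction,
        "repeat_at_extra_fraction": repeat_at_extra_fraction,
        "lem2_containment": lem2_containment,
        "npp13_at_polIII_fraction": npp13_at_polIII_fraction,
    })
    return annotations


@dataclass
class SyntheticBundle:
    truth: SyntheticTruth
    tracks: dict[str, FETrack]
    peaks: dict[str, list[PeakCall]]
    annotations: dict[str, FeatureSet]


def simulate_study(seed: int = 0, layout_params: dict | None = None,
                   site_params: dict | None = None,
                   track_params: dict | None = None,
                   annotation_params: dict | None = None) -> SyntheticBundle:
    """Generate a full study-shaped synthetic dataset with planted truth."""
    layout = make_layout(seed=seed, **(layout_params or {}))
    truth = plant_sites(layout, seed=seed, **(site_params or {}))
    bundle = synthesize_tracks(truth, **(track_params or {}))
    annotations = plant_annotations(truth, **(annotation_params or {}))
    return SyntheticBundle(truth=truth, tracks=bundle.tracks,
                           peaks=bundle.peaks, annotations=annotations)


def write_bundle(bundle: SyntheticBundle, outdir) -> None:
    """Write a bundle as the plain-text formats the pipeline consumes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    layout = bundle.truth.layout
    with open(outdir / "chrom.sizes", "w") as fh:
        for chrom, length in layout.chromosomes.items():
            fh.write(f"{chrom}\t{length}\n")
    with open(outdir / "domains.tsv", "w") as fh:
        for d in layout.all_domains():
            fh.write(f"{d.chromosome}\t{d.start}\t{d.end}\t{d.label}\n")
    for name, track in bundle.tracks.items():
        write_bedgraph(track, outdir / f"{name}.bedgraph")
    for name, peaks in bundle.peaks.items():
        write_peaks_bed(peaks, outdir / f"{name}_peaks.bed")
    for name, features in bundle.annotations.items():
        write_features(features, outdir / f"{name}.bed", format="bed")
    for mark, features in bundle.truth.h3k9_blocks.items():
        write_features(features, outdir / f"{mark}_planted_blocks.bed", format="bed")
    truth = {
        "seed": bundle.truth.seed,
        "params": bundle.truth.params,
        "designated_arms": bundle.truth.designated_arms,
        "sites": bundle.truth.sites.to_dict(orient="list"),
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, default=str)
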