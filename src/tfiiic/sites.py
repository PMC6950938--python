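"""TFIIIC site calling and Pol III co-occupancy classification.

High-confidence TFIIIC sites are TFTC-3 peaks with fold enrichment above a
cutoff that also carry a TFTC-5 peak nearby; each site is reduced to the
single base of maximal TFTC-3 FE. Sites are then split into Pol III-bound
(strong RPC-1 enrichment near the center) versus extra-TFIIIC (the rest).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .genome import FETrack, GenomeLayout, ValidationError

CLASS_EXTRA = "extra"
CLASS_POLIII = "polIII_bound"
CLASS_UNSET = "unclassified"


@dataclass(frozen=True)
class PeakCall:
    chromosome: str
    start: int
    end: int
    fe_score: float = 0.0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(f"empty peak {self.chromosome}:{self.start}-{self.end}")
        if self.fe_score < 0:
            raise ValidationError("negative peak FE score")


@dataclass(frozen=True)
class TFIIICSite:
    chromosome: str
    center: int
    tftc3_fe: float = 0.0
    polIII_max_fe: float = 0.0
    site_class: str = CLASS_UNSET


@dataclass(frozen=True)
class TFIIICSiteSet:
    """Sorted collection of TFIIIC sites plus the thresholds that produced it."""

    layout: GenomeLayout | None
    sites: tuple[TFIIICSite, ...] = ()
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.sites, key=lambda s: (s.chromosome, s.center)))
        object.__setattr__(self, "sites", ordered)

    def __len__(self) -> int:
        return len(self.sites)

    def centers(self) -> list[tuple[str, int]]:
        return [(s.chromosome, s.center) for s in self.sites]

    def by_class(self, site_class: str) -> "TFIIICSiteSet":
        return TFIIICSiteSet(
            layout=self.layout,
            sites=tuple(s for s in self.sites if s.site_class == site_class),
            params=self.params,
        )

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for s in self.sites:
            counts[s.site_class] = counts.get(s.site_class, 0) + 1
        return counts


def locate_center(track: FETrack, chromosome: str, start: int, end: int) -> int:
    """Base with the largest FE within [start, end); leftmost on ties."""
    if start >= end:
        raise ValidationError("empty interval")
    arr = track.dense(chromosome, start, end)
    return start + int(np.argmax(arr))


def read_peaks_bed(path, layout: GenomeLayout | None = None) -> list[PeakCall]:
    """Read peaks from BED where column 5 (score) carries the peak FE."""
    peaks = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            fe = float(parts[4]) if len(parts) > 4 else 0.0
            if layout is not None and parts[0] not in layout.chromosomes:
                raise ValidationError(f"peak on unknown chromosome {parts[0]!r}")
            peaks.append(PeakCall(parts[0], int(parts[1]), int(parts[2]), fe))
    return peaks


def write_peaks_bed(peaks: list[PeakCall], path) -> None:
    ordered = sorted(peaks, key=lambda p: (p.chromosome, p.start, p.end))
    with open(path, "w") as fh:
        for p in ordered:
            fh.write(f"{p.chromosome}\t{p.start}\t{p.end}\tpeak\t{p.fe_score:g}\t.\n")


def call_high_confidence_sites(
    tftc3_peaks: list[PeakCall],
    tftc3_track: FETrack,
    tftc5_peaks: list[PeakCall],
    layout: GenomeLayout,
    fe_min: float = 5.0,
    proximity: int = 100,
) -> TFIIICSiteSet:
    """Filter TFTC-3 peaks to high-confidence TFIIIC sites.

    A peak is retained when its FE score strictly exceeds ``fe_min`` AND the
    peak interval, extended by ``proximity`` bp on each side, intersects at
    least one TFTC-5 peak (edge-gap distance <= proximity). Each retained
    peak yields one site centered on its TFTC-3 FE argmax.
    """
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {p.chromosome for p in tftc5_peaks}:
        ps = sorted(
            (p for p in tftc5_peaks if p.chromosome == chrom),
            key=lambda p: (p.start, p.end),
        )
        by_chrom[chrom] = (
            np.array([p.start for p in ps], np.int64),
            np.array([p.end for p in ps], np.int64),
        )

    sites = []
    for peak in tftc3_peaks:
        if peak.chromosome not in layout.chromosomes:
            raise ValidationError(f"peak on unknown chromosome {peak.chromosome!r}")
        if not peak.fe_score > fe_min:
            continue
        if peak.chromosome not in by_chrom:
            continue
        starts5, ends5 = by_chrom[peak.chromosome]
        lo, hi = peak.start - proximity, peak.end + proximity
        # edge-gap distance <= proximity: a TFTC-5 peak starting exactly
        # `proximity` bases past the peak end still counts
        if not np.any((starts5 <= hi) & (ends5 >= lo)):
            continue
        center = locate_center(tftc3_track, peak.chromosome, peak.start, peak.end)
        fe_at_center = tftc3_track.query(peak.chromosome, center)
        sites.append(TFIIICSite(peak.chromosome, center, tftc3_fe=fe_at_center))
    return TFIIICSiteSet(
        layout=layout,
        sites=tuple(sites),
        params={"fe_min": fe_min, "proximity": proximity},
    )


def classify_sites(
    sites: TFIIICSiteSet,
    polIII_track: FETrack,
    polIII_threshold: float = 20.0,
    flank: int = 250,
) -> TFIIICSiteSet:
    """Split sites into Pol III-bound vs extra-TFIIIC by RPC-1 co-occupancy.

    A site is Pol III-bound when the maximum Pol III FE within +/- ``flank``
    bp of its center (inclusive of both endpoint bases, clipped to the
    chromosome) strictly exceeds ``polIII_threshold``; otherwise extra.
    """
    classified = []
    for s in sites.sites:
        length = sites.layout.chromosomes[s.chromosome] if sites.layout else None
        lo = max(0, s.center - flank)
        hi = s.center + flank + 1
        if length is not None:
            hi = min(hi, length)
        max_fe = polIII_track.max_in(s.chromosome, lo, hi)
        cls = CLASS_POLIII if max_fe > polIII_threshold else CLASS_EXTRA
        classified.append(replace(s, polIII_max_fe=max_fe, site_class=cls))
    params = dict(sites.params)
    params.update({"polIII_threshold": polIII_threshold, "flank": flank})
    return TFIIICSiteSet(layout=sites.layout, sites=tuple(classified), params=params)
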