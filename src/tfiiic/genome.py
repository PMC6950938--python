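"""Genome layout, fold-enrichment tracks, and feature annotations.

All internal coordinates are 0-based half-open (BED convention). GFF3 input
(1-based closed) is converted on read and back on write. Uncovered bases in a
fold-enrichment (FE) track have implicit FE 0, matching input-normalized
enrichment semantics where absence of signal is background.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

DOMAIN_LABELS = ("left_arm", "center", "right_arm", "whole")

# Chromosome names treated as non-nuclear and dropped at layout construction.
NON_NUCLEAR = {"chrM", "chrMT", "M", "MT", "MtDNA", "chrMtDNA"}


class FormatError(ValueError):
    """A file does not conform to the expected tabular format."""


class ValidationError(ValueError):
    """Coordinates or domain structure violate layout invariants."""


@dataclass(frozen=True)
class Domain:
    chromosome: str
    start: int
    end: int
    label: str

    def __post_init__(self) -> None:
        if self.label not in DOMAIN_LABELS:
            raise ValidationError(f"unknown domain label {self.label!r}")
        if not 0 <= self.start < self.end:
            raise ValidationError(
                f"bad domain interval {self.chromosome}:{self.start}-{self.end}"
            )


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome lengths plus an optional arm/center domain partition.

    ``domains`` for a partitioned chromosome tile it exactly; chromosomes
    without an explicit partition carry a single ``whole`` domain once
    :func:`attach_domains` has run.
    """

    chromosomes: dict[str, int]
    domains: tuple[Domain, ...] = ()
    autosomes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if len(set(self.chromosomes)) != len(self.chromosomes):
            raise ValidationError("duplicate chromosome names")
        for name, length in self.chromosomes.items():
            if not isinstance(length, (int, np.integer)) or length <= 0:
                raise ValidationError(f"non-positive length for {name}")
        self._validate_domains()

    def _validate_domains(self) -> None:
        by_chrom: dict[str, list[Domain]] = {}
        for d in self.domains:
            if d.chromosome not in self.chromosomes:
                raise ValidationError(f"domain on unknown chromosome {d.chromosome}")
            if d.end > self.chromosomes[d.chromosome]:
                raise ValidationError(
                    f"domain {d.chromosome}:{d.start}-{d.end} exceeds chromosome end"
                )
            by_chrom.setdefault(d.chromosome, []).append(d)
        for chrom, ds in by_chrom.items():
            ds = sorted(ds, key=lambda d: d.start)
            pos = 0
            for d in ds:
                if d.start < pos:
                    raise ValidationError(
                        f"overlapping domains at {chrom}:{d.start}-{d.end}"
                    )
                if d.start > pos:
                    raise ValidationError(
                        f"gap in domain partition of {chrom} at {pos}-{d.start}"
                    )
                pos = d.end
            if pos != self.chromosomes[chrom]:
                raise ValidationError(
                    f"domain partition of {chrom} ends at {pos}, "
                    f"expected {self.chromosomes[chrom]}"
                )

    @property
    def names(self) -> list[str]:
        return list(self.chromosomes)

    def length(self, chromosome: str) -> int:
        return self.chromosomes[chromosome]

    def domains_of(self, chromosome: str) -> list[Domain]:
        ds = [d for d in self.domains if d.chromosome == chromosome]
        if not ds:
            return [Domain(chromosome, 0, self.chromosomes[chromosome], "whole")]
        return sorted(ds, key=lambda d: d.start)

    def all_domains(self) -> list[Domain]:
        out: list[Domain] = []
        for chrom in self.chromosomes:
            out.extend(self.domains_of(chrom))
        return out

    def domain_at(self, chromosome: str, position: int) -> Domain:
        for d in self.domains_of(chromosome):
            if d.start <= position < d.end:
                return d
        raise ValidationError(f"position {chromosome}:{position} outside chromosome")

    def is_autosome(self, chromosome: str) -> bool:
        return chromosome in self.autosomes


def read_chrom_sizes(path, autosome_prefix_exclude: tuple[str, ...] = ("chrX", "X")) -> GenomeLayout:
    """Read a two-column (name, length) TSV into a :class:`GenomeLayout`.

    Mitochondrial/non-nuclear chromosomes are excluded. Chromosomes whose name
    is not in ``autosome_prefix_exclude`` are flagged as autosomes.
    """
    chroms: dict[str, int] = {}
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty chrom.sizes file")
    for i, line in enumerate(lines, 1):
        parts = line.split("\t")
        if len(parts) < 2:
            raise FormatError(f"{path}:{i}: expected 2 tab-separated columns")
        name = parts[0]
        try:
            length = int(parts[1])
        except ValueError:
            raise FormatError(f"{path}:{i}: non-integer length {parts[1]!r}") from None
        if length <= 0:
            raise FormatError(f"{path}:{i}: non-positive length")
        if name in NON_NUCLEAR:
            continue
        if name in chroms:
            raise FormatError(f"{path}:{i}: duplicate chromosome {name!r}")
        chroms[name] = length
    autosomes = frozenset(n for n in chroms if n not in autosome_prefix_exclude)
    return GenomeLayout(chromosomes=chroms, autosomes=autosomes)


def attach_domains(layout: GenomeLayout, path) -> GenomeLayout:
    """Attach a validated arm/center partition from a 4-column TSV.

    Chromosomes absent from the file receive a single ``whole`` domain.
    Partitions must tile their chromosome exactly (no gaps, no overlap).
    """
    rows: list[Domain] = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{i}: expected 4 columns")
            chrom, start, end, label = parts[0], parts[1], parts[2], parts[3]
            try:
                rows.append(Domain(chrom, int(start), int(end), label))
            except ValueError as exc:
                raise FormatError(f"{path}:{i}: {exc}") from None
    seen = {d.chromosome for d in rows}
    for chrom, length in layout.chromosomes.items():
        if chrom not in seen:
            rows.append(Domain(chrom, 0, length, "whole"))
    return replace(layout, domains=tuple(rows))


class FETrack:
    """Sparse per-base fold-enrichment signal for one factor.

    Stored as sorted non-overlapping runs (start, end, value) per chromosome;
    any base not covered by a run has FE 0.
    """

    def __init__(
        self,
        factor: str,
        runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] | None = None,
    ):
        self.factor = factor
        self.runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        if runs:
            for chrom, (s, e, v) in runs.items():
                self._set_runs(chrom, np.asarray(s), np.asarray(e), np.asarray(v))

    def _set_runs(self, chrom: str, starts, ends, values) -> None:
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        values = np.asarray(values, dtype=np.float64)
        order = np.argsort(starts, kind="stable")
        starts, ends, values = starts[order], ends[order], values[order]
        if np.any(ends <= starts):
            raise ValidationError(f"empty or inverted run on {chrom}")
        if np.any(starts[1:] < ends[:-1]):
            raise ValidationError(f"overlapping runs on {chrom}")
        if not np.all(np.isfinite(values)) or np.any(values < 0):
            raise ValidationError(f"non-finite or negative FE on {chrom}")
        self.runs[chrom] = (starts, ends, values)

    @classmethod
    def from_dense(cls, factor: str, arrays: dict[str, np.ndarray]) -> "FETrack":
        """Build a track from per-chromosome dense per-base arrays.

        Zero stretches are left uncovered; equal-valued neighbours collapse
        into single runs.
        """
        track = cls(factor)
        for chrom, arr in arrays.items():
            arr = np.asarray(arr, dtype=np.float64)
            if arr.size == 0:
                continue
            change = np.flatnonzero(arr[1:] != arr[:-1]) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            values = arr[starts]
            keep = values != 0
            if keep.any():
                track._set_runs(chrom, starts[keep], ends[keep], values[keep])
        return track

    def query(self, chromosome: str, position: int) -> float:
        """FE at a single base (0 where uncovered)."""
        if chromosome not in self.runs:
            return 0.0
        starts, ends, values = self.runs[chromosome]
        i = np.searchsorted(starts, position, side="right") - 1
        if i >= 0 and position < ends[i]:
            return float(values[i])
        return 0.0

    def dense(self, chromosome: str, start: int, end: int) -> np.ndarray:
        """Per-base FE over [start, end); bases outside any run are 0.

        ``start`` may be negative and ``end`` may exceed the chromosome; the
        out-of-range flanks are zero-filled so callers can take centred
        windows at chromosome edges.
        """
        if end <= start:
            return np.zeros(0)
        out = np.zeros(end - start, dtype=np.float64)
        if chromosome not in self.runs:
            return out
        starts, ends, values = self.runs[chromosome]
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(starts, end, side="left")
        for i in range(lo, hi):
            a = max(starts[i], start) - start
            b = min(ends[i], end) - start
            out[a:b] = values[i]
        return out

    def max_in(self, chromosome: str, start: int, end: int) -> float:
        arr = self.dense(chromosome, start, end)
        return float(arr.max()) if arr.size else 0.0

    def chromosome_dense(self, chromosome: str, length: int) -> np.ndarray:
        return self.dense(chromosome, 0, length)


def read_bedgraph(path, layout: GenomeLayout, factor: str | None = None) -> FETrack:
    """Read a 4-column bedGraph into an :class:`FETrack`.

    Runs are clipped to chromosome bounds; overlapping input runs, negative
    values and unknown chromosomes are rejected.
    """
    if factor is None:
        factor = str(path)
    try:
        df = pd.read_csv(
            path,
            sep=r"\s+",
            header=None,
            comment="#",
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str},
            float_precision="round_trip",
        )
    except pd.errors.EmptyDataError:
        return FETrack(factor)
    df = df[~df["chrom"].str.startswith(("track", "browser"))]
    if df.empty:
        return FETrack(factor)
    if df[["start", "end", "value"]].isna().any().any():
        raise FormatError(f"{path}: non-numeric coordinates or values")
    if (df["value"] < 0).any():
        raise FormatError(f"{path}: negative FE value")
    track = FETrack(factor)
    for chrom, grp in df.groupby("chrom", sort=False):
        if chrom not in layout.chromosomes:
            raise FormatError(f"{path}: unknown chromosome {chrom!r}")
        length = layout.chromosomes[chrom]
        starts = grp["start"].to_numpy(np.int64).clip(0, length)
        ends = grp["end"].to_numpy(np.int64).clip(0, length)
        values = grp["value"].to_numpy(np.float64)
        keep = ends > starts
        try:
            track._set_runs(chrom, starts[keep], ends[keep], values[keep])
        except ValidationError as exc:
            raise FormatError(f"{path}: {exc}") from None
    return track


def write_bedgraph(track: FETrack, path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.runs):
            starts, ends, values = track.runs[chrom]
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


class FeatureSet:
    """Labeled genomic intervals or points (points stored as width-1 intervals).

    Backed by a DataFrame with columns chrom, start, end, label, strand,
    sorted by (chrom, start, end) after normalization.
    """

    COLUMNS = ["chrom", "start", "end", "label", "strand"]

    def __init__(self, name: str, records: pd.DataFrame | list | None = None,
                 kind: str = "interval", layout: GenomeLayout | None = None):
        self.name = name
        self.kind = kind
        if records is None:
            df = pd.DataFrame(columns=self.COLUMNS)
        elif isinstance(records, pd.DataFrame):
            df = records.copy()
        else:
            df = pd.DataFrame(records, columns=self.COLUMNS[: len(records[0])] if records else self.COLUMNS)
        for col, default in (("label", "."), ("strand", ".")):
            if col not in df.columns:
                df[col] = default
        df = df[self.COLUMNS]
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["start"] >= df["end"]).any():
            bad = df[df["start"] >= df["end"]].iloc[0]
            raise ValidationError(
                f"{name}: empty interval {bad['chrom']}:{bad['start']}-{bad['end']}"
            )
        if layout is not None:
            for chrom, grp in df.groupby("chrom"):
                if chrom not in layout.chromosomes:
                    raise ValidationError(f"{name}: unknown chromosome {chrom!r}")
                if (grp["end"] > layout.chromosomes[chrom]).any() or (grp["start"] < 0).any():
                    raise ValidationError(f"{name}: interval outside {chrom}")
        self.df = df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)
        self._merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    def __len__(self) -> int:
        return len(self.df)

    def labels(self) -> list[str]:
        return sorted(self.df["label"].unique())

    def subset(self, label: str) -> "FeatureSet":
        return FeatureSet(f"{self.name}:{label}", self.df[self.df["label"] == label],
                          kind=self.kind)

    def merged_intervals(self, chromosome: str) -> tuple[np.ndarray, np.ndarray]:
        """Union of this set's intervals on one chromosome, sorted and disjoint."""
        if chromosome not in self._merged:
            grp = self.df[self.df["chrom"] == chromosome]
            if grp.empty:
                self._merged[chromosome] = (np.zeros(0, np.int64), np.zeros(0, np.int64))
            else:
                starts = grp["start"].to_numpy(np.int64)
                ends = grp["end"].to_numpy(np.int64)
                ms, me = [starts[0]], [ends[0]]
                for s, e in zip(starts[1:], ends[1:]):
                    if s <= me[-1]:
                        me[-1] = max(me[-1], e)
                    else:
                        ms.append(s)
                        me.append(e)
                self._merged[chromosome] = (np.array(ms, np.int64), np.array(me, np.int64))
        return self._merged[chromosome]

    def chromosomes(self) -> list[str]:
        return sorted(self.df["chrom"].unique())


def read_features(path, format: str, layout: GenomeLayout | None = None,
                  name: str | None = None, kind: str = "interval") -> FeatureSet:
    """Read BED (0-based half-open) or GFF3 (1-based closed, converted)."""
    name = name or str(path)
    records = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith(("track", "browser")):
                continue
            parts = line.split("\t")
            try:
                if format == "bed":
                    chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                    label = parts[3] if len(parts) > 3 else "."
                    strand = parts[5] if len(parts) > 5 else "."
                elif format == "gff3":
                    if len(parts) < 8:
                        raise FormatError(f"{path}:{i}: truncated GFF3 line")
                    chrom = parts[0]
                    start, end = int(parts[3]) - 1, int(parts[4])
                    strand = parts[6]
                    label = parts[2]
                    if len(parts) > 8:
                        for attr in parts[8].split(";"):
                            if attr.startswith("ID="):
                                label = attr[3:]
                                break
                else:
                    raise ValueError(f"unknown format {format!r}")
            except (ValueError, IndexError) as exc:
                if isinstance(exc, FormatError):
                    raise
                raise FormatError(f"{path}:{i}: {exc}") from None
            if start >= end:
                raise FormatError(f"{path}:{i}: start >= end after conversion")
            records.append((chrom, start, end, label, strand))
    return FeatureSet(name, records, kind=kind, layout=layout)


def write_features(features: FeatureSet, path, format: str = "bed") -> None:
    with open(path, "w") as fh:
        for row in features.df.itertuples(index=False):
            if format == "bed":
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.label}\t0\t{row.strand}\n")
            elif format == "gff3":
                fh.write(
                    f"{row.chrom}\t.\tfeature\t{row.start + 1}\t{row.end}\t.\t"
                    f"{row.strand}\t.\tID={row.label}\n"
                )
            else:
                raise ValueError(f"unknown format {format!r}")


SITES_COLUMNS = [
    "chromosome", "center_0based", "center_1based",
    "tftc3_fe", "polIII_max_fe", "site_class",
]


def write_sites_tsv(sites, path) -> None:
    """Write a classified site set as a sorted TSV (supplementary-table style).

    Centers are emitted both 0-based and 1-based; rows sorted by
    (chromosome, center).
    """
    rows = [
        (s.chromosome, s.center, s.center + 1, s.tftc3_fe, s.polIII_max_fe, s.site_class)
        for s in sites.sites
    ]
    df = pd.DataFrame(rows, columns=SITES_COLUMNS)
    df = df.sort_values(["chromosome", "center_0based"], kind="stable")
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_sites_tsv(path, layout: GenomeLayout | None = None, coords: str = "auto"):
    """Read a site TSV written by :func:`write_sites_tsv` or a similar table.

    ``coords`` controls interpretation of a single center column when both
    conventions are not present: "auto" prefers an explicit 0-based column,
    falling back to a 1-based one.
    """
    from .sites import TFIIICSite, TFIIICSiteSet

    df = pd.read_csv(path, sep="\t")
    if df.empty:
        return TFIIICSiteSet(layout=layout, sites=[])
    if "center_0based" in df.columns and coords in ("auto", "zero"):
        centers = df["center_0based"].astype(int)
    elif "center_1based" in df.columns:
        centers = df["center_1based"].astype(int) - 1
    elif "center" in df.columns:
        centers = df["center"].astype(int) - (0 if coords == "zero" else 1)
    else:
        raise FormatError(f"{path}: no center column found")
    sites = [
        TFIIICSite(
            chromosome=row["chromosome"],
            center=int(c),
            tftc3_fe=float(row.get("tftc3_fe", 0.0)),
            polIII_max_fe=float(row.get("polIII_max_fe", 0.0)),
            site_class=str(row.get("site_class", "unclassified")),
        )
        for (_, row), c in zip(df.iterrows(), centers)
    ]
    return TFIIICSiteSet(layout=layout, sites=sites)
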