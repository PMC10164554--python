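"""Genomic-interval data model, BED I/O, co-occupancy clustering and stitching.

All coordinates are BED-style: 0-based, half-open ``[start, end)``.  The
center of an interval is ``floor((start + end) / 2)``, which always lies in
``[start, end)`` for a non-empty interval.

Two interval primitives underlie the whole pipeline:

* :func:`cluster_cobound` — pool peak centers from several factors and
  group all centers lying within a fixed span (500 bp by default) into
  co-bound sites, the unit of the co-occupancy analysis.
* :func:`stitch` — merge nearby peaks of one factor into stitched enhancer
  regions (12.5 kb gap by default), respecting promoter exclusion zones;
  the substrate of super-enhancer calling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Peak",
    "PeakSet",
    "CoboundSite",
    "StitchedRegion",
    "BedParseError",
    "read_bed",
    "write_bed",
    "write_regions_bed",
    "cluster_cobound",
    "stitch",
]


class BedParseError(ValueError):
    """Raised for malformed BED lines; message carries the line number."""


@dataclass(frozen=True, slots=True)
class Peak:
    """A called binding interval.

    Parameters
    ----------
    chrom : str
        Chromosome name (non-empty).
    start, end : int
        0-based half-open interval; ``start < end``.
    score : float
        Non-negative caller score (0 when absent).
    factor : str
        Label of the ChIP'd protein this peak belongs to.
    """

    chrom: str
    start: int
    end: int
    score: float = 0.0
    factor: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start >= self.end:
            raise ValueError(f"start must be < end, got [{self.start}, {self.end})")
        if self.score < 0:
            raise ValueError("score must be non-negative")

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PeakSet:
    """Peaks of one factor, kept sorted by (chrom, start, end)."""

    factor: str
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: (p.chrom, p.start, p.end))

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def by_chrom(self) -> dict[str, list[Peak]]:
        out: dict[str, list[Peak]] = {}
        for p in self.peaks:
            out.setdefault(p.chrom, []).append(p)
        return out


@dataclass
class CoboundSite:
    """A locus where peak centers of one or more factors co-cluster.

    ``members`` maps factor label -> representative peak (one per factor);
    the span covers every member center and never exceeds the clustering
    window.
    """

    chrom: str
    span_start: int
    span_end: int
    members: dict[str, Peak]

    @property
    def n_factors(self) -> int:
        return len(self.members)

    @property
    def center(self) -> int:
        return (self.span_start + self.span_end) // 2

    @property
    def factors(self) -> frozenset[str]:
        return frozenset(self.members)


@dataclass
class StitchedRegion:
    """A cluster of peaks merged by gap-based stitching."""

    chrom: str
    start: int
    end: int
    constituents: list[Peak]
    signal_score: float = float("nan")

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    @property
    def length(self) -> int:
        return self.end - self.start


def read_bed(path: str | Path, factor: str | None = None) -> PeakSet:
    """Read a BED3/BED5 file into a :class:`PeakSet`.

    Track lines and ``#`` comments are ignored.  Column 5, when present,
    supplies the score; otherwise the score is 0.  Malformed lines
    (non-integer coordinates, ``start >= end``) raise :class:`BedParseError`
    naming the 1-based line number.
    """
    path = Path(path)
    if factor is None:
        factor = path.stem
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            score = 0.0
            if len(fields) >= 5 and fields[4] not in ("", "."):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise BedParseError(f"{path}:{lineno}: non-numeric score") from exc
            try:
                peaks.append(Peak(fields[0], start, end, score=score, factor=factor))
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return PeakSet(factor=factor, peaks=peaks)


def write_bed(peaks: Iterable[Peak], path: str | Path) -> None:
    """Write peaks as BED5 (name column carries the factor label)."""
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            name = p.factor or f"peak{i}"
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{name}\t{p.score:g}\n")


def write_regions_bed(regions: Iterable[StitchedRegion], path: str | Path) -> None:
    """Write stitched regions as BED5 with the constituent count in column 5."""
    with open(path, "w") as fh:
        for i, r in enumerate(regions):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tregion{i}\t{len(r.constituents)}\n")


def cluster_cobound(
    peaksets: Sequence[PeakSet], window: int = 500
) -> list[CoboundSite]:
    """Group peak centers from several factors into co-bound sites.

    Centers are pooled per chromosome, sorted, and clustered greedily left
    to right: the current cluster is extended with the next center iff the
    resulting span (max center - min center) stays <= ``window``; otherwise
    a new cluster starts.  Within a cluster each factor is counted once —
    when a factor contributes several peaks, the one whose center is
    nearest the cluster's mean center is kept as the representative.

    Returns one :class:`CoboundSite` per cluster, sorted by
    (chrom, span_start).  Empty input gives an empty list.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    pooled: dict[str, list[Peak]] = {}
    for ps in peaksets:
        for p in ps:
            pooled.setdefault(p.chrom, []).append(p)

    sites: list[CoboundSite] = []
    for chrom in sorted(pooled):
        peaks = sorted(pooled[chrom], key=lambda p: (p.center, p.start, p.factor))
        cluster: list[Peak] = []
        for p in peaks:
            if cluster and p.center - cluster[0].center > window:
                sites.append(_finish_cluster(chrom, cluster))
                cluster = []
            cluster.append(p)
        if cluster:
            sites.append(_finish_cluster(chrom, cluster))
    return sites


def _finish_cluster(chrom: str, cluster: list[Peak]) -> CoboundSite:
    centers = [p.center for p in cluster]
    mean_c = sum(centers) / len(centers)
    members: dict[str, Peak] = {}
    for p in cluster:
        best = members.get(p.factor)
        if best is None or abs(p.center - mean_c) < abs(best.center - mean_c):
            members[p.factor] = p
    return CoboundSite(
        chrom=chrom,
        span_start=min(centers),
        span_end=max(centers),
        members=members,
    )


def stitch(
    peaks: PeakSet | Sequence[Peak],
    gap: int = 12_500,
    exclusion: Sequence[tuple[str, int, int]] = (),
) -> list[StitchedRegion]:
    """Merge nearby peaks into stitched regions, respecting exclusion zones.

    Peaks lying entirely inside an exclusion zone (e.g. a +/-2.5 kb TSS
    promoter zone) are dropped before stitching.  Two consecutive surviving
    peaks on the same chromosome are merged when the gap between them
    (``next.start - current_region.end``) is <= ``gap`` *and* no exclusion
    zone intersects the open interval strictly between them.

    Parameters
    ----------
    peaks
        Sorted peaks of one factor.
    gap : int
        Maximum stitching distance in bp (>= 0).
    exclusion
        ``(chrom, start, end)`` zones, half-open.

    Returns
    -------
    list of StitchedRegion, disjoint and sorted, each recording its
    constituent peaks.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    if isinstance(peaks, PeakSet):
        plist = list(peaks)
    else:
        plist = sorted(peaks, key=lambda p: (p.chrom, p.start, p.end))

    zones: dict[str, list[tuple[int, int]]] = {}
    for chrom, zs, ze in exclusion:
        zones.setdefault(chrom, []).append((zs, ze))
    for zlist in zones.values():
        zlist.sort()

    def excluded(p: Peak) -> bool:
        return any(zs <= p.start and p.end <= ze for zs, ze in zones.get(p.chrom, ()))

    def zone_between(chrom: str, left_end: int, right_start: int) -> bool:
        # a zone blocks stitching when it intersects the open gap interval
        if right_start <= left_end:
            return False
        return any(
            zs < right_start and ze > left_end for zs, ze in zones.get(chrom, ())
        )

    regions: list[StitchedRegion] = []
    current: list[Peak] = []
    cur_end = 0
    for p in plist:
        if excluded(p):
            continue
        if (
            current
            and p.chrom == current[0].chrom
            and p.start - cur_end <= gap
            and not zone_between(p.chrom, cur_end, p.start)
        ):
            current.append(p)
            cur_end = max(cur_end, p.end)
        else:
            if current:
                regions.append(_finish_region(current))
            current = [p]
            cur_end = p.end
    if current:
        regions.append(_finish_region(current))
    return regions


def _finish_region(constituents: list[Peak]) -> StitchedRegion:
    return StitchedRegion(
        chrom=constituents[0].chrom,
        start=min(p.start for p in constituents),
        end=max(p.end for p in constituents),
        constituents=list(constituents),
    )
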