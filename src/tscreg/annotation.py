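"""Gene models, refFlat I/O, feature classification and target assignment.

Gene models follow the UCSC refFlat dialect (0-based half-open transcript
and exon coordinates).  The transcription start site (TSS) is strand-aware:
``txStart`` on the + strand, ``txEnd - 1`` on the - strand.

Two peak->gene rules are provided, mirroring the two conventions used in
enhancer studies:

* :func:`classify_feature` — hierarchical one-class-per-peak labelling of
  the peak *center*: promoter (+/-2 kb of a TSS) > intron > exon >
  intergenic.
* :func:`assign_targets` — target-gene assignment: every gene with a TSS
  within +/-20 kb of the peak center, optionally extended with gene-body
  containment, and a nearest-TSS fallback so that no peak on a populated
  chromosome is left unassigned.
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .intervals import Peak, PeakSet

__all__ = [
    "GeneModel",
    "GeneAnnotation",
    "TargetAssignment",
    "RefFlatParseError",
    "FEATURE_CLASSES",
    "read_refflat",
    "write_refflat",
    "classify_feature",
    "assign_targets",
    "write_assignments",
]

logger = logging.getLogger(__name__)

FEATURE_CLASSES = ("promoter", "intron", "exon", "intergenic")


class RefFlatParseError(ValueError):
    """Raised for malformed refFlat rows; message carries the row number."""


@dataclass(frozen=True)
class GeneModel:
    """One transcript of a gene, refFlat-style."""

    name: str
    transcript_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.tx_start >= self.tx_end:
            raise ValueError("tx_start must be < tx_end")
        prev_end = self.tx_start
        for s, e in self.exons:
            if s < self.tx_start or e > self.tx_end or s >= e or s < prev_end:
                raise ValueError("exons must be sorted, non-overlapping and inside the transcript")
            prev_end = e

    @property
    def tss(self) -> int:
        """Strand-aware transcription start site (a single bp position)."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    def contains(self, pos: int) -> bool:
        return self.tx_start <= pos < self.tx_end

    def in_exon(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.exons)


class GeneAnnotation:
    """Collection of gene models with per-chromosome and per-symbol lookup."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes: list[GeneModel] = list(genes)
        self._by_chrom: dict[str, list[GeneModel]] = {}
        self._by_symbol: dict[str, list[GeneModel]] = {}
        for g in self.genes:
            self._by_chrom.setdefault(g.chrom, []).append(g)
            self._by_symbol.setdefault(g.name, []).append(g)
        # TSS index per chromosome for fast window / nearest queries
        self._tss_index: dict[str, tuple[list[int], list[GeneModel]]] = {}
        for chrom, glist in self._by_chrom.items():
            order = sorted(glist, key=lambda g: (g.tss, g.name, g.transcript_id))
            self._tss_index[chrom] = ([g.tss for g in order], order)

    def __len__(self) -> int:
        return len(self.genes)

    def chroms(self) -> list[str]:
        return sorted(self._by_chrom)

    def on_chrom(self, chrom: str) -> list[GeneModel]:
        return self._by_chrom.get(chrom, [])

    def transcripts_of(self, symbol: str) -> list[GeneModel]:
        return self._by_symbol.get(symbol, [])

    def symbols(self) -> set[str]:
        return set(self._by_symbol)

    def tss_in_window(self, chrom: str, lo: int, hi: int) -> list[GeneModel]:
        """All transcripts whose TSS lies in the closed window [lo, hi]."""
        if chrom not in self._tss_index:
            return []
        positions, order = self._tss_index[chrom]
        i = bisect_left(positions, lo)
        out = []
        while i < len(positions) and positions[i] <= hi:
            out.append(order[i])
            i += 1
        return out

    def tss_exclusion_zones(self, halfwidth: int = 2500) -> list[tuple[str, int, int]]:
        """+/-halfwidth zones around every TSS (merged per chromosome)."""
        zones: list[tuple[str, int, int]] = []
        for chrom, (positions, _) in sorted(self._tss_index.items()):
            merged: list[list[int]] = []
            for t in positions:
                lo, hi = max(0, t - halfwidth), t + halfwidth + 1
                if merged and lo <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], hi)
                else:
                    merged.append([lo, hi])
            zones.extend((chrom, lo, hi) for lo, hi in merged)
        return zones


def read_refflat(path: str | Path) -> GeneAnnotation:
    """Parse a UCSC refFlat table into a :class:`GeneAnnotation`.

    Expected columns: geneName, name, chrom, strand, txStart, txEnd,
    cdsStart, cdsEnd, exonCount, exonStarts, exonEnds.  Trailing commas in
    the exon lists are tolerated; an exonCount that disagrees with the list
    lengths raises :class:`RefFlatParseError` naming the row.
    """
    path = Path(path)
    genes: list[GeneModel] = []
    with open(path) as fh:
        for rowno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 11:
                raise RefFlatParseError(f"{path}:{rowno}: expected 11 columns, got {len(fields)}")
            try:
                tx_start, tx_end = int(fields[4]), int(fields[5])
                exon_count = int(fields[8])
                starts = [int(x) for x in fields[9].rstrip(",").split(",") if x]
                ends = [int(x) for x in fields[10].rstrip(",").split(",") if x]
            except ValueError as exc:
                raise RefFlatParseError(f"{path}:{rowno}: non-integer field") from exc
            if len(starts) != exon_count or len(ends) != exon_count:
                raise RefFlatParseError(
                    f"{path}:{rowno}: exonCount={exon_count} but "
                    f"{len(starts)} starts / {len(ends)} ends"
                )
            try:
                genes.append(
                    GeneModel(
                        name=fields[0],
                        transcript_id=fields[1],
                        chrom=fields[2],
                        strand=fields[3],
                        tx_start=tx_start,
                        tx_end=tx_end,
                        exons=tuple(zip(starts, ends)),
                    )
                )
            except ValueError as exc:
                raise RefFlatParseError(f"{path}:{rowno}: {exc}") from exc
    return GeneAnnotation(genes)


def write_refflat(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            starts = ",".join(str(s) for s, _ in g.exons) + ","
            ends = ",".join(str(e) for _, e in g.exons) + ","
            fh.write(
                f"{g.name}\t{g.transcript_id}\t{g.chrom}\t{g.strand}\t"
                f"{g.tx_start}\t{g.tx_end}\t{g.tx_start}\t{g.tx_end}\t"
                f"{len(g.exons)}\t{starts}\t{ends}\n"
            )


def classify_feature(
    peak: Peak, ann: GeneAnnotation, promoter_halfwidth: int = 2000
) -> str:
    """Assign the peak center exactly one genomic feature class.

    Hierarchy: promoter (center within +/-promoter_halfwidth of any TSS) >
    intron (inside a gene body but outside that transcript's exons) >
    exon > intergenic.  Using the center point guarantees a unique class.
    """
    c = peak.center
    if ann.tss_in_window(peak.chrom, c - promoter_halfwidth, c + promoter_halfwidth):
        return "promoter"
    in_exon = False
    for g in ann.on_chrom(peak.chrom):
        if g.contains(c):
            if g.in_exon(c):
                in_exon = True
            else:
                return "intron"
    return "exon" if in_exon else "intergenic"


@dataclass(frozen=True)
class TargetAssignment:
    """One peak -> gene link with its provenance."""

    peak: Peak
    gene: str
    distance_to_tss: int
    via: str  # tss_flank | gene_body | nearest_fallback


def _signed_distance(center: int, gene: GeneModel) -> int:
    """Strand-aware center-to-TSS distance: negative = upstream of the gene."""
    d = center - gene.tss
    return d if gene.strand == "+" else -d


def assign_targets(
    peaks: PeakSet | Sequence[Peak],
    ann: GeneAnnotation,
    flank: int = 20_000,
    include_gene_body: bool = True,
    nearest_fallback: bool = True,
) -> list[TargetAssignment]:
    """Assign each peak to its target gene(s).

    A peak is linked to every gene symbol with a transcript TSS within
    ``+/-flank`` of the peak center (``via="tss_flank"``), and — when
    ``include_gene_body`` — to genes whose body contains the center
    (``via="gene_body"``).  A peak with no such gene is assigned, when
    ``nearest_fallback`` is on, to the single gene minimizing
    ``|center - TSS|`` on that chromosome; ties break toward the smaller
    TSS coordinate, then the lexicographically smaller symbol.

    Assignments are deduplicated at symbol level (the transcript with the
    smallest |distance| wins); peaks on chromosomes without genes are
    skipped with a logged warning when fallback is requested.
    """
    out: list[TargetAssignment] = []
    for p in peaks:
        c = p.center
        best: dict[str, TargetAssignment] = {}
        for g in ann.tss_in_window(p.chrom, c - flank, c + flank):
            d = _signed_distance(c, g)
            prev = best.get(g.name)
            if prev is None or abs(d) < abs(prev.distance_to_tss):
                best[g.name] = TargetAssignment(p, g.name, d, "tss_flank")
        if include_gene_body:
            for g in ann.on_chrom(p.chrom):
                if g.name not in best and g.contains(c):
                    d = _signed_distance(c, g)
                    prev = best.get(g.name)
                    if prev is None or abs(d) < abs(prev.distance_to_tss):
                        best[g.name] = TargetAssignment(p, g.name, d, "gene_body")
        if not best and nearest_fallback:
            candidates = ann.on_chrom(p.chrom)
            if not candidates:
                logger.warning(
                    "no genes on %s: skipping fallback assignment for peak at %d",
                    p.chrom,
                    c,
                )
                continue
            g = min(candidates, key=lambda g: (abs(c - g.tss), g.tss, g.name))
            best[g.name] = TargetAssignment(p, g.name, _signed_distance(c, g), "nearest_fallback")
        out.extend(sorted(best.values(), key=lambda a: a.gene))
    return out


def write_assignments(assignments: Iterable[TargetAssignment], path: str | Path) -> None:
    """TSV export: peak coordinates, factor, gene, signed distance, rule."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tfactor\tgene\tdistance_to_tss\tvia\n")
        for a in assignments:
            fh.write(
                f"{a.peak.chrom}\t{a.peak.start}\t{a.peak.end}\t{a.peak.factor}\t"
                f"{a.gene}\t{a.distance_to_tss}\t{a.via}\n"
            )
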