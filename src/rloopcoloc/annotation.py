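"""TSS-associated CpG island promoter universe and peak-to-promoter association."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .intervals import (
    GenomicInterval,
    MINUS,
    PLUS,
    PeakSet,
    UNSTRANDED,
    intersect,
)

CGI_OVERLAP = "cgi_overlap"
UPSTREAM_WINDOW = "upstream_window"


@dataclass
class PromoterRecord:
    """A TSS (5' end of a gene) with strand and its associated CpG island."""

    gene_id: str
    chrom: str
    tss: int
    strand: str
    cgi: GenomicInterval
    gc_skewed: bool = False


@dataclass
class PromoterUniverse:
    records: list[PromoterRecord] = field(default_factory=list)
    max_distance: int = 0

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def gene_ids(self) -> list[str]:
        return [rec.gene_id for rec in self.records]

    def by_id(self, gene_id: str) -> PromoterRecord:
        for rec in self.records:
            if rec.gene_id == gene_id:
                return rec
        raise KeyError(gene_id)


def tss_of(gene: GenomicInterval) -> int:
    """0-based TSS position: start for + genes, end - 1 for - genes."""
    if gene.strand == PLUS:
        return gene.start
    if gene.strand == MINUS:
        return gene.end - 1
    raise ValueError(f"gene {gene.name or str(gene)} is unstranded")


def _tss_to_interval_distance(tss: int, iv: GenomicInterval) -> int:
    """0 when the TSS lies inside the half-open interval, else the gap in bp."""
    if iv.start <= tss < iv.end:
        return 0
    if tss < iv.start:
        return iv.start - tss
    return tss - (iv.end - 1)


def build_promoter_universe(
    genes: Sequence[GenomicInterval],
    cgis: Sequence[GenomicInterval],
    max_distance: int = 0,
) -> PromoterUniverse:
    """One PromoterRecord per gene whose TSS lies within *max_distance* of a
    CpG island (0 = TSS inside the island). The nearest island wins; ties go
    to the leftmost. Unstranded genes are rejected with a warning.
    """
    cgi_by_chrom: dict[str, list[GenomicInterval]] = {}
    for cgi in cgis:
        cgi_by_chrom.setdefault(cgi.chrom, []).append(cgi)
    for lst in cgi_by_chrom.values():
        lst.sort(key=GenomicInterval.sort_key)

    records: list[PromoterRecord] = []
    for i, gene in enumerate(genes):
        if gene.strand == UNSTRANDED:
            warnings.warn(
                f"gene {gene.name or str(gene)} has no strand; skipped", stacklevel=2
            )
            continue
        tss = tss_of(gene)
        best: tuple[int, int, int] | None = None  # (distance, start, end)
        best_cgi: GenomicInterval | None = None
        for cgi in cgi_by_chrom.get(gene.chrom, ()):
            d = _tss_to_interval_distance(tss, cgi)
            if d > max_distance:
                continue
            key = (d, cgi.start, cgi.end)
            if best is None or key < best:
                best, best_cgi = key, cgi
        if best_cgi is not None:
            records.append(
                PromoterRecord(
                    gene_id=gene.name or f"gene{i}",
                    chrom=gene.chrom,
                    tss=tss,
                    strand=gene.strand,
                    cgi=best_cgi,
                    gc_skewed=False,
                )
            )
    return PromoterUniverse(records=records, max_distance=max_distance)


def upstream_interval(rec: PromoterRecord, upstream: int) -> GenomicInterval | None:
    """The oriented window [tss - upstream, tss) in forward coordinates.

    For - strand promoters upstream is rightward: [tss + 1, tss + 1 + upstream).
    Returns None when the window is entirely off the chromosome start.
    """
    if rec.strand == PLUS:
        start, end = rec.tss - upstream, rec.tss
    else:
        start, end = rec.tss + 1, rec.tss + 1 + upstream
    start = max(0, start)
    if start >= end:
        return None
    return GenomicInterval(rec.chrom, start, end)


def associate_peaks_to_promoters(
    peaks: PeakSet | Sequence[GenomicInterval],
    universe: PromoterUniverse,
    mode: str = CGI_OVERLAP,
    upstream: int = 1000,
) -> dict[str, list[GenomicInterval]]:
    """Map gene_id -> peaks associated with that promoter.

    ``cgi_overlap``: a peak associates iff it shares >= 1 bp with the
    promoter's CpG island. ``upstream_window``: iff it intersects the
    oriented [tss - upstream, tss) window. Every promoter appears as a key;
    unassociated promoters map to an empty list.
    """
    if mode not in (CGI_OVERLAP, UPSTREAM_WINDOW):
        raise ValueError(f"unknown association mode {mode!r}")
    peak_list = list(peaks.intervals if isinstance(peaks, PeakSet) else peaks)

    targets: list[GenomicInterval] = []
    target_gene: dict[int, str] = {}
    for rec in universe.records:
        if mode == CGI_OVERLAP:
            iv = GenomicInterval(rec.chrom, rec.cgi.start, rec.cgi.end, name=rec.gene_id)
        else:
            win = upstream_interval(rec, upstream)
            if win is None:
                continue
            iv = GenomicInterval(rec.chrom, win.start, win.end, name=rec.gene_id)
        target_gene[id(iv)] = rec.gene_id
        targets.append(iv)

    assoc: dict[str, list[GenomicInterval]] = {rec.gene_id: [] for rec in universe.records}
    for target_iv, peak_iv, _ov in intersect(targets, peak_list):
        assoc[target_gene[id(target_iv)]].append(peak_iv)
    return assoc


def positive_ids(assoc: dict[str, list[GenomicInterval]]) -> set[str]:
    """Gene ids with at least one associated peak."""
    return {gid for gid, hits in assoc.items() if hits}


def write_universe(universe: PromoterUniverse, path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("gene_id\tchrom\ttss\tstrand\tcgi_start\tcgi_end\tgc_skewed\n")
        for rec in universe.records:
            fh.write(
                f"{rec.gene_id}\t{rec.chrom}\t{rec.tss}\t{rec.strand}\t"
                f"{rec.cgi.start}\t{rec.cgi.end}\t{int(rec.gc_skewed)}\n"
            )


def read_universe(path: str | Path) -> PromoterUniverse:
    records: list[PromoterRecord] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("gene_id"):
            raise ValueError(f"{path}: missing universe header")
        for line in fh:
            if not line.strip():
                continue
            gid, chrom, tss, strand, cs, ce, skewed = line.rstrip("\n").split("\t")
            records.append(
                PromoterRecord(
                    gene_id=gid,
                    chrom=chrom,
                    tss=int(tss),
                    strand=strand,
                    cgi=GenomicInterval(chrom, int(cs), int(ce)),
                    gc_skewed=bool(int(skewed)),
                )
            )
    return PromoterUniverse(records=records)
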