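"""Genomic interval data model, interval-set algebra and BED/FASTA I/O.

Coordinates are 0-based, half-open (BED convention) everywhere. Intervals
may be stranded (``+``/``-``) or unstranded (``.``); unstranded intervals
match either strand in stranded queries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO

PLUS = "+"
MINUS = "-"
UNSTRANDED = "."

_STRANDS = frozenset({PLUS, MINUS, UNSTRANDED})

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class BedFormatError(ValueError):
    """Raised when a BED file cannot be parsed; carries the offending line number."""


@dataclass
class GenomicInterval:
    """A half-open span ``[start, end)`` on a named sequence.

    ``score`` is an optional real number; throughout this package it carries
    peak fold-enrichment above input when present.
    """

    chrom: str
    start: int
    end: int
    strand: str = UNSTRANDED
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.start, int) or not isinstance(self.end, int):
            raise TypeError(f"coordinates must be integers: {self.start!r}, {self.end!r}")
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "requires 0 <= start < end"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Number of shared bases with *other* (0 if on different chroms)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "GenomicInterval", min_overlap: int = 1) -> bool:
        return self.overlap_bp(other) >= min_overlap

    def sort_key(self) -> tuple:
        return (self.chrom, self.start, self.end, self.name or "")

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}({self.strand})"


class Genome:
    """Ordered mapping of sequence names to upper-case nucleotide strings."""

    def __init__(self, sequences: dict[str, str] | Iterable[tuple[str, str]]):
        items = sequences.items() if isinstance(sequences, dict) else sequences
        self._seqs: dict[str, str] = {}
        for name, seq in items:
            if name in self._seqs:
                raise ValueError(f"duplicate sequence name {name!r}")
            seq = seq.upper()
            if len(seq) < 1:
                raise ValueError(f"empty sequence {name!r}")
            self._seqs[name] = seq

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    def __getitem__(self, name: str) -> str:
        return self._seqs[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._seqs)

    def __len__(self) -> int:
        return len(self._seqs)

    @property
    def names(self) -> list[str]:
        return list(self._seqs)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self._seqs.items()}

    @property
    def total_length(self) -> int:
        return sum(len(seq) for seq in self._seqs.values())

    def fetch(self, iv: GenomicInterval) -> str:
        return self._seqs[iv.chrom][iv.start:iv.end]

    def items(self) -> Iterable[tuple[str, str]]:
        return self._seqs.items()


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PeakSet:
    """A labelled collection of peak intervals (e.g. DRIP, ORC1, SNS)."""

    label: str
    intervals: list[GenomicInterval] = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def sorted(self) -> "PeakSet":
        return replace(self, intervals=sorted(self.intervals, key=GenomicInterval.sort_key))

    def normalized(self) -> "PeakSet":
        """Sorted, merged (book-ended intervals joined) copy of this set."""
        return replace(self, intervals=merge_intervals(self.intervals))


def read_bed(path: str | Path, label: str = "other") -> PeakSet:
    """Parse a BED3-BED6 file into a :class:`PeakSet`.

    Track/browser/comment lines are ignored. Malformed coordinates reject the
    whole file with the offending line number; an unknown strand symbol
    degrades to unstranded with a warning.
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedFormatError(f"{path}: line {lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedFormatError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if start < 0 or start >= end:
                raise BedFormatError(
                    f"{path}: line {lineno}: invalid coordinates start={start} end={end}"
                )
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score: float | None = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise BedFormatError(
                        f"{path}: line {lineno}: non-numeric score {fields[4]!r}"
                    ) from exc
            strand = UNSTRANDED
            if len(fields) > 5:
                if fields[5] in _STRANDS:
                    strand = fields[5]
                else:
                    warnings.warn(
                        f"{path}: line {lineno}: unknown strand {fields[5]!r}, "
                        "treating as unstranded",
                        stacklevel=2,
                    )
            intervals.append(
                GenomicInterval(chrom, start, end, strand=strand, name=name, score=score)
            )
    return PeakSet(label=label, intervals=intervals, provenance=str(path))


def _format_score(score: float) -> str:
    if float(score).is_integer():
        return str(int(score))
    return repr(float(score))


def write_bed(intervals: Iterable[GenomicInterval] | PeakSet, path: str | Path) -> None:
    """Write sorted BED with Unix line endings.

    Emits BED6 when any interval carries a name, score or strand, else BED3.
    """
    if isinstance(intervals, PeakSet):
        intervals = intervals.intervals
    ivs = sorted(intervals, key=GenomicInterval.sort_key)
    bed6 = any(
        iv.name is not None or iv.score is not None or iv.strand != UNSTRANDED
        for iv in ivs
    )
    with open(path, "w", newline="\n") as fh:
        for iv in ivs:
            if bed6:
                fh.write(
                    "\t".join(
                        (
                            iv.chrom,
                            str(iv.start),
                            str(iv.end),
                            iv.name if iv.name is not None else ".",
                            _format_score(iv.score) if iv.score is not None else ".",
                            iv.strand,
                        )
                    )
                    + "\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Sort and merge touching or overlapping intervals per chromosome.

    Book-ended intervals ([0,10) and [10,20)) merge under the half-open
    convention. Merged intervals drop name/score/strand.
    """
    out: list[GenomicInterval] = []
    for iv in sorted(intervals, key=GenomicInterval.sort_key):
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
            continue
        out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return out


def intersect(
    a: Sequence[GenomicInterval],
    b: Sequence[GenomicInterval],
    min_overlap: int = 1,
) -> list[tuple[GenomicInterval, GenomicInterval, int]]:
    """All pairs (a_interval, b_interval, overlap_bp) sharing >= min_overlap bases.

    Symmetric in content under a/b swap. Sorted sweep per chromosome; the
    pointer into *b* only advances past intervals that can no longer overlap
    any later *a* interval.
    """
    if min_overlap < 1:
        raise ValueError(f"min_overlap must be >= 1, got {min_overlap}")
    by_chrom_b: dict[str, list[GenomicInterval]] = {}
    for iv in b:
        by_chrom_b.setdefault(iv.chrom, []).append(iv)
    for lst in by_chrom_b.values():
        lst.sort(key=GenomicInterval.sort_key)

    pairs: list[tuple[GenomicInterval, GenomicInterval, int]] = []
    by_chrom_a: dict[str, list[GenomicInterval]] = {}
    for iv in a:
        by_chrom_a.setdefault(iv.chrom, []).append(iv)
    for chrom, a_list in by_chrom_a.items():
        b_list = by_chrom_b.get(chrom)
        if not b_list:
            continue
        a_list.sort(key=GenomicInterval.sort_key)
        lo = 0
        for iv_a in a_list:
            while lo < len(b_list) and b_list[lo].end <= iv_a.start:
                lo += 1
            j = lo
            while j < len(b_list) and b_list[j].start < iv_a.end:
                ov = min(iv_a.end, b_list[j].end) - max(iv_a.start, b_list[j].start)
                if ov >= min_overlap:
                    pairs.append((iv_a, b_list[j], ov))
                j += 1
    return pairs


def coverage_bp(intervals: Sequence[GenomicInterval]) -> int:
    """Total bases covered by the union of *intervals*."""
    return sum(iv.length for iv in merge_intervals(intervals))


def read_fasta(path: str | Path) -> Genome:
    """Read a FASTA file; names are the first whitespace token of each header."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return Genome((rec.id, str(rec.seq)) for rec in records)


def write_fasta(genome: Genome, path: str | Path, width: int = 60) -> None:
    with open(path, "w", newline="\n") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def filter_by_fold_enrichment(peaks: PeakSet, threshold: float = 5.0) -> PeakSet:
    """Keep peaks with fold-enrichment score strictly greater than *threshold*."""
    for iv in peaks.intervals:
        if iv.score is None:
            raise ValueError(
                f"peak {iv.name or str(iv)} has no fold-enrichment score"
            )
    kept = [iv for iv in peaks.intervals if iv.score > threshold]
    return replace(peaks, intervals=kept)
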