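"""TSS-centered, strand-oriented composite density profiles.

Per-base hit coverage is averaged over anchor windows (upstream always
leftward) and divided by the genome-wide hit density, so a uniformly
distributed hit set has expected profile value 1 everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .intervals import Genome, GenomicInterval, MINUS, PLUS, merge_intervals
from .signals import G4Motif

Anchor = tuple[str, int, str]  # (chrom, tss, strand)

BOTH = "both"
TEMPLATE = "template"
NONTEMPLATE = "nontemplate"


@dataclass
class CompositeProfile:
    """Normalized per-base density over offsets -halfwidth .. halfwidth-1."""

    halfwidth: int
    values: np.ndarray
    n_regions: int
    genome_density: float
    raw_counts: np.ndarray
    n_valid: np.ndarray

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.halfwidth, self.halfwidth)

    def argmax_offset(self) -> int:
        return int(self.offsets[int(np.argmax(self.values))])

    def smoothed(self, width: int) -> np.ndarray:
        """Centered moving average; width must be odd."""
        if width % 2 != 1 or width < 1:
            raise ValueError("smoothing width must be a positive odd integer")
        kernel = np.ones(width) / width
        return np.convolve(self.values, kernel, mode="same")


def _chrom_lengths(genome: Genome | Mapping[str, int]) -> dict[str, int]:
    if isinstance(genome, Genome):
        return genome.lengths
    return dict(genome)


def _coverage_map(
    hits: Sequence[GenomicInterval], lengths: Mapping[str, int]
) -> dict[str, np.ndarray]:
    cov = {chrom: np.zeros(n, dtype=np.uint8) for chrom, n in lengths.items()}
    for iv in merge_intervals(list(hits)):
        if iv.chrom not in cov:
            raise KeyError(f"hit on unknown chromosome {iv.chrom!r}")
        arr = cov[iv.chrom]
        arr[iv.start : min(iv.end, len(arr))] = 1
    return cov


def _accumulate(
    cov: Mapping[str, np.ndarray],
    anchors: Sequence[Anchor],
    halfwidth: int,
    counts: np.ndarray,
    n_valid: np.ndarray,
) -> None:
    offsets = np.arange(-halfwidth, halfwidth)
    for chrom, tss, strand in anchors:
        arr = cov[chrom]
        pos = tss + offsets if strand == PLUS else tss - offsets
        valid = (pos >= 0) & (pos < len(arr))
        counts[valid] += arr[pos[valid]]
        n_valid[valid] += 1


def _finalize(
    counts: np.ndarray,
    n_valid: np.ndarray,
    halfwidth: int,
    n_regions: int,
    covered: int,
    genome_length: int,
) -> CompositeProfile:
    density = covered / genome_length if genome_length > 0 else 0.0
    values = np.zeros_like(counts, dtype=float)
    ok = n_valid > 0
    if density > 0:
        values[ok] = counts[ok] / n_valid[ok] / density
    return CompositeProfile(
        halfwidth=halfwidth,
        values=values,
        n_regions=n_regions,
        genome_density=density,
        raw_counts=counts,
        n_valid=n_valid,
    )


def composite_profile(
    hits: Sequence[GenomicInterval],
    anchors: Sequence[Anchor],
    genome: Genome | Mapping[str, int],
    halfwidth: int = 3000,
) -> CompositeProfile:
    """Per-base hit density around oriented anchors, normalized by genome-wide
    hit density.

    Windows extending past a chromosome end are truncated: positions off the
    chromosome contribute to neither numerator nor the per-position anchor
    count used as denominator.
    """
    if not anchors:
        raise ValueError("anchors must be non-empty")
    if halfwidth < 1:
        raise ValueError("halfwidth must be >= 1")
    lengths = _chrom_lengths(genome)
    cov = _coverage_map(hits, lengths)
    counts = np.zeros(2 * halfwidth, dtype=np.int64)
    n_valid = np.zeros(2 * halfwidth, dtype=np.int64)
    _accumulate(cov, anchors, halfwidth, counts, n_valid)
    covered = int(sum(int(arr.sum()) for arr in cov.values()))
    return _finalize(
        counts, n_valid, halfwidth, len(anchors), covered, sum(lengths.values())
    )


def profile_g4(
    motifs: Sequence[G4Motif],
    anchors: Sequence[Anchor],
    genome: Genome | Mapping[str, int],
    halfwidth: int = 3000,
    strand_mode: str = BOTH,
) -> CompositeProfile:
    """Composite profile of G4 motif spans around oriented anchors.

    ``nontemplate`` keeps, per anchor, motifs whose strand equals the anchor
    gene's strand; ``template`` keeps the opposite ones; ``both`` keeps all.
    The normalizer uses the genome-wide coverage of the full motif set in
    every mode, so modes are comparable on one scale.
    """
    if strand_mode not in (BOTH, TEMPLATE, NONTEMPLATE):
        raise ValueError(f"unknown strand_mode {strand_mode!r}")
    if not anchors:
        raise ValueError("anchors must be non-empty")
    lengths = _chrom_lengths(genome)
    all_ivs = [m.interval for m in motifs]
    if strand_mode == BOTH:
        prof = composite_profile(all_ivs, anchors, lengths, halfwidth)
        return prof

    cov_plus = _coverage_map([m.interval for m in motifs if m.strand == PLUS], lengths)
    cov_minus = _coverage_map([m.interval for m in motifs if m.strand == MINUS], lengths)
    counts = np.zeros(2 * halfwidth, dtype=np.int64)
    n_valid = np.zeros(2 * halfwidth, dtype=np.int64)
    for chrom, tss, strand in anchors:
        if strand_mode == NONTEMPLATE:
            cov = cov_plus if strand == PLUS else cov_minus
        else:
            cov = cov_minus if strand == PLUS else cov_plus
        _accumulate(cov, [(chrom, tss, strand)], halfwidth, counts, n_valid)
    cov_all = _coverage_map(all_ivs, lengths)
    covered = int(sum(int(arr.sum()) for arr in cov_all.values()))
    return _finalize(
        counts, n_valid, halfwidth, len(anchors), covered, sum(lengths.values())
    )
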