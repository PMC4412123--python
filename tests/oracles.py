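"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: per-base boolean
masks for interval algebra, quadratic all-pairs scans for intersection and
association, and regular expressions for motif scanning.
"""

from __future__ import annotations

import re

import numpy as np

COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(COMP)[::-1]


def mask_coverage(intervals, chrom_lengths: dict[str, int]) -> dict[str, np.ndarray]:
    """Per-base boolean coverage mask of a set of intervals."""
    masks = {c: np.zeros(n, dtype=bool) for c, n in chrom_lengths.items()}
    for iv in intervals:
        masks[iv.chrom][iv.start : iv.end] = True
    return masks


def mask_covered_bases(intervals, chrom_lengths: dict[str, int]) -> int:
    return int(sum(m.sum() for m in mask_coverage(intervals, chrom_lengths).values()))


def quadratic_intersect(a, b, min_overlap: int = 1):
    """All-pairs O(n*m) overlap scan; returns a set of coordinate tuples."""
    pairs = set()
    for ia in a:
        for ib in b:
            if ia.chrom != ib.chrom:
                continue
            ov = min(ia.end, ib.end) - max(ia.start, ib.start)
            if ov >= min_overlap:
                pairs.add((ia.chrom, ia.start, ia.end, ib.start, ib.end, ov))
    return pairs


def _g4_regex(tract: str, n_tracts: int, loop_min: int, loop_max: int) -> str:
    return f"{tract}(?:[ACGTN]{{{loop_min},{loop_max}}}?{tract}){{{n_tracts - 1}}}"


def regex_g4_forward(
    seq: str,
    policy: str,
    tract: str = "GGG",
    n_tracts: int = 4,
    loop_min: int = 1,
    loop_max: int = 7,
) -> list[tuple[int, int]]:
    """Forward-strand motif spans via regular expressions.

    ``all``: one motif per feasible start position (lookahead scan);
    ``greedy_nonoverlapping``: plain finditer, which restarts after each
    match end.
    """
    pat = _g4_regex(tract, n_tracts, loop_min, loop_max)
    if policy == "all":
        return [
            (m.start(1), m.end(1))
            for m in re.finditer(f"(?=({pat}))", seq)
        ]
    return [(m.start(), m.end()) for m in re.finditer(pat, seq)]


def regex_g4_both_strands(seq: str, policy: str, **kw) -> set[tuple[int, int, str]]:
    """Motif spans on both strands; minus strand scanned on the reverse
    complement with spans reflected back."""
    n = len(seq)
    out = {(s, e, "+") for s, e in regex_g4_forward(seq, policy, **kw)}
    for s, e in regex_g4_forward(revcomp(seq), policy, **kw):
        out.add((n - e, n - s, "-"))
    return out


def naive_skew(seq: str, window: int, step: int) -> list[tuple[int, float | None]]:
    values = []
    for start in range(0, len(seq) - window + 1, step):
        w = seq[start : start + window]
        g, c = w.count("G"), w.count("C")
        values.append((start, None if g + c == 0 else (g - c) / (g + c)))
    return values


def window_hit_bases(hits, anchors, chrom_lengths: dict[str, int], halfwidth: int) -> int:
    """Total hit-covered bases inside all (truncated) anchor windows,
    counted per anchor via a direct mask scan."""
    masks = mask_coverage(hits, chrom_lengths)
    total = 0
    for chrom, tss, strand in anchors:
        mask = masks[chrom]
        lo = max(0, tss - halfwidth + (1 if strand == "-" else 0))
        hi = min(len(mask), tss + halfwidth + (1 if strand == "-" else 0))
        total += int(mask[lo:hi].sum())
    return total


def random_intervals(rng, n, chroms, chrom_len, max_len=2000, named=False):
    """Uniform random intervals for oracle comparisons."""
    from rloopcoloc.intervals import GenomicInterval

    out = []
    for i in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        length = int(rng.integers(1, max_len))
        start = int(rng.integers(0, chrom_len - length))
        out.append(
            GenomicInterval(
                chrom, start, start + length, name=f"iv{i}" if named else None
            )
        )
    return out
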