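"""G-quadruplex motif scanning and strand-aware GC-skew profiling.

The motif model is four tracts of ``GGG`` (``CCC`` on the opposite strand)
separated by loops of 1-7 nt. Tracts are matched as exactly-3 runs that may
sit inside longer runs; loops constrain length only, so any base (including
N) may appear in a loop, while N never matches inside a tract.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass

import numpy as np

from .intervals import GenomicInterval, MINUS, PLUS, reverse_complement

GREEDY = "greedy_nonoverlapping"
ALL = "all"


@dataclass
class G4Motif:
    """One detected quadruplex motif.

    ``interval`` spans the first base of the first tract to the last base of
    the last tract; ``tract_starts`` are ascending genomic positions on the
    forward strand.
    """

    interval: GenomicInterval
    strand: str
    tract_starts: tuple[int, ...]
    loop_lengths: tuple[int, ...]

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


def _tract_positions(seq: str, tract: str) -> list[int]:
    """Start positions of every (possibly overlapping) occurrence of *tract*."""
    positions = []
    i = seq.find(tract)
    while i != -1:
        positions.append(i)
        i = seq.find(tract, i + 1)
    return positions


def _chain_from(
    positions: list[int],
    idx: int,
    n_tracts: int,
    tract_len: int,
    loop_min: int,
    loop_max: int,
) -> list[int] | None:
    """Lexicographically smallest chain of *n_tracts* tract starts beginning at
    positions[idx], each loop length within [loop_min, loop_max]; None if no
    complete chain exists (depth-first with backtracking)."""
    chain = [positions[idx]]

    def extend(last: int) -> bool:
        if len(chain) == n_tracts:
            return True
        lo = last + tract_len + loop_min
        hi = last + tract_len + loop_max
        left = bisect_left(positions, lo)
        for k in range(left, len(positions)):
            p = positions[k]
            if p > hi:
                break
            chain.append(p)
            if extend(p):
                return True
            chain.pop()
        return False

    if extend(chain[0]):
        return chain
    return None


def _scan_forward(
    seq: str,
    tract: str,
    n_tracts: int,
    loop_min: int,
    loop_max: int,
    policy: str,
) -> list[tuple[int, ...]]:
    """Tract-start chains of motifs on the forward strand of *seq*.

    ``all`` reports one motif per feasible starting tract (the leftmost
    placement of the remaining tracts); ``greedy_nonoverlapping`` reports
    motifs left to right, each starting at or after the previous motif's end.
    """
    tract_len = len(tract)
    positions = _tract_positions(seq, tract)
    chains: list[tuple[int, ...]] = []
    cursor = -1  # end of the last reported motif (greedy policy)
    for idx, pos in enumerate(positions):
        if policy == GREEDY and pos < cursor:
            continue
        chain = _chain_from(positions, idx, n_tracts, tract_len, loop_min, loop_max)
        if chain is None:
            continue
        chains.append(tuple(chain))
        if policy == GREEDY:
            cursor = chain[-1] + tract_len
    return chains


def scan_g4(
    seq: str,
    chrom: str = "seq",
    tract: str = "GGG",
    n_tracts: int = 4,
    loop_min: int = 1,
    loop_max: int = 7,
    policy: str = GREEDY,
) -> list[G4Motif]:
    """Detect quadruplex motifs on both strands of *seq*.

    Plus-strand motifs come from the tract pattern on the given sequence;
    minus-strand motifs are found by scanning the reverse complement with the
    same pattern and mapping coordinates back, so strand symmetry is exact.
    """
    if loop_min < 1 or loop_max < loop_min:
        raise ValueError(f"invalid loop bounds [{loop_min}, {loop_max}]")
    if n_tracts < 2:
        raise ValueError("n_tracts must be >= 2")
    if policy not in (GREEDY, ALL):
        raise ValueError(f"unknown overlap policy {policy!r}")

    seq = seq.upper()
    tract = tract.upper()
    tract_len = len(tract)
    motifs: list[G4Motif] = []

    for chain in _scan_forward(seq, tract, n_tracts, loop_min, loop_max, policy):
        starts = tuple(chain)
        loops = tuple(
            starts[i + 1] - (starts[i] + tract_len) for i in range(n_tracts - 1)
        )
        motifs.append(
            G4Motif(
                interval=GenomicInterval(chrom, starts[0], starts[-1] + tract_len, strand=PLUS),
                strand=PLUS,
                tract_starts=starts,
                loop_lengths=loops,
            )
        )

    rc = reverse_complement(seq)
    n = len(seq)
    for chain in _scan_forward(rc, tract, n_tracts, loop_min, loop_max, policy):
        # map rc tract [p, p+len) back to forward [n-p-len, n-p)
        fwd_starts = tuple(sorted(n - p - tract_len for p in chain))
        loops = tuple(
            fwd_starts[i + 1] - (fwd_starts[i] + tract_len)
            for i in range(n_tracts - 1)
        )
        motifs.append(
            G4Motif(
                interval=GenomicInterval(
                    chrom, fwd_starts[0], fwd_starts[-1] + tract_len, strand=MINUS
                ),
                strand=MINUS,
                tract_starts=fwd_starts,
                loop_lengths=loops,
            )
        )

    motifs.sort(key=lambda m: (m.interval.start, m.interval.end, m.strand))
    return motifs


@dataclass
class SkewTrack:
    """Windowed GC skew along one sequence.

    ``values`` holds (window start, skew) with skew = (G - C)/(G + C) counted
    on the forward strand, or None where the window has no G or C.
    """

    chrom: str
    window: int
    step: int
    values: list[tuple[int, float | None]]


def gc_skew(seq: str, window: int, step: int, chrom: str = "seq") -> SkewTrack:
    """GC skew per window placement starting at 0, *step* apart.

    Windows extending past the sequence end are discarded; a window with no
    G or C yields a missing (None) value.
    """
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    seq = seq.upper()
    n = len(seq)
    values: list[tuple[int, float | None]] = []
    if window <= n:
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        is_g = np.concatenate(([0], np.cumsum(arr == ord("G"))))
        is_c = np.concatenate(([0], np.cumsum(arr == ord("C"))))
        for start in range(0, n - window + 1, step):
            g = int(is_g[start + window] - is_g[start])
            c = int(is_c[start + window] - is_c[start])
            if g + c == 0:
                values.append((start, None))
            else:
                values.append((start, (g - c) / (g + c)))
    return SkewTrack(chrom=chrom, window=window, step=step, values=values)


def call_skewed_regions(
    track: SkewTrack, threshold: float, min_run: int
) -> list[GenomicInterval]:
    """Maximal runs of >= min_run consecutive windows with skew >= threshold.

    Each run becomes one interval from the first window's start to the last
    window's end. Missing values break runs.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    regions: list[GenomicInterval] = []
    run: list[int] = []

    def flush() -> None:
        if len(run) >= min_run:
            regions.append(
                GenomicInterval(track.chrom, run[0], run[-1] + track.window)
            )
        run.clear()

    for start, value in track.values:
        if value is not None and value >= threshold:
            run.append(start)
        else:
            flush()
    flush()
    return regions
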