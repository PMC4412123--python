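"""CpG-island-origin set construction and co-localization statistics.

The chance baseline is made explicit and dual: a label permutation over the
promoter universe (primary) and a genomic interval-shuffling null
(sensitivity check), both reported with an add-one empirical p-value.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .annotation import (
    PromoterUniverse,
    associate_peaks_to_promoters,
    positive_ids,
)
from .intervals import Genome, GenomicInterval, PeakSet


@dataclass
class OriginSet:
    """Promoters positive for BOTH SNS and ORC1 association."""

    promoters: list  # list[PromoterRecord]
    n_universe: int
    n_sns: int
    n_orc1: int
    n_both: int

    @property
    def gene_ids(self) -> set[str]:
        return {rec.gene_id for rec in self.promoters}

    @property
    def counts(self) -> dict[str, int]:
        return {
            "n_universe": self.n_universe,
            "n_sns": self.n_sns,
            "n_orc1": self.n_orc1,
            "n_both": self.n_both,
        }


@dataclass
class ColocalizationResult:
    n_query: int
    n_hit: int
    observed_fraction: float
    null_fractions: list[float]
    expected_fraction: float
    empirical_p: float
    fold: float | None
    n_perm: int
    seed: int
    null_model: str = "label_permutation"

    def to_dict(self) -> dict:
        return {
            "null_model": self.null_model,
            "n_query": self.n_query,
            "n_hit": self.n_hit,
            "observed_fraction": self.observed_fraction,
            "expected_fraction": self.expected_fraction,
            "empirical_p": self.empirical_p,
            "fold": self.fold,
            "n_perm": self.n_perm,
            "seed": self.seed,
        }


def build_origin_set(
    universe: PromoterUniverse,
    sns: PeakSet,
    orc1: PeakSet,
    mode: str = "cgi_overlap",
    upstream: int = 1000,
) -> OriginSet:
    """Promoters associated with both an SNS peak and an ORC1 peak."""
    if len(universe) == 0:
        raise ValueError("empty promoter universe")
    sns_pos = positive_ids(associate_peaks_to_promoters(sns, universe, mode, upstream))
    orc1_pos = positive_ids(associate_peaks_to_promoters(orc1, universe, mode, upstream))
    both = sns_pos & orc1_pos
    promoters = [rec for rec in universe.records if rec.gene_id in both]
    return OriginSet(
        promoters=promoters,
        n_universe=len(universe),
        n_sns=len(sns_pos),
        n_orc1=len(orc1_pos),
        n_both=len(both),
    )


def overlap_with_rloops(
    query_ids: Iterable[str], target_ids: set[str]
) -> tuple[int, int, float]:
    """(n_query, n_hit, observed_fraction) of query promoters positive for the
    target (e.g. DRIP-positive islands that are also ORC1-positive)."""
    query = list(query_ids)
    if not query:
        raise ValueError("empty query promoter set")
    n_hit = sum(1 for gid in query if gid in target_ids)
    return len(query), n_hit, n_hit / len(query)


def _summarize(
    n_query: int,
    n_hit: int,
    null_hits: np.ndarray,
    n_perm: int,
    seed: int,
    null_model: str,
) -> ColocalizationResult:
    observed = n_hit / n_query
    null_fractions = null_hits / n_query
    expected = float(null_fractions.mean())
    empirical_p = float((1 + int((null_hits >= n_hit).sum())) / (n_perm + 1))
    fold = observed / expected if expected > 0 else None
    return ColocalizationResult(
        n_query=n_query,
        n_hit=n_hit,
        observed_fraction=observed,
        null_fractions=null_fractions.tolist(),
        expected_fraction=expected,
        empirical_p=empirical_p,
        fold=fold,
        n_perm=n_perm,
        seed=seed,
        null_model=null_model,
    )


def permutation_null(
    universe: PromoterUniverse,
    query_ids: Iterable[str],
    target_ids: set[str],
    n_perm: int = 1000,
    seed: int = 0,
) -> ColocalizationResult:
    """Label-permutation null: each permutation draws ``len(query)`` promoters
    uniformly without replacement from the universe and records the
    target-positive fraction. Deterministic given *seed*.
    """
    query = list(query_ids)
    if not query:
        raise ValueError("query_size must be >= 1")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    n_universe = len(universe)
    q = len(query)
    if q > n_universe:
        raise ValueError(f"query size {q} exceeds universe size {n_universe}")

    target_flags = np.array(
        [rec.gene_id in target_ids for rec in universe.records], dtype=bool
    )
    n_hit = sum(1 for gid in query if gid in target_ids)

    rng = np.random.default_rng(seed)
    null_hits = np.empty(n_perm, dtype=np.int64)
    # random-key argpartition = uniform draw without replacement, vectorized
    chunk = max(1, min(n_perm, int(2e7) // max(n_universe, 1)))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        keys = rng.random((m, n_universe))
        idx = np.argpartition(keys, q - 1, axis=1)[:, :q]
        null_hits[done : done + m] = target_flags[idx].sum(axis=1)
        done += m
    return _summarize(q, n_hit, null_hits, n_perm, seed, "label_permutation")


def _merge_starts_ends(excluded: Sequence[GenomicInterval], chrom: str):
    from .intervals import merge_intervals

    ivs = merge_intervals([iv for iv in excluded if iv.chrom == chrom])
    starts = [iv.start for iv in ivs]
    ends = [iv.end for iv in ivs]
    return starts, ends


def shuffle_intervals_null(
    peaks: PeakSet,
    genome: Genome,
    universe: PromoterUniverse,
    query_ids: Iterable[str],
    mode: str = "cgi_overlap",
    upstream: int = 1000,
    excluded: Sequence[GenomicInterval] = (),
    n_perm: int = 100,
    seed: int = 0,
    max_tries: int = 1000,
) -> ColocalizationResult:
    """Interval-shuffling null (bedtools-shuffle-like sensitivity check).

    Each permutation re-places every peak uniformly at a random position on
    its own chromosome, preserving lengths and rejecting placements that
    touch *excluded* regions, then recomputes the fraction of query promoters
    with an associated peak.
    """
    query = list(query_ids)
    if not query:
        raise ValueError("query_size must be >= 1")
    lengths = genome.lengths
    excl = {chrom: _merge_starts_ends(excluded, chrom) for chrom in lengths}

    observed_pos = positive_ids(
        associate_peaks_to_promoters(peaks, universe, mode, upstream)
    )
    n_hit = sum(1 for gid in query if gid in observed_pos)

    rng = np.random.default_rng(seed)

    def place(iv: GenomicInterval) -> GenomicInterval:
        chrom_len = lengths[iv.chrom]
        span = iv.length
        if span > chrom_len:
            raise ValueError(f"peak {iv} longer than chromosome")
        starts, ends = excl[iv.chrom]
        for _ in range(max_tries):
            s = int(rng.integers(0, chrom_len - span + 1))
            e = s + span
            # excluded is merged+sorted, so ends are sorted too: only the
            # rightmost interval starting before e can still reach past s
            j = bisect_right(starts, e - 1)
            if j > 0 and ends[j - 1] > s:
                continue
            return GenomicInterval(iv.chrom, s, e)
        raise RuntimeError(
            f"could not place {span} bp peak on {iv.chrom} after {max_tries} tries"
        )

    null_hits = np.empty(n_perm, dtype=np.int64)
    for p in range(n_perm):
        shuffled = [place(iv) for iv in peaks.intervals]
        pos = positive_ids(
            associate_peaks_to_promoters(shuffled, universe, mode, upstream)
        )
        null_hits[p] = sum(1 for gid in query if gid in pos)
    return _summarize(len(query), n_hit, null_hits, n_perm, seed, "interval_shuffling")
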