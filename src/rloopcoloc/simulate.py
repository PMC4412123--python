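"""Seeded toy-genome simulator with recorded ground truth.

Generates a background genome, TSS-associated CpG islands with an optional
G-biased skew footprint downstream of the TSS (on the non-template strand),
planted G4 motifs upstream of the TSS, and three peak sets (DRIP/ORC1/SNS)
whose promoter-level positivity follows configurable marginal and
conditional probabilities. All randomness flows from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import (
    Genome,
    GenomicInterval,
    MINUS,
    PLUS,
    PeakSet,
    reverse_complement,
    write_bed,
    write_fasta,
)
from .annotation import PromoterRecord, PromoterUniverse, write_universe

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

G4_PLANT_SEQ = "GGGAGGGAGGGAGGG"  # minimal canonical motif, loops of 1


@dataclass
class PeakSpec:
    """Geometry of generated peaks for one label."""

    length: tuple[int, int] = (200, 600)  # inclusive range, bp
    fold: tuple[float, float] = (6.0, 20.0)  # fold enrichment of true peaks
    n_decoys: int = 30  # random background peaks per genome
    decoy_fold: tuple[float, float] = (1.0, 8.0)


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chroms: int = 3
    chrom_length: int = 2_000_000
    n_genes: int = 300
    gene_length: tuple[int, int] = (2_000, 8_000)
    cgi_length: int = 1_000
    skew_footprint: int = 1_000
    p_skewed: float = 0.75
    # background base probabilities in A, C, G, T order
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    cgi_composition: tuple[float, float, float, float] = (0.15, 0.32, 0.32, 0.21)
    p_cpg_boost: float = 0.12  # probability of emitting a CG dinucleotide in a CGI
    # skew footprint composition on the non-template strand (A, C, G, T)
    skew_composition: tuple[float, float, float, float] = (0.21, 0.14, 0.35, 0.30)
    g4_upstream_rate: float = 2.0  # expected planted motifs per promoter
    g4_upstream_span: int = 1_000  # planted motifs land within this span upstream
    g4_background_rate: float = 0.0  # expected planted motifs per bp elsewhere
    peak_specs: dict[str, PeakSpec] = field(
        default_factory=lambda: {
            "DRIP": PeakSpec(),
            "ORC1": PeakSpec(),
            "SNS": PeakSpec(),
        }
    )
    # promoter-level positivity: DRIP marginal, ORC1 conditional on DRIP,
    # ORC1 baseline otherwise, SNS conditional on ORC1, SNS baseline otherwise
    coloc_probs: dict[str, float] = field(
        default_factory=lambda: {
            "drip": 0.30,
            "orc1_given_drip": 0.30,
            "orc1_baseline": 0.06,
            "sns_given_orc1": 0.80,
            "sns_baseline": 0.20,
        }
    )
    restriction_sites: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for probs in (self.base_composition, self.cgi_composition, self.skew_composition):
            if abs(sum(probs) - 1.0) > 1e-9 or any(p < 0 for p in probs):
                raise ValueError(f"invalid base probabilities {probs}")
        for key, p in self.coloc_probs.items():
            if not 0 <= p <= 1:
                raise ValueError(f"probability {key}={p} outside [0, 1]")
        if not 0 <= self.p_skewed <= 1:
            raise ValueError("p_skewed must be in [0, 1]")
        if self.cgi_length < 2 or self.skew_footprint < 1 or self.chrom_length < 1:
            raise ValueError("lengths must be positive")


@dataclass
class SimulatedGenome:
    genome: Genome
    genes: list[GenomicInterval]
    cgis: list[GenomicInterval]
    universe: PromoterUniverse
    g4_truth: list[GenomicInterval]


def _random_codes(rng: np.random.Generator, n: int, probs: Sequence[float]) -> np.ndarray:
    return rng.choice(4, size=n, p=np.asarray(probs, dtype=float))


def _cgi_codes(rng: np.random.Generator, n: int, cfg: SimulationConfig) -> np.ndarray:
    """CG-rich sequence with explicit CpG dinucleotide enrichment."""
    out = np.empty(n, dtype=np.int64)
    probs = np.asarray(cfg.cgi_composition, dtype=float)
    singles = rng.choice(4, size=n, p=probs)
    doublet = rng.random(n) < cfg.p_cpg_boost
    i = 0
    k = 0
    while i < n:
        if doublet[k] and i + 1 < n:
            out[i] = 1  # C
            out[i + 1] = 2  # G
            i += 2
        else:
            out[i] = singles[k]
            i += 1
        k += 1
    return out


def _place_genes(
    rng: np.random.Generator, cfg: SimulationConfig
) -> list[tuple[str, int, int, str]]:
    """Non-overlapping gene placements (chrom, start, end, strand), leaving a
    margin around each TSS for the island, footprint and upstream plantings."""
    margin = cfg.cgi_length + cfg.skew_footprint + cfg.g4_upstream_span
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    per_chrom = np.full(cfg.n_chroms, cfg.n_genes // cfg.n_chroms)
    per_chrom[: cfg.n_genes % cfg.n_chroms] += 1
    placements: list[tuple[str, int, int, str]] = []
    for chrom, count in zip(chroms, per_chrom):
        taken: list[tuple[int, int]] = []
        for _ in range(int(count)):
            placed = False
            for _try in range(2000):
                glen = int(rng.integers(cfg.gene_length[0], cfg.gene_length[1] + 1))
                lo = margin
                hi = cfg.chrom_length - glen - margin
                if hi <= lo:
                    break
                start = int(rng.integers(lo, hi))
                end = start + glen
                if all(
                    end + margin <= s or start - margin >= e for s, e in taken
                ):
                    taken.append((start, end))
                    strand = PLUS if rng.random() < 0.5 else MINUS
                    placements.append((chrom, start, end, strand))
                    placed = True
                    break
            if not placed:
                raise RuntimeError(
                    f"could not place {count} genes on {chrom}: genes too dense"
                )
    return placements


def simulate_genome(config: SimulationConfig) -> SimulatedGenome:
    """Generate a toy genome with CpG island promoters and planted G4 motifs."""
    rng = np.random.default_rng(config.seed)
    chrom_codes = {
        f"chr{i + 1}": _random_codes(rng, config.chrom_length, config.base_composition)
        for i in range(config.n_chroms)
    }

    placements = _place_genes(rng, config)
    genes: list[GenomicInterval] = []
    cgis: list[GenomicInterval] = []
    records: list[PromoterRecord] = []
    g4_truth: list[GenomicInterval] = []

    for i, (chrom, gstart, gend, strand) in enumerate(placements):
        gene_id = f"gene{i:04d}"
        genes.append(GenomicInterval(chrom, gstart, gend, strand=strand, name=gene_id))
        tss = gstart if strand == PLUS else gend - 1
        codes = chrom_codes[chrom]

        cgi_start = tss - config.cgi_length // 2
        cgi_end = cgi_start + config.cgi_length
        codes[cgi_start:cgi_end] = _cgi_codes(rng, config.cgi_length, config)
        cgis.append(GenomicInterval(chrom, cgi_start, cgi_end, name=f"cgi{i:04d}"))

        skewed = bool(rng.random() < config.p_skewed)
        if skewed:
            # oriented [tss, tss + footprint) with G excess on the
            # non-template strand; reverse-complemented for minus genes
            fp_codes = _random_codes(rng, config.skew_footprint, config.skew_composition)
            if strand == PLUS:
                codes[tss : tss + config.skew_footprint] = fp_codes
            else:
                codes[tss + 1 - config.skew_footprint : tss + 1] = (3 - fp_codes)[::-1]

        n_g4 = int(rng.poisson(config.g4_upstream_rate))
        span = config.g4_upstream_span
        mlen = len(G4_PLANT_SEQ)
        for _ in range(n_g4):
            u = int(rng.integers(mlen, span))  # oriented upstream offset of motif end
            if strand == PLUS:
                mstart = tss - u
                _write_seq(codes, mstart, G4_PLANT_SEQ)
            else:
                mstart = tss + u - mlen + 1
                _write_seq(codes, mstart, reverse_complement(G4_PLANT_SEQ))
            g4_truth.append(
                GenomicInterval(chrom, mstart, mstart + mlen, strand=strand, name="G4")
            )

        records.append(
            PromoterRecord(
                gene_id=gene_id,
                chrom=chrom,
                tss=tss,
                strand=strand,
                cgi=cgis[-1],
                gc_skewed=skewed,
            )
        )

    if config.g4_background_rate > 0:
        total = config.n_chroms * config.chrom_length
        n_bg = int(rng.poisson(config.g4_background_rate * total))
        mlen = len(G4_PLANT_SEQ)
        for _ in range(n_bg):
            chrom = f"chr{int(rng.integers(config.n_chroms)) + 1}"
            mstart = int(rng.integers(0, config.chrom_length - mlen))
            strand = PLUS if rng.random() < 0.5 else MINUS
            seq = G4_PLANT_SEQ if strand == PLUS else reverse_complement(G4_PLANT_SEQ)
            _write_seq(chrom_codes[chrom], mstart, seq)
            g4_truth.append(
                GenomicInterval(chrom, mstart, mstart + mlen, strand=strand, name="G4")
            )

    genome = Genome(
        (chrom, _BASES[codes].tobytes().decode("ascii"))
        for chrom, codes in chrom_codes.items()
    )
    return SimulatedGenome(
        genome=genome,
        genes=genes,
        cgis=cgis,
        universe=PromoterUniverse(records=records),
        g4_truth=g4_truth,
    )


def _write_seq(codes: np.ndarray, start: int, seq: str) -> None:
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    codes[start : start + len(seq)] = [idx[b] for b in seq]


def _site_positions(seq: str, sites: Sequence[str]) -> np.ndarray:
    """Sorted start positions of all occurrences of any recognition site."""
    positions: list[int] = []
    for site in sites:
        i = seq.find(site)
        while i != -1:
            positions.append(i)
            i = seq.find(site, i + 1)
    return np.array(sorted(positions), dtype=np.int64)


def _snap_to_sites(
    iv: GenomicInterval, positions: np.ndarray, site_len: int, chrom_len: int
) -> GenomicInterval:
    """Snap boundaries outward to the nearest flanking site occurrence, or to
    the chromosome ends when no site flanks the peak."""
    if len(positions) == 0:
        return GenomicInterval(iv.chrom, 0, chrom_len, strand=iv.strand,
                               name=iv.name, score=iv.score)
    j = int(np.searchsorted(positions, iv.start, side="right")) - 1
    start = int(positions[j]) if j >= 0 else 0
    ends = positions + site_len
    k = int(np.searchsorted(ends, iv.end, side="left"))
    end = int(ends[k]) if k < len(ends) else chrom_len
    return GenomicInterval(iv.chrom, start, max(end, start + 1), strand=iv.strand,
                           name=iv.name, score=iv.score)


def simulate_peaks(
    config: SimulationConfig,
    sim: SimulatedGenome,
    seed: int | None = None,
) -> tuple[dict[str, PeakSet], pd.DataFrame]:
    """Generate DRIP/ORC1/SNS peak sets plus a per-promoter truth table.

    Label positivity per promoter: DRIP ~ Bernoulli(drip); ORC1 conditional
    on the DRIP outcome; SNS conditional on the ORC1 outcome. Each positive
    label gets one peak overlapping both the island and the oriented upstream
    window, so truth is recoverable in either association mode. Decoy peaks
    are scattered uniformly. DRIP boundaries are optionally snapped outward
    to restriction-site occurrences.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    probs = config.coloc_probs
    records = sim.universe.records
    lengths = sim.genome.lengths

    rows = []
    peaks: dict[str, list[GenomicInterval]] = {"DRIP": [], "ORC1": [], "SNS": []}
    for rec in records:
        drip = rng.random() < probs["drip"]
        orc1 = rng.random() < (
            probs["orc1_given_drip"] if drip else probs["orc1_baseline"]
        )
        sns = rng.random() < (
            probs["sns_given_orc1"] if orc1 else probs["sns_baseline"]
        )
        rows.append(
            {"gene_id": rec.gene_id, "drip": int(drip), "orc1": int(orc1), "sns": int(sns)}
        )
        for label, positive in (("DRIP", drip), ("ORC1", orc1), ("SNS", sns)):
            if not positive:
                continue
            spec = config.peak_specs[label]
            length = int(rng.integers(spec.length[0], spec.length[1] + 1))
            length = min(length, config.skew_footprint)
            # oriented upstream offset keeping the peak inside the upstream
            # window AND overlapping the island by >= 1 bp
            u_max = max(1, min(config.skew_footprint - length,
                               config.cgi_length // 2 - 2))
            u = int(rng.integers(0, u_max))
            if rec.strand == PLUS:
                start, end = rec.tss - u - length, rec.tss - u
            else:
                start, end = rec.tss + u + 1, rec.tss + u + 1 + length
            score = float(rng.uniform(*spec.fold))
            peaks[label].append(
                GenomicInterval(rec.chrom, start, end,
                                name=f"{label}_{rec.gene_id}", score=score)
            )

    for label, spec in config.peak_specs.items():
        for d in range(spec.n_decoys):
            chrom = f"chr{int(rng.integers(config.n_chroms)) + 1}"
            length = int(rng.integers(spec.length[0], spec.length[1] + 1))
            start = int(rng.integers(0, lengths[chrom] - length))
            score = float(rng.uniform(*spec.decoy_fold))
            peaks[label].append(
                GenomicInterval(chrom, start, start + length,
                                name=f"{label}_decoy{d}", score=score)
            )

    if config.restriction_sites:
        site_len = len(config.restriction_sites[0])
        if any(len(s) != site_len for s in config.restriction_sites):
            raise ValueError("restriction sites must share one length")
        site_pos = {
            chrom: _site_positions(sim.genome[chrom], config.restriction_sites)
            for chrom in sim.genome
        }
        peaks["DRIP"] = [
            _snap_to_sites(iv, site_pos[iv.chrom], site_len, lengths[iv.chrom])
            for iv in peaks["DRIP"]
        ]

    truth = pd.DataFrame(rows)
    sets = {
        label: PeakSet(label=label, intervals=ivs, provenance="simulated")
        for label, ivs in peaks.items()
    }
    return sets, truth


def write_simulation(
    sim: SimulatedGenome,
    peaks: dict[str, PeakSet],
    truth: pd.DataFrame,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write FASTA, BED files, the promoter universe and truth tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["genome"] = out / "genome.fa"
    write_fasta(sim.genome, paths["genome"])
    paths["genes"] = out / "genes.bed"
    write_bed(sim.genes, paths["genes"])
    paths["cgis"] = out / "cgis.bed"
    write_bed(sim.cgis, paths["cgis"])
    paths["universe"] = out / "universe.tsv"
    write_universe(sim.universe, paths["universe"])
    paths["g4_truth"] = out / "g4_truth.bed"
    write_bed(sim.g4_truth, paths["g4_truth"])
    for label, ps in peaks.items():
        paths[label] = out / f"{label.lower()}_peaks.bed"
        write_bed(ps, paths[label])
    paths["truth"] = out / "promoter_truth.tsv"
    truth.to_csv(paths["truth"], sep="\t", index=False, lineterminator="\n")
    return paths
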