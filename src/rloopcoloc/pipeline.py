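"""End-to-end orchestration: simulate -> annotate -> coloc -> scan -> profile.

A single config dict drives the run; every parameter that affects output is
recorded in the report, and the timestamp is isolated to one field so
determinism is testable.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Any

import numpy as np

from . import __version__
from .annotation import (
    associate_peaks_to_promoters,
    positive_ids,
)
from .coloc import (
    build_origin_set,
    overlap_with_rloops,
    permutation_null,
    shuffle_intervals_null,
)
from .intervals import filter_by_fold_enrichment, write_bed
from .profiles import composite_profile, profile_g4
from .signals import scan_g4
from .simulate import PeakSpec, SimulationConfig, simulate_genome, simulate_peaks, write_simulation

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 1,
    "simulate": {},
    "annotate": {"max_distance": 0},
    "coloc": {"mode": "cgi_overlap", "upstream": 1000, "null": "permute", "n_perm": 1000},
    "g4": {"loop_min": 1, "loop_max": 7, "n_tracts": 4, "policy": "greedy_nonoverlapping"},
    "profile": {"halfwidth": 3000, "strand_mode": "both"},
    "drip_fold_threshold": None,
}


def _merge_config(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge_config(out[key], value)
        else:
            out[key] = value
    return out


def resolve_config(config: dict | None) -> dict:
    return _merge_config(DEFAULT_CONFIG, config or {})


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def make_simulation_config(params: dict, seed: int) -> SimulationConfig:
    params = dict(params)
    specs = params.pop("peak_specs", None)
    cfg = SimulationConfig(seed=seed, **params)
    if specs:
        for label, spec in specs.items():
            cfg.peak_specs[label] = PeakSpec(**spec)
    return cfg


def run_all(config: dict | None, out_dir: str | Path) -> dict:
    """Execute the full pipeline on a simulated dataset; return the RunReport."""
    cfg = resolve_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])

    # --- stage: simulate -------------------------------------------------
    sim_cfg = make_simulation_config(cfg["simulate"], seed)
    sim = simulate_genome(sim_cfg)
    peaks, truth = simulate_peaks(sim_cfg, sim)
    paths = write_simulation(sim, peaks, truth, out)

    # --- stage: peak filtering ------------------------------------------
    drip = peaks["DRIP"]
    if cfg["drip_fold_threshold"] is not None:
        drip = filter_by_fold_enrichment(drip, float(cfg["drip_fold_threshold"]))

    # --- stage: annotate -------------------------------------------------
    universe = sim.universe  # simulation already provides TSS-associated islands

    # --- stage: colocalization ------------------------------------------
    mode = cfg["coloc"]["mode"]
    upstream = int(cfg["coloc"]["upstream"])
    n_perm = int(cfg["coloc"]["n_perm"])
    origin = build_origin_set(universe, peaks["SNS"], peaks["ORC1"], mode, upstream)
    write_bed(
        [rec.cgi for rec in origin.promoters], out / "origin_set.bed"
    )

    drip_pos = positive_ids(
        associate_peaks_to_promoters(drip, universe, mode, upstream)
    )
    orc1_pos = positive_ids(
        associate_peaks_to_promoters(peaks["ORC1"], universe, mode, upstream)
    )
    coloc_results = []
    if drip_pos:
        n_query, n_hit, observed = overlap_with_rloops(sorted(drip_pos), orc1_pos)
        if cfg["coloc"]["null"] in ("permute", "both"):
            coloc_results.append(
                permutation_null(universe, sorted(drip_pos), orc1_pos, n_perm, seed)
            )
        if cfg["coloc"]["null"] in ("shuffle", "both"):
            coloc_results.append(
                shuffle_intervals_null(
                    peaks["ORC1"],
                    sim.genome,
                    universe,
                    sorted(drip_pos),
                    mode,
                    upstream,
                    n_perm=min(n_perm, 200),
                    seed=seed,
                )
            )

    # --- stage: G4 scan --------------------------------------------------
    g4cfg = cfg["g4"]
    motifs = []
    for chrom in sim.genome:
        motifs.extend(
            scan_g4(
                sim.genome[chrom],
                chrom=chrom,
                n_tracts=int(g4cfg["n_tracts"]),
                loop_min=int(g4cfg["loop_min"]),
                loop_max=int(g4cfg["loop_max"]),
                policy=g4cfg["policy"],
            )
        )
    write_bed(
        [m.interval for m in motifs], out / "g4_motifs.bed"
    )

    # --- stage: profiles -------------------------------------------------
    halfwidth = int(cfg["profile"]["halfwidth"])
    anchor_recs = origin.promoters if origin.promoters else universe.records
    anchors = [(rec.chrom, rec.tss, rec.strand) for rec in anchor_recs]
    profile_summaries = {}
    tracks = {
        "ORC1": composite_profile(
            list(peaks["ORC1"].intervals), anchors, sim.genome, halfwidth
        ),
        "DRIP": composite_profile(list(drip.intervals), anchors, sim.genome, halfwidth),
        "G4": profile_g4(
            motifs, anchors, sim.genome, halfwidth, cfg["profile"]["strand_mode"]
        ),
    }
    for label, prof in tracks.items():
        np.savetxt(
            out / f"profile_{label.lower()}.tsv",
            np.column_stack([prof.offsets, prof.values]),
            fmt=("%d", "%.6g"),
            delimiter="\t",
        )
        profile_summaries[label] = {
            "argmax_offset": prof.argmax_offset(),
            "max_value": float(prof.values.max()),
            "mean_value": float(prof.values.mean()),
            "n_regions": prof.n_regions,
            "genome_density": prof.genome_density,
        }

    report = {
        "version": __version__,
        "parameters": _jsonable(cfg),
        "seed": seed,
        "input_checksums": {name: _sha256(p) for name, p in sorted(paths.items())},
        "origin_set": origin.counts,
        "n_drip_positive": len(drip_pos),
        "colocalization": [r.to_dict() for r in coloc_results],
        "n_g4_motifs": len(motifs),
        "profiles": profile_summaries,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
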