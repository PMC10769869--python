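"""End-to-end orchestration: config, full analysis run, demo run.

``run_pipeline`` executes matrix normalization, compartment/CID
calling, loop analysis, permutation tests and track statistics from a
:class:`RunConfig`, returning a JSON-serializable report.  ``run_demo``
generates a seeded synthetic dataset first and then runs the same
pipeline, so a single command exercises every stage against planted
truth.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from . import __version__
from .contacts import (
    ContactMatrix,
    correlation_matrix,
    distance_normalize,
    ice_balance,
    scale_to_row_total,
)
from .domains import (
    aggregate_boundary_profile,
    call_cid_boundaries,
    call_heid,
    compartment_index,
    directional_preference,
    insulation,
    BinTrack,
)
from .genome import CircularGenome
from .loop_analysis import call_loop_clusters, detect_loops
from .resampling import count_genes_in_segments, empirical_test, permute_loops, permute_segments
from .synthetic import SimConfig, make_truth, simulate_contacts, simulate_expression
from .tracks_analysis import expression_domain_test, rpksp

__all__ = ["RunConfig", "run_pipeline", "run_demo"]


@dataclass
class RunConfig:
    """Pipeline settings; defaults are the published analysis parameters."""

    genome_length_bp: int = 1_669_694
    bin_size_bp: int = 3000
    shift_bp: int = 117
    origins_bp: tuple = (0, 780_000)
    scale_total: float = 1000.0
    ice_max_iter: int = 500
    ice_tol: float = 1e-9
    low_coverage_fraction: float = 0.02
    dp_range_bp: int = 60000
    insulation_window_bp: int = 60000
    cid_target_len: int = 30
    corr_smooth_bins: int = 5
    corr_min_separation_bins: int = 40
    loop_min_score: float = 0.3
    n_reps: int = 1000
    seed: int = 0
    schema_version: int = 1

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "origins_bp" in raw:
            raw["origins_bp"] = tuple(raw["origins_bp"])
        return cls(**raw)

    def genome(self) -> CircularGenome:
        return CircularGenome(
            self.genome_length_bp, self.bin_size_bp, self.shift_bp, self.origins_bp
        )


def _stage(report, name, fn):
    t0 = time.perf_counter()
    try:
        out = fn()
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    report["timings_s"][name] = round(time.perf_counter() - t0, 4)
    return out


def run_pipeline(
    config: RunConfig,
    raw_matrix: ContactMatrix,
    genes=None,
    spikeins=None,
    loops=None,
) -> dict:
    """Run the full analysis on a raw contact matrix (+ optional tables).

    Returns a report dict with parameters, seeds and all computed
    statistics; deterministic for a fixed config and inputs.
    """
    report: dict = {
        "version": __version__,
        "parameters": {**asdict(config), "origins_bp": list(config.origins_bp)},
        "timings_s": {},
    }
    rng_seed = config.seed

    balanced = _stage(report, "ice", lambda: ice_balance(
        raw_matrix, config.ice_max_iter, config.ice_tol, config.low_coverage_fraction
    ))
    scaled = _stage(report, "scale", lambda: scale_to_row_total(balanced, config.scale_total))
    oe = _stage(report, "obs_exp", lambda: distance_normalize(scaled))
    corr = _stage(report, "correlation", lambda: correlation_matrix(
        oe, config.corr_smooth_bins, config.corr_min_separation_bins
    ))

    expr_track = None
    if genes is not None and spikeins is not None:
        expr = rpksp(
            genes["count"], genes["length_bp"], spikeins["count"], spikeins["length_bp"],
            gene_ids=genes["id"],
        )
        B = raw_matrix.n_bins
        expr_track = np.zeros(B)
        counts = np.zeros(B)
        np.add.at(expr_track, genes["bin"].to_numpy(int), expr.table["rpksp"].to_numpy())
        np.add.at(counts, genes["bin"].to_numpy(int), 1.0)
        with np.errstate(invalid="ignore"):
            expr_track = np.where(counts > 0, expr_track / counts, 0.0)

    orientation = (
        BinTrack(expr_track, "coverage", raw_matrix.genome)
        if expr_track is not None
        else None
    )
    pc1 = _stage(report, "pc1", lambda: compartment_index(corr, orientation))
    heid = _stage(report, "heid", lambda: call_heid(pc1))
    dp = _stage(report, "dp", lambda: directional_preference(oe, config.dp_range_bp))
    cids, boundaries = _stage(report, "cids", lambda: call_cid_boundaries(dp))
    ins = _stage(report, "insulation", lambda: insulation(scaled, config.insulation_window_bp))

    report["compartments"] = {
        "heid_segments": [[int(s), int(e)] for s, e in heid.segments],
        "heid_bins": int(len(heid.member_bins())),
    }
    report["cids"] = {
        "n_domains": len(cids.segments),
        "boundaries": [int(b) for b in boundaries],
    }
    if boundaries:
        prof = aggregate_boundary_profile(ins, boundaries, flank_bins=10)
        report["cids"]["boundary_insulation_profile"] = [
            None if not np.isfinite(v) else float(v) for v in prof
        ]

    if loops is None:
        loops = _stage(report, "detect_loops", lambda: detect_loops(oe, config.loop_min_score))
    loops = loops.filter_score(config.loop_min_score)
    clusters = _stage(report, "loop_clusters", lambda: call_loop_clusters(loops))
    report["loops"] = {
        "n_loops": len(loops),
        "n_clusters": len(clusters),
        "n_clustered_loops": len(clusters.clustered_loops()),
    }

    # permutation tests against the circular null
    if len(loops) and config.n_reps:
        def sim_clusters(rng):
            return len(call_loop_clusters(permute_loops(loops, raw_matrix.genome, rng)).clustered_loops())

        res = _stage(report, "permtest_loop_clusters", lambda: empirical_test(
            len(clusters.clustered_loops()), sim_clusters,
            n_reps=config.n_reps, direction="ge", seed=rng_seed,
        ))
        report["loops"]["cluster_permutation"] = {
            "observed": res.observed,
            "expected": res.expected_mean,
            "empirical_p": res.empirical_p,
            "summary": res.summary(),
        }

    if genes is not None and heid.segments and config.n_reps:
        observed_inside, _, _ = count_genes_in_segments(genes, heid)

        def sim_genes(rng):
            perm = permute_segments(heid, raw_matrix.genome, rng)
            return count_genes_in_segments(genes, perm)[0]

        res = _stage(report, "permtest_genes_in_heid", lambda: empirical_test(
            observed_inside, sim_genes, n_reps=config.n_reps, direction="ge", seed=rng_seed + 1,
        ))
        report["compartments"]["gene_permutation"] = {
            "observed": res.observed,
            "expected": res.expected_mean,
            "empirical_p": res.empirical_p,
            "summary": res.summary(),
        }

    if genes is not None and spikeins is not None and heid.segments:
        test = _stage(report, "expression_domain_test", lambda: expression_domain_test(
            rpksp(genes["count"], genes["length_bp"], spikeins["count"],
                  spikeins["length_bp"], gene_ids=genes["id"]),
            genes, heid,
        ))
        report["expression"] = test
    return report


def run_demo(seed: int = 0, depth: float = 1_000_000, n_reps: int = 200) -> dict:
    """Synthetic end-to-end run: generate planted data, analyse, report.

    The report additionally records the planted truth and simple
    recovery metrics (compartment-label agreement, boundary recovery).
    """
    sim = SimConfig()
    truth = make_truth(sim, seed)
    raw = simulate_contacts(truth, depth, seed + 1)
    genes, spikeins = simulate_expression(truth, n_genes=1000, n_spikein=100, seed=seed + 2)

    config = RunConfig(
        genome_length_bp=sim.genome_length_bp,
        bin_size_bp=sim.bin_size_bp,
        shift_bp=0,
        origins_bp=sim.origins_bp,
        n_reps=n_reps,
        seed=seed,
    )
    report = run_pipeline(config, raw, genes=genes, spikeins=spikeins)

    heid_true = truth.heid_membership()
    heid_called = np.zeros_like(heid_true)
    for s, e in report["compartments"]["heid_segments"]:
        heid_called[np.arange(s, e) % heid_true.size] = True
    report["truth"] = truth.to_dict()
    report["recovery"] = {
        "compartment_agreement": float((heid_true == heid_called).mean()),
        "n_true_boundaries": len(truth.cid_boundaries),
        "n_called_boundaries": len(report["cids"]["boundaries"]),
        "boundaries_recovered_within_1": _recovered_within(
            truth.cid_boundaries, report["cids"]["boundaries"], heid_true.size, tol=1
        ),
    }
    return report


def _recovered_within(true_bounds, called_bounds, B, tol=1):
    hits = 0
    for t in true_bounds:
        if any(min(abs(c - t), B - abs(c - t)) <= tol for c in called_bounds):
            hits += 1
    return hits
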