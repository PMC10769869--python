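"""Synthetic circular-genome data with planted, recorded structure.

Every downstream stage of the pipeline is testable without external
data: the generator plants chromosomal interaction domains (CIDs), one
high-expression self-interacting compartment (HEID), punctate loops
preferentially anchored inside it, expression elevated for HEID genes,
a two-origin replication gradient and a GC-dependent sequencing bias —
and records all of it in a truth object.

The contact model is Poisson around a multiplicative expectation:

    lambda_ij = c * (1 + d_ij)^(-alpha)
                  * beta_CID^[i, j in the same CID]
                  * beta_HEID^[i and j both in the HEID]
                  * gamma^[(i, j) within one pixel of a planted loop]

with d_ij the circular bp distance between bin midpoints and c set so
the expected total count matches the requested depth.  Defaults mirror
the study system: a 1,669,694 bp circle binned at 3 kb (557 bins),
19 domains (mean length ~30 bins), and a high-expression compartment
covering ~20% of the circle as a few dispersed segments (the real
compartment is likewise a set of loci spread around the chromosome,
which is what produces its long-range plaid signature).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .contacts import ContactMatrix
from .domains import SegmentSet
from .genome import CircularGenome

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "make_truth",
    "simulate_contacts",
    "simulate_expression",
    "simulate_tracks",
]


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters; defaults are the study-scale conditions."""

    genome_length_bp: int = 1_669_694
    bin_size_bp: int = 3000
    shift_bp: int = 0
    origins_bp: tuple = (0, 780_000)
    n_cids: int = 19
    heid_fraction: float = 0.20
    n_heid_segments: int = 4
    n_loops: int = 20
    loop_heid_bias: float = 0.7  # probability a loop anchor falls in the HEID
    decay_exponent: float = 1.0
    cid_boost: float = 3.0
    compartment_boost: float = 2.0
    loop_boost: float = 5.0
    expression_effect: float = 8.0
    min_cid_bins: int = 8
    min_loop_separation_bins: int = 10


@dataclass
class SyntheticTruth:
    """Planted structure: what the generators put in, for recovery tests."""

    genome: CircularGenome
    cid_boundaries: list
    heid_segments: list  # (start_bin, end_bin), end may exceed B (wrap)
    loop_pixels: list  # (bin_i, bin_j)
    decay_exponent: float
    cid_boost: float
    compartment_boost: float
    loop_boost: float
    expression_effect: float
    seed: int

    def __post_init__(self):
        B = self.genome.n_bins
        bset = sorted(set(int(b) for b in self.cid_boundaries))
        if bset != list(self.cid_boundaries):
            raise ValueError("cid_boundaries must be sorted and unique")
        if bset and not (0 <= bset[0] and bset[-1] < B):
            raise ValueError("cid boundary outside bin range")
        for i, j in self.loop_pixels:
            if i == j:
                raise ValueError("loop pixel on the diagonal")
        # SegmentSet validates non-overlap on the circle
        SegmentSet(list(self.heid_segments), "HEID", self.genome)
        if self.decay_exponent <= 0:
            raise ValueError("decay exponent must be positive")

    @property
    def heid(self) -> SegmentSet:
        return SegmentSet(list(self.heid_segments), "HEID", self.genome)

    @property
    def cids(self) -> SegmentSet:
        B = self.genome.n_bins
        b = list(self.cid_boundaries)
        segs = []
        for k, s in enumerate(b):
            e = b[(k + 1) % len(b)]
            segs.append((s, e if e > s else e + B))
        return SegmentSet(segs, "CID", self.genome)

    def heid_membership(self) -> np.ndarray:
        return self.heid.membership()

    def cid_labels(self) -> np.ndarray:
        """Per-bin CID index (0..n_cids-1)."""
        B = self.genome.n_bins
        lab = np.zeros(B, dtype=int)
        for k, (s, e) in enumerate(self.cids.segments):
            lab[np.arange(s, e) % B] = k
        return lab

    def to_dict(self) -> dict:
        return {
            "genome": {
                "length_bp": self.genome.length_bp,
                "bin_size_bp": self.genome.bin_size_bp,
                "shift_bp": self.genome.shift_bp,
                "origins_bp": list(self.genome.origins_bp),
            },
            "cid_boundaries": [int(b) for b in self.cid_boundaries],
            "heid_segments": [[int(s), int(e)] for s, e in self.heid_segments],
            "loop_pixels": [[int(i), int(j)] for i, j in self.loop_pixels],
            "decay_exponent": self.decay_exponent,
            "cid_boost": self.cid_boost,
            "compartment_boost": self.compartment_boost,
            "loop_boost": self.loop_boost,
            "expression_effect": self.expression_effect,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticTruth":
        g = d["genome"]
        genome = CircularGenome(
            g["length_bp"], g["bin_size_bp"], g["shift_bp"], tuple(g["origins_bp"])
        )
        return cls(
            genome=genome,
            cid_boundaries=[int(b) for b in d["cid_boundaries"]],
            heid_segments=[tuple(s) for s in d["heid_segments"]],
            loop_pixels=[tuple(p) for p in d["loop_pixels"]],
            decay_exponent=d["decay_exponent"],
            cid_boost=d["cid_boost"],
            compartment_boost=d["compartment_boost"],
            loop_boost=d["loop_boost"],
            expression_effect=d["expression_effect"],
            seed=d["seed"],
        )


def make_truth(config: SimConfig, seed: int) -> SyntheticTruth:
    """Draw planted boundaries, compartment segments and loop pixels."""
    genome = CircularGenome(
        config.genome_length_bp, config.bin_size_bp, config.shift_bp, config.origins_bp
    )
    B = genome.n_bins
    if genome.length_bp < 10 * genome.bin_size_bp:
        raise ValueError("genome must span at least 10 bins")
    if config.n_cids < 1:
        raise ValueError("need at least one domain")
    if config.n_cids > B:
        raise ValueError(f"requested {config.n_cids} domains but only {B} bins exist")
    rng = np.random.default_rng(seed)

    # boundaries: random gaps with a minimum domain length
    n = config.n_cids
    gmin = min(config.min_cid_bins, B // n)
    slack = B - n * gmin
    parts = rng.dirichlet(np.ones(n)) * slack
    lengths = gmin + np.floor(parts).astype(int)
    lengths[: B - lengths.sum()] += 1  # distribute rounding remainder
    offset = int(rng.integers(0, B))
    boundaries = sorted((offset + np.concatenate([[0], np.cumsum(lengths[:-1])])) % B)

    # HEID: contiguous segment(s) totalling heid_fraction of the circle
    heid_bins_total = max(2, round(config.heid_fraction * B))
    n_segs = max(1, min(config.n_heid_segments, heid_bins_total // 2))
    seg_len = heid_bins_total // n_segs
    heid = []
    taken = np.zeros(B, dtype=bool)
    attempts = 0
    while len(heid) < n_segs:
        attempts += 1
        if attempts > 10_000:
            raise RuntimeError("could not place HEID segments without overlap")
        s = int(rng.integers(0, B))
        bins = np.arange(s, s + seg_len) % B
        if taken[bins].any():
            continue
        taken[bins] = True
        heid.append((s, s + seg_len))

    # loops: anchors drawn with a bias toward HEID bins
    heid_bins = np.flatnonzero(taken)
    roc_bins = np.flatnonzero(~taken)
    loops = []
    guard = 0
    while len(loops) < config.n_loops:
        guard += 1
        if guard > 100_000:
            raise RuntimeError("could not place requested loops")

        def draw_anchor():
            if heid_bins.size and rng.random() < config.loop_heid_bias:
                return int(rng.choice(heid_bins))
            return int(rng.choice(roc_bins if roc_bins.size else heid_bins))

        i, j = draw_anchor(), draw_anchor()
        sep = min((j - i) % B, (i - j) % B)
        if sep < config.min_loop_separation_bins:
            continue
        i, j = min(i, j), max(i, j)
        if (i, j) in loops:
            continue
        loops.append((i, j))

    return SyntheticTruth(
        genome=genome,
        cid_boundaries=list(boundaries),
        heid_segments=heid,
        loop_pixels=loops,
        decay_exponent=config.decay_exponent,
        cid_boost=config.cid_boost,
        compartment_boost=config.compartment_boost,
        loop_boost=config.loop_boost,
        expression_effect=config.expression_effect,
        seed=seed,
    )


def expected_contact_matrix(truth: SyntheticTruth, depth: float) -> np.ndarray:
    """The analytic expectation lambda_ij (diagonal zero)."""
    if truth.decay_exponent <= 0:
        raise ValueError("decay exponent must be positive")
    if depth <= 0:
        raise ValueError("depth must be positive")
    g = truth.genome
    B = g.n_bins
    d = g.bin_distance_matrix_bp()
    lam = (1.0 + d) ** (-truth.decay_exponent)

    cid = truth.cid_labels()
    lam *= np.where(cid[:, None] == cid[None, :], truth.cid_boost, 1.0)
    heid = truth.heid_membership()
    lam *= np.where(heid[:, None] & heid[None, :], truth.compartment_boost, 1.0)

    loop_mask = np.zeros((B, B), dtype=bool)
    offs = np.arange(-1, 2)
    for i, j in truth.loop_pixels:
        loop_mask[np.ix_((i + offs) % B, (j + offs) % B)] = True
    loop_mask |= loop_mask.T
    lam *= np.where(loop_mask, truth.loop_boost, 1.0)

    np.fill_diagonal(lam, 0.0)
    upper = np.triu(lam)
    lam *= depth / upper.sum()
    return lam


def simulate_contacts(truth: SyntheticTruth, depth: float, seed: int) -> ContactMatrix:
    """Poisson contact counts around the planted expectation.

    ``depth`` is the expected total number of informative (inter-bin)
    pairs; each unordered bin pair is drawn once and mirrored so the
    matrix is exactly symmetric with a null diagonal.
    """
    lam = expected_contact_matrix(truth, depth)
    rng = np.random.default_rng(seed)
    B = lam.shape[0]
    iu = np.triu_indices(B, k=1)
    counts = rng.poisson(lam[iu]).astype(float)
    m = np.zeros((B, B))
    m[iu] = counts
    m = m + m.T
    return ContactMatrix(m, np.ones(B, dtype=bool), "raw", truth.genome)


def simulate_expression(
    truth: SyntheticTruth,
    n_genes: int = 1000,
    n_spikein: int = 100,
    seed: int = 0,
    base_mean: float = 50.0,
    log_sd: float = 1.0,
):
    """Tile genes on the circle and draw spike-in-calibrated counts.

    Genes are non-overlapping tiles with log-normal lengths clipped to
    [200, 6000] bp; counts are Poisson around a log-normal mean, with
    the mean multiplied by ``truth.expression_effect`` for genes fully
    inside a HEID segment.  Spike-in genes are drawn independently of
    the planted structure.

    Returns ``(genes, spikeins)`` DataFrames; ``spikeins`` carries an
    ``empty`` attribute flag when ``n_spikein`` is 0.
    """
    if n_genes < 2:
        raise ValueError("need at least two genes")
    rng = np.random.default_rng(seed)
    g = truth.genome
    L = g.length_bp

    lengths = np.clip(
        rng.lognormal(mean=math.log(900.0), sigma=0.6, size=n_genes), 200, 6000
    ).astype(int)
    gap = max(0, (L - int(lengths.sum())) // n_genes)
    if lengths.sum() + 0 > L:
        raise ValueError("genes do not fit on the genome")
    starts = np.zeros(n_genes, dtype=int)
    pos = int(rng.integers(0, L))
    for k in range(n_genes):
        starts[k] = pos % L
        pos += lengths[k] + gap
    ends = starts + lengths  # circular: end may exceed L
    strand = rng.choice(["+", "-"], size=n_genes)

    heid_bp = truth.heid.to_bp()

    def fully_inside(s, e):
        from .resampling import _circ_contains

        return any(_circ_contains(ss % L, se - ss, s % L, e - s, L) for ss, se in heid_bp)

    inside = np.array([fully_inside(s, e) for s, e in zip(starts, ends)])
    mean = base_mean * np.where(inside, truth.expression_effect, 1.0)
    mean = mean * (lengths / 1000.0)
    lam = rng.lognormal(mean=np.log(mean) - log_sd**2 / 2, sigma=log_sd)
    counts = rng.poisson(lam).astype(int)
    genes = pd.DataFrame(
        {
            "id": [f"gene_{k:04d}" for k in range(n_genes)],
            "start": starts,
            "end": ends,
            "strand": strand,
            "length_bp": lengths,
            "count": counts,
            "in_heid": inside,
            "product": ["synthetic protein"] * n_genes,
        }
    )
    genes["bin"] = (((starts + ends) // 2) % L) // g.bin_size_bp

    sp_lengths = np.clip(
        rng.lognormal(mean=math.log(900.0), sigma=0.6, size=n_spikein), 200, 6000
    ).astype(int)
    sp_lam = rng.lognormal(
        mean=np.log(np.maximum(base_mean * sp_lengths / 1000.0, 1e-9)) - log_sd**2 / 2,
        sigma=log_sd,
        size=n_spikein,
    )
    spikeins = pd.DataFrame(
        {
            "id": [f"spike_{k:04d}" for k in range(n_spikein)],
            "length_bp": sp_lengths,
            "count": rng.poisson(sp_lam).astype(int) if n_spikein else [],
        }
    )
    spikeins.attrs["empty"] = n_spikein == 0
    return genes, spikeins


@dataclass(frozen=True)
class TrackParams:
    """Knobs for the MFA / ChIP simulators."""

    mfa_bin_bp: int = 1000
    mfa_base: float = 5000.0  # ~10M reads over a 1.7 Mbp circle at 1 kb bins
    mfa_gradient: float = 0.5  # relative coverage drop at maximal origin distance
    gc_slope: float = 1.0  # relative effect of (GC - mean GC) on coverage
    chip_window_bp: int = 500
    chip_base: float = 500.0
    chip_k: float = 0.5  # coupling of ChIP signal to standardized log expression


def simulate_tracks(
    truth: SyntheticTruth,
    origins_bp=None,
    gc_track=None,
    params: TrackParams = TrackParams(),
    seed: int = 0,
) -> dict:
    """Simulate MFA coverage (1 kb bins) and ChIP/input counts (500 bp windows).

    MFA expectation decreases linearly with circular distance to the
    nearest origin (replication gradient), then picks up a GC-linked
    multiplicative bias ``1 + gc_slope * (GC - mean GC)``.  The ChIP
    expectation is ``chip_base * (1 + chip_k * z)`` with ``z`` a
    standardized log-expression track elevated inside the HEID; the
    matched input is flat.  All counts are Poisson.
    """
    g = truth.genome
    L = g.length_bp
    origins = list(origins_bp) if origins_bp is not None else list(g.origins_bp)
    if not origins:
        raise ValueError("need at least one replication origin")
    rng = np.random.default_rng(seed)

    n_mfa = math.ceil(L / params.mfa_bin_bp)
    mid = np.minimum((np.arange(n_mfa) + 0.5) * params.mfa_bin_bp, L)
    dist = np.min(
        g.circular_distance_bp(mid[:, None], np.asarray(origins, float)[None, :]), axis=1
    )
    if gc_track is None:
        gc = np.clip(0.5 + 0.08 * rng.standard_normal(n_mfa), 0.0, 1.0)
    else:
        gc = np.asarray(gc_track, dtype=float)
        if gc.shape != (n_mfa,):
            raise ValueError("gc_track length must match the 1 kb bin grid")
        if np.any((gc < 0) | (gc > 1)):
            raise ValueError("GC fractions must lie in [0, 1]")
    lin = params.mfa_base * (1.0 - params.mfa_gradient * dist / (L / 2.0))
    lam_mfa = np.maximum(lin * (1.0 + params.gc_slope * (gc - gc.mean())), 1e-9)
    mfa = pd.DataFrame(
        {
            "start": np.arange(n_mfa) * params.mfa_bin_bp,
            "gc": gc,
            "count": rng.poisson(lam_mfa),
        }
    )

    n_chip = math.ceil(L / params.chip_window_bp)
    wmid = np.minimum((np.arange(n_chip) + 0.5) * params.chip_window_bp, L)
    heid_bp = truth.heid.to_bp()
    in_heid = np.zeros(n_chip, dtype=bool)
    for ss, se in heid_bp:
        in_heid |= ((wmid - ss) % L) < (se - ss)
    log_expr = np.where(in_heid, np.log(truth.expression_effect), 0.0)
    log_expr = log_expr + 0.5 * rng.standard_normal(n_chip)
    z = (log_expr - log_expr.mean()) / log_expr.std()
    lam_chip = np.maximum(params.chip_base * (1.0 + params.chip_k * z), 1e-9)
    chip = pd.DataFrame(
        {
            "start": np.arange(n_chip) * params.chip_window_bp,
            "chip": rng.poisson(lam_chip),
            "input": rng.poisson(np.full(n_chip, params.chip_base)),
        }
    )
    return {
        "mfa": mfa,
        "chip": chip,
        "params": params,
        "latent_z": z,
        "origins_bp": origins,
    }
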