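"""Circular permutation tests and empirical p-values.

Enrichment questions on a circular chromosome (are ribosomal genes
over-represented in the HEID? are loops more clustered than chance?) are
answered by shuffling the feature of interest around the circle while
preserving its size structure: segment shuffles keep the number and
length of segments, loop shuffles keep the number of loops and each
loop's anchor separation.  The permutation is repeated ``n_reps`` times
(default 1,000); the expected value is the mean over repeats and the
empirical p-value is the fraction of repeats at least as extreme as the
observation in the stated direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import CircularGenome
from .domains import SegmentSet
from .loop_analysis import LoopSet

__all__ = [
    "PermutationResult",
    "permute_segments",
    "permute_loops",
    "empirical_test",
    "gene_segment_status",
    "count_genes_in_segments",
]

@dataclass
class PermutationResult:
    observed: float
    expected_mean: float
    simulated: np.ndarray
    empirical_p: float
    direction: str
    n_reps: int
    seed: int | None

    def summary(self) -> str:
        if self.empirical_p == 0.0:
            ptxt = f"P < {1.0 / self.n_reps:g}"
        else:
            ptxt = f"P = {self.empirical_p:g}"
        return (
            f"observed = {self.observed:g}, expected = {self.expected_mean:g} "
            f"({self.n_reps} permutations, direction {self.direction}): {ptxt}"
        )


def permute_segments(segments: SegmentSet, genome: CircularGenome, rng) -> SegmentSet:
    """Place the segments uniformly at random on the circle, no overlap.

    The multiset of segment lengths is preserved exactly; every valid
    non-overlapping arrangement is equally likely (so the start of a
    single segment is uniform over all bins).
    """
    B = genome.n_bins
    lengths = segments.lengths()
    if sum(lengths) >= B:
        raise ValueError("segments cover the whole circle; cannot permute")
    if not lengths:
        return SegmentSet([], segments.label, genome)
    L = np.asarray(lengths)
    n = L.size
    free = B - int(L.sum())
    # uniform over valid arrangements: random length order, a uniformly
    # random composition of the free space into n gaps (stars and bars),
    # and a uniformly random rotation of the whole configuration
    order = rng.permutation(n)
    if n > 1:
        cuts = np.sort(rng.choice(free + n - 1, size=n - 1, replace=False))
        gaps = np.diff(np.concatenate([[-1], cuts, [free + n - 1]])) - 1
    else:
        gaps = np.array([free])
    offset = int(rng.integers(0, B))
    starts = np.empty(n, dtype=int)
    pos = offset
    for k in range(n):
        starts[k] = pos % B
        pos += int(L[order][k]) + int(gaps[k])
    placed = [(int(s), int(s) + int(l)) for s, l in zip(starts, L[order])]
    return SegmentSet(placed, segments.label, genome)


def permute_loops(loops: LoopSet, genome: CircularGenome, rng) -> LoopSet:
    """Reposition every loop uniformly, preserving its anchor separation."""
    B = genome.n_bins
    n = len(loops)
    if n == 0:
        return LoopSet(np.array([], int), np.array([], int), np.array([], float), genome)
    sep = loops.separation
    a1 = rng.integers(0, B, size=n)
    a2 = (a1 + sep) % B
    return LoopSet(a1, a2, loops.score.copy(), genome)


def empirical_test(
    observed: float,
    simulate,
    n_reps: int = 1000,
    direction: str = "ge",
    seed: int | None = None,
    rng=None,
) -> PermutationResult:
    """Empirical p-value of ``observed`` against ``simulate(rng)`` draws.

    ``empirical_p`` is the fraction of the ``n_reps`` simulated values at
    least as extreme as the observation (``>=`` for direction 'ge',
    ``<=`` for 'le'), so its granularity is exactly 1/n_reps; a value of
    0 is reported as ``< 1/n_reps`` in the text summary.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if direction not in ("ge", "le"):
        raise ValueError("direction must be 'ge' or 'le'")
    if rng is None:
        rng = np.random.default_rng(seed)
    sims = np.empty(n_reps)
    for k in range(n_reps):
        try:
            sims[k] = simulate(rng)
        except Exception as exc:  # noqa: BLE001 - annotate with rep index
            raise RuntimeError(f"simulate failed at repetition {k}") from exc
    if direction == "ge":
        hits = int(np.sum(sims >= observed))
    else:
        hits = int(np.sum(sims <= observed))
    return PermutationResult(
        observed=float(observed),
        expected_mean=float(sims.mean()),
        simulated=sims,
        empirical_p=hits / n_reps,
        direction=direction,
        n_reps=n_reps,
        seed=seed,
    )


def _circ_overlap(astart, alen, bstart, blen, L):
    """Do circular bp intervals (astart, len) and (bstart, len) overlap?"""
    return ((bstart - astart) % L) < alen or ((astart - bstart) % L) < blen


def _circ_contains(seg_start, seg_len, g_start, g_len, L):
    return ((g_start - seg_start) % L) + g_len <= seg_len


def gene_segment_status(genes, segments: SegmentSet) -> np.ndarray:
    """Classify each gene as 'inside' / 'outside' / 'both' w.r.t. segments.

    ``genes`` is a table with 0-based half-open circular ``start``/``end``
    columns (end may exceed the genome length for wrapping genes).  A
    gene is *inside* if fully contained in one segment, *outside* if it
    overlaps no segment, and *both* otherwise (circular arithmetic
    throughout).
    """
    L = segments.genome.length_bp
    gs = genes["start"].to_numpy(dtype=np.int64) % L
    glen = genes["end"].to_numpy(dtype=np.int64) - genes["start"].to_numpy(dtype=np.int64)
    if np.any((glen <= 0) | (glen > L)):
        raise ValueError("gene with non-positive or over-long length")
    contained = np.zeros(gs.size, dtype=bool)
    overlaps = np.zeros(gs.size, dtype=bool)
    for ss, se in segments.to_bp():
        ss, slen = ss % L, se - ss
        contained |= ((gs - ss) % L) + glen <= slen
        overlaps |= (((ss - gs) % L) < glen) | (((gs - ss) % L) < slen)
    out = np.where(contained, "inside", np.where(overlaps, "both", "outside"))
    return out


def count_genes_in_segments(genes, segments: SegmentSet, group: str | None = None):
    """Three-way gene partition counts: (inside, outside, both).

    A gene counts as *inside* if fully contained in one segment,
    *outside* if it overlaps no segment, and *both* otherwise.
    ``group`` restricts the count to genes where that boolean column is
    True.
    """
    tab = genes if group is None else genes[genes[group]]
    status = gene_segment_status(tab, segments)
    return (
        int(np.sum(status == "inside")),
        int(np.sum(status == "outside")),
        int(np.sum(status == "both")),
    )
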