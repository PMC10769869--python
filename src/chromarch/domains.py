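"""Compartment and interaction-domain calling.

Two layers of chromosome organization are extracted from normalized
contact maps:

* the **compartment index** — the leading eigenvector (PC1) of the
  distance-normalized Pearson correlation matrix, computed *without*
  centering the correlation values; its sign partitions the circle into
  the high-expression insulated domain (HEID) and the rest of the
  chromosome (ROC);
* **chromosomal interaction domains (CIDs)** — called from the
  directional-preference score, the log-ratio of downstream versus
  upstream contact sums within a fixed genomic range (default 60 kb),
  with boundaries at negative-to-positive sign changes.

The insulation score and boundary/CID aggregate maps support visual and
statistical inspection of the calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .contacts import ContactMatrix, _require_stage
from .genome import CircularGenome

__all__ = [
    "BinTrack",
    "SegmentSet",
    "compartment_index",
    "call_heid",
    "directional_preference",
    "call_cid_boundaries",
    "insulation",
    "aggregate_boundary_profile",
    "aggregate_cid_map",
]


@dataclass
class BinTrack:
    """Per-bin signal vector (PC1, directional preference, insulation...)."""

    values: np.ndarray
    kind: str
    genome: CircularGenome
    flags: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.genome.n_bins,):
            raise ValueError("track length must equal bin count")


@dataclass
class SegmentSet:
    """Ordered, non-overlapping circular bin intervals.

    Each segment is ``(start, end)`` in bins with ``start < end <=
    start + B``; ``end > B`` marks the (at most one) segment wrapping
    the origin.
    """

    segments: list
    label: str
    genome: CircularGenome
    flags: dict = field(default_factory=dict)

    def __post_init__(self):
        B = self.genome.n_bins
        segs = []
        for s, e in self.segments:
            s, e = int(s), int(e)
            if not (0 <= s < B) or not (s < e <= s + B):
                raise ValueError(f"bad circular segment ({s}, {e}) for B={B}")
            segs.append((s, e))
        segs.sort()
        self.segments = segs
        covered = self.member_bins()
        if len(covered) != sum(e - s for s, e in segs):
            raise ValueError("segments overlap on the circle")

    def member_bins(self) -> set:
        B = self.genome.n_bins
        out = set()
        for s, e in self.segments:
            out.update((np.arange(s, e) % B).tolist())
        return out

    def membership(self) -> np.ndarray:
        """Boolean per-bin membership vector."""
        m = np.zeros(self.genome.n_bins, dtype=bool)
        m[sorted(self.member_bins())] = True
        return m

    def lengths(self) -> list:
        return [e - s for s, e in self.segments]

    def to_bp(self) -> list:
        """Segments as (start_bp, end_bp) circular intervals."""
        g = self.genome
        out = []
        for s, e in self.segments:
            start = int(g.bin_start_bp(s))
            n_wrapped = max(0, e - g.n_bins)
            if n_wrapped:
                end = g.length_bp + int(g.bin_end_bp(n_wrapped - 1))
            else:
                end = int(g.bin_end_bp(e - 1))
            out.append((start, end))
        return out


def compartment_index(corr: ContactMatrix, orientation_track: BinTrack | None = None) -> BinTrack:
    """Uncentered PC1 of the Pearson correlation matrix.

    The eigenvector of the correlation matrix belonging to the
    largest-magnitude eigenvalue is computed directly on the (uncentered)
    correlation values.  The sign is oriented so that positive bins have
    the higher mean of ``orientation_track`` (typically expression); with
    no track, the minority sign (fewer bins) is made positive, matching
    a small active compartment on a mostly inactive circle.
    """
    _require_stage(corr, "correlation")
    idx = np.flatnonzero(corr.mask)
    if idx.size < 3:
        raise ValueError("too few valid bins for a compartment index")
    sub = corr.values[np.ix_(idx, idx)]
    w, v = np.linalg.eigh(sub)
    order = np.argsort(np.abs(w))[::-1]
    if np.abs(np.abs(w[order[0]]) - np.abs(w[order[1]])) < 1e-10:
        raise ValueError("degenerate PC1: leading eigenvalue is not unique")
    vec = v[:, order[0]]

    pc1 = np.full(corr.n_bins, np.nan)
    pc1[idx] = vec
    flags = {}
    pos = pc1[idx] > 0
    if pos.all() or (~pos).all():
        flags["no_compartment_structure"] = True
        warnings.warn("no compartment structure: single-sign PC1", RuntimeWarning)
    if orientation_track is not None:
        t = orientation_track.values[idx]
        mean_pos = np.nanmean(t[pos]) if pos.any() else -np.inf
        mean_neg = np.nanmean(t[~pos]) if (~pos).any() else -np.inf
        if mean_pos < mean_neg:
            pc1 = -pc1
    else:
        if pos.sum() > (~pos).sum():
            pc1 = -pc1
    return BinTrack(pc1, "pc1", corr.genome, flags)


def _circular_runs(member: np.ndarray):
    """Maximal circular runs of True as (start, end) with end possibly > B."""
    B = member.size
    if member.all():
        return [(0, B)], True
    if not member.any():
        return [], True
    # rotate so position 0 is outside a run, then take linear runs
    start0 = int(np.flatnonzero(~member)[0])
    rot = np.roll(member, -start0)
    runs = []
    in_run = False
    for k in range(B):
        if rot[k] and not in_run:
            in_run, rs = True, k
        elif not rot[k] and in_run:
            in_run = False
            runs.append((rs, k))
    if in_run:
        runs.append((rs, B))
    out = []
    for rs, re in runs:
        s = (rs + start0) % B
        out.append((s, s + (re - rs)))
    return out, False


def call_heid(pc1: BinTrack, min_run: int = 2) -> SegmentSet:
    """Segment the circle into HEID (positive-PC1 runs) vs ROC.

    Maximal circular runs of consecutive positive-PC1 bins of length >=
    ``min_run`` become HEID segments; everything else is ROC.  Runs
    shorter than ``min_run`` are treated as sign noise.
    """
    if pc1.kind != "pc1":
        raise ValueError("expected a pc1 track")
    member = np.nan_to_num(pc1.values, nan=-1.0) > 0
    runs, degenerate = _circular_runs(member)
    flags = {}
    if degenerate:
        flags["single_sign"] = True
    segs = [(s, e) for s, e in runs if e - s >= min_run]
    return SegmentSet(segs, "HEID", pc1.genome, flags)


def directional_preference(obs_exp: ContactMatrix, range_bp: int = 60000) -> BinTrack:
    """log2 ratio of downstream over upstream contact sums within ``range_bp``.

    For bin i the downstream sum covers bins i+1 .. i+w and the upstream
    sum bins i-w .. i-1 (circularly), w = range_bp // bin size.  Bins
    where either sum is zero are NaN.
    """
    _require_stage(obs_exp, "obs_exp")
    g = obs_exp.genome
    if range_bp > g.length_bp / 2:
        raise ValueError("range_bp exceeds half the genome length")
    w = range_bp // g.bin_size_bp
    if w < 1:
        raise ValueError("range_bp smaller than one bin")
    B = obs_exp.n_bins
    v = np.nan_to_num(obs_exp.values)
    dp = np.full(B, np.nan)
    idx = np.arange(B)
    down = np.zeros(B)
    up = np.zeros(B)
    for k in range(1, w + 1):
        down += v[idx, (idx + k) % B]
        up += v[idx, (idx - k) % B]
    with np.errstate(divide="ignore", invalid="ignore"):
        dp = np.where((down > 0) & (up > 0), np.log2(down / up), np.nan)
    dp[~obs_exp.mask] = np.nan
    return BinTrack(dp, "directional_preference", obs_exp.genome)


def call_cid_boundaries(
    dp: BinTrack,
    min_domain_bins: int = 3,
    threshold: float = 0.1,
):
    """Call CID boundaries at negative-to-positive DP sign changes.

    A boundary sits at bin b when DP(b-1) < 0 <= DP(b) and the flanking
    2-bin means both exceed ``threshold`` in magnitude (mean of the two
    bins before b is <= -threshold, mean of the two bins from b is >=
    +threshold).  Domains are the inter-boundary intervals; domains
    shorter than ``min_domain_bins`` are merged into the neighbor with
    the stronger mean |DP|.

    Returns ``(SegmentSet of CIDs, list of boundary bins)``.
    """
    if dp.kind != "directional_preference":
        raise ValueError("expected a directional_preference track")
    x = dp.values
    B = x.size
    boundaries = []
    for b in range(B):
        prev1, prev2 = x[(b - 1) % B], x[(b - 2) % B]
        next1, next2 = x[b], x[(b + 1) % B]
        if not np.isfinite([prev1, prev2, next1, next2]).all():
            continue
        if prev1 < 0 <= next1:
            if (prev1 + prev2) / 2 <= -threshold and (next1 + next2) / 2 >= threshold:
                boundaries.append(b)

    flags = {}
    if not boundaries:
        flags["no_boundaries"] = True
        return SegmentSet([(0, B)], "CID", dp.genome, flags), []

    boundaries = sorted(boundaries)
    segs = []
    for k, s in enumerate(boundaries):
        e = boundaries[(k + 1) % len(boundaries)]
        segs.append((s, e if e > s else e + B))

    # merge slivers into the stronger-|DP| neighbor (drops the shared boundary)
    def mean_abs(seg):
        s, e = seg
        bins = np.arange(s, e) % B
        vals = x[bins]
        vals = vals[np.isfinite(vals)]
        return np.abs(vals).mean() if vals.size else 0.0

    changed = True
    while changed and len(segs) > 1:
        changed = False
        for k, seg in enumerate(segs):
            if seg[1] - seg[0] < min_domain_bins:
                left = segs[(k - 1) % len(segs)]
                right = segs[(k + 1) % len(segs)]
                if mean_abs(left) >= mean_abs(right):
                    merged = (left[0], left[0] + (seg[1] - seg[0]) + (left[1] - left[0]))
                    segs[(k - 1) % len(segs)] = merged
                else:
                    merged = (seg[0] % B, seg[0] + (seg[1] - seg[0]) + (right[1] - right[0]))
                    segs[(k + 1) % len(segs)] = merged
                del segs[k]
                changed = True
                break
    segs = [(s % B, (s % B) + (e - s)) for s, e in segs]
    kept = sorted({s for s, e in segs})
    return SegmentSet(segs, "CID", dp.genome, flags), kept


def insulation(mat: ContactMatrix, window_bp: int = 60000) -> BinTrack:
    """Insulation score: log2 of the cross-boundary square mean vs its genome mean.

    For bin i the square spans rows i-w .. i-1 and columns i .. i+w-1
    (circular, w = window_bp // bin size): the contacts that must cross
    the putative boundary at i.  Minima mark insulating boundaries.
    """
    _require_stage(mat, "scaled", "obs_exp")
    g = mat.genome
    w = window_bp // g.bin_size_bp
    if w < 2:
        raise ValueError("window must span at least 2 bins")
    B = mat.n_bins
    v = mat.values
    sq = np.full(B, np.nan)
    for i in range(B):
        rows = (np.arange(i - w, i)) % B
        cols = (np.arange(i, i + w)) % B
        block = v[np.ix_(rows, cols)]
        if np.isfinite(block).any():
            sq[i] = np.nanmean(block)
    grand = np.nanmean(sq)
    with np.errstate(divide="ignore", invalid="ignore"):
        ins = np.where(sq > 0, np.log2(sq / grand), np.nan)
    ins[~mat.mask] = np.nan
    return BinTrack(ins, "insulation", g)


def aggregate_boundary_profile(track: BinTrack, boundaries, flank_bins: int) -> np.ndarray:
    """Mean of ``track`` over circular windows centered at each boundary."""
    boundaries = list(boundaries)
    if not boundaries:
        raise ValueError("need at least one boundary")
    B = track.genome.n_bins
    offs = np.arange(-flank_bins, flank_bins + 1)
    rows = [(b + offs) % B for b in boundaries]
    return np.nanmean(track.values[np.asarray(rows)], axis=0)


def _bilinear_resample(block: np.ndarray, out_size: int) -> np.ndarray:
    """Resample a square matrix to out_size x out_size on the cell grid."""
    n = block.shape[0]
    if n == out_size:
        return block.copy()
    src = (np.arange(n) + 0.5) / n
    dst = (np.arange(out_size) + 0.5) / out_size
    dst = np.clip(dst, src[0], src[-1])
    k = np.clip(np.searchsorted(src, dst) - 1, 0, n - 2)
    t = (dst - src[k]) / (src[k + 1] - src[k])
    rows = block[k, :] * (1 - t)[:, None] + block[k + 1, :] * t[:, None]
    out = rows[:, k] * (1 - t)[None, :] + rows[:, k + 1] * t[None, :]
    return out


def aggregate_cid_map(
    obs_exp: ContactMatrix, cids: SegmentSet, target_len: int = 30
) -> np.ndarray:
    """Length-normalized aggregate contact map over CIDs.

    For each CID the sub-matrix centered on the domain and spanning one
    domain length on each side is extracted, resampled bilinearly to
    ``3 * target_len`` (default 90) bins, and averaged over domains.
    Domains longer than a third of the genome are skipped (their 3x
    window would wrap onto itself).
    """
    _require_stage(obs_exp, "obs_exp", "scaled")
    B = obs_exp.n_bins
    out_size = 3 * target_len
    acc = []
    for s, e in cids.segments:
        L = e - s
        if L < 2:
            continue
        if L > B // 3:
            warnings.warn(f"CID ({s}, {e}) longer than B/3; skipped", RuntimeWarning)
            continue
        bins = np.arange(s - L, e + L) % B
        block = obs_exp.values[np.ix_(bins, bins)]
        acc.append(_bilinear_resample(np.nan_to_num(block, nan=np.nan), out_size))
    if not acc:
        raise ValueError("no usable CIDs for aggregation")
    return np.nanmean(np.stack(acc), axis=0)
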