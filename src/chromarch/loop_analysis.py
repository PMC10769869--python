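"""Loop lists: detection plumbing, clustering, pile-ups, anchor statistics.

A loop is a punctate contact enrichment between two bins (anchors).
Loop lists normally come from a dedicated detector via BEDPE; the
convenience detector here is a simple template-correlation scorer meant
for synthetic benchmarks, not a reimplementation of any published
detector.  The cluster rule follows the study design: a cluster is
called when five or more loops anchor in one bin, or six or more anchor
within three consecutive bins (circularly); overlapping qualifying
windows merge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .contacts import ContactMatrix, _require_stage
from .genome import CircularGenome

__all__ = [
    "LoopSet",
    "ClusterSet",
    "detect_loops",
    "call_loop_clusters",
    "aggregate_loop_map",
    "loop_anchor_stats",
]


@dataclass
class LoopSet:
    """Anchor-bin pairs with scores.

    Anchors are normalized so that anchor2 lies clockwise of anchor1
    along the shorter arc (separation <= B/2).
    """

    anchor1: np.ndarray
    anchor2: np.ndarray
    score: np.ndarray
    genome: CircularGenome

    def __post_init__(self):
        a1 = np.asarray(self.anchor1, dtype=int)
        a2 = np.asarray(self.anchor2, dtype=int)
        sc = np.asarray(self.score, dtype=float)
        if not (a1.shape == a2.shape == sc.shape):
            raise ValueError("anchor/score arrays must have equal length")
        B = self.genome.n_bins
        if a1.size:
            if a1.min(initial=0) < 0 or a2.min(initial=0) < 0 or a1.max(initial=0) >= B or a2.max(initial=0) >= B:
                raise ValueError("anchor bin outside genome")
            if np.any(a1 == a2):
                raise ValueError("loop with identical anchors")
            if not np.isfinite(sc).all():
                raise ValueError("non-finite loop score")
            sep = (a2 - a1) % B
            swap = sep > B - sep
            a1s = np.where(swap, a2, a1)
            a2s = np.where(swap, a1, a2)
            tie = sep == B - sep
            a1, a2 = np.where(tie, np.minimum(a1, a2), a1s), np.where(tie, np.maximum(a1, a2), a2s)
        self.anchor1, self.anchor2, self.score = a1, a2, sc

    def __len__(self):
        return self.anchor1.size

    @property
    def separation(self) -> np.ndarray:
        return (self.anchor2 - self.anchor1) % self.genome.n_bins

    def filter_score(self, min_score: float) -> "LoopSet":
        keep = self.score > min_score
        return LoopSet(self.anchor1[keep], self.anchor2[keep], self.score[keep], self.genome)


@dataclass
class ClusterSet:
    """Clusters of loops sharing anchor bins."""

    clusters: list  # each: {"anchor_bins": set[int], "member_loops": list[int]}
    genome: CircularGenome

    def __len__(self):
        return len(self.clusters)

    def clustered_loops(self) -> set:
        out = set()
        for c in self.clusters:
            out.update(c["member_loops"])
        return out


def _loop_template(radius: int) -> np.ndarray:
    """Center-peaked donut: Gaussian bump, zero-mean over the window."""
    d = np.hypot(*np.meshgrid(np.arange(-radius, radius + 1), np.arange(-radius, radius + 1)))
    t = np.exp(-(d**2) / 2.0)
    return t - t.mean()


def detect_loops(
    obs_exp: ContactMatrix,
    min_score: float = 0.3,
    min_separation_bins: int = 2,
    radius: int = 5,
) -> LoopSet:
    """Score candidate pixels by correlation with a center-peaked template.

    Convenience detector for synthetic benchmarks: each off-diagonal
    pixel's (2r+1)^2 circular window is Pearson-correlated with a
    center-peaked donut template; local maxima exceeding ``min_score``
    with circular separation >= ``min_separation_bins`` are reported.
    """
    _require_stage(obs_exp, "obs_exp")
    B = obs_exp.n_bins
    v = np.nan_to_num(obs_exp.values)
    tmpl = _loop_template(radius)  # zero-mean
    tnorm = np.sqrt((tmpl**2).sum())
    n_win = tmpl.size
    sep_floor = max(min_separation_bins, radius + 1)

    # windowed Pearson correlation with the template via wrap convolutions
    num = ndimage.correlate(v, tmpl, mode="wrap")
    s1 = ndimage.uniform_filter(v, size=2 * radius + 1, mode="wrap") * n_win
    s2 = ndimage.uniform_filter(v * v, size=2 * radius + 1, mode="wrap") * n_win
    win_ss = np.maximum(s2 - s1**2 / n_win, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.where(win_ss > 0, num / (np.sqrt(win_ss) * tnorm), -np.inf)

    d = obs_exp.genome.bin_distance_matrix_bins()
    eligible = (d >= sep_floor) & (np.arange(B)[:, None] < np.arange(B)[None, :])
    is_max = score >= ndimage.maximum_filter(score, size=3, mode="wrap")
    hit = eligible & is_max & (score > min_score)
    a1, a2 = np.nonzero(hit)
    return LoopSet(a1, a2, score[hit], obs_exp.genome)


def call_loop_clusters(
    loops: LoopSet, min_same_bin: int = 5, min_three_bins: int = 6
) -> ClusterSet:
    """Call clusters of co-anchored loops.

    A bin with >= ``min_same_bin`` loop anchors qualifies, as does any
    circular window of three consecutive bins holding >= ``min_three_bins``
    anchors.  Qualifying bin sets sharing a bin are merged transitively;
    each cluster lists its bins and every loop with an anchor in them.
    """
    B = loops.genome.n_bins
    counts = np.zeros(B, dtype=int)
    np.add.at(counts, loops.anchor1, 1)
    np.add.at(counts, loops.anchor2, 1)

    groups = []
    for b in range(B):
        if counts[b] >= min_same_bin:
            groups.append({b})
    for w in range(B):
        bins = {w, (w + 1) % B, (w + 2) % B}
        if sum(counts[b] for b in bins) >= min_three_bins:
            groups.append(bins)

    # transitive merge of groups sharing a bin
    merged: list = []
    for g in groups:
        g = set(g)
        attached = []
        for m in merged:
            if m & g:
                attached.append(m)
        for m in attached:
            merged.remove(m)
            g |= m
        merged.append(g)

    clusters = []
    for bins in merged:
        members = [
            k
            for k in range(len(loops))
            if loops.anchor1[k] in bins or loops.anchor2[k] in bins
        ]
        clusters.append({"anchor_bins": set(bins), "member_loops": members})
    clusters.sort(key=lambda c: min(c["anchor_bins"]))
    return ClusterSet(clusters, loops.genome)


def aggregate_loop_map(obs_exp: ContactMatrix, loops: LoopSet, flank_bins: int) -> np.ndarray:
    """Mean obs/exp sub-matrix over windows centered at every loop pixel."""
    _require_stage(obs_exp, "obs_exp", "scaled", "lfd")
    if len(loops) == 0:
        raise ValueError("need at least one loop")
    B = obs_exp.n_bins
    offs = np.arange(-flank_bins, flank_bins + 1)
    acc = np.stack(
        [
            obs_exp.values[np.ix_((i + offs) % B, (j + offs) % B)]
            for i, j in zip(loops.anchor1, loops.anchor2)
        ]
    )
    return np.nanmean(acc, axis=0)


def loop_anchor_stats(loops: LoopSet, expression: np.ndarray, genes=None) -> dict:
    """Anchor-level statistics of a loop set.

    Returns Pearson r/p between the expression at the two anchors of
    each loop, Pearson r/p between loop score and anchor expression
    (each loop contributing both anchors), and, when a tagged gene table
    is given, per-group counts of loops with at least one anchor bin
    containing a group member (``genes`` needs ``bin`` plus boolean
    group columns).
    """
    expression = np.asarray(expression, dtype=float)
    if expression.shape != (loops.genome.n_bins,):
        raise ValueError("expression track must be per-bin on the loop grid")
    out: dict = {"n_loops": len(loops), "flags": []}
    e1 = expression[loops.anchor1]
    e2 = expression[loops.anchor2]
    if len(loops) < 3:
        out["flags"].append("too_few_loops")
        out["anchor_corr"] = None
        out["score_expression_corr"] = None
    else:
        if np.std(e1) == 0 or np.std(e2) == 0:
            out["flags"].append("constant_anchor_expression")
            out["anchor_corr"] = None
        else:
            r, p = stats.pearsonr(e1, e2)
            out["anchor_corr"] = {"r": float(r), "p": float(p)}
        sc = np.concatenate([loops.score, loops.score])
        ee = np.concatenate([e1, e2])
        if np.std(sc) == 0 or np.std(ee) == 0:
            out["flags"].append("constant_scores_or_expression")
            out["score_expression_corr"] = None
        else:
            r, p = stats.pearsonr(sc, ee)
            out["score_expression_corr"] = {"r": float(r), "p": float(p)}
    if genes is not None:
        group_cols = [
            c for c in genes.columns if genes[c].dtype == bool and c != "strand"
        ]
        anchored = {}
        for col in group_cols:
            bins_with = set(genes.loc[genes[col], "bin"].astype(int))
            n = sum(
                1
                for i, j in zip(loops.anchor1, loops.anchor2)
                if int(i) in bins_with or int(j) in bins_with
            )
            anchored[col] = n
        out["group_anchor_counts"] = anchored
    return out
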