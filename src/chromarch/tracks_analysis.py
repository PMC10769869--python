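"""Expression and coverage-track statistics.

Covers the quantitative genomics around the contact maps:

* RPKSP spike-in normalization of RNA-seq gene counts (reads per
  kilobase divided by the mean reads-per-kilobase of the spike-in
  organism's genes), giving absolute between-sample comparability;
* keyword-based gene grouping (hypothetical / membrane / nucleic-acid
  metabolism / ribosomal);
* domain-expression comparisons (two-sided Wilcoxon rank-sum), the
  2x2 Fisher partition test, expression deciles, and origin-distance
  correlations;
* marker-frequency-analysis (MFA) GC-bias correction by linear
  regression, n_norm = n_obs - (n_fit - n_mean);
* ChIP/input enrichment on 500 bp windows after total-read
  normalization, averaged over replicates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio

from .domains import SegmentSet
from .genome import CircularGenome
from .resampling import gene_segment_status

__all__ = [
    "ExpressionTable",
    "classify_gene_groups",
    "rpksp",
    "window_spikein_normalize",
    "lfc_table",
    "expression_domain_test",
    "fisher_partition_test",
    "decile_sets",
    "distance_to_nearest_origin",
    "mfa_normalize",
    "find_origins",
    "chip_enrichment",
]

MEMBRANE_KEYWORDS = (
    "intramembrane",
    "permease",
    "transporter",
    "secretion system",
    "channel",
    "translocating",
    "translocase",
    "flagellin",
    "flagellar",
    "pilus",
    "pilin",
)


@dataclass
class ExpressionTable:
    """Per-gene RPKSP table plus the spike-in normalization parameter."""

    table: pd.DataFrame  # columns: id, length_bp, count, rpk, rpksp
    spike_in_parameter: float

    def __post_init__(self):
        need = {"id", "length_bp", "count", "rpk", "rpksp"}
        missing = need - set(self.table.columns)
        if missing:
            raise ValueError(f"expression table missing columns {sorted(missing)}")
        if (self.table["rpksp"] < 0).any():
            raise ValueError("negative rpksp")


def classify_gene_groups(genes: pd.DataFrame, ribosomal_ids=(), go_0090304_ids=()) -> pd.DataFrame:
    """Tag genes with functional groups by product-description keywords.

    ``hypothetical``: product contains "hypothetical"; ``membrane``: any
    membrane-transport keyword; ``nucleic_acid``: the word DNA or RNA in
    the product, or membership in the supplied GO:0090304 id list;
    ``ribosomal``: membership in the supplied (manually curated) id
    list.  Matching is case-insensitive and tags are not exclusive.
    """
    out = genes.copy()
    prod = out["product"].fillna("").str.lower()
    out["hypothetical"] = prod.str.contains("hypothetical", regex=False)
    pat = "|".join(re.escape(k) for k in MEMBRANE_KEYWORDS)
    out["membrane"] = prod.str.contains(pat, regex=True)
    na_word = prod.str.contains("dna", regex=False) | prod.str.contains("rna", regex=False)
    out["nucleic_acid"] = na_word | out["id"].isin(set(go_0090304_ids))
    out["ribosomal"] = out["id"].isin(set(ribosomal_ids))
    return out


def rpksp(gene_counts, gene_lengths_bp, spikein_counts, spikein_lengths_bp, gene_ids=None) -> ExpressionTable:
    """Spike-in normalized expression (RPKSP) per gene.

    rpk = count / (length/1000); the spike-in parameter is the mean rpk
    over spike-in genes; rpksp = rpk / parameter.
    """
    gene_counts = np.asarray(gene_counts, dtype=float)
    gene_lengths = np.asarray(gene_lengths_bp, dtype=float)
    sp_counts = np.asarray(spikein_counts, dtype=float)
    sp_lengths = np.asarray(spikein_lengths_bp, dtype=float)
    if sp_counts.size == 0 or np.any(sp_lengths <= 0):
        raise ValueError("need at least one spike-in gene with positive length")
    if np.any(gene_lengths <= 0):
        raise ValueError("gene with non-positive length")
    parameter = float(np.mean(sp_counts / (sp_lengths / 1000.0)))
    if parameter == 0:
        raise ValueError("zero spike-in normalization parameter")
    rpk = gene_counts / (gene_lengths / 1000.0)
    ids = list(gene_ids) if gene_ids is not None else list(range(gene_counts.size))
    tab = pd.DataFrame(
        {
            "id": ids,
            "length_bp": gene_lengths,
            "count": gene_counts,
            "rpk": rpk,
            "rpksp": rpk / parameter,
        }
    )
    return ExpressionTable(tab, parameter)


def window_spikein_normalize(window_counts, spikein_window_counts) -> np.ndarray:
    """Window-level variant: raw window count / mean raw spike-in window count."""
    sp = np.asarray(spikein_window_counts, dtype=float)
    if sp.size == 0 or sp.mean() == 0:
        raise ValueError("zero spike-in window parameter")
    return np.asarray(window_counts, dtype=float) / sp.mean()


def _average_replicates(tables):
    tables = list(tables)
    first = tables[0].table
    out = first[["id", "length_bp"]].copy()
    vals = np.mean([t.table["rpksp"].to_numpy() for t in tables], axis=0)
    out["rpksp"] = vals
    return out


def lfc_table(expr_a, expr_b) -> pd.DataFrame:
    """Per-gene log2 fold change of replicate-averaged RPKSP, A over B.

    ``expr_a``/``expr_b`` are ExpressionTables or lists of replicate
    ExpressionTables on the same gene set.  Genes with a zero in either
    condition get NaN.
    """
    a = _average_replicates(expr_a if isinstance(expr_a, (list, tuple)) else [expr_a])
    b = _average_replicates(expr_b if isinstance(expr_b, (list, tuple)) else [expr_b])
    if list(a["id"]) != list(b["id"]):
        raise ValueError("gene sets differ between conditions")
    ra, rb = a["rpksp"].to_numpy(), b["rpksp"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.where((ra > 0) & (rb > 0), np.log2(ra / rb), np.nan)
    return pd.DataFrame({"id": a["id"], "rpksp_a": ra, "rpksp_b": rb, "lfc": lfc})


def expression_domain_test(expr: ExpressionTable, genes: pd.DataFrame, segments: SegmentSet) -> dict:
    """Two-sided Wilcoxon rank-sum of RPKSP, inside- vs outside-segment genes.

    Genes are classified by full circular containment; straddling
    ("both") genes are excluded.  Returns medians and the p-value.
    """
    merged = genes.merge(expr.table[["id", "rpksp"]], on="id")
    cls = gene_segment_status(merged, segments)
    x = merged.loc[cls == "inside", "rpksp"].to_numpy()
    y = merged.loc[cls == "outside", "rpksp"].to_numpy()
    if x.size < 2 or y.size < 2:
        raise ValueError("need >=2 genes fully inside and >=2 fully outside")
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    return {
        "n_inside": int(x.size),
        "n_outside": int(y.size),
        "n_both": int((cls == "both").sum()),
        "median_inside": float(np.median(x)),
        "median_outside": float(np.median(y)),
        "p": float(res.pvalue),
        "statistic": float(res.statistic),
    }


def fisher_partition_test(a: int, b: int, c: int, d: int) -> dict:
    """Two-sided Fisher exact test of the 2x2 table [[a, b], [c, d]].

    Two-sidedness follows the probability-mass rule (sum over tables
    with point probability <= the observed table's); the reported odds
    ratio is the conditional maximum-likelihood estimate.
    """
    table = np.array([[a, b], [c, d]], dtype=int)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero margin in 2x2 table")
    res = stats.fisher_exact(table, alternative="two-sided")
    orr = odds_ratio(table, kind="conditional")
    return {"p": float(res.pvalue), "odds_ratio": float(orr.statistic)}


def decile_sets(expr: ExpressionTable) -> dict:
    """Top-10% and bottom-10% expressed gene id sets (ties included)."""
    tab = expr.table
    if len(tab) < 10:
        raise ValueError("need at least 10 genes")
    vals = tab["rpksp"].to_numpy()
    hi_cut = np.quantile(vals, 0.9)
    lo_cut = np.quantile(vals, 0.1)
    top = set(tab.loc[vals >= hi_cut, "id"])
    bottom = set(tab.loc[vals <= lo_cut, "id"])
    flags = []
    if len(top) == len(tab) and len(bottom) == len(tab):
        flags.append("degenerate_all_equal")
    return {"top": top, "bottom": bottom, "flags": flags}


def distance_to_nearest_origin(genes: pd.DataFrame, expr: ExpressionTable, genome: CircularGenome) -> dict:
    """Circular midpoint distance to the nearest replication origin, vs RPKSP.

    Returns the per-gene distances and the two-sided Pearson r/p of
    (distance, rpksp).
    """
    if not genome.origins_bp:
        raise ValueError("need at least one origin")
    merged = genes.merge(expr.table[["id", "rpksp"]], on="id")
    mid = ((merged["start"].to_numpy() + merged["end"].to_numpy()) / 2.0) % genome.length_bp
    origins = np.asarray(genome.origins_bp, dtype=float)
    dists = np.min(
        genome.circular_distance_bp(mid[:, None], origins[None, :]), axis=1
    )
    out = {"distance_bp": dists, "ids": list(merged["id"])}
    if mid.size >= 3 and np.std(dists) > 0 and np.std(merged["rpksp"]) > 0:
        r, p = stats.pearsonr(dists, merged["rpksp"])
        out["r"], out["p"] = float(r), float(p)
    else:
        out["r"] = out["p"] = None
    return out


def mfa_normalize(counts, gc_fraction, smoothing_window_bins: int = 50) -> dict:
    """GC-bias correction of MFA coverage by linear regression.

    The theoretical count per bin comes from the OLS fit of count on GC
    fraction; the corrected count is
    ``n_norm = n_obs - (n_fit - n_mean)``, which zeroes the GC slope and
    preserves the mean exactly.  A circular moving average of the
    corrected track (default 50-bin window) is returned for display.
    """
    n_obs = np.asarray(counts, dtype=float)
    gc = np.asarray(gc_fraction, dtype=float)
    if n_obs.size != gc.size or n_obs.size < 3:
        raise ValueError("need matching count/GC tracks of length >= 3")
    if np.any((gc < 0) | (gc > 1)):
        raise ValueError("GC fractions must lie in [0, 1]")
    flags = []
    if np.ptp(gc) == 0:
        flags.append("constant_gc")
        n_theor = np.full_like(n_obs, n_obs.mean())
    else:
        fit = stats.linregress(gc, n_obs)
        n_theor = fit.intercept + fit.slope * gc
    n_norm = n_obs - (n_theor - n_obs.mean())
    w = int(smoothing_window_bins)
    kernel = np.ones(w) / w
    smooth = np.convolve(np.tile(n_norm, 3), kernel, mode="same")[n_obs.size : 2 * n_obs.size]
    return {"normalized": n_norm, "smoothed": smooth, "flags": flags}


def find_origins(
    normalized_counts,
    n_origins: int,
    bin_bp: int = 1000,
    smoothing_window_bins: int = 50,
    flank_fraction: float = 0.8,
    gap_bins: int = 5,
) -> list:
    """Locate replication origins as refined maxima of normalized MFA coverage.

    Candidate peaks are the ``n_origins`` highest points of the
    circularly smoothed track, kept apart by non-maximum suppression.
    Each peak is then refined by fitting straight lines to its two
    descending flanks (from ``gap_bins`` away out to ``flank_fraction``
    of the half-arc toward the neighboring peak) and intersecting them:
    the replication gradient is linear in distance from the origin, so
    the intersection is the natural apex estimate.  Returns origin
    positions in bp.
    """
    y = np.asarray(normalized_counts, dtype=float)
    n = y.size
    if n_origins < 1 or n_origins * 8 * gap_bins > n:
        raise ValueError("unreasonable origin count for track length")
    w = min(smoothing_window_bins, n)
    sm = np.convolve(np.tile(y, 3), np.ones(w) / w, mode="same")[n : 2 * n]
    suppress = max(1, n // (2 * n_origins))
    peaks = []
    taken = np.zeros(n, dtype=bool)
    for idx in np.argsort(sm)[::-1]:
        if taken[idx]:
            continue
        peaks.append(int(idx))
        taken[(idx + np.arange(-suppress + 1, suppress)) % n] = True
        if len(peaks) == n_origins:
            break
    peaks = sorted(peaks)
    out = []
    for k, p in enumerate(peaks):
        if len(peaks) > 1:
            arc_r = (peaks[(k + 1) % len(peaks)] - p) % n
            arc_l = (p - peaks[(k - 1) % len(peaks)]) % n
        else:
            arc_r = arc_l = n
        fl = max(gap_bins + 2, int(flank_fraction * arc_l / 2))
        fr = max(gap_bins + 2, int(flank_fraction * arc_r / 2))
        xs_l = np.arange(-fl, -gap_bins + 1)
        xs_r = np.arange(gap_bins, fr + 1)
        bl, al = np.polyfit(xs_l, y[(p + xs_l) % n], 1)
        br, ar = np.polyfit(xs_r, y[(p + xs_r) % n], 1)
        shift = (ar - al) / (bl - br) if bl != br else 0.0
        shift = float(np.clip(shift, -w, w))
        out.append(((p + shift) % n) * bin_bp)
    return sorted(out)


def chip_enrichment(chip_replicates, input_replicates) -> np.ndarray:
    """Replicate-averaged ChIP/input enrichment on a fixed window grid.

    Each replicate's windows are scaled to its total mapped reads
    before the ratio; windows with zero input coverage are NaN.
    """
    chip_replicates = [np.asarray(c, dtype=float) for c in np.atleast_2d(chip_replicates)]
    input_replicates = [np.asarray(c, dtype=float) for c in np.atleast_2d(input_replicates)]
    if len(chip_replicates) != len(input_replicates):
        raise ValueError("replicate count mismatch between ChIP and input")
    tracks = []
    for chip, inp in zip(chip_replicates, input_replicates):
        if chip.shape != inp.shape:
            raise ValueError("window grid mismatch between ChIP and input")
        if chip.sum() == 0 or inp.sum() == 0:
            raise ValueError("replicate with zero total reads")
        with np.errstate(divide="ignore", invalid="ignore"):
            enr = np.where(inp > 0, (chip / chip.sum()) / (inp / inp.sum()), np.nan)
        tracks.append(enr)
    return np.nanmean(np.stack(tracks), axis=0)
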