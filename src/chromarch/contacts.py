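"""Contact-matrix construction and normalization.

The pipeline's matrix stages, in order:

``raw``          binned ligation counts, diagonal nulled
``balanced``     ICE / iterative-proportional-fitting output (equal marginals)
``scaled``       balanced matrix rescaled so every row/column sums to 1,000
``obs_exp``      scaled matrix divided by the mean contact score at the same
                 circular bin separation (distance normalization)
``correlation``  Pearson correlation of obs/exp rows
``lfd``          log2 fold difference between two matrices

Matrices are dense, symmetric, with a per-bin validity mask; undefined
cells (masked rows/columns, empty distance classes, zeros under log)
are NaN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .genome import CircularGenome

__all__ = [
    "ContactMatrix",
    "bin_pairs",
    "sum_matrices",
    "ice_balance",
    "scale_to_row_total",
    "distance_normalize",
    "correlation_matrix",
    "lfd",
    "abundance_normalize",
]

STAGES = ("raw", "balanced", "scaled", "obs_exp", "correlation", "lfd")

_SYM_RTOL = 1e-9


@dataclass
class ContactMatrix:
    """Square symmetric per-bin contact matrix with a validity mask."""

    values: np.ndarray
    mask: np.ndarray  # True = bin is valid
    stage: str
    genome: CircularGenome
    flags: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("contact matrix must be square")
        if self.values.shape[0] != self.genome.n_bins:
            raise ValueError(
                f"matrix dimension {self.values.shape[0]} != "
                f"genome bin count {self.genome.n_bins}"
            )
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (self.values.shape[0],):
            raise ValueError("mask must be a per-bin vector")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        self._check_symmetry()

    def _check_symmetry(self):
        v = self.values
        with np.errstate(invalid="ignore"):
            both = np.isfinite(v) & np.isfinite(v.T)
        if not np.allclose(v[both], v.T[both], rtol=_SYM_RTOL, atol=1e-12):
            i, j = np.unravel_index(
                np.nanargmax(np.where(both, np.abs(v - v.T), 0)), v.shape
            )
            raise ValueError(f"matrix not symmetric: cell ({i}, {j})")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    def valid_values(self) -> np.ndarray:
        """Values restricted to the unmasked sub-matrix."""
        idx = np.flatnonzero(self.mask)
        return self.values[np.ix_(idx, idx)]

    def marginals(self) -> np.ndarray:
        """Row sums over valid columns (NaN-safe); NaN on masked rows."""
        v = np.where(self.mask[None, :], self.values, 0.0)
        out = np.nansum(v, axis=1)
        out[~self.mask] = np.nan
        return out

    def copy_with(self, values, stage=None, mask=None, flags=None) -> "ContactMatrix":
        return ContactMatrix(
            values=values,
            mask=self.mask if mask is None else mask,
            stage=self.stage if stage is None else stage,
            genome=self.genome,
            flags=dict(self.flags) if flags is None else flags,
        )


def _require_stage(mat: ContactMatrix, *stages: str):
    if mat.stage not in stages:
        raise ValueError(f"expected stage in {stages}, got {mat.stage!r}")


def _require_same_grid(a: ContactMatrix, b: ContactMatrix):
    if a.genome != b.genome or a.n_bins != b.n_bins:
        raise ValueError("matrices are on different genome/bin grids")


def bin_pairs(pairs, genome: CircularGenome) -> ContactMatrix:
    """Bin ligation pairs (pos1_bp, pos2_bp) into a raw contact matrix.

    The genome's coordinate shift is applied modulo the genome length
    before binning.  Each pair increments both (b1, b2) and (b2, b1);
    intra-bin pairs land on the diagonal which is then nulled, i.e.
    discarded.
    """
    pairs = np.asarray(list(pairs), dtype=float)
    B = genome.n_bins
    m = np.zeros((B, B))
    if pairs.size:
        if pairs.ndim != 2 or pairs.shape[1] != 2:
            raise ValueError("pairs must be (pos1, pos2) records")
        b1 = np.asarray(genome.bin_of(pairs[:, 0]), dtype=int)
        b2 = np.asarray(genome.bin_of(pairs[:, 1]), dtype=int)
        np.add.at(m, (b1, b2), 1.0)
        np.add.at(m, (b2, b1), 1.0)
    np.fill_diagonal(m, 0.0)
    return ContactMatrix(m, np.ones(B, dtype=bool), "raw", genome)


def sum_matrices(matrices) -> ContactMatrix:
    """Element-wise sum of replicate raw matrices; masks intersected."""
    matrices = list(matrices)
    if not matrices:
        raise ValueError("no matrices to sum")
    first = matrices[0]
    _require_stage(first, "raw")
    total = np.zeros_like(first.values)
    mask = np.ones(first.n_bins, dtype=bool)
    for m in matrices:
        _require_stage(m, "raw")
        _require_same_grid(first, m)
        total = total + m.values
        mask &= m.mask
    return first.copy_with(total, mask=mask)


def ice_balance(
    raw: ContactMatrix,
    max_iter: int = 500,
    tol: float = 1e-9,
    low_coverage_fraction: float = 0.02,
) -> ContactMatrix:
    """Iterative correction (matrix balancing) of a raw contact matrix.

    Bins whose marginal falls below ``low_coverage_fraction`` times the
    median marginal are masked before balancing.  Rows and columns are
    then repeatedly divided by their (mean-normalized) marginals until
    the maximum relative marginal deviation drops below ``tol`` or
    ``max_iter`` sweeps have run.  Non-convergence sets
    ``flags['ice_converged'] = False`` rather than raising.
    """
    _require_stage(raw, "raw")
    v = raw.values.copy()
    mask = raw.mask.copy()
    v[~mask, :] = 0.0
    v[:, ~mask] = 0.0

    marg = v.sum(axis=1)
    med = np.median(marg[mask]) if mask.any() else 0.0
    mask &= marg >= low_coverage_fraction * med
    if mask.sum() < 2:
        raise ValueError("all bins masked (or fewer than 2 valid bins)")
    v[~mask, :] = 0.0
    v[:, ~mask] = 0.0

    converged = False
    for _ in range(max_iter):
        marg = v.sum(axis=1)
        s = marg[mask] / marg[mask].mean()
        if np.max(np.abs(s - 1.0)) < tol:
            converged = True
            break
        f = np.ones(raw.n_bins)
        f[mask] = s
        v /= f[:, None]
        v /= f[None, :]
    if not converged:
        warnings.warn("ICE did not converge within max_iter", RuntimeWarning)

    out = np.full_like(v, np.nan)
    idx = np.flatnonzero(mask)
    out[np.ix_(idx, idx)] = v[np.ix_(idx, idx)]
    flags = dict(raw.flags)
    flags["ice_converged"] = converged
    return ContactMatrix(out, mask, "balanced", raw.genome, flags)


def scale_to_row_total(balanced: ContactMatrix, total: float = 1000.0) -> ContactMatrix:
    """Rescale a balanced matrix so each unmasked row/column sums to ``total``.

    A single global multiplier is applied (row sums are already equal
    after balancing), so symmetry is preserved exactly.
    """
    _require_stage(balanced, "balanced", "scaled")
    marg = balanced.marginals()
    mean_row = np.nanmean(marg[balanced.mask])
    if not np.isfinite(mean_row) or mean_row <= 0:
        raise ValueError("zero row sums; cannot scale")
    return balanced.copy_with(balanced.values * (total / mean_row), stage="scaled")


def _distance_class_stats(mat: ContactMatrix):
    B = mat.n_bins
    d = mat.genome.bin_distance_matrix_bins()
    valid = mat.mask[:, None] & mat.mask[None, :] & np.isfinite(mat.values)
    np.fill_diagonal(valid, False)
    sums = np.bincount(d[valid], weights=mat.values[valid], minlength=B // 2 + 1)
    counts = np.bincount(d[valid], minlength=B // 2 + 1)
    with np.errstate(invalid="ignore"):
        means = sums / counts
    return d, means, counts


def distance_normalize(scaled: ContactMatrix) -> ContactMatrix:
    """Observed/expected: divide by the mean score at each circular separation.

    The expected value at separation ``s`` is the mean of unmasked cells
    with circular bin distance ``min(|i-j|, B-|i-j|) == s``.  Separation
    classes that are entirely masked (or have zero mean) yield NaN cells.
    The diagonal (separation 0, nulled upstream) stays undefined.
    """
    _require_stage(scaled, "scaled")
    d, means, counts = _distance_class_stats(scaled)
    expected = means[d]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(expected > 0, scaled.values / expected, np.nan)
    out[~scaled.mask, :] = np.nan
    out[:, ~scaled.mask] = np.nan
    np.fill_diagonal(out, np.nan)
    return scaled.copy_with(out, stage="obs_exp")


def correlation_matrix(
    obs_exp: ContactMatrix,
    smooth_bins: int = 0,
    min_separation_bins: int = 0,
) -> ContactMatrix:
    """Pearson correlation of obs/exp rows.

    Cell (i, j) is the correlation of rows i and j across valid columns,
    excluding columns i and j themselves (their entries involve the
    nulled diagonal).  Rows with zero variance are masked; the diagonal
    is set to 1.

    For compartment estimation the raw per-cell correlation is noisy
    and dominated by domain-scale (CID) structure; ``smooth_bins``
    applies a circular uniform filter to the obs/exp values first and
    ``min_separation_bins`` drops cells closer than that circular bin
    separation, so only long-range plaid signal enters the row
    correlations (pairwise-complete Pearson in that case).  Defaults
    leave the values untouched.
    """
    _require_stage(obs_exp, "obs_exp")
    if smooth_bins or min_separation_bins:
        return _regularized_correlation(obs_exp, smooth_bins, min_separation_bins)
    B = obs_exp.n_bins
    x = obs_exp.values.copy()
    # columns usable by every pair: valid bins whose entries are finite
    # in all valid rows (except the structurally-NaN diagonal)
    col_ok = obs_exp.mask.copy()
    xi = x.copy()
    np.fill_diagonal(xi, 0.0)  # diagonal handled via per-pair exclusion below
    finite = np.isfinite(xi) | ~obs_exp.mask[:, None] | ~col_ok[None, :]
    col_ok &= finite.all(axis=0)
    x = np.where(col_ok[None, :], np.nan_to_num(xi), 0.0)

    n_cols = int(col_ok.sum())
    if n_cols < 4:
        raise ValueError("too few valid columns for row correlations")
    diag = np.zeros(B)  # x_ii after diagonal nulling

    S1 = x.sum(axis=1)
    S2 = (x * x).sum(axis=1)
    C = x @ x.T

    # exclude columns i and j from the pair (i, j); x_ii = 0 already
    Xij = np.where(col_ok[None, :], x, 0.0)
    A = S1[:, None] - diag[:, None] - Xij  # sum of row i without cols i, j
    Q = S2[:, None] - diag[:, None] ** 2 - Xij**2
    Cp = C - Xij * (diag[:, None] + diag[None, :])
    # both excluded columns must actually be usable columns to subtract n
    n_eff = n_cols - col_ok[:, None].astype(int) - col_ok[None, :].astype(int)

    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n_eff * Cp - A * A.T
        var_i = n_eff * Q - A**2
        corr = cov / np.sqrt(var_i * var_i.T)
    corr = np.clip(corr, -1.0, 1.0)

    var_row = np.nanvar(np.where(col_ok[None, :], xi, np.nan), axis=1)
    mask = obs_exp.mask & (var_row > 0)
    corr[~mask, :] = np.nan
    corr[:, ~mask] = np.nan
    np.fill_diagonal(corr, 1.0)
    corr[~mask, ~mask] = np.nan
    corr = (corr + corr.T) / 2.0  # enforce exact symmetry
    return ContactMatrix(corr, mask, "correlation", obs_exp.genome, dict(obs_exp.flags))


def _regularized_correlation(
    obs_exp: ContactMatrix, smooth_bins: int, min_separation_bins: int
) -> ContactMatrix:
    """Smoothed / long-range-only row correlation (pairwise complete)."""
    from scipy import ndimage

    v = np.nan_to_num(obs_exp.values, nan=1.0)
    np.fill_diagonal(v, 1.0)
    if smooth_bins:
        v = ndimage.uniform_filter(v, size=smooth_bins, mode="wrap")
    if min_separation_bins:
        d = obs_exp.genome.bin_distance_matrix_bins()
        v = np.where(d >= min_separation_bins, v, np.nan)
    v[~obs_exp.mask, :] = np.nan
    v[:, ~obs_exp.mask] = np.nan
    corr = np.ma.corrcoef(np.ma.masked_invalid(v)).filled(np.nan)
    var_row = np.nanvar(v, axis=1)
    mask = obs_exp.mask & (var_row > 0)
    corr = np.clip(corr, -1.0, 1.0)
    corr[~mask, :] = np.nan
    corr[:, ~mask] = np.nan
    np.fill_diagonal(corr, 1.0)
    corr[~mask, ~mask] = np.nan
    corr = (corr + corr.T) / 2.0
    return ContactMatrix(corr, mask, "correlation", obs_exp.genome, dict(obs_exp.flags))


def lfd(mat_a: ContactMatrix, mat_b: ContactMatrix) -> ContactMatrix:
    """log2 fold difference log2(a_ij / b_ij) between two matrices.

    Cells where either score is zero (or undefined) are NaN, which keeps
    the result exactly antisymmetric under argument swap.
    """
    _require_same_grid(mat_a, mat_b)
    if mat_a.stage != mat_b.stage or mat_a.stage not in ("scaled", "obs_exp"):
        raise ValueError("lfd expects two matrices at the same stage (scaled or obs_exp)")
    mask = mat_a.mask & mat_b.mask
    with np.errstate(invalid="ignore", divide="ignore"):
        ok = (mat_a.values > 0) & (mat_b.values > 0)
        out = np.where(ok, np.log2(mat_a.values / mat_b.values), np.nan)
    out[~mask, :] = np.nan
    out[:, ~mask] = np.nan
    return ContactMatrix(out, mask, "lfd", mat_a.genome)


def abundance_normalize(raw: ContactMatrix, dna_abundance) -> ContactMatrix:
    """Divide cell (i, j) by abundance_i * abundance_j, preserving the total.

    Used to correct contact counts for DNA copy-number differences along
    the chromosome (e.g., replication-driven gradients).
    """
    _require_stage(raw, "raw")
    ab = np.asarray(dna_abundance, dtype=float)
    if ab.shape != (raw.n_bins,):
        raise ValueError("abundance track length must equal bin count")
    if np.any(ab[raw.mask] <= 0):
        raise ValueError("zero or negative abundance on unmasked bin")
    out = raw.values / (ab[:, None] * ab[None, :])
    total_before = np.nansum(np.where(raw.mask[:, None] & raw.mask[None, :], raw.values, 0))
    total_after = np.nansum(np.where(raw.mask[:, None] & raw.mask[None, :], out, 0))
    if total_after > 0:
        out = out * (total_before / total_after)
    return raw.copy_with(out)
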