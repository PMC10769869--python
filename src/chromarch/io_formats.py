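"""Readers and writers for the on-disk formats the pipeline touches.

Coordinate conventions are converted at this boundary and nowhere else:

* internal coordinates are always 0-based half-open in the shifted frame;
* GFF3 is 1-based inclusive (a feature with start > end wraps the
  circular origin and is stored as a wrapping interval, end > length);
* BED / BEDPE / bedGraph are 0-based half-open;
* contact matrices travel as dense TSV (B x B) or COO text
  (``bin_i  bin_j  count``, upper triangle sufficient);
* truth / config objects as JSON.

Readers validate and reject out-of-range coordinates rather than clamp.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .contacts import ContactMatrix
from .genome import CircularGenome
from .loop_analysis import LoopSet

__all__ = [
    "load_matrix",
    "save_matrix_dense",
    "save_matrix_coo",
    "load_annotations",
    "save_genes_gff3",
    "load_loops",
    "save_loops",
    "load_bedgraph",
    "save_bedgraph",
    "save_truth",
    "load_truth",
]

_ASYM_TOL = 1e-8


def load_matrix(path, genome: CircularGenome, fmt: str | None = None) -> ContactMatrix:
    """Load a raw contact matrix from dense TSV or COO text.

    With ``fmt=None`` a file whose rows have exactly three columns (and
    is not B x B) is read as COO (``i j count``; triangular input is
    mirrored); otherwise it must be a dense B x B table.  Pass
    ``fmt='dense'`` or ``fmt='coo'`` to disambiguate tiny matrices.
    Dense input is checked for symmetry and the first offending cell is
    named on failure.
    """
    path = Path(path)
    arr = np.loadtxt(path, ndmin=2)
    B = genome.n_bins
    if arr.size == 0:
        arr = np.zeros((0, 3))
    is_coo = fmt == "coo" or (
        fmt is None and arr.shape[1] == 3 and arr.shape[0] != B
    )
    if is_coo:
        m = np.zeros((B, B))
        i = arr[:, 0].astype(int)
        j = arr[:, 1].astype(int)
        if np.any((i < 0) | (i >= B) | (j < 0) | (j >= B)):
            raise ValueError(f"COO bin index outside [0, {B}) in {path}")
        m[i, j] += arr[:, 2]
        if _is_triangular(i, j):
            m = m + m.T - np.diag(np.diag(m))
        else:
            _check_dense_symmetry(m, path)
    else:
        if arr.shape != (B, B):
            raise ValueError(
                f"dense matrix in {path} has shape {arr.shape}, expected ({B}, {B})"
            )
        m = arr
        _check_dense_symmetry(m, path)
    np.fill_diagonal(m, 0.0)
    return ContactMatrix(m, np.ones(B, dtype=bool), "raw", genome)


def _is_triangular(i, j):
    return np.all(i <= j) or np.all(i >= j)


def _check_dense_symmetry(m, path):
    diff = np.abs(m - m.T)
    if diff.size and diff.max() > _ASYM_TOL * max(1.0, np.abs(m).max()):
        i, j = np.unravel_index(np.argmax(diff), m.shape)
        raise ValueError(f"asymmetric matrix in {path}: cell ({i}, {j}) != ({j}, {i})")


def save_matrix_dense(mat: ContactMatrix, path):
    np.savetxt(path, mat.values, delimiter="\t", fmt="%.10g")


def save_matrix_coo(mat: ContactMatrix, path):
    """Write the non-zero upper triangle as ``i j count`` rows."""
    i, j = np.nonzero(np.triu(np.nan_to_num(mat.values)))
    with open(path, "w") as fh:
        for a, b in zip(i, j):
            fh.write(f"{a}\t{b}\t{mat.values[a, b]:.10g}\n")


def load_annotations(path, genome: CircularGenome) -> pd.DataFrame:
    """Load gene annotations from GFF3 or BED into internal coordinates.

    Output columns: id, start, end (0-based half-open, end > length for
    genes wrapping the circular origin), strand, product, bin (midpoint
    bin).  GFF3 features with start > end are interpreted as wrapping.
    """
    path = Path(path)
    L = genome.length_bp
    rows = []
    if path.suffix.lower() in (".gff", ".gff3"):
        for line in path.read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9:
                raise ValueError(f"malformed GFF3 line in {path}: {line[:60]}")
            start1, end1 = int(f[3]), int(f[4])
            if not (1 <= start1 <= L) or not (1 <= end1 <= L):
                raise ValueError(f"GFF3 coordinate outside genome in {path}")
            start = start1 - 1
            end = end1 if end1 >= start1 else end1 + L  # wrap notation
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            rows.append(
                {
                    "id": attrs.get("ID", f"feat_{len(rows)}"),
                    "start": start,
                    "end": end,
                    "strand": f[6],
                    "product": attrs.get("product", ""),
                }
            )
    elif path.suffix.lower() == ".bed":
        for line in path.read_text().splitlines():
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            start, end = int(f[1]), int(f[2])
            if not (0 <= start < L) or not (0 < end <= L + start):
                raise ValueError(f"BED coordinate outside genome in {path}")
            rows.append(
                {
                    "id": f[3] if len(f) > 3 else f"feat_{len(rows)}",
                    "start": start,
                    "end": end,
                    "strand": f[5] if len(f) > 5 else ".",
                    "product": "",
                }
            )
    else:
        raise ValueError(f"unsupported annotation format: {path.suffix}")
    df = pd.DataFrame(rows, columns=["id", "start", "end", "strand", "product"])
    if len(df) and (df["end"] <= df["start"]).any():
        bad = df.loc[df["end"] <= df["start"], "id"].iloc[0]
        raise ValueError(f"feature {bad!r} has end <= start after conversion")
    if len(df):
        mids = ((df["start"] + df["end"]) // 2) % L
        df["bin"] = (mids // genome.bin_size_bp).astype(int)
    else:
        df["bin"] = pd.Series(dtype=int)
    return df


def save_genes_gff3(genes: pd.DataFrame, genome: CircularGenome, path, source="chromarch"):
    """Write genes as GFF3 (1-based inclusive; wrapping genes use start > end)."""
    L = genome.length_bp
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, r in genes.iterrows():
            start1 = int(r["start"]) % L + 1
            end0 = int(r["end"])
            end1 = end0 if end0 <= L else end0 - L
            prod = str(r.get("product", "")).replace(";", ",")
            fh.write(
                f"chr\t{source}\tgene\t{start1}\t{end1}\t.\t{r['strand']}\t.\t"
                f"ID={r['id']};product={prod}\n"
            )


def load_loops(path, genome: CircularGenome) -> LoopSet:
    """Load a BEDPE loop list (0-based half-open anchors, score required)."""
    path = Path(path)
    a1, a2, sc = [], [], []
    for line in path.read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) < 7:
            raise ValueError(f"BEDPE row in {path} lacks a score column")
        s1, e1, s2, e2 = int(f[1]), int(f[2]), int(f[4]), int(f[5])
        for v in (s1, s2):
            if not (0 <= v < genome.length_bp):
                raise ValueError(f"anchor start {v} outside genome in {path}")
        for v in (e1, e2):
            if not (0 < v <= genome.length_bp):
                raise ValueError(f"anchor end {v} outside genome in {path}")
        a1.append(int(((s1 + e1) // 2) // genome.bin_size_bp))
        a2.append(int(((s2 + e2) // 2) // genome.bin_size_bp))
        sc.append(float(f[6]))
    return LoopSet(np.array(a1, int), np.array(a2, int), np.array(sc, float), genome)


def save_loops(loops: LoopSet, path):
    """Write loops as BEDPE with anchors expanded to full bins."""
    g = loops.genome
    with open(path, "w") as fh:
        for i, j, s in zip(loops.anchor1, loops.anchor2, loops.score):
            s1, e1 = int(g.bin_start_bp(i)), int(g.bin_end_bp(i))
            s2, e2 = int(g.bin_start_bp(j)), int(g.bin_end_bp(j))
            fh.write(f"chr\t{s1}\t{e1}\tchr\t{s2}\t{e2}\t{s:.6g}\n")


def load_bedgraph(path, genome: CircularGenome) -> pd.DataFrame:
    path = Path(path)
    rows = []
    for line in path.read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track")):
            continue
        f = line.split("\t")
        start, end, value = int(f[1]), int(f[2]), float(f[3])
        if not (0 <= start < genome.length_bp) or not (start < end <= genome.length_bp):
            raise ValueError(f"bedGraph interval outside genome in {path}")
        rows.append({"start": start, "end": end, "value": value})
    return pd.DataFrame(rows, columns=["start", "end", "value"])


def save_bedgraph(starts, ends, values, path, name="track"):
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{name}"\n')
        for s, e, v in zip(starts, ends, values):
            fh.write(f"chr\t{int(s)}\t{int(e)}\t{float(v):.6g}\n")


def save_truth(truth, path):
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1)


def load_truth(path):
    from .synthetic import SyntheticTruth

    with open(path) as fh:
        return SyntheticTruth.from_dict(json.load(fh))
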