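# chromarch

Chromosome-architecture analysis for small circular genomes, built around
the kind of 3C/Hi-C study performed on archaea and bacteria: a closed
circular chromosome of ~1–2 Mbp, proximity-ligation contact maps binned at
a few kb, self-interacting **chromosomal interaction domains (CIDs)**, a
transcription-defined compartment — a **high-expression insulated domain
(HEID)** standing apart from the rest of the chromosome (ROC) — punctate
**loops**, and the accompanying RNA-seq / MFA-seq / ChIP-seq tracks.

The package is aimed at microbial chromosome-biology groups who want the
full numerical pipeline of such a study as tested, reusable code: every
stage works on plain-text formats, every stochastic step is seeded, and a
synthetic-data generator plants known structure so the whole chain can be
validated end to end without any sequencing data.

## What it computes

**Contact maps** (`chromarch.contacts`). Ligation pairs are binned on the
circle (3 kb default, coordinates shifted to the first restriction site),
the diagonal is nulled, replicates are summed, and the matrix is balanced
by iterative correction (ICE, max 500 sweeps) so all bin marginals agree.
Scores are then rescaled so every row and column sums to 1,000. From the
scaled matrix the pipeline derives observed/expected matrices
(obs/exp(i,j) = n_ij / E[n at circular distance d(i,j)]), Pearson
correlation matrices of obs/exp rows, and log2 fold-difference (LFD)
matrices log2(n_ij^A / n_ij^B) between conditions.

**Compartments and domains** (`chromarch.domains`). The compartment index
is the leading eigenvector (PC1) of the correlation matrix, taken without
centering; its sign partitions the circle into HEID and ROC. CID
boundaries come from the directional preference score
DP(i) = log2(Σ downstream obs/exp / Σ upstream obs/exp) within 60 kb, with
boundaries at negative-to-positive sign changes; the insulation score
I(i) = log2(mean cross-boundary square / genome mean) confirms them.
Aggregate maps rescale every CID to 30 bins (90-bin output) before
averaging.

**Loops** (`chromarch.loop_analysis`). Loop lists (BEDPE with scores) are
filtered at score > 0.3; clusters are called when ≥5 loops anchor in one
bin or ≥6 anchor within three consecutive bins, circularly; pile-ups and
anchor-expression statistics follow.

**Permutation tests** (`chromarch.resampling`). Segment and loop shuffles
on the circle preserve segment number/length and loop separation; the
empirical p-value over 1,000 permutations is the fraction of shuffles at
least as extreme as the observation.

**Tracks** (`chromarch.tracks_analysis`). RPKSP spike-in normalization
(reads per kilobase over the mean spike-in RPK), keyword gene grouping,
two-sided Wilcoxon domain-expression tests, exact Fisher 2×2 partition
tests, expression deciles, origin-distance correlations, MFA GC-bias
correction `n_norm = n_obs − (n_fit − n_mean)` on 1 kb bins with
replication-origin localization, and ChIP/input enrichment on 500 bp
windows.

**Synthetic data** (`chromarch.synthetic`). Poisson contact maps around
λ_ij = c·(1+d_ij)^(−α)·β_CID^[same domain]·β_HEID^[both in compartment]·γ^[loop],
plus seeded gene-expression tables, MFA and ChIP tracks — with the planted
truth recorded for recovery tests.

## Worked example

```python
import chromarch as ca
report = ca.run_demo(seed=11, depth=1_000_000, n_reps=200)
```

generates a 1.669 Mbp circular genome at 3 kb bins (557 bins) with 19
planted CIDs, a 4-segment HEID covering 20% of the circle, 20 loops and
spike-in-calibrated expression, then runs the full pipeline. Printing the
key entries of the report gives:

```
compartment agreement : 0.952
CID boundaries        : 19/19 recovered (+-1 bin)
loops > 0.3           : 277  in 25 clusters
loop clustering       : observed = 206, expected = 152.565 (200 permutations, direction ge): P < 0.005
HEID vs ROC expression: median 4.5 vs 0.7, Wilcoxon p = 2.48e-52
```

meaning: PC1 sign assigns 95.2% of bins to the correct planted
compartment; all 19 domain boundaries are found within one bin; 277
loop-like pixels pass the 0.3 score filter, 206 of them fall in anchor
clusters versus 152.6 expected under circular shuffling (empirical
P < 1/200); and genes inside the planted compartment show the expected
~8-fold higher spike-in-normalized expression.

The same pipeline runs from the shell:

```bash
chromarch demo --seed 11 --out report.json
chromarch matrix normalize raw.tsv scaled.tsv --bin-size 3000
chromarch loops clusters loops.bedpe --min-score 0.3
```

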