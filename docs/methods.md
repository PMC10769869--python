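# Methods

This note documents the models, estimators and numerical choices behind
`chromarch`, in the spirit of the methods documentation of established
scientific packages: what each stage assumes, which knobs matter, what
the synthetic generator does and does not emulate, and where the design
was genuinely open.

## Coordinate model

All analyses run on a `CircularGenome`: a closed circle of `length_bp`
base pairs with non-overlapping bins of `bin_size_bp` laid from
coordinate 0 of a shifted frame (`shift_bp` lets coordinates start at a
restriction site, e.g. 117 bp into an annotated genome). Internal
coordinates are 0-based half-open everywhere; GFF3 (1-based inclusive,
with start > end denoting origin-wrapping features) and BED/BEDPE/
bedGraph conventions are converted exactly once, at the I/O boundary.
When the genome length is not a multiple of the bin size the final bin
is kept short and participates with its true midpoint; circular bp
distances are computed between bin midpoints, circular bin separations
as `min(|i−j|, B−|i−j|)`. Readers reject out-of-range coordinates
rather than clamping. Supported matrix formats are dense TSV and COO
text; all formats in and out of the package are plain text.

## Contact-map normalization

Binned ligation counts have their diagonal nulled (intra-bin ligation
is uninformative), replicates are summed, and the matrix is balanced by
iterative proportional fitting (ICE): rows and columns are repeatedly
divided by their mean-normalized marginals. Bins with marginals below
2% of the median marginal are masked first (the threshold is
configurable; typical pair-processing pipelines filter low-coverage
bins but do not publish a universal value). Convergence is declared
when the maximum relative marginal deviation falls below `tol`;
`max_iter` defaults to 500. We set `tol = 1e-9` rather than a looser
value because the downstream contract — every row and column of the
scaled matrix sums to 1,000 — is asserted to 1e-6 *absolute*, which at
a row total of 1,000 requires ~1e-9 relative convergence; Sinkhorn-type
iterations on positive matrices reach this comfortably within 500
sweeps. Non-convergence flags the result instead of raising, because a
partially balanced matrix is still inspectable.

Distance normalization divides each cell by the mean of unmasked cells
at the same circular bin separation, making the per-separation mean
exactly 1 by construction. The Pearson correlation matrix correlates
obs/exp rows pairwise, excluding columns i and j from the (i, j) cell
(they contain the structurally nulled diagonal); zero-variance rows are
masked. LFD matrices mask cells where either score is zero instead of
adding pseudocounts — this keeps `lfd(A, B) = −lfd(B, A)` exact on the
defined cells, at the cost of some masked cells at low depth.
DNA-abundance normalization divides cell (i, j) by
`abundance_i × abundance_j` and rescales to preserve the total.

## Compartment index

The compartment index is the eigenvector of the correlation matrix
belonging to the largest-magnitude eigenvalue, computed on the
uncentered correlation values; an eigen-gap below 1e-10 raises a
"degenerate PC1" error rather than returning an arbitrary vector. The
sign is oriented by an expression track when one is supplied (positive
bins get the higher mean expression — the compartment of interest is
the transcriptionally active one); without a track the minority sign is
made positive, matching a small active compartment on a mostly inactive
circle. This literal uncentered reading is the single biggest
interpretive choice in the package and is therefore validated against
planted synthetic truth, not against any published eigenvector.

For compartment estimation the correlation matrix is computed from
*regularized* obs/exp values: a circular 5-bin uniform smoothing,
and exclusion of cells closer than 40 bins (~120 kb at 3 kb bins,
safely above the ~30-bin domain scale). Both knobs default to off in
`correlation_matrix` itself; the pipeline enables them
(`corr_smooth_bins`, `corr_min_separation_bins` in `RunConfig`)
because at realistic sequencing depth (~10^6 informative pairs) the
per-cell Poisson noise and the strong domain-scale structure otherwise
compete with the long-range plaid signal for the leading eigenvector.
This mirrors the common Hi-C practice of estimating compartment
eigenvectors at coarse effective resolution. With these settings,
planted-label recovery on the default synthetic genome averages ~98%
over 20 simulations (≥95% is the design requirement); with the raw
per-cell correlation it averages ~90% with occasional failures.

HEID segmentation takes maximal circular runs of positive PC1 bins of
length ≥ 2 (single-bin runs are treated as sign noise); HEID and ROC
partition the unmasked circle exactly.

## CID calling

The directional preference score is
`DP(i) = log2(Σ_{k=1..w} oe(i, i+k) / Σ_{k=1..w} oe(i, i−k))` with
`w = 60 kb / bin size`, circularly; the prior literature's definition
is not restated in the study this package follows, so this log-ratio
form is a declared substitute validated on synthetic truth. Boundaries
sit where DP crosses from negative to positive with both flanking
2-bin means exceeding 0.1 in magnitude (ties at zero resolve to the
later bin); domains shorter than 3 bins merge into the neighbor with
the stronger mean |DP|. On default synthetic genomes (domain boost 3,
depth 10^6) all 19 planted boundaries are typically recovered within
±1 bin.

The insulation score of bin i is the log2 ratio of the mean of the
square [i−w, i) × [i, i+w) — the contacts that must cross a putative
boundary at i — to the genome-wide mean of such squares; minima mark
boundaries. Aggregate CID maps extract each domain with one
domain-length of flank, resample the submatrix to 90×90 by bilinear
interpolation on cell centers (a 30-bin domain needs no resampling),
and average; domains longer than a third of the genome are skipped
because their flanked window would wrap onto itself.

## Loops

The bundled detector scores each off-diagonal pixel by the Pearson
correlation between its (2r+1)² circular window (r = 5) and a
center-peaked Gaussian template, keeping local maxima above the score
threshold (0.3) at separations ≥ r+1 bins. It is convenience plumbing
for synthetic benchmarks — loop lists from dedicated detectors are the
intended input — and is deliberately excluded from any claim about
published loop counts. Cluster calling follows the study rule exactly:
a qualifying bin holds ≥5 loop anchors, a qualifying circular 3-bin
window holds ≥6; qualifying sets sharing a bin merge transitively
(whether published clusters could merge was unstated; transitive
merging is the deterministic choice). Anchors are normalized so
anchor2 lies clockwise of anchor1 along the shorter arc.

## Permutation machinery

Segment shuffles preserve the number and length of segments and place
them uniformly at random without overlap. Placement is constructive —
a random length order, a uniformly random composition of the free
space into gaps (stars-and-bars), and a random rotation — which makes
every valid arrangement equally likely and never fails when packing is
feasible; a rejection sampler was considered and dropped because its
acceptance probability collapses for many segments. Loop shuffles
preserve each loop's circular anchor separation and reposition
anchor1 uniformly. The empirical p-value is
`#{simulated ≥ observed}/n_reps` (or ≤ for direction "le") — the
published wording ("the same as the real observed value") is read as
"at least as extreme", with the direction explicit; granularity is
exactly 1/n_reps, and p = 0 prints as "< 1/n_reps". Under a null
statistic the p-values are uniform (KS-checked in the acceptance
suite).

Gene–segment classification is three-way: fully contained in one
segment ("inside"), overlapping no segment ("outside"), anything else
("both"); "both" genes are excluded from Wilcoxon and Fisher
computations, matching the three-way partitions the statistics are
built from.

## Track statistics

RPKSP divides each gene's reads-per-kilobase by the mean RPK of the
spike-in organism's genes, so it is invariant to any depth factor
applied jointly to sample and spike-in; the window-level variant
divides raw window counts by the mean raw spike-in window count.
Wilcoxon comparisons use the two-sided rank-sum test (exact for small
samples). The Fisher test is two-sided by the probability-mass rule
(sum of tables with point probability ≤ the observed's), with the
conditional-MLE odds ratio; this convention is stated because mid-p
variants differ. Expression deciles cut at the 10th/90th percentiles
and include all genes tied at the cut. Origin-distance analysis uses
gene midpoints (whether published analyses used midpoints or starts is
unstated; midpoints are the symmetric choice).

MFA normalization fits counts on GC fraction by ordinary least squares
and applies `n_norm = n_obs − (n_fit − n_mean)`; by construction the
post-normalization GC slope is 0 (to machine precision) and the count
mean is preserved exactly. Constant-GC input degenerates to the
identity with a flag. The display moving average is circular with a
50-bin (50 kb) default window — the published figures show "a moving
point average" without a stated window. Origin localization
(`find_origins`) takes the top smoothed peaks with non-maximum
suppression, then refines each by intersecting straight lines fitted
to the two descending flanks (from 5 bins away out to 80% of the
half-arc toward the neighboring peak): the replication gradient is
linear in origin distance, so the apex is the flank intersection. At
the default simulated coverage (5,000 reads per 1 kb bin, i.e. a
realistically multiplexed sequencing run) the mean localization error
is ~1.5 kb; individual realizations can be off by up to ~4 kb because
the tent apex is locally flat relative to counting noise — a physical
limit of any apex estimator at this depth, which is why the package
reports recovery as a mean error.

ChIP enrichment is (chip/total_chip)/(input/total_input) per 500 bp
window, replicates averaged arithmetically, zero-input windows masked.

## Synthetic generator

`simulate_contacts` draws independent Poisson counts on the upper
triangle (mirrored) around
`λ_ij = c·(1+d_ij)^(−α)·β_CID^[same CID]·β_HEID^[both HEID]·γ^[loop]`,
with `c` set so the expected total matches the requested depth.
Defaults are the study-scale conditions: a 1,669,694 bp circle at 3 kb
bins (557 bins), 19 domains with a minimum length of 8 bins (mean ~29,
matching a ~30-bin average domain), decay exponent α = 1, domain boost
3, compartment boost 2, loop boost 5 painted on a 1-pixel radius
(loops are near-punctate at 3 kb bins). The compartment covers 20% of
the circle as 4 dispersed segments: a single contiguous block would
produce no long-range plaid signal (and matrix balancing largely
absorbs a lone block's marginal excess), whereas the real compartment
is a set of loci spread around the chromosome — multiplicity is what
the eigenvector method detects. Poisson (not negative-binomial) noise
is the simplest model consistent with count data.

`simulate_expression` tiles non-overlapping genes with log-normal
lengths clipped to [200, 6000] bp and draws Poisson counts around a
log-normal mean (a Poisson-log-normal mixture: integer counts whose
mean is multiplied by `expression_effect` — default 8 — for genes fully
inside the compartment). Spike-in genes are independent of the planted
structure. `simulate_tracks` gives MFA coverage decreasing linearly
with circular distance to the nearest origin, modulated by
`1 + gc_slope·(GC − mean GC)`, and ChIP counts coupled to a
standardized log-expression track elevated in the compartment, with a
flat matched input.

What the generator does *not* emulate: read-level artifacts
(restriction-fragment geometry, dangling ends, PCR duplicates — pair
filtering is out of scope), overdispersion beyond Poisson-log-normal,
operon structure or strand-dependent expression, condition-dependent
reorganization. Passing recovery tests therefore demonstrates the
correctness and statistical behavior of the estimators under the
stated generative model, not their performance on every artifact of
real libraries.

## Determinism and problem sizes

Every stochastic component takes an explicit seed or `numpy` Generator;
pipeline runs are byte-reproducible modulo timing metadata. The test
and acceptance suites use 557-bin genomes at depth 10^6 with 10–20
simulation replicates, 200-bin matrices for normalization contracts,
and 200–500 outer replicates for permutation calibration — sizes at
which every statistical check is stable from run to run while the full
suite completes in well under a minute on one core.

## Known limitations

* The uncentered-PC1 and directional-preference definitions are
  substitutes for formulas living in prior literature that the source
  study cites but does not restate; they are validated against planted
  truth only.
* `.cool` input is not supported; matrices travel as text.
* The loop detector is not a substitute for a dedicated caller on real
  data.
* Differential-expression significance (shrinkage estimators, adjusted
  p-values) is out of scope; only raw log fold changes are computed.
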