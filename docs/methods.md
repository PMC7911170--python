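# Methods

## Counting model

Motifs are plain substrings over {A, C, G, T}; for each sequence and each
k the counter slides a length-k window one position at a time (0-based,
half-open windows internally; motif names are plain strings, so no
coordinate convention leaks into outputs). Windows are overlapping, not
disjoint: only overlapping counts satisfy the constituent identities the
Markov expectation relies on. Any window containing a letter outside
{A, C, G, T} — IUPAC ambiguity codes are accepted at load time, since real
viral genome sets contain Ns — is dropped from both the numerator and the
window total, so an ambiguous position removes at most k windows and never
biases frequencies. Only the forward strand is profiled: sequences are
analyzed exactly as deposited, with no reverse-complement aggregation and
no circular wrap-around (many viral genomes are circular but are deposited
linearly; wrap-around would add k−1 windows out of ~3,200 and was judged
not worth the convention ambiguity).

The observed frequency divides each motif's count by the number of *counted
windows* of that length, not by the number of distinct motif types: only
that denominator makes frequencies at a fixed k sum to 1 and matches the
observed-probability role the expectation formula requires. A sequence with
no valid window at some k yields a degenerate all-zero profile, flagged and
warned about rather than rejected, so mixed-quality inputs survive a run.

## The D-ratio and its null

The maximal-order expectation P_exp(m) = P_obs(prefix)·P_obs(suffix) /
P_obs(interior) conditions on all but one position of the motif: first
order for 3-mers and second order for 4-mers, and the same pattern is
extended to 5-mers (third order) because the two published orders are
visibly the k = 3, 4 instances of one formula. Dinucleotides use the
zeroth-order product of base frequencies; D of a single base is identically
1 and is not computed. Each order uses its own window count (L−k+1 differs
across orders); the small boundary mismatch this induces is O(1/L) and is
the standard convention.

If P_exp is zero the D-ratio is undefined and reported as `None`, never as
infinity or NaN. Feature-matrix assembly imputes undefined values as 0 and
records how many were imputed (`n_imputed` on the matrix, echoed in the CLI
manifest), keeping matrices finite while preserving an audit trail. The
denominators always come from the same sequence's own profiles — the score
is per-sequence, not pooled across a dataset.

Under a stationary order-(k−2) chain with strictly positive transitions the
estimator is asymptotically unbiased: the calibration experiment (100
replicates of 10,000 nt) finds every 3- and 4-mer's replicate-mean D within
[0.95, 1.05] both for iid-uniform sequences and for sequences from an
order-matched chain. The residual deviation (~0.03–0.04 at the rarest
4-mers) is the Monte Carlo error of a ratio estimator at expected counts of
a few tens per sequence, which is why the calibration chains are kept mild
(Dirichlet(20) rows, all transitions within roughly 0.1–0.4): a strongly
skewed chain starves rare motifs of counts and the experiment would measure
sampling noise instead of the model.

## Feature matrices and normalization

Rows follow input order; columns are grouped by ascending k and
lexicographic within k, and are name-addressable so motif subsets (by
explicit names, by length, or their union) are unambiguous. Normalization
is global max-abs scaling — the whole matrix divided by its single largest
absolute entry — rather than per-column scaling, preserving the relative
magnitudes of motifs against each other; it is idempotent and an all-zero
matrix is left unchanged with a warning. The pipeline applies subsetting
before normalization, so the scale is that of the features actually
analyzed.

## Clustering

The iterative algorithms are delegated to scikit-learn; the hierarchical
step to scipy. Fixed hyperparameters, all overridable and all recorded in
the result's `params`:

* **k-means** — k-means++ seeding, 10 restarts, best inertia kept;
  Euclidean assignment; explicit seed (default 0).
* **PCA + k-means** — max-abs normalize (if not already), project onto
  `n_components` = 2 mean-centered principal components (full SVD), then
  k-means in the embedding. Component signs follow a deterministic
  convention: the largest-magnitude loading of each component is positive.
* **mean shift** — flat kernel; when no bandwidth is given it is estimated
  as the mean distance to each point's (0.3·n)-th nearest neighbour
  (quantile 0.3), so the cluster count emerges from the density estimate;
  identical points (zero bandwidth estimate) collapse to one cluster with a
  warning.
* **clustermap** — agglomerative clustering of rows and of columns,
  Euclidean metric and average linkage by default, leaves ordered by the
  standard dendrogram traversal with optimal ordering disabled for
  determinism. Single linkage is available as the documented option whose
  merge heights are exactly the sorted edge weights of the minimum spanning
  tree of the distance graph (verified against an independent Prim
  implementation); average linkage is shipped as the default because it is
  the standard choice for clustered heatmaps of composition data.

Clustering quality in tests is always measured by the adjusted Rand index,
which is invariant to label permutation.

## Synthetic data: what it does and does not emulate

The generator produces iid sequences with a chosen base composition,
stationary Markov chains of arbitrary order (uniform start, row-stochastic
transition table), and planted-cluster datasets — groups of iid sequences
whose compositions differ by a controlled amount, with ground-truth labels.
The demo preset uses five compositions spanning GC 0.2–0.8 in steps of
0.15, 20 sequences each, length 3,200 (the genome-length scale of a small
circular DNA virus): at L = 2,000–3,200 the per-base sampling noise is
~0.01, so adjacent groups are separated by roughly 7σ and recovery tests
are decisive rather than marginal.

These fixtures establish that the estimators and the clustering stack do
what their contracts say under known models. They do not emulate real viral
evolution — no phylogenetic correlation between sequences, no indels,
recombination, mutational hotspots or genotype-specific motif signatures —
so passing tests show correctness of the computation, not that any
particular virus dataset will separate into clean clusters. One property of
real analyses the fixtures expose deliberately: because the D-ratio removes
exactly the composition signal the iid fixtures differ by, planted
*composition* clusters are recoverable on the frequency basis but not on
the D-ratio basis (ARI ≈ 0.1). Separating groups on the D-ratio basis
requires genuinely different dependence structure, not merely different
base frequencies.

## Numerical and interface choices

* Frequencies and D-ratios are plain double arithmetic; worked examples
  agree with hand-derived fractions to 1e-12 and the composed pipeline
  agrees with a monolithic brute-force implementation to the same
  tolerance.
* Matrix CSVs render floats with 12 significant digits and round-trip to
  better than 1e-9; re-running a command with the same manifest reproduces
  output files byte-for-byte.
* k-means nearest-center ties break toward the lowest cluster index
  (scikit-learn's argmin convention).
* Heatmaps of D-ratio matrices use a diverging colormap centered at D = 1,
  so over- and under-representation are visually symmetric; frequency
  matrices use a perceptually uniform map. Degenerate (constant) matrices
  widen the color range instead of crashing.
* The 3-D bar chart refuses matrices beyond 50 × 64 unless explicitly
  overridden — beyond that the bars are unreadable and subsetting is the
  right tool.
* The maximum motif length defaults to 5 (the 4^k column count grows
  exponentially) but is a parameter, not a constant.

## Known limitations

* No canonical (strand-collapsed) k-mers, gapped motifs, or
  significance tests for over-/under-representation; the D-ratio is a
  descriptive statistic here.
* Lower-than-maximal-order factorizations of the expectation exist but are
  not exposed; the maximal-order form is the implemented path.
* Counting is dense in 4^k and aimed at viral-genome scale (kilobases to
  a few megabases), not chromosome-scale streaming.
* FASTA only; protein input is rejected (the alphabet is nucleotide by
  construction), and compressed files must be decompressed first.
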