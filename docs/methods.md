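# Methods

This note documents the statistical procedures, the synthetic data model,
the numerical choices and the known limitations of `evintegra`.

## Study design and data model

The package assumes a factorial design: cell line × culture condition
{2D, 3D} × entity {cell, EV} × biological replicate. Small-RNA abundances
are FPKM (nonnegative; zeros are true zeros), protein abundances are
normalized reporter intensities (nonnegative; an empty/`NA` cell is
*missing*, distinct from zero — proteomics values can be absent without
being absent from the sample). miRNA and protein matrices live in separate
objects so their identifier namespaces cannot collide; the only join
between them is the explicit target edge list.

## Detection and set analysis

A feature is *detected* in a group when its value strictly exceeds a
threshold (default 0, i.e. FPKM > 0) in at least `min_replicates`
replicates (default 1, i.e. detected in at least one biological
replicate). Both defaults are the conventional expressed-call for EV
small-RNA data; the comparisons are strict (`>`), so a value exactly at
the threshold never counts. Detection is monotone: raising either
parameter can only remove calls.

Venn regions partition the detected features by their exact detection
signature across groups; regions are disjoint by construction and their
union is the set of features detected anywhere. Grouping defaults to
(condition, entity) pooled over cell lines — the pooling used for
two-cell-line Venn diagrams — with per-cell-line grouping available
through the same argument. Replicates are pooled within each group when
the detection call is made, after any cell-line pooling; since the call
is "any replicate above threshold", the two pooling orders coincide for
the default rule.

Biotype composition reports, per group, the percentage of detected
features in each small-RNA class (closed label set: miRNA, misc_RNA,
mt_tRNA, ribozyme, rRNA, scaRNA, scRNA, snoRNA, snRNA). Percentages sum
to 100 per group; a group with no detections is reported as undefined
(NaN), never as zeros.

The housekeeping filter looks for qPCR normalization candidates:
expressed in all samples (value > 0), well detected in all samples
(value > 10 000) and not differentially expressed, read strictly as
max/min ≤ 1.5 over *all* samples, which guarantees every pairwise ratio
lies in [2/3, 1.5] ⊂ [0.5, 1.5]. A `group_mean` mode bounds the ratio of
group means instead. An empty candidate list is a legal, and in practice
common, outcome.

## Fold changes, scaling and clustering

Fold change is the ratio of group means, condition B over condition A
(convention: 3D over 2D). Missing values are excluded from the means. A
zero denominator is either reported as `undefined_zero` (default — no
silent pseudo-counts) or resolved by adding a stated epsilon to both
means. Reciprocity holds for all defined records: FC(a→b)·FC(b→a) = 1.

Row Z-scores use the sample standard deviation (n−1), matching common
heatmap-scaling implementations; constant rows are emitted as all-missing
with a warning.

Hierarchical clustering is agglomerative under Euclidean distance with
single, complete or average (default) linkage via Lance–Williams updates.
It is implemented in-package because the required determinism — ties in
the minimum inter-cluster distance broken by the lowest-index pair — is
not guaranteed by library implementations; on tie-free data the merge
heights agree with `scipy.cluster.hierarchy.linkage` (verified in the
test suite). These linkages are monotone, so merge heights never
decrease. The implementation is O(n³) and intended for the matrix sizes
of this analysis (tens to a few hundred items per axis).

Top-k marker selection ranks features by ascending p-value (ties:
|log2FC| descending, then feature id). The significance measure behind
"most significantly different" is configurable and never hard-coded:
default Welch's t on log2 abundances (small-n proteomics convention),
with the exact Mann–Whitney as the alternative. Zero-variance features
with identical group means get p = 1 by convention. Whether abundances
are log-transformed before testing is likewise a flag (`log2_transform`,
default on).

qPCR relative expression follows the comparative method:
ΔCT = CT(3D) − CT(2D), relative expression 2^−ΔCT, reported per
replicate pair rather than averaged. Densitometry ratios are
(signal/control)/(signal_ref/control_ref) with the loading control
required to be positive.

## Enrichment statistics

**ORA.** For a query of size n drawn from a universe of size N and a
category with K members in the universe overlapping the query in k,
p = P(X ≥ k) under the hypergeometric law (one-sided over-representation
only; depletion is not tested). A category is flagged significant only
when nominal p < 0.05 *and* k ≥ 2 — single-member overlaps are never
called, however small their p. Benjamini–Hochberg q-values are computed
alongside but deliberately not used for that flag, which mirrors the
nominal-p reporting convention of miRNA enrichment tools; q is there for
non-legacy use.

**Running-sum enrichment.** Features are ranked (descending mean
abundance by default, log2FC optionally; ties by feature id). Walking
the list, the running sum gains +(N−k) at each of the k category members
and −k elsewhere, so it ends at 0 and stays integer-valued. The statistic
is the two-sided maximum deviation S = max|RS| (members can concentrate
at either end of the list); a one-sided option is provided. The exact
p-value P(S ≥ s) under uniform random placement of the k members uses the
identity RS(i) = jN − ik (j = members among the first i positions): a
dynamic program over states (i, j) restricted to |jN − ik| < s counts the
placements whose path never reaches ±s, and
p = 1 − #surviving/C(N, k), evaluated with Python integers and one exact
rational division (no floating-point error accumulation). Cost is
O(N·k); N in the hundreds is instantaneous. Categories with fewer than
two members in the ranked list are skipped. The DP is verified against
full enumeration of all C(N, k) placements for every N ≤ 12, k, and s in
the test suite, and its null rejection rate at α = 0.05 is calibrated by
permutation (10 000 permuted rankings at N = 164, k = 20 give a rate
within 0.04–0.06; the exact attainable level there is 0.0491 because the
statistic is discrete).

## Exact Mann–Whitney U

U is computed from mid-ranks. For n1 + n2 ≤ 20 with no ties, the null
distribution of U is built by the standard counting recurrence (largest
rank from sample 1 contributes n2 to U1) and the two-sided p is
P(U ≤ min(u, n1n2 − u)) doubled and capped at 1 — symmetric and
deterministic. With ties or larger samples the normal approximation with
tie correction and 0.5 continuity correction is used, and the method is
recorded in the result. The exact route is verified against enumeration
of all C(n1+n2, n1) labelings for n1, n2 ≤ 7 and cross-checked against
`scipy.stats.mannwhitneyu(method="exact")`. Note the exact test is
discrete: at n = 5 vs 5 the attainable two-sided levels near 0.05 are
{0.0317, 0.0635}, so the null rejection rate at α = 0.05 is exactly
8/252 ≈ 0.032 — conservative, never anti-conservative.

EVs-per-cell is the per-replicate ratio of NTA particle count to the
total number of cells retrieved from the culture (whatever the caller
counts as retrieved — e.g. including cells recovered from the
conditioned-medium low-speed pellet); condition summaries are mean ±
sample sd, with a warning below four replicates. NTA size summaries
report the arithmetic mean and the center of the most populated
histogram bin (nearest-center binning, half-way points up, ties to the
smaller center).

## Integration network

Edge criteria: (1) the target edge list links miRNA→protein, filtered to
`strong_only` or `strong_or_weak` (default — both grades count);
(2) anti-correlated deregulation. With two biological replicates a
correlation coefficient is not estimable, so "negatively correlated" is
operationalized by default as strictly opposite non-flat directions of
the 3D-vs-2D log2 fold changes at a magnitude threshold (default 0.5
log2 — an artifact default, not protocol-specified). A `pearson` mode
(r ≤ r_max < 0 across ≥ 4 matched samples) exists for richer designs.
All parameters are recorded in the network's provenance; no default is
presented as the upstream study's own setting, which is unstated.

The miRNA direction is taken from cells, and when a secondary EV fold-
change table is supplied, a strictly conflicting EV direction flattens
the call (the conservative reading of "consistent where detected in
both"); the protein direction comes from EVs, the only proteome measured.
Clusters are connected components of the bipartite graph, ordered by
size then lexicographically smallest node, with shared-target proteins
(degree > 1) annotated. Raising the magnitude threshold can only remove
edges.

## Synthetic data generator

The generator emulates the study conditions, not any particular dataset:

| parameter | default | why |
|---|---|---|
| n_mirna / n_protein | 200 / 150 | desk-scale stand-ins for ~10³ small RNAs / 430 proteins |
| replicates per group | 2 | two biological replicates per design cell |
| planted pairs | 20 | enough for stable precision/recall estimates |
| miRNA effect (3D) | +1.5 log2 | planted upregulation in 3D cells and EVs |
| protein effect (3D EV) | −1.0 log2 | planted downregulation of targets in 3D EVs (optionally also cells) |
| noise sd | 0.25 log2 | per-measurement log-normal noise |
| EV zero-inflation | 0.4 | EV small-RNA dropout (far fewer species detected in EVs than cells) |
| baseline log2 mean/sd | 7 / 2 | right-skewed FPKM-like abundances |
| exclusive fraction per group | 0.05 | material for the Venn/exclusivity analysis |
| decoy edges | 200 | negatives for network precision |
| other small RNAs | 30 | non-miRNA biotypes for composition tables |

Abundances are log-normal with multiplicative effects (positive,
right-skewed, like FPKM and reporter intensities). Zero-inflation applies
only to EV small-RNA samples; planted and group-exclusive features are
exempt so the ground truth stays exactly recoverable. Exclusive features
are keyed on (condition, entity) groups pooled over cell lines, matching
the Venn construction. The protein matrix covers EV samples only. No
quantitative noise model for EV RNA exists upstream; these defaults are
explicit stand-ins and every one is configurable. Identical seeds give
bit-identical output (single `numpy.random.default_rng` stream).

What the generator does **not** emulate: library-size/normalization
artifacts, batch effects, correlated features, missing-not-at-random
proteomics dropout, cell-line-specific effect sizes. Passing recovery
tests therefore shows the pipeline's logic is correct under its stated
model, not that real EV data will yield 0.9+ precision.

Companion generators produce category databases (one category = the
planted set, plus uniform random null categories), paired qPCR CT tables
(CT = 35 − log2(mean FPKM) + noise, so planted miRNAs show 2^−ΔCT > 1)
and EV-yield records (log-normal ratios with set means and CV; the demo
uses 2 500 vs 10 000 particles/cell at CV 0.3, n = 5 — a 4-fold 3D excess).

## Pipeline and reproducibility

`run_pipeline` executes detection → differential → enrichment → network
(→ yield when records exist) from one YAML config or a synthetic
section; every stage writes plain-text tables and the manifest records
parameters, package versions, the seed and sha256 checksums of every
output. All randomness derives from the single root seed
(per-stage seeds are fixed affine functions of it), so a rerun at the
same seed is bit-identical; the manifest differs only in its timestamp.
A failing stage is recorded in the manifest before the error propagates.

Problem sizes used in the verification suite — enumeration oracles at
N ≤ 12 (running sum, hypergeometric) and n ≤ 7 per arm (Mann–Whitney),
10 000-replicate null calibrations, ten to twenty generator seeds for
recovery — were chosen as the smallest sizes at which the checks are
exhaustive or statistically stable; all run in seconds.

## Known limitations

- No moderated-variance (empirical-Bayes) differential testing, batch
  correction or proteomics imputation; the top-k test is a plain Welch t.
- The O(n³) clustering is not meant for thousands of items per axis.
- ORA tests over-representation only.
- The opposite-sign network criterion discards magnitude information
  beyond the threshold and cannot express partial anti-correlation.
- Graphical output (heatmaps, Venn diagrams, network layouts) is out of
  scope; results are emitted as tables/JSON/GraphML for external viewers.
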