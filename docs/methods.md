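# Methods

## Skeleton estimation

The conditional-independence test is the Fisher-z test on partial
correlations: for variables *i*, *j* and conditioning set *S*,
ρ(i,j|S) is obtained by inverting the correlation submatrix over
{i, j} ∪ S (a classical recursion over single conditioning variables is
implemented as an independent cross-check; the two routes agree to
1e−10 on random SPD matrices). The statistic
z = √(n−|S|−3)·atanh(ρ) is compared to the two-sided normal quantile
at level α; ρ is clamped to ±(1−1e−12) before the transform. When
n−|S|−3 ≤ 0 the test is unavailable and the edge is retained —
conservative by design: lack of power never manufactures independence.
A singular submatrix or a zero-variance variable raises a
degenerate-input error naming the offender.

The search is **PC-stable**: at each conditioning-set size ℓ the
neighbourhoods consulted are a snapshot taken before any removal at
that level, so the result does not depend on variable order. Subsets
of adj(i)\{j} and adj(j)\{i} are enumerated in lexicographic order and
the first separating set found is recorded; since only the skeleton is
consumed (no orientation, no v-structures), the choice of sepset is
immaterial but kept deterministic. There is no default cap on ℓ; a
`max_order` cap is exposed for speed. The stable variant was chosen
because the aggregation scheme assumes run-to-run comparability;
order-dependence of classic PC would make tile results depend on
arbitrary within-tile gene order.

## Expansion engine

Tiles are **resampled at every iteration**. The F_rel denominator
(# runs with the gene in the input) is only informative when tile
membership varies between runs; a `fixed_tiles` flag provides the
frozen-plan variant. Because the tiles partition the non-seed genes,
the denominator equals the iteration count for every gene, and the
last tile is simply left smaller rather than padded — padding would
inflate input counts asymmetrically for the padded genes.

The seed's Pearson correlation with every gene is computed once over
all samples (not per tile) and stored in each record, so that network
edges can be signed by anticorrelation downstream. Ranking is by
descending F_rel, ties broken by larger |Pearson r| and then gene ID —
deterministic, with the secondary key a biologically sensible signal.

Randomness is a single root seed; iteration *k* uses the stream
`SeedSequence(entropy=root, spawn_key=(k,))`. Iterations are therefore
independently reproducible and may run concurrently (`n_jobs`), with
results identical to sequential execution. Internally the gene universe
is put into sorted order before any correlation or tiling computation,
which makes the output byte-identical under permutation of the input
matrix's row order (floating-point dot products in a BLAS matrix
product otherwise differ in the last ulp depending on row position).

## Network tools

"Mutual presence" is read strictly: an edge requires each seed in the
other's trimmed list; a `one_sided` flag relaxes this (weight = the
single available F_rel). Edge sign is negative when *either*
direction's stored correlation is negative — correlation is symmetric
up to sampling noise, so discordance (which is logged) is resolved
conservatively toward flagging anticorrelation. Weight classes cut the
displayed band [f_min, 1] into equal thirds
(solid ≥ f_min + 2/3·(1−f_min), then dashed, then dotted), anchored
only by the band's endpoints. Aggregation (`expand_network`) orders
candidates by the maximum F_rel over source lists (the mean is also
reported): max preserves "best evidence from any seed".

## Enrichment and promoters

The enrichment statistic is the classic per-term one-sided
hypergeometric tail (equivalently the one-sided Fisher exact test of
the 2×2 study/population × in-term/not-in-term table) on true-path
propagated annotations, ranked by raw p-value; a Benjamini–Hochberg
adjusted column is added because any multi-term report needs
multiplicity context, but the raw-p ordering is kept as the primary
ranking. Decorrelating variants (elim/weight-style) are deliberately
out of scope: the classic test is exactly reproducible against
brute-force enumeration, which the test-suite and acceptance script do
for every table with population ≤ 30.

Promoters are anchored at the annotated gene start (no TSS
refinement): plus strand [start−L, start−1], minus strand the reverse
complement of [end+1, end+L], L defaulting to 1000 bp, clipped at
chromosome boundaries and preserving the genome's case. OBO parsing
uses `obonet` (is_a + part_of as the parent relation); FASTA access
uses `pyfaidx`; GFF3 uses `gffutils`.

## Synthetic benchmark

The generator samples a linear-Gaussian structural equation model
X_j = Σ_{i∈pa(j)} w_ij X_i + ε_j, ε_j ~ N(0, σ_j²), in topological
order from an Erdős–Rényi DAG drawn over the upper triangle of a
random topological order. Defaults: |w| uniform in [0.5, 1.5] with
random sign, σ = 1. The magnitude floor keeps the model comfortably
faithful — with weights near zero, true edges would be statistically
invisible at benchmark sample sizes. Sample covariance converges to
the analytic (I−W)⁻ᵀ D (I−W)⁻¹, which the suite checks at n = 10,000.

Named fixtures with hard-coded seeds define the standard instances:
`tiny-collider` (X→Z←Y), `chain-5`, `dag-20` (20 genes, edge
probability 0.15), `dag-50` (50 genes, edge probability 0.08). The
standard recovery benchmark runs the dag-50 fixture with 1000 samples,
200 iterations, tiles of 25 and α = 0.05 — sizes chosen so the full
suite and the acceptance script each complete in about half a minute
on one CPU while still exercising multi-tile, multi-iteration
aggregation.

What the generator does **not** emulate: the noise structure of real
expression compendia (batch effects, heteroscedastic counts,
platform mixtures), probe-mapping ambiguity, or non-linear regulation.
Passing benchmarks therefore demonstrate correctness of the machinery
under its own Gaussian, faithful, linear assumptions — not performance
on real transcriptomes.

### Known limitation: path cancellation

Even in the linear-Gaussian regime, a DAG with signed weights can put
a true direct neighbour close to marginal independence when parallel
directed paths nearly cancel its correlation (in the dag-20 fixture,
one edge of weight −0.98 has population correlation 0.15). Such
neighbours receive genuinely low F_rel at any sample size — visible in
the worked example, where the weak neighbour ranks 8th. This is a
property of relative-frequency scoring under near-unfaithfulness, not
an implementation artifact; the regression tests freeze the measured
behaviour rather than an idealised one.

## Model/results interface

The expansion engine is additionally exposed in the fit/results idiom
of statistical modelling packages: `SeedExpansion(matrix, seed)` holds
the data and seed, `.fit(...)` runs the expansion and returns an
`ExpansionResult` with the records table, `summary()` and
`recovery(truth)` diagnostics. The file-level tools (`simulate`,
`expand`, `create-net`, `expand-net`, `enrich`, `promoters`) are thin
CLI wrappers over the same library functions; every output carries a
provenance header with the tool version, resolved parameters and RNG
seed.
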