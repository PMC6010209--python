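# Methods

This note records the models implemented in dropkit, the estimators and
numerical choices behind them, what the synthetic generator does and does
not emulate, and the known limitations. Symbols follow the README: `L` UMI
length, `m` pool size, `p(u)` UMI probability, `S_g` distinct UMIs of a
gene in a cell, `R`/`r` read counts of a target UMI and a smaller neighbor,
`q` the mean Phred score of a neighbor's distinguishing position.

## UMI collision correction

For `n` molecules drawn independently from a UMI distribution, the expected
number of distinct UMIs is `E[k|n] = Σᵢ (1 − (1 − pᵢ)ⁿ)`. The collision
table inverts this curve: `n(k)` is the molecule count at which the
expected distinct count equals `k`. The table is built stepwise from
`n(1) = 1`; each step uses the expected number of draws until a new
distinct UMI, `1 / p(u′∉G_k)` with `p(u′∉G_k) = Σᵢ pᵢ(1 − pᵢ)ⁿ`, as a
predictor and Newton iterations on `E[k|n] = k` as a corrector
(`d E[k|n]/dn ≈ p(u′∉G_k)`, so the predictor is itself an approximate
Newton step). Solving to convergence matters: the bare unit-step recursion
is an Euler scheme whose discretization error reaches several percent for
small pools (m = 64), while the converged inverse agrees with the uniform
closed form `n = −m ln(1 − k/m)` to 0.8% there and far better for larger
pools. The table stops at `k = m − 1` (the inverse diverges at saturation)
or when a step exceeds a configurable cap; counts are adjusted entry-wise
and zeros are untouched. When `k/m` is below a negligibility threshold
(default 0.01) the uniform helper returns `k` unchanged.

The empirical model puts mass only on observed UMI sequences (unobserved
sequences have unknown probabilities); the uniform comparator uses the full
`4^L` pool. The distribution is estimated once, before error filtering, as
occurrence counts over all cell–gene molecules. Estimating it from distinct
molecules slightly flattens the true pool distribution (popular UMIs are
collision-merged within genes more often); at the saturations exercised
here the effect on `n(k)` is below the Monte-Carlo validation tolerance.

## Bayesian UMI error filtering

For each target UMI `U` (processed in descending read order within each
cell–gene group) the Hamming-1 neighborhood splits into `N_S` small
neighbors (`r ≤ R`, the error candidates) and `N_L` larger ones. The
unnormalized probability of a split of the candidates into erroneous
(`Ω_E`) and real (`Ω_¬E`) sets is the product of

* quality likelihoods: `Π_{u∈Ω_E} p(q_u|Err) · Π_{u∈Ω_¬E} p(q_u)` — the
  marginal `p(q)` stands in for `p(q|¬Err)` because a non-error of `U` may
  still be an error of some other UMI;
* the real-count prior `p(#Real = |Ω_¬E|)`, read from an occupancy model:
  picking `S_g − 1` molecules from the pool, each is adjacent to `U` with
  probability `p_adj(U) = Σ_{u∈Adjacent(U)} p(u)`, and a new adjacent
  sequence occupies one of `K = 3L` slots. The chain over states
  (distinct adjacent count, picks) is evaluated by dynamic programming,
  cached over `p_adj` quantized at Δp = 0.01 (p_adj = 0 maps to the first
  bin). Conditioning on `N′ ≥ N_L` and truncating to `0..N_S` reduces, after
  normalization, to `p(#Real = n) ∝ p(N′ = n + N_L | S_g − 1 picks)`;
* the error-count term `Σ_{i=|Ω_E|}^{N_S} p(#Collisions = i − |Ω_E|) ·
  p(#Errors_T = i)`. Total error reads over a candidate prefix follow a
  binomial with `R + r_E` trials and per-read rate `p_E` (the `i = 0` term
  is the probability of zero error reads in `R` trials); collisions among
  error events reuse the occupancy table with adjacency probability 1.

Candidates enter `Ω_E` ordered by ascending reads, then descending quality
likelihood ratio `p(q|Err)/p(q)`, then lexicographically (for determinism);
evaluating only the nested prefixes of this order reduces the search from
`2^|Ω|` to `|Ω| + 1` splits, and the posterior is normalized over those
nested splits. The prefix at the MAP error count is deleted and its reads
are reassigned to `U` (reads are conserved; configurable in principle, but
conservation is the invariant the test suite asserts). Groups are
re-processed until a pass deletes nothing, capped at 10 iterations.

### Quality model and the per-read error rate

Training data are genes containing exactly two adjacent UMIs: the smaller
member (by reads, then distinguishing-position quality, then sequence) is
treated as the error. `p(q)` pools the distinguishing-position qualities of
all ordered adjacent pairs, quantized to at most `k = 15` support points
(uniform quantiles, near-duplicates merged, every value rounded to the
nearest support point); `p(q|Err)` is the quantized histogram of the
training errors, with a 0.5 pseudocount per bin so that unseen quality
levels never produce hard zeros.

The plug-in rate `p_E = Σr / Σ(r + R)` over the training genes estimates a
*conditional* quantity — the training set exists only when at least one
error read occurred — and it is contaminated by pairs that are adjacent by
chance. Both effects are negligible for deep libraries (many reads per
molecule, error-dominated adjacency), which is where the plug-in form is
appropriate, and the plug-in value is what `train_quality_model` returns
when no UMI distribution is supplied. Given a distribution, two corrections
are applied:

1. **Chance decontamination.** The probability that two independent
   distinct draws are adjacent, `p_pair = Σ_u p(u) p_adj(u) / (1 − Σ_u
   p(u)²)`, times the observed number of non-adjacent two-UMI genes,
   estimates the number of chance pairs in the training set. Their expected
   contribution (read moments from the non-adjacent pairs; quality from the
   marginal) is subtracted from the conditional histogram and the read
   moments.
2. **Zero-truncation correction.** The conditioning on ≥ 1 error read is
   undone by solving `r̄ = n̄ p / (1 − (1 − p)ⁿ̄)` for `p`. When the
   de-contaminated mean error reads are at the truncation floor (`r̄ ≤ 1`),
   or when chance pairs are estimated to be the majority of the training
   set (short, saturated UMIs), the rate is unidentifiable from reads and a
   conservative floor of 10⁻³ per read is used — conservative in the sense
   that it favors keeping molecules.

On the default synthetic library (generative rate 0.01/read, mean 4
reads/molecule) the uncorrected plug-in gives p_E ≈ 0.28 and the corrected
estimator ≈ 0.001–0.01; within that corrected range the method's ranking
against the baselines is insensitive to the exact value.

### Baselines

`cluster` drops a UMI with any adjacent neighbor of ≥ reads (equal-read
ties: the lexicographically smaller UMI survives — the classical rule is
silent on ties and determinism is required); `cluster-neq` requires
strictly more reads; `directional` requires more than twice the reads and
is evaluated once on the original group, which is already the fixpoint of
iterating the rule over the adjacency network since removals do not change
read counts. All filters reassign removed UMIs' reads along the chain of
dominating neighbors to a survivor.

## Cellular barcode merging

Compositions are per-cell maps gene → UMI set. The observed overlap of two
cells is `C_ij = Σ_g |S_{i,g} ∩ S_{j,g}|`; its expectation under
independence uses collision-adjusted set sizes `S′ = n(|S|)` and is
memoized per size pair. `C_ij` is modeled as Poisson(`EC_ij`) and the
p-value is the upper tail `P(X ≥ C_ij)`. Each barcode is tested against
candidates with at least as many molecules within Hamming distance 2
(neighborhood enumeration, not an all-pairs scan; unequal-length barcodes
are never candidates); p-values are Bonferroni-multiplied by the
candidate count (per-source scope; the family-wise framing of a single
merge decision), and the source merges into the candidate with the smallest
adjusted p-value below α = 0.01. Sources are processed small → large in one
pass; if a former target later merges itself, its sources are re-pointed to
the final target so the plan stays a forest. Merging relabels records and
re-aggregates, so gene–UMI sets union and reads are conserved.

The simple baseline merges into the largest strictly-bigger neighbor within
the radius; the whitelist method reassigns each unknown barcode to the
nearest valid barcode with at least as many molecules (equidistant matches
resolved by the composition test when a distribution is available, else by
size then lexicographic order), dropping barcodes farther than the radius
from every valid sequence.

The two-species audit removes cells under a minimum expressed-gene count,
assigns each cell the species with more molecules, declares the largest
`n_real` cells real, and reports the fraction of merges into real cells
that cross species — wrong by construction. At desk scale this fraction is
quantized by the small number of merges (one chance-level false merge among
~20 true ones is ~5%), so comparisons between methods use the ratio rather
than the absolute level.

## Cell quality classification

The log(size) vs log(rank) curve is concave over the large-cell region,
roughly linear through the cell/background transition, and convex as it
enters the background plateau. A smoothing spline (quartic, smoothing
`0.0025·n` — about 0.05 log-units of residual per barcode) estimates the
curvature; the near-zero band is 10% of the maximum |curvature|; the upper
threshold `t_U` is the size where curvature first returns to the band after
the concave region and the lower threshold `t_L` the size just before it
turns convex. Curves without this structure (linear, flat, or no convex
tail) raise an error directing the user to manual thresholds, which the
configuration accepts.

Initial labels: `low` below `t_L`; `high` for the largest 75% of cells
above `t_U` (size-ranked, so deterministic; a random 75% would be
seed-dependent); everything else `unknown`. Features are standardized by
median/MAD and reduced to three sparse principal components
(`sklearn` SparsePCA, sparsity penalty 1); class-conditional densities on
the scores use diagonal Gaussian kernels with the normal-reference
bandwidth per dimension, and the score is the equal-prior posterior of the
high class (the training set is size-biased, so empirical priors would be
meaningless). Extreme mitochondrial / intergenic fractions (beyond the 20%
trimmed mean plus four raw median absolute deviations) are relabeled low
*before* the final fit when the corresponding feature carries ≥ 5% of a
retained component's total |loading|, and otherwise force a score of zero
after scoring. Final selection keeps cells above `t_U` unless their score
falls below 0.1 and rescues cells below `t_U` whose score exceeds 0.9,
subject to a minimum expressed-gene count.

## Diagnostics

The edit-distance check pools pairwise Hamming distances within cell–gene
groups (groups above 10³ UMIs are subsampled with a seed to bound the
quadratic cost) and compares them against the Monte-Carlo distribution of
the distance between two independent draws from the UMI distribution
(closed form Binomial(L, 3/4) for the uniform pool); the summed per-distance
relative difference `|P − P*|/P*` summarizes over- and under-correction.
The adjacency-excess ratio divides observed Hamming-1 pairs by
`Σ_groups C(S,2) · p_pair` — the explicit independence null with the
distinct-draw correction described above.

UMI trimming shortens sequences and quality vectors from either end,
merging colliding records with read-weighted mean qualities — a natural
collision model. The trimming benchmark counts per (cell, gene), applies
each correction method and collision-adjustment mode to the trimmed data,
and reports percentage errors against full-length benchmark counts,
summarized per gene (entries summed over cells) with expression deciles of
the per-gene benchmark total. Per-gene summaries avoid a degeneracy of
per-entry medians at desk scale: most top-decile entries have no collision
at all, so the per-entry median rewards not correcting. The benchmark
filter must be near-exact at full length — the classical cluster filter
when full-length UMIs are long enough that chance adjacency is rare, the
Bayesian filter for saturated full-length data (the default here is
cluster; the validation protocol uses Bayesian because the 6-base library
is saturated).

## Synthetic data generator

The generator emulates, with per-molecule ground truth: a skewed UMI pool
(Dirichlet with concentration 2 over all `4^L` sequences, multiplied by
`1 + 3·(run−1)` where `run` is the longest homopolymer run — heavier tails
with more low-complexity mass, as in real libraries); power-law gene
expression (exponent 1, 60 genes); lognormal cell sizes (median 1000
molecules) over 24 cells with 480 background barcodes (median 25 molecules)
drawing from the pooled expression profile; shifted-geometric reads per
molecule (mean 4; halved for background); per-read UMI errors at rate 0.01
(uniform position and substitution; the parent always keeps one read), with
60% of error bases stamped with low quality (Q≈12) and 40% left at the
ordinary level (Q≈35), reflecting that a substantial minority of errors
arise before sequencing and are invisible to quality scores; barcode splits
rerouting about half the reads of ~20% of molecules from 30% of cells to a
fresh Hamming ≤ 2 child barcode; 8-base cellular barcodes — short enough
that Hamming ≤ 2 neighbors among a few hundred barcodes are common, the
regime in which composition testing matters (with 12-base barcodes and a
desk-scale barcode count the simple and Poisson methods are trivially
identical because no chance neighbors exist); damaged cells (15%) with a
severity latent in [0.5, 1] (healthy cells [0, 0.2]) driving quadratic
boosts of mitochondrial load and intergenic reads and a reduction in reads
per molecule — quadratic so healthy cells sit at the ambient baseline;
optional two-species gene labels with pure single-species cells.

What the generator does **not** emulate: PCR lineage structure (errors are
i.i.d. per read, not clonal), indel errors in UMIs or barcodes, doublets,
gene-specific UMI biases, positional quality profiles along the read, or
realistic transcriptome scale (dozens of genes, not tens of thousands).
Passing benchmarks on this data therefore demonstrates the correctness and
the comparative behavior of the estimators under the modeled error
processes, not end-to-end accuracy on a real library. Cell-quality
benchmarks use a larger, shallower configuration (150 cells, 1500
background barcodes, 300 molecules/cell) because the classifier needs at
least 20 labeled cells per class; with continuous severity, the score
separates damaged from healthy cells sharply (medians near 0 and 1) but
rank correlation with the latent within the healthy group is noise by
construction.

## Numerical choices and degenerate inputs

Duplicate record keys aggregate with read-weighted mean qualities; empty
input files yield empty datasets with a warning; non-ACGT sequences, ragged
UMI lengths and non-positive read counts are hard errors naming the row.
Matrix Market output uses 17 significant digits so real-valued matrices
round-trip exactly; cells are ordered by descending molecule count then
lexicographically, genes lexicographically. The DP prior grows its pick
dimension on demand and treats `p_adj` below the first quantization bin as
the first bin. A real-count prior with zero mass on the observed
configuration falls back to uniform over the support. All randomness flows
from explicit seeds; pipeline reruns with the same seed are byte-identical.

## Known limitations

* The collision table assumes i.i.d. draws from a fixed pool; within-cell
  amplification bursts violate this and are not modeled.
* The per-read error rate is a single constant; real error rates vary by
  position and cycle.
* The composition test treats genes independently; correlated expression
  (e.g., ambient contamination shared across barcodes) inflates overlaps
  and can produce occasional chance-level false merges, visible in the
  two-species audit at the ~1-merge level.
* The knee detector expects a two-regime rank curve; gradual or multi-modal
  curves need manual thresholds.
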