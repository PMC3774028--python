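# Methods

## Model and scoring

Network inference treats each gene in turn as a regression target. With
standardized expression rows (mean 0, unit Euclidean norm — so
cross-products are Pearson correlations), the coefficient vector of gene
*i* is grown by componentwise L2 boosting: each round proposes, for every
candidate predictor *j*, the shrunken univariate update
`Δβ_ij = ν · x_jᵀ r_i` (ν the shrinkage, `r_i` the current residual), and
accepts the single proposal maximizing the structure score

```
score_i = −log(RSS_i + ε) + log(C²)
```

The first term is a log-likelihood surrogate for the Gaussian regression
fit. The second is a scale-free network prior: weighted degrees
`d_j = Σ_m |β_mj|` are binned to integers ≥ 1, the empirical frequency
π(d) of each occupied bin is computed, and `C` is the Pearson correlation
of `(log d, log π(d))` over the occupied bins. `|C| = 1` (log-log
linearity, i.e. a perfect power law) gives the maximal prior `log C² = 0`;
any departure from linearity is a penalty. Taking π(d) to be literally
`d^−λ` would make `C ≡ −1` and the prior a constant, so the empirical
frequency reading is the only one under which the prior actually pushes
the degree distribution toward the scale-free regime; the nominal exponent
`λ` (default 2.5, a typical biological-network value) is kept in the
configuration as documentation of that regime but does not enter the
score. With fewer than three occupied degree bins, or a degenerate
correlation, the prior is neutral (0).

Boosting stops early for a target as soon as the best candidate fails to
increase the score; accepted scores are therefore strictly increasing.
Ties in the candidate argmax break to the lowest gene index, making the
fit fully deterministic. Degrees are column sums over the *whole*
coefficient matrix and are updated immediately on every accepted
coefficient, so targets processed later see the degree structure built by
earlier ones.

The binary network sets an edge *i–j* when both `β_ij ≠ 0` and
`β_ji ≠ 0` — mutual selection — regardless of the product's polarity
(activation and repression both count; a same-sign-only variant sits
behind a flag). For threshold-sweep evaluation a continuous edge
confidence is used instead: the mean of the two directed coefficient
magnitudes, `(|β_ij| + |β_ji|)/2`, the usual way directed importance
scores are symmetrized in regression-based network inference.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `n_iterations` | 100 | boosting rounds per target; caps model size at ν·rounds of total coefficient mass |
| `shrinkage` ν | 0.1 | step length; smaller = slower, more stable selection |
| `lam` | 2.5 | nominal power-law exponent of the prior's target regime |
| `rss_epsilon` | 1e−12 | floor inside the log so a perfect fit scores finitely |
| `coefficient_zero_tol` | 1e−10 | snap-to-zero threshold after fitting |
| hub `min_degree` | 5 | differential-degree threshold (inclusive) |
| hub `max_p` | 0.01 | DE p-value threshold (inclusive) |
| GeneRank `damping` | 0.5 | weights connectivity vs. differential expression equally |
| DE `fc_threshold` | 2 | linear-scale fold change, strict inequality |
| DE `p_threshold` | 0.01 | Student t-test p-value, strict inequality |

The DE screen uses the equal-variance Student t-test (Welch behind a
flag), a symmetric fold change `2^|Δ log2 mean|` so down-regulation also
passes, and no multiple-testing correction by default. The hub p-value is
the gene's step-1 DE p-value — the only per-gene significance computed
upstream. GeneRank's expression-change vector is |log2 fold change|,
nonnegative as the algorithm requires; scores are computed on the full
differential network and read off for the hubs.

## Synthetic benchmark

The generator emulates SynTReN-style benchmarks without wrapping the
original tool: defaults are 200 genes, 100 samples per condition, a
500-edge scale-free topology, and noise σ = 0.5. Topologies come from
preferential attachment with an exact edge budget (a small seed clique,
then degree-proportional attachment, residual budget filled with
degree-weighted extra edges). Expression is linear-Gaussian along the
acyclic orientation induced by node age: roots are N(0, 1); every child is
its weighted parent sum rescaled to unit empirical variance plus
N(0, σ²). The rescaling keeps σ interpretable as noise relative to a
unit-variance regulatory signal at every cascade depth (SNR = 1/σ²);
without it, noise inherited by a parent propagates into the child's
"signal" and parent–child correlations become nearly scale-invariant in σ.
Edge weights are uniform ±[0.3, 0.9]; with the rescaling only their
relative magnitudes among co-parents matter.

Case/control pairs share one base topology and its weights; the case copy
rewires a fraction (default 0.1) of edges — removals become
control-specific truth, additions case-specific — and 20 genes get a
+1.5 log2 mean shift in case samples. What this emulates: condition-
specific rewiring on a scale-free background with realistic noise. What it
does not: nonlinear (Hill/Michaelis–Menten) kinetics, probe-level artifacts,
batch effects, or correlated noise — so passing benchmarks here shows the
statistical machinery recovers linear-Gaussian structure, not that it is
robust to every property of real microarray data.

## Evaluation

Edge recovery sweeps thresholds over the distinct values of a per-pair
score vector (ties grouped), with trapezoidal AUC; a brute-force
Mann–Whitney concordance count serves as the test oracle. PPV and FDR
(= 1 − PPV) curves are reported against recall. Gene-based baselines (|t|
and lasso |coefficient| on the ±1 group label) are lifted to pair scores
by the min-of-endpoints rule — a pair is as credible as its weaker
endpoint — since a per-gene method has no native edge ranking. Robustness
is AUC across noise levels over independent simulation replicates (a
cross-validation split is not meaningful for unsupervised structure
recovery), with SNR estimated as mean per-gene variance above the noise
floor divided by σ². The benchmark driver infers from the control samples
and scores against the control topology, giving all three methods the same
underlying network, with 10 replicates per setting.

## Numerical choices and degenerate inputs

- Zero pooled variance in the t-test: p = 1 when the group means agree,
  p = 0 (infinite t, logged) when they differ.
- Zero-variance genes are dropped at standardization with a warning; an
  all-constant matrix is an error.
- Candidate RSS is computed by the rank-one update
  `RSS′ = RSS − ν(2 − ν)(x_jᵀ r)²` (exact for unit-norm predictors) and
  clipped at 0 against rounding.
- GeneRank uses fixed-point iteration (L1 tolerance 1e−10); isolated genes
  get the standard dangling-node fix (their column replaced by the
  expression vector), so scores sum to 1. A direct linear solve is the
  test oracle.
- An empty DE panel aborts the pipeline with a clear message rather than
  inferring a network on nothing.

## Problem sizes

The shipped benchmarks run 10 replicates at the default 200-gene scale
(about 2–3 s per boosting fit), which keeps the full test suite and the
reproduction script each around half a minute on one CPU while leaving the
benchmark conditions themselves untouched.

## Known limitations

- The boosting score couples targets through the global degree vector, so
  the fit is order-dependent by construction (deterministic, but a
  different gene ordering could select slightly different edges).
- The prior's integer binning is coarse for very small networks (< 3
  occupied bins ⇒ neutral prior), so on toy problems the method reduces to
  likelihood-only boosting.
- Differential edges are detected only through disagreement of two
  independently thresholded networks; no per-edge significance test is
  attached to them.
- The lasso baseline's penalty (default 0.01) is fixed, not cross-
  validated; it is a comparison baseline, not a tuned competitor.
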