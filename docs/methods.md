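# Methods

## Model and decomposition

`phylodiv` works on rooted topologies without branch lengths (classification
trees). Any lengths present in input Newick are parsed and discarded with a
warning; no computation reads them. Polytomies are preserved, never
arbitrarily resolved.

Diversity of a single quantitative trait at the tips is Rao's quadratic
entropy with half-squared-difference dissimilarity, which equals the
divisor-*n* variance; it is computed as such. The per-node contribution is

    ν_k = p_k · d_k,
    d_k = QE(tips under k) − Σ_j (n_j / n_k) · QE(tips under child j),
    p_k = n_k / n,

i.e. `d_k` is the size-weighted variance of child-clade means (law of total
variance). The contributions telescope, so `Σ ν_k` equals the total QE to
machine precision; the decomposition uses streaming (count, sum,
sum-of-squares) accumulation, and `|d_k| < 1e-12` negatives arising from
cancellation are clamped to zero while anything larger raises an error.
Variances use divisor *n* (not *n−1*) throughout: with divisor *n* the
decomposition is exactly additive and, after standardization, contributions
read as proportions of total variance. The general pairwise-dissimilarity
form of QE would extend to multi-trait distances; only the single-trait path
is implemented and tested.

## Enlarged trees and depth ranks

A species with ≥ 2 population measurements has its tip replaced, in place,
by an artificial internal node whose children are one virtual tip per
population (`species::population` labels). Artificial nodes are never
nested, always subtend only tips, and collapse back to the original species
tree exactly. `S_c` is the sum of ν over artificial nodes; independently of
any tree it equals the within-species sum-of-squares share of the table
(verified exactly in tests), but the node form is what generalizes to
per-node questions.

For `S_3`, internal nodes are ordered by their distance to the tips **of a
reference tree** (the full classification before pruning), so unbalanced
pruning cannot distort the ordering: each non-artificial node maps to the
most recent common ancestor of its species in the reference, its depth is
the maximum edge-count distance to any descendant tip there, and nodes are
ranked by decreasing depth (average ranks on ties) then mapped affinely to
[0, 1], 0 = most tip-distant. *Max* distance (not min) is used because it is
stable when one child lineage is pruned away. Artificial nodes hang below
original species tips, hence are closer to the tips than any reference node;
they receive rank 1 by convention (the reference tree cannot rank nodes that
do not exist in it). `S_3 = Σ (ν_k / total) · rank_k` is a convex
combination of ranks, so it lies in [0, 1]; small values mean root-ward
diversity.

## Preprocessing

Per metric, pooled species × population values are Box-Cox transformed
(λ maximizing the profile log-likelihood over [−5, 5], tolerance 1e-8, via
scipy; a shift of `−min + 1e-6·range` is applied first when values are not
strictly positive) and then standardized to unit divisor-*n* variance. The
pooled fit — rather than a fit on species means — keeps one transform per
metric for values that enter the tree at population resolution; the
automatic shift handles metrics that can be zero or negative. Centering
during standardization is cosmetic (the decomposition sees only
differences) but numerically hygienic.

## Permutation tests

All tests share one null: trait values are shuffled jointly across **all**
tips of the (enlarged) tree — not stratified within species — so under the
null the diversity among species under an inter-specific node is
exchangeable with the diversity among populations under an intra-specific
node. P-values use the `(r+1)/(N+1)` estimator, which keeps the test valid
(p ≥ 1/(N+1)) and effectively counts the observed value as a member of the
null set; ties are detected with a 1e-10 relative tolerance because
permutations of the same multiset can differ in the last few ulps.
Default N = 1000; the conservation test is left-tailed, the S_3 test doubles
the smaller tail and caps at 1, the C_mean test is upper-tailed. Every test
takes a mandatory seed, recorded in the result.

Null recomputation is vectorized: clade membership and child-size ratios are
precomputed once, so all node contributions for N permutations cost two
(N × n)(n × K) matrix products. The same quantities recomputed through the
plain per-dataset decomposition agree to machine precision (tested).

`C_mean` uses the plain path-product proximity matrix with zero diagonal
(`a_ij = Π 1/DDC` over internal nodes on the tip-to-tip path, endpoints'
ancestors up to and including the MRCA). Row-sum-modified or
diagonal-adjusted proximity variants used by some legacy implementations are
deliberately out of scope, so numeric equality with analyses using those
variants is not claimed. On a star tree the statistic reduces to Moran's
*I* with equal weights, −1/(n−1), a closed form used as a test oracle.

Hochberg's step-up correction (via statsmodels, verified against the
explicit `min_{j≥i}(m−j+1)p_(j)` definition) is applied **within each
statistic family across metrics** — C_mean p-values form one family, S_c
another, S_3 a third — never pooled across families.

## Synthetic data generator

The generator emulates the shape of comparative dispersal datasets: a
pure-birth (uniform lineage-splitting) topology; a Brownian trait on unit
edges (root 0, child = parent + N(0, σ_b²)) supplying inter-specific signal;
and per-species replicates drawn N(μ_s, σ_w²) (a species with one
population copies μ_s exactly). Defaults — 18 species, 7 replicated with
3–6 populations — mirror published dispersal tables (10–28 species, 3–11
replicated, up to 8 populations). Unit edge lengths are the simplest
signal-generating choice on a lengths-free topology and are used for
fixtures only, never for inference.

The designed within-species variance share accounts for both the residual
sum of squares and the sampling noise of realized species means:

    share = σ_w²A / (σ_w²A + Var_w(μ) + σ_w²C),
    A = Σ (r_s − 1)/n,   C = Σ w_s(1 − w_s)/r_s (replicated species),

with `w_s = r_s/n`. Dropping the `C` term — i.e. equating the between part
with the variance of the true species values — overstates the share by up
to ~0.07 at share 0.5 with 4 replicates, which is why the exact form is
used; with it, the mean observed S_c over 200 simulated datasets lands
within ~0.005 of the design target.

What the generator does **not** emulate: measurement error distinct from
population-level variation, non-Gaussian or heteroscedastic within-species
scatter, correlated sampling of populations, and non-Brownian trait
evolution. Passing tests therefore certify the arithmetic and calibration of
the method under a clean nested-Gaussian model, not robustness to those
real-data features.

A note on calibration checks: the permutation null is *exchangeability of
all tip values*. A generator with distinct species means is not exchangeable
at any within-share setting — under permutation the expected S_c is
`Σ(r_s−1)/(n−1)`, regardless of the generated share — so uniform p-values
are verified under the genuinely exchangeable special case (equal species
means, iid residuals), and type-I error under iid values.

## Problem sizes and numerical choices

The statistical suites use 200 random trees (4–64 tips) for additivity, 200
scenarios for the S_c identity, 2000 permutations against exhaustive
enumeration on 4–6 tips, 400 datasets × 199 permutations for type-I
calibration, and 200 datasets per recovery target — sizes at which binomial
and Monte-Carlo error bands are tight enough to be informative while the
whole suite runs in well under a minute each. Degenerate inputs (constant
values, zero total diversity, trees with fewer than 2 tips, metrics with a
single species) raise typed errors rather than returning NaN; the CLI maps
validation errors to exit code 2 and degenerate statistics to exit code 3.
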