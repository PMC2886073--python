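"""Permutation tests and multiple-testing correction.

Three tests are provided, all built on the same null model: trait values are
shuffled jointly across *all* tips of the tree, mixing intra- and
inter-specific variation, so that under the null the diversity among species
descending from an inter-specific node is exchangeable with the diversity
among populations descending from an intra-specific (artificial) node.

* :func:`conservation_test` — is the intra-specific share of diversity
  (S_c) lower than expected?  Left-tailed.
* :func:`skewness_to_root_test` — is diversity concentrated at root-ward
  nodes (S_3)?  Two-sided, doubled smaller tail.
* :func:`abouheif_test` — phylogenetic autocorrelation of species means
  (Abouheif's C_mean, Moran form with path-product proximities).
  Upper-tailed.

P-values use the (r+1)/(N+1) estimator, which keeps the test valid and the
p-value strictly positive; the observed value thereby counts as one member
of the null set.  Family-wise error over a family of metrics is controlled
with Hochberg's step-up procedure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .decomp import (
    DecompositionError,
    decompose_diversity,
    s3_statistic,
    sc_statistic,
)
from .phylo import DepthRanks, EnlargedTree, Tree

__all__ = [
    "TestResult",
    "InferenceError",
    "conservation_test",
    "skewness_to_root_test",
    "abouheif_proximity",
    "abouheif_cmean",
    "abouheif_test",
    "hochberg_adjust",
]


class InferenceError(ValueError):
    """Raised when a test's preconditions are not met."""


@dataclass(frozen=True)
class TestResult:
    """Outcome of one permutation test.

    ``null_sample`` holds the statistic recomputed under each of ``n_perm``
    joint tip-value permutations; ``p_value`` uses the (r+1)/(N+1)
    construction, so it lies in [1/(N+1), 1].
    """

    statistic_name: str
    observed: float
    null_sample: np.ndarray
    n_perm: int
    p_value: float
    alternative: str
    seed: int

    def to_dict(self) -> dict:
        return {
            "statistic_name": self.statistic_name,
            "observed": self.observed,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "alternative": self.alternative,
            "p_value": self.p_value,
        }


def _tie_tol(obs: float) -> float:
    # permutations of identical multisets can differ in the last few ulps
    return 1e-10 + 1e-10 * abs(obs)


def _p_left(null: np.ndarray, obs: float) -> float:
    r = int(np.sum(null <= obs + _tie_tol(obs)))
    return (r + 1) / (null.size + 1)


def _p_right(null: np.ndarray, obs: float) -> float:
    r = int(np.sum(null >= obs - _tie_tol(obs)))
    return (r + 1) / (null.size + 1)


def _check_nperm(n_perm: int) -> None:
    if n_perm < 1:
        raise InferenceError("n_perm must be at least 1")


def _tip_values_vector(tree: Tree, tip_values: Mapping[str, float]) -> np.ndarray:
    labels = [tree.tip_label[t] for t in tree.tips]
    missing = sorted(set(labels) - set(tip_values))
    if missing:
        raise InferenceError(f"tips without a trait value: {missing}")
    return np.array([tip_values[l] for l in labels], dtype=float)


class _NodeEngine:
    """Vectorized recomputation of node contributions under permutations.

    For an n-tip tree with K internal nodes it precomputes the tip-membership
    matrix of every internal clade and the child-clade size ratios, so the
    per-node among-clade diversities d_k for P permuted value vectors cost a
    couple of (P, n) x (n, K) matrix products.
    """

    def __init__(self, tree: Tree):
        self.tree = tree
        tips = tree.tips
        self.n = len(tips)
        tip_index = {t: i for i, t in enumerate(tips)}
        internal = list(tree.internal_nodes)
        self.internal = internal
        col = {nd: j for j, nd in enumerate(internal)}
        K = len(internal)
        A = np.zeros((self.n, K))
        n_k = np.zeros(K)
        for j, nd in enumerate(internal):
            idx = [tip_index[t] for t in tree.tips_under(nd)]
            A[idx, j] = 1.0
            n_k[j] = len(idx)
        C = np.zeros((K, K))
        for j, nd in enumerate(internal):
            for ch in tree.children[nd]:
                if tree.children[ch]:  # internal child; tip clades have QE 0
                    C[j, col[ch]] = n_k[col[ch]] / n_k[j]
        self.A = A
        self.n_k = n_k
        self.C = C
        self.p_k = n_k / self.n

    def node_nu(self, V: np.ndarray) -> np.ndarray:
        """Contributions nu_k for each row of the (P, n) value matrix V."""
        S = V @ self.A
        SS = (V * V) @ self.A
        var = SS / self.n_k - (S / self.n_k) ** 2
        d = var - var @ self.C.T
        np.clip(d, 0.0, None, out=d)  # fp cancellation only; see decomp
        return d * self.p_k


def _permutation_matrix(
    x: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    P = np.empty((n_perm, x.size))
    for i in range(n_perm):
        P[i] = x[rng.permutation(x.size)]
    return P


def conservation_test(
    enlarged: EnlargedTree,
    tip_values: Mapping[str, float],
    n_perm: int = 1000,
    seed: int = 0,
) -> TestResult:
    """Trait-conservation test on the intra-specific diversity share S_c.

    The observed S_c is compared against its distribution under joint
    permutation of all tip values; intra-specific conservation shows up as an
    unusually *low* S_c, so the alternative is "less".
    """
    _check_nperm(n_perm)
    if not enlarged.artificial_nodes:
        raise InferenceError(
            "conservation test undefined: the tree has no artificial nodes"
        )
    dec = decompose_diversity(enlarged, tip_values)
    observed = sc_statistic(dec, enlarged.artificial_nodes).value

    tree = enlarged.tree
    x = _tip_values_vector(tree, tip_values)
    engine = _NodeEngine(tree)
    art_cols = np.array(
        [j for j, nd in enumerate(engine.internal)
         if nd in enlarged.artificial_nodes]
    )
    rng = np.random.default_rng(seed)
    V = _permutation_matrix(x, n_perm, rng)
    null = engine.node_nu(V)[:, art_cols].sum(axis=1)

    return TestResult(
        statistic_name="S_c",
        observed=observed,
        null_sample=null,
        n_perm=n_perm,
        p_value=_p_left(null, observed),
        alternative="less",
        seed=seed,
    )


def skewness_to_root_test(
    enlarged: EnlargedTree,
    tip_values: Mapping[str, float],
    ranks: DepthRanks,
    n_perm: int = 1000,
    seed: int = 0,
) -> TestResult:
    """Skewness-to-root test on S_3 (two-sided).

    Low S_3 means diversity clustered at the most tip-distant nodes; the
    two-sided p doubles the smaller of the two (r+1)/(N+1) tails, capped at 1.
    """
    _check_nperm(n_perm)
    dec = decompose_diversity(enlarged, tip_values)
    observed = s3_statistic(dec, ranks).value

    tree = enlarged.tree
    x = _tip_values_vector(tree, tip_values)
    engine = _NodeEngine(tree)
    r = np.array([ranks.rank.get(nd, 0.0) for nd in engine.internal])
    total = float(x.var(ddof=0))  # invariant under permutation
    rng = np.random.default_rng(seed)
    V = _permutation_matrix(x, n_perm, rng)
    null = (engine.node_nu(V) @ r) / total

    p_low = _p_left(null, observed)
    p_high = _p_right(null, observed)
    return TestResult(
        statistic_name="S_3",
        observed=observed,
        null_sample=null,
        n_perm=n_perm,
        p_value=min(1.0, 2.0 * min(p_low, p_high)),
        alternative="two-sided",
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Abouheif's C_mean


def abouheif_proximity(tree: Tree) -> tuple[np.ndarray, list[str]]:
    """Path-product proximity matrix between tips.

    a_ij is the product, over the internal nodes on the path from tip i to
    tip j (both endpoints' ancestors up to and including their most recent
    common ancestor), of 1 / (number of direct descendants of that node);
    the diagonal is zero.  Returns the matrix and the tip labels in row order.
    """
    tips = tree.tips
    labels = [tree.tip_label[t] for t in tips]
    parents = tree.parent_map()
    ddc = {nd: len(tree.children[nd]) for nd in tree.internal_nodes}

    def path_to_root(t: int) -> list[int]:
        path = []
        n = t
        while n in parents:
            n = parents[n]
            path.append(n)
        return path

    anc = {t: path_to_root(t) for t in tips}
    n = len(tips)
    A = np.zeros((n, n))
    for i in range(n):
        anc_i = anc[tips[i]]
        pos_i = {nd: k for k, nd in enumerate(anc_i)}
        for j in range(i + 1, n):
            anc_j = anc[tips[j]]
            mrca = next(nd for nd in anc_j if nd in pos_i)
            # ancestors of i up to the mrca (inclusive) + ancestors of j
            # strictly below the mrca: the internal nodes on the i-j path
            path_nodes = anc_i[: pos_i[mrca] + 1] + anc_j[: anc_j.index(mrca)]
            prod = 1.0
            for nd in path_nodes:
                prod *= 1.0 / ddc[nd]
            A[i, j] = A[j, i] = prod
    return A, labels


def abouheif_cmean(tree: Tree, species_values: Mapping[str, float]) -> float:
    """Abouheif's C_mean: Moran's I with path-product proximities.

    C_mean = (n / W) * (sum_{i!=j} a_ij z_i z_j) / (sum_i z_i^2) with z the
    centered species values and W the sum of off-diagonal proximities.
    """
    if tree.n_tips < 3:
        raise InferenceError("C_mean needs at least 3 species")
    A, labels = abouheif_proximity(tree)
    missing = sorted(set(labels) - set(species_values))
    if missing:
        raise InferenceError(f"species without a value: {missing}")
    x = np.array([species_values[l] for l in labels], dtype=float)
    if np.ptp(x) == 0:
        raise InferenceError("C_mean undefined for constant values")
    z = x - x.mean()
    W = A.sum()
    return float((len(z) / W) * (z @ A @ z) / (z @ z))


def abouheif_test(
    tree: Tree,
    species_values: Mapping[str, float],
    n_perm: int = 1000,
    seed: int = 0,
) -> TestResult:
    """Upper-tailed permutation test for phylogenetic signal via C_mean."""
    _check_nperm(n_perm)
    observed = abouheif_cmean(tree, species_values)
    A, labels = abouheif_proximity(tree)
    x = np.array([species_values[l] for l in labels], dtype=float)
    z = x - x.mean()
    W = A.sum()
    n = len(z)
    denom = z @ z

    rng = np.random.default_rng(seed)
    Z = _permutation_matrix(z, n_perm, rng)
    null = (n / W) * np.einsum("pi,ij,pj->p", Z, A, Z) / denom

    return TestResult(
        statistic_name="C_mean",
        observed=observed,
        null_sample=null,
        n_perm=n_perm,
        p_value=_p_right(null, observed),
        alternative="greater",
        seed=seed,
    )


def hochberg_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Hochberg step-up adjusted p-values, in input order.

    adjusted_(i) = min_{j >= i} min(1, (m - j + 1) * p_(j)) over the
    ascending order statistics.  Controls the family-wise error rate; never
    decreases a p-value.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise InferenceError("p-values must lie in [0, 1]")
    return multipletests(p, method="simes-hochberg")[1]
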