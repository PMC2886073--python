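"""Quadratic-entropy decomposition of trait diversity among tree nodes.

The diversity of a single quantitative trait measured on the tips of a
rooted tree is the quadratic entropy

    QE = (1/n^2) * sum_ij d_ij,   d_ij = (x_i - x_j)^2 / 2,

which for this dissimilarity equals the divisor-n variance of the tip
values.  Every internal node k receives a contribution

    nu_k = p_k * d_k,

where p_k = n_k / n is the fraction of tips descending from k and d_k is the
diversity *among the child clades* of k: the total QE under k minus the
size-weighted QE within each child clade (the between-group term of the law
of total variance).  The contributions telescope, so sum_k nu_k equals the
total QE exactly.

On an enlarged tree whose artificial nodes hold within-species replicates,
the sum of nu_k over artificial nodes — the S_c statistic — is the share of
trait variance that is intra-specific; the S_3 statistic locates the
diversity along the root-to-tip axis as a contribution-weighted mean of
tipward depth ranks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .phylo import DepthRanks, EnlargedTree, Tree

__all__ = [
    "NodeDecomposition",
    "ScStatistic",
    "S3Statistic",
    "DecompositionError",
    "quadratic_entropy",
    "decompose_diversity",
    "sc_statistic",
    "s3_statistic",
]

# |d_k| below this is floating-point cancellation and is clamped to zero;
# larger negatives indicate a bug upstream.
_NEG_TOL = 1e-12


class DecompositionError(ValueError):
    """Raised for inputs on which the decomposition is undefined."""


def quadratic_entropy(values: Iterable[float]) -> float:
    """Rao's quadratic entropy of a value vector.

    With the half-squared-difference dissimilarity this equals the divisor-n
    variance, and that identity is how it is computed.
    """
    x = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                   dtype=float)
    if x.size == 0:
        raise DecompositionError("quadratic entropy of an empty value set")
    return float(x.var(ddof=0))


@dataclass(frozen=True)
class NodeDecomposition:
    """Per-node diversity contributions for one tree and one trait.

    Arrays are aligned over ``node_ids`` (the internal nodes in preorder):
    ``p`` the fraction of tips subtended, ``d`` the diversity among child
    clades, ``nu = p * d`` the node's contribution.  ``total`` is the
    quadratic entropy of all tip values; the ``nu`` sum to it exactly.
    """

    node_ids: tuple[int, ...]
    p: np.ndarray
    d: np.ndarray
    nu: np.ndarray
    total: float
    clade_labels: tuple[frozenset[str], ...]

    @property
    def contribution(self) -> dict[int, float]:
        return dict(zip(self.node_ids, self.nu.tolist()))

    def to_frame(
        self,
        artificial_nodes: frozenset[int] | None = None,
        ranks: DepthRanks | None = None,
    ) -> pd.DataFrame:
        """Tabular view: one row per internal node (the numeric counterpart of
        a node-circle diagram)."""
        art = artificial_nodes or frozenset()
        rows = {
            "node_id": self.node_ids,
            "clade_tips": [",".join(sorted(s)) for s in self.clade_labels],
            "p": self.p,
            "d": self.d,
            "nu": self.nu,
            "is_artificial": [n in art for n in self.node_ids],
        }
        if ranks is not None:
            rows["rank"] = [ranks.rank.get(n, np.nan) for n in self.node_ids]
        return pd.DataFrame(rows)


def _as_tree(tree: Tree | EnlargedTree) -> Tree:
    return tree.tree if isinstance(tree, EnlargedTree) else tree


def decompose_diversity(
    tree: Tree | EnlargedTree, tip_values: Mapping[str, float]
) -> NodeDecomposition:
    """Split the quadratic entropy of tip values among internal nodes.

    ``tip_values`` maps tip labels to trait values; every tip must be
    covered.  For each internal node k with child clades of sizes n_j,

        d_k = QE(values under k) - sum_j (n_j / n_k) * QE(values under j)
        nu_k = (n_k / n) * d_k.
    """
    t = _as_tree(tree)
    labels = [t.tip_label[tip] for tip in t.tips]
    missing = sorted(set(labels) - set(tip_values))
    if missing:
        raise DecompositionError(f"tips without a trait value: {missing}")
    if t.n_tips < 2:
        raise DecompositionError("decomposition needs at least 2 tips")

    n = t.n_tips
    node_ids: list[int] = []
    p_list: list[float] = []
    d_list: list[float] = []
    clades: list[frozenset[str]] = []

    # postorder accumulation of (count, sum, sum of squares) per node
    moments: dict[int, tuple[int, float, float]] = {}

    def visit(node: int) -> tuple[int, float, float]:
        kids = t.children[node]
        if not kids:
            v = float(tip_values[t.tip_label[node]])
            m = (1, v, v * v)
            moments[node] = m
            return m
        acc = [visit(k) for k in kids]
        m = (
            sum(a[0] for a in acc),
            sum(a[1] for a in acc),
            sum(a[2] for a in acc),
        )
        moments[node] = m
        return m

    visit(t.root)

    def var_of(m: tuple[int, float, float]) -> float:
        c, s, ss = m
        return ss / c - (s / c) ** 2

    # preorder listing keeps parents before children in the output table
    stack = [t.root]
    order: list[int] = []
    while stack:
        nd = stack.pop()
        if t.children[nd]:
            order.append(nd)
            stack.extend(reversed(t.children[nd]))

    for node in order:
        m = moments[node]
        within = sum(
            (moments[k][0] / m[0]) * var_of(moments[k]) for k in t.children[node]
        )
        d = var_of(m) - within
        if d < 0:
            if d < -_NEG_TOL * max(1.0, abs(var_of(m))):
                raise DecompositionError(
                    f"negative among-clade diversity {d!r} at node {node}"
                )
            d = 0.0
        node_ids.append(node)
        p_list.append(m[0] / n)
        d_list.append(d)
        clades.append(t.labels_under(node))

    p = np.array(p_list)
    d = np.array(d_list)
    return NodeDecomposition(
        node_ids=tuple(node_ids),
        p=p,
        d=d,
        nu=p * d,
        total=var_of(moments[t.root]),
        clade_labels=tuple(clades),
    )


@dataclass(frozen=True)
class ScStatistic:
    """Intra-specific share of trait diversity.

    ``value`` is the sum of node contributions over artificial nodes; on
    unit-variance input it is the proportion of trait variance attributable
    to within-species variation.
    """

    value: float
    artificial_contributions: Mapping[int, float]


def sc_statistic(
    dec: NodeDecomposition, artificial_nodes: frozenset[int] | Iterable[int]
) -> ScStatistic:
    """Sum the decomposition's contributions over the artificial nodes."""
    art = frozenset(artificial_nodes)
    unknown = art - set(dec.node_ids)
    if unknown:
        raise DecompositionError(
            f"artificial nodes absent from decomposition: {sorted(unknown)}"
        )
    contrib = {n: nu for n, nu in zip(dec.node_ids, dec.nu) if n in art}
    return ScStatistic(value=float(sum(contrib.values())),
                       artificial_contributions=contrib)


@dataclass(frozen=True)
class S3Statistic:
    """Contribution-weighted mean tipward rank of trait diversity.

    Values near 0 mean the diversity sits at the most tip-distant (root-most)
    nodes; values near 1 mean it sits at the most tipward nodes.
    """

    value: float


def s3_statistic(dec: NodeDecomposition, ranks: DepthRanks) -> S3Statistic:
    """Locate diversity along the root-to-tip axis.

    S_3 = sum_k (nu_k / total) * rank_k over internal nodes; undefined when
    the total diversity is zero.
    """
    if dec.total <= 0:
        raise DecompositionError("S_3 undefined: total diversity is zero")
    missing = [n for n, nu in zip(dec.node_ids, dec.nu)
               if nu > 0 and n not in ranks.rank]
    if missing:
        raise DecompositionError(f"contributing nodes without a rank: {missing}")
    r = np.array([ranks.rank.get(n, 0.0) for n in dec.node_ids])
    return S3Statistic(value=float(np.dot(dec.nu, r) / dec.total))
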