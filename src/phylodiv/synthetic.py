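"""Synthetic trees and trait tables with known intra-/inter-specific structure.

The generator emulates the shape of comparative dispersal datasets: a rooted
species topology (pure-birth), a Brownian inter-specific trait component
that carries phylogenetic signal, and within-species replicate measurements
drawn around each species value with controllable intra-specific variance.
A :class:`Scenario` bundles the pieces together with the within-species
variance share its design implies, so parameter-recovery checks have a known
truth to compare against.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import traits as traits_mod
from .phylo import EnlargedTree, Tree, enlarge_with_replicates
from .traits import TraitTable

__all__ = [
    "Scenario",
    "simulate_yule_topology",
    "collapse_random_edges",
    "simulate_bm_trait",
    "add_population_replicates",
    "within_share",
    "sigma_within_for_share",
    "simulate_scenario",
]


def _seed_of(rng_or_seed) -> np.random.Generator:
    if isinstance(rng_or_seed, np.random.Generator):
        return rng_or_seed
    return np.random.default_rng(rng_or_seed)


def simulate_yule_topology(n_species: int, seed: int) -> Tree:
    """Rooted binary topology from uniform random lineage splitting.

    Starting from a two-tip cherry, a uniformly chosen extant tip is split
    until ``n_species`` tips exist (a pure-birth topology).  Tips are
    labelled sp001.. in left-to-right order; output is deterministic per seed.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    rng = _seed_of(seed)
    children: dict[int, tuple[int, ...]] = {0: (1, 2), 1: (), 2: ()}
    tips = [1, 2]
    next_id = 3
    while len(tips) < n_species:
        k = int(rng.integers(len(tips)))
        node = tips[k]
        a, b = next_id, next_id + 1
        next_id += 2
        children[node] = (a, b)
        children[a] = ()
        children[b] = ()
        tips[k] = a
        tips.append(b)

    # relabel tips in traversal order for stable, readable names
    tip_label: dict[int, str] = {}
    order = [t for t in _preorder_tips(children, 0)]
    width = max(3, len(str(n_species)))
    for i, t in enumerate(order, start=1):
        tip_label[t] = f"sp{i:0{width}d}"
    tree = Tree(root=0, children=children, tip_label=tip_label)
    tree.validate()
    return tree


def _preorder_tips(children: Mapping[int, tuple[int, ...]], root: int):
    stack = [root]
    while stack:
        n = stack.pop()
        kids = children[n]
        if not kids:
            yield n
        else:
            stack.extend(reversed(kids))


def collapse_random_edges(tree: Tree, prob: float, seed: int) -> Tree:
    """Create polytomies by collapsing each internal edge with probability
    ``prob`` (the child's children are promoted to its parent).  The root is
    never removed."""
    rng = _seed_of(seed)
    collapse = {
        n for n in tree.internal_nodes
        if n != tree.root and rng.random() < prob
    }

    children: dict[int, tuple[int, ...]] = {}
    tip_label: dict[int, str] = {}
    next_id = [0]

    def visit(n: int, out: list[int] | None = None) -> int | None:
        """Materialize node n; if collapsed, splice children into ``out``."""
        kids = tree.children[n]
        if kids and n in collapse and out is not None:
            for k in kids:
                child_out: list[int] = []
                res = visit(k, child_out)
                out.extend(child_out if res is None else [res])
            return None
        nid = next_id[0]
        next_id[0] += 1
        if not kids:
            children[nid] = ()
            tip_label[nid] = tree.tip_label[n]
            return nid
        acc: list[int] = []
        for k in kids:
            child_out = []
            res = visit(k, child_out)
            acc.extend(child_out if res is None else [res])
        children[nid] = tuple(acc)
        return nid

    root = visit(tree.root)
    assert root is not None
    out_tree = Tree(root=root, children=children, tip_label=tip_label)
    out_tree.validate()
    return out_tree


def simulate_bm_trait(
    tree: Tree, sigma_between: float, seed: int
) -> dict[str, float]:
    """Brownian walk on the topology with unit-length edges.

    The root value is 0; each child adds an independent Normal(0,
    sigma_between^2) increment, so deeper tips accumulate more variance and
    sister species stay correlated — the minimal signal-generating model on a
    branch-length-free tree.
    """
    if sigma_between <= 0:
        raise ValueError("sigma_between must be positive")
    rng = _seed_of(seed)
    values: dict[str, float] = {}

    def walk(node: int, value: float) -> None:
        kids = tree.children[node]
        if not kids:
            values[tree.tip_label[node]] = value
            return
        for k in kids:
            walk(k, value + sigma_between * rng.standard_normal())

    walk(tree.root, 0.0)
    return values


def add_population_replicates(
    species_values: Mapping[str, float],
    design: Mapping[str, int],
    sigma_within: float,
    seed: int,
    metric: str = "trait",
) -> TraitTable:
    """Expand species values into a population-level trait table.

    Species s with ``design[s] = r >= 2`` populations gets r values drawn
    Normal(mu_s, sigma_within^2), ids p1..pr; r = 1 copies mu_s exactly.
    """
    if sigma_within < 0:
        raise ValueError("sigma_within must be non-negative")
    if any(r < 1 for r in design.values()):
        raise ValueError("population counts must be >= 1")
    rng = _seed_of(seed)
    rows = []
    for sp, mu in species_values.items():
        r = design.get(sp, 1)
        for i in range(r):
            v = mu if r == 1 else mu + sigma_within * rng.standard_normal()
            rows.append(
                {"metric": metric, "species": sp, "population": f"p{i + 1}",
                 "value": float(v)}
            )
    return traits_mod.from_records(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Within-species variance share algebra
#
# With species values mu_s, r_s populations each and residuals
# e ~ Normal(0, sigma_w^2) (exact copies when r_s = 1), the expected
# within-species sum of squares per value is sigma_w^2 * A with
# A = sum_s (r_s - 1) / n, while the expected between part is the weighted
# variance of the mu plus the sampling noise of the realized species means,
# sigma_w^2 * C with C = sum_{r_s >= 2} w_s (1 - w_s) / r_s, w_s = r_s / n.
# The share below accounts for both terms; dropping C would overstate the
# share by up to ~0.07 at share 0.5 with small replicate counts.


def _design_constants(
    species_values: Mapping[str, float], design: Mapping[str, int]
) -> tuple[float, float, float]:
    mu = np.array([species_values[s] for s in species_values], dtype=float)
    r = np.array([design.get(s, 1) for s in species_values], dtype=float)
    n = r.sum()
    w = r / n
    V = float(np.sum(w * mu**2) - np.sum(w * mu) ** 2)
    rep = r >= 2
    A = float(np.sum(r[rep] - 1) / n)
    C = float(np.sum(w[rep] * (1 - w[rep]) / r[rep]))
    return V, A, C


def within_share(
    species_values: Mapping[str, float],
    design: Mapping[str, int],
    sigma_within: float,
) -> float:
    """Expected within-species variance fraction implied by the design."""
    V, A, C = _design_constants(species_values, design)
    s2 = sigma_within**2
    denom = s2 * A + V + s2 * C
    return 0.0 if denom == 0 else s2 * A / denom


def sigma_within_for_share(
    species_values: Mapping[str, float],
    design: Mapping[str, int],
    share: float,
) -> float:
    """Residual scale sigma_within that yields a target within-species share."""
    if not 0 <= share < 1:
        raise ValueError("share must lie in [0, 1)")
    if share == 0:
        return 0.0
    V, A, C = _design_constants(species_values, design)
    denom = (1 - share) * A - share * C
    if denom <= 0:
        raise ValueError(
            "target share unreachable for this replication design"
        )
    return float(np.sqrt(share * V / denom))


@dataclass(frozen=True)
class Scenario:
    """A complete synthetic dataset with known ground truth."""

    species_tree: Tree
    enlarged: EnlargedTree
    table: TraitTable
    true_within_share: float
    sigma_between: float
    sigma_within: float
    seed: int


def simulate_scenario(
    n_species: int = 18,
    n_replicated: int = 7,
    pops_range: tuple[int, int] = (3, 6),
    sigma_between: float = 1.0,
    sigma_within: float | None = None,
    target_within_share: float | None = None,
    polytomy_prob: float = 0.0,
    seed: int = 0,
    metric: str = "trait",
) -> Scenario:
    """Generate a full dataset: tree, replicate design, trait table.

    Defaults mirror the shape of comparative dispersal datasets: 10-28
    species of which a handful carry 3-8 population replicates each.  Either
    ``sigma_within`` or ``target_within_share`` fixes the intra-specific
    scatter (the latter solves for the former given the realized species
    values); giving neither defaults to a within-share of 0.3.
    """
    if sigma_within is not None and target_within_share is not None:
        raise ValueError("give sigma_within or target_within_share, not both")
    ss = np.random.SeedSequence(seed)
    s_topo, s_poly, s_bm, s_rep, s_design = (
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(5)
    )
    tree = simulate_yule_topology(n_species, s_topo)
    if polytomy_prob > 0:
        tree = collapse_random_edges(tree, polytomy_prob, s_poly)
    species_values = simulate_bm_trait(tree, sigma_between, s_bm)

    rng = np.random.default_rng(s_design)
    species = [tree.tip_label[t] for t in tree.tips]
    replicated = list(rng.choice(species, size=min(n_replicated, n_species),
                                 replace=False))
    lo, hi = pops_range
    design = {sp: 1 for sp in species}
    for sp in replicated:
        design[sp] = int(rng.integers(lo, hi + 1))

    if sigma_within is None:
        share = 0.3 if target_within_share is None else target_within_share
        sigma_within = sigma_within_for_share(species_values, design, share)
    table = add_population_replicates(
        species_values, design, sigma_within, s_rep, metric=metric
    )
    enlarged = enlarge_with_replicates(
        tree, {sp: table.replicate_design(metric)[sp]
               for sp in species if design[sp] >= 2}
    )
    return Scenario(
        species_tree=tree,
        enlarged=enlarged,
        table=table,
        true_within_share=within_share(species_values, design, sigma_within),
        sigma_between=sigma_between,
        sigma_within=float(sigma_within),
        seed=seed,
    )
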