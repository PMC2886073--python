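"""Rooted, branch-length-free phylogenies and the tree surgery used by the
diversity decomposition.

Trees here are pure topologies: Newick branch lengths are parsed (via
dendropy) and then discarded with a warning, because every downstream
computation is defined on the classification alone.  The module provides

* :func:`parse_newick` / :func:`write_newick` — I/O for the standard dialect;
* :func:`prune_to_taxa` — restrict a tree to the species with data,
  suppressing the unary nodes that pruning leaves behind;
* :func:`enlarge_with_replicates` — graft population-level replicate
  measurements under a species tip as *virtual sister-taxa*, held together by
  a new artificial internal node;
* :func:`depth_ranks` — order internal nodes by their topological distance to
  the tips of a reference tree, as required by the skewness-to-root statistic.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
from scipy.stats import rankdata

__all__ = [
    "Tree",
    "EnlargedTree",
    "DepthRanks",
    "NewickParseError",
    "TreeValidationError",
    "parse_newick",
    "write_newick",
    "prune_to_taxa",
    "enlarge_with_replicates",
    "collapse_artificial_nodes",
    "depth_ranks",
]

VIRTUAL_TIP_SEP = "::"


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed."""


class TreeValidationError(ValueError):
    """Raised when a tree violates a structural requirement."""


@dataclass(frozen=True)
class Tree:
    """A rooted topology with labelled tips and no branch lengths.

    Nodes are small integers; ``children`` maps every node to the ordered
    tuple of its children (empty for tips) and ``tip_label`` maps tip nodes
    to their unique labels.  Polytomies are allowed; unary internal nodes are
    not (they are suppressed on construction by the factory functions).
    """

    root: int
    children: Mapping[int, tuple[int, ...]]
    tip_label: Mapping[int, str]

    # -- basic accessors ---------------------------------------------------
    @property
    def nodes(self) -> tuple[int, ...]:
        return tuple(self.children)

    @property
    def tips(self) -> tuple[int, ...]:
        return tuple(n for n, c in self.children.items() if not c)

    @property
    def internal_nodes(self) -> tuple[int, ...]:
        return tuple(n for n, c in self.children.items() if c)

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    def parent_map(self) -> dict[int, int]:
        return {c: p for p, kids in self.children.items() for c in kids}

    def label_of(self, tip: int) -> str:
        return self.tip_label[tip]

    def tip_by_label(self) -> dict[str, int]:
        return {lab: n for n, lab in self.tip_label.items()}

    def tips_under(self, node: int) -> tuple[int, ...]:
        """Tips of the clade rooted at ``node``, in traversal order."""
        out: list[int] = []
        stack = [node]
        while stack:
            n = stack.pop()
            kids = self.children[n]
            if not kids:
                out.append(n)
            else:
                stack.extend(reversed(kids))
        return tuple(out)

    def labels_under(self, node: int) -> frozenset[str]:
        return frozenset(self.tip_label[t] for t in self.tips_under(node))

    def validate(self) -> None:
        """Check the structural invariants; raise TreeValidationError."""
        if self.root not in self.children:
            raise TreeValidationError("root is not a node of the tree")
        parents = self.parent_map()
        for n in self.children:
            if n != self.root and n not in parents:
                raise TreeValidationError(f"node {n} is disconnected")
        # one parent slot per non-root node rules out shared or repeated children
        slots = sum(len(k) for k in self.children.values())
        if slots != len(self.children) - 1:
            raise TreeValidationError("tree is not a single rooted component")
        labels = list(self.tip_label.values())
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeValidationError(f"duplicate tip labels: {dupes}")
        for n, kids in self.children.items():
            if len(kids) == 1:
                raise TreeValidationError(f"unary internal node {n}")

    def to_newick(self) -> str:
        return write_newick(self)


@dataclass(frozen=True)
class EnlargedTree:
    """A species tree with population replicates grafted in as virtual tips.

    ``artificial_nodes`` are the internal nodes inserted where a replicated
    species' tip used to be; their children are the virtual sister-taxa (one
    tip per population).  ``virtual_tip_species`` maps *every* tip of the
    enlarged tree to its species, so trait values recorded per population can
    be placed on the tree unambiguously.
    """

    tree: Tree
    artificial_nodes: frozenset[int]
    species_of_artificial: Mapping[int, str]
    virtual_tip_species: Mapping[int, str]

    def validate(self) -> None:
        self.tree.validate()
        parents = self.tree.parent_map()
        species_seen: set[str] = set()
        for a in self.artificial_nodes:
            kids = self.tree.children[a]
            if len(kids) < 2 or any(self.tree.children[k] for k in kids):
                raise TreeValidationError(
                    f"artificial node {a} must subtend >=2 tips only"
                )
            anc = parents.get(a)
            while anc is not None:
                if anc in self.artificial_nodes:
                    raise TreeValidationError("nested artificial nodes")
                anc = parents.get(anc)
            sp = self.species_of_artificial[a]
            if sp in species_seen:
                raise TreeValidationError(f"species {sp!r} has two artificial nodes")
            species_seen.add(sp)


@dataclass(frozen=True)
class DepthRanks:
    """Tipward rank of every internal node, in [0, 1].

    0 marks the node(s) farthest from the tips of the reference tree (the
    root-most stratum); 1 marks the most tipward stratum.  Artificial nodes,
    which hang below original species tips, always receive rank 1.
    """

    rank: Mapping[int, float]


# ---------------------------------------------------------------------------
# Newick I/O


def _from_dendropy(dtree: dendropy.Tree) -> Tree:
    children: dict[int, tuple[int, ...]] = {}
    tip_label: dict[int, str] = {}
    ids: dict[object, int] = {}

    def visit(dnode) -> int:
        nid = ids.setdefault(dnode, len(ids))
        kids = dnode.child_nodes()
        if not kids:
            label = dnode.taxon.label if dnode.taxon else (dnode.label or "")
            tip_label[nid] = label.strip()
            children[nid] = ()
        else:
            children[nid] = tuple(visit(k) for k in kids)
        return nid

    root = visit(dtree.seed_node)
    return Tree(root=root, children=children, tip_label=tip_label)


def _suppress_unary(tree: Tree) -> Tree:
    """Remove internal nodes with a single child, re-indexing nodes."""

    def resolve(n: int) -> int:
        while len(tree.children[n]) == 1:
            n = tree.children[n][0]
        return n

    children: dict[int, tuple[int, ...]] = {}
    tip_label: dict[int, str] = {}
    ids: dict[int, int] = {}

    def visit(n: int) -> int:
        n = resolve(n)
        nid = ids.setdefault(n, len(ids))
        kids = tree.children[n]
        if not kids:
            tip_label[nid] = tree.tip_label[n]
            children[nid] = ()
        else:
            children[nid] = tuple(visit(k) for k in kids)
        return nid

    root = visit(tree.root)
    return Tree(root=root, children=children, tip_label=tip_label)


def parse_newick(text: str) -> Tree:
    """Parse a Newick string into a branch-length-free :class:`Tree`.

    Branch lengths, if present, are discarded with a warning; internal node
    labels are dropped.  Duplicate tip labels and single-tip trees are
    rejected.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy error messages carry the position
        if "Duplicate" in type(exc).__name__:
            raise TreeValidationError(f"duplicate tip labels: {exc}") from exc
        raise NewickParseError(f"malformed Newick: {exc}") from exc

    if any(e.length is not None for e in dtree.preorder_edge_iter()):
        warnings.warn(
            "branch lengths present in Newick input were discarded; "
            "all computations use the topology only",
            UserWarning,
            stacklevel=2,
        )
    tree = _suppress_unary(_from_dendropy(dtree))
    if tree.n_tips < 2:
        raise TreeValidationError("a tree must have at least 2 tips")
    tree.validate()
    return tree


def _needs_quoting(label: str) -> bool:
    return any(c in label for c in "()[]{}:;,'\" \t\n")


def _format_label(label: str) -> str:
    if _needs_quoting(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: Tree) -> str:
    """Serialize a tree to Newick (no branch lengths, semicolon-terminated)."""

    def fmt(n: int) -> str:
        kids = tree.children[n]
        if not kids:
            return _format_label(tree.tip_label[n])
        return "(" + ",".join(fmt(k) for k in kids) + ")"

    return fmt(tree.root) + ";"


def read_newick_file(path) -> Tree:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_newick(fh.read())


# ---------------------------------------------------------------------------
# Tree surgery


def prune_to_taxa(tree: Tree, keep: Iterable[str]) -> Tree:
    """Restrict ``tree`` to the tips labelled in ``keep``.

    Internal nodes left with a single child are suppressed, so the relative
    topology among the kept tips is preserved exactly.
    """
    keep = set(keep)
    labels = set(tree.tip_label.values())
    unknown = sorted(keep - labels)
    if unknown:
        raise TreeValidationError(f"taxa not in tree: {unknown}")
    if len(keep) < 2:
        raise TreeValidationError("need at least 2 taxa to keep")

    def build(n: int) -> tuple[int, ...] | None:
        """Return surviving subtree rooted at n as nested structure, or None."""
        kids = tree.children[n]
        if not kids:
            return (n,) if tree.tip_label[n] in keep else None
        surviving = [s for s in (build(k) for k in kids) if s is not None]
        if not surviving:
            return None
        if len(surviving) == 1:
            return surviving[0]
        return (n, surviving)

    built = build(tree.root)
    assert built is not None

    children: dict[int, tuple[int, ...]] = {}
    tip_label: dict[int, str] = {}
    next_id = [0]

    def mat(node) -> int:
        nid = next_id[0]
        next_id[0] += 1
        if len(node) == 1:
            children[nid] = ()
            tip_label[nid] = tree.tip_label[node[0]]
        else:
            children[nid] = tuple(mat(k) for k in node[1])
        return nid

    root = mat(built)
    out = Tree(root=root, children=children, tip_label=tip_label)
    out.validate()
    return out


def virtual_tip_label(species: str, population: str) -> str:
    """Label used for a population's virtual tip on an enlarged tree."""
    return f"{species}{VIRTUAL_TIP_SEP}{population}"


def enlarge_with_replicates(
    tree: Tree, replicates: Mapping[str, Sequence[str]]
) -> EnlargedTree:
    """Graft population replicates under species tips as virtual sister-taxa.

    For each species with >=2 populations, the species tip is replaced — at
    exactly the same position — by an artificial internal node whose children
    are one virtual tip per population (labelled ``species::population``).
    Species with a single listed population, or not listed, remain ordinary
    tips.
    """
    for sp, pops in replicates.items():
        if len(pops) == 0:
            raise TreeValidationError(f"species {sp!r} has an empty replicate list")
        if len(set(pops)) != len(pops):
            raise TreeValidationError(f"species {sp!r} has duplicate population ids")
    tip_labels = set(tree.tip_label.values())
    missing = sorted(set(replicates) - tip_labels)
    if missing:
        raise TreeValidationError(f"replicated species not in tree: {missing}")

    children: dict[int, tuple[int, ...]] = {}
    tip_label: dict[int, str] = {}
    artificial: set[int] = set()
    species_of_artificial: dict[int, str] = {}
    virtual_tip_species: dict[int, str] = {}
    next_id = [0]

    def new_id() -> int:
        nid = next_id[0]
        next_id[0] += 1
        return nid

    def visit(n: int) -> int:
        kids = tree.children[n]
        nid = new_id()
        if kids:
            children[nid] = tuple(visit(k) for k in kids)
            return nid
        sp = tree.tip_label[n]
        pops = replicates.get(sp)
        if pops is None or len(pops) == 1:
            children[nid] = ()
            tip_label[nid] = sp
            virtual_tip_species[nid] = sp
            return nid
        # replicated species: nid becomes the artificial node
        virt = []
        for pop in pops:
            vid = new_id()
            children[vid] = ()
            tip_label[vid] = virtual_tip_label(sp, str(pop))
            virtual_tip_species[vid] = sp
            virt.append(vid)
        children[nid] = tuple(virt)
        artificial.add(nid)
        species_of_artificial[nid] = sp
        return nid

    root = visit(tree.root)
    out = EnlargedTree(
        tree=Tree(root=root, children=children, tip_label=tip_label),
        artificial_nodes=frozenset(artificial),
        species_of_artificial=species_of_artificial,
        virtual_tip_species=virtual_tip_species,
    )
    out.validate()
    return out


def collapse_artificial_nodes(enlarged: EnlargedTree) -> Tree:
    """Undo :func:`enlarge_with_replicates`: artificial nodes become species tips."""
    tree = enlarged.tree
    children: dict[int, tuple[int, ...]] = {}
    tip_label: dict[int, str] = {}
    next_id = [0]

    def visit(n: int) -> int:
        nid = next_id[0]
        next_id[0] += 1
        if n in enlarged.artificial_nodes:
            children[nid] = ()
            tip_label[nid] = enlarged.species_of_artificial[n]
            return nid
        kids = tree.children[n]
        if not kids:
            children[nid] = ()
            tip_label[nid] = tree.tip_label[n]
            return nid
        children[nid] = tuple(visit(k) for k in kids)
        return nid

    root = visit(tree.root)
    out = Tree(root=root, children=children, tip_label=tip_label)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Depth ranks


def _tip_depths(tree: Tree) -> dict[int, int]:
    """Max edge-count distance from each node down to a descendant tip."""
    depth: dict[int, int] = {}

    def visit(n: int) -> int:
        kids = tree.children[n]
        d = 0 if not kids else 1 + max(visit(k) for k in kids)
        depth[n] = d
        return d

    visit(tree.root)
    return depth


def _mrca(tree: Tree, tips: Sequence[int]) -> int:
    parents = tree.parent_map()

    def ancestors(n: int) -> list[int]:
        path = [n]
        while n in parents:
            n = parents[n]
            path.append(n)
        return path

    common = set(ancestors(tips[0]))
    for t in tips[1:]:
        common &= set(ancestors(t))
    # deepest common ancestor = the one farthest from root on tips[0]'s path
    for n in ancestors(tips[0]):
        if n in common:
            return n
    raise TreeValidationError("tips share no common ancestor")  # pragma: no cover


def depth_ranks(reference: Tree, enlarged: EnlargedTree) -> DepthRanks:
    """Rank the internal nodes of an enlarged tree by tip distance.

    Each non-artificial internal node is mapped to the reference tree (as the
    most recent common ancestor of its species) and assigned the maximum
    edge-count distance from that reference node to any of its descendant
    tips *in the reference tree*.  Nodes are then ranked by decreasing depth
    (average ranks on ties) and the ranks mapped affinely onto [0, 1]: 0 for
    the most tip-distant stratum.  Artificial nodes sit below original tips
    and receive the maximal tipward rank 1.
    """
    ref_depth = _tip_depths(reference)
    ref_tip = reference.tip_by_label()
    tree = enlarged.tree

    regular = [
        n for n in tree.internal_nodes if n not in enlarged.artificial_nodes
    ]
    depths: list[int] = []
    for n in regular:
        species = {
            enlarged.virtual_tip_species.get(t, tree.tip_label[t])
            for t in tree.tips_under(n)
        }
        missing = sorted(sp for sp in species if sp not in ref_tip)
        if missing:
            raise TreeValidationError(
                f"clade at node {n} has species absent from the reference "
                f"tree: {missing}"
            )
        mrca = _mrca(reference, [ref_tip[sp] for sp in species])
        depths.append(ref_depth[mrca])

    rank: dict[int, float] = {}
    if regular:
        raw = rankdata([-d for d in depths])  # 1 = deepest, ties averaged
        lo, hi = raw.min(), raw.max()
        span = hi - lo
        for n, r in zip(regular, raw):
            rank[n] = float((r - lo) / span) if span > 0 else 0.0
    for a in enlarged.artificial_nodes:
        rank[a] = 1.0
    return DepthRanks(rank=rank)
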