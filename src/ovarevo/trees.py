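"""Rooted phylogenies, newick I/O, and Brownian-motion covariance matrices.

A :class:`Phylogeny` is a rooted tree with branch lengths in absolute time
units.  Branch lengths must be non-negative (a Brownian-motion variance is
never negative); zero-length branches are allowed and contribute no
variance.  Tip labels are normalized (lowercased, trimmed, internal
whitespace collapsed to underscores) so that trait tables and trees can be
matched exactly.  Polytomies are preserved in the data model; likelihood
code that requires a bifurcating tree resolves them internally with
zero-length branches.

Newick parsing and writing are delegated to dendropy, including bracketed
``[&key=value]`` comment metadata used to serialize regime paintings and
ancestral-state paintings, and nexus ``trees`` blocks with translate
tables for posterior samples.
"""

from __future__ import annotations

import hashlib
import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import dendropy
import numpy as np

__all__ = [
    "TreeError",
    "Node",
    "Phylogeny",
    "TreeSample",
    "CovarianceMatrix",
    "normalize_label",
    "read_newick",
    "read_tree_sample",
    "write_newick",
    "write_annotated_newick",
    "write_tree_sample",
    "phylo_covariance",
    "prune_and_match",
    "branch_id",
]


class TreeError(ValueError):
    """Raised for malformed trees or tree/data mismatches."""


_WS = re.compile(r"\s+")


def normalize_label(label: str) -> str:
    """Normalize a taxon label: trim, lowercase, whitespace -> underscore."""
    return _WS.sub("_", label.strip().lower())


class Node:
    """A tree node; the branch above a non-root node belongs to that node."""

    __slots__ = ("index", "label", "parent", "children", "length", "annotations")

    def __init__(self, label: str | None = None, length: float | None = None):
        self.index: int = -1
        self.label = label
        self.parent: "Node | None" = None
        self.children: list["Node"] = []
        self.length = length
        self.annotations: dict[str, str] = {}

    @property
    def is_tip(self) -> bool:
        return not self.children

    @property
    def is_root(self) -> bool:
        return self.parent is None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "tip" if self.is_tip else f"internal({len(self.children)})"
        return f"<Node {self.index} {self.label!r} {kind} len={self.length}>"


class Phylogeny:
    """A rooted tree with branch lengths, indexed in preorder.

    ``nodes[0]`` is the root; iterating ``nodes`` visits parents before
    children, and iterating it reversed visits children before parents
    (a valid postorder for dynamic programming on the tree).
    """

    def __init__(self, root: Node, validate: bool = True):
        self.root = root
        self.nodes: list[Node] = []
        self._reindex()
        if validate:
            self._validate()

    def _reindex(self) -> None:
        self.nodes = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            node.index = len(self.nodes)
            self.nodes.append(node)
            stack.extend(reversed(node.children))

    def _validate(self) -> None:
        labels = [t.label for t in self.tips]
        if any(lbl is None or lbl == "" for lbl in labels):
            raise TreeError("every tip must carry a label")
        dup = {lbl for lbl in labels if labels.count(lbl) > 1}
        if dup:
            raise TreeError(f"duplicate tip label(s): {sorted(dup)}")
        for node in self.nodes:
            if node.is_root:
                continue
            if node.length is None:
                raise TreeError(f"missing branch length above {node.label!r}")
            if node.length < 0:
                raise TreeError(
                    f"negative branch length {node.length} above {node.label!r}"
                )

    # -- traversal ---------------------------------------------------------
    def preorder(self) -> Iterator[Node]:
        return iter(self.nodes)

    def postorder(self) -> Iterator[Node]:
        return reversed(self.nodes)

    @property
    def tips(self) -> list[Node]:
        return [n for n in self.nodes if n.is_tip]

    @property
    def internal_nodes(self) -> list[Node]:
        return [n for n in self.nodes if not n.is_tip]

    @property
    def tip_labels(self) -> list[str]:
        return [t.label for t in self.tips]

    @property
    def n_tips(self) -> int:
        return sum(1 for n in self.nodes if n.is_tip)

    # -- geometry ----------------------------------------------------------
    def depths(self) -> np.ndarray:
        """Root-to-node path length for every node, indexed by node.index."""
        out = np.zeros(len(self.nodes))
        for node in self.nodes:
            if node.parent is not None:
                out[node.index] = out[node.parent.index] + node.length
        return out

    @property
    def total_length(self) -> float:
        return float(sum(n.length for n in self.nodes if not n.is_root))

    @property
    def height(self) -> float:
        d = self.depths()
        return float(max(d[t.index] for t in self.tips))

    def is_ultrametric(self, tol: float = 1e-6) -> bool:
        d = self.depths()
        tip_d = [d[t.index] for t in self.tips]
        return (max(tip_d) - min(tip_d)) < tol

    def clade_tip_sets(self) -> dict[int, frozenset[str]]:
        """Tip-label set of the clade below each node, keyed by node index."""
        sets: dict[int, set[str]] = {n.index: set() for n in self.nodes}
        for node in self.postorder():
            if node.is_tip:
                sets[node.index].add(node.label)
            if node.parent is not None:
                sets[node.parent.index].update(sets[node.index])
        return {i: frozenset(s) for i, s in sets.items()}

    def find_tip(self, label: str) -> Node:
        label = normalize_label(label)
        for t in self.tips:
            if t.label == label:
                return t
        raise TreeError(f"tip {label!r} not in tree")

    def copy(self) -> "Phylogeny":
        def _clone(node: Node) -> Node:
            new = Node(node.label, node.length)
            new.annotations = dict(node.annotations)
            for child in node.children:
                new.add_child(_clone(child))
            return new

        return Phylogeny(_clone(self.root), validate=False)

    def resolve_polytomies(self) -> "Phylogeny":
        """Copy with every polytomy replaced by zero-length bifurcations."""
        out = self.copy()
        changed = False
        for node in list(out.nodes):
            while len(node.children) > 2:
                changed = True
                a = node.children.pop()
                b = node.children.pop()
                joint = Node(None, 0.0)
                joint.add_child(a)
                joint.add_child(b)
                node.add_child(joint)
        if changed:
            out._reindex()
        return out

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Phylogeny {self.n_tips} tips, {len(self.nodes)} nodes>"


@dataclass
class TreeSample:
    """An ordered posterior-like sample of trees plus a designated summary tree.

    All trees must share one tip-label set.  The summary tree (by default
    index 0) stands in for a maximum-clade-credibility tree; computing an
    MCC tree from the sample is out of scope.
    """

    trees: list[Phylogeny]
    summary_index: int = 0

    def __post_init__(self) -> None:
        if not self.trees:
            raise TreeError("TreeSample requires at least one tree")
        ref = set(self.trees[0].tip_labels)
        for i, t in enumerate(self.trees[1:], 1):
            if set(t.tip_labels) != ref:
                raise TreeError(f"tree {i} has a different tip set than tree 0")
        if not 0 <= self.summary_index < len(self.trees):
            raise TreeError("summary_index out of range")

    @property
    def summary(self) -> Phylogeny:
        return self.trees[self.summary_index]

    def cycled(self, i: int) -> Phylogeny:
        """Tree for replicate ``i``: replicate i uses posterior tree i (cycled)."""
        return self.trees[i % len(self.trees)]

    def __len__(self) -> int:
        return len(self.trees)


@dataclass
class CovarianceMatrix:
    """Shared-path-length (Brownian motion) covariance among tips."""

    matrix: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.labels), len(self.labels)):
            raise TreeError("covariance shape does not match label count")

    @property
    def n(self) -> int:
        return len(self.labels)

    def reorder(self, labels: Sequence[str]) -> "CovarianceMatrix":
        idx = [self.labels.index(normalize_label(l)) for l in labels]
        return CovarianceMatrix(self.matrix[np.ix_(idx, idx)], tuple(self.labels[i] for i in idx))


# ---------------------------------------------------------------------------
# newick I/O (via dendropy)
# ---------------------------------------------------------------------------


def _from_dendropy(dtree: dendropy.Tree) -> Phylogeny:
    def _convert(dnode) -> Node:
        label = None
        if dnode.taxon is not None and dnode.taxon.label is not None:
            label = normalize_label(dnode.taxon.label)
        elif dnode.label:
            label = normalize_label(dnode.label)
        node = Node(label, dnode.edge.length)
        for key, value in dnode.annotations.values_as_dict().items():
            node.annotations[str(key)] = str(value)
        for dchild in dnode.child_nodes():
            node.add_child(_convert(dchild))
        return node

    root = _convert(dtree.seed_node)
    if root.length is None:
        root.length = None  # root carries no branch
    try:
        return Phylogeny(root)
    except TreeError as exc:
        raise TreeError(f"invalid tree: {exc}") from exc


def read_newick(text: str) -> Phylogeny:
    """Parse a single newick tree (optionally with ``[&k=v]`` annotations).

    Raises :class:`TreeError` naming the offending token for unbalanced
    parentheses, duplicate tip labels, or negative branch lengths.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            extract_comment_metadata=True,
        )
    except Exception as exc:
        raise TreeError(f"newick parse error: {exc}") from exc
    return _from_dendropy(dtree)


def read_tree_sample(
    text: str | None = None,
    path: str | None = None,
    schema: str = "newick",
    summary_index: int = 0,
) -> TreeSample:
    """Read a multi-tree file (newick, one tree per line, or nexus trees block)."""
    if (text is None) == (path is None):
        raise ValueError("provide exactly one of text or path")
    src = {"data": text} if text is not None else {"path": path}
    try:
        dtrees = dendropy.TreeList.get(
            schema=schema,
            suppress_internal_node_taxa=True,
            extract_comment_metadata=True,
            **src,
        )
    except Exception as exc:
        raise TreeError(f"tree sample parse error: {exc}") from exc
    if len(dtrees) == 0:
        raise TreeError("no trees found")
    return TreeSample([_from_dendropy(t) for t in dtrees], summary_index=summary_index)


def _to_dendropy(
    tree: Phylogeny,
    annotations: Mapping[int, Mapping[str, str]] | None = None,
    taxon_namespace: dendropy.TaxonNamespace | None = None,
) -> dendropy.Tree:
    ns = taxon_namespace if taxon_namespace is not None else dendropy.TaxonNamespace()
    dtree = dendropy.Tree(taxon_namespace=ns)

    def _convert(node: Node, dnode) -> None:
        dnode.edge.length = node.length
        if node.is_tip:
            dnode.taxon = ns.require_taxon(label=node.label)
        merged = dict(node.annotations)
        if annotations is not None and node.index in annotations:
            merged.update(annotations[node.index])
        for key, value in merged.items():
            dnode.annotations.add_new(key, value)
        for child in node.children:
            _convert(child, dnode.new_child())

    _convert(tree.root, dtree.seed_node)
    return dtree


def write_newick(tree: Phylogeny, annotations: Mapping[int, Mapping[str, str]] | None = None) -> str:
    """Serialize to newick; branch lengths at full double precision."""
    dtree = _to_dendropy(tree, annotations)
    s = dtree.as_string(
        schema="newick",
        suppress_annotations=False,
        suppress_rooting=True,
        real_value_format_specifier=".17g",
    )
    return s.strip() + "\n"


def write_annotated_newick(
    tree: Phylogeny,
    annotations: Mapping[int, str] | Mapping[Node, str] | None = None,
    key: str = "regime",
) -> str:
    """Newick with one ``[&key=label]`` comment per annotated branch.

    ``annotations`` maps nodes (or node indices) to a label attached to the
    branch subtending that node.  ``read_newick`` of the output recovers
    topology, lengths, and annotations.
    """
    per_node: dict[int, dict[str, str]] = {}
    if annotations:
        for k, label in annotations.items():
            idx = k.index if isinstance(k, Node) else int(k)
            if not 0 <= idx < len(tree.nodes):
                raise TreeError(f"annotation key {k!r} is not a node of this tree")
            per_node[idx] = {key: str(label)}
    return write_newick(tree, per_node)


def write_tree_sample(sample: TreeSample) -> str:
    """Multi-tree newick, one tree per line, summary tree first if index 0."""
    return "".join(write_newick(t) for t in sample.trees)


# ---------------------------------------------------------------------------
# covariance, pruning, identifiers
# ---------------------------------------------------------------------------


def phylo_covariance(tree: Phylogeny, tips: Sequence[str] | None = None) -> CovarianceMatrix:
    """Brownian-motion covariance: C[i,j] = root-to-MRCA(i,j) path length.

    The diagonal holds root-to-tip depths.  ``tips`` selects and orders the
    tips; unknown labels raise :class:`TreeError` listing the missing ones.
    """
    all_tips = tree.tips
    order = {t.index: k for k, t in enumerate(all_tips)}
    n = len(all_tips)
    C = np.zeros((n, n))
    # membership mask of tips under each node, built tips-first (postorder)
    masks = np.zeros((len(tree.nodes), n), dtype=bool)
    for node in tree.postorder():
        if node.is_tip:
            masks[node.index, order[node.index]] = True
        if node.parent is not None:
            masks[node.parent.index] |= masks[node.index]
    for node in tree.nodes:
        if node.is_root or node.length == 0:
            continue
        m = masks[node.index]
        C[np.ix_(m, m)] += node.length
    labels = tuple(t.label for t in all_tips)
    cov = CovarianceMatrix(C, labels)
    if tips is not None:
        wanted = [normalize_label(t) for t in tips]
        missing = [w for w in wanted if w not in labels]
        if missing:
            raise TreeError(f"tips not in tree: {missing}")
        cov = cov.reorder(wanted)
    return cov


def prune_and_match(tree: Phylogeny, taxa: Iterable[str]) -> Phylogeny:
    """Restrict the tree to the requested tips.

    Unbranched internal nodes are suppressed with branch lengths summed, so
    every retained tip keeps its original root-to-tip depth.  The root is
    retained even if it ends up with a single child.
    """
    wanted = {normalize_label(t) for t in taxa}
    present = wanted & set(tree.tip_labels)
    if not present:
        raise TreeError("no requested taxa present in tree")

    def _prune(node: Node) -> Node | None:
        if node.is_tip:
            if node.label in present:
                new = Node(node.label, node.length)
                new.annotations = dict(node.annotations)
                return new
            return None
        kept = [c for c in (_prune(ch) for ch in node.children) if c is not None]
        if not kept:
            return None
        if len(kept) == 1 and node.parent is not None:
            # suppress this unary node: splice child onto the parent edge
            child = kept[0]
            child.length = (child.length or 0.0) + (node.length or 0.0)
            return child
        new = Node(node.label, node.length)
        new.annotations = dict(node.annotations)
        for c in kept:
            new.add_child(c)
        return new

    root = _prune(tree.root)
    assert root is not None
    return Phylogeny(root)


def branch_id(tree: Phylogeny, node: Node) -> str:
    """Stable identifier for the branch above ``node``.

    Tips use their label; internal branches use a short hash of the sorted
    tip set of their clade, so the id survives serialization round trips.
    """
    if node.is_tip:
        return node.label
    sets = tree.clade_tip_sets()
    return _clade_hash(sets[node.index])


def _clade_hash(labels: frozenset[str]) -> str:
    joined = "|".join(sorted(labels))
    return "c" + hashlib.md5(joined.encode()).hexdigest()[:12]


def branch_id_map(tree: Phylogeny) -> dict[int, str]:
    """branch_id for every non-root node, computed in one pass."""
    sets = tree.clade_tip_sets()
    out = {}
    for node in tree.nodes:
        if node.is_root:
            continue
        out[node.index] = node.label if node.is_tip else _clade_hash(sets[node.index])
    return out
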