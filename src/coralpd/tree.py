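"""Rooted ultrametric time trees: data model, Newick I/O, pruning, polytomy
resolution and root-clade extraction.

A :class:`TimeTree` stores node *ages* in millions of years before present
(tips at 0, root oldest); edge lengths are derived as ``parent.age - age``.
All downstream statistics (gamma, Colless, the D statistic, Faith's PD)
operate on this representation.  Trees are treated as immutable once built:
every operation returns a new tree, which lets us cache a flattened array
encoding used by the vectorised null-model machinery.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "TimeTree",
    "Node",
    "TreeSample",
    "TreeError",
    "parse_newick",
    "write_newick",
    "read_tree_file",
    "prune_to",
    "resolve_polytomies",
    "root_daughter_clades",
]

ULTRAMETRIC_TOL = 1e-6  # absolute, My


class TreeError(ValueError):
    """Raised for malformed or invalid trees."""


class Node:
    """A tree node: ``age`` in My before present; ``label`` set on tips only."""

    __slots__ = ("children", "age", "label")

    def __init__(self, age: float = 0.0, label: str | None = None,
                 children: list["Node"] | None = None):
        self.age = age
        self.label = label
        self.children = children if children is not None else []

    @property
    def is_tip(self) -> bool:
        return not self.children


@dataclass
class _FlatTree:
    """Array encoding of a tree in postorder, for vectorised computation.

    ``parent[i]`` is -1 for the root; ``edge[i]`` is the length of the edge
    above node ``i`` (0 for the root).  ``tip_pos[j]`` is the flat index of
    the j-th tip in ``tip_labels`` order.  ``left``/``right`` are child
    indices for binary trees (-1 on tips) and are only populated when the
    tree is strictly binary.
    """

    parent: np.ndarray
    edge: np.ndarray
    age: np.ndarray
    children: list[list[int]]
    tip_pos: np.ndarray
    tip_labels: list[str]
    left: np.ndarray | None = None
    right: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)


class TimeTree:
    """Rooted ultrametric phylogeny with node ages in My before present."""

    def __init__(self, root: Node, validate: bool = True):
        self.root = root
        self._flat: _FlatTree | None = None
        if validate:
            self.validate()

    # -- traversal ---------------------------------------------------------
    def postorder(self):
        """Yield nodes children-first (iterative; safe for deep trees)."""
        stack = [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                yield node
            else:
                stack.append((node, True))
                for c in reversed(node.children):
                    stack.append((c, False))

    def preorder(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            for c in reversed(node.children):
                stack.append(c)

    @property
    def tips(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_tip]

    @property
    def tip_labels(self) -> list[str]:
        return [n.label for n in self.tips]

    @property
    def n_tips(self) -> int:
        return sum(1 for n in self.postorder() if n.is_tip)

    @property
    def root_age(self) -> float:
        return self.root.age

    @property
    def is_binary(self) -> bool:
        return all(len(n.children) == 2 for n in self.postorder()
                   if not n.is_tip)

    def total_branch_length(self) -> float:
        """Sum of all edge lengths (My); Faith's PD of the full tip set."""
        total = 0.0
        for node in self.postorder():
            for c in node.children:
                total += node.age - c.age
        return total

    def internal_ages(self) -> np.ndarray:
        return np.array([n.age for n in self.postorder() if not n.is_tip])

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        tips = self.tips
        if len(tips) < 2:
            raise TreeError(f"tree has {len(tips)} tip(s); need at least 2")
        labels = [t.label for t in tips]
        if any(not lab for lab in labels):
            raise TreeError("every tip needs a non-empty label")
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeError(f"duplicate tip labels: {dup}")
        if not self.root.age > 0:
            raise TreeError(f"root age must be positive, got {self.root.age}")
        worst_lab, worst_age = None, 0.0
        for t in tips:
            if abs(t.age) > abs(worst_age):
                worst_lab, worst_age = t.label, t.age
        if abs(worst_age) > ULTRAMETRIC_TOL:
            raise TreeError(
                f"tree is not ultrametric: tip {worst_lab!r} has age "
                f"{worst_age:.6g} My (|age| > {ULTRAMETRIC_TOL:g})")
        for node in self.postorder():
            for c in node.children:
                if node.age - c.age < -ULTRAMETRIC_TOL:
                    raise TreeError(
                        f"negative edge length {node.age - c.age:.6g} above "
                        f"node aged {c.age:.6g}")

    # -- derived structures ------------------------------------------------
    def flat(self) -> _FlatTree:
        """Flattened postorder array encoding (cached)."""
        if self._flat is None:
            order = list(self.postorder())
            index = {id(n): i for i, n in enumerate(order)}
            m = len(order)
            parent = np.full(m, -1, dtype=np.int64)
            edge = np.zeros(m)
            age = np.zeros(m)
            children: list[list[int]] = [[] for _ in range(m)]
            for i, node in enumerate(order):
                age[i] = node.age
                for c in node.children:
                    j = index[id(c)]
                    parent[j] = i
                    edge[j] = node.age - c.age
                    children[i].append(j)
            tip_pos = np.array([i for i, n in enumerate(order) if n.is_tip],
                               dtype=np.int64)
            tip_labels = [order[i].label for i in tip_pos]
            binary = all(len(c) in (0, 2) for c in children)
            left = right = None
            if binary:
                left = np.full(m, -1, dtype=np.int64)
                right = np.full(m, -1, dtype=np.int64)
                for i, cs in enumerate(children):
                    if cs:
                        left[i], right[i] = cs
            self._flat = _FlatTree(parent, edge, age, children, tip_pos,
                                   tip_labels, left, right)
        return self._flat

    def copy(self) -> "TimeTree":
        def rec(node: Node) -> Node:
            return Node(node.age, node.label, [rec(c) for c in node.children])
        return TimeTree(rec(self.root), validate=False)

    def scaled(self, factor: float) -> "TimeTree":
        """Return a copy with all ages multiplied by ``factor`` (> 0)."""
        if factor <= 0:
            raise TreeError("scale factor must be positive")
        out = self.copy()
        for node in out.postorder():
            node.age *= factor
        return out

    def tip_distance_matrix(self) -> tuple[list[str], np.ndarray]:
        """Pairwise patristic distances between tips (brute force).

        On an ultrametric tree d(x, y) = 2 * age(MRCA(x, y)); computed here
        from root-to-tip paths so it doubles as an independent check.
        """
        labs = self.tip_labels
        n = len(labs)
        paths: dict[str, list[Node]] = {}

        def walk(node, acc):
            acc = acc + [node]
            if node.is_tip:
                paths[node.label] = acc
            for c in node.children:
                walk(c, acc)

        walk(self.root, [])
        dist = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                pi, pj = paths[labs[i]], paths[labs[j]]
                shared = 0
                for a, b in zip(pi, pj):
                    if a is b:
                        shared += 1
                    else:
                        break
                mrca = pi[shared - 1]
                dist[i, j] = dist[j, i] = 2 * mrca.age
        return labs, dist


@dataclass
class TreeSample:
    """An ordered sample of trees over one shared tip-label set, e.g. a
    posterior sample with one tree per Newick line."""

    trees: list[TimeTree] = field(default_factory=list)

    def __post_init__(self):
        if not self.trees:
            raise TreeError("TreeSample must contain at least one tree")
        ref = set(self.trees[0].tip_labels)
        for k, t in enumerate(self.trees[1:], start=1):
            if set(t.tip_labels) != ref:
                raise TreeError(
                    f"tree {k} has a different tip set from tree 0")

    def __len__(self):
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def __getitem__(self, i):
        return self.trees[i]

    @property
    def tip_labels(self) -> list[str]:
        return self.trees[0].tip_labels


# ---------------------------------------------------------------------------
# Newick I/O (parsing delegated to dendropy)
# ---------------------------------------------------------------------------

def _from_dendropy(dtree: dendropy.Tree) -> TimeTree:
    depth: dict[int, float] = {id(dtree.seed_node): 0.0}
    for dnode in dtree.preorder_node_iter():
        if dnode is dtree.seed_node:
            continue
        if dnode.edge.length is None:
            raise TreeError("branch length missing on a non-root edge")
        depth[id(dnode)] = depth[id(dnode.parent_node)] + dnode.edge.length
    leaves = list(dtree.leaf_node_iter())
    if len(leaves) < 2:
        raise TreeError(f"tree has {len(leaves)} tip(s); need at least 2")
    root_age = max(depth[id(l)] for l in leaves)
    worst = max(leaves, key=lambda l: abs(root_age - depth[id(l)]))
    worst_dev = root_age - depth[id(worst)]
    if abs(worst_dev) > ULTRAMETRIC_TOL:
        raise TreeError(
            f"tree is not ultrametric: tip "
            f"{worst.taxon.label if worst.taxon else '?'!r} sits "
            f"{worst_dev:.6g} My off the present (tol {ULTRAMETRIC_TOL:g})")

    def rec(dnode) -> Node:
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon else dnode.label
            return Node(0.0, label)
        return Node(root_age - depth[id(dnode)], None,
                    [rec(c) for c in dnode.child_nodes()])

    return TimeTree(rec(dtree.seed_node))


def parse_newick(text: str) -> TimeTree:
    """Parse one rooted ultrametric Newick string into a :class:`TimeTree`.

    Node ages are reconstructed from root-to-node path lengths, taking the
    root age as the maximum root-to-tip distance; deviations from
    ultrametricity beyond 1e-6 My are rejected.
    """
    try:
        dtree = dendropy.Tree.get(data=text, schema="newick",
                                  suppress_internal_node_taxa=True)
    except Exception as exc:  # dendropy raises assorted error types
        raise TreeError(f"malformed Newick: {exc}") from exc
    return _from_dendropy(dtree)


def _fmt_label(label: str) -> str:
    if any(ch in label for ch in " \t(),:;[]'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: TimeTree) -> str:
    """Serialise a tree to Newick with branch lengths; round-trips through
    :func:`parse_newick` with edge lengths preserved to ~1e-12 relative."""
    out = io.StringIO()

    def rec(node: Node, parent_age: float | None):
        if node.is_tip:
            out.write(_fmt_label(node.label))
        else:
            out.write("(")
            for k, c in enumerate(node.children):
                if k:
                    out.write(",")
                rec(c, node.age)
            out.write(")")
        if parent_age is not None:
            out.write(":" + format(parent_age - node.age, ".12g"))

    rec(tree.root, None)
    out.write(";")
    return out.getvalue()


def read_tree_file(path) -> TreeSample:
    """Read a tree sample: plain Newick (one tree per line) or a NEXUS file
    with a trees block (translate tables handled by dendropy)."""
    with open(path) as fh:
        text = fh.read()
    if text.lstrip().upper().startswith("#NEXUS"):
        dlist = dendropy.TreeList.get(data=text, schema="nexus")
        trees = [_from_dendropy(t) for t in dlist]
    else:
        trees = [parse_newick(line) for line in text.splitlines()
                 if line.strip()]
    if not trees:
        raise TreeError(f"no trees found in {path}")
    return TreeSample(trees)


# ---------------------------------------------------------------------------
# Structural operations
# ---------------------------------------------------------------------------

def prune_to(tree: TimeTree, keep) -> TimeTree:
    """Induced subtree on ``keep`` (>= 2 tip labels).

    Unary nodes created by the pruning are suppressed (incident edge lengths
    merge because ages are kept); the result is rooted at the MRCA of the
    kept tips, with no stem edge above it.
    """
    keep = set(keep)
    have = set(tree.tip_labels)
    unknown = sorted(keep - have)
    if unknown:
        raise TreeError(f"labels not in tree: {unknown}")
    if len(keep) < 2:
        raise TreeError(f"need at least 2 tips to keep, got {len(keep)}")

    def rec(node: Node) -> Node | None:
        if node.is_tip:
            return Node(node.age, node.label) if node.label in keep else None
        kept = [k for k in (rec(c) for c in node.children) if k is not None]
        if not kept:
            return None
        if len(kept) == 1:
            return kept[0]  # unary suppression: child keeps its own age
        return Node(node.age, None, kept)

    return TimeTree(rec(tree.root))


def resolve_polytomies(tree: TimeTree, rng: np.random.Generator) -> TimeTree:
    """Randomly resolve every multifurcation into bifurcations.

    Children of a polytomy are paired sequentially, each pair chosen
    uniformly at random; each new internal node's age is drawn uniformly
    between the polytomy's age and the older of the two children it joins,
    so ultrametricity and non-negative edge lengths are preserved.
    Deterministic for a given generator state.
    """
    out = tree.copy()
    for node in list(out.postorder()):
        while len(node.children) > 2:
            i, j = rng.choice(len(node.children), size=2, replace=False)
            i, j = (int(i), int(j)) if i < j else (int(j), int(i))
            b = node.children.pop(j)
            a = node.children.pop(i)
            lo = max(a.age, b.age)
            age = float(rng.uniform(lo, node.age))
            node.children.append(Node(age, None, [a, b]))
    out._flat = None
    out.validate()
    return out


def root_daughter_clades(tree: TimeTree) -> tuple[set[str], set[str]]:
    """Tip-label sets of the two clades subtended by a binary root."""
    if len(tree.root.children) != 2:
        raise TreeError(
            f"root has {len(tree.root.children)} children; resolve "
            "polytomies first")

    a, b = tree.root.children
    return _tips_below(a), _tips_below(b)


def _tips_below(node: Node) -> set[str]:
    out, stack = set(), [node]
    while stack:
        n = stack.pop()
        if n.is_tip:
            out.add(n.label)
        else:
            stack.extend(n.children)
    return out
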