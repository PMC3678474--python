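"""Tree-shape statistics and their pure-birth (Yule) nulls.

Two classic statistics summarise an ultrametric tree:

* the gamma statistic, which compares the spacing of internal-node ages to
  the pure-birth expectation — asymptotically standard normal under the
  Yule model, positive when divergences crowd toward the present;
* Colless' imbalance index, the sum over internal nodes of the absolute
  difference in descendant-tip counts between the two daughter clades,
  compared against a Monte-Carlo Yule null (topology only, so null trees
  need no age rescaling).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tree import Node, TimeTree, TreeError

__all__ = [
    "LineageIntervals",
    "ShapeStats",
    "lineage_intervals",
    "gamma_statistic",
    "colless_index",
    "simulate_yule",
    "colless_yule_test",
]


@dataclass
class LineageIntervals:
    """Internode intervals of an ultrametric binary tree.

    ``g[k]`` (k = 2..n) is the duration in My during which exactly k
    lineages exist, walking from the root toward the present; stored as an
    array of length n-1 with ``g[0]`` corresponding to k = 2.  ``T`` is the
    total lineage-time sum_{j=2}^{n} j * g_j.
    """

    n: int
    g: np.ndarray

    @property
    def T(self) -> float:
        k = np.arange(2, self.n + 1)
        return float(np.sum(k * self.g))

    @property
    def root_age(self) -> float:
        return float(np.sum(self.g))


def lineage_intervals(tree: TimeTree) -> LineageIntervals:
    """Compute g[2..n] from the sorted internal-node ages of a binary tree.

    Simultaneous splits (tied ages) produce legal zero-length intervals.
    """
    n = tree.n_tips
    if n < 3:
        raise TreeError(f"lineage intervals need n >= 3 tips, got {n}")
    if not tree.is_binary:
        raise TreeError("tree must be binary; resolve polytomies first")
    ages = np.sort(tree.internal_ages())[::-1]  # a_1 = root age, descending
    g = np.empty(n - 1)
    g[:-1] = ages[:-1] - ages[1:]   # g_k = a_{k-1} - a_k, k = 2..n-1
    g[-1] = ages[-1]                # g_n: last split to the present
    return LineageIntervals(n=n, g=g)


def gamma_statistic(tree: TimeTree) -> float:
    """Pybus–Harvey gamma; standard normal under the Yule model.

    gamma = [ (1/(n-2)) * sum_{i=2}^{n-1} sum_{k=2}^{i} k*g_k  -  T/2 ]
            / ( T * sqrt(1 / (12 (n-2))) )

    Positive gamma: internal nodes concentrated near the present (edges
    near the root longer than near the tips); negative: the reverse.
    Invariant under rescaling all ages by a positive constant.
    """
    iv = lineage_intervals(tree)
    n, g = iv.n, iv.g
    k = np.arange(2, n + 1)
    kg = k * g
    inner = np.cumsum(kg)[:-1]          # sum_{k=2}^{i} k*g_k for i = 2..n-1
    T = iv.T
    num = inner.mean() - T / 2.0
    den = T * np.sqrt(1.0 / (12.0 * (n - 2)))
    return float(num / den)


def _tip_counts(tree: TimeTree) -> dict[int, int]:
    counts: dict[int, int] = {}
    for node in tree.postorder():
        counts[id(node)] = 1 if node.is_tip else sum(
            counts[id(c)] for c in node.children)
    return counts


def colless_index(tree: TimeTree) -> int:
    """Sum over internal nodes of |tips(left) - tips(right)|.

    0 for a fully balanced tree, (n-1)(n-2)/2 for a caterpillar; depends on
    topology only, so it is invariant under child-order permutation and any
    branch-length change.
    """
    if not tree.is_binary:
        raise TreeError("Colless' index requires a binary tree")
    counts = _tip_counts(tree)
    total = 0
    for node in tree.postorder():
        if not node.is_tip:
            a, b = node.children
            total += abs(counts[id(a)] - counts[id(b)])
    return total


def simulate_yule(n: int, rng: np.random.Generator) -> TimeTree:
    """Simulate a pure-birth tree with n tips and unit speciation rate.

    Starting from two lineages at the root, the process waits an
    Exponential(k) time while k lineages exist and splits a uniformly
    chosen lineage, up to n lineages; a final Exponential(n) interval
    separates the last split from the present, so the internode intervals
    g_k are independent Exponential(k) draws — the construction under which
    gamma is asymptotically standard normal.
    """
    if n < 2:
        raise TreeError(f"need n >= 2 tips, got {n}")
    g = rng.exponential(1.0 / np.arange(2, n + 1))  # g_k, k = 2..n
    total = float(g.sum())
    root = Node(age=total)
    a, b = Node(), Node()
    root.children = [a, b]
    active = [a, b]
    t = 0.0
    for k in range(2, n):  # create lineages 3..n
        t += g[k - 2]
        i = int(rng.integers(len(active)))
        node = active[i]
        node.age = total - t
        c1, c2 = Node(), Node()
        node.children = [c1, c2]
        active[i] = c1
        active.append(c2)
    for j, node in enumerate(active):
        node.age = 0.0
        node.label = f"t{j + 1}"
    return TimeTree(root)


@dataclass
class ShapeStats:
    """Shape summary for one tree: gamma, Colless and its Yule-null p."""

    n: int
    gamma: float
    colless: int
    colless_p: float
    yule_reps: int
    seed: int | None = None


def colless_yule_test(tree: TimeTree, reps: int = 1000,
                      rng: np.random.Generator | None = None,
                      seed: int | None = None) -> ShapeStats:
    """Compare the observed Colless' index against ``reps`` simulated Yule
    trees of the same tip count.

    The one-tailed upper p-value uses the add-one Monte-Carlo convention
    p = (1 + #{null >= observed}) / (reps + 1), which never returns 0.
    """
    if reps < 1:
        raise ValueError(f"reps must be >= 1, got {reps}")
    n = tree.n_tips
    if n < 4:
        raise TreeError(f"Colless test needs n >= 4 tips, got {n}")
    if rng is None:
        rng = np.random.default_rng(seed)
    obs = colless_index(tree)
    exceed = 0
    for _ in range(reps):
        if colless_index(simulate_yule(n, rng)) >= obs:
            exceed += 1
    p = (1 + exceed) / (reps + 1)
    return ShapeStats(n=n, gamma=gamma_statistic(tree), colless=obs,
                      colless_p=p, yule_reps=reps, seed=seed)
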