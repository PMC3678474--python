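"""Phylogenetic clustering of a binary trait: the D statistic.

D measures how clumped the 1-state of a binary trait is on a phylogeny.
The raw quantity d is the sum of sister-clade disparities: nodal trait
values are estimated bottom-up as the mean of the two daughter values
(tips contribute their 0/1 state) and d adds |left - right| over all
internal nodes.  d is then centred and scaled between two prevalence-
conditioned nulls,

    D = (d_obs - mean d_Brownian) / (mean d_random - mean d_Brownian),

so that D = 1 matches random label shuffles and D = 0 matches a trait
produced by thresholding a Brownian liability (maximally phylogenetically
conserved at that prevalence).  Values outside [0, 1] are legitimate and
are not clamped.  d depends on topology only; the Brownian null (and hence
D) also depends on branch lengths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tree import TimeTree, TreeError

__all__ = [
    "TraitVector",
    "DResult",
    "sister_clade_disparity_sum",
    "simulate_bm_threshold",
    "phylo_d",
]


class TraitVector:
    """Binary (0/1) trait over a set of tip labels."""

    def __init__(self, states: dict[str, int], name: str | None = None):
        bad = {k: v for k, v in states.items() if v not in (0, 1)}
        if bad:
            raise ValueError(f"non-binary trait states: {bad}")
        self.states = dict(states)
        self.name = name

    def __len__(self):
        return len(self.states)

    def __getitem__(self, label):
        return self.states[label]

    @property
    def prevalence(self) -> float:
        return sum(self.states.values()) / len(self.states)

    @property
    def n_ones(self) -> int:
        return sum(self.states.values())

    def carriers(self) -> set[str]:
        return {k for k, v in self.states.items() if v == 1}

    def restrict(self, labels) -> "TraitVector":
        labels = set(labels)
        return TraitVector({k: v for k, v in self.states.items()
                            if k in labels}, name=self.name)

    def values_for(self, tree: TimeTree) -> np.ndarray:
        """0/1 array aligned with ``tree.tip_labels`` order."""
        missing = [lab for lab in tree.tip_labels if lab not in self.states]
        if missing:
            raise TreeError(
                f"trait missing {len(missing)} tip(s), e.g. {missing[:5]}")
        return np.array([self.states[lab] for lab in tree.tip_labels],
                        dtype=float)


def _require_binary(tree: TimeTree):
    ft = tree.flat()
    if ft.left is None:
        raise TreeError("operation requires a binary tree")
    return ft


def _disparity_sums(tree: TimeTree, tip_values: np.ndarray) -> np.ndarray:
    """Sister-clade disparity sum for each column of ``tip_values``.

    ``tip_values`` has shape (n_tips, R) in ``tree.tip_labels`` order; one
    postorder sweep handles all R replicates at once.
    """
    ft = _require_binary(tree)
    m = ft.n_nodes
    R = tip_values.shape[1]
    vals = np.empty((m, R))
    vals[ft.tip_pos] = tip_values
    d = np.zeros(R)
    left, right = ft.left, ft.right
    for i in range(m):  # postorder: children precede parents
        l = left[i]
        if l >= 0:
            r = right[i]
            d += np.abs(vals[l] - vals[r])
            vals[i] = 0.5 * (vals[l] + vals[r])
    return d


def sister_clade_disparity_sum(tree: TimeTree, trait: TraitVector) -> float:
    """The raw d: sum over internal nodes of |value(left) - value(right)|
    with nodal values the recursive daughter means."""
    v = trait.values_for(tree)
    k = int(v.sum())
    if k == 0 or k == len(v):
        raise TreeError("D undefined: trait is monomorphic on this tree")
    return float(_disparity_sums(tree, v[:, None])[0])


def _bm_tip_liabilities(tree: TimeTree, R: int,
                        rng: np.random.Generator) -> np.ndarray:
    """R independent Brownian liabilities at the tips (rate 1 per My,
    root value 0); shape (n_tips, R)."""
    ft = tree.flat()
    m = ft.n_nodes
    sd = np.sqrt(np.maximum(ft.edge, 0.0))
    z = rng.standard_normal((m, R))
    vals = np.empty((m, R))
    for i in range(m - 1, -1, -1):  # reverse postorder = parents first
        p = ft.parent[i]
        if p < 0:
            vals[i] = 0.0
        else:
            vals[i] = vals[p] + sd[i] * z[i]
    return vals[ft.tip_pos]


def _threshold_top_k(liab: np.ndarray, k: int) -> np.ndarray:
    """Binarise each column of ``liab`` by ranking: top-k liabilities -> 1.

    Rank thresholding preserves the prevalence exactly, matching the
    prevalence-conditioned construction of the D nulls.
    """
    n, R = liab.shape
    order = np.argsort(-liab, axis=0, kind="stable")
    out = np.zeros((n, R))
    np.put_along_axis(out, order[:k], 1.0, axis=0)
    return out


def simulate_bm_threshold(tree: TimeTree, n_ones: int,
                          rng: np.random.Generator) -> TraitVector:
    """One Brownian-threshold trait: simulate a liability by Brownian
    motion along branches (variance proportional to branch length in My)
    and assign state 1 to the ``n_ones`` tips with the largest values."""
    n = tree.n_tips
    if not 1 <= n_ones <= n - 1:
        raise ValueError(f"n_ones must be in [1, {n - 1}], got {n_ones}")
    liab = _bm_tip_liabilities(tree, 1, rng)
    states = _threshold_top_k(liab, n_ones)[:, 0]
    return TraitVector({lab: int(s) for lab, s in
                        zip(tree.tip_labels, states)})


@dataclass
class DResult:
    """Observed disparity sum, its two null means, scaled D and one-tailed
    p-values against each null."""

    d_obs: float
    mean_d_random: float
    mean_d_brownian: float
    D: float
    p_random: float      # departure from the shuffle null toward clumping
    p_brownian: float    # departure from the Brownian null toward random
    reps: int
    seed: int | None = None

    @property
    def ns_vs_random(self) -> bool:
        """Not highly significantly different from random (D = 1)."""
        return self.p_random > 0.01

    @property
    def ns_vs_clumped(self) -> bool:
        """Not highly significantly different from clumped (D = 0)."""
        return self.p_brownian > 0.01


def phylo_d(tree: TimeTree, trait: TraitVector, reps: int = 1000,
            rng: np.random.Generator | None = None,
            seed: int | None = None) -> DResult:
    """Estimate D with ``reps`` shuffle-null and ``reps`` Brownian-null
    replicates, both conditioned on the observed prevalence.

    p_random  = (1 + #{d_shuffle <= d_obs}) / (reps + 1)
    p_brownian = (1 + #{d_brownian >= d_obs}) / (reps + 1)
    """
    if reps < 1:
        raise ValueError(f"reps must be >= 1, got {reps}")
    if rng is None:
        rng = np.random.default_rng(seed)
    v = trait.values_for(tree)
    n = len(v)
    k = int(v.sum())
    if k == 0 or k == n:
        raise TreeError("D undefined: trait is monomorphic on this tree")
    d_obs = float(_disparity_sums(tree, v[:, None])[0])

    # shuffle null: permute labels, prevalence preserved
    perm = np.argsort(rng.random((reps, n)), axis=1)
    shuffled = v[perm].T                      # (n, reps)
    d_rand = _disparity_sums(tree, shuffled)

    # Brownian-threshold null at the same prevalence
    liab = _bm_tip_liabilities(tree, reps, rng)
    d_bm = _disparity_sums(tree, _threshold_top_k(liab, k))

    mean_rand = float(d_rand.mean())
    mean_bm = float(d_bm.mean())
    denom = mean_rand - mean_bm
    if denom == 0.0:
        raise TreeError("degenerate D denominator: shuffle and Brownian "
                        "null means coincide (tree too small?)")
    D = (d_obs - mean_bm) / denom
    p_random = (1 + int(np.sum(d_rand <= d_obs))) / (reps + 1)
    p_brownian = (1 + int(np.sum(d_bm >= d_obs))) / (reps + 1)
    return DResult(d_obs=d_obs, mean_d_random=mean_rand,
                   mean_d_brownian=mean_bm, D=float(D),
                   p_random=p_random, p_brownian=p_brownian,
                   reps=reps, seed=seed)
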