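"""Faith's phylogenetic diversity, scenario pruning and the
random-extinction null.

PD of a survivor set is the total branch length of the minimal subtree
connecting the survivors to the *original root* (the rooted convention:
the path from the survivors' MRCA up to the root is counted).  A threat
scenario dooms every carrier of a trait; its PD loss is compared with a
null in which the same number of tips is removed uniformly at random,
summarised as

    %dE(PD) = 100 * (E[PD_null survivors] - PD_observed survivors)
                   / E[PD_null survivors],

positive when the scenario destroys more PD than random extinction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .tree import TimeTree, TreeError

__all__ = [
    "PDLossResult",
    "faith_pd",
    "random_extinction_null",
    "percent_delta_epd",
]


def _survivor_pd_many(tree: TimeTree, survivor_mask: np.ndarray) -> np.ndarray:
    """PD of survivors for each column of a boolean (n_tips, R) mask.

    An edge counts toward a replicate's PD iff any surviving tip lies
    below it; one postorder sweep marks occupancy for all replicates.
    """
    ft = tree.flat()
    m = ft.n_nodes
    R = survivor_mask.shape[1]
    occ = np.zeros((m, R), dtype=bool)
    occ[ft.tip_pos] = survivor_mask
    for i in range(m):  # postorder
        for c in ft.children[i]:
            occ[i] |= occ[c]
    return occ.T @ ft.edge  # edge[root] = 0


def _mask_for(tree: TimeTree, survivors) -> np.ndarray:
    labels = tree.tip_labels
    idx = {lab: i for i, lab in enumerate(labels)}
    unknown = sorted(set(survivors) - set(labels))
    if unknown:
        raise TreeError(f"labels not in tree: {unknown}")
    mask = np.zeros((len(labels), 1), dtype=bool)
    for lab in survivors:
        mask[idx[lab], 0] = True
    return mask


def faith_pd(tree: TimeTree, survivors) -> float:
    """Faith's PD (My) of a survivor tip set under the rooted convention.

    With all tips surviving this equals the total branch length.
    """
    survivors = set(survivors)
    if not survivors:
        raise TreeError("survivor set is empty")
    return float(_survivor_pd_many(tree, _mask_for(tree, survivors))[0])


def random_extinction_null(tree: TimeTree, n_doomed: int, reps: int = 1000,
                           rng: np.random.Generator | None = None,
                           seed: int | None = None,
                           exhaustive: bool = False):
    """Survivor-PD distribution when ``n_doomed`` tips are removed
    uniformly at random without replacement.

    Returns ``(null_mean, null_sd, values)``.  With ``exhaustive=True``
    every C(n, n_doomed) removal is enumerated instead of Monte-Carlo
    sampling (intended for small trees; values then carry equal weight and
    the sd is the population sd).
    """
    n = tree.n_tips
    if not 0 < n_doomed < n:
        raise TreeError(f"n_doomed must be in (0, {n}), got {n_doomed}")
    if exhaustive:
        combos = list(itertools.combinations(range(n), n_doomed))
        mask = np.ones((n, len(combos)), dtype=bool)
        for j, combo in enumerate(combos):
            mask[list(combo), j] = False
        values = _survivor_pd_many(tree, mask)
        return float(values.mean()), float(values.std(ddof=0)), values
    if reps < 2:
        raise ValueError(f"reps must be >= 2, got {reps}")
    if rng is None:
        rng = np.random.default_rng(seed)
    doomed_idx = np.argsort(rng.random((reps, n)), axis=1)[:, :n_doomed]
    mask = np.ones((n, reps), dtype=bool)
    mask[doomed_idx.T, np.arange(reps)] = False
    values = _survivor_pd_many(tree, mask)
    return float(values.mean()), float(values.std(ddof=1)), values


@dataclass
class PDLossResult:
    """Survivor PD under a scenario vs. the random-extinction null."""

    pd_total: float
    pd_survivors_observed: float
    null_mean: float
    null_sd: float
    percent_delta_epd: float
    n_doomed: int
    reps: int
    seed: int | None = None


def percent_delta_epd(tree: TimeTree, doomed, reps: int = 1000,
                      rng: np.random.Generator | None = None,
                      seed: int | None = None,
                      exhaustive: bool = False) -> PDLossResult:
    """%dE(PD) for the scenario dooming the given tip labels.

    Positive values mean the scenario destroys more PD than random
    extinction of the same number of species; negative means less.
    """
    doomed = set(doomed)
    labels = set(tree.tip_labels)
    unknown = sorted(doomed - labels)
    if unknown:
        raise TreeError(f"labels not in tree: {unknown}")
    survivors = labels - doomed
    if not doomed:
        raise TreeError("doomed set is empty")
    if len(survivors) < 2:
        raise TreeError(f"need >= 2 survivors, got {len(survivors)}")
    pd_obs = faith_pd(tree, survivors)
    null_mean, null_sd, _ = random_extinction_null(
        tree, len(doomed), reps=reps, rng=rng, seed=seed,
        exhaustive=exhaustive)
    pct = 100.0 * (null_mean - pd_obs) / null_mean
    return PDLossResult(pd_total=tree.total_branch_length(),
                        pd_survivors_observed=pd_obs,
                        null_mean=null_mean, null_sd=null_sd,
                        percent_delta_epd=pct, n_doomed=len(doomed),
                        reps=reps, seed=seed)
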