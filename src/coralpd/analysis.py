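"""Per-category threat analysis across a tree sample, the per-category
summary table, and the cross-category regressions.

For each threat category (a binary trait) and each tree in the sample the
pipeline computes the D statistic (phylogenetic clustering of the threat)
and %dE(PD) (excess projected PD loss relative to random extinction of the
same number of species), then aggregates mean +/- SD across trees.  Across
categories, ordinary least squares relates mean %dE(PD) to mean D or to
the category's prevalence (as a fraction).

Randomness is derived reproducibly from one master seed: the stream for
tree index i and category name c is seeded with the sequence
(master_seed, i, crc32(c)), so results are bit-stable, independent of
execution order, and invariant under reordering of the category columns.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .pdloss import percent_delta_epd
from .signal import TraitVector, phylo_d
from .tree import TreeError, TreeSample, prune_to, root_daughter_clades

__all__ = [
    "ThreatTable",
    "CategoryResult",
    "RegressionSummary",
    "run_category",
    "run_all",
    "run_clade",
    "regress",
    "derive_rng",
]

log = logging.getLogger("coralpd")


def derive_rng(master_seed: int, *indices: int) -> np.random.Generator:
    """Child generator for (master seed, tree index, category index, ...)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed), *map(int, indices)]))


class ThreatTable:
    """Species x threat-category matrix with strictly 0/1 entries."""

    def __init__(self, df: pd.DataFrame):
        if df.shape[1] < 1:
            raise ValueError("threat table needs at least one category")
        vals = df.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("threat table entries must be 0 or 1")
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()].tolist()
            raise ValueError(f"duplicate species in threat table: {dup[:5]}")
        self.df = df.astype(int)

    @classmethod
    def from_csv(cls, path) -> "ThreatTable":
        return cls(pd.read_csv(path, index_col=0))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index_label="species")

    @property
    def categories(self) -> list[str]:
        return list(self.df.columns)

    @property
    def species(self) -> list[str]:
        return list(self.df.index)

    def trait(self, category: str) -> TraitVector:
        if category not in self.df.columns:
            raise KeyError(f"unknown category {category!r}; "
                           f"have {self.categories}")
        return TraitVector(self.df[category].to_dict(), name=category)

    def aligned_to(self, tip_labels) -> "ThreatTable":
        """Align the table to a tree's tip set.

        Species absent from the tree are dropped (logged); tips absent from
        the table are added with all-zero states (unassessed species are
        treated as unthreatened), also logged.
        """
        tips = list(tip_labels)
        extra = set(self.df.index) - set(tips)
        missing = [t for t in tips if t not in self.df.index]
        if extra:
            log.info("dropping %d table species not in the trees", len(extra))
        if missing:
            log.info("%d tree tips not in the table; treated as state 0",
                     len(missing))
        df = self.df.reindex(tips, fill_value=0)
        return ThreatTable(df)


@dataclass
class CategoryResult:
    """One row of the per-category summary: prevalence, clustering (D) and
    excess PD loss, aggregated over the tree sample."""

    category: str
    percent_species: float
    d_mean: float
    d_sd: float
    pdelta_mean: float
    pdelta_sd: float
    ns_vs_random: bool
    ns_vs_clumped: bool
    n_trees: int
    note: str = ""
    per_tree: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def defined(self) -> bool:
        return self.note == ""


def run_category(trees: TreeSample, trait: TraitVector, reps: int = 1000,
                 seed: int = 0, category: str | None = None) -> CategoryResult:
    """D and %dE(PD) for one threat category on every tree, aggregated.

    A category monomorphic on the shared tip set yields an undefined row
    (NaN statistics with an explanatory note) rather than an exception, so
    clade-restricted runs can report it.
    """
    name = category or trait.name or "trait"
    labels = trees.tip_labels
    trait = trait.restrict(labels)
    if len(trait) != len(labels):
        raise TreeError("trait does not cover the tree tip set")
    k = trait.n_ones
    n = len(labels)
    pct = 100.0 * k / n
    if k == 0 or k == n or n - k < 2:
        return CategoryResult(
            category=name, percent_species=pct, d_mean=np.nan, d_sd=np.nan,
            pdelta_mean=np.nan, pdelta_sd=np.nan, ns_vs_random=False,
            ns_vs_clumped=False, n_trees=len(trees),
            note="undefined: trait monomorphic or leaves < 2 survivors")
    doomed = trait.carriers()
    cat_key = zlib.crc32(name.encode())
    rows = []
    for i, tree in enumerate(trees):
        rng = derive_rng(seed, i, cat_key)
        dres = phylo_d(tree, trait, reps=reps, rng=rng)
        pdres = percent_delta_epd(tree, doomed, reps=reps, rng=rng)
        rows.append({"tree_index": i, "category": name, "D": dres.D,
                     "p_random": dres.p_random,
                     "p_brownian": dres.p_brownian,
                     "pdelta": pdres.percent_delta_epd,
                     "pd_survivors": pdres.pd_survivors_observed,
                     "null_mean": pdres.null_mean,
                     "null_sd": pdres.null_sd})
    per_tree = pd.DataFrame(rows)
    one = len(per_tree) == 1
    return CategoryResult(
        category=name, percent_species=pct,
        d_mean=float(per_tree["D"].mean()),
        d_sd=0.0 if one else float(per_tree["D"].std(ddof=1)),
        pdelta_mean=float(per_tree["pdelta"].mean()),
        pdelta_sd=0.0 if one else float(per_tree["pdelta"].std(ddof=1)),
        ns_vs_random=bool((per_tree["p_random"] > 0.01).mean() >= 0.5),
        ns_vs_clumped=bool((per_tree["p_brownian"] > 0.01).mean() >= 0.5),
        n_trees=len(trees), per_tree=per_tree)


def run_all(trees: TreeSample, table: ThreatTable, reps: int = 1000,
            seed: int = 0) -> list[CategoryResult]:
    """Run every category of the table, preserving its column order."""
    table = table.aligned_to(trees.tip_labels)
    results = []
    for j, cat in enumerate(table.categories):
        log.info("category %s (%d/%d)", cat, j + 1, len(table.categories))
        results.append(run_category(trees, table.trait(cat), reps=reps,
                                    seed=seed, category=cat))
    return results


def run_clade(trees: TreeSample, table: ThreatTable, which: str,
              reps: int = 1000, seed: int = 0) -> list[CategoryResult]:
    """Repeat the full analysis within one root-daughter clade.

    The clade membership ("first" = the root child listed first in the
    first tree) is fixed from the first tree and every tree in the sample
    is pruned to that tip set, so categories stay comparable across trees
    even if deep topology varies.  Prevalences are recomputed relative to
    the clade's species count.
    """
    if which not in ("first", "second"):
        raise ValueError("which must be 'first' or 'second'")
    a, b = root_daughter_clades(trees[0])
    keep = a if which == "first" else b
    if len(keep) < 4:
        raise TreeError(f"clade {which!r} has only {len(keep)} tips")
    pruned = TreeSample([prune_to(t, keep) for t in trees])
    return run_all(pruned, table, reps=reps, seed=seed)


@dataclass
class RegressionSummary:
    """OLS of %dE(PD) on D or on prevalence-as-fraction across categories."""

    predictor: str
    mode: str
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_points: int
    slope_ci_low: float | None = None
    slope_ci_high: float | None = None


def _xy_from_results(results, predictor: str):
    if isinstance(results, pd.DataFrame):
        df = results
        y = df["pdelta_mean"].to_numpy(float)
        if predictor == "D":
            x = df["d_mean"].to_numpy(float)
        elif predictor == "prevalence":
            x = df["percent_species"].to_numpy(float) / 100.0
        else:
            raise ValueError(f"unknown predictor {predictor!r}")
        return x, y
    rows = [r for r in results if r.defined]
    y = np.array([r.pdelta_mean for r in rows])
    if predictor == "D":
        x = np.array([r.d_mean for r in rows])
    elif predictor == "prevalence":
        x = np.array([r.percent_species / 100.0 for r in rows])
    else:
        raise ValueError(f"unknown predictor {predictor!r}")
    return x, y


def _ols(x: np.ndarray, y: np.ndarray):
    if len(x) < 3:
        raise ValueError(f"need >= 3 points for the regression, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor: regression undefined")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return (float(fit.params[1]), float(fit.params[0]),
            float(fit.rsquared), float(fit.pvalues[1]))


def regress(results, predictor: str = "D",
            mode: str = "on_means") -> RegressionSummary:
    """Cross-category OLS of %dE(PD) on the chosen predictor.

    ``results`` is a list of :class:`CategoryResult` or a DataFrame with
    columns ``d_mean``/``percent_species`` and ``pdelta_mean`` (e.g. a
    published summary table).  Prevalence enters as a fraction in [0, 1].

    mode "on_means" fits the category means; mode "per_tree" (lists only)
    fits within each tree and reports the across-tree mean slope and R^2
    with an empirical 95% interval on the slope.
    """
    if mode == "on_means":
        x, y = _xy_from_results(results, predictor)
        slope, intercept, r2, p = _ols(x, y)
        return RegressionSummary(predictor=predictor, mode=mode, slope=slope,
                                 intercept=intercept, r_squared=r2,
                                 p_value=p, n_points=len(x))
    if mode != "per_tree":
        raise ValueError(f"unknown mode {mode!r}")
    if isinstance(results, pd.DataFrame):
        raise ValueError("per_tree mode needs CategoryResult lists with "
                         "per-tree records")
    rows = [r for r in results if r.defined and r.per_tree is not None]
    if len(rows) < 3:
        raise ValueError("need >= 3 defined categories with per-tree records")
    n_trees = rows[0].n_trees
    prev = {r.category: r.percent_species / 100.0 for r in rows}
    slopes, r2s, ps, intercepts = [], [], [], []
    for i in range(n_trees):
        xs, ys = [], []
        for r in rows:
            rec = r.per_tree[r.per_tree["tree_index"] == i].iloc[0]
            xs.append(rec["D"] if predictor == "D" else prev[r.category])
            ys.append(rec["pdelta"])
        s, c, r2, p = _ols(np.array(xs), np.array(ys))
        slopes.append(s)
        intercepts.append(c)
        r2s.append(r2)
        ps.append(p)
    lo, hi = np.percentile(slopes, [2.5, 97.5])
    return RegressionSummary(
        predictor=predictor, mode=mode, slope=float(np.mean(slopes)),
        intercept=float(np.mean(intercepts)),
        r_squared=float(np.mean(r2s)), p_value=float(np.mean(ps)),
        n_points=len(rows), slope_ci_low=float(lo), slope_ci_high=float(hi))


def results_frame(results: list[CategoryResult]) -> pd.DataFrame:
    """Tabular view of a list of CategoryResult (summary-table analogue)."""
    return pd.DataFrame([{
        "category": r.category,
        "percent_species": r.percent_species,
        "d_mean": r.d_mean, "d_sd": r.d_sd,
        "pdelta_mean": r.pdelta_mean, "pdelta_sd": r.pdelta_sd,
        "ns_vs_random": r.ns_vs_random, "ns_vs_clumped": r.ns_vs_clumped,
        "n_trees": r.n_trees, "note": r.note,
    } for r in results])
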