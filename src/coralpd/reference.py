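"""Published per-category summary statistics for reef-building corals.

The IUCN Red List assessment of reef corals scores each species for eight
forms of extinction vulnerability: three aggregate status levels
(Endangered and above, Vulnerable and above, Near Threatened and above)
and five threat correlates (rarity, restricted/fragmented range, and
susceptibility to bleaching, disease and crown-of-thorns predation).  The
published fossil-calibrated analysis of the full Scleractinia reef-coral
phylogeny reports, for each category, the percentage of species affected,
the D statistic (mean +/- SD over a 1000-tree sample) and the excess
projected PD loss %dE(PD) (mean +/- SD), for the complete tree, for a
reduced mtDNA-only tree set, and separately for the two deep root-daughter
clades (complex and robust).

These numbers are the published inputs to the cross-category regressions;
:func:`published_summary` exposes them as a tidy DataFrame whose columns
match :func:`coralpd.analysis.results_frame`, so
:func:`coralpd.analysis.regress` runs on them directly.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["published_summary", "BLOCKS", "CATEGORIES"]

BLOCKS = ("scleractinia", "mtdna", "complex", "robust")

CATEGORIES = (
    "Endangered and above",
    "Vulnerable and above",
    "Near Threatened and above",
    "Rare",
    "Susceptible to bleaching",
    "Susceptible to disease",
    "Susceptible to CoTs predation",
    "Restricted/fragmented range",
)

# block -> rows of (percent_species, d_mean, d_sd, pdelta_mean, pdelta_sd),
# in CATEGORIES order.
_TABLE = {
    "scleractinia": [
        (3.92, 0.891, 0.035, -0.263, 0.278),
        (32.70, 0.897, 0.019, -0.162, 0.927),
        (57.99, 0.837, 0.017, 0.657, 1.177),
        (11.77, 0.966, 0.024, 1.387, 0.954),
        (41.86, 0.200, 0.010, 6.766, 1.254),
        (30.96, 0.069, 0.011, 6.706, 1.083),
        (27.33, 0.007, 0.011, 1.953, 0.987),
        (12.35, 0.925, 0.026, -1.033, 0.378),
    ],
    "mtdna": [
        (2.03, 0.359, 0.069, -0.138, 0.136),
        (23.19, 0.731, 0.025, -1.023, 0.527),
        (50.14, 0.763, 0.019, 0.774, 0.979),
        (3.77, 1.038, 0.061, -0.641, 0.165),
        (43.77, 0.215, 0.010, 1.435, 1.076),
        (34.78, 0.056, 0.012, 1.279, 1.091),
        (30.72, -0.100, 0.011, -3.557, 0.910),
        (4.06, 0.845, 0.047, -0.421, 0.221),
    ],
    "complex": [
        (4.74, 0.876, 0.059, -0.135, 0.572),
        (42.62, 0.938, 0.034, -1.521, 1.965),
        (63.79, 0.909, 0.033, -3.621, 2.495),
        (13.37, 0.975, 0.038, 2.868, 1.976),
        (68.25, 0.139, 0.018, 13.461, 3.227),
        (53.48, 0.055, 0.020, 10.994, 2.589),
        (48.75, -0.122, 0.017, 3.422, 2.539),
        (12.26, 0.912, 0.048, -1.284, 0.678),
    ],
    "robust": [
        (3.04, 0.881, 0.041, -0.402, 0.215),
        (21.88, 0.959, 0.026, 0.640, 0.748),
        (51.67, 0.757, 0.022, 4.107, 1.139),
        (10.03, 0.950, 0.033, 0.238, 0.659),
        (13.07, 0.533, 0.030, -1.177, 0.502),
        (6.38, 0.105, 0.013, 2.534, 0.954),
        (3.95, 0.849, 0.087, -0.439, 0.294),
        (12.46, 0.921, 0.029, -0.959, 0.481),
    ],
}


def published_summary(block: str = "scleractinia") -> pd.DataFrame:
    """Published per-category summary for one tree set.

    ``block`` is one of ``scleractinia`` (full reef-coral tree), ``mtdna``
    (reduced molecular tree), ``complex`` or ``robust`` (the two deep
    root-daughter clades).  Columns: category, percent_species, d_mean,
    d_sd, pdelta_mean, pdelta_sd.
    """
    if block not in _TABLE:
        raise KeyError(f"unknown block {block!r}; choose from {BLOCKS}")
    rows = _TABLE[block]
    return pd.DataFrame(
        [(c, *r) for c, r in zip(CATEGORIES, rows)],
        columns=["category", "percent_species", "d_mean", "d_sd",
                 "pdelta_mean", "pdelta_sd"])
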