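# coralpd

**Projected loss of phylogenetic diversity under clustered extinction
threats, on rooted ultrametric time trees.**

Anthropogenic threats do not strike a phylogeny at random: susceptibility
to coral bleaching, disease, or crown-of-thorns predation runs in clades,
while rarity and range restriction scatter across the tree. How much
evolutionary history a threat would erase therefore depends on *where* its
carriers sit on the tree, not just how many there are. `coralpd`
implements the full analysis chain used to ask that question for
reef-building corals (Scleractinia), and a synthetic generator of
coral-like tree samples and threat tables so the entire pipeline can be
exercised, calibrated and tested without any external data.

## What it computes

Given a sample of rooted ultrametric trees (Newick, one per line; branch
lengths in My) and a species × category table of binary threat states:

- **Tree shape** — the Pybus–Harvey **gamma** statistic (standard normal
  under the Yule model; strongly positive for "tippy" trees like the
  coral phylogeny) and **Colless' imbalance index**
  $I = \sum_{v}\,|L_v - R_v|$, tested against a Monte-Carlo Yule null.
- **Phylogenetic clustering of each threat** — the **D statistic** for
  binary traits: the sum of sister-clade disparities
  $d = \sum_v |\bar{x}_{\mathrm{left}(v)} - \bar{x}_{\mathrm{right}(v)}|$
  scaled between two prevalence-conditioned nulls,
  $D = \dfrac{d_{\mathrm{obs}} - \bar d_{\mathrm{BM}}}
             {\bar d_{\mathrm{shuffle}} - \bar d_{\mathrm{BM}}}$,
  so that D ≈ 1 for a phylogenetically random trait and D ≈ 0 for one as
  clumped as a thresholded Brownian liability; values outside [0, 1] are
  possible and reported as-is.
- **Projected PD loss** — Faith's phylogenetic diversity
  $\mathrm{PD}(S) = \sum_{e \in \mathrm{tree}(S)} \ell_e$ of the
  survivors (rooted convention: the path to the original root counts),
  compared with a null that removes the same number of species uniformly
  at random:
  $\%\Delta E(\mathrm{PD}) = 100\,
   \dfrac{E[\mathrm{PD}_{\mathrm{null}}] - \mathrm{PD}_{\mathrm{obs}}}
         {E[\mathrm{PD}_{\mathrm{null}}]}$,
  positive when the threat destroys **more** PD than random extinction.
- **Cross-category regressions** — OLS of mean %ΔE(PD) on mean D (the
  headline: more clustered threats, lower D, prune more history) and on
  prevalence-as-fraction, either on the category means or per tree.
- **Clade-restricted runs** — everything repeated inside each of the two
  deep root-daughter clades (the "complex" and "robust" coral clades).

The published per-category summaries for the real reef-coral assessment
(percent of species, D, %ΔE(PD) for the full tree, an mtDNA-only tree
set, and the two deep clades) ship in `coralpd.reference` and feed the
same regression code.

## Worked example

Generate a coral-like fixture (200 species, 5-tree sample, 8 threat
categories with graded clustering) and run the pipeline:

```bash
coralpd synth --preset coral --n-tips 200 --n-trees 5 --seed 11 --out-dir demo
coralpd run --trees demo/trees.nwk --traits demo/threats.csv \
            --reps 500 --seed 11 --out-prefix demo/coral
```

`demo/coral_table.tsv` (abridged; mean ± SD over the 5 trees):

| category          | % species | D      | %ΔE(PD) |
|-------------------|-----------|--------|---------|
| bleaching         | 42.0      | 0.310  | +25.2   |
| disease           | 31.0      | −0.026 | +12.4   |
| cots              | 27.5      | 0.111  | +13.3   |
| rare              | 12.0      | 1.000  | +2.4    |
| restricted_range  | 12.5      | 0.918  | −0.8    |

The clumped threats (D near 0) project PD losses well above random;
the scattered ones sit near zero. `demo/coral_regressions.tsv` fits the
relationship across all 8 categories:

```
predictor  mode      slope    r_squared  p_value
D          on_means  -13.30   0.337      0.131
```

— a negative slope: each unit decrease in D (more clustering) costs
roughly 13 percentage points of extra expected PD.

The same machinery is available as a library
(`parse_newick`, `gamma_statistic`, `phylo_d`, `percent_delta_epd`,
`run_all`, `regress`, …); see the module docstrings.

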