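# Methods

This note documents the models, estimators, null constructions and design
choices behind `coralpd`, and what the synthetic calibrations do and do
not establish about real data.

## Tree model

Trees are rooted, ultrametric, and parameterised by node **ages** in
millions of years before present (tips at 0); an edge's length is the age
difference between its endpoints. Parsing reconstructs ages from
root-to-node path lengths, taking the root age as the maximum root-to-tip
distance; tips must sit within **1e-6 My** of the present (posterior tree
files carry limited decimal precision; anything worse is treated as a
data error, and the offending tip is named). Trees are immutable once
built — every operation returns a new tree — which allows a cached
postorder array encoding used to evaluate thousands of null replicates in
single vectorised sweeps.

Pruning to a tip subset keeps node ages, suppresses unary nodes (the two
incident edge lengths merge automatically), and roots the result at the
MRCA of the kept tips with no stem above it: this is the standard rooted
subtree on which pairwise tip distances are exactly conserved. Faith's PD
(below) deliberately uses a different convention.

Polytomies are resolved by uniformly random sequential pairing of a
node's children, with each new node's age drawn uniformly between the
polytomy's age and the older member of the pair. This is the simplest
scheme that preserves ultrametricity and cannot create zero-length edges
(which would degenerate gamma); it stands in for resolution under a dated
model with posterior age priors, which is out of scope.

## Tree-shape statistics

**Gamma** is computed from the internode intervals g_k (time with exactly
k lineages, k = 2..n):

    gamma = [ (1/(n-2)) * sum_{i=2}^{n-1} sum_{k=2}^{i} k g_k - T/2 ]
            / ( T sqrt(1/(12(n-2))) ),      T = sum_j j g_j.

Tied node ages are legal (g_k = 0). Gamma is scale-invariant and
asymptotically standard normal under the Yule model; the suite verifies
mean within 0.15 of 0 and SD within [0.85, 1.15] over 1000 simulated
pure-birth trees (n = 100).

**Colless' index** is the sum of |left − right| descendant-tip
disparities over internal nodes; it depends on topology only, so its
Monte-Carlo Yule null needs no age rescaling. The null p-value uses the
add-one convention p = (1 + b)/(reps + 1), which never returns 0.

The **Yule simulator** draws g_k ~ Exponential(k) (unit speciation rate),
including a final Exponential(n) interval between the last split and the
present, and splits a uniformly chosen lineage at each event — the
construction under which the g_k are independent exponentials and the
gamma calibration holds. Its mean Colless is checked against exact
enumeration of the leaf-choice process at small n.

## The D statistic

Nodal trait values are estimated bottom-up as the mean of the two
daughter values (tips contribute their 0/1 state), and
d = Σ |left − right| over internal nodes. D scales d between the means of
two prevalence-conditioned nulls — label shuffles (anchor D = 1) and
Brownian-threshold traits (anchor D = 0). The Brownian null simulates a
liability with variance proportional to branch length (rate 1 per My,
root value 0) and assigns state 1 to the top-k tips by rank, which
preserves prevalence exactly. Two one-tailed add-one p-values are
reported: p_random = P(d_shuffle ≤ d_obs) tests departure from random
toward clumping; p_brownian = P(d_BM ≥ d_obs) tests departure from
clumped toward random. A trait more dispersed than every Brownian
replicate floors p_brownian at 1/(reps+1) and can have D > 1; one more
clumped than Brownian has D < 0 and p_brownian = 1 (it cannot reject
clumpedness). D is never clamped.

The daughter-mean nodal estimator is a declared design choice: it
reproduces both anchors by construction of the scaling — which is the
only property the downstream analysis consumes — and the calibration
suite confirms mean D within [0.85, 1.15] (shuffles) and [−0.15, 0.15]
(Brownian thresholds) on 200-tip pure-birth trees.

## PD loss and %ΔE(PD)

Faith's PD of a survivor set is the total length of edges on the union of
root-to-survivor paths, **including the path to the original root**. The
rooted convention matters precisely for deep two-clade trees, where the
two root edges can hold a large share of total PD; the clade-restricted
analyses exist to quantify that concern.

The random-extinction null removes the same number of tips uniformly
without replacement (default 1000 replicates, redrawn independently per
tree). For small trees an exhaustive mode enumerates all C(n, k)
removals; the Monte-Carlo path is tested against it. The excess-loss
metric is normalised by the null expectation of **survivor** PD:

    %dE(PD) = 100 (E[PD_null] − PD_obs) / E[PD_null],

positive when the scenario destroys more PD than random. The cited
original formulation is not reprinted in the source literature; this
normalisation reproduces the published sign structure (bleaching/disease
positive, range-restricted negative) and the worked 4-tip example
(dooming a cherry: +18.18%; dooming one tip from each side: −9.09%), but
absolute magnitudes on other data may differ from other normalisations by
a scale factor.

## Orchestration and regressions

Per category and per tree, the pipeline computes D and %ΔE(PD) with the
carriers of the category as the doomed set, then aggregates mean ± SD
across trees; a category monomorphic on the analysed tip set yields an
explicit "undefined" row rather than an exception (this happens routinely
in clade-restricted runs). Species present in the threat table but absent
from the trees are dropped; tree tips missing from the table are treated
as unthreatened (state 0); both are logged with counts — mirroring real
assessments that cover most but not all of a phylogeny.

Cross-category OLS regresses %ΔE(PD) on D or on prevalence **as a
fraction** (required for slope magnitudes to be comparable across
analyses). `on_means` fits the 8 category means; `per_tree` fits within
each tree and reports the across-tree mean slope and R² with an empirical
95% interval. On the bundled published summaries, the fit to the means
reproduces the published slopes to within 1% (−5.71 vs −5.70 for the full
tree on D; −9.86 vs −9.83 for the complex clade; 8.21 on prevalence for
the robust clade), while its R² is larger than published (e.g. 0.62 vs
0.58) — consistent with the published R² deriving from per-tree fits;
both modes are exposed and only slopes are treated as reproducible.
Slope p-values are classical two-sided t-tests on n − 2 df, appropriate
to 8 points.

Clade-restricted runs fix the two root-daughter tip sets on the first
tree of the sample and prune every tree to that set, keeping categories
comparable across trees; prevalences are recomputed relative to the clade.

All randomness descends from one master seed: the stream for tree i and
category c is seeded with (master, i, crc32(c)), making results
bit-stable, order-independent, and invariant under reordering of table
columns.

## Synthetic data: what it emulates

The generator targets the gross features of the reef-coral phylogeny:
**~365 My root** splitting the species **55.1% / 44.9%** into two deep
clades joined by long stems (clade crown ages drawn as root_age ×
U(0.6, 0.9)); **strongly positive gamma** via a power transform of
within-clade ages, a → A·(a/A)^β with β ≥ 1 (monotone, fixes the clade
crown and the present, hence preserves ultrametricity); and an optional
**imbalance bias** κ ≥ 1 that makes deeper lineages speciate
preferentially (weight κ^rank of tip depth), inflating Colless above the
Yule expectation. At β = κ = 1 a clade reduces exactly to pure birth.
Defaults: β = 2.5 and κ = 1 give mean gamma ≈ 22 at 400 tips (≈ 32 at the
real clade size of 838, bracketing the published 28.6).

κ = 1 in the default preset is a deliberate trade-off. Any κ > 1
necessarily freezes early lineages into ancient pendant edges; on
ultrametric trees those few edges come to dominate total PD, and whether
a fixed carrier set happens to include them injects heavy-tailed,
seed-persistent noise of many percentage points into per-category
%ΔE(PD). At desk-scale sample sizes this noise swamps the
clustering–loss relationship entirely (the slope's sign becomes a coin
flip) — itself a vivid instance of the general point that tree shape
modulates PD loss. With κ = 1 the deep two-clade, strongly tippy
geometry alone reproduces the published qualitative headline: the
cross-category slope of %ΔE(PD) on D is negative in 10/10 seeds at the
default scale (400 tips, 10 trees, 8 categories, 200 null replicates;
about 2 s per run).

A tree **sample** emulates a posterior over one inferred topology: the
first tree is generated from scratch and the rest share its topology
with freshly drawn ages (rank-preserving reassignment keeps parents older
than children). Independent topologies per tree were rejected: a fixed
threat table then loses its clustering on every tree except the one it
was generated from, contradicting the small across-tree D dispersions
seen in real posterior analyses.

Threat categories have exact prevalence (round(p·n) carriers) and a
clustering weight w: Binomial(k, w) carriers come from the top of a
Brownian liability ranking on the first tree, the rest uniformly at
random. w = 1 reproduces the Brownian anchor (mean D ≈ 0), w = 0 the
shuffle anchor (mean D ≈ 1), and mean D decreases monotonically in w.
The default preset mirrors the eight published reef-coral categories'
prevalences (3.9–58.0%) with w graded 1 → 0 in order of increasing
published D. Categories are generated independently; real threat
categories overlap (the same genera are bleaching- and predation-
susceptible), which the generator does not model.

**What passing calibrations show** — that the estimators are correctly
anchored, the nulls correctly conditioned, and the qualitative
clustering–loss mechanism recoverable under coral-like geometry. They do
not show that synthetic magnitudes of %ΔE(PD) match real corals: the
generator has no taxonomy, no category overlap, no posterior correlation
structure in ages, and its default preset deliberately omits above-Yule
imbalance (see above).

## Numerical and degenerate-input choices

- Ultrametricity tolerance 1e-6 My absolute everywhere.
- All Monte-Carlo p-values use (1 + b)/(reps + 1).
- D requires both states present and ≥ 2 survivors; n < 3 is rejected
  for gamma (undefined); n < 4 for the Colless test.
- Exhaustive nulls report the population SD; Monte-Carlo nulls the
  sample SD (ddof = 1).
- Newick writing uses 12 significant digits; round-trips are verified to
  1e-9.
- Problem sizes in the test suite and acceptance script (e.g. 50–100
  calibration replicates, 200–500 null replicates, 400-tip preset runs)
  are chosen so the entire suite completes in about a minute while
  keeping every Monte-Carlo assertion several standard errors away from
  its threshold.

## Known limitations

- The %ΔE(PD) normalisation is one of several in use; comparisons across
  studies should check the denominator convention.
- The D implementation uses the daughter-mean nodal estimator rather than
  the original package's estimator; anchors and discrimination are
  calibrated, but individual D values on real data may differ slightly
  from other implementations.
- The Yule null for Colless conditions on n only (topology-only
  statistic); gamma-based extensions would need to decide whether to
  condition on age as well.
- `per_tree` regression p-values are averaged across trees and should be
  read as descriptive, not as a single calibrated test.
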