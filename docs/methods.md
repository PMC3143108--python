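# Methods

`cladesel` detects regions of a multiple alignment of closely related
species whose substitution rate departs from a neutral background in a
lineage-specific way. This note documents the model, the detector, the
calibration and evaluation protocols, the synthetic-data generator, and the
numerical choices behind them.

## Phylogenetic model

The neutral background is a standard time-reversible phylogenetic model
`psi = (Q, tau, beta, pi)`: a 4x4 GTR rate matrix `Q`, a rooted topology
`tau`, branch lengths `beta` in expected substitutions per site, and
equilibrium base frequencies `pi`. Models are read from phyloFit-style
`.mod` files. On construction `Q` is projected onto the reversible manifold
(symmetrizing the probability flux `pi_i Q_ij`, which absorbs the finite
precision of printed rate matrices; a genuine detailed-balance violation
above a 1e-3 relative tolerance is only warned about) and rescaled so the
expected substitution rate at stationarity is 1, keeping branch lengths in
substitutions/site.

Column probabilities `p(k; psi)` come from Felsenstein pruning. Transition
matrices `P(t) = exp(Qt)` are computed through the eigendecomposition of
the pi-symmetrized rate matrix, which is real-symmetric for a reversible
`Q`; a dense `scipy.linalg.expm` is the fallback for non-reversible input.
Gaps and `N` are missing data with the all-ones partial-likelihood
convention, so a column with no data has probability 1 and never
contributes to any score. Alignments are collapsed to their distinct column
patterns once per block; every model evaluated against the block then pays
per-pattern cost, which is what makes scoring a few hundred scenario models
against megabase-scale alignments practical on one core.

## Selection scenarios

A scenario `(s, u, rho)` rescales branch lengths of the neutral model with
a single factor `rho` in (0, 1]; smaller `rho` means stronger selection:

* **gain** at clade `u`: all branches inside `tau_u` *and* the parent edge
  `(u_p, u)` are multiplied by `rho` — the clade came under purifying
  selection.
* **loss** at `u`: every branch *outside* `tau_u` and its parent edge is
  multiplied by `rho` — the clade (parent edge included) drifts neutrally
  while the rest of the tree is conserved. The parent edge belongs to the
  drifting side: if it were conserved with the complement, loss at a leaf
  would collapse to whole-tree conservation (a leaf's only edge is its
  parent edge) and single-species loss would be undetectable in principle.
* **acceleration** at `u`: the parent edge is divided by `rho`. At a
  degree-2 root the two root edges form a single unrooted branch, so
  acceleration at either root child rescales that entire branch; this makes
  the two scenarios exactly indistinguishable (they are one unrooted
  event), and the detector reports such predictions once, flagged as an
  ambiguous root pair. Without an outgroup no method can split this tie.
* **conserved_all**: every branch is multiplied by `rho` — whole-tree
  conservation, kept as its own type because the root has no parent edge.

The per-column score of a scenario is the log-likelihood ratio
`log p(k; psi_{s,u,rho}) - log p(k; psi_neutral)`; the score of a column
interval is the sum over its columns, maximized over a fixed grid of `rho`
values, default `(0.05, 0.1, 0.2, 0.3, 0.4, 0.5)`. Ties between grid values
break toward the smallest `rho` (strongest selection). Expected per-column
score is `-KL < 0` under neutral data and positive under matching selected
data, which is what makes maximal-segment search the right primitive.

## Detection

For each scenario and each grid `rho`, one linear left-to-right pass
(Ruzzo–Tompa maximal-scoring-subsequence scan, compiled with numba) finds
all disjoint maximal positive-sum segments. Overlapping segments from
different `rho` values collapse to the best-scoring one, and each survivor
is re-scored over the whole grid. A candidate is kept if its score exceeds
the calibrated threshold for its `(type, clade)` and it spans at least the
minimum element length (default 50 columns, user-overridable).

**Anti-clustering.** A candidate that contains a sub-region of at least the
minimum length whose *negated* score exceeds the deviation threshold — that
is, strong evidence of neutrality or of selection of a different type — is
split: the deviating core is discarded and the flanks are re-examined
recursively. This prevents two nearby selected regions from being merged
across a stretch that does not support the scenario. The deviation
threshold reuses the main threshold of the same scenario: a sub-region
whose evidence *against* selection is as strong as the evidence required
*for* calling selection is a significant deviation.

**Overlap resolution.** Candidates from all scenarios are accepted greedily
by descending score (ties: longer interval, then smaller start, then type
order gain < loss < acceleration < conserved_all); a candidate overlapping
an accepted element is retained in the audit output but flagged as
suppressed. Greedy-by-score is deliberately a heuristic, not optimal
weighted-interval scheduling: in a chain A–B–C with scores 9, 8, 7 it keeps
A and C.

**Positive-selection candidates.** An accelerated element is a
positive-selection candidate when its clade is *internally conserved*: the
likelihood is recomputed over the element's columns with every species
outside the clade masked as missing, and the element is flagged if the
whole-tree-conservation score of that masked alignment exceeds the
conserved_all threshold. Internal conservation is undefined for a one-leaf
clade; there the element instead must not look like simple drift of that
leaf (its loss score for the leaf must sit below the loss threshold). This
filter separates acceleration-then-conservation (the positive-selection
signature) from relaxation of constraint; power is limited for small clades
because few species carry the internal signal.

## Threshold calibration

Thresholds target a **column-level false-positive rate**: the fraction of
neutral columns covered by called elements. The default target is 0.1%,
applied to the whole detector, i.e. to the union of all scenarios'
predictions. Calibration runs detection machinery (without anti-clustering,
which is the conservative direction — splitting only lowers candidate
scores) on a neutral simulation of at least `10 / target_fpr` columns and
collects each scenario's merged maximal segments.

The global column budget is shared equally across scenarios, and each
per-(type, clade) threshold is placed by an exponential tail fit to that
scenario's segment scores: maximal-segment score tails are asymptotically
exponential (Karlin–Altschul), so a fitted rate `lambda` extrapolates
beyond the observed maximum instead of sitting exactly on it — a threshold
at the empirical maximum would be exceeded about once per scenario on
independent data. The threshold is the smallest `t` whose *expected
held-out coverage*, `sum_i len_i * exp(-lambda * max(t - s_i, 0))` over
the observed segments, fits the scenario's budget. Weighting each
segment's exceedance probability by its own length matters: weak scenarios
(e.g. conservation of a single short branch) produce few but extremely
long maximal segments — near-zero-drift random-walk excursions of
thousands of columns — and a count-based budget under-protects exactly
there, where one false call can spend the whole global budget. Only half
the nominal budget is targeted, absorbing tail-fit error, so the realized
held-out FPR lands well below the target rather than at it. Scenarios with
too few callable segments to fit fall back to the maximum observed segment
score of any length plus a three-e-folding margin. A conservative
threshold costs detection power only where there was almost no power to
begin with.

## Simulator

Sites evolve independently: the root sequence is drawn i.i.d. from `pi` and
each branch applies its transition matrix (no indel process, no rate
variation across sites). Selected elements are simulated under the
scenario-scaled model — the same `build_scaled_model` used for scoring, so
simulation and inference cannot drift apart — and embedded at a uniform
random integer offset inside a neutral stretch twice the element length,
flanked by 1000 further neutral columns per side: an element of `m` columns
yields an alignment of `2m + 2000` columns with a recorded truth interval.
Element lengths of 50–1000 columns and scaling factors
`rho* in {0.01, ..., 0.5}` form the benchmark grid, default 100 replicates
per (type, clade, length, rho) cell. Missing-data structure of real
alignments can be copied onto simulated blocks column-block-wise from a
template alignment, preserving per-species deletion patterns and coverage.

For studies of acceleration-with-internal-conservation the simulator
accepts an additional `subtree_rho` multiplying the branches *inside* the
accelerated clade.

What the generator does **not** emulate: indels and alignment error,
regional variation of the neutral rate, GC-biased substitution clusters,
and correlated selection across neighboring elements. Passing tests
therefore demonstrate correctness of the method under its own model
assumptions, not robustness to real-alignment artifacts; the packaged
14-taxon model (primate-like topology, GTR rates with transition bias,
total tree length ~0.68 substitutions/site) is a synthetic stand-in whose
scale mimics fourfold-degenerate-site models of primates.

## Evaluation

Accuracy is the arithmetic mean of site-level precision and recall. A truth
column counts as recovered only when covered by a primary prediction of
matching type *and* clade (strict matching; acceleration at either child of
a degree-2 root matches either label, reflecting the unrooted ambiguity).
Precision is taken over all primary predicted columns. Counts are pooled
over the replicates of a benchmark cell, and clade-averaged tables mirror
the per-type length-by-rho layout, with whole-tree conservation reported as
its own section. When there are no predictions and non-empty truth,
precision (and accuracy) are 0.

## Problem sizes

Default choices used by the shipped protocols, chosen to resolve the
quantities they measure: calibration and the held-out FPR experiment use
two independent simulations of 2,000,000 columns (at a 0.1% target the
held-out run carries an expected ~2000 false columns' worth of resolution);
the trend benchmark in the test suite uses 12 replicates per cell over four
representative clades (one leaf, three multi-species clades), two lengths
(200, 1000) and two selection strengths (0.05, 0.3); threshold tables for
detector-level tests are calibrated on 200,000 neutral columns. Larger
grids are available through the `benchmark` CLI command.

## Known limitations

* Thresholds are deliberately conservative; absolute accuracies at weak
  signal (gain in small clades, large `rho`) are lower than an
  FPR-matched oracle could achieve.
* The deviation threshold of the anti-clustering rule reuses the main
  threshold; no separate calibration of sub-region significance exists.
* Loss in a clade adjacent to the root and gain in its sister clade differ
  only by the sister's parent edge and are easily confused at strong
  selection; likewise loss at a leaf resembles whole-tree conservation
  whenever the leaf branch is short.
* `p(k)` assumes a single uniform neutral model per run; regional neutral
  variation must be handled upstream by supplying a different `.mod`.
* Scores are heuristics, not calibrated p-values; downstream statistical
  validation of candidate elements is out of scope.
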