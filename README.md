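# cladesel

Lineage-specific selection detection in multiple alignments of closely
related species.

Given an alignment of orthologous regions (MAF or aligned FASTA) and a
neutral phylogenetic model (phyloFit-style `.mod`: GTR rate matrix, tree
with branch lengths in expected substitutions/site, base frequencies),
`cladesel` finds the regions, and the clades, where the substitution rate
departs from neutrality:

* **gain** — a clade (branches inside the subtree plus its parent edge) is
  conserved: purifying selection arose on that lineage;
* **loss** — a clade drifts neutrally while the rest of the tree is
  conserved: constraint was lost on that lineage;
* **acceleration** — the branch into a clade is longer than neutral;
  accelerated elements whose clade is internally conserved are additionally
  flagged as positive-selection candidates;
* **conserved_all** — conservation across the whole phylogeny.

The tool is aimed at comparative genomics of closely related species
(e.g. primates), where per-branch signal is weak and the lineage under
selection is not known in advance: every clade of the phylogeny is tested
at once.

## Method in brief

With the neutral model `psi_n = (Q, tau, beta, pi)`, each scenario
`(s, u, rho)` rescales branch lengths: gain multiplies the clade `tau_u`
and its parent edge by `rho in (0,1)`, loss multiplies the complement,
acceleration divides the parent edge `(u_p, u)` by `rho`. The score of
columns `i..j` is

```
S(i, j, s, u) = max_rho  sum_{k=i..j} [ log p(k; psi_{s,u,rho}) - log p(k; psi_n) ]
```

with `p(k; psi)` the Felsenstein-pruning column probability and `rho` on a
fixed grid, default `(0.05, 0.1, 0.2, 0.3, 0.4, 0.5)`. A linear
maximal-scoring-segment scan per scenario finds all disjoint intervals with
`S` above a threshold calibrated on neutral simulations to a column-level
false-positive rate below 0.1%; candidates containing a sub-region that
significantly contradicts the scenario are split, overlaps across
scenarios resolve to the maximum-scoring element, and accelerations at the
two children of the root (one unrooted event) are reported once. Scoring a
block costs one pattern-collapsed likelihood pass per scenario model —
linear in alignment length.

See `docs/methods.md` for the full model, calibration and evaluation
protocols, and limitations.

## Worked example

A packaged synthetic 14-taxon primate-like model
(`src/cladesel/data/primate14.mod`) makes the tool runnable without any
external data. Calibrate thresholds, simulate a 500-column element that
lost constraint in the ape clade, and detect it:

```
cladesel calibrate --mod primate14.mod --sim-length 200000 --seed 7 --out cal
cladesel simulate  --mod primate14.mod --length 500 --type loss --node apes \
                       --rho 0.05 --seed 21 --out sim
cladesel detect    --mod primate14.mod --fasta sim/alignment.fa \
                       --thresholds cal/thresholds.json --out det
```

`sim/truth.bed` records where the element was embedded, and
`det/elements.bed` what was found:

```
# truth
ref  1391  1891  loss|apes|0.05  0     +
# detected
ref  1385  1892  loss|apes|0.05  1000  +
```

The audit table `det/candidates.tsv` carries the underlying score — here a
single primary element, interval [1385, 1892), log-likelihood-ratio score
246.5 at `rho = 0.05`:

```
block start end   type  node  rho   score     primary ...
0     1385  1892  loss  apes  0.05  246.4784  1
```

The detected interval covers the truth to within a few columns, the clade
and selection type are identified exactly, and the strongest grid value of
`rho` is chosen. Python users can drive the same pipeline with
`cladesel.calibrate_thresholds`, `cladesel.simulate_region` and
`cladesel.detect_elements`; `cladesel.run_benchmark` reproduces whole
precision/recall grids over (type, clade, length, rho) cells.

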