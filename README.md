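# cccnet — cell–cell communication network analysis of human hematopoiesis

`cccnet` reconstructs and analyzes the directional cell–cell communication
(CCC) network of the human hematopoietic system: how 12 stem, progenitor and
mature blood cell types signal to each other through secreted ligands, and
how those signals feed back on hematopoietic stem cell (HSC) fate. It is
written for computational systems biologists who want a tested, reproducible
implementation of the full analysis chain, from an expression matrix and a
ligand–receptor table to feedback-network predictions, with a synthetic-data
generator standing in for the original microarray and flow-cytometry data.

## The model

A CCC network is a directional bipartite graph over cell nodes and ligand
nodes. From per-cell-type differential over-expression calls (one-sided
Wilcoxon rank-sum vs every other cell type, Benjamini–Hochberg adjustment
per comparison, a gene is called when it beats ≥ 6 of the 11 other types at
FDR 10%) and a curated ligand→receptor table, two matrices are built:

* **production** `A[i,j] = 1` iff cell *i* over-expresses ligand *j*;
* **binding** `B[j,i]` = number of receptor species (or complete heteromeric
  complexes) cell *i* over-expresses for ligand *j*.

Cell *i* signals to cell *k* via ligand *j* iff `A[i,j] = 1` and
`B[j,k] ≥ 1`; orphan ligands are wired to an aggregate "Others" pseudo-cell.
On top of this graph the package computes:

* **structure** — Jaccard/Ward clustering of the production network with
  silhouette-selected module count; Dhillon bipartite spectral co-clustering
  of the binding network; a two-sample t-test on the inter-module
  shared-ligand vectors *S* (production) vs *T* (binding);
* **competition** — the frequency-weighted potential of apparent competition
  with weights `w_ik = f_i · R_ik`:
  `P_ij = Σ_k (w_ik / Σ_k' w_ik') · (w_jk / Σ_l w_lk)`, a row-stochastic
  matrix of which cells deprive which of shared ligands;
* **compartmentalization** — a Monte-Carlo OR-gate model in which the ligand
  sets of four compartments (HSCe autocrine, progenitors, niche mature,
  peripheral mature) reach the stem cells with probabilities
  (1, 0.8, 0.7, 0.1), scored as process enrichment
  `E = |M_HSCe ∩ B| / |B|` averaged over 500 simulations;
* **ligand effects** — signed one-tail p-values from a random-intercept
  mixed linear model on log culture counts (experiment id as random effect),
  classified by a 17-row arrow-pattern decision table into quiescence /
  self-renewal / differentiation / proliferation induction, proliferation
  inhibition, or neutral; a binomial B(33, 0.5) prediction-capacity test;
  hypergeometric Z-score enrichment per cell type; and weighted feedback
  networks (receptor-level, frequency and compartment weighting).

## Worked example

```sh
cccnet run-all --seed 0 --out runs/demo     # or: python analysis/01_...py .. 08_...py
```

Running the numbered drivers under `analysis/` on the default synthetic
design (12 cell types, 4 planted production modules, promiscuous binding)
prints, among other things:

```
silhouette-selected module count: k = 4
  module 1: CMP, GMP, HSCe, MEP, MLP
  module 2: Baso, Eos, Mega, PreB
  module 3: Mono, Neut
  module 4: EryB

scenario mnc_like: most frequent top competitor = Neut
  HSCe self-competition share: 0.002, dominated by Neut
scenario progenitor_enriched: most frequent top competitor = CMP
  HSCe self-competition share: 0.084, dominated by CMP

prediction capacity, X ~ B(33, 0.5): expected 16.5 (~16),
P(X = 27) = 0.0001, P(X >= 27) = 0.0002
```

The module partition exactly matches the planted one (a primitive
stem/progenitor module, a neutrophil–monocyte module, an erythroid module,
and the remaining mature cells). The competition scenarios show the key
frequency effect: in a neutrophil-dominated mono-nucleated-cell mixture the
stem cells have almost no ligand access (self share 0.002), while progenitor
enrichment restores it. The binomial test shows that 27 effective ligands
out of 33 tested is far beyond the chance expectation of ~16.

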