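# Methods

This note documents the models, defaults and numerical choices behind
`cccnet`, and what the synthetic study conditions do and do not establish
about real data.

## Differential over-expression

For cell type *c* and gene *g*, the samples of *c* are compared against each
other cell type with a one-sided (greater) Wilcoxon rank-sum test. The exact
small-sample null is used whenever both groups have ≤ 10 samples (replicate
counts in hematopoietic sorting studies are typically 3–10); otherwise the
tie-corrected normal approximation. P-values are Benjamini–Hochberg adjusted
**per pairwise comparison, across the gene universe** (the union of ligand
and receptor genes by default); the adjustment universe is a genuine
modelling choice — per-comparison adjustment matches the framing of one
test family per cell-type pair. A gene is called for *c* when its adjusted p
is ≤ the FDR threshold in at least `min_wins` comparisons; the default
`min_wins = 6` of 11 is a deliberately permissive majority rule and is
exposed as configuration. Calls therefore shrink monotonically as the FDR
decreases or `min_wins` grows.

A consequence of exact rank tests worth knowing: with *n* = 5 vs 5 the
smallest attainable one-sided p is 1/252, so after BH adjustment over a
small universe a single planted gene can be *uncallable* at strict
thresholds. Recovery statements below use ≥ 4–5 replicates and universes
large enough that true positives share ranks.

The FDR threshold is selected by ROC against a benchmark of known
cell-type-associated receptors (bundled in
`src/cccnet/data/benchmark_receptors.tsv`): sensitivity is the fraction of
benchmark (cell type, receptor) pairs recovered; specificity treats the
non-benchmark receptor universe as negatives (an all-genes variant is
reported alongside, since either convention is defensible). The chosen
threshold maximizes Youden's J, ties broken toward the smaller threshold
(conservatism).

## Network construction

Production is binary; binding counts receptor species, the working
assumption being that more receptor species for a ligand means a higher
chance the ligand binds the cell. Independent-subunit counting is the
default; `heteromeric_mode` counts a declared receptor complex once and only
when *all* subunits are called (it can only lower binding entries — a
tested invariant). "Others" is a single aggregate pseudo-cell with no
receptor profile of its own: it produces ligands bound but not produced by
modeled cells, and absorbs ligands produced but not bound. Ligands with
neither producer nor binder are dropped.

## Structure analysis

Production modularity: pairwise Jaccard distances between the cells'
produced-ligand sets (a metric, property-tested); pairs of empty sets get
distance 0 with a warning. Agglomerative Ward clustering; for each candidate
k in 2..6 the dendrogram is cut and silhouette widths computed on the
Jaccard distance matrix; the returned partition maximizes mean silhouette,
ties toward smaller k. Tied merge heights can make a k-cluster cut
unreachable; such k get an undefined (NaN) silhouette and are skipped.

Binding promiscuity: Dhillon's bipartite spectral co-clustering, implemented
directly so the singular spectrum is visible to callers — normalize
`A_n = D_r^{-1/2} B D_c^{-1/2}`, embed rows and columns with singular
vectors 2..⌈log₂k⌉+1 (scaled by the degree factors), joint k-means with a
fixed seed (default 0, `n_init = 10`). `is_separable()` reports False when
the informative singular values sit within 5% of the leading singular value
above the trailing ones — a flat spectrum (e.g. an all-ones matrix) carries
no block structure. sklearn's `SpectralCoclustering` is used as an
independent cross-check in the tests, never as the implementation.

Comparison: the inter-module shared-ligand count vectors S (production) and
T (binding) are compared with a two-sample two-sided t-test. Welch is the
default variant with a pooled option, and both are reported: on the
reference vectors S = {9,13,10,12,12,17}, T = {75,75,69} both give
p < 0.001, so the conclusion is variant-robust. How the three binding
modules underlying T were derived is not fully determined by the source
analysis, so the comparison takes the binding partition as explicit input.

## Potential of apparent competition

With normalized cell frequencies `f` and receptor counts `R`, weights
`w_ik = f_i R_ik` give `P_ij = Σ_k (w_ik/Σ_k' w_ik')(w_jk/Σ_l w_lk)`. P is
row-stochastic by construction — this is asserted as the contract (whether
the original edge widths were row-normalized before plotting cannot be
confirmed, so row-stochasticity is a documented assumption). With equal
frequencies and binary counts the formula reduces to the classic unweighted
apparent-competition index, checked against a brute-force loop
implementation. Cells with zero weighted binding are dropped with a warning
rather than given a fabricated uniform row (`on_zero="raise"` restores
strict validation). The bundled MNC-like and progenitor-enriched
composition vectors are clearly-labelled synthetic stand-ins for measured
flow-cytometry compositions: they reproduce the qualitative regime
(neutrophil dominance vs progenitor enrichment), not measured numbers.

## Compartment (OR-gate) model

Bernoulli indicators are drawn per ligand, per compartment, per simulation
(independent); a `shared_fate` flag switches to one draw per compartment.
A ligand in several compartments reaches the stem cells if it reaches via
any (OR). Closed form: `P(reach) = 1 − Π_c (1 − p_c·[lig ∈ L_c])`, and
`E[E_B]` is the mean reach over the process's ligands — the Monte-Carlo
mean at 500 simulations agrees within 3 binomial standard errors (tested).
Significance of a process is judged against a permutation null (its ligand
labels redrawn uniformly from the universe, 1,000 draws, 95th percentile);
the original gray-out criterion is unstated, so this null is this package's
documented substitute. The distance sweep carves a target cell's ligands
into their own compartment and sweeps its reach probability, reporting ΔE
against the p = 0 baseline.

## Ligand effects

Culture counts are modeled on the log scale with a +1 offset (the fold-change
framing of culture outputs is multiplicative; the exact transform was a free
choice). For each output population, `log(count+1)` is regressed on a
condition indicator with a per-experiment random intercept (statsmodels
`MixedLM`, REML). The p-value uses a Wald t with denominator degrees of
freedom `N − n_experiments − 1` (the nlme-style within-group df), which
simulation shows is well calibrated at the study's size (3 experiments × 3
wells). Singular fits or single-experiment data degrade to an OLS comparison
with a warning. The signed one-tail p is the two-sided p halved, carrying
the sign of the estimated effect; consequently `|p|` is uniform on (0, 0.5)
under the null and `|p| ≤ α` fires at rate 2α. Calibration statements
therefore quote the *directional* false-call rate `P(0 < p ≤ α) = α` —
the size of the one-sided test — which the null simulation confirms
(≈ 0.021–0.024 at α = 0.02 over 1,000 replicates).

Classification: arrows ↑/↓/– per population at threshold α ∈ {0.01, 0.02,
0.05} (high/intermediate/low confidence), looked up in the 17-row decision
table; the other 10 of the 27 possible triples are indeterminate
(exhaustively tested). A ligand's category is taken at its most effective
dose — the dose with the smallest |signed p| on any population, ties to the
lower dose; all-null ligands report their highest dose. Ligands whose
category flips across the three thresholds are flagged context-sensitive
and excluded from enrichment.

Enrichment uses the standardized hypergeometric Z
`(k − nm/N)/√(n(m/N)(1−m/N)(N−n)/(N−1))` over the universe of categorized
target-binding ligands, with the conventional enrichment call at Z > 1.15;
it matches standardization of the exhaustively enumerated hypergeometric
pmf to 1e-9 for N ≤ 50. Feedback strength from cell *i* in category *k* is
the additive sum of the target cell's expression levels over the cognate
receptors of *i*'s category-*k* ligands (the exact weighting equation was
underdetermined; the additive receptor-level sum is this package's
documented choice), optionally × cell frequency (mode `frequency`; "Others"
is dropped for lack of a frequency) and × a compartment reach factor
(mode `compartment`, peripheral cells 0.1).

## Synthetic study conditions

The generator's defaults are the study conditions: 12 cell types named and
partitioned as in the hematopoietic system (primitive HSCe+MLP+CMP+MEP+GMP;
Neut+Mono; EryB; Baso+Eos+Mega+PreB), 5 replicates per type (the typical
replicate count), 60 ligand genes split evenly over the modules, 80 receptor
genes, 20% housekeeping genes to exercise universe filtering, log-normal
intensities with baseline log-mean N(5, 1), planted log-scale shift 2.0
against noise SD 0.5 (a 4σ effect — strong, clean over-expression), and
binding promiscuity 0.8 (the promiscuous-binding regime; receptors of
promiscuous ligands are shared across ligand groups and planted one per
module, mirroring shared cytokine receptor chains). Orphan ligands and
unbound ligands exercise the "Others" wiring. Culture counts use the
reference baseline (704 total cells; 6.35% / 27.75% / 65.90% split into
HSC-enriched / progenitor / mature), per-experiment random-intercept SD 0.3
and residual SD 0.3 on the log scale (≈ 35% count CV, matching noisy
40-cell-input cultures), with the log-normal mean bias subtracted so
arithmetic count means hit the baseline; category effects shift population
log-means by 0.6 along the category's canonical arrow pattern.

Planted-block co-clustering recovery is evaluated at promiscuity 0.05
(≈ 5% off-block ligands): a fully promiscuous binding matrix has, by
construction, no blocks to recover — that *is* the promiscuity finding.

What passing these conditions shows: the pipeline's inference machinery
recovers strong, cleanly planted structure essentially perfectly, and its
statistics are calibrated under their own generating models. What it does
not show: robustness to cross-platform batch effects, probe-level noise,
correlated genes, unbalanced replicate counts, or mis-curated interaction
tables — none of which the generator emulates.

## Known limitations

* The analysis operates on transcript-level calls; protein-level evidence
  is out of scope.
* Reach probabilities in the compartment model are abstract stand-ins for
  spatial distance, not fitted quantities.
* The pathway-content permutation analysis is provided only as a generic
  label-shuffling utility; curated pathway annotations are not reproduced.
* Real-data network counts (edge and ligand totals) depend on the original
  microarray data and curation files and are not reproduced here.
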