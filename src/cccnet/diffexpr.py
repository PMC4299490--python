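"""Differentially over-expressed ligands and receptors per cell type.

For each cell type, each gene is compared against every other cell type with
a one-sided (greater) Wilcoxon rank-sum test; p-values are BH-adjusted per
pairwise comparison across the gene universe, and a gene is called for the
cell type when it beats at least ``min_wins`` of the other types at the FDR
threshold (default 6 of 11 for 12 cell types).  The FDR threshold itself is
chosen by ROC against a benchmark list of known cell-type-associated
receptors.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionDataset

logger = logging.getLogger(__name__)

DEFAULT_FDR = 0.10
DEFAULT_MIN_WINS = 6
CANDIDATE_FDRS = (0.01, 0.05, 0.10, 0.20, 0.25)


@dataclass
class OverexpressionCalls:
    """Per-cell-type sets of over-expressed ligand and receptor genes."""

    ligands: dict[str, set[str]]
    receptors: dict[str, set[str]]
    fdr_threshold: float
    min_wins: int
    #: genes called regardless of role, per cell type
    genes: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.genes:
            self.genes = {
                ct: self.ligands.get(ct, set()) | self.receptors.get(ct, set())
                for ct in set(self.ligands) | set(self.receptors)
            }

    @property
    def cell_types(self) -> list[str]:
        return sorted(self.genes)


def pairwise_adjusted_pvalues(
    data: ExpressionDataset, gene_universe: set[str] | list[str]
) -> dict[tuple[str, str], pd.Series]:
    """BH-adjusted one-sided rank-sum p-values per ordered cell-type pair.

    The exact small-sample null is used when both groups have <= 10 samples
    (the study's replicate counts are 3-10), the tie-corrected normal
    approximation otherwise.
    """
    universe = [g for g in data.genes if g in set(gene_universe)]
    missing = set(gene_universe) - set(universe)
    if missing:
        raise ValueError(f"gene universe not in dataset: {sorted(missing)[:5]}")
    sub = data.values.loc[universe]
    blocks = {ct: sub.loc[:, data.samples_of(ct)].to_numpy() for ct in data.cell_types}

    out: dict[tuple[str, str], pd.Series] = {}
    for c in data.cell_types:
        for d in data.cell_types:
            if c == d:
                continue
            x, y = blocks[c], blocks[d]
            method = "exact" if max(x.shape[1], y.shape[1]) <= 10 else "asymptotic"
            res = stats.mannwhitneyu(x, y, axis=1, alternative="greater", method=method)
            adj = multipletests(res.pvalue, method="fdr_bh")[1]
            out[(c, d)] = pd.Series(adj, index=universe)
    return out


def _wins_table(adj_p: dict[tuple[str, str], pd.Series], fdr: float) -> dict[str, pd.Series]:
    """Per cell type, number of other types each gene beats at the threshold."""
    wins: dict[str, pd.Series] = {}
    for (c, _d), p in adj_p.items():
        hit = (p <= fdr).astype(int)
        wins[c] = hit if c not in wins else wins[c] + hit
    return wins


def call_overexpressed(
    data: ExpressionDataset,
    ligand_genes: set[str],
    receptor_genes: set[str],
    fdr: float = DEFAULT_FDR,
    min_wins: int = DEFAULT_MIN_WINS,
    gene_universe: set[str] | None = None,
    _adj_p: dict | None = None,
) -> OverexpressionCalls:
    """Call differentially over-expressed ligands and receptors per cell type."""
    if not 0.0 < fdr < 1.0:
        raise ValueError("fdr must lie in (0, 1)")
    n_types = len(data.cell_types)
    if not 1 <= min_wins <= n_types - 1:
        raise ValueError(f"min_wins must lie in [1, {n_types - 1}]")
    if gene_universe is None:
        gene_universe = (set(ligand_genes) | set(receptor_genes)) & set(data.genes)
    adj_p = _adj_p if _adj_p is not None else pairwise_adjusted_pvalues(data, gene_universe)

    ligands: dict[str, set[str]] = {}
    receptors: dict[str, set[str]] = {}
    for ct, wins in _wins_table(adj_p, fdr).items():
        called = set(wins.index[wins >= min_wins])
        ligands[ct] = called & set(ligand_genes)
        receptors[ct] = called & set(receptor_genes)
    return OverexpressionCalls(ligands, receptors, fdr, min_wins)


# -- ROC-based FDR threshold selection -----------------------------------

def select_fdr_by_roc(
    data: ExpressionDataset,
    benchmark: dict[str, set[str]],
    receptor_genes: set[str],
    candidate_fdrs: tuple[float, ...] = CANDIDATE_FDRS,
    min_wins: int = DEFAULT_MIN_WINS,
    ligand_genes: set[str] = frozenset(),
    gene_universe: set[str] | None = None,
) -> tuple[float, pd.DataFrame]:
    """Pick the FDR maximizing Youden's J against benchmark receptors.

    Sensitivity: fraction of benchmark (cell type, receptor) pairs recovered.
    Specificity: fraction of non-benchmark (cell type, receptor-universe
    gene) pairs not called; an all-genes variant is reported alongside.
    Ties break toward the smaller (more conservative) threshold.
    """
    if not candidate_fdrs:
        raise ValueError("candidate FDR list is empty")
    bench_pairs = {
        (ct, r) for ct, recs in benchmark.items() for r in recs
    }
    if not bench_pairs:
        raise ValueError("benchmark receptor list is empty")
    outside = {r for _, r in bench_pairs} - set(receptor_genes)
    if outside:
        raise ValueError(f"benchmark receptors outside the receptor universe: {sorted(outside)[:5]}")

    if gene_universe is None:
        gene_universe = (set(ligand_genes) | set(receptor_genes)) & set(data.genes)
    adj_p = pairwise_adjusted_pvalues(data, gene_universe)
    cell_types = data.cell_types
    receptor_pairs = {(ct, r) for ct in cell_types for r in receptor_genes}
    all_pairs = {(ct, g) for ct in cell_types for g in gene_universe}

    rows = []
    for fdr in sorted(candidate_fdrs):
        calls = call_overexpressed(
            data, ligand_genes, receptor_genes, fdr, min_wins,
            gene_universe=gene_universe, _adj_p=adj_p,
        )
        called_pairs = {(ct, g) for ct, gs in calls.genes.items() for g in gs}
        tp = len(called_pairs & bench_pairs)
        sens = tp / len(bench_pairs)
        neg_rec = receptor_pairs - bench_pairs
        spec_rec = 1.0 - len((called_pairs & neg_rec)) / len(neg_rec)
        neg_all = all_pairs - bench_pairs
        spec_all = 1.0 - len((called_pairs & neg_all)) / len(neg_all)
        rows.append(
            {
                "fdr": fdr,
                "sensitivity": sens,
                "specificity_receptors": spec_rec,
                "specificity_all_genes": spec_all,
                "youden_j": sens + spec_rec - 1.0,
            }
        )
    table = pd.DataFrame(rows)
    best = table.loc[table["youden_j"].idxmax(), "fdr"]  # idxmax keeps first (smallest fdr)
    return float(best), table


def load_benchmark_receptors() -> dict[str, set[str]]:
    """The printed benchmark of known cell-type-associated receptors."""
    path = importlib.resources.files("cccnet").joinpath("data/benchmark_receptors.tsv")
    df = pd.read_csv(path, sep="\t")
    return {ct: set(sub["receptor"]) for ct, sub in df.groupby("cell_type")}


# -- I/O -----------------------------------------------------------------

def write_calls(calls: OverexpressionCalls, path) -> None:
    rows = [
        {"cell_type": ct, "gene": g, "role": role}
        for role, mapping in (("ligand", calls.ligands), ("receptor", calls.receptors))
        for ct in sorted(mapping)
        for g in sorted(mapping[ct])
    ]
    pd.DataFrame(rows, columns=["cell_type", "gene", "role"]).to_csv(path, sep="\t", index=False)


def read_calls(path, fdr: float = DEFAULT_FDR, min_wins: int = DEFAULT_MIN_WINS) -> OverexpressionCalls:
    df = pd.read_csv(path, sep="\t")
    ligands: dict[str, set[str]] = {}
    receptors: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        target = ligands if row["role"] == "ligand" else receptors
        target.setdefault(row["cell_type"], set()).add(row["gene"])
    for ct in set(ligands) | set(receptors):
        ligands.setdefault(ct, set())
        receptors.setdefault(ct, set())
    return OverexpressionCalls(ligands, receptors, fdr, min_wins)
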