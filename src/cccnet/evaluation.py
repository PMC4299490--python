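"""Planted-truth recovery and calibration studies on synthetic data.

These routines quantify how well the pipeline recovers what the generator
planted: over-expression calls, production modules, binding co-clusters, and
the nominal size of the mixed-model test.  They are shared by the test
suite, the analysis drivers, and the acceptance script.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from . import diffexpr, structure, synthetic
from .effects import signed_pvalues
from .synthetic import SyntheticDesign, generate_expression, generate_invitro_counts


def match_label_accuracy(truth: pd.Series, predicted: pd.Series) -> float:
    """Best-matching label accuracy via Hungarian assignment on the confusion matrix."""
    truth, predicted = truth.align(predicted, join="inner")
    conf = pd.crosstab(truth, predicted).to_numpy()
    r, c = linear_sum_assignment(-conf)
    return conf[r, c].sum() / len(truth)


def planted_call_recovery(
    design: SyntheticDesign,
    fdr: float = diffexpr.DEFAULT_FDR,
    min_wins: int = diffexpr.DEFAULT_MIN_WINS,
) -> tuple[float, float]:
    """(recovery, false-discovery proportion) of planted over-expression calls."""
    data = generate_expression(design)
    ligand_genes = set(design.ligand_names) | set(design.orphan_ligand_names)
    receptor_genes = set(design.receptor_names)
    calls = diffexpr.call_overexpressed(data, ligand_genes, receptor_genes, fdr, min_wins)
    truth = design.planted_calls()
    n_true = sum(len(s) for s in truth.values())
    tp = sum(len(calls.genes.get(ct, set()) & truth[ct]) for ct in truth)
    n_called = sum(len(s) for s in calls.genes.values())
    recovery = tp / n_true if n_true else float("nan")
    fdp = (n_called - tp) / n_called if n_called else 0.0
    return recovery, fdp


def recovery_over_seeds(
    design: SyntheticDesign, seeds: list[int], **kwargs
) -> pd.DataFrame:
    rows = []
    for s in seeds:
        rec, fdp = planted_call_recovery(replace(design, seed=int(s)), **kwargs)
        rows.append({"seed": int(s), "recovery": rec, "fdp": fdp})
    return pd.DataFrame(rows)


def production_module_recovery(
    design: SyntheticDesign,
    fdr: float = diffexpr.DEFAULT_FDR,
    min_wins: int = diffexpr.DEFAULT_MIN_WINS,
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6),
) -> tuple[int, float]:
    """(silhouette-selected k, accuracy vs the planted cell partition).

    Runs the full path: expression -> calls -> network -> Jaccard/Ward
    clustering with silhouette-based module count selection.
    """
    from .network import build_network, production_network

    data = generate_expression(design)
    lr = synthetic.generate_lr_table(design)
    ligand_genes = set(design.ligand_names) | set(design.orphan_ligand_names)
    calls = diffexpr.call_overexpressed(
        data, ligand_genes, set(design.receptor_names), fdr, min_wins
    )
    net = build_network(calls, lr, include_others=False)
    A = production_network(net)
    A = A.loc[[c for c in A.index if c in design.cell_types]]
    part = structure.cluster_production(A, k_range=k_range)
    truth = pd.Series(
        {c: mod for mod, cells in design.planted_production_modules.items() for c in cells}
    )
    acc = match_label_accuracy(truth.loc[part.assignment.index], part.assignment)
    return part.k, acc


def binding_block_recovery(
    design: SyntheticDesign,
    fdr: float = diffexpr.DEFAULT_FDR,
    min_wins: int = diffexpr.DEFAULT_MIN_WINS,
    seed: int = 0,
) -> float:
    """Co-clustering accuracy on the planted binding blocks (block ligands + cells).

    Runs expression -> calls -> network -> spectral co-clustering with
    k = number of planted modules, then scores ligand rows (against each
    block ligand's module) and cell columns (against the planted partition)
    jointly, with Hungarian label matching.  Promiscuous ligands bind every
    cell by construction and carry no block label, so they are excluded from
    the score.
    """
    from .network import binding_network, build_network

    data = generate_expression(design)
    lr = synthetic.generate_lr_table(design)
    ligand_genes = set(design.ligand_names) | set(design.orphan_ligand_names)
    calls = diffexpr.call_overexpressed(
        data, ligand_genes, set(design.receptor_names), fdr, min_wins
    )
    net = build_network(calls, lr, include_others=False)
    B = binding_network(net)
    k = len(design.planted_production_modules)
    res = structure.cocluster_binding(B, k=k, seed=seed)

    module_of_lig = design.ligand_module()
    prom = design.promiscuous_ligands()
    block_ligs = [
        l for l in res.row_assignment.index if l in module_of_lig and l not in prom
    ]
    truth_cells = pd.Series(
        {c: mod for mod, cells in design.planted_production_modules.items() for c in cells}
    )
    truth = pd.concat(
        [
            pd.Series({l: module_of_lig[l] for l in block_ligs}),
            truth_cells.reindex(res.col_assignment.index).dropna(),
        ]
    )
    pred = pd.concat([res.row_assignment.loc[block_ligs], res.col_assignment])
    return match_label_accuracy(truth, pred.loc[truth.index])


def mixed_model_type1_error(
    n_reps: int = 1000,
    alpha: float = 0.02,
    n_experiments: int = 3,
    replicates: int = 3,
    experiment_sd: float = 0.3,
    residual_sd: float = 0.3,
    seed: int = 0,
) -> float:
    """Directional false-call rate of the signed one-tail p under the null.

    Simulates a functionally neutral ligand and counts, across replicates
    and the three populations, how often the signed p calls an *increase*
    at threshold alpha (P(0 < p <= alpha), the size of the one-sided test;
    a calibrated test yields alpha).
    """
    rng = np.random.default_rng(seed)
    hits = total = 0
    for _ in range(n_reps):
        counts = generate_invitro_counts(
            {"NULLLIG": "neutral"},
            n_experiments=n_experiments,
            replicates=replicates,
            experiment_sd=experiment_sd,
            residual_sd=residual_sd,
            seed=int(rng.integers(2**31)),
        )
        for p in signed_pvalues(counts, "NULLLIG"):
            total += 1
            hits += 0 < p <= alpha
    return hits / total


def null_signed_pvalues(
    n_reps: int = 200, seed: int = 0, **kwargs
) -> np.ndarray:
    """Signed p-values of a neutral ligand over replicate simulations."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_reps):
        counts = generate_invitro_counts(
            {"NULLLIG": "neutral"}, seed=int(rng.integers(2**31)), **kwargs
        )
        out.extend(signed_pvalues(counts, "NULLLIG"))
    return np.array(out)
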