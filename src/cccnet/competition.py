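"""Potential of apparent competition (PAC) between cell types via shared ligands.

Cells "compete" for ligands in the sense of apparent-competition food webs:
the more of ligand k's total uptake capacity cell j holds, and the larger a
share of cell i's binding portfolio ligand k represents, the stronger j's
potential to deprive i.  With w_ik = f_i * R_ik (cell frequency times
receptor count), the PAC of cell i toward cell j is

    P_ij = sum_k (w_ik / sum_k' w_ik') * (w_jk / sum_l w_lk)

so every row of P sums to 1 and the diagonal is each cell's
self-competition share.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def load_frequency_vector(path) -> pd.Series:
    """Two-column (cell_type, frequency) TSV, normalized to sum to 1 on load."""
    df = pd.read_csv(path, sep="\t")
    missing = {"cell_type", "frequency"} - set(df.columns)
    if missing:
        raise ValueError(f"frequency file {path} is missing columns: {sorted(missing)}")
    return normalize_frequencies(pd.Series(df["frequency"].to_numpy(), index=df["cell_type"]))


def normalize_frequencies(freq: pd.Series) -> pd.Series:
    freq = freq.astype(float)
    if (freq < 0).any():
        raise ValueError("frequencies must be non-negative")
    total = freq.sum()
    if total <= 0:
        raise ValueError("frequencies sum to zero")
    return freq / total


def compute_pac(
    B: pd.DataFrame, freq: pd.Series, on_zero: str = "drop"
) -> pd.DataFrame:
    """Frequency-weighted PAC matrix from the ligand x cell binding matrix.

    Cells whose total weighted binding is zero are dropped with a warning
    (``on_zero="raise"`` turns them into a validation error instead): a cell
    binding nothing has no competition portfolio to normalize.
    """
    cells = list(B.columns)
    missing = [c for c in cells if c not in freq.index]
    if missing:
        raise ValueError(f"frequency vector missing cells: {missing}")
    f = normalize_frequencies(freq.reindex(cells))

    W = B.to_numpy(dtype=float) * f.to_numpy()[None, :]  # w[k, i] = f_i * R_ik
    col_tot = W.sum(axis=0)
    dead = [c for c, tot in zip(cells, col_tot) if tot == 0]
    if dead:
        if on_zero == "raise":
            raise ValueError(f"cells with zero weighted binding: {dead}")
        logger.warning("dropping cells with zero weighted binding: %s", dead)
        keep = [c for c in cells if c not in dead]
        if not keep:
            return pd.DataFrame(dtype=float)
        return compute_pac(B[keep], freq, on_zero="raise")

    portfolio = W / col_tot[None, :]  # cell i's share of its own binding on each ligand
    row_tot = W.sum(axis=1)
    live = row_tot > 0  # ligands nobody binds contribute nothing
    uptake = np.zeros_like(W)
    uptake[live] = W[live] / row_tot[live, None]  # cell j's share of ligand k's uptake
    P = portfolio.T @ uptake
    return pd.DataFrame(P, index=cells, columns=cells)


def pac_scenarios(
    B: pd.DataFrame, scenarios: dict[str, pd.Series], on_zero: str = "drop"
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """PAC under each named cell-composition scenario, plus a dominance summary.

    The summary reports, per scenario and cell, the strongest competitor
    overall and the strongest competitor other than the cell itself.
    """
    matrices: dict[str, pd.DataFrame] = {}
    rows = []
    for name, freq in scenarios.items():
        P = compute_pac(B, freq, on_zero=on_zero)
        matrices[name] = P
        for cell in P.index:
            row = P.loc[cell]
            others = row.drop(cell)
            rows.append(
                {
                    "scenario": name,
                    "cell": cell,
                    "top_competitor": row.idxmax(),
                    "top_competitor_share": float(row.max()),
                    "top_other_competitor": others.idxmax() if len(others) else "",
                    "self_share": float(row[cell]),
                }
            )
    return matrices, pd.DataFrame(rows)


# Illustrative synthetic compositions for the two scenarios the analysis
# contrasts.  These are constructed stand-ins (the study measured real
# compositions by flow cytometry): a mono-nucleated-cell-like mixture
# dominated by neutrophils, and a lineage-depleted progenitor-enriched
# mixture in which stem/progenitor types are abundant.
MNC_LIKE_FREQUENCIES = pd.Series(
    {
        "HSCe": 0.0005, "MLP": 0.0045, "CMP": 0.010, "MEP": 0.010, "GMP": 0.015,
        "Neut": 0.400, "Mono": 0.180, "EryB": 0.250,
        "Baso": 0.020, "Eos": 0.030, "Mega": 0.010, "PreB": 0.070,
    }
)

PROGENITOR_ENRICHED_FREQUENCIES = pd.Series(
    {
        "HSCe": 0.080, "MLP": 0.100, "CMP": 0.200, "MEP": 0.150, "GMP": 0.180,
        "Neut": 0.050, "Mono": 0.060, "EryB": 0.080,
        "Baso": 0.020, "Eos": 0.020, "Mega": 0.010, "PreB": 0.050,
    }
)


def example_scenarios() -> dict[str, pd.Series]:
    return {
        "mnc_like": normalize_frequencies(MNC_LIKE_FREQUENCIES),
        "progenitor_enriched": normalize_frequencies(PROGENITOR_ENRICHED_FREQUENCIES),
    }


def write_pac(P: pd.DataFrame, path) -> None:
    P.to_csv(path, sep="\t")
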