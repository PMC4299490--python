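"""The directional bipartite cell-cell communication (CCC) network.

Cells connect through ligands: cell B -> ligand x -> cell A means B
over-expresses ligand x and A over-expresses at least one receptor for x.
The network is stored as two matrices: a binary production matrix A (cell x
ligand) and a binding matrix B (ligand x cell) counting the receptor species
— or, in heteromeric mode, complete receptor complexes — the cell
over-expresses for the ligand.  Ligands whose producer or binder is absent
from the modeled cell types are wired to an aggregate "Others" pseudo-cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .diffexpr import OverexpressionCalls
from .lr import LRInteractionTable

logger = logging.getLogger(__name__)

OTHERS = "Others"


@dataclass
class CCCNetwork:
    production: pd.DataFrame  # cells x ligands, binary
    binding: pd.DataFrame  # ligands x cells, receptor-species counts
    heteromeric_mode: bool = False

    def __post_init__(self) -> None:
        if list(self.production.columns) != list(self.binding.index):
            raise ValueError("production columns and binding rows must list the same ligands")
        if list(self.production.index) != list(self.binding.columns):
            raise ValueError("production rows and binding columns must list the same cells")
        isolated = [
            lig
            for lig in self.production.columns
            if self.production[lig].sum() == 0 and self.binding.loc[lig].sum() == 0
        ]
        if isolated:
            raise ValueError(f"isolated ligand nodes: {isolated[:5]}")

    @property
    def cell_nodes(self) -> list[str]:
        return list(self.production.index)

    @property
    def ligand_nodes(self) -> list[str]:
        return list(self.production.columns)

    def cell_edges(self) -> pd.DataFrame:
        """All producer -> ligand -> binder relationships with binding weight."""
        rows = []
        for lig in self.ligand_nodes:
            producers = self.production.index[self.production[lig] >= 1]
            binders = self.binding.columns[self.binding.loc[lig] >= 1]
            for src in producers:
                for dst in binders:
                    rows.append(
                        {
                            "source": src,
                            "ligand": lig,
                            "target": dst,
                            "n_receptors": int(self.binding.loc[lig, dst]),
                        }
                    )
        return pd.DataFrame(rows, columns=["source", "ligand", "target", "n_receptors"])


def build_network(
    calls: OverexpressionCalls,
    lr: LRInteractionTable,
    heteromeric_mode: bool = False,
    include_others: bool = True,
) -> CCCNetwork:
    """Assemble the CCC network from over-expression calls and the LR table."""
    known = lr.ligands | lr.receptors
    stray = {
        g for sets in (calls.ligands, calls.receptors) for s in sets.values() for g in s
    } - known
    if stray:
        logger.warning(
            "%d called genes absent from the interaction table were ignored", len(stray)
        )

    cells = calls.cell_types
    ligands = sorted(lr.ligands)
    production = pd.DataFrame(0, index=cells, columns=ligands, dtype=int)
    binding = pd.DataFrame(0, index=ligands, columns=cells, dtype=int)

    units = {lig: lr.receptor_units(lig, heteromeric=heteromeric_mode) for lig in ligands}
    for ct in cells:
        produced = calls.ligands.get(ct, set())
        expressed = calls.receptors.get(ct, set())
        for lig in ligands:
            if lig in produced:
                production.loc[ct, lig] = 1
            binding.loc[lig, ct] = sum(1 for unit in units[lig] if unit <= expressed)

    produced_any = production.sum(axis=0) >= 1
    bound_any = binding.sum(axis=1) >= 1
    if include_others:
        production.loc[OTHERS] = (~produced_any & bound_any).astype(int)
        binding[OTHERS] = (produced_any & ~bound_any).astype(int)
        keep = produced_any | bound_any
    else:
        keep = produced_any & bound_any
    dropped = [lig for lig in ligands if not keep[lig]]
    if dropped:
        logger.info("dropped %d ligands with no modeled producer or binder", len(dropped))
    kept = [lig for lig in ligands if keep[lig]]
    return CCCNetwork(
        production=production[kept],
        binding=binding.loc[kept],
        heteromeric_mode=heteromeric_mode,
    )


def production_network(net: CCCNetwork) -> pd.DataFrame:
    """Binary cell x ligand production matrix, zero rows/columns dropped."""
    a = net.production
    a = a.loc[a.sum(axis=1) >= 1, a.columns[a.sum(axis=0) >= 1]]
    return a.copy()


def binding_network(net: CCCNetwork) -> pd.DataFrame:
    """Ligand x cell receptor-count matrix, zero rows/columns dropped."""
    b = net.binding
    b = b.loc[b.sum(axis=1) >= 1, b.columns[b.sum(axis=0) >= 1]]
    return b.copy()


def rank_cells_by_degree(net: CCCNetwork) -> pd.DataFrame:
    """Per cell, the number of produced ligands and of bound ligand species."""
    if not net.cell_nodes:
        return pd.DataFrame(columns=["n_produced_ligands", "n_bound_ligands"])
    produced = net.production.sum(axis=1).astype(int)
    bound = (net.binding >= 1).sum(axis=0).astype(int)
    return pd.DataFrame(
        {"n_produced_ligands": produced, "n_bound_ligands": bound.reindex(produced.index)}
    )


# -- export --------------------------------------------------------------

def to_graph(net: CCCNetwork) -> nx.DiGraph:
    """Bipartite directed graph: cell -> ligand (production), ligand -> cell (binding)."""
    g = nx.DiGraph()
    for cell in net.cell_nodes:
        g.add_node(cell, kind="cell")
    for lig in net.ligand_nodes:
        g.add_node(lig, kind="ligand")
        for cell in net.production.index[net.production[lig] >= 1]:
            g.add_edge(cell, lig, weight=1)
        for cell in net.binding.columns[net.binding.loc[lig] >= 1]:
            g.add_edge(lig, cell, weight=int(net.binding.loc[lig, cell]))
    return g


def write_graphml(net: CCCNetwork, path) -> None:
    nx.write_graphml(to_graph(net), path)


def write_edge_list(net: CCCNetwork, path) -> None:
    net.cell_edges().to_csv(path, sep="\t", index=False)


def write_matrices(net: CCCNetwork, production_path, binding_path) -> None:
    net.production.to_csv(production_path, sep="\t")
    net.binding.to_csv(binding_path, sep="\t")
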