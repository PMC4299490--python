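"""Gene-by-sample expression container with per-sample cell-type labels."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ExpressionDataset:
    """A gene x sample matrix of non-negative intensities plus sample labels.

    ``values`` is indexed by gene symbol (no duplicates; probe-level signals
    are assumed pre-averaged per gene) and has one column per sample.
    ``cell_type_of`` maps each sample id to its cell-type label; every cell
    type must have at least two samples so that rank tests are defined.
    """

    values: pd.DataFrame
    cell_type_of: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene symbols: {dups[:5]}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        self.cell_type_of = self.cell_type_of.reindex(self.values.columns)
        if self.cell_type_of.isna().any():
            missing = self.cell_type_of[self.cell_type_of.isna()].index.tolist()
            raise ValueError(f"samples without a cell-type label: {missing[:5]}")
        counts = self.cell_type_of.value_counts()
        thin = counts[counts < 2]
        if len(thin):
            raise ValueError(
                f"cell types with fewer than 2 samples: {sorted(thin.index.tolist())}"
            )

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def cell_types(self) -> list[str]:
        # first-appearance order of the labels
        return list(dict.fromkeys(self.cell_type_of))

    def samples_of(self, cell_type: str) -> list[str]:
        return list(self.cell_type_of.index[self.cell_type_of == cell_type])

    def matrix_of(self, cell_type: str) -> np.ndarray:
        """Gene x replicate value block for one cell type."""
        return self.values.loc[:, self.samples_of(cell_type)].to_numpy()


def write_expression(data: ExpressionDataset, path) -> None:
    """Write genes x samples TSV with a two-row header (sample id, cell type)."""
    with open(path, "w") as fh:
        fh.write("gene\t" + "\t".join(map(str, data.samples)) + "\n")
        fh.write("cell_type\t" + "\t".join(map(str, data.cell_type_of)) + "\n")
        data.values.to_csv(fh, sep="\t", header=False, float_format="%.6g")


def read_expression(path) -> ExpressionDataset:
    """Read the two-row-header TSV written by :func:`write_expression`."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        labels = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "gene" or labels[0] != "cell_type":
            raise ValueError(f"{path} is not a two-row-header expression matrix")
        samples = header[1:]
        values = pd.read_csv(fh, sep="\t", header=None, index_col=0)
    values.columns = samples
    values.index.name = "gene"
    cell_type_of = pd.Series(labels[1:], index=samples, name="cell_type")
    return ExpressionDataset(values=values, cell_type_of=cell_type_of)
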