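"""Ligand-receptor interaction table and ligand-set annotations.

The interaction table is the curated list of ligand -> receptor pairs that
defines which secreted signals each cell type can, in principle, produce or
bind.  Receptors that only signal as hetero-multimeric complexes (e.g. the
class-1 cytokine receptors, IL6R + IL6ST for IL6) can be grouped so that a
complex counts as a single receptor unit only when every subunit is present.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

LIGAND_COL = "ligand"
RECEPTOR_COL = "receptor"
CONFIDENCE_COL = "confidence"
COMPLEX_COL = "complex_group"


@dataclass
class LRInteractionTable:
    """Curated ligand->receptor pairs with optional confidence and complex grouping.

    Parameters
    ----------
    pairs
        One interaction per row with columns ``ligand``, ``receptor``,
        ``confidence`` (in [0, 1], default 1.0) and ``complex_group``
        (label shared by receptor subunits that signal jointly; empty string
        for independent receptors).
    """

    pairs: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.pairs.copy()
        for col in (LIGAND_COL, RECEPTOR_COL):
            if col not in df.columns:
                raise ValueError(f"interaction table is missing the '{col}' column")
            df[col] = df[col].astype(str).str.upper().str.strip()
        if CONFIDENCE_COL not in df.columns:
            df[CONFIDENCE_COL] = 1.0
        df[CONFIDENCE_COL] = df[CONFIDENCE_COL].fillna(1.0).astype(float)
        if ((df[CONFIDENCE_COL] < 0) | (df[CONFIDENCE_COL] > 1)).any():
            raise ValueError("confidence scores must lie in [0, 1]")
        if COMPLEX_COL not in df.columns:
            df[COMPLEX_COL] = ""
        df[COMPLEX_COL] = df[COMPLEX_COL].fillna("").astype(str)
        if df.empty:
            raise ValueError("interaction table contains no interactions")

        n_dup = df.duplicated(subset=[LIGAND_COL, RECEPTOR_COL]).sum()
        if n_dup:
            logger.warning("collapsed %d duplicated ligand-receptor pairs", n_dup)
            df = df.drop_duplicates(subset=[LIGAND_COL, RECEPTOR_COL], keep="first")

        # a declared complex must have >= 2 subunits for its ligand
        grouped = df[df[COMPLEX_COL] != ""]
        for (lig, grp), sub in grouped.groupby([LIGAND_COL, COMPLEX_COL]):
            if len(sub) < 2:
                raise ValueError(
                    f"heteromeric group '{grp}' of ligand {lig} has fewer than 2 subunits"
                )
        self.pairs = df.reset_index(drop=True)

    # -- queries ---------------------------------------------------------
    @property
    def ligands(self) -> set[str]:
        return set(self.pairs[LIGAND_COL])

    @property
    def receptors(self) -> set[str]:
        return set(self.pairs[RECEPTOR_COL])

    def cognate_receptors(self, ligand: str) -> set[str]:
        """Receptor genes documented to bind ``ligand`` (empty set if absent)."""
        sub = self.pairs[self.pairs[LIGAND_COL] == str(ligand).upper()]
        return set(sub[RECEPTOR_COL])

    def cognate_ligands(self, receptor: str) -> set[str]:
        """Ligand genes documented to bind ``receptor`` (empty set if absent)."""
        sub = self.pairs[self.pairs[RECEPTOR_COL] == str(receptor).upper()]
        return set(sub[LIGAND_COL])

    def receptor_units(self, ligand: str, heteromeric: bool = False) -> list[frozenset[str]]:
        """Receptor units of a ligand: singletons, or complexes when ``heteromeric``.

        In heteromeric mode the subunits sharing a ``complex_group`` label
        collapse into one unit; a unit only counts as expressed when all of
        its subunits are expressed.
        """
        sub = self.pairs[self.pairs[LIGAND_COL] == str(ligand).upper()]
        if not heteromeric:
            return [frozenset([r]) for r in sub[RECEPTOR_COL]]
        units: list[frozenset[str]] = []
        for grp, rows in sub.groupby(COMPLEX_COL, sort=True):
            if grp == "":
                units.extend(frozenset([r]) for r in rows[RECEPTOR_COL])
            else:
                units.append(frozenset(rows[RECEPTOR_COL]))
        return units

    def ligand_confidence(self, ligand: str, aggregate: str = "max") -> float:
        """Aggregate interaction confidence of a ligand over its receptors."""
        sub = self.pairs[self.pairs[LIGAND_COL] == str(ligand).upper()]
        if sub.empty:
            return float("nan")
        if aggregate == "max":
            return float(sub[CONFIDENCE_COL].max())
        if aggregate == "mean":
            return float(sub[CONFIDENCE_COL].mean())
        raise ValueError(f"unknown aggregation rule '{aggregate}'")

    def __len__(self) -> int:
        return len(self.pairs)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LRInteractionTable):
            return NotImplemented
        a = self.pairs.sort_values([LIGAND_COL, RECEPTOR_COL]).reset_index(drop=True)
        b = other.pairs.sort_values([LIGAND_COL, RECEPTOR_COL]).reset_index(drop=True)
        return a.equals(b)


@dataclass
class LigandSetAnnotation:
    """A named biological process with its annotated member ligands."""

    process_name: str
    member_ligands: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.member_ligands = {str(g).upper() for g in self.member_ligands}
        if not self.member_ligands:
            raise ValueError(f"annotation '{self.process_name}' has an empty ligand set")


# -- I/O -----------------------------------------------------------------

def read_lr_table(path) -> LRInteractionTable:
    """Read a tab-separated interaction table (ligand, receptor[, confidence, complex_group])."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"interaction table {path} is empty") from exc
    if df.empty:
        raise ValueError(f"interaction table {path} contains no interactions")
    missing = {LIGAND_COL, RECEPTOR_COL} - set(df.columns)
    if missing:
        raise ValueError(f"interaction table {path} is missing columns: {sorted(missing)}")
    if CONFIDENCE_COL in df.columns:
        df[CONFIDENCE_COL] = df[CONFIDENCE_COL].astype(float)
    return LRInteractionTable(df)


def write_lr_table(table: LRInteractionTable, path) -> None:
    table.pairs.to_csv(path, sep="\t", index=False)


def read_ligand_annotations(path) -> list[LigandSetAnnotation]:
    """Read long-format (process, ligand) annotations, one row per membership."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"process", "ligand"} - set(df.columns)
    if missing:
        raise ValueError(f"annotation file {path} is missing columns: {sorted(missing)}")
    return [
        LigandSetAnnotation(process, set(sub["ligand"]))
        for process, sub in df.groupby("process", sort=True)
    ]


def write_ligand_annotations(annotations: list[LigandSetAnnotation], path) -> None:
    rows = [
        {"process": ann.process_name, "ligand": lig}
        for ann in annotations
        for lig in sorted(ann.member_ligands)
    ]
    pd.DataFrame(rows, columns=["process", "ligand"]).to_csv(path, sep="\t", index=False)
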