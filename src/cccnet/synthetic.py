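"""Synthetic inputs with the statistical structure of the hematopoietic study.

The generator emulates the three data layers the analysis consumes:

* an expression matrix over 12 hematopoietic cell types (stem, progenitor and
  mature populations, 3-10 replicates each) with cell-type-specific
  over-expression planted on ligand and receptor genes — modular ligand
  production, promiscuous ligand binding;
* a ligand-receptor interaction table wired to the planted truth, including
  multi-receptor ligands, optional heteromeric receptor complexes, and orphan
  ligands/receptors that exercise the "Others" pseudo-cell;
* per-well in vitro culture counts of three output populations under a basal
  cytokine control and per-ligand conditions, with a nested per-experiment
  random effect matching the mixed linear model fitted downstream.

Expression intensities are log-normal (normal on the log scale): the
downstream differential test is rank-based, and log-normal draws mimic
microarray intensities.  Fixing the seed fixes every output bit-for-bit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .effects import CATEGORY_EFFECT_DIRECTIONS
from .expression import ExpressionDataset
from .lr import LigandSetAnnotation, LRInteractionTable

logger = logging.getLogger(__name__)

#: the 12 modeled cell types
CELL_TYPES = (
    "HSCe", "MLP", "CMP", "MEP", "GMP",
    "Neut", "Mono",
    "EryB",
    "Baso", "Eos", "Mega", "PreB",
)

#: planted partition of the cell types into ligand-production modules:
#: primitive stem/progenitor module, neutrophil-monocyte module, erythroid
#: module, and the remaining mature cell types
DEFAULT_MODULES: dict[str, tuple[str, ...]] = {
    "primitive": ("HSCe", "MLP", "CMP", "MEP", "GMP"),
    "neut_mono": ("Neut", "Mono"),
    "erythroid": ("EryB",),
    "other_mature": ("Baso", "Eos", "Mega", "PreB"),
}

#: basal-cytokine control culture reference: ~704 total cells per well
#: splitting 6.35% / 27.75% / 65.90% into HSC-enriched / progenitor / mature
BASELINE_TOTAL_CELLS = 704.0
BASELINE_FRACTIONS = {"hsc_enriched": 0.0635, "progenitor": 0.2775, "mature": 0.6590}

COUNT_COLUMNS = ("n_hsc_enriched", "n_progenitor", "n_mature")


@dataclass
class SyntheticDesign:
    """Ground-truth layout of one synthetic hematopoietic dataset.

    ``binding_promiscuity`` is the fraction of ligands whose receptor species
    collectively cover all cell types (so every cell binds them); the
    remaining ligands have receptors confined to their own production module,
    giving the binding matrix a planted block structure.
    ``effect_size`` is the additive shift on the natural-log scale applied to
    a planted gene in its over-expressing cell types.
    """

    n_cell_types: int = 12
    n_replicates_per_type: int = 5
    n_ligand_genes: int = 60
    n_receptor_genes: int = 80
    planted_production_modules: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_MODULES)
    )
    binding_promiscuity: float = 0.8
    effect_size: float = 2.0
    noise_sd: float = 0.5
    multi_receptor_fraction: float = 0.2
    n_orphan_ligands: int = 2
    n_unbound_ligands: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cell_types < 2 or self.n_replicates_per_type < 2:
            raise ValueError("need at least 2 cell types and 2 replicates per type")
        if self.n_ligand_genes < 2 or self.n_receptor_genes < 2:
            raise ValueError("need at least 2 ligand and 2 receptor genes")
        if not 0.0 <= self.binding_promiscuity <= 1.0:
            raise ValueError("binding_promiscuity must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        cells = [c for mod in self.planted_production_modules.values() for c in mod]
        if len(cells) != len(set(cells)):
            raise ValueError("production modules must be disjoint")
        if len(cells) != self.n_cell_types:
            raise ValueError(
                f"modules cover {len(cells)} cell types, expected {self.n_cell_types}"
            )
        needed = self.n_receptors_required()
        if self.n_receptor_genes < needed:
            raise ValueError(
                f"n_receptor_genes={self.n_receptor_genes} but the wiring needs {needed}"
            )

    # -- derived layout (pure functions of the fields) -------------------
    @property
    def cell_types(self) -> list[str]:
        return [c for mod in self.planted_production_modules.values() for c in mod]

    @property
    def module_names(self) -> list[str]:
        return list(self.planted_production_modules)

    @property
    def ligand_names(self) -> list[str]:
        return [f"LIG{i:03d}" for i in range(1, self.n_ligand_genes + 1)]

    @property
    def orphan_ligand_names(self) -> list[str]:
        return [f"OLIG{i:02d}" for i in range(1, self.n_orphan_ligands + 1)]

    @property
    def receptor_names(self) -> list[str]:
        return [f"REC{i:03d}" for i in range(1, self.n_receptor_genes + 1)]

    def ligand_module(self) -> dict[str, str]:
        """Contiguous even split of the planted ligands over the modules."""
        mods = self.module_names
        out: dict[str, str] = {}
        for i, lig in enumerate(self.ligand_names):
            out[lig] = mods[i * len(mods) // self.n_ligand_genes]
        return out

    def promiscuous_ligands(self) -> set[str]:
        """The first round(promiscuity * module size) ligands of each module."""
        by_mod: dict[str, list[str]] = {m: [] for m in self.module_names}
        for lig, mod in self.ligand_module().items():
            by_mod[mod].append(lig)
        chosen: set[str] = set()
        for mod, ligs in by_mod.items():
            k = round(self.binding_promiscuity * len(ligs))
            chosen.update(ligs[:k])
        return chosen

    def unbound_ligands(self) -> set[str]:
        """Block ligands whose receptors are planted in no modeled cell type."""
        block = [l for l in self.ligand_names if l not in self.promiscuous_ligands()]
        return set(block[-self.n_unbound_ligands:]) if self.n_unbound_ligands else set()

    def n_receptors_required(self) -> int:
        return len(self._wiring()[0])

    # internal: (receptor -> target module or None, pair rows)
    def _wiring(self):
        module_of = self.ligand_module()
        prom = self.promiscuous_ligands()
        unbound = self.unbound_ligands()
        mods = self.module_names

        receptor_target: dict[str, str | None] = {}
        rows: list[dict] = []
        counter = [0]

        def new_receptor(target: str | None) -> str:
            counter[0] += 1
            name = f"REC{counter[0]:03d}"
            receptor_target[name] = target
            return name

        # promiscuous ligands in groups of 4 share one receptor per module,
        # mirroring shared cytokine receptor chains
        prom_sorted = [l for l in self.ligand_names if l in prom]
        shared: list[str] | None = None
        for i, lig in enumerate(prom_sorted):
            if i % 4 == 0:
                shared = [new_receptor(m) for m in mods]
            for rec in shared:
                rows.append({"ligand": lig, "receptor": rec, "complex_group": ""})

        block_sorted = [l for l in self.ligand_names if l not in prom]
        n_multi = round(self.multi_receptor_fraction * len(block_sorted))
        for i, lig in enumerate(block_sorted):
            target = None if lig in unbound else module_of[lig]
            n_rec = 2 if i < n_multi else 1
            # alternate multi-receptor ligands between independent receptors
            # and a 2-subunit heteromeric complex
            group = f"{lig}_CPLX" if (n_rec == 2 and i % 2 == 1) else ""
            for _ in range(n_rec):
                rows.append(
                    {"ligand": lig, "receptor": new_receptor(target), "complex_group": group}
                )

        for i, lig in enumerate(self.orphan_ligand_names):
            target = mods[i % len(mods)]
            rows.append({"ligand": lig, "receptor": new_receptor(target), "complex_group": ""})

        return receptor_target, rows

    def receptor_target_modules(self) -> dict[str, str | None]:
        """Receptor -> module whose cells over-express it (None = nowhere).

        Receptor genes beyond the wired ones are planted in a single rotating
        cell type but never appear in the interaction table.
        """
        targets, _ = self._wiring()
        cells = self.cell_types
        for i, rec in enumerate(self.receptor_names):
            if rec not in targets:
                targets[rec] = f"cell:{cells[i % len(cells)]}"
        return targets

    def housekeeping_names(self) -> list[str]:
        n_signal = self.n_ligand_genes + self.n_orphan_ligands + self.n_receptor_genes
        n_hk = round(n_signal / 4)  # 20% of the final matrix
        return [f"HK{i:03d}" for i in range(1, n_hk + 1)]

    def expression_truth(self) -> pd.DataFrame:
        """Boolean gene x cell-type matrix of planted over-expression."""
        module_cells = {m: set(cs) for m, cs in self.planted_production_modules.items()}
        module_of = self.ligand_module()
        rec_target = self.receptor_target_modules()
        genes = (
            self.ligand_names
            + self.orphan_ligand_names
            + self.receptor_names
            + self.housekeeping_names()
        )
        truth = pd.DataFrame(False, index=genes, columns=list(self.cell_types))
        for lig, mod in module_of.items():
            truth.loc[lig, list(module_cells[mod])] = True
        for rec, target in rec_target.items():
            if target is None:
                continue
            if target.startswith("cell:"):
                truth.loc[rec, target[5:]] = True
            else:
                truth.loc[rec, list(module_cells[target])] = True
        return truth

    def planted_calls(self) -> dict[str, set[str]]:
        """Cell type -> planted over-expressed genes (the recovery target)."""
        truth = self.expression_truth()
        return {ct: set(truth.index[truth[ct]]) for ct in truth.columns}


# -- generators ----------------------------------------------------------

def generate_expression(design: SyntheticDesign) -> ExpressionDataset:
    """Draw the log-normal expression matrix with planted over-expression."""
    rng = np.random.default_rng(design.seed)
    truth = design.expression_truth()
    genes = truth.index
    cells = design.cell_types
    n_rep = design.n_replicates_per_type

    base = rng.normal(5.0, 1.0, size=len(genes))  # per-gene baseline log-intensity
    cols, blocks = [], []
    for ct in cells:
        shift = design.effect_size * truth[ct].to_numpy()[:, None]
        noise = rng.normal(0.0, design.noise_sd, size=(len(genes), n_rep))
        blocks.append(np.exp(base[:, None] + shift + noise))
        cols.extend(f"{ct}_{r + 1}" for r in range(n_rep))
    values = pd.DataFrame(np.hstack(blocks), index=genes, columns=cols)
    labels = pd.Series(
        np.repeat(cells, n_rep), index=cols, name="cell_type"
    )
    return ExpressionDataset(values=values, cell_type_of=labels)


def generate_lr_table(design: SyntheticDesign) -> LRInteractionTable:
    """Interaction table wired to the planted truth (seeded confidences)."""
    rng = np.random.default_rng(design.seed + 1)
    _, rows = design._wiring()
    df = pd.DataFrame(rows)
    df["confidence"] = np.round(rng.uniform(0.5, 1.0, size=len(df)), 3)
    return LRInteractionTable(df[["ligand", "receptor", "confidence", "complex_group"]])


def generate_ligand_annotations(
    design: SyntheticDesign, n_processes: int = 8, ligands_per_process: int = 10
) -> list[LigandSetAnnotation]:
    """Module-biased ligand sets standing in for curated biological processes."""
    rng = np.random.default_rng(design.seed + 2)
    module_of = design.ligand_module()
    by_mod: dict[str, list[str]] = {m: [] for m in design.module_names}
    for lig, mod in module_of.items():
        by_mod[mod].append(lig)
    annotations = []
    for i in range(n_processes):
        home = design.module_names[i % len(design.module_names)]
        n_home = max(1, round(0.6 * ligands_per_process))
        members = set(
            rng.choice(by_mod[home], size=min(n_home, len(by_mod[home])), replace=False)
        )
        rest = ligands_per_process - len(members)
        if rest > 0:
            pool = [l for l in design.ligand_names if l not in members]
            members |= set(rng.choice(pool, size=min(rest, len(pool)), replace=False))
        annotations.append(LigandSetAnnotation(f"process_{i + 1:02d}", members))
    return annotations


def generate_invitro_counts(
    true_categories: dict[str, str],
    n_experiments: int = 3,
    replicates: int = 3,
    experiment_sd: float = 0.3,
    residual_sd: float = 0.3,
    effect_size: float = 0.6,
    doses: tuple[float, ...] = (100.0,),
    seed: int = 0,
    control: str = "BC",
) -> pd.DataFrame:
    """Per-well culture counts under a basal control and per-ligand conditions.

    Counts of the three output populations are rounded log-normal draws
    sharing a per-experiment random intercept (variance ``experiment_sd**2``
    on the log scale), so the downstream random-intercept mixed model is the
    generating model.  A ligand's functional category shifts the population
    log-means up/down according to its canonical arrow pattern.
    """
    if n_experiments < 2 or replicates < 2:
        raise ValueError("need at least 2 experiments and 2 replicate wells")
    if experiment_sd < 0 or residual_sd <= 0:
        raise ValueError("experiment_sd must be >= 0 and residual_sd > 0")
    for lig, cat in true_categories.items():
        if cat not in CATEGORY_EFFECT_DIRECTIONS:
            raise ValueError(f"unknown functional category '{cat}' for ligand {lig}")

    rng = np.random.default_rng(seed)
    # subtract the log-normal mean bias so arithmetic count means match the
    # baseline reference culture
    bias = (experiment_sd**2 + residual_sd**2) / 2.0
    base_log = {
        pop: math.log(BASELINE_TOTAL_CELLS * frac) - bias
        for pop, frac in BASELINE_FRACTIONS.items()
    }
    pops = list(BASELINE_FRACTIONS)

    rows = []
    for e in range(1, n_experiments + 1):
        b_e = rng.normal(0.0, experiment_sd) if experiment_sd > 0 else 0.0
        conditions: list[tuple[str, float, tuple[int, int, int]]] = [
            (control, 0.0, (0, 0, 0))
        ]
        for lig, cat in true_categories.items():
            for dose in doses:
                conditions.append((lig, float(dose), CATEGORY_EFFECT_DIRECTIONS[cat]))
        for cond, dose, directions in conditions:
            for _ in range(replicates):
                counts = {}
                for pop, direction in zip(pops, directions):
                    mu = base_log[pop] + b_e + direction * effect_size
                    counts[pop] = int(max(0, round(np.exp(mu + rng.normal(0.0, residual_sd)))))
                rows.append(
                    {
                        "experiment": f"exp{e}",
                        "condition": cond,
                        "dose": dose,
                        "n_hsc_enriched": counts["hsc_enriched"],
                        "n_progenitor": counts["progenitor"],
                        "n_mature": counts["mature"],
                    }
                )
    df = pd.DataFrame(rows)
    df["n_total"] = df[list(COUNT_COLUMNS)].sum(axis=1)
    return df


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index=False)


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"experiment", "condition", "dose", *COUNT_COLUMNS} - set(df.columns)
    if missing:
        raise ValueError(f"culture count table {path} is missing columns: {sorted(missing)}")
    if "n_total" not in df.columns:
        df["n_total"] = df[list(COUNT_COLUMNS)].sum(axis=1)
    return df
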