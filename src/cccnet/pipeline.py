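"""Staged pipeline: synthetic inputs -> network -> structure -> simulations -> effects.

Stages follow the study workflow: (1a) inputs, (1b) differential
over-expression, (1c) network construction; (2a) structure analysis,
(2b) frequency-weighted competition and compartment simulation; (3a) ligand
effect classification, (3b) feedback networks.  Every stage writes TSV
outputs into the run directory and records parameters, input hashes and
seeds in a provenance manifest, so identical configurations reproduce
identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import competition, compartments, diffexpr, effects, network, structure, synthetic
from .expression import read_expression, write_expression
from .lr import read_ligand_annotations, read_lr_table, write_ligand_annotations, write_lr_table

logger = logging.getLogger(__name__)

STAGES = ("simulate", "diffexpr", "build_net", "structure", "pac", "compartments", "effects", "feedback")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    out_dir: str = "runs/demo"
    seed: int = 0
    # synthetic design
    n_replicates_per_type: int = 5
    n_ligand_genes: int = 60
    n_receptor_genes: int = 80
    binding_promiscuity: float = 0.8
    effect_size: float = 2.0
    noise_sd: float = 0.5
    # analysis parameters
    fdr: float = diffexpr.DEFAULT_FDR
    min_wins: int = diffexpr.DEFAULT_MIN_WINS
    heteromeric_mode: bool = False
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6)
    cocluster_k: int = 4
    alpha_level: str = "intermediate"
    n_sims: int = 500
    reach_probs: dict = field(default_factory=lambda: dict(compartments.DEFAULT_REACH_PROBS))
    # optional external inputs (paths); synthetic data is generated when absent
    expression_path: str | None = None
    lr_table_path: str | None = None
    counts_path: str | None = None
    annotations_path: str | None = None
    scenario_paths: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**raw)
        for name in ("expression_path", "lr_table_path", "counts_path", "annotations_path"):
            p = getattr(cfg, name)
            if p is not None and not Path(p).exists():
                raise ValueError(f"config field '{name}' points to a missing file: {p}")
        for label, p in cfg.scenario_paths.items():
            if not Path(p).exists():
                raise ValueError(f"scenario '{label}' points to a missing file: {p}")
        return cfg

    def design(self) -> synthetic.SyntheticDesign:
        return synthetic.SyntheticDesign(
            n_replicates_per_type=self.n_replicates_per_type,
            n_ligand_genes=self.n_ligand_genes,
            n_receptor_genes=self.n_receptor_genes,
            binding_promiscuity=self.binding_promiscuity,
            effect_size=self.effect_size,
            noise_sd=self.noise_sd,
            seed=self.seed,
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class PipelineRun:
    """Holds the run directory and the in-memory artifacts between stages."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(config).items()
            },
            "stages": {},
            "inputs": {},
        }

    def _record(self, stage: str, outputs: list[Path]) -> None:
        self.manifest["stages"][stage] = {
            "outputs": {p.name: _sha256(p) for p in outputs}
        }
        self.write_manifest()

    def write_manifest(self) -> None:
        (self.out / "manifest.json").write_text(json.dumps(self.manifest, indent=2, sort_keys=True))

    # -- stage 1a: inputs ------------------------------------------------
    def stage_simulate(self) -> None:
        cfg = self.config
        design = cfg.design()
        if cfg.expression_path:
            self.data = read_expression(cfg.expression_path)
            self.manifest["inputs"]["expression"] = _sha256(Path(cfg.expression_path))
        else:
            self.data = synthetic.generate_expression(design)
        if cfg.lr_table_path:
            self.lr = read_lr_table(cfg.lr_table_path)
            self.manifest["inputs"]["lr_table"] = _sha256(Path(cfg.lr_table_path))
        else:
            self.lr = synthetic.generate_lr_table(design)
        if cfg.annotations_path:
            self.annotations = read_ligand_annotations(cfg.annotations_path)
        else:
            self.annotations = synthetic.generate_ligand_annotations(design)
        if cfg.counts_path:
            self.counts = synthetic.read_counts(cfg.counts_path)
        else:
            module_of = design.ligand_module()
            cats = list(effects.CATEGORY_EFFECT_DIRECTIONS)
            true_cats = {
                lig: cats[i % len(cats)]
                for i, lig in enumerate(sorted(module_of))
                if i < 12  # a dozen tested ligands in the demo assay
            }
            self.counts = synthetic.generate_invitro_counts(true_cats, seed=cfg.seed + 3)
        self.design = design

        paths = [
            self.out / "expression.tsv",
            self.out / "lr_table.tsv",
            self.out / "annotations.tsv",
            self.out / "culture_counts.tsv",
        ]
        write_expression(self.data, paths[0])
        write_lr_table(self.lr, paths[1])
        write_ligand_annotations(self.annotations, paths[2])
        synthetic.write_counts(self.counts, paths[3])
        self._record("simulate", paths)

    # -- stage 1b: differential over-expression --------------------------
    def stage_diffexpr(self) -> None:
        cfg = self.config
        ligand_genes = self.lr.ligands & set(self.data.genes)
        receptor_genes = self.lr.receptors & set(self.data.genes)
        self.calls = diffexpr.call_overexpressed(
            self.data, ligand_genes, receptor_genes, cfg.fdr, cfg.min_wins
        )
        path = self.out / "overexpression_calls.tsv"
        diffexpr.write_calls(self.calls, path)
        self._record("diffexpr", [path])

    # -- stage 1c: network construction ----------------------------------
    def stage_build_net(self) -> None:
        self.net = network.build_network(
            self.calls, self.lr, heteromeric_mode=self.config.heteromeric_mode
        )
        paths = [
            self.out / "ccc_network.graphml",
            self.out / "ccc_edges.tsv",
            self.out / "production_matrix.tsv",
            self.out / "binding_matrix.tsv",
            self.out / "cell_degree_ranks.tsv",
        ]
        network.write_graphml(self.net, paths[0])
        network.write_edge_list(self.net, paths[1])
        network.write_matrices(self.net, paths[2], paths[3])
        network.rank_cells_by_degree(self.net).to_csv(paths[4], sep="\t")
        self._record("build_net", paths)

    # -- stage 2a: structure ---------------------------------------------
    def stage_structure(self) -> None:
        cfg = self.config
        A = network.production_network(self.net)
        A_cells = A.loc[[c for c in A.index if c != network.OTHERS]]
        self.partition = structure.cluster_production(A_cells, k_range=cfg.k_range)
        B = network.binding_network(self.net)
        B_cells = B[[c for c in B.columns if c != network.OTHERS]]
        B_cells = B_cells.loc[B_cells.sum(axis=1) > 0]
        self.cocluster = structure.cocluster_binding(B_cells, k=cfg.cocluster_k, seed=cfg.seed)
        prod_sets = structure.module_ligand_sets(A_cells, self.partition.assignment)
        bind_sets = structure.module_ligand_sets(B_cells.T, self.cocluster.col_assignment)
        comparison = {}
        for variant in ("welch", "pooled"):
            try:
                cmp = structure.compare_module_overlap(prod_sets, bind_sets, variant)
                comparison[variant] = dataclasses.asdict(cmp)
            except ValueError as exc:  # degenerate single-module side
                comparison[variant] = {"error": str(exc)}
        paths = [
            self.out / "production_modules.tsv",
            self.out / "silhouette_by_k.tsv",
            self.out / "binding_coclusters.tsv",
            self.out / "overlap_comparison.json",
        ]
        structure.write_partition(self.partition, paths[0])
        self.partition.mean_silhouette_per_k.to_csv(paths[1], sep="\t", index=False)
        pd.concat(
            [self.cocluster.row_assignment, self.cocluster.col_assignment]
        ).rename_axis("node").to_frame().to_csv(paths[2], sep="\t")
        paths[3].write_text(json.dumps(comparison, indent=2))
        self._record("structure", paths)

    # -- stage 2b(i): frequency-weighted competition ----------------------
    def stage_pac(self) -> None:
        scenarios = (
            {
                name: competition.load_frequency_vector(p)
                for name, p in self.config.scenario_paths.items()
            }
            if self.config.scenario_paths
            else competition.example_scenarios()
        )
        B = network.binding_network(self.net)
        B = B[[c for c in B.columns if c != network.OTHERS]]
        B = B.loc[B.sum(axis=1) > 0]
        matrices, summary = competition.pac_scenarios(B, scenarios)
        paths = []
        for name, P in matrices.items():
            p = self.out / f"pac_{name}.tsv"
            competition.write_pac(P, p)
            paths.append(p)
        spath = self.out / "pac_dominance.tsv"
        summary.to_csv(spath, sep="\t", index=False)
        paths.append(spath)
        self._record("pac", paths)

    # -- stage 2b(ii): compartment simulation -----------------------------
    def stage_compartments(self) -> None:
        cfg = self.config
        sets = compartments.compartment_ligand_sets(self.calls.ligands)
        self.model = compartments.CompartmentModel(
            ligand_sets=sets, reach_prob=dict(cfg.reach_probs),
            n_sims=cfg.n_sims, seed=cfg.seed,
        )
        profile = compartments.enrichment_profile(self.model, self.annotations)
        path = self.out / "compartment_enrichment.tsv"
        profile.to_csv(path, sep="\t", index=False)
        self._record("compartments", [path])

    # -- stage 3a: ligand effects -----------------------------------------
    def stage_effects(self) -> None:
        self.records = effects.classify_records(
            self.counts, confidence_level=self.config.alpha_level
        )
        df = pd.DataFrame(
            [
                {
                    "ligand": r.ligand,
                    "dose": r.dose,
                    "p_hsc_enriched": r.signed_p[0],
                    "p_progenitor": r.signed_p[1],
                    "p_mature": r.signed_p[2],
                    "category": r.category,
                    "confidence_level": r.confidence_level,
                }
                for r in self.records
            ]
        )
        path = self.out / "ligand_effects.tsv"
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
        self._record("effects", [path])

    # -- stage 3b: feedback networks --------------------------------------
    def stage_feedback(self) -> None:
        # tested ligands are named by gene in the synthetic assay; receptor
        # levels of the target cell come from the expression matrix
        hsce_receptors = self.calls.receptors.get("HSCe", set())
        levels = (
            self.data.values.loc[sorted(hsce_receptors & set(self.data.genes))]
            .T.groupby(self.data.cell_type_of)
            .mean()
            .T.get("HSCe", pd.Series(dtype=float))
        )
        freqs = competition.example_scenarios()["mnc_like"]
        comp_w = {
            c: (0.1 if compartments.COMPARTMENT_OF_CELL.get(c) == "MCP" else 1.0)
            for c in self.net.cell_nodes
        }
        paths = []
        for mode in effects.FEEDBACK_MODES:
            edges = effects.build_feedback_network(
                self.net, self.records, self.lr, levels, mode=mode,
                freqs=freqs, compartment_weights=comp_w,
            )
            p = self.out / f"feedback_{mode}.tsv"
            edges.to_csv(p, sep="\t", index=False, float_format="%.6g")
            paths.append(p)
        self._record("feedback", paths)


STAGE_METHODS = {
    "simulate": PipelineRun.stage_simulate,
    "diffexpr": PipelineRun.stage_diffexpr,
    "build_net": PipelineRun.stage_build_net,
    "structure": PipelineRun.stage_structure,
    "pac": PipelineRun.stage_pac,
    "compartments": PipelineRun.stage_compartments,
    "effects": PipelineRun.stage_effects,
    "feedback": PipelineRun.stage_feedback,
}


def run_pipeline(config: PipelineConfig, stages: tuple[str, ...] = STAGES) -> PipelineRun:
    """Run the requested stages in order; abort with a stage-named error on failure."""
    run = PipelineRun(config)
    for stage in STAGES:
        if stage not in stages:
            continue
        logger.info("running stage %s", stage)
        try:
            STAGE_METHODS[stage](run)
        except Exception as exc:
            run.manifest["stages"][stage] = {"error": str(exc)}
            run.write_manifest()
            raise StageError(stage, exc) from exc
    return run
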