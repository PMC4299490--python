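import numpy as np
import pandas as pd
import pytest

from cccnet.diffexpr import call_overexpressed
from cccnet.lr import read_lr_table, write_lr_table
from cccnet.synthetic import (
    BASELINE_FRACTIONS,
    BASELINE_TOTAL_CELLS,
    DEFAULT_MODULES,
    SyntheticDesign,
    generate_expression,
    generate_invitro_counts,
    generate_ligand_annotations,
    generate_lr_table,
)


def test_design_validation():
    with pytest.raises(ValueError, match="at least 2"):
        SyntheticDesign(n_replicates_per_type=1)
    with pytest.raises(ValueError, match="noise_sd"):
        SyntheticDesign(noise_sd=0.0)
    with pytest.raises(ValueError, match="disjoint"):
        SyntheticDesign(
            planted_production_modules={"a": ("HSCe", "CMP"), "b": ("CMP",)},
            n_cell_types=3,
        )


def test_planted_ligand_subsets_are_disjoint_and_cover_all_ligands(small_design):
    module_of = small_design.ligand_module()
    assert set(module_of) == set(small_design.ligand_names)
    lr = generate_lr_table(small_design)
    # every generated ligand appears in at least one interaction pair
    assert set(small_design.ligand_names) <= lr.ligands


def test_expression_shape_and_determinism(small_design):
    data = generate_expression(small_design)
    n_genes = (
        small_design.n_ligand_genes
        + small_design.n_orphan_ligands
        + small_design.n_receptor_genes
        + len(small_design.housekeeping_names())
    )
    assert data.values.shape == (n_genes, 12 * small_design.n_replicates_per_type)
    again = generate_expression(small_design)
    assert np.array_equal(data.values.to_numpy(), again.values.to_numpy())
    assert (data.values.to_numpy() > 0).all()


def test_planted_genes_shift_only_their_cell_types(small_design):
    data = generate_expression(small_design)
    truth = small_design.expression_truth()
    lig = small_design.ligand_names[-1]  # a planted ligand
    planted_types = set(truth.columns[truth.loc[lig]])
    assert planted_types  # sanity: this ligand is planted somewhere
    logv = np.log(data.values.loc[lig])
    means = logv.groupby(data.cell_type_of).mean()
    gap = means[sorted(planted_types)].min() - means.drop(sorted(planted_types)).max()
    # 4-sigma planted shift with 4 replicates: clear separation of group means
    assert gap > small_design.effect_size / 2


def test_null_design_yields_fdr_controlled_false_positives():
    design = SyntheticDesign(
        effect_size=0.0, n_ligand_genes=24, n_receptor_genes=40,
        n_replicates_per_type=4, seed=5,
    )
    data = generate_expression(design)
    calls = call_overexpressed(
        data,
        set(design.ligand_names) | set(design.orphan_ligand_names),
        set(design.receptor_names),
        fdr=0.10,
        min_wins=6,
    )
    n_universe = len(design.ligand_names) + design.n_orphan_ligands + design.n_receptor_genes
    n_calls = sum(len(s) for s in calls.genes.values())
    # with no signal the 6-of-11 rule leaves essentially nothing
    assert n_calls / (12 * n_universe) <= 0.10


def test_full_promiscuity_gives_all_positive_binding_rows():
    design = SyntheticDesign(binding_promiscuity=1.0, n_ligand_genes=16,
                             n_receptor_genes=40, seed=1)
    lr = generate_lr_table(design)
    targets = design.receptor_target_modules()
    modules = set(DEFAULT_MODULES)
    for lig in design.ligand_names:
        covered = {targets[r] for r in lr.cognate_receptors(lig)}
        assert covered >= modules  # receptors span every module -> every cell binds


def test_zero_promiscuity_gives_block_diagonal_binding():
    design = SyntheticDesign(binding_promiscuity=0.0, n_ligand_genes=16,
                             n_receptor_genes=40, n_unbound_ligands=0, seed=1)
    lr = generate_lr_table(design)
    targets = design.receptor_target_modules()
    module_of = design.ligand_module()
    for lig in design.ligand_names:
        covered = {targets[r] for r in lr.cognate_receptors(lig)}
        assert covered == {module_of[lig]}


def test_lr_table_round_trips(tmp_path, small_design):
    lr = generate_lr_table(small_design)
    path = tmp_path / "lr.tsv"
    write_lr_table(lr, path)
    assert read_lr_table(path) == lr


def test_annotations_are_nonempty_and_deterministic(small_design):
    a1 = generate_ligand_annotations(small_design)
    a2 = generate_ligand_annotations(small_design)
    assert [x.member_ligands for x in a1] == [y.member_ligands for y in a2]
    assert all(x.member_ligands for x in a1)


class TestInvitroCounts:
    def test_baseline_emulates_reference_culture(self):
        counts = generate_invitro_counts(
            {"L1": "neutral"}, n_experiments=40, replicates=3,
            experiment_sd=0.2, residual_sd=0.2, seed=0,
        )
        bc = counts[counts["condition"] == "BC"]
        assert bc["n_total"].mean() == pytest.approx(BASELINE_TOTAL_CELLS, rel=0.10)
        fracs = (
            bc[["n_hsc_enriched", "n_progenitor", "n_mature"]].sum()
            / bc["n_total"].sum()
        )
        for pop, expected in zip(fracs.index, BASELINE_FRACTIONS.values()):
            assert fracs[pop] == pytest.approx(expected, abs=0.03)

    def test_population_counts_sum_to_total(self):
        counts = generate_invitro_counts({"L1": "proliferation_induction"}, seed=2)
        total = counts[["n_hsc_enriched", "n_progenitor", "n_mature"]].sum(axis=1)
        assert (total == counts["n_total"]).all()

    def test_every_experiment_contains_the_basal_control(self):
        counts = generate_invitro_counts({"L1": "neutral"}, n_experiments=4, seed=3)
        assert all(
            "BC" in sub["condition"].values
            for _, sub in counts.groupby("experiment")
        )

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError, match="unknown functional category"):
            generate_invitro_counts({"L1": "mystery"})

    def test_zero_experiment_sd_gives_negligible_between_experiment_variance(self):
        counts = generate_invitro_counts(
            {"L1": "neutral"}, n_experiments=10, replicates=5,
            experiment_sd=0.0, residual_sd=0.2, seed=4,
        )
        bc = counts[counts["condition"] == "BC"]
        y = np.log(bc["n_hsc_enriched"] + 1)
        between = y.groupby(bc["experiment"]).mean().var()
        within = y.var()
        # experiment means only vary through residual noise (var/n_rep)
        assert between < within / 2
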