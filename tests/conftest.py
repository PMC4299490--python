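import pandas as pd
import pytest

from cccnet.diffexpr import OverexpressionCalls
from cccnet.lr import LRInteractionTable
from cccnet.synthetic import SyntheticDesign


@pytest.fixture
def small_design():
    """12 cell types, reduced gene counts: fast but structurally complete."""
    return SyntheticDesign(
        n_ligand_genes=24,
        n_receptor_genes=40,
        n_replicates_per_type=4,
        binding_promiscuity=0.5,
        seed=11,
    )


@pytest.fixture
def block_design():
    """Low promiscuity: the binding matrix has 4 planted blocks."""
    return SyntheticDesign(binding_promiscuity=0.05, seed=3)


@pytest.fixture
def two_cell_calls():
    """Minimal calls: cell A produces LIGX, cell B expresses two receptors for it."""
    return OverexpressionCalls(
        ligands={"A": {"LIGX"}, "B": set()},
        receptors={"A": set(), "B": {"R1", "R2"}},
        fdr_threshold=0.1,
        min_wins=1,
    )


@pytest.fixture
def two_receptor_lr():
    return LRInteractionTable(
        pd.DataFrame(
            {"ligand": ["LIGX", "LIGX"], "receptor": ["R1", "R2"]}
        )
    )
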