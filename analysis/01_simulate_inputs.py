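"""Generate the synthetic study inputs: expression, interactions, counts, annotations.

The generator emulates the hematopoietic study conditions: 12 cell types in
4 production modules, log-normal expression with planted over-expression of
ligand/receptor genes, a wired ligand-receptor table with promiscuous and
block ligands, culture counts with a per-experiment random effect, and
module-biased ligand-set annotations.
"""

from _common import RESULTS, get_run

run = get_run(("simulate",))
d = run.design
print(f"cell types: {len(d.cell_types)} in {len(d.planted_production_modules)} planted modules")
print(f"expression matrix: {run.data.values.shape[0]} genes x {run.data.values.shape[1]} samples")
print(f"interaction table: {len(run.lr)} pairs, {len(run.lr.ligands)} ligands, "
      f"{len(run.lr.receptors)} receptors")
print(f"culture counts: {len(run.counts)} wells, "
      f"{run.counts['condition'].nunique() - 1} ligand conditions")
print(f"annotations: {len(run.annotations)} processes")
print(f"outputs -> {RESULTS}")
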