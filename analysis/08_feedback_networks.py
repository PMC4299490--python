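"""Weighted feedback networks: which cells send which signals to the stem cells.

Three weighting modes: receptor expression levels of the target cell,
additionally cell frequency, and additionally compartment reach (peripheral
cells attenuated to 10%).
"""

import pandas as pd

from _common import RESULTS, get_run

run = get_run(("simulate", "diffexpr", "build_net", "effects", "feedback"))
for mode in ("receptor", "frequency", "compartment"):
    edges = pd.read_csv(RESULTS / f"feedback_{mode}.tsv", sep="\t")
    print(f"\nmode={mode}: {len(edges)} cell->category edges")
    if len(edges):
        top = edges.sort_values("weight", ascending=False).head(5)
        print(top[["cell", "category", "weight"]].to_string(index=False))
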