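"""Frequency-weighted potential of apparent competition between cell types.

Contrasts two compositions: an MNC-like mixture where neutrophils dominate
ligand uptake, and a progenitor-enriched mixture where stem cells regain
access to ligand resources.
"""

import pandas as pd

from _common import RESULTS, get_run

run = get_run(("simulate", "diffexpr", "build_net", "pac"))
dom = pd.read_csv(RESULTS / "pac_dominance.tsv", sep="\t")
for scen, sub in dom.groupby("scenario"):
    top = sub["top_competitor"].mode().iat[0]
    hsce = sub[sub["cell"] == "HSCe"]
    print(f"scenario {scen}: most frequent top competitor = {top}")
    if len(hsce):
        print(f"  HSCe self-competition share: {hsce['self_share'].iat[0]:.3f}, "
              f"dominated by {hsce['top_competitor'].iat[0]}")
print("\nrows of each PAC matrix sum to 1; see results/pipeline/pac_*.tsv")
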