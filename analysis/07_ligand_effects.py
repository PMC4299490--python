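"""Classify ligand effects on stem-cell fate from in vitro culture counts.

Mixed-model signed one-tail p-values per output population, decision-table
classification at the intermediate confidence level (alpha = 0.02), and the
binomial prediction-capacity test for 27 effective of 33 tested ligands.
"""

from _common import get_run
from cccnet.effects import prediction_capacity_test

run = get_run(("simulate", "effects"))
for r in run.records:
    ps = ", ".join(f"{p:+.4f}" for p in r.signed_p)
    print(f"{r.ligand:>8} @ {r.dose:g}: ({ps}) -> {r.category}")

cap = prediction_capacity_test(33, 27, 0.5)
print(f"\nprediction capacity, X ~ B(33, 0.5): expected {cap.expectation:.1f} (~16), "
      f"P(X = 27) = {cap.point:.4f}, P(X >= 27) = {cap.tail:.4f}")
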