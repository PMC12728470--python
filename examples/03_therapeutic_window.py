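"""Dose-response curves and the therapeutic window of a synthetic drug.

Simulates a 6-dose course in which the tumor compartment responds from
dose 2 and the neuronal compartment only from dose 5, builds the
two-compartment dose-response curve, and derives the therapeutic window:
the dose range with significant anti-tumor effect but no significant
neuronal toxicity. The printed window should recover [2, 4].
"""

import pandas as pd

from tboscreen import dose, quantify, screen
from tboscreen.synthetic import (
    SMALL_PHANTOM, dose_truth_table, generate_screen_dataset, screen_layout,
)

truth = dose_truth_table(
    "etoposide-like",
    doses=[1, 2, 3, 4, 5, 6],
    k_T=[0.0, 0.4, 0.6, 0.8, 0.9, 0.95],
    k_N=[0.0, 0.0, 0.0, 0.0, 0.4, 0.6],
    n_organoids=8,
)
spec = SMALL_PHANTOM.with_treatment(0, 0, seed=23)

measurements = quantify.measure_stacks(
    ((well, stack) for well, stack, _ in generate_screen_dataset(truth, spec)),
    background="compartment",
)
groups = screen.groups_from_measurements(
    pd.DataFrame([m.as_row() for m in measurements]), screen_layout(truth)
)
control = next(g for g in groups if g.role == "control")
treated = [g for g in groups if g.role != "control"]

curve = dose.build_curve(treated, control)
print(curve.table.round(4).to_string(index=False))

window = dose.therapeutic_window(curve, alpha=0.01)
print(f"\nfirst significant tumor dose:    {dose.first_significant_dose(curve, 'tumor', 0.01)}")
print(f"first significant neuronal dose: {dose.first_significant_dose(curve, 'neuronal', 0.01)}")
print(f"therapeutic window: [{window.lower:g}, {window.upper:g}] (exists={window.exists})")
# 'mean' is normalized to the dose-0 DMSO control (1.0 = no effect); the
# window spans doses that kill tumor without significant neuronal loss.
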