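"""One-way sensitivity analysis.

Re-runs the comparison under structural variations — drug cost only
(no visit costs), a 5-year horizon, a cohort starting at age 60 — all on
the same random numbers as the base case, and prints the scenario table
with the percent change in ICER.
"""

import pandas as pd

from amdcea import ScenarioSpec, load_parameters, run_scenarios

params = load_parameters()
specs = [
    ScenarioSpec("drug cost only", {"drug_only": True}),
    ScenarioSpec("5-year horizon", {"horizon_months": 60}),
    ScenarioSpec("starting age 60", {"fixed_age": 60.0}),
]

table = run_scenarios(specs, params, n_patients=5000, seed=1)
pd.set_option("display.width", 160)
print(table.round(3).to_string(index=False))
print("\nShared seeds mean cost-only scenarios leave the QALY columns exactly")
print("unchanged, and a younger cohort (less background mortality) gains more")
print("QALYs in both arms. How the ICER moves with the horizon depends on the")
print("comparator's decline curve, which here is a documented stand-in.")
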