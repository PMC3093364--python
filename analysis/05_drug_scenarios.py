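"""Drug scenarios: colchicine arrest, MG132, non-degradable Cyclin A.

Phenomenological checks of the loading machinery under perturbation:

* colchicine — cells arrest at metaphase (spindle checkpoint) but loading
  is spindle-independent, so arrested cells load like unarrested metaphases
  and the mitotic fraction grows roughly linearly with arrest time;
* MG132 — proteasome inhibition suppresses metaphase loading efficiency to
  ~9% of control;
* ND-CYCA — non-degradable Cyclin A gives a milder, partial suppression
  (~79% of control) in the transfected subpopulation.

Writes results/drug_scenarios.csv.
"""

import pandas as pd

from centrodyn.cellcycle import (
    CellCycleParams,
    LabelingProtocol,
    LoadingRule,
    simulate_population,
    stage_positivity_table,
)

cc = CellCycleParams()
protocol = LabelingProtocol(block_efficiency=0.97)
rows = []
for scenario, chase in (("none", 1.0), ("colchicine_arrest", 4.0),
                        ("mg132", 4.0), ("nd_cyca", 4.0)):
    rule = LoadingRule(loading_stages={"metaphase": 1.0}, scenario=scenario)
    records = simulate_population(20_000, cc, protocol, rule, chase, seed=55)
    table = stage_positivity_table(records)
    rows.append(
        {
            "scenario": scenario,
            "chase_h": chase,
            "mitotic_fraction": round(table.loc["mitotic", "n"] / len(records), 3),
            "metaphase_percent_positive": round(
                table.loc["metaphase", "percent_positive"], 1
            ),
        }
    )
    print(rows[-1])

pd.DataFrame(rows).to_csv("results/drug_scenarios.csv", index=False)
print(
    "\nColchicine inflates the mitotic fraction without changing the "
    "metaphase loading rate; MG132 nearly abolishes it; ND-CYCA reduces it "
    "partially."
)
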