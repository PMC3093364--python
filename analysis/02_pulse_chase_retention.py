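"""Pulse-chase turnover of the three centromeric proteins.

Runs the full synthetic pipeline (images -> spot quantification -> IQR
filter -> day-2/day-1 ratio) for CID, CENP-C and CAL1 at 200 cells per day.
CID and CENP-C dilute two-fold per division (semi-conservative segregation
of centromeric chromatin); CAL1 retains only about a third of its pool,
i.e. two thirds of pre-existing CAL1 is exchanged every division.

Writes per-protein per-cell tables and results/retention_summary.csv.
"""

import pandas as pd

from centrodyn.config import load_config
from centrodyn.experiments import run_pulse_chase_experiment

rows = []
for i, protein in enumerate(("CID", "CENP-C", "CAL1")):
    cfg = load_config(
        {
            "seed": 100 + i,
            "protein": protein,
            "n_day1": 200,
            "n_day2": 200,
            "outdir": f"results/pulse_chase_{protein.replace('-', '').lower()}",
        }
    )
    report = run_pulse_chase_experiment(cfg)
    rows.append(
        {
            "protein": protein,
            "retention_percent": round(report["retention_percent"], 1),
            "se_percent": round(report["se_percent"], 2),
            "n_day1": report["n_filtered"]["day1"],
            "n_day2": report["n_filtered"]["day2"],
        }
    )
    print(
        f"{protein}: {report['retention_percent']:.1f}% retained "
        f"(+/- {report['se_percent']:.1f}), "
        f"n={report['n_filtered']['day1']}/{report['n_filtered']['day2']} after IQR filter"
    )

summary = pd.DataFrame(rows)
summary.to_csv("results/retention_summary.csv", index=False)
print("\nCID and CENP-C sit near the 50% semi-conservative prediction;")
print("CAL1 sits near 34%, the signature of two-thirds per-division exchange.")
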