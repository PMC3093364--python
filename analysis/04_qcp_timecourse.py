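"""Quench-chase-pulse time-course: when is new protein loaded?

Simulates an asynchronous population (10,000 cells, 24 h cycle, 97% block
efficiency) at chase times 1, 2, 10 and 24 h for each protein preset:

* CID  — single pulse at metaphase,
* CAL1 — single pulse at prophase,
* CENP-C — continuous low-rate loading through the whole cycle.

Writes the per-stage positivity tables and Fisher exact tests of each
mitotic stage against interphase under results/qcp_<protein>/, and prints
the 1 h stage profile, which separates the three loading programs: under
metaphase loading the earliest positive stage is metaphase; under prophase
loading it is prophase; continuous loading needs a long chase before any
stage lights up strongly.  It also prints the interphase positivity floor
expected from 3% block escape alone.
"""

from centrodyn.config import load_config
from centrodyn.experiments import run_qcp_experiment

for i, protein in enumerate(("CID", "CAL1", "CENP-C")):
    cfg = load_config(
        {
            "seed": 200 + i,
            "protein": protein,
            "n_population": 10_000,
            "outdir": f"results/qcp_{protein.replace('-', '').lower()}",
        }
    )
    report = run_qcp_experiment(cfg)
    table = {r["stage"]: r for r in report["timepoints"]["1h"]["stage_table"]}
    print(f"\n{protein} at 1 h chase:")
    for stage in ("interphase", "prophase", "metaphase", "anaphase_telophase",
                  "cytokinesis"):
        row = table[stage]
        if row["n"]:
            print(f"  {stage:>20s}: {row['percent_positive']:5.1f}% of {row['n']}")
    p = report["timepoints"]["1h"]["fisher_vs_interphase"].get("mitotic")
    print(f"  Fisher mitotic vs interphase: p = {p:.2e}")
print(
    "\nWith a 97% block, ~3% of cells score positive in every stage from "
    "block escape alone — the floor beneath any interphase signal."
)
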