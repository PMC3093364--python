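# centrodyn

Quantitative pipeline for centromeric chromatin assembly dynamics in
Drosophila S2 cells — for chromatin and cell-cycle researchers who want the
analysis behind SNAP-tag pulse-chase and quench-chase-pulse imaging as
tested, reproducible code.

Centromere identity is propagated epigenetically by the histone H3 variant
CID (CENP-A), together with CENP-C and the Diptera-specific chaperone
candidate CAL1. DNA replication dilutes centromeric nucleosomes two-fold;
the questions are how the pre-existing proteins are partitioned to daughter
cells and when the gap is refilled. The package implements the three
quantitative pillars of that analysis:

1. **Inheritance.** A centromere complement of *n* labeled units divides
   semi-conservatively (each unit to a daughter with probability 1/2, with
   optional per-unit exchange *e*) or with direct net retention *r*.
   Expected retention per division is 0.5(1−e), or *r*. Pulse-chase
   retention is estimated as
   100 · mean(C day 2) / mean(C day 1) after per-day 1.5·IQR outlier
   removal, where C = T − A·m is the background-corrected centromeric spot
   intensity (T summed spot signal, A spot area, m median non-spot nuclear
   intensity).
2. **Quantification.** Synthetic two-channel microscopy with per-focus
   ground truth (pixel-integrated Gaussian PSF, Poisson + read noise),
   DAPI nucleus segmentation, DoG spot detection with a median + k·MAD
   threshold, and the C and whole-cell W measures.
3. **Loading stage.** An asynchronous cell-cycle population simulator
   (24-h cycle, 30-min mitosis, 97% quench efficiency) that tests where in
   the cycle new protein must be loaded to reproduce observed per-stage
   positivity: a metaphase pulse for CID, a prophase pulse for CAL1,
   continuous loading for CENP-C, plus colchicine/MG132/ND-CYCA scenarios,
   scored with an enumerated two-sided Fisher exact test.

## Worked example

```python
from centrodyn.config import load_config
from centrodyn.experiments import run_pulse_chase_experiment

for i, protein in enumerate(("CID", "CENP-C", "CAL1")):
    cfg = load_config({"seed": 100 + i, "protein": protein,
                       "n_day1": 200, "n_day2": 200})
    rep = run_pulse_chase_experiment(cfg, write=False)
    print(f"{protein}: {rep['retention_percent']:.1f}% "
          f"(+/- {rep['se_percent']:.1f})")
```

prints:

```
CID: 50.6% (+/- 1.2)
CENP-C: 47.0% (+/- 1.1)
CAL1: 32.9% (+/- 0.8)
```

CID and CENP-C sit at the ~50% expected from semi-conservative segregation
of centromeric chromatin; CAL1 sits near 34%, the signature of two thirds
of the pre-existing pool being exchanged every division. Each number is a
full run of the pipeline: 200 synthetic cells per timepoint are rendered,
segmented and spot-quantified, outliers removed per day, and the day-ratio
formed.

The numbered scripts under `analysis/` run the individual studies and
write their tables under `results/`:

```bash
python analysis/01_simulate_images.py      # demo image set + ground truth
python analysis/02_pulse_chase_retention.py
python analysis/03_metaphase_doubling.py   # whole-cell metaphase vs interphase
python analysis/04_qcp_timecourse.py       # per-stage positivity vs chase time
python analysis/05_drug_scenarios.py
```

A `centrodyn` CLI exposes the same steps
(`simulate-images`, `quantify`, `pulse-chase`, `qcp-sim`, `stats`).

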