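"""End-to-end reproducible experiment runs.

Each run takes a :class:`~centrodyn.config.RunConfig`, fans the global seed
out to per-module child seeds, executes the pipeline, writes CSV tables and a
JSON report (with the full parameter echo and seed embedded), and returns the
report as a dict.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from . import __version__
from .cellcycle import (
    simulate_population,
    stage_positivity_table,
)
from .config import RunConfig, child_seeds
from .inheritance import estimate_retention
from .spot_quant import measure_dataset
from .stages import MITOTIC_STAGES
from .stats import ContingencyTable2x2, fisher_exact_2x2
from .synthetic_imaging import (
    make_population_image_set,
    make_pulse_chase_dataset,
    population_if_params,
)

logger = logging.getLogger("centrodyn")

__all__ = [
    "run_pulse_chase_experiment",
    "run_qcp_experiment",
    "run_stage_intensity_experiment",
]


def _report_path(config: RunConfig, name: str) -> Path:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    return outdir / name


def run_pulse_chase_experiment(config: RunConfig, write: bool = True) -> dict:
    """Pulse-chase turnover run: images -> quantification -> retention.

    Generates day-1/day-2 synthetic image sets under the configured protein's
    inheritance model, quantifies both days with the spot pipeline, applies
    per-day IQR filtering, and reports the day-2/day-1 percent retention.
    """
    model = config.retention_model()
    seed_imaging, _ = child_seeds(config.seed, 2)
    logger.info(
        "pulse-chase run: protein=%s model=%s seed=%d", config.protein, model, config.seed
    )
    dataset = make_pulse_chase_dataset(
        config.imaging, model, config.n_day1, config.n_day2, seed=seed_imaging
    )
    frames = {
        "day1": measure_dataset(dataset.day1, config.quant),
        "day2": measure_dataset(dataset.day2, config.quant),
    }
    estimate = estimate_retention(frames["day1"]["C"], frames["day2"]["C"])
    report = {
        "experiment": "pulse_chase",
        "protein": config.protein,
        "retention_percent": estimate.ratio,
        "se_percent": estimate.se,
        "n_filtered": {"day1": estimate.n_day1, "day2": estimate.n_day2},
        "n_quantified": {"day1": len(frames["day1"]), "day2": len(frames["day2"])},
        "iqr_bounds": {
            "day1": list(estimate.bounds_day1),
            "day2": list(estimate.bounds_day2),
        },
        "per_experiment_ratios": list(estimate.per_experiment),
        "seed": config.seed,
        "version": __version__,
        "config": config.echo(),
    }
    if write:
        for day, frame in frames.items():
            frame.to_csv(_report_path(config, f"pulse_chase_{day}.csv"), index=False)
        _report_path(config, "pulse_chase_report.json").write_text(
            json.dumps(report, indent=2)
        )
    return report


def run_qcp_experiment(config: RunConfig, write: bool = True) -> dict:
    """Quench-chase-pulse run: population simulation at each chase time.

    Emits the per-stage positivity table for every configured chase time and
    Fisher exact p-values comparing each mitotic stage against interphase.
    """
    rule = config.loading_rule()
    seeds = child_seeds(config.seed, len(config.protocol.chase_times))
    logger.info(
        "qcp run: protein=%s rule=%s scenario=%s seed=%d",
        config.protein,
        rule.loading_stages,
        rule.scenario,
        config.seed,
    )
    timepoints = {}
    for chase, seed in zip(config.protocol.chase_times, seeds):
        records = simulate_population(
            config.n_population, config.cellcycle, config.protocol, rule, chase, seed
        )
        table = stage_positivity_table(records)
        inter = table.loc["interphase"]
        fisher = {}
        for stage in sorted(MITOTIC_STAGES) + ["mitotic"]:
            row = table.loc[stage]
            if row["n"] == 0:
                continue
            fisher[stage] = fisher_exact_2x2(
                ContingencyTable2x2(
                    int(row["n_positive"]),
                    int(row["n_negative"]),
                    int(inter["n_positive"]),
                    int(inter["n_negative"]),
                )
            )
        timepoints[chase] = {
            "stage_table": table.reset_index().to_dict(orient="records"),
            "fisher_vs_interphase": fisher,
        }
        if write:
            table.to_csv(_report_path(config, f"qcp_stage_table_{chase:g}h.csv"))
    report = {
        "experiment": "quench_chase_pulse",
        "protein": config.protein,
        "scenario": rule.scenario,
        "timepoints": {f"{k:g}h": v for k, v in timepoints.items()},
        "seed": config.seed,
        "version": __version__,
        "config": config.echo(),
    }
    if write:
        _report_path(config, "qcp_report.json").write_text(json.dumps(report, indent=2))
    return report


def run_stage_intensity_experiment(
    config: RunConfig,
    n_interphase: int = 100,
    n_metaphase: int = 30,
    metaphase_fold: float = 2.0,
    write: bool = True,
) -> dict:
    """Whole-cell stage comparison: does metaphase carry double the protein?

    Renders an immunofluorescence-style population (interphase cells across
    G1/S/G2 plus metaphase cells) in which each metaphase cell's true total
    is ``metaphase_fold`` times a draw from the interphase distribution —
    the expectation under loading at metaphase followed by halving at
    division.  Quantifies every cell with the DAPI-mask whole-cell measure
    and reports the ratio of stage means.
    """
    import numpy as np
    import pandas as pd

    from .spot_quant import quantify_image
    from .stats import mann_whitney

    params = population_if_params()
    seed = child_seeds(config.seed, 3)[2]
    n_total = n_interphase + n_metaphase
    mix = {
        "G1": n_interphase / n_total / 3,
        "S": n_interphase / n_total / 3,
        "G2": n_interphase / n_total / 3,
        "metaphase": n_metaphase / n_total,
    }

    def rule(stage, rng):
        base = rng.lognormal(
            np.log(params.total_intensity_median), params.total_intensity_sigma
        )
        return metaphase_fold * base if stage == "metaphase" else base

    cells = make_population_image_set(params, mix, rule, n_total, seed=seed)
    rows = []
    for cell in cells:
        found = quantify_image(
            cell.image, config.quant, cell_id=cell.truth.cell_id, stage=cell.truth.stage
        )
        if found:
            rows.append(
                {
                    "cell_id": cell.truth.cell_id,
                    "stage": cell.truth.stage,
                    "W": found[0].whole_cell_corrected,
                    "true_total": cell.truth.true_total,
                }
            )
    frame = pd.DataFrame(rows)
    inter = frame[frame["stage"].isin(("G1", "S", "G2"))]["W"]
    meta = frame[frame["stage"] == "metaphase"]["W"]
    _, p = mann_whitney(inter, meta)
    report = {
        "experiment": "stage_intensity",
        "metaphase_over_interphase": float(meta.mean() / inter.mean()),
        "n": {"interphase": int(inter.size), "metaphase": int(meta.size)},
        "mann_whitney_p": p,
        "seed": config.seed,
        "version": __version__,
    }
    if write:
        frame.to_csv(_report_path(config, "stage_intensity.csv"), index=False)
        _report_path(config, "stage_intensity_report.json").write_text(
            json.dumps(report, indent=2)
        )
    return report
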