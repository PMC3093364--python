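"""Synthetic two-channel cell images with known ground truth.

Emulates fixed Drosophila S2 cells imaged for centromeric fluorescence: a
DAPI channel containing one round nucleus, and a TMR channel containing a
uniform nucleoplasmic background plus a handful of diffraction-limited
centromeric foci.  S2 cells carry ~13 chromosomes whose centromeres cluster
into 3-6 distinguishable foci in interphase and de-cluster into individually
resolvable spots in mitosis; the generator reproduces those counts and keeps
the per-focus integrated signal as ground truth so every downstream
quantification step can be checked against what was actually drawn.

Point sources are rendered with a pixel-integrated isotropic 2-D Gaussian
PSF (error-function differences per pixel), so the noise-free integrated
excess over background equals the true signal up to PSF truncation at the
frame edge.  Noise is Poisson photon noise followed by additive Gaussian
read noise, both optional.  All randomness flows through one seeded
generator; identical parameters and seed give bit-identical images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy.ndimage import gaussian_filter
from scipy.special import erf

from .inheritance import RetentionModel, simulate_division
from .stages import INTERPHASE_STAGES, validate_stage

__all__ = [
    "ImagingParams",
    "GroundTruthCell",
    "RenderedCell",
    "render_cell",
    "make_ground_truth",
    "render_cells",
    "make_pulse_chase_truths",
    "make_pulse_chase_dataset",
    "make_population_image_set",
    "make_cytokinesis_pair",
    "write_image_set",
    "read_image_set",
]

#: number of chromosomes (hence centromeres) per S2 cell
N_CENTROMERES = 13


def population_if_params(**overrides) -> "ImagingParams":
    """Imaging preset for immunofluorescence of endogenous centromere protein.

    Unlike live SNAP-TMR labeling, fixed-cell IF of endogenous CID has no
    soluble labeled pool: the stained signal is essentially all centromeric,
    so the nucleoplasm carries no excess over the slide background, and the
    total endogenous pool per cell is tightly regulated (low log-normal
    sigma).  Used for whole-cell stage-comparison experiments.
    """
    defaults = dict(
        nucleoplasm_background=20.0,
        outside_background=20.0,
        total_intensity_sigma=0.1,
    )
    defaults.update(overrides)
    return ImagingParams(**defaults)


@dataclass(frozen=True)
class ImagingParams:
    """Geometry, optics, intensity and noise settings for rendered cells.

    ``total_intensity_median`` / ``total_intensity_sigma`` parameterize the
    log-normal distribution of the per-cell labeled total (AU), which is
    split across the 13 centromeres and grouped into foci.
    """

    image_size: tuple[int, int] = (128, 128)
    nucleus_radius: tuple[float, float] = (26.0, 32.0)  # px, sampled uniformly
    n_foci_interphase: tuple[int, int] = (3, 6)  # inclusive range
    n_foci_mitotic: int = N_CENTROMERES
    total_intensity_median: float = 20000.0  # AU per cell
    total_intensity_sigma: float = 0.25  # log-normal sigma (natural log)
    psf_sigma: float = 1.5  # px
    nucleoplasm_background: float = 100.0  # AU / px inside the nucleus
    outside_background: float = 20.0  # AU / px outside
    dapi_level: float = 400.0  # AU / px inside the nucleus (DAPI channel)
    poisson_noise: bool = True
    read_sigma: float = 3.0  # AU, additive Gaussian read noise
    min_focus_separation: float = 6.0  # px, mitotic foci
    seed: int | None = None

    def __post_init__(self) -> None:
        h, w = self.image_size
        r_lo, r_hi = self.nucleus_radius
        if r_lo <= 0 or r_hi < r_lo:
            raise ValueError("nucleus_radius must be a positive (lo, hi) range")
        if r_hi + 4 >= min(h, w) / 2:
            raise ValueError("nucleus does not fit inside the frame")
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be > 0")
        if self.total_intensity_median < 0:
            raise ValueError("amplitudes must be >= 0")
        lo, hi = self.n_foci_interphase
        if not (1 <= lo <= hi):
            raise ValueError("n_foci_interphase must be an increasing range >= 1")


@dataclass(frozen=True)
class GroundTruthCell:
    """Simulated truth behind one rendered cell."""

    cell_id: str
    stage: str
    true_spot_signals: tuple[float, ...]  # integrated AU per focus
    pair_id: str | None = None  # cytokinesis partner linkage

    def __post_init__(self) -> None:
        validate_stage(self.stage)
        if any(s < 0 for s in self.true_spot_signals):
            raise ValueError("spot signals must be >= 0")

    @property
    def true_total(self) -> float:
        return float(sum(self.true_spot_signals))


@dataclass(frozen=True)
class RenderedCell:
    """A rendered cell: channel-major image stack plus its ground truth."""

    truth: GroundTruthCell
    image: np.ndarray  # (2, H, W) uint16; [0] = DAPI, [1] = TMR
    nucleus_mask: np.ndarray  # (H, W) bool, the analytic disk
    nucleus_radius: float
    spot_positions: tuple[tuple[float, float], ...]  # (row, col) per focus


def _pixel_integrated_gaussian(
    shape: tuple[int, int], center: tuple[float, float], sigma: float
) -> np.ndarray:
    """Unit-mass 2-D Gaussian integrated over pixel areas.

    Pixel (i, j) covers [i-0.5, i+0.5] x [j-0.5, j+0.5] around its 0-based
    center, so the sum over an infinite grid is exactly 1; truncation at the
    frame edge is the only loss.
    """
    h, w = shape
    s = sigma * math.sqrt(2.0)
    rows = np.arange(h, dtype=float) - center[0]
    cols = np.arange(w, dtype=float) - center[1]
    fy = 0.5 * (erf((rows + 0.5) / s) - erf((rows - 0.5) / s))
    fx = 0.5 * (erf((cols + 0.5) / s) - erf((cols - 0.5) / s))
    return np.outer(fy, fx)


def _disk_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def _place_foci(
    n: int,
    center: tuple[float, float],
    radius: float,
    min_sep: float,
    rng: np.random.Generator,
    max_tries: int = 2000,
) -> list[tuple[float, float]]:
    """Rejection-sample ``n`` focus centers inside the nucleus with a minimum
    pairwise separation; raises if the nucleus is too small to host them."""
    pts: list[tuple[float, float]] = []
    tries = 0
    while len(pts) < n:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {n} foci with separation {min_sep} "
                f"inside radius {radius:.1f} after {max_tries} tries"
            )
        tries += 1
        rho = radius * math.sqrt(rng.random())
        theta = 2 * math.pi * rng.random()
        cand = (center[0] + rho * math.sin(theta), center[1] + rho * math.cos(theta))
        if all(math.hypot(cand[0] - p[0], cand[1] - p[1]) >= min_sep for p in pts):
            pts.append(cand)
    return pts


def make_ground_truth(
    params: ImagingParams,
    stage: str,
    total_signal: float,
    rng: np.random.Generator,
    cell_id: str = "cell",
    pair_id: str | None = None,
) -> GroundTruthCell:
    """Split a per-cell labeled total into per-focus signals for a stage.

    The 13 centromeres receive Dirichlet-distributed shares of the total.
    Interphase cells group them into 3-6 clusters (each focus is a cluster
    sum); mitotic cells keep them as 13 separable foci.
    """
    validate_stage(stage)
    if total_signal < 0:
        raise ValueError("total_signal must be >= 0")
    if stage in INTERPHASE_STAGES:
        shares = rng.dirichlet(np.full(N_CENTROMERES, 10.0))
        per_centromere = total_signal * shares
        lo, hi = params.n_foci_interphase
        k = int(rng.integers(lo, hi + 1))
        # every cluster holds at least one centromere
        assignment = np.concatenate(
            [np.arange(k), rng.integers(0, k, N_CENTROMERES - k)]
        )
        rng.shuffle(assignment)
        signals = tuple(
            float(per_centromere[assignment == c].sum()) for c in range(k)
        )
    else:
        shares = rng.dirichlet(np.full(params.n_foci_mitotic, 10.0))
        signals = tuple(float(s) for s in total_signal * shares)
    return GroundTruthCell(cell_id, stage, signals, pair_id=pair_id)


def render_cell(
    params: ImagingParams,
    truth: GroundTruthCell,
    rng: np.random.Generator,
) -> RenderedCell:
    """Render one cell as a (DAPI, TMR) uint16 stack with its nucleus mask."""
    h, w = params.image_size
    r = float(rng.uniform(*params.nucleus_radius))
    center = (
        h / 2 + float(rng.uniform(-2, 2)),
        w / 2 + float(rng.uniform(-2, 2)),
    )
    mask = _disk_mask((h, w), center, r)

    mitotic = truth.stage not in INTERPHASE_STAGES
    # keep foci away from the nuclear rim so PSF tails stay inside the mask
    margin = 4.0 * params.psf_sigma
    if r <= margin:
        raise RuntimeError("nucleus too small for the PSF margin")
    sep = params.min_focus_separation if mitotic else 2.0 * params.psf_sigma
    positions = _place_foci(
        len(truth.true_spot_signals), center, r - margin, sep, rng
    )

    tmr = np.full((h, w), params.outside_background, dtype=float)
    tmr[mask] = params.nucleoplasm_background
    for (py, px), s in zip(positions, truth.true_spot_signals):
        if s > 0:
            tmr += s * _pixel_integrated_gaussian((h, w), (py, px), params.psf_sigma)

    dapi = np.full((h, w), params.outside_background, dtype=float)
    dapi[mask] += params.dapi_level
    # soften the nuclear edge a little, as real DAPI is not a hard disk
    dapi = gaussian_filter(dapi, 1.0)

    stack = np.stack([dapi, tmr])
    if params.poisson_noise:
        stack = rng.poisson(stack).astype(float)
    if params.read_sigma > 0:
        stack = stack + rng.normal(0.0, params.read_sigma, stack.shape)
    stack = np.clip(np.rint(stack), 0, 65535).astype(np.uint16)
    return RenderedCell(
        truth=truth,
        image=stack,
        nucleus_mask=mask,
        nucleus_radius=r,
        spot_positions=tuple((float(y), float(x)) for y, x in positions),
    )


def render_cells(
    params: ImagingParams,
    truths: list[GroundTruthCell],
    rng: np.random.Generator,
) -> list[RenderedCell]:
    return [render_cell(params, t, rng) for t in truths]


def _draw_totals(params: ImagingParams, n: int, rng: np.random.Generator) -> np.ndarray:
    mu = math.log(params.total_intensity_median) if params.total_intensity_median > 0 else -np.inf
    if params.total_intensity_median == 0:
        return np.zeros(n)
    return rng.lognormal(mu, params.total_intensity_sigma, n)


def make_pulse_chase_truths(
    params: ImagingParams,
    model: RetentionModel,
    n_day1: int,
    n_day2: int,
    rng: np.random.Generator,
    stage: str = "G2",
) -> tuple[list[GroundTruthCell], list[GroundTruthCell]]:
    """Ground truth for a pulse-chase pair of timepoints.

    Day-1 totals are log-normal draws; each day-2 cell derives from an
    independent day-1-distributed parent by one simulated division: the
    parent's ``model.n_units`` labeled units are partitioned and the daughter
    keeps its share of the parent's intensity.
    """
    if n_day1 <= 0 or n_day2 <= 0:
        raise ValueError("cell counts must be > 0")
    day1 = [
        make_ground_truth(params, stage, t, rng, cell_id=f"d1_{i:04d}")
        for i, t in enumerate(_draw_totals(params, n_day1, rng))
    ]
    parents = _draw_totals(params, n_day2, rng)
    day2 = []
    for i, parent_total in enumerate(parents):
        kept, _ = simulate_division(model, model.n_units, rng)
        total = parent_total * kept / model.n_units
        day2.append(
            make_ground_truth(params, stage, total, rng, cell_id=f"d2_{i:04d}")
        )
    return day1, day2


@dataclass(frozen=True)
class PulseChaseDataset:
    day1: list[RenderedCell] = field(default_factory=list)
    day2: list[RenderedCell] = field(default_factory=list)


def make_pulse_chase_dataset(
    params: ImagingParams,
    model: RetentionModel,
    n_day1: int,
    n_day2: int,
    seed: int | None = None,
) -> PulseChaseDataset:
    """Render a full two-timepoint pulse-chase image set with ground truth."""
    rng = np.random.default_rng(params.seed if seed is None else seed)
    t1, t2 = make_pulse_chase_truths(params, model, n_day1, n_day2, rng)
    return PulseChaseDataset(
        day1=render_cells(params, t1, rng),
        day2=render_cells(params, t2, rng),
    )


def make_population_image_set(
    params: ImagingParams,
    stage_mix: dict[str, float],
    intensity_rule,
    n_cells: int,
    seed: int | None = None,
) -> list[RenderedCell]:
    """Render an asynchronous-population image set.

    ``stage_mix`` maps stage -> proportion (must sum to 1); ``intensity_rule``
    is ``rule(stage, rng) -> total AU`` and defines each cell's true total
    (e.g. metaphase draws twice the interphase distribution under the
    metaphase-loading hypothesis).  Cell counts per stage are the rounded
    expectations, so an empty stage class emits no cells.
    """
    for s in stage_mix:
        validate_stage(s)
    props = np.array(list(stage_mix.values()), dtype=float)
    if props.min() < 0 or abs(props.sum() - 1.0) > 1e-8:
        raise ValueError("stage_mix proportions must be >= 0 and sum to 1")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    counts = {s: int(round(p * n_cells)) for s, p in stage_mix.items()}
    cells: list[RenderedCell] = []
    i = 0
    for stage, k in counts.items():
        for _ in range(k):
            total = float(intensity_rule(stage, rng))
            truth = make_ground_truth(
                params, stage, total, rng, cell_id=f"pop_{i:04d}"
            )
            cells.append(render_cell(params, truth, rng))
            i += 1
    return cells


def make_cytokinesis_pair(
    params: ImagingParams,
    totals: tuple[float, float],
    rng: np.random.Generator,
    pair_id: str = "pair_0",
) -> tuple[RenderedCell, RenderedCell]:
    """Render the two daughters of a cytokinesis figure as linked images."""
    out = []
    for i, total in enumerate(totals):
        truth = make_ground_truth(
            params,
            "cytokinesis",
            total,
            rng,
            cell_id=f"{pair_id}_daughter{i}",
            pair_id=pair_id,
        )
        out.append(render_cell(params, truth, rng))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# on-disk format: one channel-major multi-page 16-bit TIFF per cell plus a
# ground-truth CSV and a YAML metadata echo (parameters and seed)


def write_image_set(
    directory, cells: list[RenderedCell], params: ImagingParams, seed: int | None
) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for c in cells:
        fname = f"{c.truth.cell_id}.tif"
        tifffile.imwrite(directory / fname, c.image)
        rows.append(
            {
                "cell_id": c.truth.cell_id,
                "stage": c.truth.stage,
                "file": fname,
                "n_foci": len(c.truth.true_spot_signals),
                "true_total": c.truth.true_total,
                "pair_id": c.truth.pair_id if c.truth.pair_id is not None else "",
            }
        )
    pd.DataFrame(rows).to_csv(directory / "ground_truth.csv", index=False)
    meta = {"seed": seed, "params": {k: _yamlable(v) for k, v in vars(params).items()}}
    (directory / "metadata.yaml").write_text(yaml.safe_dump(meta))
    return directory


def _yamlable(v):
    if isinstance(v, tuple):
        return list(v)
    if isinstance(v, (np.integer, np.floating)):
        return v.item()
    return v


def read_image_set(directory) -> tuple[list[np.ndarray], pd.DataFrame, dict]:
    """Load a written image set: image stacks, ground-truth table, metadata."""
    directory = Path(directory)
    truth = pd.read_csv(directory / "ground_truth.csv", keep_default_na=False)
    meta = yaml.safe_load((directory / "metadata.yaml").read_text())
    images = [tifffile.imread(directory / f) for f in truth["file"]]
    return images, truth, meta
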