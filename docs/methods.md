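# Methods

`centrodyn` models the quantitative core of a centromere assembly-dynamics
study in Drosophila S2 cells: how the centromeric proteins CID (the CENP-A
histone variant), CENP-C and CAL1 are inherited across cell division, and at
which cell-cycle stage newly synthesized protein is deposited. Because the
raw microscopy for such experiments is rarely deposited, every analysis here
runs on synthetic data with known ground truth; the generator is first-class,
tested code, and its defaults define the study conditions.

## Synthetic imaging

Each simulated cell is a two-channel (DAPI, TMR) 16-bit raster, 128x128 px.
The nucleus is a disk (radius drawn uniformly from 26-32 px) carrying a DAPI
level of 400 AU/px over a 20 AU/px slide background; the TMR channel carries
a nucleoplasmic background (default 100 AU/px, modeling unbound soluble
SNAP-TMR) plus diffraction-limited centromeric foci. S2 cells have ~13
chromosomes whose centromeres form 3-6 clustered foci in interphase and
de-cluster in mitosis; the generator draws a per-cell labeled total,
splits it over 13 centromeres with mildly variable Dirichlet(10) shares, and
groups them into 3-6 clusters (interphase) or keeps them separate (mitosis).
Per-focus ground truth is stored alongside every image.

Foci are rendered with a pixel-integrated isotropic 2-D Gaussian PSF
(sigma 1.5 px, error-function differences per pixel), so the noise-free
integrated excess over background equals the true signal up to frame-edge
truncation (<1% with foci kept 4 sigma inside the nuclear rim). Noise is
Poisson photon noise followed by additive Gaussian read noise (sigma 3 AU),
both optional. Z-stacks are not simulated; the analysis operates on
projections, with `max_project` provided for stack input.

The per-cell labeled total is log-normal: median 20,000 AU with sigma 0.25
for SNAP-TMR pulse labeling (moderate cell-to-cell labeling variability).
For immunofluorescence of endogenous protein (`population_if_params`) the
nucleoplasmic excess is zero — fixed-cell IF of a centromeric antigen has
essentially no soluble pool — and sigma is 0.10, reflecting the tight
regulation of total endogenous CID per cell. These two imaging regimes are
deliberate: the whole-cell measure W subtracts only the extranuclear
background, so in the SNAP-TMR regime W includes the nucleoplasmic pedestal
(as it would in a real TMR image), while in the IF regime W isolates the
centromeric total, which is what the metaphase-vs-interphase comparison
measures.

What the generator does *not* emulate: 3-D PSFs, optical aberrations,
deconvolution artifacts, photobleaching, nuclear shape variation, touching
cells, or staging errors (stage labels are ground truth, standing in for
phospho-H3/tubulin staging). Passing tests therefore show that the analysis
recovers truth under an idealized but noise-realistic imaging model, not
that it is robust to segmentation failure on real micrographs.

## Quantification

Nuclei are segmented from DAPI by Gaussian smoothing (sigma 2), Otsu
thresholding with a bimodality guard, hole filling and a 200-px minimum
area. Spots are detected inside each nucleus by difference-of-Gaussians
enhancement (sigmas 1.5/4.5, matched to the PSF); before filtering,
extranuclear pixels are replaced by the nuclear median so the nuclear rim
(a large step) does not inflate the threshold statistics. The threshold is
median + k*MAD of the enhanced nuclear pixels. k defaults to 7: because
DoG-filtered shot noise is spatially correlated, suprathreshold noise
blobs of >=2 px are not vanishingly rare at lower k (at k=5, ~23% of
noise-only cells contain one; at k=6, ~3%), whereas k=7 yields no false
blob in 300 noise-only calibration cells while leaving the retention
estimates unchanged. Components smaller than 2 px are removed and the
mask is dilated by 2 px to recover PSF tails.

The per-cell measure reproduces the standard background-corrected spot
intensity: C = T − A·m, with T the summed TMR over spot pixels, A the spot
area and m the median TMR over nuclear non-spot pixels. Conventions stated
once: 0-based pixel-center coordinates; boolean raster masks; midpoint
interpolation for even-count medians; negative C retained (never clamped)
so the noise-only null stays unbiased. The whole-cell measure is
W = sum(channel over DAPI mask) − |mask|·median(outside all nuclei).
Cytokinesis daughters are rendered as two linked images and summed
record-wise.

Measured performance under defaults: C tracks true total with unit slope
within 5% and near-zero intercept over a 10x range; noise-only cells
average C = 0 within 3 SE. Known limitation: crowded mitotic figures
(13 separable foci in a ~30-px nucleus) quantify ~5% low because each
focus sits on its neighbors' PSF tails, which both suppresses the DoG
response of dim foci and slightly inflates the background median.

Positivity scoring (done manually in bench practice) is a parameterized
policy: an absolute cutoff, or mean + k·SD (default k=3) of the corrected
intensities of amplitude-zero calibration cells.

## Inheritance model and retention estimation

A centromere complement carries `n_units` (default 100) labeled units.
Three per-division modes:

* `semiconservative_random` — each unit assigned to a daughter with
  probability 1/2, then each retained unit survives exchange with
  probability 1 − e. Expected one-division retention 0.5(1 − e).
* `conservative_block` — contiguous blocks segregate wholesale; identical
  mean, larger per-cell variance (25 vs 125 units² at block size 5,
  parent 100).
* `direct_retention` — each daughter keeps each unit with probability r;
  net retention agnostic about mechanism.

Presets: CID and CENP-C use semi-conservative segregation with e = 0
(expected retention 50%); CAL1 uses direct retention r = 0.34, i.e. two
thirds of the pre-existing centromeric pool exchanged per division. The
r = 0.34 reading interprets "two-thirds exchanged" as total per-division
loss (100 − 34 = 66), not exchange stacked on top of two-fold dilution;
the alternative reading (0.5·(1−e) with e = 0.32) would predict exactly
the same Day-2/Day-1 ratio, so the pulse-chase observable cannot
distinguish them — the model represents net retention only.

The estimator mirrors the bench analysis: per-day single-pass 1.5*IQR
outlier removal (type-7 quartiles), per-day means, ratio in percent.
The two chase timepoints are one doubling apart; the earlier one is the
reference (`t_ref`), regardless of whether a protocol labels them Day 0/1
or Day 1/2. Multiple experiments are averaged at the ratio level after
optional normalization to a labeling-day reference. The delta-method SE
combines the two relative SEs.

## Cell-cycle population simulator

Cells occupy a 24-h cycle: G1 2.4 h (10%), S 11 h, G2 10.1 h, mitosis
0.5 h split 30/30/20/20% into prophase, metaphase, anaphase/telophase and
cytokinesis. Initial ages are uniform by default; an exponential
age-structure option weights ages by the renewal density 2·ln2/T·2^(−a/T)
of a growing population. Note the two stated facts "mitosis lasts ~30 min"
and "3-5% of cells are mitotic" are mutually inconsistent under any
steady-state age model (0.5/24 ≈ 2.1% uniform, ~1.45% with the growth
correction, since mitosis sits at the end of the cycle where the age
density is lowest); the simulator keeps the durations as primary and
leaves the mitotic index to follow from them, with durations exposed for
tuning.

A quench-chase-pulse run quenches pre-existing label with probability
beta (default 0.97); escapees score TMR-positive regardless of loading —
the confound that caps interpretation of rare interphase signals. Cells
advance for the chase, divide on completing cytokinesis (new-label
intensity halves; cells that divided are scored at their true fixation
stage, i.e. interphase), and load new label on traversing a loading stage
after an optional synthesis delay (default 0): one Bernoulli attempt per
traversal in pulse mode (+1 intensity on success), or continuous Poisson
accrual at `rate_per_hour` (CENP-C preset, 0.07/h, chosen so ~50% of
cells are positive by a 10-h chase). Loading presets: CID pulses at
metaphase, CAL1 at prophase, CENP-C loads continuously.

Scenarios are phenomenological, not mechanistic: colchicine arrests cells
at the end of metaphase (loading still permitted, one attempt per arrest);
MG132 multiplies loading efficiency by 0.09 (the treated/control metaphase
positivity ratio); non-degradable Cyclin A multiplies it by 0.79 for a
transfected subpopulation. Exact per-stage positivity percentages at short
chases depend on unmeasured synthesis and detection kinetics, so the
simulator exposes efficiency and delay as free parameters rather than
asserting a reconciliation of any particular printed percentages.

## Statistics

* `iqr_filter` — single pass, fences Q1 − 1.5·IQR and Q3 + 1.5·IQR,
  type-7 (linear-interpolation) quartiles; fewer than four values pass
  through with a warning. The median is never removed.
* `fisher_exact_2x2` — two-sided by full hypergeometric enumeration,
  probability-mass definition with relative tolerance 1e-7 on mass ties;
  zero-margin tables return p = 1 with a warning by convention. Verified
  exhaustively against an independent implementation for all tables with
  N ≤ 18 and sampled to N = 30.
* `t_test` (Welch by default — no variance-equality claim is warranted),
  `mann_whitney` (exact for both n ≤ 20 without ties, midrank/normal
  approximation otherwise) and `one_way_anova` wrap scipy.

## Reproducibility and problem sizes

Every run is a pure function of (config, seed); a single global seed fans
out to per-module child seeds via `SeedSequence`, and reports embed the
seed plus the full parameter echo. Default problem sizes — 200 cells per
day for retention pipelines, ~130 cells for the stage-intensity
comparison, 10,000 cells for population simulations, 10,000 repetitions
for Monte-Carlo division — put sampling error comfortably inside the
tolerances quoted in the tests while keeping any single analysis under a
minute on one CPU.
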