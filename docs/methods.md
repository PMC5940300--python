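# Methods

## G1 licensing model

The simulator is deterministic and population-level: it does not model
individual origins, only the aggregate licensing fraction of one cell
transiting G1. Time is measured in units of the *minimum G1 period* — the
time a cell needs to grow before S entry regardless of licensing — and the
model has three parameters that matter:

| parameter | meaning | default |
|---|---|---|
| `rate` | licensing per minimum-G1 period once loading starts; 1 ⇒ fully licensed exactly at minimum G1 | 1.0 |
| `unlicensed_fraction` (*u*) | initial pause with no licensing, in minimum-G1 units | 0.0 |
| `checkpoint_threshold` (*c*) | licensing required for S entry; < 1 models checkpoint loss | 1.0 |

Licensing at time *t* is `clip((t − u) · rate, 0, c)` and G1 exit occurs at
`T = max(1, u + c/rate)`. The pause and the ramp share one clock that
starts at G1 entry, so the pause counts toward the minimum G1 period.

Discretisation: minimum G1 is divided into `n_steps = 10,000` equal steps
and the licensing fraction is recorded at the end of every step **until G1
exit**, not just for the first `n_steps` samples. For `u + c/rate ≤ 1` this
yields exactly 10,000 samples; for slow licensing the recording is longer.
This reading makes the sampled trajectory an unbiased steady-state snapshot
in every parameter regime, which is the property the ergodic analysis
needs; it is verified against an explicit brute-force snapshot (below).

Histogramming: samples are assigned to the nearest of 101 bin centers
(0%, 1%, …, 100%), rounding half-up. Background is modelled as an additive
shift of `round(background · 100)` percentage points (default 5%), with
mass clipped into the top bin — an additive rather than proportional
reading of a "+5%" flow background, since the scale is percent of maximal
licensing. Measurement spread is modelled by two sequential neighbour-push
passes (default 80%): ascending, each visited bin pushes 80% of its current
count to the next-larger bin; then descending symmetrically. The terminal
bin of each pass keeps its count, so both operations conserve totals
exactly (asserted to 1e−9 relative in tests).

### Ergodic oracle

`population_snapshot_oracle` is the independent check on the ergodic
shortcut: cells enter G1 as a Poisson stream at constant rate over a
warm-up window of `2T`, and a snapshot records the licensing fraction of
every cell still in G1. With 100,000 expected resident cells, the
trajectory-derived histogram and the snapshot agree within 4 multinomial
standard deviations per bin across rates 0.5–4 and pauses 0–0.5.

### Peak detection

The unlicensed-peak call finds the highest-occupancy bin in the lower
quarter of the histogram and sums a window of one background-width (±5
bins at defaults) around it. A peak is present when the window holds >10%
of total mass **and** its mean per-bin occupancy exceeds 3× that of a
reference ramp region above the window. The reference region is separated
from the window by a one-window guard band because the smoothing passes
smear a delta peak geometrically (0.8^k tails) into the adjacent bins;
comparing against immediately adjacent bins would mask genuine peaks. Both
thresholds are configurable; they are conventions for an effect the source
data support only qualitatively. Note the window sums everything below
~5.5% raw licensing, so the reported `peak_fraction` exceeds the pure
pause dwell time `u/T` by the ramp transit time `0.055/rate`.

### Parameter fitting

`fit_params` is a plain grid search: each lattice point runs the full
pipeline and is compared with the (normalized) observed histogram by L2
distance, ties broken to the lexicographically smallest point. On
noiseless self-generated input the generating point is recovered exactly;
the suite asserts recovery within one grid cell on a 5×5 lattice.

## Synthetic crypt population

The generator emulates segmented-cell tables from 3D imaging or flow
cytometry of intestinal crypts. It does **not** model images, lineage
dynamics over time, spillover/compensation, or doublets; it emits one
snapshot of single cells.

Geometry: a cylinder of radius 15 µm closed by a flat base disk, base
reference point at the disk center. A cell with target distance *d* below
the radius sits on the base disk, otherwise on the wall at height
√(d² − r²), so its Euclidean distance to the reference equals *d* exactly.
Geometry affects only distance statistics, not marker logic.

Composition: six axial zones (stem <40 µm, four TA zones to 120 µm,
differentiated 120–160 µm) each carry a cell-class mix and per-class
ground-truth phase tables. These are calibration constants living in
`src/cryptcycle/data/homeostasis.yaml`, chosen once so that the
homeostatic crypt shows the expected structure: ~58% of stem-class cells
unlicensed (so the UEA-negative stem-zone majority is unlicensed), ~12%
licensed in the crypt base, a licensed-G1 maximum in the 40–60 µm zone,
S-phase-rich mid-TA zones, and a terminal TA zone where cohorts finish
with late-S/G2 (no newly licensed or early-S cells) before exiting into
unlicensed/transition states — which yields the distal ordering
max(bound-Mcm2⁺) < max(EdU⁺) < max(total-Mcm2⁺).

Channel rules (noise-free, arbitrary units anchored to TA S-entry bound
Mcm2 = 1.0): unlicensed G1 and G2/M cells carry the bound background 0.05;
licensed G1 ramps uniformly from background to the S-entry level; early/mid
S declines linearly with replicated fraction, reaching background at the
early/late boundary (replicated fraction 0.6, DNA content 1.6); late S/G2
stays at background. Stem-class cells carry `stem_license_factor = 2.0`
times the TA S-entry level. Total Mcm2 is high in all cycling phases
(stem 2.5, TA 1.5, differentiated 0.8) and ~0 in G0; Ki67 is high in
cycling phases, intermediate-low (0.15) in the transition state and ~0 in
G0. Noise is multiplicative mean-one lognormal, CV 0.15 per channel and
0.05 for DNA content; the paperless choice of a noise model is the main
idealisation — real flow data have heavier tails, autofluorescence and
spillover, so passing tests here demonstrate pipeline correctness, not
robustness to every real-world artefact.

Scenarios are sequential probability-mass transfers between phases applied
to every zone table (see the YAML): `egfr_inhibited` moves cycling mass
into unlicensed G1; `deep_g0` additionally drains unlicensed G1 through
the transition state into G0; `apc_mutant` empties the unlicensed pool
into licensed G1 and draws per-cell S-entry bound levels from U(0.3, 1.0)
of the normal level (sub-maximal licensing at S entry). `label_chase`
halves H2B–GFP per division (`initial · 0.5^k`, k Poisson per class: stem
3, TA 6, differentiated 5; label-retaining and Paneth cells 0). Halving
per division is the standard dilution model; the source observation is
qualitative.

## Gating

The Mcm2-negative gate is the 0.99 quantile of DNA-bound Mcm2 among
4N-gated cells (DNA content 1.8–2.2), operationalising "set from the Mcm2
intensity of G2 cells": G2 cells have displaced their loaded helicases, so
their bound signal is pure background. Remaining thresholds default to
fixed values in anchored units (EdU 0.25, Ki67 0.4, total-Mcm2 0.3) and
are overridable; positivity is strictly greater-than, so ties classify
negative and calls are invariant to rescaling a channel with its
threshold.

Six-state gating is sequential: DNA windows first (2N 0.8–1.2; S call
1.2–1.6; late S/G2/M 1.6–2.2; outside 0.8–2.2 left ungated), then Ki67
splits 2N cells into quiescent and cycling, then total Mcm2 separates G0
(negative) from the transition state (positive) and bound Mcm2 separates
unlicensed from licensed G1. The S/late-S boundary at DNA 1.6 matches the
generator's early/late split. The irreducible error of this scheme is
early-S cells that still have 2N-window DNA content (replicated fraction
<0.2): they are called licensed G1, which caps six-state accuracy on the
default crypt at ~95–96%. The G0-vs-transition Ki67 convention (G0 = Ki67
low *and* total Mcm2 low; transition = total high, Ki67 low) reflects
Ki67 being lost before Mcm2 during quiescence deepening.

## Spatial analysis

Distances are Euclidean norms to the base reference point. Distance bins
are half-open `[a, a + w)` with default width 20 µm; no cell is
double-binned. Multi-crypt profiles average per-crypt fractions with equal
weight per crypt (not per cell) and report across-crypt variance. Zone
comparisons default to the 40/80 µm boundaries. The most-distal-positive
statistic uses a deliberately conservative positivity threshold (0.3 in
anchored units for the Mcm2 channels, an analogue of manual scoring)
rather than the derived Mcm2-negative gate, because a 99th-percentile gate
leaves ~1% false positives whose extreme order statistic would sit at the
far end of the crypt; "no positive cells" is an explicit result, never a
zero distance.

## Problem sizes and determinism

The test suite and acceptance script use 10,000 simulator steps, 100,000
snapshot cells, 10,000-cell crypts (6,000 for scenario contrasts) — sizes
at which every statistical margin above holds with room while the whole
suite runs in seconds. The simulator is deterministic (no seed); the
snapshot oracle and the generator consume explicit seeds, and a fixed
config + seed reproduces tables byte-identically.

## Known limitations

* The generator's zone compositions are calibrated constants, not fitted
  to data; conclusions drawn from them are about pipeline behaviour.
* Phase durations within a cell (licensed-G1 progress, S-phase replicated
  fraction) are drawn uniformly rather than from the ergodic occupancy a
  full cell-cycle model would imply.
* The six-state scheme cannot distinguish just-entered S cells from fully
  licensed G1 cells without EdU; accuracy claims account for this.
* No FCS binary export; CSV is the interchange format.
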