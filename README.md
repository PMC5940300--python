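# cryptcycle

Tools for analysing DNA replication **origin licensing** in intestinal
crypt cell populations: a deterministic simulator of MCM2–7 loading through
G1 with ergodic-rate analysis, a seeded synthetic generator of per-cell
crypt marker tables, flow-cytometry-style cell-cycle gating, and spatial
profiling along the crypt–villus axis.

## The scientific problem

Before a cell can replicate its DNA it must *license* its replication
origins by loading MCM2–7 helicase complexes onto chromatin during G1.
Comparing total Mcm2 protein with the DNA-bound (detergent-resistant)
fraction distinguishes a G1 state that proliferation markers cannot see:
cells with 2N DNA, abundant soluble Mcm2 and Ki67, but *no* chromatin-bound
MCM2–7 — an **unlicensed G1** state in which intestinal stem cells pause
before committing to division. `cryptcycle` packages the quantitative
machinery behind that conclusion for reuse: given either simulator
parameters or a per-cell marker table, it asks whether a population shows a
discrete unlicensed-G1 peak, where along the crypt axis each cell-cycle
state lives, and how licensing differs between stem and transit-amplifying
(TA) cells.

## The model

A cell entering G1 waits for an optional unlicensed pause of length *u*
(in units of the minimum G1 period), then licenses origins at constant
rate *r* (fraction of full licensing per minimum-G1 period), and exits G1
at time

&nbsp;&nbsp;&nbsp;&nbsp;*T* = max(1, *u* + *c*/*r*),

where *c* is the licensing-checkpoint threshold (*c* = 1 for a robust
checkpoint; *c* < 1 models checkpoint loss, as in Apc-mutant cells).
Because unsynchronised cells enter G1 at a constant rate, steady-state
occupancy of each licensing level is proportional to the time spent there
(ergodic rate analysis: density ∝ 1/speed). The simulator divides minimum
G1 into 10,000 steps, records licensing at each step, bins the values into
101 bins (0–100% licensing), shifts everything up by a 5% flow-cytometry
background, and smooths with two sequential 80% neighbour-push passes.
A long pause produces a discrete low-licensing peak; slow licensing alone
spreads cells uniformly — the two hypotheses the peak detector separates.

## Worked example

Simulate a population with a long unlicensed pause (`u = 0.5`, `rate = 4`)
and test for the unlicensed peak:

```bash
$ cryptcycle simulate --rate 4 -u 0.5 --out paused.csv
cryptcycle: simulate: rate=4 pause=0.5 checkpoint=1 exit_time=1
wrote 101-bin smoothed histogram to paused.csv
```

```python
>>> from cryptcycle import licensing, io
>>> licensing.detect_unlicensed_peak(io.read_histogram("paused.csv"))
PeakReport(present=True, peak_fraction=0.284, peak_bin=0, window=(0, 5))
```

The pause puts half of G1 time at zero licensing, so after background and
smoothing ~28% of cells sit in the low-licensing window and the peak is
called present; with `u = 0` and `rate = 1` the same call returns
`present=False` (uniform occupancy).

Generate a synthetic homeostatic crypt and classify it:

```bash
$ cryptcycle generate --n-cells 10000 --seed 0 --out cells.csv
wrote 10000 cells to cells.csv
$ cryptcycle classify --cells cells.csv --out calls.csv
cryptcycle: thresholds: mcm2_neg=0.06869 (quantile 0.99 of bound_mcm2 in 4N gate)
classified 9969 gated cells -> calls.csv
```

The six-state population fractions land in `calls.fractions.json`:

```
G0 0.295, TRANSITION 0.133, UNLICENSED_G1 0.199,
LICENSED_G1 0.133, S_PHASE 0.057, LATE_S_G2M 0.184
```

i.e. roughly 20% of gated cells are Ki67-positive, Mcm2-expressing cells
with 2N DNA and only background DNA-bound Mcm2 — the unlicensed-G1 pool,
concentrated in the stem compartment (<40 µm from the crypt base), where
it exceeds half of the UEA-negative (non-Paneth) cells.
`cryptcycle profile --cells calls.csv --out profile.csv` then shows the
licensed-G1 fraction peaking in the 40–60 µm bin, just above the stem
compartment.

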