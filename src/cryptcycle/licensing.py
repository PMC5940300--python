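"""Deterministic G1 origin-licensing simulator and ergodic-rate analysis.

The model describes a population of cells transiting G1 under three rules:

* a *minimum G1 period* (the unit of time) that must elapse before S entry,
  regardless of licensing status;
* MCM2-7 loading ("licensing") at a constant rate once it starts, where a
  rate of 1 means full licensing is reached exactly at the end of the
  minimum G1 period;
* an optional *unlicensed G1 pause* at the start of G1 during which no
  loading occurs, and a *licensing checkpoint* that forbids S entry until a
  required licensing fraction has been reached.

Because unsynchronised cells enter G1 at a constant rate, the time a cell
spends at each licensing level maps directly onto the occupancy of that
level in a single population snapshot (the ergodic principle: occupancy is
inversely proportional to transit speed).  A single simulated trajectory,
sampled on a uniform time grid, therefore doubles as the steady-state
histogram of DNA-bound MCM2-7 across an asynchronous G1 population.
:func:`population_snapshot_oracle` provides the explicit many-cell
simulation of the same steady state and is used to verify that equivalence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "LicensingParams",
    "LicensingTrajectory",
    "LicensingHistogram",
    "PeakReport",
    "FitResult",
    "simulate_trajectory",
    "build_histogram",
    "apply_background",
    "smooth_histogram",
    "population_snapshot_oracle",
    "detect_unlicensed_peak",
    "fit_params",
]


@dataclass(frozen=True)
class LicensingParams:
    """Parameters of the deterministic G1 licensing model.

    Parameters
    ----------
    rate
        Fraction of full licensing achieved per minimum-G1 period once
        loading has started.  ``rate=1`` means a cell becomes fully
        licensed exactly at the end of the minimum G1 period.
    unlicensed_fraction
        Duration of the initial no-licensing pause, in minimum-G1 units.
    checkpoint_threshold
        Licensing fraction required before S entry is permitted.  ``1.0``
        is a robust licensing checkpoint; values below 1 model cells
        (e.g. Apc-mutant) that enter S phase at sub-maximal licensing.
    n_steps
        Number of equal time steps the minimum G1 period is divided into.
    background
        Additive licensing offset (on the 0-1 scale) modelling the
        background signal recorded by flow cytometry.
    push_fraction
        Fraction of a bin's counts pushed into the neighbouring bin per
        smoothing pass, modelling flow-cytometry measurement error.
    n_bins
        Number of histogram bins from 0 (no licensing) to 100% (maximal).
    """

    rate: float = 1.0
    unlicensed_fraction: float = 0.0
    checkpoint_threshold: float = 1.0
    n_steps: int = 10_000
    background: float = 0.05
    push_fraction: float = 0.8
    n_bins: int = 101

    def __post_init__(self) -> None:
        if not self.rate > 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        if self.unlicensed_fraction < 0:
            raise ValueError("unlicensed_fraction must be nonnegative")
        if not 0 < self.checkpoint_threshold <= 1:
            raise ValueError("checkpoint_threshold must be in (0, 1]")
        if self.n_steps < 1:
            raise ValueError("n_steps must be a positive integer")
        if self.n_bins < 2:
            raise ValueError("n_bins must be at least 2")
        if not 0 <= self.background < 1:
            raise ValueError("background must be in [0, 1)")
        if not 0 <= self.push_fraction < 1:
            raise ValueError("push_fraction must be in [0, 1)")

    @property
    def exit_time(self) -> float:
        """G1 exit time in minimum-G1 units.

        Cells leave G1 only once the checkpoint is satisfied *and* the
        minimum G1 period has elapsed, so the exit time is
        ``max(1, unlicensed_fraction + checkpoint_threshold / rate)``.
        """
        return max(
            1.0, self.unlicensed_fraction + self.checkpoint_threshold / self.rate
        )


@dataclass(frozen=True)
class LicensingTrajectory:
    """Licensing fraction of one cell recorded at the end of each step."""

    samples: np.ndarray
    step_duration: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.size == 0:
            raise ValueError("trajectory must contain at least one sample")
        if np.any(np.diff(samples) < 0):
            raise ValueError("licensing samples must be nondecreasing")
        if samples[0] < 0 or samples[-1] > 1:
            raise ValueError("licensing samples must lie in [0, 1]")


@dataclass(frozen=True)
class LicensingHistogram:
    """Frequency distribution of licensing levels across a G1 population."""

    bin_centers: np.ndarray  # percent licensing, 0..100
    counts: np.ndarray
    stage: str = "raw"  # raw | background_adjusted | smoothed

    STAGES = ("raw", "background_adjusted", "smoothed")

    def __post_init__(self) -> None:
        object.__setattr__(self, "bin_centers", np.asarray(self.bin_centers, float))
        object.__setattr__(self, "counts", np.asarray(self.counts, float))
        if self.stage not in self.STAGES:
            raise ValueError(f"unrecognized histogram stage {self.stage!r}")
        if self.bin_centers.shape != self.counts.shape:
            raise ValueError("bin_centers and counts must have equal length")
        if np.any(self.counts < -1e-12):
            raise ValueError("histogram counts must be nonnegative")

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def frequencies(self) -> np.ndarray:
        """Counts normalized to sum to one."""
        total = self.total
        if total == 0:
            raise ValueError("cannot normalize an empty histogram")
        return self.counts / total


@dataclass(frozen=True)
class PeakReport:
    """Outcome of unlicensed-peak detection on a licensing histogram."""

    present: bool
    peak_fraction: float
    peak_bin: int
    window: tuple[int, int]


@dataclass(frozen=True)
class FitResult:
    """Best-fitting lattice point from a grid search over model parameters."""

    best_rate: float
    best_unlicensed_fraction: float
    best_checkpoint_threshold: float
    distance: float
    grid: list = field(repr=False, default_factory=list)


def simulate_trajectory(params: LicensingParams) -> LicensingTrajectory:
    """Simulate one cell's licensing fraction through G1.

    The minimum G1 period is divided into ``n_steps`` equal steps and the
    degree of licensing is recorded at the end of every step, from G1 entry
    until G1 exit.  Licensing is zero during the initial pause, then rises
    linearly at ``rate`` until it is clamped at ``checkpoint_threshold``.
    When the exit time exceeds the minimum G1 period (slow licensing or a
    long pause) recording continues past ``n_steps`` samples, so that the
    trajectory remains an unbiased steady-state population snapshot.
    """
    dt = 1.0 / params.n_steps
    n_samples = math.ceil(params.exit_time * params.n_steps - 1e-9)
    t = np.arange(1, n_samples + 1, dtype=float) / params.n_steps
    licensing = np.clip(
        (t - params.unlicensed_fraction) * params.rate,
        0.0,
        params.checkpoint_threshold,
    )
    return LicensingTrajectory(samples=licensing, step_duration=dt)


def build_histogram(traj: LicensingTrajectory, n_bins: int = 101) -> LicensingHistogram:
    """Distribute trajectory samples into equally spaced licensing bins.

    Bin centers run from 0 to 100% licensing; each sample is assigned to
    the nearest bin center (half-up rounding).  By the ergodic principle
    the resulting raw histogram is the steady-state snapshot of an
    asynchronous G1 population.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    idx = np.floor(traj.samples * (n_bins - 1) + 0.5).astype(int)
    idx = np.clip(idx, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    centers = np.linspace(0.0, 100.0, n_bins)
    return LicensingHistogram(bin_centers=centers, counts=counts, stage="raw")


def apply_background(hist: LicensingHistogram, background: float = 0.05) -> LicensingHistogram:
    """Shift all licensing values up by the flow-cytometry background.

    The shift is additive on the 0-100% licensing scale: every count moves
    ``round(background * (n_bins - 1))`` bins toward the top, and mass that
    would exceed 100% licensing accumulates in the top bin.  Totals are
    conserved exactly.
    """
    if not 0 <= background < 1:
        raise ValueError("background must be in [0, 1)")
    n = hist.n_bins
    shift = int(round(background * (n - 1)))
    if shift == 0:
        return replace(hist, stage="background_adjusted")
    counts = np.zeros_like(hist.counts)
    counts[shift:] = hist.counts[: n - shift]
    counts[-1] += hist.counts[n - shift :].sum()
    return replace(hist, counts=counts, stage="background_adjusted")


def smooth_histogram(hist: LicensingHistogram, push_fraction: float = 0.8) -> LicensingHistogram:
    """Smooth a histogram by two sequential neighbour-push passes.

    The forward pass visits bins in ascending order and at each visit moves
    ``push_fraction`` of the bin's *current* count into the next-larger
    bin; the backward pass does the symmetric sweep in descending order.
    The terminal bin of each pass keeps its count, so the total is
    conserved exactly.  This models flow-cytometry measurement spread.
    """
    if not 0 <= push_fraction < 1:
        raise ValueError("push_fraction must be in [0, 1)")
    counts = hist.counts.astype(float).copy()
    n = counts.size
    for i in range(n - 1):
        moved = counts[i] * push_fraction
        counts[i] -= moved
        counts[i + 1] += moved
    for i in range(n - 1, 0, -1):
        moved = counts[i] * push_fraction
        counts[i] -= moved
        counts[i - 1] += moved
    return replace(hist, counts=counts, stage="smoothed")


def process_histogram(params: LicensingParams) -> LicensingHistogram:
    """Full simulator pipeline: trajectory -> raw -> background -> smoothed."""
    hist = build_histogram(simulate_trajectory(params), params.n_bins)
    hist = apply_background(hist, params.background)
    return smooth_histogram(hist, params.push_fraction)


def population_snapshot_oracle(
    params: LicensingParams, n_cells: int, seed: int
) -> LicensingHistogram:
    """Brute-force steady-state snapshot of an asynchronous G1 population.

    Cells enter G1 as a constant-rate (Poisson) stream over a warm-up
    window long enough that the oldest possible G1 resident entered within
    it; a snapshot at the end of the window records the current licensing
    fraction of every cell still in G1.  ``n_cells`` sets the expected
    number of in-G1 cells at the snapshot.  This is the independent oracle
    for the ergodic equivalence with
    ``build_histogram(simulate_trajectory(params))``.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be at least 1")
    rng = np.random.default_rng(seed)
    exit_time = params.exit_time
    window = 2.0 * exit_time
    entry_rate = n_cells / exit_time
    n_entries = rng.poisson(entry_rate * window)
    entry_times = rng.uniform(0.0, window, size=n_entries)
    ages = window - entry_times
    ages = ages[ages < exit_time]
    licensing = np.clip(
        (ages - params.unlicensed_fraction) * params.rate,
        0.0,
        params.checkpoint_threshold,
    )
    idx = np.floor(licensing * (params.n_bins - 1) + 0.5).astype(int)
    idx = np.clip(idx, 0, params.n_bins - 1)
    counts = np.bincount(idx, minlength=params.n_bins).astype(float)
    centers = np.linspace(0.0, 100.0, params.n_bins)
    return LicensingHistogram(bin_centers=centers, counts=counts, stage="raw")


def detect_unlicensed_peak(
    hist: LicensingHistogram,
    background: float = 0.05,
    min_mass: float = 0.10,
    neighbor_factor: float = 3.0,
) -> PeakReport:
    """Decide whether a histogram shows a discrete unlicensed-G1 peak.

    The candidate peak position is the highest-occupancy bin in the lower
    quarter of the histogram.  The peak window spans one background-width
    on either side of that position.  A peak is reported when the window
    holds more than ``min_mass`` of the total *and* its mean per-bin
    occupancy exceeds ``neighbor_factor`` times that of a reference ramp
    region above the window (separated by a one-window guard band, so that
    smoothing spill-over does not mask the contrast).
    """
    total = hist.total
    if hist.n_bins == 0 or total == 0:
        raise ValueError("cannot detect a peak in an empty histogram")
    n = hist.n_bins
    width = max(1, int(round(background * (n - 1))))
    search_hi = max(width + 1, n // 4)
    pos = int(np.argmax(hist.counts[:search_hi]))
    lo = max(0, pos - width)
    hi = min(n - 1, pos + width)
    window_counts = hist.counts[lo : hi + 1]
    peak_fraction = float(window_counts.sum() / total)
    ref_lo = hi + width + 1
    ref_hi = min(n - 1, hi + 4 * width)
    if ref_lo <= ref_hi:
        ref_mean = float(hist.counts[ref_lo : ref_hi + 1].mean())
        contrast_ok = window_counts.mean() > neighbor_factor * ref_mean
    else:  # no ramp above the window; fall back to the mass criterion alone
        contrast_ok = True
    present = bool(peak_fraction > min_mass and contrast_ok)
    return PeakReport(
        present=present, peak_fraction=peak_fraction, peak_bin=pos, window=(lo, hi)
    )


def fit_params(
    observed: LicensingHistogram,
    rates,
    unlicensed_fractions,
    checkpoint_thresholds=(1.0,),
    n_steps: int = 10_000,
    background: float = 0.05,
    push_fraction: float = 0.8,
    n_bins: int | None = None,
) -> FitResult:
    """Grid search for the simulator parameters best matching ``observed``.

    Every lattice point is pushed through the full pipeline (simulate,
    bin, background-adjust, smooth, normalize) and compared with the
    normalized observed histogram by L2 distance.  Ties break to the
    lexicographically smallest (rate, unlicensed_fraction,
    checkpoint_threshold) point.
    """
    rates = sorted(float(r) for r in rates)
    unlicensed_fractions = sorted(float(u) for u in unlicensed_fractions)
    checkpoint_thresholds = sorted(float(c) for c in checkpoint_thresholds)
    if not rates or not unlicensed_fractions or not checkpoint_thresholds:
        raise ValueError("parameter grid must be nonempty")
    if n_bins is None:
        n_bins = observed.n_bins
    obs = observed.frequencies()
    grid = []
    best = None
    for rate in rates:
        for u in unlicensed_fractions:
            for c in checkpoint_thresholds:
                params = LicensingParams(
                    rate=rate,
                    unlicensed_fraction=u,
                    checkpoint_threshold=c,
                    n_steps=n_steps,
                    background=background,
                    push_fraction=push_fraction,
                    n_bins=n_bins,
                )
                freq = process_histogram(params).frequencies()
                distance = float(np.sqrt(((freq - obs) ** 2).sum()))
                grid.append((rate, u, c, distance))
                if best is None or distance < best[3]:
                    best = (rate, u, c, distance)
    return FitResult(
        best_rate=best[0],
        best_unlicensed_fraction=best[1],
        best_checkpoint_threshold=best[2],
        distance=best[3],
        grid=grid,
    )
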