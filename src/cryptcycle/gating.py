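"""Threshold derivation and cell-cycle classification from marker tables.

Implements the two gating schemes used to read cell-cycle state out of
per-cell marker intensities:

* a four-group scheme from DNA-bound Mcm2 and EdU (unlicensed/negative,
  licensed G1, early/mid S, late S/G2) mirroring image-based scoring of an
  extracted, EdU-pulsed crypt;
* a six-state flow-style scheme from DNA content, Ki67, total Mcm2 and
  DNA-bound Mcm2 (G0, transition, unlicensed G1, licensed G1, S phase,
  late S/G2/M) for quantifying quiescence-depth transitions.

The Mcm2-negative gate is derived from the data themselves: since G2 cells
have displaced their loaded MCM2-7, the DNA-bound Mcm2 of 4N-gated cells is
pure background, and a high quantile of it separates unlicensed from
licensed cells.  Ties at a threshold classify as negative (positivity is a
strict inequality), so classification is invariant to rescaling a channel
together with its threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GatingConfig",
    "Thresholds",
    "FOUR_GROUPS",
    "SIX_STATES",
    "SixStateResult",
    "LabelingIndex",
    "derive_thresholds",
    "classify_mcm_edu",
    "gate_flow_profile",
    "six_state_truth",
    "labeling_index",
    "s_entry_bound_ratio",
]

FOUR_GROUPS = ("unlicensed_or_negative", "licensed_g1", "s_early_mid", "late_s_g2")
SIX_STATES = (
    "G0",
    "TRANSITION",
    "UNLICENSED_G1",
    "LICENSED_G1",
    "S_PHASE",
    "LATE_S_G2M",
)
UNGATED = "UNGATED"

#: ground-truth phase -> expected six-state call
_TRUTH_TO_SIX = {
    "G0": "G0",
    "TRANSITION": "TRANSITION",
    "UNLICENSED_G1": "UNLICENSED_G1",
    "LICENSED_G1": "LICENSED_G1",
    "S_EARLY_MID": "S_PHASE",
    "LATE_S_G2": "LATE_S_G2M",
    "G2M": "LATE_S_G2M",
}


@dataclass(frozen=True)
class GatingConfig:
    """Rules for resolving classification thresholds.

    ``mcm2_neg_quantile`` operationalizes setting the Mcm2-negative gate
    from the DNA-bound Mcm2 intensity of G2 cells.  The remaining
    thresholds default to fixed values in the anchored intensity units and
    can be overridden per dataset.  DNA windows are in DNA-content units
    (1.0 = 2N, 2.0 = 4N); the S-phase call spans DNA between the 2N window
    and ``s_late_boundary``, late S/G2/M spans from there to the 4N upper
    edge.
    """

    mcm2_neg_quantile: float = 0.99
    dna_2n_window: tuple[float, float] = (0.8, 1.2)
    dna_4n_window: tuple[float, float] = (1.8, 2.2)
    s_late_boundary: float = 1.6
    edu_pos_threshold: float = 0.25
    ki67_low_threshold: float = 0.4
    total_mcm2_low_threshold: float = 0.3

    def __post_init__(self) -> None:
        if not 0 < self.mcm2_neg_quantile < 1:
            raise ValueError("mcm2_neg_quantile must be in (0, 1)")
        if self.dna_2n_window[1] > self.dna_4n_window[0]:
            raise ValueError("2N and 4N DNA windows must be disjoint")
        if not self.dna_2n_window[1] <= self.s_late_boundary <= self.dna_4n_window[1]:
            raise ValueError("s_late_boundary must lie between the DNA windows")


@dataclass(frozen=True)
class Thresholds:
    """Resolved thresholds with the provenance of their derivation."""

    mcm2_neg: float
    edu_pos: float
    ki67_low: float
    total_mcm2_low: float
    dna_2n_window: tuple[float, float]
    dna_4n_window: tuple[float, float]
    s_late_boundary: float
    provenance: dict = field(default_factory=dict)


@dataclass(frozen=True)
class SixStateResult:
    calls: pd.Series
    fractions: dict
    counts: dict
    n_gated: int


@dataclass(frozen=True)
class LabelingIndex:
    fraction: float
    n_positive: int
    n_total: int


def _require_columns(cells: pd.DataFrame, columns) -> None:
    missing = [c for c in columns if c not in cells.columns]
    if missing:
        raise KeyError(f"cell table is missing required column(s): {missing}")


def derive_thresholds(cells: pd.DataFrame, config: GatingConfig | None = None) -> Thresholds:
    """Resolve classification thresholds from a cell table.

    The Mcm2-negative threshold is the configured quantile of DNA-bound
    Mcm2 among 4N-gated cells (G2/M plus late-S cells, whose bound Mcm2 is
    background).  An empty 4N gate is an error: pass explicit thresholds
    instead of deriving them from data that cannot support the derivation.
    """
    if config is None:
        config = GatingConfig()
    _require_columns(cells, ["dna_content", "bound_mcm2"])
    lo, hi = config.dna_4n_window
    g2 = cells[(cells["dna_content"] >= lo) & (cells["dna_content"] <= hi)]
    if len(g2) == 0:
        raise ValueError(
            "no cells fall in the 4N DNA window; cannot derive the "
            "Mcm2-negative gate -- supply an explicit Thresholds override"
        )
    mcm2_neg = float(g2["bound_mcm2"].quantile(config.mcm2_neg_quantile))
    return Thresholds(
        mcm2_neg=mcm2_neg,
        edu_pos=config.edu_pos_threshold,
        ki67_low=config.ki67_low_threshold,
        total_mcm2_low=config.total_mcm2_low_threshold,
        dna_2n_window=config.dna_2n_window,
        dna_4n_window=config.dna_4n_window,
        s_late_boundary=config.s_late_boundary,
        provenance={
            "mcm2_neg": {
                "rule": f"quantile {config.mcm2_neg_quantile} of bound_mcm2 in 4N gate",
                "n_control": int(len(g2)),
            },
            "edu_pos": {"rule": "configured absolute threshold"},
            "ki67_low": {"rule": "configured absolute threshold"},
            "total_mcm2_low": {"rule": "configured absolute threshold"},
        },
    )


def classify_mcm_edu(cells: pd.DataFrame, thresholds: Thresholds) -> pd.Series:
    """Four-group classification from DNA-bound Mcm2 and EdU positivity.

    The 2x2 assignment: Mcm2- EdU- is the unlicensed/negative composite
    (G0, unlicensed G1 or G2), Mcm2+ EdU- is licensed G1, Mcm2+ EdU+ is
    early/mid S phase, Mcm2- EdU+ is late S/G2.
    """
    _require_columns(cells, ["bound_mcm2", "edu"])
    mcm_pos = cells["bound_mcm2"].to_numpy() > thresholds.mcm2_neg
    edu_pos = cells["edu"].to_numpy() > thresholds.edu_pos
    calls = np.where(
        edu_pos,
        np.where(mcm_pos, "s_early_mid", "late_s_g2"),
        np.where(mcm_pos, "licensed_g1", "unlicensed_or_negative"),
    )
    return pd.Series(calls, index=cells.index, name="called_group")


def gate_flow_profile(cells: pd.DataFrame, thresholds: Thresholds) -> SixStateResult:
    """Six-state gating from DNA content, Ki67, total and DNA-bound Mcm2.

    Gates are applied sequentially: DNA windows first (2N-like cells, S
    phase between the 2N window and the late-S boundary, late S/G2/M up to
    the 4N upper edge; anything outside is left ungated), then Ki67 splits
    the 2N cells into quiescent and cycling, then Mcm2 states resolve G0
    versus transition (total Mcm2) and unlicensed versus licensed G1
    (DNA-bound Mcm2).  Fractions are over gated cells and sum to one.
    """
    _require_columns(cells, ["dna_content", "total_mcm2", "bound_mcm2", "ki67"])
    if len(cells) == 0:
        raise ValueError("cannot gate an empty cell table")
    dna = cells["dna_content"].to_numpy()
    ki67 = cells["ki67"].to_numpy()
    total = cells["total_mcm2"].to_numpy()
    bound = cells["bound_mcm2"].to_numpy()

    calls = np.full(len(cells), UNGATED, dtype=object)
    lo2, hi2 = thresholds.dna_2n_window
    _, hi4 = thresholds.dna_4n_window
    in_2n = (dna >= lo2) & (dna <= hi2)
    in_s = (dna > hi2) & (dna <= thresholds.s_late_boundary)
    in_late = (dna > thresholds.s_late_boundary) & (dna <= hi4)

    calls[in_s] = "S_PHASE"
    calls[in_late] = "LATE_S_G2M"
    cycling = ki67 > thresholds.ki67_low
    calls[in_2n & ~cycling & (total > thresholds.total_mcm2_low)] = "TRANSITION"
    calls[in_2n & ~cycling & (total <= thresholds.total_mcm2_low)] = "G0"
    calls[in_2n & cycling & (bound > thresholds.mcm2_neg)] = "LICENSED_G1"
    calls[in_2n & cycling & (bound <= thresholds.mcm2_neg)] = "UNLICENSED_G1"

    series = pd.Series(calls, index=cells.index, name="called_phase")
    gated = series[series != UNGATED]
    n_gated = int(len(gated))
    counts = {state: int((gated == state).sum()) for state in SIX_STATES}
    fractions = {
        state: (counts[state] / n_gated if n_gated else float("nan"))
        for state in SIX_STATES
    }
    return SixStateResult(
        calls=series, fractions=fractions, counts=counts, n_gated=n_gated
    )


def six_state_truth(true_phase: pd.Series) -> pd.Series:
    """Map ground-truth phases onto the six-state call vocabulary."""
    return true_phase.map(_TRUTH_TO_SIX)


def s_entry_bound_ratio(
    cells: pd.DataFrame,
    marker: str = "lgr5",
    marker_threshold: float = 0.3,
    dna_max: float = 1.1,
    edu_threshold: float = 0.25,
) -> tuple[float, int, int]:
    """Ratio of DNA-bound Mcm2 at S entry between marker+ and marker- cells.

    Cells just entering S phase are selected as EdU-positive with
    near-2N DNA content (``dna_content < dna_max``), where bound Mcm2 is
    still at its licensing maximum.  Returns the ratio of mean bound Mcm2
    in marker-positive (e.g. Lgr5+ stem) versus marker-negative cells,
    with the two group sizes.
    """
    _require_columns(cells, ["dna_content", "bound_mcm2", "edu", marker])
    early_s = cells[
        (cells["edu"] > edu_threshold) & (cells["dna_content"] < dna_max)
    ]
    pos = early_s[early_s[marker] > marker_threshold]
    neg = early_s[early_s[marker] <= marker_threshold]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError(
            "need both marker-positive and marker-negative early-S cells"
        )
    ratio = float(pos["bound_mcm2"].mean() / neg["bound_mcm2"].mean())
    return ratio, len(pos), len(neg)


def labeling_index(
    cells: pd.DataFrame, channel: str, threshold: float
) -> LabelingIndex:
    """Fraction of cells whose ``channel`` intensity exceeds ``threshold``."""
    _require_columns(cells, [channel])
    if len(cells) == 0:
        raise ValueError("cannot compute a labeling index on an empty table")
    positive = int((cells[channel].to_numpy() > threshold).sum())
    return LabelingIndex(
        fraction=positive / len(cells), n_positive=positive, n_total=len(cells)
    )
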