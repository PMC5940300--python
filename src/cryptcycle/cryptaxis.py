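"""Spatial analysis along the crypt-villus axis.

Distances are Euclidean distances (um) from each cell to a reference point
at the crypt base.  Cells are grouped into half-open, uniform-width
distance bins [a, b) so that no cell is double-counted, and per-bin phase
composition, most-distal-positive statistics and zone comparisons are
computed from the per-cell calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CryptProfile",
    "MostDistalResult",
    "distance_to_base",
    "profile_by_distance",
    "most_distal_positive",
    "zone_composition",
]

DEFAULT_ZONES = (("stem", 0.0, 40.0), ("early_TA", 40.0, 80.0))


@dataclass(frozen=True)
class CryptProfile:
    """Per-distance-bin phase composition.

    ``fractions`` is indexed by bin start (um) with one column per phase;
    occupied bins' fractions sum to one.  ``counts`` holds per-bin cell
    counts.  For multi-crypt input the fractions are the equal-weight mean
    of the per-crypt fractions and ``variance`` holds the across-crypt
    variance per bin and phase.
    """

    bin_edges: np.ndarray
    fractions: pd.DataFrame
    counts: pd.Series
    variance: pd.DataFrame | None = None


@dataclass(frozen=True)
class MostDistalResult:
    distance: float | None
    n_positive: int

    @property
    def any_positive(self) -> bool:
        return self.n_positive > 0


def distance_to_base(points: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Euclidean distance of each 3D point to the base reference point."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    reference = np.asarray(reference, dtype=float)
    if points.shape[1] != reference.shape[0]:
        raise ValueError(
            f"dimension mismatch: points are {points.shape[1]}D, "
            f"reference is {reference.shape[0]}D"
        )
    return np.linalg.norm(points - reference, axis=1)


def _bin_fractions(
    cells: pd.DataFrame, edges: np.ndarray, call_col: str, phases: list
) -> tuple[pd.DataFrame, pd.Series]:
    starts = edges[:-1]
    idx = np.digitize(cells["dist_to_base_um"].to_numpy(), edges[1:], right=False)
    frac = pd.DataFrame(0.0, index=pd.Index(starts, name="bin_start_um"), columns=phases)
    counts = pd.Series(0, index=frac.index, name="n_cells")
    for b, start in enumerate(starts):
        sub = cells[idx == b]
        counts.iloc[b] = len(sub)
        if len(sub):
            vc = sub[call_col].value_counts(normalize=True)
            for ph in vc.index:
                frac.loc[start, ph] = vc[ph]
    return frac, counts


def profile_by_distance(
    cells: pd.DataFrame,
    bin_width: float = 20.0,
    call_col: str = "called_phase",
    crypt_col: str | None = None,
) -> CryptProfile:
    """Phase composition per half-open distance bin [a, a + bin_width).

    With ``crypt_col`` given, per-crypt fractions are averaged with equal
    weight per crypt and their across-crypt variance is reported.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    for col in ("dist_to_base_um", call_col):
        if col not in cells.columns:
            raise KeyError(f"cell table is missing required column {col!r}")
    max_dist = float(cells["dist_to_base_um"].max())
    n_bins = max(1, int(np.ceil((max_dist + 1e-12) / bin_width)))
    edges = np.arange(n_bins + 1, dtype=float) * bin_width
    phases = sorted(cells[call_col].unique())

    if crypt_col is None:
        frac, counts = _bin_fractions(cells, edges, call_col, phases)
        return CryptProfile(bin_edges=edges, fractions=frac, counts=counts)

    per_crypt = []
    counts_total = None
    for _, sub in cells.groupby(crypt_col):
        frac, counts = _bin_fractions(sub, edges, call_col, phases)
        per_crypt.append(frac)
        counts_total = counts if counts_total is None else counts_total + counts
    stacked = np.stack([f.to_numpy() for f in per_crypt])
    mean = pd.DataFrame(
        stacked.mean(axis=0), index=per_crypt[0].index, columns=phases
    )
    var = pd.DataFrame(
        stacked.var(axis=0, ddof=1) if len(per_crypt) > 1 else np.zeros_like(stacked[0]),
        index=per_crypt[0].index,
        columns=phases,
    )
    return CryptProfile(
        bin_edges=edges, fractions=mean, counts=counts_total, variance=var
    )


def most_distal_positive(
    cells: pd.DataFrame, channel: str, threshold: float
) -> MostDistalResult:
    """Distance to base of the most distal cell positive for ``channel``.

    A cell is positive when its intensity strictly exceeds ``threshold``.
    When no cell is positive the result reports that explicitly rather
    than returning a zero distance.
    """
    for col in ("dist_to_base_um", channel):
        if col not in cells.columns:
            raise KeyError(f"cell table is missing required column {col!r}")
    positive = cells[cells[channel] > threshold]
    if len(positive) == 0:
        return MostDistalResult(distance=None, n_positive=0)
    return MostDistalResult(
        distance=float(positive["dist_to_base_um"].max()), n_positive=len(positive)
    )


def zone_composition(
    cells: pd.DataFrame,
    zones=DEFAULT_ZONES,
    call_col: str = "called_phase",
    subset: pd.Series | None = None,
) -> pd.DataFrame:
    """Phase composition per axial zone for a designated cell subset.

    ``zones`` is an iterable of (name, lower_um, upper_um) half-open
    intervals partitioning the axis; ``subset`` is an optional boolean
    mask (e.g. UEA-negative cells in the stem compartment).  Returns a
    table indexed by zone with one fraction column per phase plus a cell
    count; empty zones report a zero count and NaN fractions.
    """
    for col in ("dist_to_base_um", call_col):
        if col not in cells.columns:
            raise KeyError(f"cell table is missing required column {col!r}")
    if subset is not None:
        cells = cells[subset]
    phases = sorted(cells[call_col].unique())
    rows = {}
    for name, lo, hi in zones:
        sub = cells[
            (cells["dist_to_base_um"] >= lo) & (cells["dist_to_base_um"] < hi)
        ]
        row = {ph: np.nan for ph in phases}
        if len(sub):
            vc = sub[call_col].value_counts(normalize=True)
            row = {ph: float(vc.get(ph, 0.0)) for ph in phases}
        row["n_cells"] = len(sub)
        rows[name] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "zone"
    return out
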