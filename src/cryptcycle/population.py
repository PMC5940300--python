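"""Seeded generator of synthetic per-cell crypt marker tables.

Emits segmented-cell tables (one row per cell) with the statistical
structure that the downstream gating and spatial analyses assume: an
asynchronous cell cycle whose DNA-bound Mcm2 follows the licensing profile
of crypt flow cytometry (unlicensed G1 cells indistinguishable from G2
cells), a stem compartment below 40 um dominated by unlicensed-G1 cells, an
S-phase-rich transit-amplifying compartment, a two-fold higher bound-Mcm2
level at S entry in stem versus TA cells, H2B-GFP dilution by division, and
quiescence-depth scenarios (EGFR inhibition, deep G0, Apc-mutant checkpoint
loss).

Ground-truth phase and class labels are carried alongside the noisy
channels so classifiers can be scored against the generating truth.  All
randomness flows through the seed in the configuration; a fixed
configuration yields a byte-identical table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PHASES",
    "CELL_CLASSES",
    "SCENARIOS",
    "PopulationConfig",
    "load_config",
    "generate_population",
    "assign_positions",
    "apply_label_chase",
]

PHASES = (
    "G0",
    "TRANSITION",
    "UNLICENSED_G1",
    "LICENSED_G1",
    "S_EARLY_MID",
    "LATE_S_G2",
    "G2M",
)
CELL_CLASSES = ("stem", "paneth", "TA", "differentiated", "LRC")
SCENARIOS = ("homeostasis", "egfr_inhibited", "deep_g0", "apc_mutant", "label_chase")

_FRACTION_TOL = 1e-6


@dataclass
class PopulationConfig:
    """Validated generator configuration (see ``data/homeostasis.yaml``)."""

    n_cells: int
    seed: int
    scenario: str
    stem_license_factor: float
    crypt: dict
    noise_cv: dict
    channels: dict
    zones: list
    scenarios: dict
    label_chase: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be at least 1")
        if self.scenario not in SCENARIOS:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; expected one of {SCENARIOS}"
            )
        if self.stem_license_factor < 1:
            raise ValueError("stem_license_factor must be >= 1")
        weights = [z["weight"] for z in self.zones]
        if abs(sum(weights) - 1.0) > _FRACTION_TOL:
            raise ValueError(f"zone weights must sum to 1, got {sum(weights)}")
        self._check_zone_coverage()
        for zone in self.zones:
            class_sum = sum(zone["classes"].values())
            if abs(class_sum - 1.0) > _FRACTION_TOL:
                raise ValueError(
                    f"class fractions in zone {zone['name']!r} sum to {class_sum}"
                )
            for cls, table in zone["phases"].items():
                if cls not in CELL_CLASSES:
                    raise ValueError(f"unknown cell class {cls!r}")
                phase_sum = sum(table.values())
                if abs(phase_sum - 1.0) > _FRACTION_TOL:
                    raise ValueError(
                        f"phase fractions for {cls!r} in zone {zone['name']!r} "
                        f"sum to {phase_sum}, expected 1"
                    )
                for phase in table:
                    if phase not in PHASES:
                        raise ValueError(f"unknown phase {phase!r}")

    def _check_zone_coverage(self) -> None:
        spans = sorted(tuple(z["range_um"]) for z in self.zones)
        length = float(self.crypt["length_um"])
        if spans[0][0] != 0:
            raise ValueError("zones must start at the crypt base (0 um)")
        for (a_lo, a_hi), (b_lo, b_hi) in zip(spans, spans[1:]):
            if b_lo < a_hi - _FRACTION_TOL:
                raise ValueError(f"zones overlap at {b_lo} um")
            if b_lo > a_hi + _FRACTION_TOL:
                raise ValueError(f"gap between zones at {a_hi} um")
        if abs(spans[-1][1] - length) > _FRACTION_TOL:
            raise ValueError("zones must cover the full crypt length")


def load_config(path: str | Path | None = None, **overrides) -> PopulationConfig:
    """Load a generator configuration, defaulting to the packaged calibration.

    Keyword overrides replace top-level keys (e.g. ``n_cells``, ``seed``,
    ``scenario``) after the file is read.
    """
    if path is None:
        text = (
            resources.files("cryptcycle").joinpath("data/homeostasis.yaml").read_text()
        )
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    raw.update(overrides)
    return PopulationConfig(
        n_cells=int(raw["n_cells"]),
        seed=int(raw["seed"]),
        scenario=raw["scenario"],
        stem_license_factor=float(raw["stem_license_factor"]),
        crypt=raw["crypt"],
        noise_cv=raw["noise_cv"],
        channels=raw["channels"],
        zones=raw["zones"],
        scenarios=raw.get("scenarios", {}),
        label_chase=raw.get("label_chase", {}),
    )


def _apply_scenario(phase_table: dict, scenario_spec: dict) -> dict:
    """Apply sequential probability-mass transfers to one phase table."""
    table = dict(phase_table)
    for rule in scenario_spec.get("transfers", []):
        src, dst, frac = rule["from"], rule["to"], float(rule["fraction"])
        if src in table:
            moved = table[src] * frac
            table[src] -= moved
            table[dst] = table.get(dst, 0.0) + moved
    return table


def generate_population(config: PopulationConfig) -> pd.DataFrame:
    """Generate a synthetic crypt cell table.

    Cells are assigned to axial zones by the configured weights, to classes
    and ground-truth phases by the per-zone composition tables (after any
    scenario mass transfers), placed on the crypt surface within their
    zone, given noise-free channel intensities by the phase rules, and
    finally perturbed with multiplicative lognormal noise.
    """
    rng = np.random.default_rng(config.seed)
    scenario_spec = config.scenarios.get(config.scenario, {}) or {}

    n = config.n_cells
    zone_weights = np.array([z["weight"] for z in config.zones], dtype=float)
    zone_idx = rng.choice(len(config.zones), size=n, p=zone_weights / zone_weights.sum())

    zone_names = np.empty(n, dtype=object)
    cell_class = np.empty(n, dtype=object)
    phase = np.empty(n, dtype=object)
    for zi, zone in enumerate(config.zones):
        mask = zone_idx == zi
        m = int(mask.sum())
        if m == 0:
            continue
        zone_names[mask] = zone["name"]
        classes = list(zone["classes"])
        probs = np.array([zone["classes"][c] for c in classes], dtype=float)
        cls_draw = rng.choice(len(classes), size=m, p=probs / probs.sum())
        cls_arr = np.array(classes, dtype=object)[cls_draw]
        cell_class[mask] = cls_arr
        for ci, cls in enumerate(classes):
            sub = np.where(mask)[0][cls_draw == ci]
            if sub.size == 0:
                continue
            table = _apply_scenario(zone["phases"][cls], scenario_spec)
            phases = list(table)
            p = np.array([table[ph] for ph in phases], dtype=float)
            draw = rng.choice(len(phases), size=sub.size, p=p / p.sum())
            phase[sub] = np.array(phases, dtype=object)[draw]

    cells = pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "zone": zone_names,
            "cell_class": cell_class,
            "true_phase": phase,
        }
    )
    cells = assign_positions(cells, config, rng)
    cells = _synthesize_channels(cells, config, scenario_spec, rng)

    if config.scenario == "label_chase":
        cells = apply_label_chase(
            cells,
            config.label_chase.get("mean_divisions", {}),
            rng,
            initial=float(config.channels.get("h2b_initial", 1.0)),
            noise_cv=float(config.noise_cv.get("default", 0.15)),
        )
    return cells


def assign_positions(
    cells: pd.DataFrame, config: PopulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Place cells on the crypt surface within their assigned zone.

    The crypt is a cylinder of the configured radius closed by a flat base
    disk; the base reference point is the disk center.  For a target
    distance-to-base d drawn uniformly within the cell's zone, the cell
    sits on the base disk when d is below the radius and on the cylinder
    wall at height sqrt(d^2 - r^2) otherwise, so its Euclidean distance to
    the reference point equals d exactly and zone membership is exact.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    radius = float(config.crypt["radius_um"])
    spans = {z["name"]: tuple(z["range_um"]) for z in config.zones}
    n = len(cells)
    dist = np.empty(n)
    for name, (lo, hi) in spans.items():
        mask = (cells["zone"] == name).to_numpy()
        dist[mask] = rng.uniform(lo, hi, size=int(mask.sum()))
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    on_wall = dist >= radius
    rho = np.where(on_wall, radius, dist)
    height = np.where(on_wall, np.sqrt(np.maximum(dist**2 - radius**2, 0.0)), 0.0)
    out = cells.copy()
    out["x_um"] = rho * np.cos(theta)
    out["y_um"] = rho * np.sin(theta)
    out["z_um"] = height
    out["dist_to_base_um"] = dist
    return out


def _synthesize_channels(
    cells: pd.DataFrame,
    config: PopulationConfig,
    scenario_spec: dict,
    rng: np.random.Generator,
) -> pd.DataFrame:
    ch = config.channels
    n = len(cells)
    phase = cells["true_phase"].to_numpy()
    cls = cells["cell_class"].to_numpy()

    b0 = float(ch["bound_background"])
    s_split = float(ch.get("s_boundary_fraction", 0.6))
    baseline = float(ch.get("baseline", 0.02))

    # Bound-Mcm2 level reached at S entry: the TA anchor, doubled in stem
    # cells; Apc-mutant cells may enter S at sub-maximal licensing.
    s_entry = np.full(n, float(ch["ta_s_entry_bound"]))
    s_entry[cls == "stem"] *= config.stem_license_factor
    sub = scenario_spec.get("sub_maximal_s_entry")
    if sub:
        s_entry *= rng.uniform(float(sub["low"]), float(sub["high"]), size=n)

    dna = np.ones(n)
    bound = np.full(n, b0)
    edu = np.full(n, baseline)
    ki67 = np.empty(n)
    total = np.empty(n)

    ki67_table = ch["ki67"]
    for ph in PHASES:
        ki67[phase == ph] = float(ki67_table[ph])
    total_table = ch["total_mcm2"]
    for c in CELL_CLASSES:
        total[cls == c] = float(total_table[c])

    is_g0 = phase == "G0"
    total[is_g0] = float(ch["g0_total"])
    bound[is_g0] = float(ch["g0_bound"])

    is_lic = phase == "LICENSED_G1"
    progress = rng.uniform(0.0, 1.0, size=n)
    bound[is_lic] = b0 + progress[is_lic] * (s_entry[is_lic] - b0)

    is_s = phase == "S_EARLY_MID"
    frac = rng.uniform(0.0, s_split, size=n)
    dna[is_s] = 1.0 + frac[is_s]
    # bound Mcm2 declines linearly with replicated fraction, reaching the
    # background level by the end of early/mid S (most MCM2-7 displaced)
    bound[is_s] = b0 + (s_entry[is_s] - b0) * (1.0 - frac[is_s] / s_split)
    edu[is_s] = float(ch["edu_positive"])

    is_ls = phase == "LATE_S_G2"
    late_frac = rng.uniform(s_split, 1.0, size=n)
    dna[is_ls] = 1.0 + late_frac[is_ls]
    edu[is_ls] = float(ch["edu_positive"])

    dna[phase == "G2M"] = 2.0

    lgr5 = np.where(
        np.isin(cls, ["stem", "LRC"]), float(ch["lgr5_positive"]), baseline
    )
    uea = cls == "paneth"

    out = cells.copy()
    out["dna_content"] = dna
    out["total_mcm2"] = np.maximum(total, bound)  # soluble pool never negative
    out["bound_mcm2"] = bound
    out["ki67"] = ki67
    out["edu"] = edu
    out["lgr5"] = lgr5
    out["h2b_gfp"] = np.full(n, baseline)
    out["uea_positive"] = uea
    out["divisions_since_label"] = np.zeros(n, dtype=int)

    cv = float(config.noise_cv.get("default", 0.15))
    cv_dna = float(config.noise_cv.get("dna_content", 0.05))
    for col in ("total_mcm2", "bound_mcm2", "ki67", "edu", "lgr5", "h2b_gfp"):
        out[col] = out[col].to_numpy() * _lognormal_noise(rng, cv, n)
    out["dna_content"] = out["dna_content"].to_numpy() * _lognormal_noise(
        rng, cv_dna, n
    )
    return out


def _lognormal_noise(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with coefficient of variation cv."""
    if cv <= 0:
        return np.ones(n)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n)


def apply_label_chase(
    cells: pd.DataFrame,
    mean_divisions: dict,
    rng: np.random.Generator,
    initial: float = 1.0,
    noise_cv: float = 0.15,
) -> pd.DataFrame:
    """Dilute an H2B-GFP label by cell division.

    Each division halves the label, so ``h2b_gfp = initial * 0.5**k`` for a
    cell that divided ``k`` times since labelling.  Division counts are
    Poisson-distributed with per-class means; label-retaining cells (LRC)
    and post-mitotic Paneth cells do not divide during the chase and keep
    the full label.
    """
    if initial <= 0:
        raise ValueError("initial label intensity must be positive")
    if any(v < 0 for v in mean_divisions.values()):
        raise ValueError("mean division counts must be nonnegative")
    out = cells.copy()
    n = len(out)
    cls = out["cell_class"].to_numpy()
    divisions = np.zeros(n, dtype=int)
    for c, mean in mean_divisions.items():
        mask = cls == c
        divisions[mask] = rng.poisson(float(mean), size=int(mask.sum()))
    divisions[np.isin(cls, ["LRC", "paneth"])] = 0
    out["divisions_since_label"] = divisions
    label = initial * np.power(0.5, divisions.astype(float))
    out["h2b_gfp"] = label * _lognormal_noise(rng, noise_cv, n)
    return out
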