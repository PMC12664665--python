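"""Inversion-timing search for the three background-suppression schemes.

Three two-pulse BS schemes are supported:

``regular``
    Constrained placement (inversion pulses only during the post-labeling
    delay).  Targets roughly 5% residual signal in gray and white matter
    with all residuals kept non-negative, so that magnitude images remain
    usable without sign bookkeeping.
``enhanced``
    Unconstrained placement.  Drives gray- and white-matter residuals
    below 1% of M0 regardless of sign; CSF is left free.
``csf``
    Unconstrained placement.  Drives the CSF residual below 1% while
    keeping gray/white residuals as small as possible.

The search is an exhaustive grid over (TI1, TI2) pairs followed by a local
fine-grid refinement; the objective is piecewise smooth and the domain is
tiny, so this is both fast and fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .bloch import BSSequenceTiming, PulseEfficiency, TissueRelaxation, residual_mz

__all__ = [
    "SchemeObjective",
    "TimingSolution",
    "grid_residuals",
    "optimize_timings",
    "per_pld_schedule",
    "GUARD_GAP_MS",
]

# Minimum spacing (ms) between the two inversion pulses and between the
# second pulse and the readout: physical pulses have finite duration.
GUARD_GAP_MS = 5.0

SCHEMES = ("regular", "enhanced", "csf")
TISSUES = ("GM", "WM", "CSF")


@dataclass(frozen=True)
class SchemeObjective:
    """Which scheme to design and under which placement rule."""

    scheme: str
    placement: str = "auto"  # "constrained", "unconstrained" or "auto"
    residual_bound_pct: float = 1.0
    regular_target_pct: float = 5.0

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}; one of {SCHEMES}")
        if self.placement not in ("constrained", "unconstrained", "auto"):
            raise ValueError(f"unknown placement {self.placement!r}")
        if self.scheme == "regular" and self.placement == "unconstrained":
            raise ValueError("the regular scheme uses constrained placement")

    @property
    def constrained(self) -> bool:
        if self.placement == "auto":
            return self.scheme == "regular"
        return self.placement == "constrained"


@dataclass(frozen=True)
class TimingSolution:
    """An inversion-timing pair with its per-tissue residuals (percent)."""

    inversion_times: tuple[float, float]
    residuals: dict[str, float]
    feasible: bool
    objective_value: float
    pld: float | None = None

    def timing(self, label_duration: float, pld: float) -> BSSequenceTiming:
        return BSSequenceTiming(
            label_duration=label_duration,
            pld=pld,
            inversion_times=self.inversion_times,
        )


def _residual_table(
    ti1: np.ndarray,
    ti2: np.ndarray,
    readout: float,
    t1s: TissueRelaxation,
    eff: PulseEfficiency,
) -> dict[str, np.ndarray]:
    """Vectorized closed-form residual (percent) for arrays of TI pairs."""
    beta = eff.inversion_efficiency
    m0_start = 1.0 - eff.saturation_efficiency
    out: dict[str, np.ndarray] = {}
    for tissue, t1 in t1s.as_dict().items():
        m1 = 1.0 - (1.0 - m0_start) * np.exp(-ti1 / t1)
        m2 = 1.0 - (1.0 + beta * m1) * np.exp(-(ti2 - ti1) / t1)
        mz = 1.0 - (1.0 + beta * m2) * np.exp(-(readout - ti2) / t1)
        out[tissue] = 100.0 * mz
    return out


def _candidate_pairs(
    label_duration: float,
    pld: float,
    constrained: bool,
    step: float,
    guard: float = GUARD_GAP_MS,
) -> tuple[np.ndarray, np.ndarray]:
    readout = label_duration + pld
    lo = label_duration if constrained else step
    hi = readout - guard
    ti = np.arange(lo, hi + 1e-9, step)
    ti = ti[(ti > 0) & (ti <= hi)]
    if ti.size < 2:
        return np.empty(0), np.empty(0)
    a, b = np.meshgrid(ti, ti, indexing="ij")
    keep = b >= a + guard
    return a[keep], b[keep]


def grid_residuals(
    label_duration: float,
    pld: float,
    placement: str = "unconstrained",
    t1s: TissueRelaxation = TissueRelaxation(),
    eff: PulseEfficiency = PulseEfficiency(),
    step: float = 1.0,
) -> dict[str, np.ndarray]:
    """Exhaustive residual table over all admissible (TI1, TI2) pairs.

    Returns arrays ``ti1``, ``ti2`` and one residual array (percent) per
    tissue.  Constrained placement restricts both pulses to the
    post-labeling delay; unconstrained allows them anywhere after the
    pre-saturation.  An empty grid (PLD too short for the guard gaps)
    yields zero-length arrays rather than an error.
    """
    if step < 1.0:
        raise ValueError("grid step must be >= 1 ms")
    constrained = placement == "constrained"
    ti1, ti2 = _candidate_pairs(label_duration, pld, constrained, step)
    table = {"ti1": ti1, "ti2": ti2}
    if ti1.size:
        table.update(_residual_table(ti1, ti2, label_duration + pld, t1s, eff))
    else:
        table.update({tissue: np.empty(0) for tissue in TISSUES})
    return table


def _score(
    objective: SchemeObjective, table: dict[str, np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """(objective value, feasibility) per grid point for the scheme."""
    gm, wm, csf = table["GM"], table["WM"], table["CSF"]
    bound = objective.residual_bound_pct
    if objective.scheme == "regular":
        # aim: GM/WM near +target with every residual kept positive; a
        # design that misses the target by more than the target itself
        # (e.g. both pulses squeezed into a very short PLD) has failed
        target = objective.regular_target_pct
        value = np.maximum(np.abs(gm - target), np.abs(wm - target))
        feasible = (gm >= 0) & (wm >= 0) & (csf >= 0) & (value <= target)
    elif objective.scheme == "enhanced":
        value = np.abs(gm) + np.abs(wm)
        feasible = (np.abs(gm) < bound) & (np.abs(wm) < bound)
    else:  # csf
        value = np.maximum(np.abs(gm), np.abs(wm))
        feasible = np.abs(csf) < bound
    return value, feasible


def _violation(objective: SchemeObjective, table: dict[str, np.ndarray]) -> np.ndarray:
    """Constraint violation used to rank candidates when nothing is feasible."""
    gm, wm, csf = table["GM"], table["WM"], table["CSF"]
    bound = objective.residual_bound_pct
    if objective.scheme == "regular":
        return np.maximum.reduce([-gm, -wm, -csf, np.zeros_like(gm)])
    if objective.scheme == "enhanced":
        return np.maximum(np.abs(gm), np.abs(wm)) - bound
    return np.abs(csf) - bound


def _pick_best(
    objective: SchemeObjective, table: dict[str, np.ndarray]
) -> tuple[int, bool]:
    value, feasible = _score(objective, table)
    if feasible.any():
        idx = np.flatnonzero(feasible)
        # lexicographic: objective value, then earliest TI1, then earliest TI2
        order = np.lexsort((table["ti2"][idx], table["ti1"][idx], value[idx]))
        return int(idx[order[0]]), True
    violation = _violation(objective, table)
    order = np.lexsort((table["ti2"], table["ti1"], value, violation))
    return int(order[0]), False


def _solution_at(
    ti1: float,
    ti2: float,
    objective: SchemeObjective,
    label_duration: float,
    pld: float,
    t1s: TissueRelaxation,
    eff: PulseEfficiency,
    feasible: bool,
) -> TimingSolution:
    timing = BSSequenceTiming(
        label_duration=label_duration, pld=pld, inversion_times=(ti1, ti2)
    )
    residuals = {
        tissue: 100.0 * residual_mz(timing, t1, eff)
        for tissue, t1 in t1s.as_dict().items()
    }
    table = {k: np.asarray([v]) for k, v in residuals.items()}
    table["ti1"], table["ti2"] = np.asarray([ti1]), np.asarray([ti2])
    value, feas = _score(objective, table)
    return TimingSolution(
        inversion_times=(float(ti1), float(ti2)),
        residuals=residuals,
        feasible=bool(feas[0]) and feasible,
        objective_value=float(value[0]),
        pld=pld,
    )


def optimize_timings(
    objective: SchemeObjective,
    label_duration: float,
    pld: float,
    t1s: TissueRelaxation = TissueRelaxation(),
    eff: PulseEfficiency = PulseEfficiency(),
    step: float = 1.0,
    refine: bool = True,
) -> TimingSolution:
    """Best two-pulse timing for a scheme at one labeling-duration/PLD.

    Runs the exhaustive grid, then (optionally) refines on a 0.1 ms local
    grid around the incumbent.  When the scheme's constraints cannot be
    met anywhere on the grid the least-violating candidate is returned
    with ``feasible=False`` — infeasibility is a value, not an error.
    """
    constrained = objective.constrained
    placement = "constrained" if constrained else "unconstrained"
    table = grid_residuals(label_duration, pld, placement, t1s, eff, step)
    if table["ti1"].size == 0:
        return TimingSolution(
            inversion_times=(float("nan"), float("nan")),
            residuals={tissue: float("nan") for tissue in TISSUES},
            feasible=False,
            objective_value=float("inf"),
            pld=pld,
        )
    idx, feasible = _pick_best(objective, table)
    ti1, ti2 = float(table["ti1"][idx]), float(table["ti2"][idx])

    if refine:
        readout = label_duration + pld
        lo = label_duration if constrained else 0.1
        span = np.arange(-step, step + 1e-9, 0.1)
        c1 = np.clip(ti1 + span, lo, readout - 2 * GUARD_GAP_MS)
        c2 = np.clip(ti2 + span, lo + GUARD_GAP_MS, readout - GUARD_GAP_MS)
        a, b = np.meshgrid(np.unique(c1), np.unique(c2), indexing="ij")
        keep = b >= a + GUARD_GAP_MS
        if keep.any():
            local = {"ti1": a[keep], "ti2": b[keep]}
            local.update(_residual_table(local["ti1"], local["ti2"], readout, t1s, eff))
            jdx, feasible = _pick_best(objective, local)
            ti1, ti2 = float(local["ti1"][jdx]), float(local["ti2"][jdx])

    return _solution_at(ti1, ti2, objective, label_duration, pld, t1s, eff, feasible)


def per_pld_schedule(
    objective: SchemeObjective,
    label_duration: float,
    plds: Sequence[float],
    t1s: TissueRelaxation = TissueRelaxation(),
    eff: PulseEfficiency = PulseEfficiency(),
    step: float = 1.0,
) -> list[TimingSolution]:
    """Independently optimized timing for each PLD of a multi-delay protocol.

    Duplicate PLDs (acquired twice for averaging) share one solution.
    Infeasible PLDs are flagged, not dropped.
    """
    if not plds:
        raise ValueError("plds must be non-empty")
    cache: dict[float, TimingSolution] = {}
    out = []
    for pld in plds:
        key = float(pld)
        if key not in cache:
            cache[key] = optimize_timings(
                objective, label_duration, key, t1s, eff, step
            )
        out.append(cache[key])
    return out
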