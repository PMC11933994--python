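"""Waiting-list and organ-supply expansion strategies.

The study grid holds 19 strategies: the status quo, waiting-list expansion
alone (10%, 50%), and each expansion level crossed with four deceased-donor
(DDT) supply multipliers or four living-donor (LDT) supply multipliers.

Except for the status quo, transplant *numbers* are fixed by design: organ
supply is enforced as a per-cycle expected-count budget. Each cycle the
per-person transplant probabilities are scaled by a common factor λ (capped
at 1 per cell) chosen so that the expected number of transplants equals the
budget — a growing list therefore dilutes per-person transplant chances
rather than creating organs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .errors import ProbabilityOverflowError, ValidationError
from .parameters import AnnualTargets, MonthlyTransitionSet

__all__ = [
    "ScenarioSpec",
    "OrganBudget",
    "STATUS_QUO",
    "build_scenario_grid",
    "apply_list_expansion",
    "derive_budget",
    "budget_from_trace",
    "allocate_budgeted_transplants",
]

LIST_FACTORS = (1.1, 1.5)
DDT_MULTIPLIERS = (1.1, 1.25, 1.5, 2.0)
LDT_MULTIPLIERS = (1.25, 1.5, 2.0, 3.0)


@dataclass(frozen=True)
class ScenarioSpec:
    """One strategy: initial/annual list expansion plus supply multipliers."""

    name: str
    list_factor: float = 1.0
    ddt_multiplier: float = 1.0
    ldt_multiplier: float = 1.0
    ldt_on_list: bool = False

    def __post_init__(self) -> None:
        if self.list_factor < 1.0:
            raise ValidationError("list_factor must be >= 1")
        if self.ddt_multiplier < 0 or self.ldt_multiplier < 0:
            raise ValidationError("supply multipliers must be non-negative")
        if self.ldt_on_list != (self.ldt_multiplier > 1.0):
            raise ValidationError(
                "on-list LDT is allowed exactly when LDT supply is expanded"
            )
        if self.ddt_multiplier > 1.0 and self.ldt_multiplier > 1.0:
            raise ValidationError(
                "strategies expand at most one of DDT and LDT supply"
            )

    @property
    def is_status_quo(self) -> bool:
        return (
            self.list_factor == 1.0
            and self.ddt_multiplier == 1.0
            and self.ldt_multiplier == 1.0
        )


STATUS_QUO = ScenarioSpec("status_quo")


def _pct(factor: float) -> str:
    return f"{round((factor - 1) * 100):d}"


def build_scenario_grid() -> list[ScenarioSpec]:
    """The 19 modelled strategies, named after their expansion levels
    (e.g. ``wl10_ddt25`` = 10% longer waiting list + 25% more DDT)."""
    grid = [STATUS_QUO]
    for lf in LIST_FACTORS:
        grid.append(ScenarioSpec(f"wl{_pct(lf)}", list_factor=lf))
    for lf in LIST_FACTORS:
        for dm in DDT_MULTIPLIERS:
            grid.append(
                ScenarioSpec(
                    f"wl{_pct(lf)}_ddt{_pct(dm)}", list_factor=lf, ddt_multiplier=dm
                )
            )
    for lf in LIST_FACTORS:
        for lm in LDT_MULTIPLIERS:
            grid.append(
                ScenarioSpec(
                    f"wl{_pct(lf)}_ldt{_pct(lm)}",
                    list_factor=lf,
                    ldt_multiplier=lm,
                    ldt_on_list=True,
                )
            )
    return grid


def scenario_by_name(name: str) -> ScenarioSpec:
    for spec in build_scenario_grid():
        if spec.name == name:
            return spec
    raise ValidationError(f"unknown scenario {name!r}")


def apply_list_expansion(
    params: MonthlyTransitionSet, factor: float
) -> MonthlyTransitionSet:
    """Scale both listing probabilities by ``factor`` (>= 1), modelling
    ``factor - 1`` more additions per year; everything else untouched."""
    if factor < 1.0:
        raise ValidationError(f"list expansion factor {factor} < 1")
    if factor == 1.0:
        return params
    try:
        return params.with_values(
            p_list_ckd=params["p_list_ckd"] * factor,
            p_list_dialysis=params["p_list_dialysis"] * factor,
        )
    except ValidationError as exc:
        raise ProbabilityOverflowError(
            f"list expansion by {factor} pushes competing exits above 1: {exc}"
        ) from exc


@dataclass(frozen=True)
class OrganBudget:
    """Per-cycle expected transplant counts enforced by the allocator.

    Each field is an array indexed by cycle (or None for probability-driven
    behaviour). ``ldt_onlist`` is the *incremental* LDT supply directed to
    wait-listed patients under LDT expansion; ``ldt_offlist`` pins the
    pre-existing off-list LDT pathway to its status-quo counts.
    """

    ddt: np.ndarray | None = None
    ldt_offlist: np.ndarray | None = None
    ldt_onlist: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("ddt", "ldt_offlist", "ldt_onlist"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if np.any(arr < 0):
                    raise ValidationError(f"negative {name} budget")
                object.__setattr__(self, name, arr)

    def for_cycle(self, cycle: int) -> tuple[float | None, float | None, float | None]:
        """Budgets applying during the cycle that starts at occupancy index
        ``cycle`` (0-based)."""

        def pick(arr):
            if arr is None:
                return None
            return float(arr[min(cycle, len(arr) - 1)])

        return pick(self.ddt), pick(self.ldt_offlist), pick(self.ldt_onlist)


def derive_budget(
    baseline_annual: AnnualTargets, spec: ScenarioSpec, horizon: int = 120
) -> OrganBudget:
    """Constant per-cycle budgets: annual baseline × multiplier, spread
    evenly over the 12 cycles of each year.

    Computed for any strategy; the status quo itself normally runs
    probability-driven (no budget), with its realized counts defining the
    baselines via :func:`budget_from_trace`."""
    ddt = np.full(horizon, baseline_annual.ddt * spec.ddt_multiplier / 12.0)
    ldt_off = np.full(horizon, baseline_annual.ldt / 12.0)
    ldt_on = None
    if spec.ldt_multiplier > 1.0:
        ldt_on = np.full(
            horizon, baseline_annual.ldt * (spec.ldt_multiplier - 1.0) / 12.0
        )
    return OrganBudget(ddt=ddt, ldt_offlist=ldt_off, ldt_onlist=ldt_on)


def budget_from_trace(status_quo_trace, spec: ScenarioSpec) -> OrganBudget:
    """Budgets tracking the status quo's realized per-cycle transplant
    counts, so scenario totals match the status quo year by year."""
    if spec.is_status_quo:
        return OrganBudget()
    ddt = np.array([ev.ddt for ev in status_quo_trace.events], dtype=float)
    ldt = np.array([ev.ldt for ev in status_quo_trace.events], dtype=float)
    ldt_on = ldt * (spec.ldt_multiplier - 1.0) if spec.ldt_multiplier > 1.0 else None
    return OrganBudget(
        ddt=ddt * spec.ddt_multiplier, ldt_offlist=ldt, ldt_onlist=ldt_on
    )


def allocate_budgeted_transplants(
    counts: np.ndarray,
    base_p: np.ndarray,
    budget: float,
    cap: np.ndarray | float = 1.0,
) -> np.ndarray:
    """Per-cell transplant probabilities ``min(λ·base_p, cap)`` with λ >= 0
    solved so the expected number of transplants equals
    ``min(budget, feasible maximum)``.

    Relative allocation across cells is preserved wherever the cap does not
    bind. ``cap`` defaults to 1; the cohort engine passes each cell's
    competing-exit headroom (1 minus the cell's other monthly exits) so that
    supply outstripping the remaining candidate pool is left unused rather
    than forcing exit probabilities above 1. When every ``base_p`` is zero
    but mass and budget are positive, allocation falls back to a uniform
    per-person probability (mass-proportional) — the on-list LDT case,
    where no baseline on-list pathway exists.
    """
    counts = np.asarray(counts, dtype=float)
    base_p = np.broadcast_to(np.asarray(base_p, dtype=float), counts.shape)
    cap = np.broadcast_to(np.asarray(cap, dtype=float), counts.shape)
    if budget < 0:
        raise ValidationError("budget must be non-negative")
    if np.any(base_p < 0) or np.any(base_p > 1):
        raise ValidationError("base probabilities must lie in [0, 1]")
    if np.any(cap < -1e-12) or np.any(cap > 1.0 + 1e-12):
        raise ValidationError("caps must lie in [0, 1]")
    cap = np.clip(cap, 0.0, 1.0)
    probs = np.zeros_like(counts)
    if budget == 0 or counts.sum() == 0:
        return probs
    feasible = float((cap * counts).sum())
    target = min(budget, feasible)
    if target == 0.0:
        return probs
    weights = np.where(counts > 0, base_p, 0.0)
    if weights.max() == 0.0:
        weights = np.where(counts > 0, 1.0, 0.0)
    # uncapped solution is exact; fall back to root-finding when capping binds
    expected_at_unit = float((weights * counts).sum())
    lam = target / expected_at_unit
    if np.any(lam * weights > cap):
        def excess(l: float) -> float:
            return float((np.minimum(l * weights, cap) * counts).sum()) - target

        pos = weights > 0
        lam_hi = float(np.max(cap[pos] / weights[pos])) * (1.0 + 1e-12)
        if excess(lam_hi) < 0:  # float round-off at target ~= feasible maximum
            lam = lam_hi
        else:
            lam = brentq(excess, 0.0, lam_hi, xtol=1e-15, rtol=1e-14)
    return np.minimum(lam * weights, cap)
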