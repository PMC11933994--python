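"""Deterministic expected-value cohort engine.

Occupancy is expected person-counts indexed by (age stratum, health state)
with listed states additionally resolved by months-since-listing — a tunnel
dimension needed to read wait-time distributions off the trace. Each cycle
applies the competing monthly exit probabilities of every origin state as
mutually exclusive one-step probabilities (no half-cycle correction), moves
newly listed mass in at duration 0, and advances surviving listed mass one
duration bucket.

The transition graph is declared once in :data:`UNLISTED_EXITS` /
:data:`LISTED_EXITS` and consumed both here and by the individual-level
microsimulation in :mod:`kidneywait.synthetic`, so the two cannot drift
apart structurally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import NamedTuple

import numpy as np

from .errors import EngineError, ProbabilityOverflowError, ValidationError
from .parameters import (
    N_STRATA,
    STRATA,
    AgeStratum,
    CohortSpec,
    HealthState,
    MonthlyTransitionSet,
)
from .scenarios import (
    STATUS_QUO,
    OrganBudget,
    ScenarioSpec,
    allocate_budgeted_transplants,
    apply_list_expansion,
)

__all__ = [
    "Occupancy",
    "EventCounts",
    "CohortTrace",
    "make_initial_occupancy",
    "step_cycle",
    "run_model",
    "annual_counts",
    "UNLISTED_EXITS",
    "LISTED_EXITS",
    "TRANSPLANT",
]

# order of the single-bucket (non-tunnel) states in Occupancy.unlisted
UNLISTED_ORDER = (
    HealthState.CKD_UNLISTED,
    HealthState.DIALYSIS_UNLISTED,
    HealthState.REMOVED,
    HealthState.GRAFT_FUNCTIONING,
    HealthState.DEAD,
)
# order of the duration-resolved states in Occupancy.listed
LISTED_ORDER = (HealthState.CKD_LISTED, HealthState.DIALYSIS_LISTED)

_U = {s: i for i, s in enumerate(UNLISTED_ORDER)}
_L = {s: i for i, s in enumerate(LISTED_ORDER)}

#: pseudo-destination: resolved into DEAD / GRAFT_FUNCTIONING by p_periop_death
TRANSPLANT = "TRANSPLANT"


class Exit(NamedTuple):
    param: str          # name in MonthlyTransitionSet
    dest: object        # HealthState or TRANSPLANT
    event: str | None   # EventCounts field incremented by this flow


UNLISTED_EXITS: dict[HealthState, tuple[Exit, ...]] = {
    HealthState.CKD_UNLISTED: (
        Exit("p_death_ckd", HealthState.DEAD, "ckd_deaths"),
        Exit("p_progress", HealthState.DIALYSIS_UNLISTED, None),
        Exit("p_list_ckd", HealthState.CKD_LISTED, "listings"),
        Exit("p_ldt_unlisted", TRANSPLANT, "ldt_offlist"),
    ),
    HealthState.DIALYSIS_UNLISTED: (
        Exit("p_death_dialysis", HealthState.DEAD, "dialysis_deaths"),
        Exit("p_list_dialysis", HealthState.DIALYSIS_LISTED, "listings"),
        Exit("p_ldt_unlisted", TRANSPLANT, "ldt_offlist"),
    ),
    HealthState.REMOVED: (
        Exit("p_death_removed", HealthState.DEAD, "removed_deaths"),
    ),
    HealthState.GRAFT_FUNCTIONING: (
        Exit("p_death_posttx", HealthState.DEAD, "posttx_deaths"),
        Exit("p_graft_failure", HealthState.DIALYSIS_UNLISTED, "graft_failures"),
    ),
    HealthState.DEAD: (),
}

# listed CKD patients who progress stay on the list (lateral move into the
# dialysis-listed tunnel; the wait-time clock keeps running)
LISTED_EXITS: dict[HealthState, tuple[Exit, ...]] = {
    HealthState.CKD_LISTED: (
        Exit("p_death_listed", HealthState.DEAD, "waitlist_deaths"),
        Exit("p_removal", HealthState.REMOVED, "removals"),
        Exit("p_ddt_listed", TRANSPLANT, "ddt"),
        Exit("p_ldt_listed", TRANSPLANT, "ldt_onlist"),
        Exit("p_progress", HealthState.DIALYSIS_LISTED, None),
    ),
    HealthState.DIALYSIS_LISTED: (
        Exit("p_death_listed", HealthState.DEAD, "waitlist_deaths"),
        Exit("p_removal", HealthState.REMOVED, "removals"),
        Exit("p_ddt_listed", TRANSPLANT, "ddt"),
        Exit("p_ldt_listed", TRANSPLANT, "ldt_onlist"),
    ),
}


@dataclass
class Occupancy:
    """Expected person-counts: ``unlisted[stratum, state]`` single buckets
    and ``listed[stratum, state, months_since_listing]`` tunnels."""

    unlisted: np.ndarray  # (3, 5)
    listed: np.ndarray    # (3, 2, D)

    def __post_init__(self) -> None:
        self.unlisted = np.asarray(self.unlisted, dtype=float)
        self.listed = np.asarray(self.listed, dtype=float)
        if self.unlisted.shape != (N_STRATA, len(UNLISTED_ORDER)):
            raise ValidationError(f"unlisted shape {self.unlisted.shape} invalid")
        if self.listed.ndim != 3 or self.listed.shape[:2] != (N_STRATA, len(LISTED_ORDER)):
            raise ValidationError(f"listed shape {self.listed.shape} invalid")
        if np.any(self.unlisted < -1e-12) or np.any(self.listed < -1e-12):
            raise ValidationError("negative occupancy")

    @property
    def max_duration(self) -> int:
        return self.listed.shape[2] - 1

    @property
    def total(self) -> float:
        return float(self.unlisted.sum() + self.listed.sum())

    def state_total(self, state: HealthState) -> float:
        if state in _L:
            return float(self.listed[:, _L[state], :].sum())
        return float(self.unlisted[:, _U[state]].sum())

    @property
    def listed_total(self) -> float:
        return float(self.listed.sum())

    def copy(self) -> "Occupancy":
        return Occupancy(self.unlisted.copy(), self.listed.copy())

    def state_counts(self) -> dict[HealthState, float]:
        return {s: self.state_total(s) for s in HealthState}


@dataclass
class EventCounts:
    """Expected event counts over one cycle (or summed over cycles)."""

    listings: float = 0.0
    ddt: float = 0.0
    ldt_offlist: float = 0.0
    ldt_onlist: float = 0.0
    removals: float = 0.0
    waitlist_deaths: float = 0.0
    dialysis_deaths: float = 0.0
    ckd_deaths: float = 0.0
    removed_deaths: float = 0.0
    posttx_deaths: float = 0.0
    periop_deaths: float = 0.0
    graft_failures: float = 0.0
    unused_ddt_budget: float = 0.0
    unused_ldt_budget: float = 0.0

    @property
    def ldt(self) -> float:
        return self.ldt_offlist + self.ldt_onlist

    def __add__(self, other: "EventCounts") -> "EventCounts":
        return EventCounts(
            **{f.name: getattr(self, f.name) + getattr(other, f.name) for f in fields(self)}
        )

    def as_dict(self) -> dict[str, float]:
        out = {f.name: getattr(self, f.name) for f in fields(self)}
        out["ldt"] = self.ldt
        return out


@dataclass
class CohortTrace:
    """Full run record: occupancy per cycle, events per cycle, and the
    listing-duration-resolved transplant/censoring flows the Kaplan-Meier
    layer consumes."""

    occupancies: list[Occupancy]
    events: list[EventCounts]
    tx_by_duration: np.ndarray    # (horizon, D): transplants from listed, by duration
    cens_by_duration: np.ndarray  # (horizon, D): listed deaths + removals, by duration
    scenario: ScenarioSpec = STATUS_QUO
    params: MonthlyTransitionSet | None = None

    @property
    def horizon(self) -> int:
        return len(self.events)

    def events_frame(self):
        import pandas as pd

        rows = []
        for i, ev in enumerate(self.events, start=1):
            row = ev.as_dict()
            row["cycle"] = i
            rows.append(row)
        return pd.DataFrame(rows).set_index("cycle")

    def occupancy_frame(self):
        """Tidy export: cycle, stratum, state, duration, count."""
        import pandas as pd

        rows = []
        for c, occ in enumerate(self.occupancies):
            for i, s in enumerate(STRATA):
                for st in UNLISTED_ORDER:
                    rows.append((c, s.value, st.value, None, occ.unlisted[i, _U[st]]))
                for st in LISTED_ORDER:
                    for d in range(occ.listed.shape[2]):
                        v = occ.listed[i, _L[st], d]
                        if v != 0.0:
                            rows.append((c, s.value, st.value, d, v))
        return pd.DataFrame(
            rows, columns=["cycle", "stratum", "state", "duration", "count"]
        )


def make_initial_occupancy(
    spec: CohortSpec, list_expansion_factor: float = 1.0
) -> Occupancy:
    """Cycle-0 occupancy from the cohort split, optionally with the waiting
    list scaled up at model start.

    The expansion increment is drawn from the corresponding unlisted pool
    (CKD-listed from CKD-unlisted, dialysis-listed from dialysis-unlisted),
    applied equally to both lists; total mass is preserved and every listed
    person starts at months-since-listing 0.
    """
    if list_expansion_factor < 1.0:
        raise ValidationError(f"list expansion factor {list_expansion_factor} < 1")
    D = spec.horizon + 1
    unlisted = np.zeros((N_STRATA, len(UNLISTED_ORDER)))
    listed = np.zeros((N_STRATA, len(LISTED_ORDER), D))
    for (stratum, state), count in spec.counts().items():
        i = STRATA.index(AgeStratum(stratum))
        st = HealthState(state)
        if st in _L:
            listed[i, _L[st], 0] += count
        else:
            unlisted[i, _U[st]] += count
    if list_expansion_factor > 1.0:
        source = {
            HealthState.CKD_LISTED: HealthState.CKD_UNLISTED,
            HealthState.DIALYSIS_LISTED: HealthState.DIALYSIS_UNLISTED,
        }
        for lst, src in source.items():
            inc = listed[:, _L[lst], 0] * (list_expansion_factor - 1.0)
            pool = unlisted[:, _U[src]]
            if np.any(inc > pool + 1e-9):
                raise ValidationError(
                    f"not enough unlisted {src.value} mass to expand the list "
                    f"by factor {list_expansion_factor}"
                )
            unlisted[:, _U[src]] -= inc
            listed[:, _L[lst], 0] += inc
    return Occupancy(unlisted, listed)


def _listed_override_probs(
    occ: Occupancy,
    params: MonthlyTransitionSet,
    ddt_budget: float | None,
    ldt_on_budget: float | None,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Per-cell DDT and on-list-LDT probabilities (3, 2, D) after budget
    allocation; also the unused portion of each budget."""
    shape = occ.listed.shape
    base_ddt = np.broadcast_to(params["p_ddt_listed"][:, None, None], shape)
    base_ldt = np.broadcast_to(params["p_ldt_listed"][:, None, None], shape)
    # competing-exit headroom per cell: death + removal (+ progression for
    # the CKD-listed tunnel) may not be displaced by transplant allocation
    other = params["p_death_listed"] + params["p_removal"]
    other_by_k = np.stack(
        [other + params["p_progress"], other], axis=1
    )  # (3, 2)
    headroom = np.clip(1.0 - other_by_k[:, :, None], 0.0, 1.0)
    headroom = np.broadcast_to(headroom, shape)
    unused_ddt = unused_ldt = 0.0
    if ddt_budget is None:
        p_ddt = np.array(base_ddt)
    else:
        p_ddt = allocate_budgeted_transplants(
            occ.listed, base_ddt, ddt_budget, cap=headroom
        )
        realized = float((p_ddt * occ.listed).sum())
        unused_ddt = max(0.0, ddt_budget - realized)
    if ldt_on_budget is None:
        p_ldt = np.array(base_ldt)
    else:
        p_ldt = allocate_budgeted_transplants(
            occ.listed, base_ldt, ldt_on_budget, cap=headroom - p_ddt
        )
        realized = float((p_ldt * occ.listed).sum())
        unused_ldt = max(0.0, ldt_on_budget - realized)
    return p_ddt, p_ldt, unused_ddt, unused_ldt


def _offlist_ldt_probs(
    occ: Occupancy, params: MonthlyTransitionSet, budget: float | None
) -> tuple[np.ndarray, float]:
    """Off-list LDT probabilities per (stratum, unlisted CKD/dialysis)."""
    counts = occ.unlisted[:, [_U[HealthState.CKD_UNLISTED], _U[HealthState.DIALYSIS_UNLISTED]]]
    base = np.broadcast_to(params["p_ldt_unlisted"][:, None], counts.shape)
    if budget is None:
        return np.array(base), 0.0
    other = np.stack(
        [
            params["p_death_ckd"] + params["p_progress"] + params["p_list_ckd"],
            params["p_death_dialysis"] + params["p_list_dialysis"],
        ],
        axis=1,
    )
    probs = allocate_budgeted_transplants(
        counts, base, budget, cap=np.clip(1.0 - other, 0.0, 1.0)
    )
    realized = float((probs * counts).sum())
    return probs, max(0.0, budget - realized)


def step_cycle(
    occ: Occupancy,
    params: MonthlyTransitionSet,
    budgets: tuple[float | None, float | None, float | None] | None = None,
) -> tuple[Occupancy, EventCounts, np.ndarray, np.ndarray]:
    """Advance the cohort one month.

    ``budgets`` is the cycle's ``(ddt, ldt_offlist, ldt_onlist)`` expected-
    count triple (each None = probability-driven). Returns the next
    occupancy, the cycle's events, and the duration-resolved transplant and
    censoring (death/removal) flows from listed states.

    Raises :class:`ProbabilityOverflowError` if competing exits from any
    cell exceed 1 after budget scaling — never silently renormalises.
    """
    ddt_b, ldt_off_b, ldt_on_b = budgets if budgets is not None else (None, None, None)
    D = occ.listed.shape[2]
    ev = EventCounts()
    new_unlisted = np.zeros_like(occ.unlisted)
    new_listed = np.zeros_like(occ.listed)
    tx_by_dur = np.zeros(D)
    cens_by_dur = np.zeros(D)
    tx_mass = np.zeros(N_STRATA)  # transplanted this cycle, by stratum

    p_ldt_off, unused_ldt_off = _offlist_ldt_probs(occ, params, ldt_off_b)
    p_ddt_cells, p_ldt_cells, ev.unused_ddt_budget, unused_ldt_on = _listed_override_probs(
        occ, params, ddt_b, ldt_on_b
    )
    ev.unused_ldt_budget = unused_ldt_off + unused_ldt_on

    def bump(event: str | None, amount: float) -> None:
        if event is not None:
            setattr(ev, event, getattr(ev, event) + amount)

    # --- unlisted origins -------------------------------------------------
    off_idx = {HealthState.CKD_UNLISTED: 0, HealthState.DIALYSIS_UNLISTED: 1}
    for origin, exits in UNLISTED_EXITS.items():
        j = _U[origin]
        mass = occ.unlisted[:, j]
        probs = []
        for ex in exits:
            if ex.param == "p_ldt_unlisted":
                probs.append(p_ldt_off[:, off_idx[origin]])
            else:
                probs.append(params[ex.param])
        total_exit = sum(probs, np.zeros(N_STRATA))
        if np.any(total_exit > 1.0 + 1e-9):
            raise ProbabilityOverflowError(
                f"competing exits from {origin.value} sum above 1"
            )
        for ex, p in zip(exits, probs):
            flow = mass * p
            bump(ex.event, float(flow.sum()))
            if ex.dest is TRANSPLANT:
                tx_mass += flow
            elif ex.dest in _L:
                new_listed[:, _L[ex.dest], 0] += flow  # newly listed: duration 0
            else:
                new_unlisted[:, _U[ex.dest]] += flow
        new_unlisted[:, j] += mass * (1.0 - total_exit)

    # --- listed origins (duration tunnels) --------------------------------
    stay = np.zeros_like(occ.listed)
    lateral = np.zeros((N_STRATA, D))  # CKD_LISTED -> DIALYSIS_LISTED, same clock
    for origin, exits in LISTED_EXITS.items():
        k = _L[origin]
        mass = occ.listed[:, k, :]  # (3, D)
        probs = []
        for ex in exits:
            if ex.param == "p_ddt_listed":
                probs.append(p_ddt_cells[:, k, :])
            elif ex.param == "p_ldt_listed":
                probs.append(p_ldt_cells[:, k, :])
            else:
                probs.append(np.broadcast_to(params[ex.param][:, None], mass.shape))
        total_exit = sum(probs, np.zeros_like(mass))
        if np.any(total_exit > 1.0 + 1e-9):
            raise ProbabilityOverflowError(
                f"competing exits from {origin.value} sum above 1 after scaling"
            )
        for ex, p in zip(exits, probs):
            flow = mass * p
            bump(ex.event, float(flow.sum()))
            if ex.dest is TRANSPLANT:
                tx_mass += flow.sum(axis=1)
                tx_by_dur += flow.sum(axis=0)
            elif ex.dest in _L:  # lateral progression: stays listed
                lateral += flow
            else:
                new_unlisted[:, _U[ex.dest]] += flow.sum(axis=1)
                cens_by_dur += flow.sum(axis=0)
        stay[:, k, :] = mass * (1.0 - total_exit)
    stay[:, _L[HealthState.DIALYSIS_LISTED], :] += lateral

    # advance surviving listed mass one duration bucket (top bucket pools)
    new_listed[:, :, 1:] += stay[:, :, :-1]
    new_listed[:, :, -1] += stay[:, :, -1]

    # --- transplant resolution: perioperative death vs graft function -----
    periop = tx_mass * params["p_periop_death"]
    ev.periop_deaths = float(periop.sum())
    new_unlisted[:, _U[HealthState.DEAD]] += periop
    new_unlisted[:, _U[HealthState.GRAFT_FUNCTIONING]] += tx_mass - periop

    return Occupancy(new_unlisted, new_listed), ev, tx_by_dur, cens_by_dur


def run_model(
    occ0: Occupancy,
    params: MonthlyTransitionSet,
    scenario: ScenarioSpec = STATUS_QUO,
    horizon: int = 120,
    budget: OrganBudget | None = None,
) -> CohortTrace:
    """Run the cohort engine for ``horizon`` monthly cycles.

    The scenario's listing expansion is applied to the parameters here;
    its *initial-list* expansion must already be in ``occ0`` (see
    :func:`make_initial_occupancy`). ``budget`` carries the per-cycle
    transplant-count constraints for non-status-quo strategies.
    Deterministic: identical inputs give bit-identical traces.
    """
    if horizon < 0:
        raise ValidationError("horizon must be >= 0")
    params_eff = apply_list_expansion(params, scenario.list_factor)
    if budget is None:
        budget = OrganBudget()
    D = occ0.listed.shape[2]
    total0 = occ0.total
    occupancies = [occ0.copy()]
    events: list[EventCounts] = []
    tx_hist = np.zeros((horizon, D))
    cens_hist = np.zeros((horizon, D))
    occ = occ0
    for cycle in range(horizon):
        try:
            occ, ev, tx_d, cens_d = step_cycle(occ, params_eff, budget.for_cycle(cycle))
        except (ProbabilityOverflowError, ValidationError) as exc:
            raise EngineError(f"cycle {cycle + 1}: {exc}") from exc
        if abs(occ.total - total0) > 1e-9 * max(total0, 1.0):
            raise EngineError(
                f"cycle {cycle + 1}: occupancy not conserved "
                f"({occ.total!r} vs {total0!r})"
            )
        occupancies.append(occ.copy())
        events.append(ev)
        tx_hist[cycle] = tx_d
        cens_hist[cycle] = cens_d
    return CohortTrace(occupancies, events, tx_hist, cens_hist, scenario, params_eff)


def annual_counts(trace: CohortTrace, year: int) -> EventCounts:
    """Sum cycle-level events over the 12 cycles of ``year`` (1-based)."""
    if year < 1 or 12 * year > trace.horizon:
        raise ValidationError(
            f"year {year} outside the trace's {trace.horizon}-cycle horizon"
        )
    out = EventCounts()
    for ev in trace.events[12 * (year - 1): 12 * year]:
        out = out + ev
    return out
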