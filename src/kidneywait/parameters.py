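"""Domain types and parameter handling for the waiting-list cohort model.

The model follows a closed cohort of transplant-eligible adults (CKD with
eGFR <= 20 mL/min/1.73 m2, or ESKD on dialysis) through monthly cycles.
Patients belong to one of three age strata and occupy one of seven health
states. All transition probabilities are *monthly*; annual registry rates
are converted with the constant-hazard formula ``1 - (1 - p)**(1/12)``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "AgeStratum",
    "HealthState",
    "MonthlyTransitionSet",
    "CohortSpec",
    "AnnualTargets",
    "REGISTRY_2022",
    "PARAM_NAMES",
    "annual_to_monthly",
    "monthly_to_annual",
    "load_parameters",
    "save_parameters",
]


class AgeStratum(str, enum.Enum):
    """Closed age bands; patients outside 18-79 never enter the model."""

    Y18_44 = "18-44"
    Y45_64 = "45-64"
    Y65_79 = "65-79"


STRATA = tuple(AgeStratum)
N_STRATA = len(STRATA)


class HealthState(str, enum.Enum):
    CKD_UNLISTED = "CKD_UNLISTED"
    CKD_LISTED = "CKD_LISTED"
    DIALYSIS_UNLISTED = "DIALYSIS_UNLISTED"
    DIALYSIS_LISTED = "DIALYSIS_LISTED"
    REMOVED = "REMOVED"
    GRAFT_FUNCTIONING = "GRAFT_FUNCTIONING"
    DEAD = "DEAD"


LISTED_STATES = (HealthState.CKD_LISTED, HealthState.DIALYSIS_LISTED)

#: every monthly probability the model takes, one value per age stratum
PARAM_NAMES = (
    "p_progress",        # CKD -> dialysis
    "p_list_ckd",        # CKD addition to the waiting list
    "p_list_dialysis",   # dialysis addition to the waiting list
    "p_ldt_unlisted",    # off-list living-donor transplant
    "p_ldt_listed",      # on-list LDT; nonzero only under LDT expansion
    "p_ddt_listed",      # deceased-donor transplant while listed
    "p_removal",         # delisting without transplant
    "p_death_ckd",
    "p_death_dialysis",
    "p_death_listed",
    "p_death_removed",
    "p_death_posttx",
    "p_graft_failure",   # graft loss -> back to dialysis, relistable
    "p_periop_death",    # one-time probability applied at transplant
)

# competing exits that must sum to <= 1 for each origin state
_EXIT_GROUPS = {
    "CKD_UNLISTED": ("p_death_ckd", "p_progress", "p_list_ckd", "p_ldt_unlisted"),
    "DIALYSIS_UNLISTED": ("p_death_dialysis", "p_list_dialysis", "p_ldt_unlisted"),
    "CKD_LISTED": ("p_death_listed", "p_removal", "p_ddt_listed", "p_ldt_listed", "p_progress"),
    "DIALYSIS_LISTED": ("p_death_listed", "p_removal", "p_ddt_listed", "p_ldt_listed"),
    "REMOVED": ("p_death_removed",),
    "GRAFT_FUNCTIONING": ("p_death_posttx", "p_graft_failure"),
}


def annual_to_monthly(p_annual: float) -> float:
    """Convert an annual probability to the monthly probability with the
    same constant hazard: ``1 - (1 - p)**(1/12)``."""
    p = np.asarray(p_annual, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValidationError(f"annual probability outside [0, 1]: {p_annual!r}")
    out = 1.0 - (1.0 - p) ** (1.0 / 12.0)
    return float(out) if np.ndim(p_annual) == 0 else out


def monthly_to_annual(p_monthly: float) -> float:
    """Inverse of :func:`annual_to_monthly`: ``1 - (1 - p)**12``."""
    p = np.asarray(p_monthly, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValidationError(f"monthly probability outside [0, 1]: {p_monthly!r}")
    out = 1.0 - (1.0 - p) ** 12
    return float(out) if np.ndim(p_monthly) == 0 else out


@dataclass
class MonthlyTransitionSet:
    """Per-stratum monthly transition probabilities — the model's full
    parameter vector.

    ``values`` maps each name in :data:`PARAM_NAMES` to a float array of
    length 3 ordered like :data:`STRATA`.
    """

    values: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for name in PARAM_NAMES:
            if name not in self.values:
                raise ValidationError(f"missing parameter {name!r}")
            arr = np.asarray(self.values[name], dtype=float)
            if arr.shape != (N_STRATA,):
                raise ValidationError(
                    f"{name}: expected {N_STRATA} per-stratum values, got shape {arr.shape}"
                )
            clean[name] = arr
        extra = set(self.values) - set(PARAM_NAMES)
        if extra:
            raise ValidationError(f"unknown parameters: {sorted(extra)}")
        self.values = clean
        self.validate()

    def __getitem__(self, name: str) -> np.ndarray:
        return self.values[name]

    def validate(self) -> None:
        for name, arr in self.values.items():
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"{name}: non-finite value")
            for s, v in zip(STRATA, arr):
                if not (0.0 <= v <= 1.0):
                    raise ValidationError(
                        f"{name} [{s.value}] = {v} outside [0, 1]"
                    )
        for origin, names in _EXIT_GROUPS.items():
            total = sum(self.values[n] for n in names)
            for s, v in zip(STRATA, total):
                if v > 1.0 + 1e-12:
                    raise ValidationError(
                        f"competing exits from {origin} sum to {v:.6f} > 1 in stratum {s.value}"
                    )
        bad = self.values["p_death_removed"] < self.values["p_death_dialysis"] - 1e-12
        if np.any(bad):
            s = STRATA[int(np.argmax(bad))]
            raise ValidationError(
                f"p_death_removed < p_death_dialysis in stratum {s.value}; "
                "removal reflects deteriorating health"
            )

    def with_values(self, **updates: np.ndarray) -> "MonthlyTransitionSet":
        """Return a copy with the named parameters replaced (revalidated)."""
        new = {k: v.copy() for k, v in self.values.items()}
        for name, arr in updates.items():
            if name not in PARAM_NAMES:
                raise ValidationError(f"unknown parameter {name!r}")
            new[name] = np.broadcast_to(np.asarray(arr, dtype=float), (N_STRATA,)).copy()
        return MonthlyTransitionSet(new)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"stratum": s.value, "parameter": name, "value": float(arr[i])}
            for name, arr in self.values.items()
            for i, s in enumerate(STRATA)
        ]
        return pd.DataFrame(rows, columns=["stratum", "parameter", "value"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MonthlyTransitionSet":
        required = {"stratum", "parameter", "value"}
        if not required.issubset(df.columns):
            raise ValidationError(
                f"parameter table needs columns {sorted(required)}, got {list(df.columns)}"
            )
        labels = [s.value for s in STRATA]
        values: dict[str, np.ndarray] = {}
        for name, grp in df.groupby("parameter"):
            grp = grp.set_index("stratum")
            missing = [lab for lab in labels if lab not in grp.index]
            if missing:
                raise ValidationError(f"{name}: missing strata {missing}")
            vals = pd.to_numeric(grp.loc[labels, "value"], errors="coerce")
            if vals.isna().any():
                raise ValidationError(f"{name}: non-numeric value")
            values[str(name)] = vals.to_numpy(dtype=float)
        return cls(values)


def save_parameters(params: MonthlyTransitionSet, path) -> None:
    """Write a parameter set as diff-able CSV (stratum, parameter, value)."""
    params.to_frame().to_csv(path, index=False, float_format="%.17g")


def load_parameters(path) -> MonthlyTransitionSet:
    """Read and validate a parameter CSV written by :func:`save_parameters`."""
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ValidationError(f"cannot read parameter file {path}: {exc}") from exc
    return MonthlyTransitionSet.from_frame(df)


@dataclass(frozen=True)
class CohortSpec:
    """Closed-cohort definition: who is in the model at cycle 0.

    ``state_split`` maps ``(AgeStratum, HealthState)`` to the fraction of
    ``total_count`` starting in that cell; fractions sum to 1 and no mass
    starts DEAD or REMOVED.
    """

    total_count: float
    state_split: dict[tuple[AgeStratum, HealthState], float]
    horizon: int = 120
    cycle_length_months: int = field(default=1)

    def __post_init__(self) -> None:
        if self.total_count <= 0:
            raise ValidationError("total_count must be positive")
        if self.horizon < 0:
            raise ValidationError("horizon must be >= 0")
        if self.cycle_length_months != 1:
            raise ValidationError("cycle length is fixed at one month")
        total = 0.0
        for (s, st), frac in self.state_split.items():
            if frac < 0:
                raise ValidationError(f"negative split fraction for ({s}, {st})")
            if st in (HealthState.DEAD, HealthState.REMOVED) and frac > 0:
                raise ValidationError(f"no initial occupancy allowed in {st.value}")
            total += frac
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"state_split fractions sum to {total}, not 1")

    def counts(self) -> dict[tuple[AgeStratum, HealthState], float]:
        return {k: self.total_count * v for k, v in self.state_split.items()}


@dataclass(frozen=True)
class AnnualTargets:
    """Annual registry event totals used for calibration."""

    ddt: float
    ldt: float
    additions: float
    removals: float
    waitlist_deaths: float

    def __post_init__(self) -> None:
        for name in ("ddt", "ldt", "additions", "removals", "waitlist_deaths"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")

    def as_dict(self) -> dict[str, float]:
        return {
            "ddt": self.ddt,
            "ldt": self.ldt,
            "additions": self.additions,
            "removals": self.removals,
            "waitlist_deaths": self.waitlist_deaths,
        }


#: 2022 SRTR/USRDS annual totals for the US kidney waiting list
REGISTRY_2022 = AnnualTargets(
    ddt=19_944,
    ldt=5_660,
    additions=33_215,
    removals=6_040,
    waitlist_deaths=4_454,
)
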