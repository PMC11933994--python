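"""Wait-time estimation: pooled Kaplan-Meier product-limit curves.

Every listing spell — whether listed at model start, newly listed, or
relisted after graft failure — enters a common time-since-listing axis at
duration 0. Transplant (deceased-donor, plus on-list living-donor under LDT
expansion) is the event; death on the list, removal, and reaching the end
of the 10-year horizon censor. The product-limit estimator runs directly on
the cohort engine's expected (fractional) counts.

Month ``t`` on the risk-set axis is the t-th month spent on the list:
mass at duration ``t-1`` at a cycle start is at risk during month ``t``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import CohortTrace
from .errors import ValidationError

__all__ = [
    "RiskSetTable",
    "KMCurve",
    "WaitTimeSummary",
    "risk_set_from_trace",
    "km_product_limit",
    "percentile",
    "summarize",
]


@dataclass
class RiskSetTable:
    """Pooled life table over months since listing (month index 1..T)."""

    n: np.ndarray  # at risk entering month t
    d: np.ndarray  # transplant events during month t
    c: np.ndarray  # censorings during month t (deaths, removals, horizon end)

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        if not (self.n.shape == self.d.shape == self.c.shape) or self.n.ndim != 1:
            raise ValidationError("n, d, c must be 1-D arrays of equal length")
        if np.any(self.n < -1e-9) or np.any(self.d < -1e-9) or np.any(self.c < -1e-9):
            raise ValidationError("negative risk-set entry")
        if np.any(self.d > self.n + 1e-9):
            raise ValidationError("events exceed the at-risk count")
        drop = self.n[:-1] - self.d[:-1] - self.c[:-1]
        if np.any(np.abs(self.n[1:] - drop) > 1e-9 * np.maximum(self.n[:-1], 1.0)):
            raise ValidationError("risk set not consistent: n[t+1] != n[t] - d[t] - c[t]")

    def __len__(self) -> int:
        return len(self.n)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"month": np.arange(1, len(self) + 1), "n": self.n, "d": self.d, "c": self.c}
        )


@dataclass
class KMCurve:
    """Probability of still waiting, on a monthly grid starting at S(0)=1."""

    months: np.ndarray
    survival: np.ndarray

    def __post_init__(self) -> None:
        self.months = np.asarray(self.months, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        if self.months.shape != self.survival.shape:
            raise ValidationError("months and survival lengths differ")
        if len(self.survival) == 0 or self.survival[0] != 1.0:
            raise ValidationError("curve must start at S(0) = 1")
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValidationError("survival must be non-increasing")
        if np.any(self.survival < -1e-12) or np.any(self.survival > 1.0 + 1e-12):
            raise ValidationError("survival outside [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"month": self.months, "survival": self.survival})


@dataclass(frozen=True)
class WaitTimeSummary:
    """Median and quartiles of wait time, in months; None when the curve
    never reaches the corresponding quantile within the horizon (the
    'median not calculable' situation)."""

    median: float | None
    q25: float | None
    q75: float | None

    def __post_init__(self) -> None:
        vals = [v for v in (self.q25, self.median, self.q75) if v is not None]
        if vals != sorted(vals):
            raise ValidationError("quantiles out of order")


def risk_set_from_trace(trace: CohortTrace) -> RiskSetTable:
    """Pool every listing-entry cohort in the trace onto one
    time-since-listing axis.

    At-risk mass entering month t = listed occupancy at duration t-1 at the
    start of each cycle, summed over cycles and strata. Events and dynamic
    censorings come from the trace's duration-resolved flows; listed mass
    still present at the horizon is administratively censored in the month
    it last completed.
    """
    H = trace.horizon
    D = trace.occupancies[0].listed.shape[2]
    if H == 0:
        return RiskSetTable(np.zeros(0), np.zeros(0), np.zeros(0))
    # occupancy at the start of each of the H cycles, pooled over strata/list
    at_start = np.stack(
        [occ.listed.sum(axis=(0, 1)) for occ in trace.occupancies[:H]]
    )  # (H, D)
    n = at_start.sum(axis=0)            # n[t-1] = at risk during month t
    d = trace.tx_by_duration.sum(axis=0)
    c = trace.cens_by_duration.sum(axis=0)
    # horizon-end censoring: final mass at duration t completed month t last
    final = trace.occupancies[H].listed.sum(axis=(0, 1))
    c[: D - 1] += final[1:]
    T = int(max(np.max(np.nonzero(n)[0], initial=-1) + 1, 0))
    return RiskSetTable(n[:T], d[:T], c[:T])


def km_product_limit(table: RiskSetTable) -> KMCurve:
    """Product-limit estimator S(t) = prod_{u<=t} (1 - d_u/n_u); months
    with an empty risk set contribute factor 1."""
    with np.errstate(divide="ignore", invalid="ignore"):
        haz = np.where(table.n > 0, table.d / np.where(table.n > 0, table.n, 1.0), 0.0)
    surv = np.concatenate([[1.0], np.cumprod(1.0 - haz)])
    months = np.arange(len(table) + 1, dtype=float)
    return KMCurve(months, surv)


def percentile(curve: KMCurve, q: float, interpolate: bool = False) -> float | None:
    """Wait-time quantile: the smallest month t with S(t) <= 1 - q, or None
    if the curve never gets there within the horizon.

    With ``interpolate=True`` the crossing is located by linear
    interpolation between the bracketing monthly grid points, giving the
    sub-month resolution used in reported tables.
    """
    if not (0.0 < q < 1.0):
        raise ValidationError(f"quantile {q} outside (0, 1)")
    level = 1.0 - q
    below = np.nonzero(curve.survival <= level + 1e-12)[0]
    if len(below) == 0:
        return None
    i = int(below[0])
    if not interpolate or i == 0:
        return float(curve.months[i])
    s0, s1 = curve.survival[i - 1], curve.survival[i]
    if s0 == s1:
        return float(curve.months[i])
    frac = (s0 - level) / (s0 - s1)
    return float(curve.months[i - 1] + frac * (curve.months[i] - curve.months[i - 1]))


def summarize(curve: KMCurve, interpolate: bool = False) -> WaitTimeSummary:
    """Median wait time with IQR read off the product-limit curve."""
    return WaitTimeSummary(
        median=percentile(curve, 0.5, interpolate),
        q25=percentile(curve, 0.25, interpolate),
        q75=percentile(curve, 0.75, interpolate),
    )
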