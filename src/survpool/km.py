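"""Kaplan-Meier step functions, digitized curves and number-at-risk tables.

These are the in-memory forms of what a published KM figure provides: the
step curve itself, the coordinates a digitizer would read off it, and the
at-risk counts printed beneath it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

__all__ = [
    "StepFunction",
    "DigitizedCurve",
    "RiskTable",
    "km_estimate",
    "digitize_curve",
    "make_risk_table",
]


@dataclass(frozen=True)
class StepFunction:
    """Right-continuous survival step function.

    ``times`` are the drop locations (strictly increasing) and ``values`` the
    survival level from each drop onwards; the level is 1 before the first
    drop.
    """

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be 1-D and equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("step times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        if self.times.size == 0:  # no events anywhere
            out = np.ones_like(t)
            return out if out.ndim else 1.0
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx >= 0, self.values[np.clip(idx, 0, None)], 1.0)
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class DigitizedCurve:
    """One arm's digitized KM coordinates, ordered in time."""

    trial_id: str
    arm_id: str
    times: np.ndarray
    survival: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.survival, dtype=float)
        if t.size == 0:
            raise ValueError("digitized curve is empty")
        if np.any(np.diff(t) <= 0):
            raise ValueError("digitized times must be strictly increasing")
        if s[0] > 1.0 + 1e-12 or np.any(s < -1e-12) or np.any(s > 1.0 + 1e-12):
            raise ValueError("survival values must lie in [0, 1]")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "survival", np.clip(s, 0.0, 1.0))

    @property
    def is_monotone(self) -> bool:
        return bool(np.all(np.diff(self.survival) <= 1e-12))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial_id": self.trial_id,
                "arm_id": self.arm_id,
                "time_months": self.times,
                "survival": self.survival,
            }
        )


@dataclass(frozen=True)
class RiskTable:
    """Numbers at risk at scheduled times, starting at time 0.

    The count at a time is interpreted as the number at risk just before it,
    so a subject whose event falls exactly on a table time still counts.
    ``total_events`` is the published total event count, when reported.
    """

    trial_id: str
    arm_id: str
    times: np.ndarray
    n_risk: np.ndarray
    total_events: int | None = field(default=None)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        n = np.asarray(self.n_risk, dtype=int)
        if t.size == 0 or t[0] != 0:
            raise ValueError("risk table must start at time 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("risk-table times must be strictly increasing")
        if np.any(np.diff(n) > 0):
            raise ValueError("numbers at risk must be non-increasing over time")
        if np.any(n < 0):
            raise ValueError("numbers at risk must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "n_risk", n)

    @property
    def n_randomized(self) -> int:
        return int(self.n_risk[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial_id": self.trial_id,
                "arm_id": self.arm_id,
                "time_months": self.times,
                "n_risk": self.n_risk,
            }
        )


def km_estimate(ipd: pd.DataFrame) -> StepFunction:
    """Product-limit estimate of the survival function of one arm.

    ``ipd`` needs columns ``time_months`` and ``event``.  The result is the
    step function dropping at each distinct event time.
    """
    if len(ipd) == 0:
        raise ValueError("km_estimate requires at least one record")
    time = np.asarray(ipd["time_months"], dtype=float)
    if np.any(time <= 0):
        raise ValueError("km_estimate requires all times > 0")
    event = np.asarray(ipd["event"], dtype=int)
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    sf = kmf.survival_function_.iloc[:, 0]
    # keep only the drop points (distinct event times)
    vals = sf.to_numpy()
    times = sf.index.to_numpy(dtype=float)
    keep = np.concatenate([[False], np.diff(vals) < 0])
    return StepFunction(times=times[keep], values=vals[keep])


def digitize_curve(
    km: StepFunction,
    grid,
    trial_id: str = "synthetic",
    arm_id: str = "arm",
) -> DigitizedCurve:
    """Sample a KM step function on a digitization grid.

    Emulates reading coordinates off a published figure: the value recorded
    at each grid time is the step function's (right-continuous) level there.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("digitization grid is empty")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("digitization grid must be strictly increasing")
    if grid[0] < 0:
        raise ValueError("digitization grid must start at or after 0")
    return DigitizedCurve(
        trial_id=trial_id, arm_id=arm_id, times=grid, survival=km(grid)
    )


def make_risk_table(
    ipd: pd.DataFrame,
    times,
    trial_id: str = "synthetic",
    arm_id: str = "arm",
    total_events: int | None = None,
) -> RiskTable:
    """Tabulate numbers at risk at scheduled times (must start at 0)."""
    times = np.asarray(times, dtype=float)
    obs = np.asarray(ipd["time_months"], dtype=float)
    n_risk = (obs[None, :] >= times[:, None]).sum(axis=1)
    # everyone is at risk at time 0 regardless of ties at the origin
    n_risk[times == 0] = len(obs)
    return RiskTable(
        trial_id=trial_id,
        arm_id=arm_id,
        times=times,
        n_risk=n_risk,
        total_events=total_events,
    )
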