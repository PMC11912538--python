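"""Calendar-time survival data: cohorts, analysis snapshots, and
nonparametric estimators.

A trial observed at calendar time ``t`` induces administrative censoring:
a subject recruited at calendar time ``R`` contributes at most ``t - R``
units of follow-up.  The :class:`Cohort` holds the subject tuples
``(R, Z, T, C*)`` (entry, arm, event time, random-dropout time, the last
two on the trial-time scale); :func:`snapshot` truncates them to what is
observable at a given analysis date.  Kaplan-Meier and Nelson-Aalen
estimators operate on snapshots, with ties resolved by the standard
counting-process convention (events precede censorings; the risk set at
``s`` counts subjects with observed time >= ``s``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Cohort",
    "Snapshot",
    "StepFunction",
    "StepSurvival",
    "snapshot",
    "kaplan_meier",
    "nelson_aalen",
    "read_cohort_csv",
    "write_cohort_csv",
]


def _as_1d(a, name: str) -> np.ndarray:
    arr = np.asarray(a, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return arr


@dataclass(frozen=True)
class Cohort:
    """Subject-level trial data in calendar time.

    Parameters
    ----------
    entry_time : array of calendar entry times ``R_i >= 0``.
    group : array of arm indicators ``Z_i in {0, 1}`` (1 = experimental).
    event_time : array of event times ``T_i > 0`` since entry.  ``inf``
        encodes "no event observed within any horizon" and is how
        :meth:`from_observed` represents censored records.
    dropout_time : array of random-dropout times since entry; ``inf``
        means no random dropout (the default).
    """

    entry_time: np.ndarray
    group: np.ndarray
    event_time: np.ndarray
    dropout_time: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        entry = _as_1d(self.entry_time, "entry_time")
        grp = np.asarray(self.group)
        ev = _as_1d(self.event_time, "event_time")
        if self.dropout_time is None:
            drop = np.full(entry.shape, np.inf)
        else:
            drop = _as_1d(self.dropout_time, "dropout_time")
        if not (entry.shape == grp.shape == ev.shape == drop.shape):
            raise ValueError("all cohort columns must have the same length")
        if entry.size == 0:
            raise ValueError("empty cohort")
        if not np.all(np.isfinite(entry)) or np.any(entry < 0):
            raise ValueError("entry times must be finite and nonnegative")
        if np.any(ev <= 0) or np.any(np.isnan(ev)):
            raise ValueError("event times must be positive")
        if np.any(drop <= 0) or np.any(np.isnan(drop)):
            raise ValueError("dropout times must be positive (inf = none)")
        if not np.isin(grp, (0, 1)).all():
            raise ValueError("group must contain only 0/1")
        object.__setattr__(self, "entry_time", entry)
        object.__setattr__(self, "group", grp.astype(np.int8))
        object.__setattr__(self, "event_time", ev)
        object.__setattr__(self, "dropout_time", drop)

    @property
    def n(self) -> int:
        return self.entry_time.size

    @classmethod
    def from_observed(cls, entry, group, time, status) -> "Cohort":
        """Build a cohort from observed (possibly censored) records.

        ``status == 1`` rows carry the event at the recorded time;
        ``status == 0`` rows become a dropout at the recorded time, so that
        re-snapshotting at any earlier calendar date reproduces the correct
        administrative truncation.
        """
        time = _as_1d(time, "time")
        status = np.asarray(status)
        if not np.isin(status, (0, 1)).all():
            raise ValueError("status must contain only 0/1")
        ev = np.where(status == 1, time, np.inf)
        drop = np.where(status == 0, time, np.inf)
        return cls(entry, group, ev, drop)


@dataclass(frozen=True)
class Snapshot:
    """Data observable at one calendar analysis time.

    ``time`` is the observed follow-up ``X_i(t) = T_i ^ C*_i ^ (t - R_i)+``
    and ``status`` is 1 iff the event was observed by ``t``.  Only subjects
    with ``R_i <= t`` are included.
    """

    analysis_time: float
    time: np.ndarray
    status: np.ndarray
    group: np.ndarray

    @property
    def n(self) -> int:
        return self.time.size

    def group_mask(self, group) -> np.ndarray:
        if group == "pooled":
            return np.ones(self.n, dtype=bool)
        if group not in (0, 1):
            raise ValueError("group must be 0, 1 or 'pooled'")
        return self.group == group


@dataclass(frozen=True)
class StepFunction:
    """Right-continuous step function with jumps at ``x`` (increasing)."""

    x: np.ndarray
    y: np.ndarray
    y0: float

    def _eval(self, s, side):
        s = np.asarray(s, dtype=float)
        idx = np.searchsorted(self.x, s, side=side)
        vals = np.concatenate(([self.y0], self.y))
        out = vals[idx]
        return out if s.ndim else float(out)

    def __call__(self, s):
        return self._eval(s, "right")

    def left_limit(self, s):
        return self._eval(s, "left")


class StepSurvival(StepFunction):
    """Survival step function: starts at 1, nonincreasing."""


def snapshot(cohort: Cohort, t: float) -> Snapshot:
    """Truncate a cohort to the data observable at calendar time ``t``.

    Subjects with ``R_i > t`` are excluded; those with ``R_i == t`` are
    enrolled with zero follow-up and contribute to no statistic.
    """
    if t < 0:
        raise ValueError("analysis time must be nonnegative")
    mask = cohort.entry_time <= t
    entry = cohort.entry_time[mask]
    admin = np.maximum(t - entry, 0.0)
    ev = cohort.event_time[mask]
    cens = np.minimum(cohort.dropout_time[mask], admin)
    x = np.minimum(ev, cens)
    delta = (ev <= cens).astype(np.int8)
    return Snapshot(analysis_time=float(t), time=x, status=delta,
                    group=cohort.group[mask])


def _event_risk_table(time: np.ndarray, status: np.ndarray):
    """Distinct event times with event counts and risk-set sizes.

    Risk set ``Y(u)`` counts subjects with observed time >= ``u``; tied
    censored subjects therefore remain at risk for tied events.
    """
    d = status.astype(bool)
    if not d.any():
        return np.empty(0), np.empty(0), np.empty(0)
    et = np.unique(time[d])
    tsorted = np.sort(time)
    y = time.size - np.searchsorted(tsorted, et, side="left")
    te = np.sort(time[d])
    dcount = (np.searchsorted(te, et, side="right")
              - np.searchsorted(te, et, side="left"))
    return et, dcount.astype(float), y.astype(float)


def kaplan_meier(snap: Snapshot, group="pooled") -> StepSurvival:
    """Product-limit survival estimate on a snapshot."""
    mask = snap.group_mask(group)
    if not mask.any():
        raise ValueError(f"no subjects in group {group!r}")
    time, status = snap.time[mask], snap.status[mask]
    et, dcount, y = _event_risk_table(time, status)
    if et.size == 0:
        return StepSurvival(x=np.empty(0), y=np.empty(0), y0=1.0)
    return StepSurvival(x=et, y=np.cumprod(1.0 - dcount / y), y0=1.0)


def nelson_aalen(snap: Snapshot, group="pooled") -> StepFunction:
    """Nelson-Aalen cumulative-hazard estimate on a snapshot."""
    mask = snap.group_mask(group)
    if not mask.any():
        raise ValueError(f"no subjects in group {group!r}")
    time, status = snap.time[mask], snap.status[mask]
    et, dcount, y = _event_risk_table(time, status)
    if et.size == 0:
        return StepFunction(x=np.empty(0), y=np.empty(0), y0=0.0)
    return StepFunction(x=et, y=np.cumsum(dcount / y), y0=0.0)


def read_cohort_csv(path) -> Cohort:
    """Read a cohort from delimited text.

    Latent cohorts (simulator output) carry columns
    ``entry,group,time,status,dropout`` with ``time`` the true event time;
    observed data carry ``entry,group,time,status`` with ``time`` the
    recorded (possibly censored) follow-up.
    """
    df = pd.read_csv(path)
    required = {"entry", "group", "time", "status"}
    if not required.issubset(df.columns):
        missing = sorted(required - set(df.columns))
        raise ValueError(f"missing required columns: {missing}")
    if "dropout" in df.columns:
        return Cohort(df["entry"].to_numpy(), df["group"].to_numpy(),
                      df["time"].to_numpy(), df["dropout"].to_numpy())
    return Cohort.from_observed(df["entry"].to_numpy(),
                                df["group"].to_numpy(),
                                df["time"].to_numpy(),
                                df["status"].to_numpy())


def write_cohort_csv(cohort: Cohort, path) -> None:
    """Write a latent cohort (with dropout column) to CSV."""
    pd.DataFrame({
        "entry": cohort.entry_time,
        "group": cohort.group,
        "time": cohort.event_time,
        "status": np.isfinite(cohort.event_time).astype(int),
        "dropout": cohort.dropout_time,
    }).to_csv(path, index=False)
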