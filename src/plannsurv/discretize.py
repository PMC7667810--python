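"""Person-period (long-format) transformation of right-censored survival data.

Discrete-time survival models such as the partial logistic artificial
neural network (PLANN) operate on a longitudinal expansion of the usual
subject-level ``(time, event, covariates)`` table: follow-up is cut into
``k`` non-overlapping half-open intervals ``I_j = (tau_{j-1}, tau_j]`` and
each subject contributes one row per interval at risk, with a binary
target that is 1 only in the interval where the event occurred.  The
interval membership is encoded as ``k`` separate indicator columns so that
time itself enters the model as an input variable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SurvivalDataset",
    "IntervalGrid",
    "LongFormatData",
    "make_interval_grid",
    "interval_of",
    "to_long_train",
    "to_long_test",
    "censor_at",
]


@dataclass
class SurvivalDataset:
    """Subject-level right-censored survival data.

    Parameters
    ----------
    time:
        Non-negative follow-up times (years).
    event:
        Event indicator, 1 = event observed, 0 = right-censored.
    covariates:
        One column per (dummy-coded or continuous) covariate; no missing
        values (imputation is upstream of this package).
    ids:
        Subject identifiers; defaults to ``0..n-1``.
    group_map:
        Maps each covariate column to its parent variable, used to
        aggregate per-level importances back to the factor level.
        Defaults to the identity mapping.
    """

    time: np.ndarray
    event: np.ndarray
    covariates: pd.DataFrame
    ids: np.ndarray | None = None
    group_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if not isinstance(self.covariates, pd.DataFrame):
            self.covariates = pd.DataFrame(np.asarray(self.covariates))
            self.covariates.columns = [f"x{i}" for i in range(self.covariates.shape[1])]
        n = self.time.shape[0]
        if self.event.shape[0] != n or len(self.covariates) != n:
            raise ValueError("time, event and covariates must have equal length")
        if np.any(self.time < 0):
            raise ValueError("negative survival times are not allowed")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event indicator must be 0/1")
        if self.covariates.isna().any().any():
            raise ValueError("covariates contain missing values; impute upstream")
        if self.ids is None:
            self.ids = np.arange(n)
        else:
            self.ids = np.asarray(self.ids)
            if self.ids.shape[0] != n:
                raise ValueError("ids length mismatch")
        if not self.group_map:
            self.group_map = {c: c for c in self.covariates.columns}
        else:
            missing = set(self.covariates.columns) - set(self.group_map)
            extra = set(self.group_map) - set(self.covariates.columns)
            if missing or extra:
                raise ValueError(
                    f"group_map must cover every covariate exactly once "
                    f"(missing={sorted(missing)}, extra={sorted(extra)})"
                )
        self.covariates = self.covariates.reset_index(drop=True)

    @property
    def n(self) -> int:
        return self.time.shape[0]

    @property
    def covariate_names(self) -> list[str]:
        return list(self.covariates.columns)

    @property
    def event_rate(self) -> float:
        return float(self.event.mean())

    def subset(self, index: np.ndarray) -> "SurvivalDataset":
        """Row subset (positional indices); group_map is shared."""
        index = np.asarray(index)
        return SurvivalDataset(
            time=self.time[index],
            event=self.event[index],
            covariates=self.covariates.iloc[index].reset_index(drop=True),
            ids=self.ids[index],
            group_map=dict(self.group_map),
        )

    def drop_covariates(self, columns: Sequence[str]) -> "SurvivalDataset":
        keep = [c for c in self.covariates.columns if c not in set(columns)]
        return SurvivalDataset(
            time=self.time.copy(),
            event=self.event.copy(),
            covariates=self.covariates[keep].copy(),
            ids=self.ids.copy(),
            group_map={c: self.group_map[c] for c in keep},
        )

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"id": self.ids, "time": self.time, "event": self.event})
        return pd.concat([out, self.covariates], axis=1)

    def to_csv(self, path, sep: str = ",") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)

    @classmethod
    def from_csv(
        cls,
        path,
        sep: str = ",",
        id_col: str = "id",
        time_col: str = "time",
        event_col: str = "event",
        group_map: dict[str, str] | None = None,
    ) -> "SurvivalDataset":
        df = pd.read_csv(path, sep=sep)
        cov_cols = [c for c in df.columns if c not in (id_col, time_col, event_col)]
        return cls(
            time=df[time_col].to_numpy(),
            event=df[event_col].to_numpy(),
            covariates=df[cov_cols],
            ids=df[id_col].to_numpy() if id_col in df else None,
            group_map=group_map or {},
        )


@dataclass(frozen=True)
class IntervalGrid:
    """Ordered boundaries ``0 = tau_0 < tau_1 < ... < tau_k`` defining the
    half-open intervals ``I_j = (tau_{j-1}, tau_j]``."""

    boundaries: tuple[float, ...]

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        if b.ndim != 1 or b.shape[0] < 2:
            raise ValueError("need at least two boundaries (k >= 1)")
        if b[0] != 0:
            raise ValueError("first boundary must be 0")
        if np.any(np.diff(b) <= 0):
            raise ValueError("boundaries must be strictly increasing")
        object.__setattr__(self, "boundaries", tuple(float(x) for x in b))

    @property
    def k(self) -> int:
        return len(self.boundaries) - 1

    @property
    def upper(self) -> float:
        return self.boundaries[-1]

    @property
    def midpoints(self) -> np.ndarray:
        b = np.asarray(self.boundaries)
        return (b[:-1] + b[1:]) / 2.0

    def interval_of(self, time):
        return interval_of(time, self)


def make_interval_grid(max_time, k: int | None = None) -> IntervalGrid:
    """Equal-width grid ``tau_j = j * max_time / k``.

    Passing a sequence as the first argument instead builds the grid from
    those explicit boundaries.
    """
    if np.ndim(max_time) == 1:  # explicit boundary list
        return IntervalGrid(tuple(np.asarray(max_time, dtype=float)))
    if k is None:
        raise TypeError("k is required for an equal-width grid")
    max_time = float(max_time)
    if max_time <= 0 or k < 1:
        raise ValueError("max_time must be positive and k >= 1")
    return IntervalGrid(tuple(np.arange(k + 1) * max_time / k))


def interval_of(time, grid: IntervalGrid):
    """1-based index j with ``tau_{j-1} < time <= tau_j`` (right-closed)."""
    t = np.asarray(time, dtype=float)
    if np.any(t <= 0) or np.any(t > grid.upper):
        raise ValueError(
            f"times must lie in (0, {grid.upper}]; censor at the horizon first"
        )
    idx = np.searchsorted(np.asarray(grid.boundaries), t, side="left")
    return int(idx) if np.ndim(time) == 0 else idx.astype(int)


def censor_at(data: SurvivalDataset, horizon: float) -> SurvivalDataset:
    """Administrative censoring: follow-up beyond ``horizon`` is truncated
    (time set to the horizon, event set to censored)."""
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    over = data.time > horizon
    time = np.where(over, horizon, data.time)
    event = np.where(over, 0, data.event)
    return replace(data, time=time, event=event,
                   covariates=data.covariates.copy(), ids=data.ids.copy(),
                   group_map=dict(data.group_map))


@dataclass
class LongFormatData:
    """Person-period rows: one row per subject per interval at risk
    (training role) or per every interval (test role).

    ``frame`` columns: ``subject_id``, ``interval`` plus the covariates,
    the k interval-indicator columns ``interval_1..interval_k`` (exactly
    one hot per row) and, for the training role, the binary ``target``.
    """

    frame: pd.DataFrame
    role: str
    k: int
    covariate_names: list[str]
    time_encoding: str = "onehot"

    @property
    def indicator_names(self) -> list[str]:
        return [f"interval_{j}" for j in range(1, self.k + 1)]

    @property
    def feature_names(self) -> list[str]:
        if self.time_encoding == "onehot":
            return self.covariate_names + self.indicator_names
        return self.covariate_names + ["interval_midpoint"]

    @property
    def n_subjects(self) -> int:
        return self.frame["subject_id"].nunique()

    def features(self) -> np.ndarray:
        return self.frame[self.feature_names].to_numpy(dtype=float)

    def targets(self) -> np.ndarray:
        if self.role != "train":
            raise ValueError("targets are only defined for the training role")
        return self.frame["target"].to_numpy(dtype=float)

    def to_csv(self, path, sep: str = ",") -> None:
        self.frame.to_csv(path, sep=sep, index=False)


def _expand(
    data: SurvivalDataset,
    grid: IntervalGrid,
    n_rows: np.ndarray,
    role: str,
    time_encoding: str,
) -> pd.DataFrame:
    reps = np.repeat(np.arange(data.n), n_rows)
    intervals = (
        np.concatenate([np.arange(1, m + 1) for m in n_rows])
        if len(n_rows) else np.array([], dtype=int)
    )
    frame = pd.DataFrame({"subject_id": data.ids[reps], "interval": intervals})
    cov = data.covariates.iloc[reps].reset_index(drop=True)
    frame = pd.concat([frame, cov], axis=1)
    if time_encoding == "onehot":
        onehot = np.zeros((len(frame), grid.k))
        onehot[np.arange(len(frame)), intervals - 1] = 1.0
        for j in range(grid.k):
            frame[f"interval_{j + 1}"] = onehot[:, j]
    elif time_encoding == "midpoint":
        frame["interval_midpoint"] = grid.midpoints[intervals - 1]
    else:
        raise ValueError("time_encoding must be 'onehot' or 'midpoint'")
    return frame


def to_long_train(
    data: SurvivalDataset,
    grid: IntervalGrid,
    censored_partial: str = "include",
    time_encoding: str = "onehot",
) -> LongFormatData:
    """Expand training data: a subject observed up to interval m yields
    rows for intervals 1..m with target 0 everywhere except (for events)
    the final row.

    ``censored_partial`` controls the convention for subjects censored
    strictly inside interval m: ``"include"`` (default) keeps the partial
    row m with target 0; ``"drop"`` keeps only rows 1..m-1.
    """
    if censored_partial not in ("include", "drop"):
        raise ValueError("censored_partial must be 'include' or 'drop'")
    if np.any(data.time > grid.upper):
        raise ValueError(
            "some times exceed the grid horizon; apply censor_at(data, horizon) first"
        )
    if np.any(data.time <= 0):
        raise ValueError("non-positive survival times cannot be discretized")
    m = interval_of(data.time, grid)
    n_rows = m.copy()
    if censored_partial == "drop":
        partial = (data.event == 0) & (data.time < np.asarray(grid.boundaries)[m])
        n_rows = np.where(partial, m - 1, m)
    keep = n_rows > 0
    sub = data.subset(np.flatnonzero(keep)) if not keep.all() else data
    n_rows_kept = n_rows[keep]
    frame = _expand(sub, grid, n_rows_kept, "train", time_encoding)
    # event in the subject's final interval -> 1 on the last row only
    last_row = np.cumsum(n_rows_kept) - 1
    target = np.zeros(len(frame))
    target[last_row[sub.event == 1]] = 1.0
    frame["target"] = target
    return LongFormatData(frame, "train", grid.k, data.covariate_names, time_encoding)


def to_long_test(
    data: SurvivalDataset,
    grid: IntervalGrid,
    time_encoding: str = "onehot",
) -> LongFormatData:
    """Expand test data: every subject yields exactly k rows (all intervals),
    so the model can be queried for a full hazard profile."""
    n_rows = np.full(data.n, grid.k, dtype=int)
    frame = _expand(data, grid, n_rows, "test", time_encoding)
    return LongFormatData(frame, "test", grid.k, data.covariate_names, time_encoding)
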