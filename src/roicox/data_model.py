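"""Survival-data containers, CSV I/O, and the preprocessing / QC operators.

A *task* is one cohort with one time-to-event outcome: a feature matrix
``X`` (n patients x p features), event/censoring times ``t`` in days, and
status indicators ``e`` (1 = event observed, 0 = censored).  A *paired*
task carries a second, related outcome (auxiliary time/status) on the same
patients; the auxiliary outcome is used during training only.

The CSV layout is ``sample_id, <feature...>, time, event[, time_aux,
event_aux]`` with a header row; missing feature values may be encoded as
empty cells or ``NA``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    ConfigurationError,
    EmptyResultError,
    ParseError,
    ShapeError,
    ValidationError,
)

__all__ = [
    "SurvivalTask",
    "PairedSurvivalTask",
    "TaskQCReport",
    "read_survival_csv",
    "write_survival_csv",
    "filter_missing",
    "standardize",
    "select_top_mad",
    "qc_task",
]

_NA_VALUES = ["", "NA"]


def _check_outcome(t: np.ndarray, e: np.ndarray, n: int, label: str) -> None:
    if t.shape != (n,) or e.shape != (n,):
        raise ShapeError(f"{label}: time/status vectors must have length {n}")
    if not np.all(np.isfinite(t)) or np.any(t <= 0):
        raise ValidationError(f"{label}: all times must be finite and strictly positive")
    if not np.all(np.isin(e, (0, 1))):
        raise ValidationError(f"{label}: status indicators must be 0 or 1")


@dataclass
class SurvivalTask:
    """One cohort with one outcome.

    ``X`` may contain NaN immediately after reading raw data; run
    :func:`filter_missing` (and optionally :func:`standardize`) before
    fitting — the fitters reject non-finite features.
    """

    sample_ids: list
    X: np.ndarray
    t: np.ndarray
    e: np.ndarray
    name: str = "task"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        self.e = np.asarray(self.e, dtype=int)
        if self.X.ndim != 2:
            raise ShapeError("X must be a 2-D matrix")
        n = self.X.shape[0]
        if len(self.sample_ids) != n:
            raise ShapeError("sample_ids length must match number of rows of X")
        _check_outcome(self.t, self.e, n, self.name)

    @property
    def n_patients(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def n_events(self) -> int:
        return int(self.e.sum())

    def subset(self, idx: Sequence[int], name: str | None = None) -> "SurvivalTask":
        idx = np.asarray(idx)
        return SurvivalTask(
            sample_ids=[self.sample_ids[i] for i in idx],
            X=self.X[idx],
            t=self.t[idx],
            e=self.e[idx],
            name=name or self.name,
        )


@dataclass
class PairedSurvivalTask:
    """A cohort with a primary and an auxiliary outcome sharing the same X."""

    base: SurvivalTask
    t_aux: np.ndarray
    e_aux: np.ndarray

    def __post_init__(self) -> None:
        self.t_aux = np.asarray(self.t_aux, dtype=float)
        self.e_aux = np.asarray(self.e_aux, dtype=int)
        _check_outcome(self.t_aux, self.e_aux, self.base.n_patients, "auxiliary outcome")

    @property
    def X(self) -> np.ndarray:
        return self.base.X

    @property
    def n_patients(self) -> int:
        return self.base.n_patients

    def aux_task(self, name: str | None = None) -> SurvivalTask:
        """The auxiliary outcome viewed as a stand-alone task."""
        return SurvivalTask(
            sample_ids=list(self.base.sample_ids),
            X=self.base.X,
            t=self.t_aux,
            e=self.e_aux,
            name=name or f"{self.base.name}_aux",
        )

    def swapped(self) -> "PairedSurvivalTask":
        """Exchange the roles of the primary and auxiliary outcomes."""
        return PairedSurvivalTask(
            base=self.aux_task(name=f"{self.base.name}_swapped"),
            t_aux=self.base.t,
            e_aux=self.base.e,
        )

    def subset(self, idx: Sequence[int]) -> "PairedSurvivalTask":
        idx = np.asarray(idx)
        return PairedSurvivalTask(
            base=self.base.subset(idx), t_aux=self.t_aux[idx], e_aux=self.e_aux[idx]
        )


@dataclass
class TaskQCReport:
    """Cohort-level quality-control summary used to filter weak tasks."""

    n_patients: int
    n_events: int
    n_censored: int
    ec_ratio: float
    passed: bool

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        if np.isinf(d["ec_ratio"]):
            d["ec_ratio"] = None  # JSON has no Infinity
        return json.dumps(d)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_survival_csv(
    path: str | Path,
    primary_cols: tuple[str, str] = ("time", "event"),
    aux_cols: tuple[str, str] | None = None,
    id_col: str = "sample_id",
) -> SurvivalTask | PairedSurvivalTask:
    """Read a survival table; returns a paired task when ``aux_cols`` is given.

    Every column other than the identifier and outcome columns is treated
    as a numeric feature; the column order of the file is preserved.
    """
    path = Path(path)
    df = pd.read_csv(
        path, na_values=_NA_VALUES, keep_default_na=False, float_precision="round_trip"
    )
    outcome_cols = list(primary_cols) + (list(aux_cols) if aux_cols else [])
    missing = [c for c in outcome_cols if c not in df.columns]
    if missing:
        raise ConfigurationError(f"{path}: missing required columns {missing}")

    if id_col in df.columns:
        sample_ids = df[id_col].tolist()
    else:
        sample_ids = list(range(len(df)))

    feature_cols = [c for c in df.columns if c != id_col and c not in outcome_cols]
    feats = pd.DataFrame(index=df.index)
    for col in feature_cols:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"{path}: non-numeric feature value {df[col].iloc[row]!r} "
                f"at row {row}, column {col!r}"
            )
        feats[col] = converted

    def outcome(tc: str, ec: str) -> tuple[np.ndarray, np.ndarray]:
        t = pd.to_numeric(df[tc], errors="coerce").to_numpy(float)
        e = pd.to_numeric(df[ec], errors="coerce").to_numpy(float)
        if np.isnan(t).any() or np.isnan(e).any():
            raise ValidationError(f"{path}: missing values in outcome columns {tc}/{ec}")
        return t, e.astype(int)

    t, e = outcome(*primary_cols)
    base = SurvivalTask(
        sample_ids=sample_ids, X=feats.to_numpy(float), t=t, e=e, name=path.stem
    )
    if aux_cols is None:
        return base
    t_aux, e_aux = outcome(*aux_cols)
    return PairedSurvivalTask(base=base, t_aux=t_aux, e_aux=e_aux)


def write_survival_csv(
    task: SurvivalTask | PairedSurvivalTask,
    path: str | Path,
    feature_names: Sequence[str] | None = None,
) -> None:
    """Write the standard survival CSV; inverse of :func:`read_survival_csv`."""
    base = task.base if isinstance(task, PairedSurvivalTask) else task
    p = base.n_features
    names = list(feature_names) if feature_names is not None else [f"f{j}" for j in range(p)]
    if len(names) != p:
        raise ShapeError("feature_names length must equal the number of features")
    df = pd.DataFrame(base.X, columns=names)
    df.insert(0, "sample_id", base.sample_ids)
    df["time"] = base.t
    df["event"] = base.e
    if isinstance(task, PairedSurvivalTask):
        df["time_aux"] = task.t_aux
        df["event_aux"] = task.e_aux
    # shortest-repr floats round-trip bitwise through a correct parser
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Preprocessing operators
# ---------------------------------------------------------------------------

def filter_missing(
    X_raw: np.ndarray, sample_threshold: float = 0.2
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Drop heavily-missing rows, then any column still containing a missing value.

    Rows whose fraction of missing entries exceeds ``sample_threshold`` are
    removed first; columns with any remaining missing value are removed
    second, so the result is complete.  Returns the clean matrix plus the
    kept row and column indices into ``X_raw``.
    """
    if not 0 <= sample_threshold <= 1:
        raise ConfigurationError("sample_threshold must lie in [0, 1]")
    X_raw = np.asarray(X_raw, dtype=float)
    miss = np.isnan(X_raw)
    row_frac = miss.mean(axis=1) if X_raw.shape[1] else np.zeros(X_raw.shape[0])
    rows = np.flatnonzero(row_frac <= sample_threshold)
    if rows.size == 0:
        raise EmptyResultError("missingness filter removed every row")
    cols = np.flatnonzero(~miss[rows].any(axis=0))
    if cols.size == 0:
        raise EmptyResultError("missingness filter removed every column")
    return X_raw[np.ix_(rows, cols)], rows, cols


def standardize(
    X_train: np.ndarray, X_apply: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None, tuple[np.ndarray, np.ndarray]]:
    """Center and scale to unit variance using *training* statistics only.

    Uses the population variance convention (divide by n).  Constant
    columns are mapped to zero with a unit scale so no division by zero
    occurs.  ``X_apply`` (e.g. a held-out fold) is transformed with the
    training means/scales.
    """
    X_train = np.asarray(X_train, dtype=float)
    if X_train.size == 0:
        raise ShapeError("X_train must be nonempty")
    mean = X_train.mean(axis=0)
    scale = X_train.std(axis=0)  # population std
    scale = np.where(scale == 0, 1.0, scale)
    Xt = (X_train - mean) / scale
    Xa = None
    if X_apply is not None:
        X_apply = np.asarray(X_apply, dtype=float)
        if X_apply.shape[1] != X_train.shape[1]:
            raise ShapeError(
                f"feature-count mismatch: train has {X_train.shape[1]}, "
                f"apply has {X_apply.shape[1]}"
            )
        Xa = (X_apply - mean) / scale
    return Xt, Xa, (mean, scale)


def select_top_mad(X: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Keep the ``k`` columns with the largest mean absolute deviation.

    MAD here is the mean of |x - column mean| — an unsupervised variability
    ranking that never looks at the outcome.  Ties break toward the lower
    column index and the original relative column order is preserved.
    """
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    if k > p:
        raise ConfigurationError(f"k={k} exceeds the number of features p={p}")
    mad = np.mean(np.abs(X - X.mean(axis=0)), axis=0)
    # stable sort on -mad: equal MADs keep ascending column order
    ranked = np.argsort(-mad, kind="stable")[:k]
    cols = np.sort(ranked)
    return X[:, cols], cols


def qc_task(
    task: SurvivalTask,
    min_patients: int = 50,
    min_events: int = 20,
    min_ec: float = 0.2,
) -> TaskQCReport:
    """Cohort quality control: enough patients, enough events, high enough E/C.

    The events-to-censored ratio with zero censored patients is +inf and
    passes the E/C criterion.
    """
    n = task.n_patients
    n_ev = task.n_events
    n_cen = n - n_ev
    ec = float(n_ev) / n_cen if n_cen > 0 else float("inf")
    passed = (n >= min_patients) and (n_ev >= min_events) and (ec >= min_ec)
    return TaskQCReport(
        n_patients=n, n_events=n_ev, n_censored=n_cen, ec_ratio=ec, passed=passed
    )
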