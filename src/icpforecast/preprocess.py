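"""Turn raw minute-resolution ICP streams into discretized interval features.

The forecasting model works on 10-minute intervals. Each interval carries two
summaries of the minute samples inside it:

* ``mean_icp`` — the mean ICP, which defines the binary *response* class
  (1: mean < 20 mmHg, 2: mean >= 20 mmHg);
* ``q3_icp`` — the third quartile, which defines the three-level *predictor*
  code (1: Q3 < 15, 2: 15 <= Q3 < 20, 3: Q3 >= 20 mmHg).

A prediction window pairs the predictor levels of six consecutive intervals
(one hour of history) with the response class of an interval one to six steps
ahead. This module builds those windows and never lets one span a long
recording gap or a patient boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MinuteSeries",
    "CsvDialect",
    "WindowedDataset",
    "load_minute_series",
    "clean_series",
    "make_intervals",
    "make_windows",
    "discretize_q3",
    "INTERVAL_COLUMNS",
    "WINDOW_META_COLUMNS",
]

#: Minutes per interval; the model's native time step.
INTERVAL_MINUTES = 10

#: Columns of an interval table (one row per 10-min bin, 0-based indices).
INTERVAL_COLUMNS = [
    "patient_id",
    "interval_index",
    "mean_icp",
    "q3_icp",
    "q3_level",
    "response_class",
    "valid",
]

#: Non-lag columns of a window frame.
WINDOW_META_COLUMNS = ["patient_id", "anchor", "horizon", "y"]

_PLAUSIBLE_ICP = (-10.0, 150.0)


@dataclass(frozen=True)
class CsvDialect:
    """Column naming and missing-value convention for minute-level CSV files."""

    patient_col: str = "patient_id"
    minute_col: str = "minute"
    icp_col: str = "icp"
    sep: str = ","
    missing_tokens: tuple[str, ...] = ("", "NA", "NaN", "nan")


@dataclass(frozen=True)
class MinuteSeries:
    """One patient's minute-resolution ICP stream.

    ``minutes`` is a strictly increasing integer index; ``icp`` holds mmHg
    values with ``NaN`` marking missing minutes. Values outside a physically
    plausible band (−10..150 mmHg) only raise a warning — probe drift and
    drainage events do produce odd readings.
    """

    patient_id: str
    minutes: np.ndarray
    icp: np.ndarray

    def __post_init__(self) -> None:
        minutes = np.asarray(self.minutes, dtype=np.int64)
        icp = np.asarray(self.icp, dtype=float)
        if minutes.shape != icp.shape or minutes.ndim != 1:
            raise ValueError("minutes and icp must be 1-D arrays of equal length")
        if minutes.size and np.any(np.diff(minutes) <= 0):
            bad = minutes[1:][np.diff(minutes) <= 0][0]
            raise ValueError(
                f"minutes must be strictly increasing (violation at minute {bad}"
                f" for patient {self.patient_id!r})"
            )
        if np.any(np.isinf(icp)):
            raise ValueError("icp must be finite where not missing")
        observed = icp[~np.isnan(icp)]
        if observed.size and (
            observed.min() < _PLAUSIBLE_ICP[0] or observed.max() > _PLAUSIBLE_ICP[1]
        ):
            warnings.warn(
                f"patient {self.patient_id!r}: ICP values outside the plausible "
                f"range {_PLAUSIBLE_ICP} mmHg",
                stacklevel=2,
            )
        object.__setattr__(self, "minutes", minutes)
        object.__setattr__(self, "icp", icp)

    def __len__(self) -> int:
        return int(self.minutes.size)


@dataclass
class WindowedDataset:
    """Lagged predictor/response pairs ready for model fitting.

    ``frame`` has one row per (anchor interval, horizon) with columns
    ``patient_id, anchor, horizon, y, x1..x{d1}``. Lag columns are ordered
    oldest to newest: ``x1`` is the interval ``d1 - 1`` steps before the
    anchor and ``x{d1}`` is the anchor itself. Levels are floats so that
    ``NaN`` can mark a missing lag at prediction time; training rows are
    always fully observed.
    """

    frame: pd.DataFrame
    d1: int = 6
    m: int = 6

    def __post_init__(self) -> None:
        expected = WINDOW_META_COLUMNS + self.lag_columns
        missing = [c for c in expected if c not in self.frame.columns]
        if missing:
            raise ValueError(f"window frame is missing columns {missing}")
        self.frame = self.frame[expected].reset_index(drop=True)

    @property
    def lag_columns(self) -> list[str]:
        return [f"x{j}" for j in range(1, self.d1 + 1)]

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def horizons(self) -> np.ndarray:
        return np.sort(self.frame["horizon"].unique())

    def rows_for_horizon(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(X, y)`` for horizon ``k``: levels as floats, classes as ints."""
        sub = self.frame[self.frame["horizon"] == k]
        X = sub[self.lag_columns].to_numpy(dtype=float)
        y = sub["y"].to_numpy(dtype=int)
        return X, y

    def subset_anchors(self, keep: pd.DataFrame) -> "WindowedDataset":
        """Restrict to the (patient_id, anchor) pairs listed in ``keep``."""
        merged = self.frame.merge(keep[["patient_id", "anchor"]], on=["patient_id", "anchor"])
        return WindowedDataset(merged, d1=self.d1, m=self.m)

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "WindowedDataset":
        frame = pd.read_csv(path)
        lag_cols = [c for c in frame.columns if c.startswith("x")]
        d1 = len(lag_cols)
        m = int(frame["horizon"].max()) if len(frame) else 0
        return cls(frame, d1=d1, m=max(m, 1))

    @classmethod
    def concat(cls, parts: list["WindowedDataset"]) -> "WindowedDataset":
        if not parts:
            raise ValueError("no datasets to concatenate")
        d1, m = parts[0].d1, parts[0].m
        if any(p.d1 != d1 or p.m != m for p in parts):
            raise ValueError("cannot concatenate datasets with differing d1 or m")
        frame = pd.concat([p.frame for p in parts], ignore_index=True)
        return cls(frame, d1=d1, m=m)


def load_minute_series(
    path: str | Path, dialect: CsvDialect | None = None
) -> list[MinuteSeries]:
    """Read a delimited minute-level file into one :class:`MinuteSeries` per patient.

    Rows are sorted by minute within each patient; a duplicated minute index is
    an error naming the offending patient and minute, and a non-numeric ICP
    cell (other than a configured missing token) is an error naming its row.
    """
    dialect = dialect or CsvDialect()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(
        path,
        sep=dialect.sep,
        dtype=str,
        keep_default_na=False,
        skipinitialspace=True,
    )
    if raw.empty:
        raise ValueError(f"{path}: file contains no data rows")
    for col in (dialect.patient_col, dialect.minute_col, dialect.icp_col):
        if col not in raw.columns:
            raise ValueError(f"{path}: required column {col!r} not found")

    icp_str = raw[dialect.icp_col].str.strip()
    is_missing = icp_str.isin(dialect.missing_tokens)
    icp = pd.to_numeric(icp_str.where(~is_missing), errors="coerce")
    bad = (~is_missing) & icp.isna()
    if bad.any():
        # +2: header line plus 1-based file numbering
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise ValueError(f"{path}: unparseable ICP value on line {row}: {icp_str[bad].iloc[0]!r}")
    minute = pd.to_numeric(raw[dialect.minute_col], errors="coerce")
    if minute.isna().any():
        row = int(np.flatnonzero(minute.isna().to_numpy())[0]) + 2
        raise ValueError(f"{path}: unparseable minute index on line {row}")

    table = pd.DataFrame(
        {
            "patient": raw[dialect.patient_col].str.strip(),
            "minute": minute.astype(np.int64),
            "icp": icp.astype(float),
        }
    )
    out: list[MinuteSeries] = []
    for pid, grp in table.groupby("patient", sort=True):
        grp = grp.sort_values("minute")
        dup = grp["minute"].duplicated()
        if dup.any():
            raise ValueError(
                f"{path}: duplicate minute {int(grp['minute'][dup].iloc[0])} "
                f"for patient {pid!r}"
            )
        out.append(
            MinuteSeries(
                patient_id=str(pid),
                minutes=grp["minute"].to_numpy(),
                icp=grp["icp"].to_numpy(),
            )
        )
    return out


def _contiguous(s: MinuteSeries) -> MinuteSeries:
    """Re-express the series on a contiguous minute grid, absent minutes as NaN."""
    if len(s) == 0:
        return s
    first, last = int(s.minutes[0]), int(s.minutes[-1])
    grid = np.arange(first, last + 1, dtype=np.int64)
    icp = np.full(grid.size, np.nan)
    icp[s.minutes - first] = s.icp
    return MinuteSeries(s.patient_id, grid, icp)


def clean_series(s: MinuteSeries, max_gap_minutes: int = 2) -> MinuteSeries:
    """Interpolate short recording dropouts; leave long gaps missing.

    Missing runs of at most ``max_gap_minutes`` with observed neighbours on
    both sides are filled by linear interpolation (a stand-in for the brief
    probe-handling artifacts that minute-level data still carries). Longer
    runs stay missing and will later invalidate their intervals, which breaks
    any prediction window across them. The returned series lives on a
    contiguous minute grid; the input is untouched.
    """
    s = _contiguous(s)
    icp = s.icp.copy()
    missing = np.isnan(icp)
    if missing.all():
        warnings.warn(
            f"patient {s.patient_id!r}: series is entirely missing; returned unchanged",
            stacklevel=2,
        )
        return s
    if not missing.any():
        return s

    # run-length encode the missing mask; fill only short interior runs
    edges = np.flatnonzero(np.diff(np.concatenate(([0], missing.view(np.int8), [0]))))
    starts, stops = edges[::2], edges[1::2]
    interp = pd.Series(icp).interpolate(method="linear", limit_area="inside").to_numpy()
    for a, b in zip(starts, stops):
        if (b - a) <= max_gap_minutes and a > 0 and b < icp.size:
            icp[a:b] = interp[a:b]
    return replace(s, icp=icp)


def discretize_q3(q3_icp: np.ndarray, thresholds: tuple[float, float] = (15.0, 20.0)) -> np.ndarray:
    """Map third-quartile ICP (mmHg) to predictor levels {1, 2, 3}.

    Level 1: Q3 < 15; level 2: 15 <= Q3 < 20; level 3: Q3 >= 20. Boundary
    values belong to the upper level. NaN input yields 0 (no level).
    """
    q3 = np.asarray(q3_icp, dtype=float)
    lo, hi = thresholds
    if not lo < hi:
        raise ValueError("thresholds must be strictly increasing")
    level = np.where(q3 < lo, 1, np.where(q3 < hi, 2, 3))
    return np.where(np.isnan(q3), 0, level).astype(int)


def make_intervals(
    s: MinuteSeries,
    *,
    min_samples: int = 8,
    thresholds: tuple[float, float] = (15.0, 20.0),
    response_threshold: float = 20.0,
    quantile_method: str = "linear",
) -> pd.DataFrame:
    """Bin a (cleaned) series into consecutive 10-minute intervals.

    Bins start at the patient's first recorded minute; the interval count is
    ``floor(span / 10)``. Per bin, the mean and third quartile are computed
    over non-missing minutes (``quantile_method`` is handed to
    :func:`numpy.quantile`; the default linear interpolation is the usual
    "type 7" convention, which matters with only 10 samples). Bins with fewer
    than ``min_samples`` observed minutes are marked invalid.
    """
    if not 1 <= min_samples <= INTERVAL_MINUTES:
        raise ValueError("min_samples must be in 1..10")
    s = _contiguous(s)
    n_bins = len(s) // INTERVAL_MINUTES
    rows = []
    for i in range(n_bins):
        chunk = s.icp[i * INTERVAL_MINUTES : (i + 1) * INTERVAL_MINUTES]
        obs = chunk[~np.isnan(chunk)]
        if obs.size:
            mean_icp = float(obs.mean())
            q3_icp = float(np.quantile(obs, 0.75, method=quantile_method))
        else:
            mean_icp = q3_icp = np.nan
        rows.append(
            {
                "patient_id": s.patient_id,
                "interval_index": i,
                "mean_icp": mean_icp,
                "q3_icp": q3_icp,
                "q3_level": int(discretize_q3(np.array([q3_icp]), thresholds)[0]),
                "response_class": (
                    0 if np.isnan(mean_icp) else (2 if mean_icp >= response_threshold else 1)
                ),
                "valid": bool(obs.size >= min_samples),
            }
        )
    return pd.DataFrame(rows, columns=INTERVAL_COLUMNS)


def make_windows(
    intervals: pd.DataFrame, d1: int = 6, m: int = 6
) -> WindowedDataset:
    """Assemble lagged prediction windows from one or more interval tables.

    A row is emitted for every anchor interval ``t`` that closes a run of
    ``d1`` consecutive valid intervals, and every horizon ``k`` in ``1..m``
    whose response interval ``t + k`` exists and is valid. Windows never span
    invalid intervals or patient boundaries, so the output is invariant to the
    ordering of patients in the input.
    """
    if d1 < 1 or m < 1:
        raise ValueError("d1 and m must be positive integers")
    missing = [c for c in INTERVAL_COLUMNS if c not in intervals.columns]
    if missing:
        raise ValueError(f"interval table is missing columns {missing}")

    parts = []
    for pid, grp in intervals.groupby("patient_id", sort=True):
        grp = grp.sort_values("interval_index").reset_index(drop=True)
        valid = grp["valid"].to_numpy(dtype=bool)
        levels = grp["q3_level"].to_numpy(dtype=float)
        resp = grp["response_class"].to_numpy(dtype=int)
        n = len(grp)
        if n < d1 + 1:
            continue
        # anchor t is usable iff intervals t-d1+1..t are all valid
        run_ok = np.all(
            np.lib.stride_tricks.sliding_window_view(valid, d1), axis=1
        )  # run_ok[i] covers intervals i..i+d1-1
        for t in range(d1 - 1, n):
            if not run_ok[t - d1 + 1]:
                continue
            hist = levels[t - d1 + 1 : t + 1]
            for k in range(1, m + 1):
                if t + k >= n or not valid[t + k]:
                    continue
                parts.append(
                    (pid, t, k, resp[t + k], *hist)
                )
    cols = WINDOW_META_COLUMNS + [f"x{j}" for j in range(1, d1 + 1)]
    frame = pd.DataFrame(parts, columns=cols)
    return WindowedDataset(frame, d1=d1, m=m)
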