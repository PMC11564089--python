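"""Time-stratified case-crossover referent selection.

Each case (a birth with the outcome of interest) is compared with itself on
control days sharing the weekday and calendar month-and-year of the case day,
so confounders that are stable within a month — including individual-level
obstetric risk factors — cancel out of the conditional likelihood.  Control
days are separated from the case day by multiples of 7 days, which also
breaks weekday effects and damps serial autocorrelation in exposure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exposure import (
    LagVector,
    MissingExposureError,
    TemperatureSeries,
    lag_matrix,
)

__all__ = [
    "CaseCrossoverStratum",
    "StrataSet",
    "OUTCOME_COLUMNS",
    "select_control_days",
    "build_strata",
    "read_births_table",
    "write_births_table",
]

OUTCOME_COLUMNS = (
    "stillbirth",
    "antepartum_stillbirth",
    "intrapartum_stillbirth",
    "early_neonatal_death_24h",
    "perinatal_death",
)

BIRTH_COLUMNS = (
    "hospital_id",
    "country",
    "birth_date",
    *OUTCOME_COLUMNS,
    "maternal_age_ge35",
    "parity_ge2",
    "hiv_positive",
    "hypertensive_disorder",
    "female_infant",
    "preterm",
    "low_birth_weight",
    "prolonged_obstructed_labor",
    "antepartum_hemorrhage",
    "referred",
)


def select_control_days(case_date) -> list[np.datetime64]:
    """All days in the same calendar month-and-year as ``case_date`` sharing
    its weekday, excluding the case day itself; ascending.  Every month holds
    four or five of each weekday, so the result has 3 or 4 entries."""
    d = np.datetime64(case_date, "D")
    month = d.astype("datetime64[M]")
    first, next_month = month.astype("datetime64[D]"), (month + 1).astype("datetime64[D]")
    out = []
    c = d - ((d - first).astype(int) // 7) * 7 * np.timedelta64(1, "D")
    # c is the earliest same-weekday day of the month
    while c < next_month:
        if c != d:
            out.append(c)
        c = c + np.timedelta64(7, "D")
    return out


@dataclass
class CaseCrossoverStratum:
    """One case day plus its matched control days with exposure histories."""

    stratum_id: int
    case_index: int  # positional index of the case row in the births table
    case_date: np.datetime64
    control_dates: list[np.datetime64]
    exposure_rows: list[LagVector]
    case_indicator: np.ndarray  # one flag per date; exactly one True

    @property
    def dates(self) -> list[np.datetime64]:
        return [self.case_date] + list(self.control_dates)


@dataclass
class StrataSet:
    """Array-backed collection of case-crossover strata.

    Rows are grouped by ``stratum_id`` (contiguous, ascending) with the case
    row first in each stratum.  ``lag_temps`` holds one exposure history per
    row (column k = lag k).  ``rh_lags``, if present, holds the matching
    relative-humidity histories.
    """

    stratum_id: np.ndarray
    is_case: np.ndarray
    row_date: np.ndarray
    lag_temps: np.ndarray
    case_index: np.ndarray  # per-row: births-table position of the stratum's case
    metric: str
    L: int
    n_excluded_missing_exposure: int = 0
    rh_lags: np.ndarray | None = None

    @property
    def n_strata(self) -> int:
        return 0 if self.stratum_id.size == 0 else int(self.stratum_id.max()) + 1

    def strata(self) -> list[CaseCrossoverStratum]:
        """Materialize per-stratum objects (convenience view of the arrays)."""
        out = []
        for sid in range(self.n_strata):
            rows = np.flatnonzero(self.stratum_id == sid)
            case_row = rows[np.argmax(self.is_case[rows])]
            ctrl_rows = [r for r in rows if not self.is_case[r]]
            out.append(
                CaseCrossoverStratum(
                    stratum_id=sid,
                    case_index=int(self.case_index[case_row]),
                    case_date=self.row_date[case_row],
                    control_dates=[self.row_date[r] for r in ctrl_rows],
                    exposure_rows=[
                        LagVector(self.row_date[r], self.lag_temps[r], self.metric)
                        for r in rows
                    ],
                    case_indicator=self.is_case[rows],
                )
            )
        return out


def _control_day_matrix(case_dates: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized referent selection: all same-weekday/month candidate dates
    at offsets -4..4 weeks; returns the candidate matrix and validity mask."""
    d = case_dates.astype("datetime64[D]")
    month = d.astype("datetime64[M]")
    first = month.astype("datetime64[D]")
    next_first = (month + 1).astype("datetime64[D]")
    offsets = np.arange(-4, 5) * 7
    cand = d[:, None] + offsets[None, :].astype("timedelta64[D]")
    valid = (cand >= first[:, None]) & (cand < next_first[:, None]) & (offsets != 0)[None, :]
    return cand, valid


def build_strata(
    births: pd.DataFrame,
    series_by_hospital: dict[str, TemperatureSeries],
    outcome: str,
    L: int = 6,
    metric: str = "mean",
    with_humidity: bool = False,
) -> StrataSet:
    """Build one time-stratified stratum per birth with ``outcome`` true.

    Exposure histories come from the birth hospital's temperature series via
    lags 0..L; cases whose series does not cover the full lag window on the
    case day or any control day are dropped and counted
    (``n_excluded_missing_exposure``).  Unknown hospital ids raise KeyError.
    """
    if outcome not in OUTCOME_COLUMNS:
        raise ValueError(f"outcome must be one of {OUTCOME_COLUMNS}, got {outcome!r}")
    cases = births.loc[births[outcome].astype(bool)]
    case_dates = cases["birth_date"].to_numpy().astype("datetime64[D]")
    case_hosp = cases["hospital_id"].astype(str).to_numpy()
    case_pos = cases.index.to_numpy()

    unknown = set(case_hosp) - set(series_by_hospital)
    if unknown:
        raise KeyError(f"no temperature series for hospital(s): {sorted(unknown)}")

    cand, valid = _control_day_matrix(case_dates)

    sid_rows: list[np.ndarray] = []
    case_rows: list[np.ndarray] = []
    date_rows: list[np.ndarray] = []
    temp_rows: list[np.ndarray] = []
    rh_rows: list[np.ndarray] = []
    idx_rows: list[np.ndarray] = []
    n_excluded = 0
    next_sid = 0
    offsets = np.arange(L + 1)

    for hid in sorted(set(case_hosp)):
        series = series_by_hospital[hid]
        sel = np.flatnonzero(case_hosp == hid)
        if sel.size == 0:
            continue
        # full per-stratum date matrix: column 0 = case day, then candidates
        all_dates = np.concatenate([case_dates[sel][:, None], cand[sel]], axis=1)
        all_valid = np.concatenate(
            [np.ones((sel.size, 1), dtype=bool), valid[sel]], axis=1
        )
        pos = (all_dates - series.start).astype(int)
        covered = (pos - L >= 0) & (pos < len(series))
        # a case is usable only if every referent day has a full lag window
        stratum_ok = np.all(covered | ~all_valid, axis=1)
        n_excluded += int((~stratum_ok).sum())
        if not stratum_ok.any():
            continue
        keep = all_valid & stratum_ok[:, None]
        row_pos = pos[keep]
        vals = series.values(metric)
        temp_rows.append(vals[row_pos[:, None] - offsets[None, :]])
        if with_humidity:
            rh = series.relative_humidity()
            rh_rows.append(rh[row_pos[:, None] - offsets[None, :]])
        date_rows.append(all_dates[keep])
        case_rows.append(np.concatenate([[True], np.zeros(9, bool)])[None, :].repeat(
            sel.size, axis=0
        )[keep])
        counts = keep.sum(axis=1)[stratum_ok]
        sids = next_sid + np.arange(counts.size)
        sid_rows.append(np.repeat(sids, counts))
        idx_rows.append(np.repeat(case_pos[sel][stratum_ok], counts))
        next_sid += counts.size

    if next_sid == 0:
        empty = np.empty(0)
        return StrataSet(
            stratum_id=empty.astype(int),
            is_case=empty.astype(bool),
            row_date=empty.astype("datetime64[D]"),
            lag_temps=np.empty((0, L + 1)),
            case_index=empty.astype(int),
            metric=metric,
            L=L,
            n_excluded_missing_exposure=n_excluded,
            rh_lags=np.empty((0, L + 1)) if with_humidity else None,
        )

    return StrataSet(
        stratum_id=np.concatenate(sid_rows),
        is_case=np.concatenate(case_rows),
        row_date=np.concatenate(date_rows),
        lag_temps=np.vstack(temp_rows),
        case_index=np.concatenate(idx_rows),
        metric=metric,
        L=L,
        n_excluded_missing_exposure=n_excluded,
        rh_lags=np.vstack(rh_rows) if with_humidity else None,
    )


def read_births_table(path) -> pd.DataFrame:
    """Read a delimited birth registry (one row per birth, BirthRecord
    columns, 0/1 flags, ISO-8601 dates)."""
    df = pd.read_csv(path, parse_dates=["birth_date"])
    missing = set(BIRTH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"births table missing columns: {sorted(missing)}")
    df["birth_date"] = df["birth_date"].astype("datetime64[s]")
    return df


def write_births_table(births: pd.DataFrame, path) -> None:
    df = births.copy()
    df["birth_date"] = pd.to_datetime(df["birth_date"]).dt.strftime("%Y-%m-%d")
    flag_cols = [c for c in df.columns if df[c].dtype == bool]
    df[flag_cols] = df[flag_cols].astype(int)
    df.to_csv(path, index=False)
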