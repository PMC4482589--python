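"""Reading and writing the pipeline's file formats.

Annual input is CSV with header ``year,value``; daily input is CSV with
header ``date,value`` (ISO-8601 dates).  Gap years are rejected explicitly —
series must be trimmed to a gapless span upstream.  Writers emit RFC-4180
CSV with floats at 6 significant digits so repeated runs are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .series import AnnualSeries, DailySeries
from .windows import MetricDefinition, WindowSpec

__all__ = [
    "read_annual_csv",
    "read_daily_csv",
    "write_table",
    "write_annual_csv",
    "write_json",
    "load_metric_registry",
]

FLOAT_FORMAT = "%.6g"


def _numeric_or_die(col: pd.Series, path, colname: str) -> np.ndarray:
    out = pd.to_numeric(col, errors="coerce")
    bad = out.isna() & col.notna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise ValueError(
            f"{path}: non-numeric {colname!r} value {col[bad.idxmax()]!r} "
            f"on line {line}"
        )
    if out.isna().any():
        line = int(out.isna().idxmax()) + 2
        raise ValueError(f"{path}: missing {colname!r} value on line {line}")
    return out.to_numpy()


def read_annual_csv(path, name: str | None = None) -> AnnualSeries:
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    if list(df.columns[:2]) != ["year", "value"]:
        raise ValueError(f"{path}: expected header 'year,value', got {list(df.columns)}")
    years = _numeric_or_die(df["year"], path, "year").astype(np.int64)
    values = _numeric_or_die(df["value"], path, "value").astype(float)
    diffs = np.diff(years)
    if np.any(diffs != 1):
        missing = []
        for a, b in zip(years[:-1], years[1:]):
            if b - a > 1:
                missing.extend(range(int(a) + 1, int(b)))
            elif b - a < 1:
                raise ValueError(f"{path}: years not strictly increasing near {a}")
        raise ValueError(f"{path}: gap years missing from record: {missing}")
    return AnnualSeries(name or path.stem, years, values)


def read_daily_csv(path, name: str | None = None) -> DailySeries:
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    if list(df.columns[:2]) != ["date", "value"]:
        raise ValueError(f"{path}: expected header 'date,value', got {list(df.columns)}")
    try:
        dates = pd.to_datetime(df["date"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: unparsable ISO-8601 date ({exc})") from exc
    values = _numeric_or_die(df["value"], path, "value").astype(float)
    return DailySeries(name or path.stem, pd.DatetimeIndex(dates), values)


def write_table(path, df: pd.DataFrame, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=index, float_format=FLOAT_FORMAT, lineterminator="\r\n")


def write_annual_csv(path, series: AnnualSeries) -> None:
    write_table(path, pd.DataFrame({"year": series.years, "value": series.values}))


def write_json(path, obj) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     default=default) + "\n")


def _window_spec_from_dict(d: dict) -> WindowSpec:
    end = d.get("end_date")
    if isinstance(end, str):
        m, day = end.split("-")
        end = (int(m), int(day))
    elif isinstance(end, (list, tuple)):
        end = tuple(int(v) for v in end)
    return WindowSpec(
        mode=d["mode"], statistic=d.get("statistic", "mean"),
        length_days=int(d.get("length_days", 1)), end_date=end,
        season_extremum=d.get("season_extremum"),
    )


def load_metric_registry(path) -> list[MetricDefinition]:
    """YAML registry: list of {name, category, record_start_year, window:{...}}."""
    raw = yaml.safe_load(Path(path).read_text())
    metrics = raw["metrics"] if isinstance(raw, dict) else raw
    out = []
    for entry in metrics:
        out.append(MetricDefinition(
            name=entry["name"], category=entry["category"],
            window=_window_spec_from_dict(entry["window"]),
            record_start_year=int(entry["record_start_year"]),
        ))
    return out
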