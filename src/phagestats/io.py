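"""Delimited-text I/O for experiment records.

Two schemas, both comma-separated UTF-8 with a required header row:

* presence/absence series — ``label,volume_ul,n_vessels,n_positive``,
  one experiment per row;
* plate counts — ``label,volume_ul,count``, one vessel per row; rows
  sharing a (label, volume) pair form one :class:`~phagestats.distfit.CountSample`.

Malformed rows are reported with their 1-based file line number.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Sequence

import pandas as pd

from .distfit import CountSample
from .poisson import AliquotSeries

__all__ = [
    "read_series",
    "write_series",
    "read_counts",
    "write_counts",
    "read_monitor_series",
    "write_report",
]

_SERIES_COLUMNS = ["label", "volume_ul", "n_vessels", "n_positive"]
_COUNT_COLUMNS = ["label", "volume_ul", "count"]


def _load_table(path: str | Path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return df


def read_series(path: str | Path) -> list[AliquotSeries]:
    """Read presence/absence series, one per row."""
    df = _load_table(path, _SERIES_COLUMNS)
    out: list[AliquotSeries] = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            out.append(
                AliquotSeries(
                    label=str(row["label"]),
                    volume=float(row["volume_ul"]),
                    n_vessels=int(row["n_vessels"]),
                    n_positive=int(row["n_positive"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}, line {line}: {exc}") from exc
    return out


def write_series(series: Sequence[AliquotSeries], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "label": s.label,
                "volume_ul": s.volume,
                "n_vessels": s.n_vessels,
                "n_positive": s.n_positive,
            }
            for s in series
        ],
        columns=_SERIES_COLUMNS,
    ).to_csv(path, index=False)


def read_counts(path: str | Path) -> list[CountSample]:
    """Read per-vessel counts; rows group into samples by (label, volume)."""
    df = _load_table(path, _COUNT_COLUMNS)
    for idx, row in df.iterrows():
        line = idx + 2
        c = row["count"]
        try:
            ok = float(c) == int(c) and int(c) >= 0
        except (ValueError, TypeError):
            ok = False
        if not ok:
            raise ValueError(
                f"{path}, line {line}: count must be a non-negative "
                f"integer, got {c!r}"
            )
    samples: list[CountSample] = []
    for (label, volume), grp in df.groupby(["label", "volume_ul"], sort=False):
        try:
            samples.append(
                CountSample(
                    counts=tuple(int(c) for c in grp["count"]),
                    volume=float(volume),
                    label=str(label),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}, group ({label}, {volume}): {exc}") from exc
    return samples


def write_counts(samples: Sequence[CountSample], path: str | Path) -> None:
    rows = [
        {"label": s.label, "volume_ul": s.volume, "count": c}
        for s in samples
        for c in s.counts
    ]
    pd.DataFrame(rows, columns=_COUNT_COLUMNS).to_csv(path, index=False)


def read_monitor_series(path: str | Path) -> list[float]:
    """Read a control-chart monitoring series (``label,value``)."""
    df = _load_table(path, ["label", "value"])
    return [float(v) for v in df["value"]]


def write_report(report: dict[str, Any], path: str | Path, fmt: str = "json") -> None:
    """Write a structured report; currently JSON only."""
    if fmt != "json":
        raise ValueError(f"unsupported report format {fmt!r}")
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=False) + "\n")
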