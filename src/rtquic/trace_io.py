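"""Reading and writing of plate-reader trace exports, plate maps and call tables.

The canonical on-disk trace format is a LONG CSV with header ``well,time_h,rfu``
(one row per reading). A WIDE dialect — one ``time_h`` column plus one column
per well, mimicking common plate-reader exports — is accepted read-only and
converted to the same in-memory representation. All times are in hours.
"""

from __future__ import annotations

import csv
import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Specimen",
    "Diagnosis",
    "FluorescenceTrace",
    "PlateMapEntry",
    "PlateMap",
    "AssayMetadata",
    "ReplicateCall",
    "SampleCall",
    "TraceFormatError",
    "TraceValidationError",
    "PlateMapError",
    "UnmappedWellError",
    "read_trace_csv",
    "write_trace_csv",
    "read_plate_map",
    "write_plate_map",
    "annotate_traces",
    "write_calls_csv",
    "read_calls_csv",
]


class TraceFormatError(ValueError):
    """Raised when a trace CSV lacks the required columns or structure."""


class TraceValidationError(ValueError):
    """Raised when trace content violates an invariant (NaN, non-monotone time...)."""


class PlateMapError(ValueError):
    """Raised on malformed plate maps (duplicate wells, unknown tokens...)."""


class UnmappedWellError(KeyError):
    """Raised when traces contain a well absent from the plate map."""


class Specimen(enum.Enum):
    """Specimen type: nasal swab from agger nasi / middle turbinate, or CSF."""

    NS_AN = "NS_AN"
    NS_MT = "NS_MT"
    CSF = "CSF"


class Diagnosis(enum.Enum):
    PD = "PD"
    NON_PD = "NON_PD"
    CONTROL = "CONTROL"


def _parse_enum(cls, token: str, column: str):
    try:
        return cls[token.strip().upper()]
    except KeyError:
        allowed = ", ".join(m.name for m in cls)
        raise PlateMapError(
            f"unknown {column} value {token!r}; allowed (case-insensitive): {allowed}"
        ) from None


@dataclass(frozen=True)
class FluorescenceTrace:
    """One well's ThT fluorescence time course.

    ``times`` are reaction times in hours (strictly increasing); ``rfu`` the
    raw relative-fluorescence-unit readings, one per time point.
    """

    well_id: str
    times: np.ndarray
    rfu: np.ndarray
    sample_id: str = ""
    replicate_index: int = 1

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        rfu = np.asarray(self.rfu, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "rfu", rfu)
        if times.ndim != 1 or rfu.ndim != 1 or len(times) != len(rfu):
            raise TraceValidationError(
                f"well {self.well_id}: times and rfu must be 1-D and equal length"
            )
        if len(times) < 2:
            raise TraceValidationError(f"well {self.well_id}: at least 2 readings required")
        if not np.all(np.isfinite(times)) or not np.all(np.isfinite(rfu)):
            raise TraceValidationError(f"well {self.well_id}: non-finite reading")
        if np.any(np.diff(times) <= 0):
            raise TraceValidationError(f"well {self.well_id}: times not strictly increasing")
        if times[0] < 0:
            raise TraceValidationError(f"well {self.well_id}: negative time")
        if self.replicate_index < 1:
            raise TraceValidationError(f"well {self.well_id}: replicate_index must be >= 1")


@dataclass(frozen=True)
class PlateMapEntry:
    well_id: str
    subject_id: str
    sample_id: str
    specimen: Specimen
    diagnosis: Diagnosis
    replicate_index: int
    center: str = ""


@dataclass(frozen=True)
class PlateMap:
    """Mapping of wells to sample/subject identity and replicate structure."""

    entries: tuple[PlateMapEntry, ...]

    def __post_init__(self):
        wells = [e.well_id for e in self.entries]
        if len(set(wells)) != len(wells):
            dupes = sorted({w for w in wells if wells.count(w) > 1})
            raise PlateMapError(f"duplicate well(s) in plate map: {dupes}")
        by_sample: dict[str, list[int]] = {}
        for e in self.entries:
            by_sample.setdefault(e.sample_id, []).append(e.replicate_index)
        for sid, reps in by_sample.items():
            if len(set(reps)) != len(reps):
                raise PlateMapError(f"sample {sid!r}: replicate indices not unique")

    def __getitem__(self, well_id: str) -> PlateMapEntry:
        for e in self.entries:
            if e.well_id == well_id:
                return e
        raise UnmappedWellError(well_id)

    def __contains__(self, well_id: str) -> bool:
        return any(e.well_id == well_id for e in self.entries)

    @property
    def sample_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.sample_id)
        return list(seen)

    def sample_entry(self, sample_id: str) -> PlateMapEntry:
        for e in self.entries:
            if e.sample_id == sample_id:
                return e
        raise KeyError(sample_id)


@dataclass(frozen=True)
class AssayMetadata:
    """Run-level metadata; only the timing fields feed computation."""

    reading_interval: float = 0.75  # hours (45-min plate-reader cycles)
    cutoff_time: float = 80.0  # hours
    temperature: str = ""
    wavelengths: str = ""

    def __post_init__(self):
        if self.reading_interval <= 0 or self.cutoff_time <= 0:
            raise ValueError("reading_interval and cutoff_time must be positive")


@dataclass(frozen=True)
class ReplicateCall:
    """Threshold-crossing decision for one replicate well."""

    well_id: str
    crossed: bool
    lag_time: float | None  # hours; first reading at/above threshold
    threshold_used: float  # percent of normalization maximum

    def __post_init__(self):
        if self.crossed != (self.lag_time is not None):
            raise ValueError("crossed must hold exactly when lag_time is present")


@dataclass(frozen=True)
class SampleCall:
    """Per-sample positivity call aggregated over replicate wells."""

    sample_id: str
    subject_id: str
    specimen: Specimen
    diagnosis: Diagnosis
    replicate_calls: tuple[ReplicateCall, ...]
    call: str  # "positive" | "negative"
    endpoint_mean_percent: float
    flags: tuple[str, ...] = ()

    @property
    def n_replicates(self) -> int:
        return len(self.replicate_calls)

    @property
    def n_positive_replicates(self) -> int:
        return sum(rc.crossed for rc in self.replicate_calls)

    @property
    def positive(self) -> bool:
        return self.call == "positive"

    @property
    def lag_times(self) -> list[float]:
        return [rc.lag_time for rc in self.replicate_calls if rc.lag_time is not None]


# ---------------------------------------------------------------------------
# trace CSV

_LONG_COLUMNS = ["well", "time_h", "rfu"]


def read_trace_csv(
    path, dialect: str = "long", time_unit: str = "hours"
) -> list[FluorescenceTrace]:
    """Read a trace CSV (long or wide dialect) into one trace per well.

    ``time_unit="minutes"`` converts the time column to hours on read.
    """
    if dialect not in ("long", "wide"):
        raise ValueError(f"dialect must be 'long' or 'wide', got {dialect!r}")
    if time_unit not in ("hours", "minutes"):
        raise ValueError(f"time_unit must be 'hours' or 'minutes', got {time_unit!r}")
    df = pd.read_csv(path)
    scale = 1.0 / 60.0 if time_unit == "minutes" else 1.0

    if dialect == "long":
        missing = [c for c in _LONG_COLUMNS if c not in df.columns]
        if missing:
            raise TraceFormatError(f"{path}: long trace CSV missing column(s) {missing}")
        if df[["well", "time_h"]].duplicated().any():
            dup = df[df[["well", "time_h"]].duplicated()].iloc[0]
            raise TraceValidationError(
                f"{path}: duplicated (well, time) row: well {dup['well']!r} t={dup['time_h']}"
            )
        traces = []
        for well, grp in df.groupby("well", sort=True):
            if grp["rfu"].isna().any():
                row = int(grp.index[grp["rfu"].isna()][0]) + 2  # 1-based + header
                raise TraceValidationError(f"{path}: NaN rfu in well {well!r} (file row {row})")
            grp = grp.sort_values("time_h")
            traces.append(
                FluorescenceTrace(
                    well_id=str(well),
                    times=grp["time_h"].to_numpy(dtype=float) * scale,
                    rfu=grp["rfu"].to_numpy(dtype=float),
                )
            )
        return traces

    # wide dialect
    if "time_h" not in df.columns:
        raise TraceFormatError(f"{path}: wide trace CSV missing 'time_h' column")
    well_cols = [c for c in df.columns if c != "time_h"]
    if not well_cols:
        raise TraceFormatError(f"{path}: wide trace CSV has no well columns")
    t = df["time_h"].to_numpy(dtype=float) * scale
    traces = []
    for well in sorted(well_cols):
        col = df[well]
        if col.isna().any():
            row = int(col.index[col.isna()][0]) + 2
            raise TraceValidationError(f"{path}: NaN rfu in well {well!r} (file row {row})")
        order = np.argsort(t, kind="stable")
        traces.append(
            FluorescenceTrace(well_id=str(well), times=t[order], rfu=col.to_numpy(float)[order])
        )
    return traces


def write_trace_csv(traces: Sequence[FluorescenceTrace], path) -> None:
    """Write traces in the canonical long dialect (6 significant digits)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_LONG_COLUMNS)
        for tr in traces:
            for t, y in zip(tr.times, tr.rfu):
                w.writerow([tr.well_id, format(t, ".6g"), format(y, ".6g")])


# ---------------------------------------------------------------------------
# plate map CSV

_MAP_COLUMNS = ["well", "subject", "sample", "specimen", "diagnosis", "replicate"]


def read_plate_map(path) -> PlateMap:
    """Read a plate-map CSV (``well,subject,sample,specimen,diagnosis,replicate[,center]``)."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _MAP_COLUMNS if c not in df.columns]
    if missing:
        raise PlateMapError(f"{path}: plate map missing column(s) {missing}")
    entries = []
    for _, row in df.iterrows():
        entries.append(
            PlateMapEntry(
                well_id=str(row["well"]),
                subject_id=str(row["subject"]),
                sample_id=str(row["sample"]),
                specimen=_parse_enum(Specimen, row["specimen"], "specimen"),
                diagnosis=_parse_enum(Diagnosis, row["diagnosis"], "diagnosis"),
                replicate_index=int(row["replicate"]),
                center=str(row["center"]) if "center" in df.columns and pd.notna(row.get("center")) else "",
            )
        )
    return PlateMap(entries=tuple(entries))


def write_plate_map(plate_map: PlateMap, path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_MAP_COLUMNS + ["center"])
        for e in plate_map.entries:
            w.writerow(
                [e.well_id, e.subject_id, e.sample_id, e.specimen.name,
                 e.diagnosis.name, e.replicate_index, e.center]
            )


def annotate_traces(
    traces: Iterable[FluorescenceTrace],
    plate_map: PlateMap,
    ignore_unmapped: bool = False,
) -> list[FluorescenceTrace]:
    """Attach sample identity from the plate map to bare well traces.

    Wells absent from the map raise :class:`UnmappedWellError` unless
    ``ignore_unmapped`` is set (silent dropping hides plate-layout mistakes).
    """
    out = []
    for tr in traces:
        if tr.well_id not in plate_map:
            if ignore_unmapped:
                continue
            raise UnmappedWellError(f"unmapped well {tr.well_id!r} (not in plate map)")
        e = plate_map[tr.well_id]
        out.append(replace(tr, sample_id=e.sample_id, replicate_index=e.replicate_index))
    return out


# ---------------------------------------------------------------------------
# calls CSV

_CALL_COLUMNS = [
    "sample", "subject", "specimen", "diagnosis", "n_replicates",
    "n_positive_replicates", "call", "lag_times", "endpoint_mean_percent",
]


def write_calls_csv(calls: Sequence[SampleCall], path) -> None:
    """Write one row per sample; lag times semicolon-joined (empty if none crossed)."""
    if not calls:
        raise ValueError("write_calls_csv: empty call list (refusing to write empty file)")
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_CALL_COLUMNS)
        for c in calls:
            lags = ";".join(format(x, ".6g") for x in c.lag_times)
            w.writerow(
                [c.sample_id, c.subject_id, c.specimen.name, c.diagnosis.name,
                 c.n_replicates, c.n_positive_replicates, c.call, lags,
                 format(c.endpoint_mean_percent, ".6g")]
            )


def read_calls_csv(path) -> pd.DataFrame:
    """Read a calls CSV back as a DataFrame (lag_times parsed to float lists)."""
    df = pd.read_csv(path, dtype={"lag_times": str})
    missing = [c for c in _CALL_COLUMNS if c not in df.columns]
    if missing:
        raise TraceFormatError(f"{path}: calls CSV missing column(s) {missing}")
    df["lag_times"] = [
        [float(x) for x in s.split(";")] if isinstance(s, str) and s else []
        for s in df["lag_times"]
    ]
    return df
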