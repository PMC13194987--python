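"""Columnar storage for sensor streams and behavioural event logs.

Streams are plain CSV with one row per sensor sample:

    timestamp,acc_x,acc_y,acc_z,gyr_x,gyr_y,gyr_z,mag_x,mag_y,mag_z,light,tod,missing

ISO-8601 naive-local timestamps; a row flagged ``missing`` keeps its
timestamp but serialises every channel field as empty.  Event logs are CSV
``timestamp,kind,level`` with kind in {smoke, lapse, craving}; ``level``
(craving intensity 1-5) is present exactly for craving rows.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

#: channel column order shared by every stream file and window matrix
CHANNELS: tuple[str, ...] = (
    "acc_x", "acc_y", "acc_z",
    "gyr_x", "gyr_y", "gyr_z",
    "mag_x", "mag_y", "mag_z",
    "light", "tod",
)

STREAM_COLUMNS: tuple[str, ...] = ("timestamp", *CHANNELS, "missing")
EVENT_COLUMNS: tuple[str, ...] = ("timestamp", "kind", "level")
EVENT_KINDS: frozenset[str] = frozenset({"smoke", "lapse", "craving"})


class ParseError(ValueError):
    """A stream/event file violated the dialect; the message names the line."""


@dataclass
class SensorStream:
    """One participant-phase's timestamped multi-channel samples.

    ``frame`` holds one row per sample with columns ``STREAM_COLUMNS``;
    channel values are NaN exactly where ``missing`` is True.  Timestamps
    are strictly increasing.
    """

    participant_id: str
    phase: int
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if self.phase not in (1, 2):
            raise ValueError(f"phase must be 1 or 2, got {self.phase!r}")
        f = self.frame
        if list(f.columns) != list(STREAM_COLUMNS):
            raise ValueError("stream frame columns do not match the dialect")
        ts = f["timestamp"].to_numpy()
        if len(ts) > 1 and not (ts[1:] > ts[:-1]).all():
            bad = int(np.flatnonzero(~(ts[1:] > ts[:-1]))[0]) + 2
            raise ParseError(f"timestamps not strictly increasing at row {bad}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def channel_matrix(self) -> np.ndarray:
        """(n_rows, 11) float array of channel values (NaN where missing)."""
        return self.frame[list(CHANNELS)].to_numpy(dtype=float)

    @property
    def missing_mask(self) -> np.ndarray:
        return self.frame["missing"].to_numpy(dtype=bool)

    @property
    def time_range(self) -> tuple[pd.Timestamp, pd.Timestamp]:
        ts = self.frame["timestamp"]
        return ts.iloc[0], ts.iloc[-1]


@dataclass
class EventLog:
    """Timestamped behavioural events for one participant-phase.

    kind 'smoke' belongs to Phase 1 (pre-quit cigarettes); 'lapse' and
    'craving' to Phase 2.  ``level`` is the self-reported craving intensity,
    1 (very low) to 5 (very high), and is present iff kind == 'craving'.
    """

    frame: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            {"timestamp": pd.Series(dtype="datetime64[ns]"),
             "kind": pd.Series(dtype=object),
             "level": pd.Series(dtype="Int64")})
    )

    def __post_init__(self) -> None:
        f = self.frame
        if list(f.columns) != list(EVENT_COLUMNS):
            raise ValueError("event frame columns must be timestamp,kind,level")
        bad_kind = ~f["kind"].isin(sorted(EVENT_KINDS))
        if bad_kind.any():
            raise ParseError(
                f"unknown event kind at row {int(np.flatnonzero(bad_kind)[0]) + 2}")
        is_craving = f["kind"] == "craving"
        has_level = f["level"].notna()
        if (is_craving & ~has_level).any():
            row = int(np.flatnonzero((is_craving & ~has_level).to_numpy())[0]) + 2
            raise ParseError(f"craving event without level at row {row}")
        if (~is_craving & has_level).any():
            row = int(np.flatnonzero((~is_craving & has_level).to_numpy())[0]) + 2
            raise ParseError(f"non-craving event carries a level at row {row}")
        lv = f.loc[has_level, "level"]
        if len(lv) and not lv.isin([1, 2, 3, 4, 5]).all():
            raise ParseError("craving level outside 1..5")

    def __len__(self) -> int:
        return len(self.frame)


PathLike = Union[str, Path, _stdio.IOBase]


def _read_csv(path: PathLike, columns: tuple[str, ...]) -> pd.DataFrame:
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas message forwarded
        raise ParseError(f"unreadable CSV: {exc}") from exc
    if list(frame.columns) != list(columns):
        raise ParseError(
            f"header mismatch: expected {','.join(columns)}, "
            f"got {','.join(map(str, frame.columns))}")
    return frame


def _parse_timestamps(raw: pd.Series) -> pd.Series:
    try:
        ts = pd.to_datetime(raw, format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ParseError(f"unparseable timestamp: {exc}") from exc
    return ts


def read_stream(path: PathLike, participant_id: str, phase: int) -> SensorStream:
    """Parse a stream CSV, enforcing the dialect and monotone timestamps."""
    raw = _read_csv(path, STREAM_COLUMNS)
    out = pd.DataFrame({"timestamp": _parse_timestamps(raw["timestamp"])})
    missing = raw["missing"].str.strip()
    if not missing.isin(["0", "1"]).all():
        row = int(np.flatnonzero(~missing.isin(["0", "1"]).to_numpy())[0]) + 2
        raise ParseError(f"missing flag must be 0 or 1 at row {row}")
    miss = missing == "1"
    for col in CHANNELS:
        vals = raw[col].str.strip()
        empty = vals == ""
        if (empty != miss).any():
            row = int(np.flatnonzero((empty != miss).to_numpy())[0]) + 2
            raise ParseError(
                f"channel emptiness disagrees with missing flag at row {row}")
        try:
            parsed = pd.to_numeric(vals.where(~empty, other=None))
        except (ValueError, TypeError) as exc:
            raise ParseError(f"unparseable value in column {col}: {exc}") from exc
        out[col] = parsed.astype(float)
    tod = out["tod"].to_numpy()
    ok = np.isnan(tod) | ((tod >= 0.0) & (tod <= 1.0))
    if not ok.all():
        raise ParseError(
            f"tod outside [0,1] at row {int(np.flatnonzero(~ok)[0]) + 2}")
    out["missing"] = miss.to_numpy()
    dup = out["timestamp"].diff().iloc[1:] <= pd.Timedelta(0)
    if dup.any():
        raise ParseError(
            f"timestamps not strictly increasing at row {int(np.flatnonzero(dup.to_numpy())[0]) + 3}")
    return SensorStream(participant_id=participant_id, phase=phase, frame=out)


def write_stream(stream: SensorStream, path: Union[str, Path]) -> None:
    """Serialise a stream; missing rows get empty channel fields."""
    f = stream.frame.copy()
    out = pd.DataFrame()
    out["timestamp"] = f["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    miss = f["missing"].to_numpy(dtype=bool)
    for col in CHANNELS:
        vals = f[col].map(lambda v: "" if pd.isna(v) else repr(float(v)))
        vals[miss] = ""
        out[col] = vals
    out["missing"] = np.where(miss, "1", "0")
    out.to_csv(path, index=False)


def read_events(path: PathLike) -> EventLog:
    """Parse an event-log CSV, enforcing the level<->craving invariant."""
    raw = _read_csv(path, EVENT_COLUMNS)
    ts = _parse_timestamps(raw["timestamp"])
    kind = raw["kind"].str.strip()
    lvl_raw = raw["level"].str.strip()
    try:
        level = pd.to_numeric(lvl_raw.where(lvl_raw != "", other=None)).astype("Int64")
    except (ValueError, TypeError) as exc:
        raise ParseError(f"unparseable craving level: {exc}") from exc
    return EventLog(pd.DataFrame({"timestamp": ts, "kind": kind, "level": level}))


def write_events(log: EventLog, path: Union[str, Path]) -> None:
    f = log.frame
    out = pd.DataFrame({
        "timestamp": f["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S"),
        "kind": f["kind"],
        "level": f["level"].map(lambda v: "" if pd.isna(v) else str(int(v))),
    })
    out.to_csv(path, index=False)
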