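"""Raw sensor event streams and their segmentation into measurement groupings.

A *measurement grouping* is a maximal run of raw sensor timestamps
separated from the next run by a gap of at least half the off-cycle.
It represents one attempt by the phone application to collect data; a
grouping expected by design but never observed is sensor non-collection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .schedule import SensorSchedule

logger = logging.getLogger(__name__)

EVENT_COLUMNS = ["participant_id", "study_id", "sensor", "timestamp_ms"]


@dataclass
class EventStream:
    """Ordered raw measurement timestamps for one participant x sensor."""

    participant_id: str
    study_id: str
    sensor_name: str
    timestamps_ms: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps_ms, dtype=np.int64)
        if ts.size and ts.min() < 0:
            raise ValueError("timestamps must be non-negative epoch milliseconds")
        if ts.size > 1 and np.any(np.diff(ts) < 0):
            logger.warning(
                "unsorted event stream for participant %s sensor %s; sorting",
                self.participant_id,
                self.sensor_name,
            )
            ts = np.sort(ts)
        self.timestamps_ms = ts

    def __len__(self) -> int:
        return int(self.timestamps_ms.size)


@dataclass(frozen=True)
class MeasurementGrouping:
    """A maximal run of events from a single collection attempt."""

    start_ms: int
    end_ms: int
    n_events: int

    def __post_init__(self) -> None:
        if self.start_ms > self.end_ms:
            raise ValueError("grouping start must not exceed end")
        if self.n_events < 1:
            raise ValueError("a grouping contains at least one event")


def segment_events(
    stream: EventStream, schedule: SensorSchedule
) -> list[MeasurementGrouping]:
    """Split an event stream into measurement groupings.

    A new grouping starts at the first event and at every event whose gap
    to the previous event is at least half the off-cycle ("at least half"
    means a gap of exactly ``off_cycle_s / 2`` starts a new grouping).
    Grouping start/end are the first/last event times of the run, so the
    groupings partition the events of the stream.

    With ``off_cycle_s == 0`` the threshold is 0 ms and only strictly
    positive gaps split; duplicate timestamps always stay together.
    """
    ts = stream.timestamps_ms
    if ts.size == 0:
        return []
    threshold_ms = schedule.off_cycle_s * 1000 / 2
    gaps = np.diff(ts)
    # boundary tie: gap == off/2 starts a new grouping; zero-gap never splits
    is_break = gaps >= threshold_ms if threshold_ms > 0 else gaps > 0
    starts = np.concatenate(([0], np.flatnonzero(is_break) + 1))
    ends = np.concatenate((starts[1:], [ts.size])) - 1
    return [
        MeasurementGrouping(int(ts[s]), int(ts[e]), int(e - s + 1))
        for s, e in zip(starts, ends)
    ]


def read_events_csv(path: str | Path) -> pd.DataFrame:
    """Read an event log CSV (``participant_id,study_id,sensor,timestamp_ms``)."""
    df = pd.read_csv(path, dtype={"participant_id": str, "study_id": str, "sensor": str})
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"event log {path} lacks required columns {missing}")
    df["timestamp_ms"] = df["timestamp_ms"].astype(np.int64)
    return df[EVENT_COLUMNS]


def read_beiwe_file(
    path: str | Path, participant_id: str, study_id: str, sensor: str
) -> pd.DataFrame:
    """Read one Beiwe-style per-hour sensor CSV.

    Beiwe writes one file per participant/sensor/hour whose first column
    is the UTC timestamp in milliseconds; remaining payload columns are
    ignored (timestamps are the only data used downstream).
    """
    df = pd.read_csv(path)
    ts = df.iloc[:, 0].astype(np.int64)
    return pd.DataFrame(
        {
            "participant_id": participant_id,
            "study_id": study_id,
            "sensor": sensor,
            "timestamp_ms": ts,
        }
    )


def streams_from_frame(events: pd.DataFrame) -> list[EventStream]:
    """Group a long event table into per-(participant, sensor) streams."""
    streams = []
    for (pid, sid, sensor), grp in events.groupby(
        ["participant_id", "study_id", "sensor"], sort=True
    ):
        streams.append(
            EventStream(str(pid), str(sid), str(sensor), grp["timestamp_ms"].to_numpy())
        )
    return streams


def write_events_csv(
    streams: Iterable[EventStream] | Sequence[EventStream], path: str | Path
) -> None:
    frames = [
        pd.DataFrame(
            {
                "participant_id": s.participant_id,
                "study_id": s.study_id,
                "sensor": s.sensor_name,
                "timestamp_ms": s.timestamps_ms,
            }
        )
        for s in streams
    ]
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=EVENT_COLUMNS)
    )
    out.to_csv(path, index=False)
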