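"""Sensor sampling schedules and the design-implied expected data volume.

Duty-cycled smartphone sensors alternate between an *on-cycle*, during
which the sensor records, and an *off-cycle*, during which it sleeps.
The schedule is chosen by the investigator, so the number of collection
attempts per day — and hence the expected number of measurement
groupings — is known at the design stage.  Everything observed short of
that expectation is sensor non-collection.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import yaml

SECONDS_PER_DAY = 86_400


class InvalidScheduleError(ValueError):
    """Raised when a sampling schedule has a non-positive cycle length."""


@dataclass(frozen=True)
class SensorSchedule:
    """Investigator-chosen on/off duty cycle for one sensor.

    Parameters
    ----------
    sensor_name : str
        Label of the sensor (e.g. ``"gps"``, ``"accelerometer"``).
    on_cycle_s : int
        Seconds per cycle during which the sensor records.  Must be >= 1.
    off_cycle_s : int
        Seconds per cycle during which the sensor sleeps.  Must be >= 0.
    """

    sensor_name: str
    on_cycle_s: int
    off_cycle_s: int

    def __post_init__(self) -> None:
        if int(self.on_cycle_s) != self.on_cycle_s or int(self.off_cycle_s) != self.off_cycle_s:
            raise InvalidScheduleError("cycle durations must be whole seconds")
        if self.on_cycle_s < 1:
            raise InvalidScheduleError(
                f"on_cycle_s must be >= 1 s, got {self.on_cycle_s}"
            )
        if self.off_cycle_s < 0:
            raise InvalidScheduleError(
                f"off_cycle_s must be >= 0 s, got {self.off_cycle_s}"
            )

    @property
    def cycle_length_s(self) -> int:
        """Full period of the duty cycle in seconds (on + off)."""
        return int(self.on_cycle_s + self.off_cycle_s)


def expected_groupings_per_day(schedule: SensorSchedule) -> int:
    """Expected number of measurement groupings per 24-h day, ``E``.

    This is the known, fixed offset of the non-collection model: the
    number of times per day the application attempts to collect data,
    ``floor(86400 / cycle_length)``.  A partial trailing cycle is not
    counted as an expected grouping.
    """
    if schedule.cycle_length_s < 1:
        raise InvalidScheduleError("cycle length must be >= 1 s")
    return SECONDS_PER_DAY // schedule.cycle_length_s


def expected_daily_coverage(schedule: SensorSchedule) -> tuple[float, float]:
    """Design coverage of a schedule.

    Returns
    -------
    fraction : float
        Fraction of wall-clock time the sensor is on, ``on / (on + off)``.
    hours_per_day : float
        Expected hours of recorded data per 24-h period, ``fraction * 24``.

    Examples
    --------
    A 1-min on-cycle with a 9-min off-cycle gives 10% coverage, i.e.
    2.4 h of data per day:

    >>> expected_daily_coverage(SensorSchedule("gps", 60, 540))
    (0.1, 2.4)
    """
    if schedule.cycle_length_s < 1:
        raise InvalidScheduleError("cycle length must be >= 1 s")
    fraction = schedule.on_cycle_s / schedule.cycle_length_s
    return fraction, fraction * 24.0


@dataclass(frozen=True)
class StudyDesign:
    """Per-study sampling design: sensor schedules plus the local timezone
    used to cut event streams into calendar days."""

    study_id: str
    schedules: Mapping[str, SensorSchedule]
    timezone: str = "UTC"

    def schedule_for(self, sensor_name: str) -> SensorSchedule:
        try:
            return self.schedules[sensor_name]
        except KeyError:
            raise KeyError(
                f"study {self.study_id!r} has no schedule for sensor {sensor_name!r}; "
                f"known sensors: {sorted(self.schedules)}"
            ) from None


def load_design_config(path: str | Path) -> dict[str, StudyDesign]:
    """Read a YAML/JSON study-design config.

    Expected layout::

        study_a:
          timezone: America/New_York   # optional, default UTC
          sensors:
            gps: {on_cycle_s: 60, off_cycle_s: 540}
            accelerometer: {on_cycle_s: 10, off_cycle_s: 10}
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"design config {path} must map study ids to designs")
    designs: dict[str, StudyDesign] = {}
    for study_id, entry in raw.items():
        sensors = entry.get("sensors", {})
        schedules = {
            name: SensorSchedule(name, int(s["on_cycle_s"]), int(s["off_cycle_s"]))
            for name, s in sensors.items()
        }
        designs[str(study_id)] = StudyDesign(
            study_id=str(study_id),
            schedules=schedules,
            timezone=str(entry.get("timezone", "UTC")),
        )
    return designs
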