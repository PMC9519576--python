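"""Reading, writing and assembly of DAM2 activity-monitor data.

The TriKinetics Drosophila Activity Monitor (DAM2) houses 32 glass tubes,
each bisected by an infra-red beam; the unit of locomotor activity is one
beam break.  The monitor software exports one tab-separated text file per
monitor with one row per acquisition interval (one minute by default) and
42 fields: reading index, date (``dd mon yy``), time (``HH:MM:SS``), an
acquisition status code, six reserved instrument fields -- the last of
which carries the light-sensor flag -- and the 32 per-channel beam-break
counts.

This module parses that dialect loss-free, validates a channel-metadata
table mapping (monitor, channel) to fly line, sex, genome type, mtDNA
haplogroup, block and tube status, and assembles per-fly
:class:`BeamBreakSeries` annotated with the light phase.  The light phase
is derived from the configured lights-on clock time and photoperiod rather
than from the monitor's light sensor, which is unreliable in practice; the
sensor flag can be requested explicitly.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from datetime import datetime, time, timedelta
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

N_CHANNELS = 32
N_RESERVED = 6
N_FIELDS = 4 + N_RESERVED + N_CHANNELS  # 42
STATUS_VALID = 1

#: mtDNA haplogroup of each strain, used to auto-fill missing metadata.
#: Haplogroup I carries the shared ND1/ND2/ND5/ATP6 replacement variants;
#: haplogroup II comprises the European haplotypes.
HAPLOGROUP_BY_LINE = {
    "ORT": "I",
    "KSA2": "I",
    "BOG1": "I",
    "WT5A": "I",
    "M2": "I",
    "PYR2": "II",
    "LS": "II",
    "BS1": "II",
}

META_COLUMNS = [
    "monitor_id",
    "channel",
    "line",
    "sex",
    "genome_type",
    "haplogroup",
    "block",
    "replicate",
    "status",
]

_DATE_FMT = "%d %b %y"
_TIME_FMT = "%H:%M:%S"


class DamFormatError(ValueError):
    """Raised when a monitor file or metadata table violates the dialect."""


@dataclass(frozen=True)
class MonitorRecord:
    """One acquisition row of a DAM2 monitor file."""

    index: int
    timestamp: datetime
    status: int
    extras: tuple[str, ...]  # six reserved fields; extras[-1] is the light flag
    counts: np.ndarray  # (32,) non-negative ints, channels 1..32

    @property
    def light(self) -> int:
        return int(self.extras[-1])

    @property
    def valid(self) -> bool:
        """Whether the status code marks a valid acquisition."""
        return self.status == STATUS_VALID


@dataclass(frozen=True)
class ChannelMeta:
    """Metadata for one monitor channel (one tube)."""

    monitor_id: str
    channel: int
    line: str
    sex: str
    genome_type: str
    haplogroup: str
    block: str
    replicate: int
    status: str  # fly | blank | empty


@dataclass
class BeamBreakSeries:
    """One fly's (or blank tube's) per-minute beam-break counts."""

    fly_id: str
    meta: ChannelMeta
    minutes: np.ndarray  # datetime64[s], contiguous at the acquisition interval
    counts: np.ndarray  # non-negative ints, aligned with minutes
    light: np.ndarray  # 0|1, aligned with minutes

    def __post_init__(self) -> None:
        if not (len(self.minutes) == len(self.counts) == len(self.light)):
            raise ValueError("minutes, counts and light must have equal length")


def read_monitor_file(path: str | Path, acquisition_interval: int = 60) -> list[MonitorRecord]:
    """Parse a DAM2 monitor file into :class:`MonitorRecord` rows.

    Rows whose status code differs from 1 are retained and flagged via
    :attr:`MonitorRecord.valid`.  Raises :class:`DamFormatError` naming the
    offending line for malformed rows, non-monotone timestamps, or an empty
    file.
    """
    path = Path(path)
    records: list[MonitorRecord] = []
    prev_ts: datetime | None = None
    step = timedelta(seconds=acquisition_interval)
    with open(path, "r", encoding="ascii") as fh:
        for lineno, raw in enumerate(fh, start=1):
            raw = raw.rstrip("\n")
            if not raw:
                continue
            fields = raw.split("\t")
            if len(fields) != N_FIELDS:
                raise DamFormatError(
                    f"{path.name}:{lineno}: expected {N_FIELDS} tab-separated "
                    f"fields, got {len(fields)}"
                )
            try:
                idx = int(fields[0])
                ts = datetime.strptime(fields[1] + " " + fields[2], _DATE_FMT + " " + _TIME_FMT)
                status = int(fields[3])
                counts = np.array([int(x) for x in fields[4 + N_RESERVED:]], dtype=np.int64)
            except ValueError as exc:
                raise DamFormatError(f"{path.name}:{lineno}: malformed field ({exc})") from None
            if (counts < 0).any():
                raise DamFormatError(f"{path.name}:{lineno}: negative count")
            if prev_ts is not None and ts != prev_ts + step:
                raise DamFormatError(
                    f"{path.name}:{lineno}: timestamps must increase by "
                    f"{acquisition_interval}s (got {prev_ts} -> {ts})"
                )
            prev_ts = ts
            records.append(
                MonitorRecord(
                    index=idx,
                    timestamp=ts,
                    status=status,
                    extras=tuple(fields[4 : 4 + N_RESERVED]),
                    counts=counts,
                )
            )
    if not records:
        raise DamFormatError(f"{path.name}: empty monitor file")
    return records


def write_monitor_file(records: Sequence[MonitorRecord], path: str | Path) -> None:
    """Write records in the DAM2 dialect; inverse of :func:`read_monitor_file`."""
    path = Path(path)
    with open(path, "w", encoding="ascii", newline="") as fh:
        for rec in records:
            fields = [
                str(rec.index),
                rec.timestamp.strftime(_DATE_FMT),
                rec.timestamp.strftime(_TIME_FMT),
                str(rec.status),
                *rec.extras,
                *(str(int(c)) for c in rec.counts),
            ]
            fh.write("\t".join(fields) + "\n")


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise DamFormatError(msg)


def read_channel_meta(path: str | Path) -> list[ChannelMeta]:
    """Read and validate the channel-metadata CSV.

    The table must carry the header ``monitor_id,channel,line,sex,
    genome_type,haplogroup,block,replicate,status``.  A missing haplogroup
    is auto-filled from the strain name via :data:`HAPLOGROUP_BY_LINE`;
    an unknown strain with no haplogroup given, an inconsistent haplogroup,
    or a duplicate (monitor, channel) pair is an error.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in META_COLUMNS if c not in df.columns]
    _require(not missing, f"channel metadata missing columns: {missing}")
    seen: set[tuple[str, int]] = set()
    out: list[ChannelMeta] = []
    for i, row in df.iterrows():
        where = f"channel metadata row {i + 2}"
        try:
            channel = int(row["channel"])
        except ValueError:
            raise DamFormatError(f"{where}: non-integer channel {row['channel']!r}") from None
        key = (row["monitor_id"], channel)
        _require(key not in seen, f"{where}: duplicate (monitor, channel) {key}")
        seen.add(key)
        status = row["status"]
        _require(status in {"fly", "blank", "empty"}, f"{where}: bad status {status!r}")
        line, sex, gtype, hap = row["line"], row["sex"], row["genome_type"], row["haplogroup"]
        replicate = int(row["replicate"]) if row["replicate"] else 0
        if status == "fly":
            _require(sex in {"female", "male"}, f"{where}: bad sex {sex!r}")
            _require(
                gtype in {"coevolved", "cybrid"}, f"{where}: bad genome_type {gtype!r}"
            )
            known = HAPLOGROUP_BY_LINE.get(line)
            if not hap:
                _require(
                    known is not None,
                    f"{where}: unknown line {line!r} and no haplogroup given",
                )
                hap = known
            elif known is not None:
                _require(
                    hap == known,
                    f"{where}: haplogroup {hap!r} inconsistent with line {line!r} "
                    f"(expected {known!r})",
                )
        out.append(
            ChannelMeta(
                monitor_id=row["monitor_id"],
                channel=channel,
                line=line,
                sex=sex,
                genome_type=gtype,
                haplogroup=hap,
                block=row["block"],
                replicate=replicate,
                status=status,
            )
        )
    return out


def write_channel_meta(meta: Iterable[ChannelMeta], path: str | Path) -> None:
    """Write a channel-metadata CSV readable by :func:`read_channel_meta`."""
    with open(path, "w", encoding="ascii", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(META_COLUMNS)
        for m in meta:
            w.writerow(
                [
                    m.monitor_id,
                    m.channel,
                    m.line,
                    m.sex,
                    m.genome_type,
                    m.haplogroup,
                    m.block,
                    m.replicate if m.status == "fly" else "",
                    m.status,
                ]
            )


def schedule_light(
    timestamps: Sequence[datetime] | np.ndarray,
    lights_on: time,
    photoperiod_h: float = 12.0,
) -> np.ndarray:
    """Light-phase vector (1 = lights on) from the configured LD schedule."""
    on_min = lights_on.hour * 60 + lights_on.minute
    if isinstance(timestamps, np.ndarray) and np.issubdtype(timestamps.dtype, np.datetime64):
        secs = timestamps.astype("datetime64[s]").astype("int64")
        mod = (secs // 60) % 1440
    else:
        mod = np.array([t.hour * 60 + t.minute for t in timestamps], dtype=np.int64)
    phase = (mod - on_min) % 1440
    return (phase < photoperiod_h * 60).astype(np.int8)


def assemble_series(
    records: Sequence[MonitorRecord],
    meta: Sequence[ChannelMeta],
    lights_on: time = time(9, 0),
    photoperiod_h: float = 12.0,
    acquisition_s: int = 60,
    window_days: int = 3,
    burn_in_h: float = 0.0,
    light_source: str = "schedule",
) -> list[BeamBreakSeries]:
    """Assemble per-channel beam-break series from one monitor's records.

    The analysis window is the first complete lights-on-anchored
    ``window_days``-day stretch after discarding ``burn_in_h`` hours from
    the start of the file.  One series is emitted per metadata row with
    status ``fly`` or ``blank``; ``empty`` channels are skipped.  The light
    vector comes from the LD schedule unless ``light_source='file'``.
    """
    if not records:
        raise DamFormatError("no records to assemble")
    for m in meta:
        if not (1 <= m.channel <= N_CHANNELS):
            raise DamFormatError(
                f"metadata channel {m.channel} outside 1..{N_CHANNELS} "
                f"({m.monitor_id})"
            )
    per_day = int(round(86400 / acquisition_s))
    n_window = window_days * per_day
    earliest = records[0].timestamp + timedelta(hours=burn_in_h)
    start = None
    for i, rec in enumerate(records):
        if rec.timestamp >= earliest and rec.timestamp.time() == lights_on:
            start = i
            break
    if start is None or start + n_window > len(records):
        raise DamFormatError(
            f"no complete lights-on-anchored {window_days}-day window in file"
        )
    window = records[start : start + n_window]
    minutes = np.array([r.timestamp for r in window], dtype="datetime64[s]")
    if light_source == "file":
        light = np.array([r.light for r in window], dtype=np.int8)
    else:
        light = schedule_light(minutes, lights_on, photoperiod_h)
    count_mat = np.stack([r.counts for r in window])  # (n_window, 32)
    out: list[BeamBreakSeries] = []
    for m in meta:
        if m.status == "empty":
            continue
        out.append(
            BeamBreakSeries(
                fly_id=f"{m.monitor_id}:c{m.channel:02d}",
                meta=m,
                minutes=minutes,
                counts=count_mat[:, m.channel - 1].copy(),
                light=light.copy(),
            )
        )
    return out


def load_experiment(
    data_dir: str | Path,
    meta_file: str = "channel_meta.csv",
    **assemble_kwargs,
) -> list[BeamBreakSeries]:
    """Read all ``Monitor*.txt`` files plus the metadata CSV in a directory
    and assemble every fly/blank series."""
    data_dir = Path(data_dir)
    meta = read_channel_meta(data_dir / meta_file)
    by_monitor: dict[str, list[ChannelMeta]] = {}
    for m in meta:
        by_monitor.setdefault(m.monitor_id, []).append(m)
    series: list[BeamBreakSeries] = []
    for monitor_id in sorted(by_monitor):
        path = data_dir / f"{monitor_id}.txt"
        if not path.exists():
            raise DamFormatError(f"monitor file {path.name} referenced by metadata not found")
        records = read_monitor_file(path)
        series.extend(assemble_series(records, by_monitor[monitor_id], **assemble_kwargs))
    return series
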