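"""Sleep scoring, QC and per-fly phenotypes.

Sleep in *Drosophila* is scored with the field-standard rule: a 5-minute
time bin with zero beam breaks counts as sleep.  From the binned series
each fly yields three phenotypes over the analysis window:

``total_activity``
    total beam breaks,
``prop_asleep``
    fraction of 5-min bins scored asleep,
``mean_awake_activity``
    beam breaks per awake 5-min bin (undefined when every bin is asleep).

These satisfy the exact identity
``total_activity = mean_awake_activity * n_bins * (1 - prop_asleep)``.

QC removes dead flies (a terminal run of sleep bins spanning at least
``dead_tail_hours``, default 12 h, in a fly that was active earlier),
channels with no activity at all, and blank control channels; a blank
channel that registered counts is flagged as a monitor fault.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .dam_io import BeamBreakSeries, ChannelMeta

DEFAULT_BIN_MINUTES = 5
DEFAULT_DEAD_TAIL_HOURS = 12.0

PHENOTYPE_COLUMNS = [
    "fly_id",
    "line",
    "sex",
    "genome_type",
    "haplogroup",
    "block",
    "replicate",
    "total_activity",
    "prop_asleep",
    "n_sleep_bins",
    "n_bins",
    "mean_awake_activity",
    "qc_status",
]


@dataclass
class BinnedSeries:
    """A beam-break series aggregated onto the sleep-scoring bin grid."""

    fly_id: str
    bin_start: np.ndarray  # datetime64[s], anchored at the window start
    bin_counts: np.ndarray  # int, sum of per-minute counts in each bin
    asleep: np.ndarray  # bool, bin_counts == 0
    light: np.ndarray  # 0|1, majority phase of the bin's minutes
    bin_minutes: int


@dataclass
class PhenotypeRow:
    """Per-fly derived traits over the analysis window."""

    fly_id: str
    meta: ChannelMeta
    total_activity: int
    n_bins: int
    n_sleep_bins: int
    prop_asleep: float
    mean_awake_activity: float  # NaN when no awake bins
    qc_status: str


def bin_series(s: BeamBreakSeries, bin_minutes: int = DEFAULT_BIN_MINUTES) -> BinnedSeries:
    """Aggregate a 1-min series into ``bin_minutes`` bins and score sleep.

    Bins are half-open ``[t, t + bin_minutes)`` anchored at the window
    start; a bin is asleep iff its summed count is zero.  The window length
    must be a multiple of ``bin_minutes`` (the window is pre-truncated to
    whole days upstream).
    """
    n = len(s.counts)
    if n == 0:
        raise ValueError("empty series")
    if n % bin_minutes != 0:
        raise ValueError(
            f"window of {n} minutes is not a multiple of bin_minutes={bin_minutes}"
        )
    n_bins = n // bin_minutes
    counts = np.asarray(s.counts).reshape(n_bins, bin_minutes)
    bin_counts = counts.sum(axis=1)
    light = (
        np.asarray(s.light).reshape(n_bins, bin_minutes).mean(axis=1) > 0.5
    ).astype(np.int8)
    return BinnedSeries(
        fly_id=s.fly_id,
        bin_start=s.minutes[::bin_minutes].copy(),
        bin_counts=bin_counts,
        asleep=bin_counts == 0,
        light=light,
        bin_minutes=bin_minutes,
    )


def qc_classify(
    b: BinnedSeries,
    meta: ChannelMeta,
    dead_tail_hours: float = DEFAULT_DEAD_TAIL_HOURS,
) -> str:
    """Classify a binned series as ``ok``, ``dead``, ``all_zero`` or
    ``blank_active``.

    A fly is ``dead`` when its terminal run of sleep-scored bins spans at
    least ``dead_tail_hours`` and it was active earlier in the window --
    long enough that a genuine sleep bout is implausible.  A fly channel
    with no counts at all is ``all_zero`` (likely an empty or failed tube).
    A blank control that registered counts is ``blank_active``.
    """
    total = int(b.bin_counts.sum())
    if meta.status == "blank":
        return "blank_active" if total > 0 else "ok"
    if total == 0:
        return "all_zero"
    awake_idx = np.nonzero(~b.asleep)[0]
    tail_bins = len(b.asleep) - 1 - awake_idx[-1]
    tail_hours = tail_bins * b.bin_minutes / 60.0
    if tail_hours >= dead_tail_hours:
        return "dead"
    return "ok"


def compute_phenotypes(b: BinnedSeries, meta: ChannelMeta, qc_status: str = "ok") -> PhenotypeRow:
    """Compute the three per-fly phenotypes from a binned series."""
    n_bins = len(b.bin_counts)
    n_sleep = int(b.asleep.sum())
    total = int(b.bin_counts.sum())
    n_awake = n_bins - n_sleep
    mean_awake = total / n_awake if n_awake > 0 else math.nan
    return PhenotypeRow(
        fly_id=b.fly_id,
        meta=meta,
        total_activity=total,
        n_bins=n_bins,
        n_sleep_bins=n_sleep,
        prop_asleep=n_sleep / n_bins,
        mean_awake_activity=mean_awake,
        qc_status=qc_status,
    )


def phenotype_table(
    series: Sequence[BeamBreakSeries],
    bin_minutes: int = DEFAULT_BIN_MINUTES,
    dead_tail_hours: float = DEFAULT_DEAD_TAIL_HOURS,
) -> tuple[pd.DataFrame, dict]:
    """Score, QC and phenotype a whole experiment.

    Returns a phenotype table (one row per surviving fly) and a run log
    with counts at every exclusion step.  Dead, all-zero and blank channels
    are dropped; raising if no fly survives.
    """
    log = {
        "n_series": len(series),
        "n_fly_channels": 0,
        "n_blank": 0,
        "n_blank_active": 0,
        "n_dead": 0,
        "n_all_zero": 0,
        "n_ok": 0,
    }
    rows = []
    for s in series:
        b = bin_series(s, bin_minutes=bin_minutes)
        status = qc_classify(b, s.meta, dead_tail_hours=dead_tail_hours)
        if s.meta.status == "blank":
            log["n_blank"] += 1
            if status == "blank_active":
                log["n_blank_active"] += 1
            continue
        log["n_fly_channels"] += 1
        if status == "dead":
            log["n_dead"] += 1
            continue
        if status == "all_zero":
            log["n_all_zero"] += 1
            continue
        log["n_ok"] += 1
        p = compute_phenotypes(b, s.meta, qc_status=status)
        rows.append(
            {
                "fly_id": p.fly_id,
                "line": s.meta.line,
                "sex": s.meta.sex,
                "genome_type": s.meta.genome_type,
                "haplogroup": s.meta.haplogroup,
                "block": s.meta.block,
                "replicate": s.meta.replicate,
                "total_activity": p.total_activity,
                "prop_asleep": p.prop_asleep,
                "n_sleep_bins": p.n_sleep_bins,
                "n_bins": p.n_bins,
                "mean_awake_activity": p.mean_awake_activity,
                "qc_status": p.qc_status,
            }
        )
    if not rows:
        raise ValueError("no fly channels survived QC; nothing to phenotype")
    return pd.DataFrame(rows, columns=PHENOTYPE_COLUMNS), log


def day_night_summary(b: BinnedSeries) -> dict:
    """Day/night decomposition of sleep and activity for one fly.

    Reported for inspection; the fitted models use whole-window metrics.
    """
    out = {}
    for name, mask in (("day", b.light == 1), ("night", b.light == 0)):
        n = int(mask.sum())
        asleep = int(b.asleep[mask].sum())
        out[f"{name}_prop_asleep"] = asleep / n if n else math.nan
        out[f"{name}_activity"] = int(b.bin_counts[mask].sum())
    return out
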