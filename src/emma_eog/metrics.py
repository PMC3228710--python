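"""Downstream quantification of detected eye movements.

REM density is the number of detected REM per 4-s epoch of a given sleep
stage; a REM burst is a maximal run of at least two events whose consecutive
gaps do not exceed 200 ms.  Densities and morphology summaries are reported
per stage, per light/dark period and per 2-h zeitgeber bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .signal import Epoch

logger = logging.getLogger(__name__)

DEFAULT_MAX_GAP_MS = 200.0


@dataclass
class REMBurst:
    """A maximal run of >= 2 events with inter-event gaps <= the limit."""

    event_indices: list      # positional indices into the event table
    start_ms: float
    end_ms: float
    epoch_index: int         # epoch of the first member event

    @property
    def size(self) -> int:
        return len(self.event_indices)


def group_bursts(
    events: pd.DataFrame,
    max_gap_ms: float = DEFAULT_MAX_GAP_MS,
    gap_mode: str = "end_to_start",
) -> tuple[list[REMBurst], pd.DataFrame]:
    """Partition events (sorted by start) into bursts and isolated events.

    The gap between consecutive events is end-of-previous to start-of-next
    (``gap_mode="peak_to_peak"`` measures peak distances instead).  Returns
    the bursts and the isolated-event rows; every event lands in exactly one
    of the two.
    """
    if gap_mode not in ("end_to_start", "peak_to_peak"):
        raise ValueError(f"unknown gap_mode {gap_mode!r}")
    if len(events) == 0:
        return [], events.copy()
    ev = events.sort_values("start_ms").reset_index(drop=True)
    if gap_mode == "end_to_start":
        gaps = ev["start_ms"].to_numpy()[1:] - ev["end_ms"].to_numpy()[:-1]
    else:
        gaps = np.diff(ev["peak_ms"].to_numpy())
    linked = gaps <= max_gap_ms

    bursts: list[REMBurst] = []
    isolated_idx: list[int] = []
    run = [0]
    for i, lk in enumerate(linked):
        if lk:
            run.append(i + 1)
        else:
            _close_run(run, ev, bursts, isolated_idx)
            run = [i + 1]
    _close_run(run, ev, bursts, isolated_idx)
    return bursts, ev.iloc[isolated_idx]


def _close_run(run: list[int], ev: pd.DataFrame, bursts: list[REMBurst], isolated: list[int]) -> None:
    if len(run) >= 2:
        bursts.append(REMBurst(
            list(run),
            float(ev["start_ms"].iloc[run[0]]),
            float(ev["end_ms"].iloc[run[-1]]),
            int(ev["epoch_index"].iloc[run[0]]),
        ))
    else:
        isolated.extend(run)


# ---------------------------------------------------------------------------
# time bins
# ---------------------------------------------------------------------------

def _bin_of(zt: float, bins: str, bin_hours: float = 2.0) -> str:
    """Bin label for a zeitgeber hour.

    ``bins``: "day" (whole day), "period" (light ZT0-12 / dark ZT12-24) or
    "zt" (right-edge-labelled bins of ``bin_hours``, e.g. ZT2 = [ZT0, ZT2)).
    """
    if bins == "day":
        return "day"
    if bins == "period":
        return "light" if zt < 12.0 else "dark"
    if bins == "zt":
        right = (int(zt // bin_hours) + 1) * bin_hours
        return f"ZT{right:g}"
    raise ValueError(f"unknown bin spec {bins!r}")


def _density(
    count_by_epoch: dict[int, int],
    epochs: Sequence[Epoch],
    stage: str,
    bins: str,
    bin_hours: float,
    value_name: str,
) -> pd.DataFrame:
    rows: dict[str, dict] = {}
    for ep in epochs:
        if ep.stage != stage:
            continue
        label = _bin_of(ep.zt, bins, bin_hours)
        r = rows.setdefault(label, {"stage": stage, "bin": label, "n_epochs": 0, "n_items": 0})
        r["n_epochs"] += 1
        r["n_items"] += count_by_epoch.get(ep.index, 0)
    if not rows:
        logger.info("no %s epochs; density table empty", stage)
    out = pd.DataFrame(rows.values(), columns=["stage", "bin", "n_epochs", "n_items"])
    if len(out):
        out[value_name] = out["n_items"] / out["n_epochs"]
    else:
        out[value_name] = pd.Series(dtype=float)
    return out.reset_index(drop=True)


def rem_density(
    events: pd.DataFrame,
    epochs: Sequence[Epoch],
    stage: str,
    bins: str = "day",
    bin_hours: float = 2.0,
) -> pd.DataFrame:
    """Events per 4-s epoch of ``stage``, within each time bin.

    Events are assigned to the epoch containing their peak (``epoch_index``
    column); bins with zero epochs of the stage are omitted.
    """
    counts: dict[int, int] = {}
    for i in events["epoch_index"]:
        counts[int(i)] = counts.get(int(i), 0) + 1
    return _density(counts, epochs, stage, bins, bin_hours, "rem_density")


def burst_density(
    bursts: Sequence[REMBurst],
    epochs: Sequence[Epoch],
    stage: str,
    bins: str = "day",
    bin_hours: float = 2.0,
) -> pd.DataFrame:
    """Bursts per 4-s epoch of ``stage``; a burst counts in its first event's epoch."""
    counts: dict[int, int] = {}
    for b in bursts:
        counts[b.epoch_index] = counts.get(b.epoch_index, 0) + 1
    return _density(counts, epochs, stage, bins, bin_hours, "burst_density")


def density_table(
    events: pd.DataFrame,
    epochs: Sequence[Epoch],
    animal_id: str = "animal",
    day_id: str = "day",
    bins: str = "day",
    bin_hours: float = 2.0,
    max_gap_ms: float = DEFAULT_MAX_GAP_MS,
) -> pd.DataFrame:
    """Joint REM-density / burst-density table for one recording.

    Rows are keyed by (animal, day, stage, bin); multiple recordings
    concatenate into the full study table.
    """
    bursts, _ = group_bursts(events, max_gap_ms=max_gap_ms)
    frames = []
    for stage in ("REM", "NREM"):
        rd = rem_density(events, epochs, stage, bins, bin_hours)
        bd = burst_density(bursts, epochs, stage, bins, bin_hours)
        if len(rd) == 0:
            continue
        m = rd.merge(bd[["bin", "burst_density"]], on="bin", how="left")
        m["burst_density"] = m["burst_density"].fillna(0.0)
        frames.append(m)
    if not frames:
        return pd.DataFrame(columns=["animal", "day", "stage", "bin", "n_epochs",
                                     "rem_density", "burst_density"])
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "animal", animal_id)
    out.insert(1, "day", day_id)
    return out[["animal", "day", "stage", "bin", "n_epochs", "rem_density", "burst_density"]]


def morphology_summary(
    events: pd.DataFrame,
    epochs: Optional[Sequence[Epoch]] = None,
    by: Sequence[str] = ("stage",),
    max_gap_ms: float = DEFAULT_MAX_GAP_MS,
) -> pd.DataFrame:
    """Grouped mean +- sd of event morphology.

    Groupers (``by``) may include "stage", "in_burst", "period" and "zt_bin"
    (the latter two require ``epochs`` for zeitgeber lookup).  Reported per
    group: n, mean/sd of duration_ms, |amplitude|, v_initial, v_return, the
    proportion of upward deflections and the proportion of events in bursts.
    Empty selections yield no row (NA by omission).
    """
    ev = events.sort_values("start_ms").reset_index(drop=True).copy()
    if len(ev) == 0:
        return pd.DataFrame()
    bursts, _ = group_bursts(ev, max_gap_ms=max_gap_ms)
    in_burst = np.zeros(len(ev), dtype=bool)
    for b in bursts:
        in_burst[b.event_indices] = True
    ev["in_burst"] = in_burst
    ev["abs_amplitude"] = ev["amplitude_mV"].abs()
    ev["upward"] = (ev["direction"] == "upward").astype(float)
    if epochs is not None:
        zt = {e.index: e.zt for e in epochs}
        ev["period"] = [_bin_of(zt[int(i)], "period") for i in ev["epoch_index"]]
        ev["zt_bin"] = [_bin_of(zt[int(i)], "zt") for i in ev["epoch_index"]]
        if "stage" not in ev.columns:
            stages = {e.index: e.stage for e in epochs}
            ev["stage"] = [stages[int(i)] for i in ev["epoch_index"]]

    missing = [g for g in by if g not in ev.columns]
    if missing:
        raise ValueError(f"unknown groupers: {missing}")
    agg = ev.groupby(list(by), observed=True).agg(
        n=("duration_ms", "size"),
        duration_ms_mean=("duration_ms", "mean"),
        duration_ms_sd=("duration_ms", "std"),
        amplitude_mean=("abs_amplitude", "mean"),
        amplitude_sd=("abs_amplitude", "std"),
        v_initial_mean=("v_initial", "mean"),
        v_initial_sd=("v_initial", "std"),
        v_return_mean=("v_return", "mean"),
        v_return_sd=("v_return", "std"),
        prop_upward=("upward", "mean"),
        prop_in_burst=("in_burst", "mean"),
    )
    return agg.reset_index()
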