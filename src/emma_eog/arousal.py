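"""Micro-arousal detection from RMS-EMG and REM/arousal association.

A micro-arousal is a transient (< 4 s) EMG increase during sleep.  Detection
thresholds the RMS-EMG against ``k`` times a rolling-median sleep baseline;
runs lasting 4 s or more are excluded as state transitions.  Association of
events/bursts with arousals is interval overlap (optionally padded, or
same-epoch co-occurrence), tabulated per sleep stage into 2x2 contingency
tables tested with the (Yates-corrected by default) chi-square statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, chi2 as chi2_dist

from .signal import Hypnogram, Recording, SLEEP_STAGES, epoch_grid

logger = logging.getLogger(__name__)


@dataclass
class MicroArousal:
    start: int               # sample indices
    end: int                 # exclusive
    duration_ms: float
    peak_emg_ratio: float    # peak RMS-EMG / local baseline


def detect_microarousals(
    emg_rms: np.ndarray,
    hyp: Hypnogram,
    fs: float = 64.0,
    k_threshold: float = 3.0,
    baseline_win_s: float = 30.0,
    max_duration_s: float = 4.0,
) -> list[MicroArousal]:
    """Maximal supra-threshold EMG runs during sleep, shorter than 4 s.

    The baseline is a centred rolling median of the RMS-EMG over sleep-only
    samples (wake samples are masked out); a sample is active when
    ``emg_rms > k_threshold * baseline``.  Runs reaching ``max_duration_s``
    are excluded (state transitions) and logged.
    """
    if emg_rms is None:
        raise ValueError("no EMG-RMS channel available")
    x = np.asarray(emg_rms, dtype=float)
    spe = int(round(fs * hyp.epoch_len))
    sleep = np.zeros(x.size, dtype=bool)
    for i, st in enumerate(hyp.stages):
        if st in SLEEP_STAGES:
            sleep[i * spe:(i + 1) * spe] = True

    ser = pd.Series(np.where(sleep, x, np.nan))
    win = int(round(baseline_win_s * fs))
    base = ser.rolling(win, center=True, min_periods=max(8, win // 8)).median()
    base = base.ffill().bfill().to_numpy()

    active = sleep & (x > k_threshold * base)
    out: list[MicroArousal] = []
    edges = np.flatnonzero(np.diff(np.concatenate([[0], active.view(np.int8), [0]])))
    for s, e in zip(edges[::2], edges[1::2]):
        dur_s = (e - s) / fs
        if dur_s >= max_duration_s:
            logger.info("EMG run of %.1f s at sample %d excluded (>= 4 s)", dur_s, s)
            continue
        ratio = float(np.max(x[s:e] / base[s:e]))
        out.append(MicroArousal(int(s), int(e), dur_s * 1000.0, ratio))
    return out


def arousals_to_frame(arousals: Sequence[MicroArousal], fs: float) -> pd.DataFrame:
    return pd.DataFrame(
        [{"start": a.start, "end": a.end,
          "start_ms": a.start / fs * 1000.0, "end_ms": a.end / fs * 1000.0,
          "duration_ms": a.duration_ms, "peak_emg_ratio": a.peak_emg_ratio}
         for a in arousals],
        columns=["start", "end", "start_ms", "end_ms", "duration_ms", "peak_emg_ratio"],
    )


def associate(
    items: pd.DataFrame,
    arousals: pd.DataFrame,
    window_ms: float = 0.0,
    mode: str = "overlap",
    epoch_len: float = 4.0,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Flag each item (event or burst) as micro-arousal associated.

    ``items`` needs ``start_ms``/``end_ms`` (and ``stage`` for tabulation);
    ``arousals`` needs ``start_ms``/``end_ms``.  In "overlap" mode an item is
    associated iff its interval overlaps any arousal padded by ``window_ms``;
    in "epoch" mode iff any arousal touches the item's 4-s epoch (the mode
    used for published-style tables, which scored within epochs).  Returns
    per-item flags and a per-stage 2x2 table {stage: [[assoc, not-assoc]]}.
    """
    n = len(items)
    flags = np.zeros(n, dtype=bool)
    if n and len(arousals):
        a_s = arousals["start_ms"].to_numpy(float) - window_ms
        a_e = arousals["end_ms"].to_numpy(float) + window_ms
        if mode == "overlap":
            i_s = items["start_ms"].to_numpy(float)
            i_e = items["end_ms"].to_numpy(float)
        elif mode == "epoch":
            spe_ms = epoch_len * 1000.0
            ep = np.floor(items["start_ms"].to_numpy(float) / spe_ms)
            i_s, i_e = ep * spe_ms, (ep + 1) * spe_ms
        else:
            raise ValueError(f"unknown association mode {mode!r}")
        for j in range(n):
            flags[j] = bool(np.any((a_s <= i_e[j]) & (a_e >= i_s[j])))
    tables: dict[str, np.ndarray] = {}
    if "stage" in items.columns:
        for stage, grp in items.assign(assoc=flags).groupby("stage"):
            a = int(grp["assoc"].sum())
            tables[str(stage)] = np.array([a, len(grp) - a])
    return flags, tables


def contingency_2x2(row_a: np.ndarray, row_b: np.ndarray) -> np.ndarray:
    """Stack two (associated, not-associated) rows into a 2x2 table."""
    t = np.vstack([row_a, row_b]).astype(int)
    if t.min() < 0 or t.sum() == 0:
        raise ValueError("invalid contingency table")
    return t


def chi_square_2x2(table: np.ndarray, correction: str = "yates") -> dict:
    """Pearson chi-square for a 2x2 table, Yates-corrected by default.

    Returns ``{"statistic", "df", "p"}``; a zero marginal makes the
    statistic undefined (NaN, with a warning).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if t.sum() <= 0:
        raise ValueError("empty table")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        logger.warning("zero marginal; chi-square undefined")
        return {"statistic": np.nan, "df": 1, "p": np.nan}
    if correction not in ("yates", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    stat, p, df, _ = chi2_contingency(t, correction=(correction == "yates"))
    return {"statistic": float(stat), "df": int(df), "p": float(p)}


def sample_association_epochs(
    items: pd.DataFrame,
    per_cell: int = 10,
    by: Sequence[str] = ("animal", "day", "stage"),
    seed: int = 0,
) -> pd.DataFrame:
    """Seeded random draw of item epochs, ``per_cell`` per stratum.

    Mirrors a stratified visual-scoring sample (e.g. 10 epochs x animals x
    days x stages); cells with fewer items contribute all of them.
    """
    rng = np.random.default_rng(seed)
    parts = []
    for _, grp in items.groupby(list(by)):
        k = min(per_cell, len(grp))
        pick = rng.choice(len(grp), size=k, replace=False)
        parts.append(grp.iloc[np.sort(pick)])
    return pd.concat(parts, ignore_index=True) if parts else items.iloc[:0]
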