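"""The EMMA detection pipeline.

Per 4-s analysis window: low-cut filter -> finest-scale wavelet modulus
maxima (singularity candidates) -> delineation into start/peak/end ->
amplitude criterion (signed peak beyond 4 x P85 / 4 x P15 of the signal)
-> adjacent-singularity resolution -> lag-2 difference criterion against
2 x Q95 of the candidate-free background.  Each epoch is analysed on three
overlapping windows (-1 s, 0 s, +1 s offsets) and detections are
deduplicated across windows.

The percentile/quantile thresholds are computed, by default, over the
filtered sleep portion of the whole recording (``threshold_support =
"recording"``), mirroring threshold derivation from a training stretch of
signal; ``"window"`` computes them per 4-s analysis window instead.  All
thresholds are relative to the signal itself, so detection is equivariant
under positive rescaling, and the pipeline is fully deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .signal import Epoch, Hypnogram, Recording, SLEEP_STAGES, epoch_grid
from .wavelet import (
    cwt_mexhat,
    dyadic_lowcut,
    finest_scale_maxima,
    local_maxima,
    universal_threshold,
)

logger = logging.getLogger(__name__)


@dataclass
class DetectorConfig:
    """Thresholds and wavelet parameters of the detector.

    Defaults follow the published criteria: amplitude beyond 4 x the 85th /
    15th percentile of the signal, lag-2 difference above 2 x the 95th
    quantile of the candidate-free background, 8-scale dyadic low-cut with
    scales 4-8 zeroed, Mexican-hat CWT on 8 octaves x 8 voices, three
    overlapping windows offset by -1/0/+1 s around each 4-s epoch.
    """

    amp_hi_mult: float = 4.0
    amp_lo_mult: float = 4.0
    amp_hi_pct: float = 85.0
    amp_lo_pct: float = 15.0
    lag2_mult: float = 2.0
    lag2_q: float = 0.95
    lag: int = 2
    window_offsets_s: tuple = (-1.0, 0.0, 1.0)
    epoch_len: float = 4.0
    octaves: int = 8
    voices: int = 8
    finest_scale: float = 2.0
    lowcut_scales: int = 8
    lowcut_zero: tuple = (4, 5, 6, 7, 8)
    lowcut_wavelet: str = "bior2.2"
    apply_lowcut: bool = True
    threshold_support: str = "recording"   # or "window"
    dedup_tol: int = 2          # samples: cross-window peak merge distance
    failed_span: int = 5        # +-samples excluded around failed candidates
    stages: tuple = SLEEP_STAGES

    def __post_init__(self) -> None:
        for name in ("amp_hi_mult", "amp_lo_mult", "lag2_mult"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.threshold_support not in ("recording", "window"):
            raise ValueError("threshold_support must be 'recording' or 'window'")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class REMEvent:
    """One detected rapid eye movement with its morphology.

    Sample indices are absolute within the recording; the event is assigned
    to the epoch containing its peak.  ``amplitude`` is the signed filtered
    EOG value at the peak in mV (including amplification); velocities are
    magnitudes in mV/ms for the initial (start->peak) and return (peak->end)
    deflections.
    """

    start: int
    peak: int
    end: int
    epoch_index: int
    amplitude: float
    direction: str          # "upward" | "downward"
    duration_ms: float
    v_initial: float
    v_return: float

    def __post_init__(self) -> None:
        if not (self.start < self.peak < self.end):
            raise ValueError("event landmarks must satisfy start < peak < end")
        if (self.amplitude > 0) != (self.direction == "upward"):
            raise ValueError("direction inconsistent with amplitude sign")


@dataclass
class _Thresholds:
    """Signal-relative thresholds shared by one detection run."""

    amp_hi: float
    amp_lo: float
    lag2: Optional[float] = None   # None -> per-window background
    wtmm: Optional[float] = None   # None -> per-window universal threshold


# ---------------------------------------------------------------------------
# single-window primitives
# ---------------------------------------------------------------------------

def candidate_positions(epoch_signal: np.ndarray, cfg: DetectorConfig = DetectorConfig()) -> np.ndarray:
    """Singularity candidates of an already low-cut-filtered window."""
    c = cwt_mexhat(epoch_signal, cfg.octaves, cfg.voices, cfg.finest_scale)
    return finest_scale_maxima(c).positions


def _amp_thresholds(signal: np.ndarray, cfg: DetectorConfig) -> tuple[float, float]:
    hi = cfg.amp_hi_mult * np.percentile(signal, cfg.amp_hi_pct)
    lo = cfg.amp_lo_mult * np.percentile(signal, cfg.amp_lo_pct)
    return float(hi), float(lo)


def amplitude_criterion(
    signal: np.ndarray, peaks: Sequence[int], cfg: DetectorConfig = DetectorConfig()
) -> list[int]:
    """Keep candidates whose signed peak value clears the amplitude criterion.

    ``peaks`` are the delineated peak indices associated with the candidates;
    a peak passes iff signal[peak] > 4*P85(signal) or < 4*P15(signal).
    """
    hi, lo = _amp_thresholds(signal, cfg)
    return [int(p) for p in peaks if signal[p] > hi or signal[p] < lo]


def lag2_criterion(
    signal: np.ndarray,
    candidates: Sequence[tuple[int, int]],
    cfg: DetectorConfig = DetectorConfig(),
    extra_exclude: Sequence[tuple[int, int]] = (),
    threshold: Optional[float] = None,
) -> list[bool]:
    """Instantaneous-amplitude screen against regular fast artifacts.

    ``candidates`` are (start, end) spans (inclusive).  The background is
    every lag-2 difference with both samples outside all candidate spans and
    ``extra_exclude`` zones; a candidate passes iff its own maximal absolute
    lag-2 difference exceeds ``lag2_mult`` x Q95 of that background (or the
    precomputed ``threshold`` when given).  With no background left, nothing
    is rejected (warned).
    """
    x = np.asarray(signal, dtype=float)
    lag = cfg.lag
    if x.size <= lag:
        raise ValueError("signal too short for lag differences")
    diffs = np.abs(x[lag:] - x[:-lag])          # diffs[t] spans samples [t, t+lag]
    if threshold is None:
        in_span = np.zeros(x.size, dtype=bool)
        for s, e in list(candidates) + list(extra_exclude):
            in_span[max(0, s):min(x.size, e + 1)] = True
        bg_mask = ~(in_span[lag:] | in_span[:-lag])
        if not bg_mask.any():
            logger.warning("lag-2 criterion: no candidate-free background; rejecting none")
            return [True] * len(candidates)
        threshold = cfg.lag2_mult * float(np.quantile(diffs[bg_mask], cfg.lag2_q))
    out = []
    for s, e in candidates:
        seg = diffs[max(0, s - lag):min(e, diffs.size - 1) + 1]
        cand_max = float(seg.max()) if seg.size else 0.0
        out.append(cand_max > threshold)
    return out


def delineate(
    signal: np.ndarray, singularity: int, coef_sign: float = 1.0
) -> Optional[tuple[int, int, int]]:
    """Locate start/peak/end of the deflection around a singularity.

    For a positive deflection (``coef_sign >= 0``) the peak is the local
    maximum nearest to the singularity (the wavelet localises the peak to
    within a sample or two, so the nearest extremum of the indicated branch
    is taken; distance ties resolve to the earlier sample), the start the
    nearest local minimum before the peak and the end the nearest local
    minimum after it.  For a negative deflection minima and maxima are
    exchanged.  Returns ``None`` (caller logs and discards) if a required
    extremum does not exist.
    """
    x = np.asarray(signal, dtype=float)
    s = x if coef_sign >= 0 else -x
    maxima = local_maxima(s)
    minima = local_maxima(-s)
    if maxima.size == 0:
        return None
    peak = int(maxima[np.argmin(np.abs(maxima - singularity))])
    before = minima[minima < peak]
    after = minima[minima > peak]
    if before.size == 0 or after.size == 0:
        return None
    start = int(before[-1])
    end = int(after[0])
    if not (start < peak < end):
        return None
    return start, peak, end


def resolve_adjacent(
    signal: np.ndarray,
    singularities: Sequence[int],
    cfg: DetectorConfig = DetectorConfig(),
    coef_signs: Optional[Sequence[float]] = None,
    thresholds: Optional[_Thresholds] = None,
) -> tuple[list[tuple[int, int, int]], list[tuple[int, int]]]:
    """Delineate candidates and resolve stacked (chained) deflections.

    When the peak of one event is the start of the next, the second event is
    retained only if its own peak clears the amplitude criterion; otherwise
    it is merged into the first event's return phase.  Returns the kept
    (start, peak, end) triples and the spans of rejected/failed candidates
    (for background exclusion in the lag-2 criterion).
    """
    x = np.asarray(signal, dtype=float)
    if coef_signs is None:
        coef_signs = [1.0] * len(singularities)
    if thresholds is None:
        hi, lo = _amp_thresholds(x, cfg)
    else:
        hi, lo = thresholds.amp_hi, thresholds.amp_lo

    delineated: list[tuple[int, int, int]] = []
    rejected_spans: list[tuple[int, int]] = []
    seen = set()
    for sing, sgn in zip(singularities, coef_signs):
        tri = delineate(x, int(sing), sgn)
        if tri is None:
            logger.debug("candidate at %d: no bracketing extremum, discarded", sing)
            rejected_spans.append((int(sing) - cfg.failed_span, int(sing) + cfg.failed_span))
            continue
        if tri in seen:
            continue
        seen.add(tri)
        delineated.append(tri)
    delineated.sort(key=lambda t: (t[0], t[1]))

    kept: list[tuple[int, int, int]] = []
    for tri in delineated:
        start, peak, end = tri
        if x[peak] > hi or x[peak] < lo:
            if kept and start < kept[-1][2] and peak == kept[-1][1]:
                continue            # same deflection described twice
            kept.append(tri)
        else:
            if kept and start in (kept[-1][1], kept[-1][2]):
                # sub-threshold follower sharing a change point with the
                # previous event: absorb into its return phase
                prev = kept[-1]
                kept[-1] = (prev[0], prev[1], max(prev[2], end))
            else:
                rejected_spans.append((start, end))
    # enforce non-overlap (shared endpoints allowed): on conflict keep the
    # deflection with the larger absolute peak -- a large rebound between or
    # after deflections is that deflection's return phase, not a new event
    out: list[tuple[int, int, int]] = []
    for tri in kept:
        if out and tri[0] < out[-1][2]:
            if abs(x[tri[1]]) > abs(x[out[-1][1]]):
                out[-1] = tri
            continue
        out.append(tri)
    return out, rejected_spans


# ---------------------------------------------------------------------------
# windowing machinery
# ---------------------------------------------------------------------------

def _window_events(
    fwin: np.ndarray,
    finest: np.ndarray,
    cfg: DetectorConfig,
    thresholds: Optional[_Thresholds],
) -> list[tuple]:
    """Full chain on one filtered window given its finest-scale coefficients.

    Returns tuples ``(start, peak, end, f_start, f_peak, f_end)``.
    """
    m = np.abs(finest)
    if thresholds is not None and thresholds.wtmm is not None:
        thr = thresholds.wtmm
    else:
        thr = universal_threshold(m, m.size)
    idx = local_maxima(m)
    idx = idx[m[idx] > thr]
    if idx.size == 0:
        return []
    signs = np.sign(finest[idx])
    triples, rejected = resolve_adjacent(fwin, idx, cfg, signs, thresholds)
    if not triples:
        return []
    spans = [(s, e) for s, _, e in triples]
    keep = lag2_criterion(fwin, spans, cfg, extra_exclude=rejected,
                          threshold=None if thresholds is None else thresholds.lag2)
    return [
        (s, p, e, float(fwin[s]), float(fwin[p]), float(fwin[e]))
        for (s, p, e), k in zip(triples, keep) if k
    ]


def _reflect_slice(x: np.ndarray, start: int, length: int) -> np.ndarray:
    """Slice with symmetric reflection beyond the array bounds."""
    n = x.size
    if start >= 0 and start + length <= n:
        return x[start:start + length]
    idx = np.arange(start, start + length)
    idx = np.abs(idx)
    idx = np.where(idx >= n, 2 * (n - 1) - idx, idx)
    return x[idx]


@dataclass
class _RunContext:
    """Whole-recording precomputation shared across epochs.

    The low-cut filter and the finest-scale CWT are shift invariant, so the
    full-signal transforms sliced per window coincide with per-window
    transforms away from the recording edges, at a fraction of the cost.
    """

    filtered: np.ndarray
    finest: np.ndarray
    thresholds: Optional[_Thresholds]


def _sleep_mask(rec: Recording, hyp: Hypnogram, cfg: DetectorConfig) -> np.ndarray:
    spe = int(round(rec.fs * hyp.epoch_len))
    mask = np.zeros(rec.n_samples, dtype=bool)
    for i, st in enumerate(hyp.stages):
        if st in cfg.stages:
            mask[i * spe:(i + 1) * spe] = True
    return mask


def _build_context(rec: Recording, hyp: Hypnogram, cfg: DetectorConfig) -> _RunContext:
    f = dyadic_lowcut(rec.eog, cfg.lowcut_scales, cfg.lowcut_zero,
                      cfg.lowcut_wavelet) if cfg.apply_lowcut else rec.eog.astype(float)
    c = cwt_mexhat(f, octaves=1, voices=1, finest=cfg.finest_scale).finest
    if cfg.threshold_support == "window":
        return _RunContext(f, c, None)
    mask = _sleep_mask(rec, hyp, cfg)
    support = f[mask] if mask.any() else f
    hi = cfg.amp_hi_mult * float(np.percentile(support, cfg.amp_hi_pct))
    lo = cfg.amp_lo_mult * float(np.percentile(support, cfg.amp_lo_pct))
    # candidate-free background for the lag-2 quantile: exclude the vicinity
    # of every finest-scale modulus maximum above the (256-sample convention)
    # universal threshold
    m = np.abs(c)
    thr = universal_threshold(m[mask] if mask.any() else m,
                              int(round(rec.fs * hyp.epoch_len)))
    cand = local_maxima(m)
    cand = cand[m[cand] > thr]
    excl = np.zeros(f.size, dtype=bool)
    for p in cand:
        excl[max(0, p - cfg.failed_span):p + cfg.failed_span + 1] = True
    lag = cfg.lag
    diffs = np.abs(f[lag:] - f[:-lag])
    bg = mask[lag:] & mask[:-lag] & ~(excl[lag:] | excl[:-lag])
    if not bg.any():
        bg = ~(excl[lag:] | excl[:-lag])
    lag2_thr = cfg.lag2_mult * float(np.quantile(diffs[bg], cfg.lag2_q))
    return _RunContext(f, c, _Thresholds(hi, lo, lag2_thr, thr))


def detect_epoch(
    rec: Recording,
    epoch: Epoch,
    cfg: DetectorConfig = DetectorConfig(),
    _ctx: Optional[_RunContext] = None,
) -> list[REMEvent]:
    """Detect REM in one epoch using three overlapping windows.

    Windows start at the epoch offset by -1, 0 and +1 s (portions beyond the
    recording are filled by symmetric reflection); events whose peaks agree
    within ``cfg.dedup_tol`` samples are deduplicated keeping the detection
    whose peak lies farthest from its window's edges, and only events
    peaking inside the epoch span are returned.

    Standalone calls (without the context prepared by :func:`detect`) fall
    back to per-window threshold support.
    """
    fs = rec.fs
    wlen = int(round(cfg.epoch_len * fs))
    n = rec.n_samples
    # (abs start, abs peak, abs end, f_start, f_peak, f_end, edge distance)
    found: list[tuple] = []
    for off_s in cfg.window_offsets_s:
        wstart = epoch.start + int(round(off_s * fs))
        if _ctx is None:
            win = _reflect_slice(rec.eog, wstart, wlen)
            fwin = dyadic_lowcut(win, cfg.lowcut_scales, cfg.lowcut_zero,
                                 cfg.lowcut_wavelet) if cfg.apply_lowcut else win
            finest = cwt_mexhat(fwin, octaves=1, voices=1, finest=cfg.finest_scale).finest
            thresholds = None
        else:
            fwin = _reflect_slice(_ctx.filtered, wstart, wlen)
            finest = _reflect_slice(_ctx.finest, wstart, wlen)
            thresholds = _ctx.thresholds
        for s, p, e, fs_v, fp_v, fe_v in _window_events(fwin, finest, cfg, thresholds):
            a_s, a_p, a_e = s + wstart, p + wstart, e + wstart
            if a_s < 0 or a_e >= n:
                continue
            edge = min(p, wlen - 1 - p)
            found.append((a_s, a_p, a_e, fs_v, fp_v, fe_v, edge))

    found.sort(key=lambda t: (t[1], -t[6]))
    merged: list[tuple] = []
    for ev in found:
        if merged and abs(ev[1] - merged[-1][1]) <= cfg.dedup_tol:
            if ev[6] > merged[-1][6]:
                merged[-1] = ev
            continue
        merged.append(ev)

    out: list[REMEvent] = []
    for s, p, e, fs_v, fp_v, fe_v, _ in merged:
        if not (epoch.start <= p < epoch.end):
            continue
        if out and s < out[-1].end:
            continue
        if fp_v == 0:
            continue
        dur_ms = (e - s) / fs * 1000.0
        up_ms = (p - s) / fs * 1000.0
        down_ms = (e - p) / fs * 1000.0
        out.append(REMEvent(
            s, p, e, epoch.index, fp_v,
            "upward" if fp_v > 0 else "downward", dur_ms,
            abs(fp_v - fs_v) / up_ms if up_ms else 0.0,
            abs(fe_v - fp_v) / down_ms if down_ms else 0.0,
        ))
    return out


def events_to_frame(events: Iterable[REMEvent], fs: float) -> pd.DataFrame:
    rows = [{
        "epoch_index": e.epoch_index,
        "start": e.start, "peak": e.peak, "end": e.end,
        "start_ms": e.start / fs * 1000.0,
        "peak_ms": e.peak / fs * 1000.0,
        "end_ms": e.end / fs * 1000.0,
        "amplitude_mV": e.amplitude,
        "direction": e.direction,
        "duration_ms": e.duration_ms,
        "v_initial": e.v_initial,
        "v_return": e.v_return,
    } for e in events]
    cols = ["epoch_index", "start", "peak", "end", "start_ms", "peak_ms",
            "end_ms", "amplitude_mV", "direction", "duration_ms",
            "v_initial", "v_return"]
    return pd.DataFrame(rows, columns=cols)


def detect(
    rec: Recording,
    hyp: Hypnogram,
    cfg: DetectorConfig = DetectorConfig(),
) -> pd.DataFrame:
    """Run the detector over every sleep epoch of a recording.

    Returns one row per detected event (see :func:`events_to_frame`) plus a
    ``stage`` column; only epochs whose stage is in ``cfg.stages`` (default
    NREM and REM sleep) are scanned.
    """
    epochs = epoch_grid(rec, hyp)
    ctx = _build_context(rec, hyp, cfg)
    events: list[REMEvent] = []
    for ep in epochs:
        if ep.stage not in cfg.stages:
            continue
        events.extend(detect_epoch(rec, ep, cfg, _ctx=ctx))
    df = events_to_frame(events, rec.fs)
    df["stage"] = [epochs[i].stage for i in df["epoch_index"]] if len(df) else pd.Series(dtype=object)
    return df


def validate_against_reference(
    detected: pd.DataFrame,
    reference: pd.DataFrame,
    n_epochs: int,
    fs: float = 64.0,
    tol_ms: float = 50.0,
    epoch_len: float = 4.0,
) -> dict:
    """Score detections against a reference event list.

    Event level: a reference event is a true positive when a detection peak
    falls within ``tol_ms`` of its peak (greedy one-to-one matching in time
    order); sensitivity and PPV are reported.  Epoch level: 2x2 tabulation of
    event presence per epoch gives sensitivity, specificity, PPV and NPV.
    With no reference and no detected events all metrics are NaN.
    """
    det_peaks = np.sort(detected["peak_ms"].to_numpy(float)) if len(detected) else np.empty(0)
    ref_peaks = np.sort(reference["peak_ms"].to_numpy(float)) if len(reference) else np.empty(0)

    matched_ref = 0
    used = np.zeros(det_peaks.size, dtype=bool)
    j = 0
    for rp in ref_peaks:
        while j < det_peaks.size and det_peaks[j] < rp - tol_ms:
            j += 1
        k = j
        while k < det_peaks.size and det_peaks[k] <= rp + tol_ms:
            if not used[k]:
                used[k] = True
                matched_ref += 1
                break
            k += 1
    tp_det = int(used.sum())

    event = {
        "sensitivity": matched_ref / ref_peaks.size if ref_peaks.size else np.nan,
        "ppv": tp_det / det_peaks.size if det_peaks.size else np.nan,
        "n_reference": int(ref_peaks.size),
        "n_detected": int(det_peaks.size),
    }

    spe_ms = epoch_len * 1000.0
    ref_ep = set((ref_peaks // spe_ms).astype(int))
    det_ep = set((det_peaks // spe_ms).astype(int))
    all_ep = set(range(n_epochs))
    tp = len(ref_ep & det_ep)
    fn = len(ref_ep - det_ep)
    fp = len(det_ep - ref_ep)
    tn = len(all_ep - ref_ep - det_ep)

    def _ratio(a, b):
        return a / b if b else np.nan

    epoch = {
        "sensitivity": _ratio(tp, tp + fn),
        "specificity": _ratio(tn, tn + fp),
        "ppv": _ratio(tp, tp + fp),
        "npv": _ratio(tn, tn + fn),
        "table": {"tp": tp, "fp": fp, "fn": fn, "tn": tn},
    }
    return {"event": event, "epoch": epoch}
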