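"""Recording/hypnogram containers, file I/O and the 4-s epoch grid.

Conventions: sample indices are 0-based with half-open spans; the epoch grid
is anchored at sample 0; zeitgeber time (ZT) is hours since lights-on with
``t0`` supplied by the user (ZT0 = lights on in a 12:12 light/dark cycle).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STAGES = ("WAKE", "NREM", "REM")
SLEEP_STAGES = ("NREM", "REM")

DEFAULT_EPOCH_LEN = 4.0   # seconds
DEFAULT_FS = 64.0         # Hz


@dataclass
class Recording:
    """Synchronized EOG (and optional RMS-EMG) channels on one sample grid.

    ``eog`` is the electrooculogram in mV (post-amplification); ``emg_rms``
    the root-mean-square transformed neck EMG in arbitrary units.
    """

    eog: np.ndarray
    emg_rms: Optional[np.ndarray] = None
    fs: float = DEFAULT_FS
    t0: float = 0.0             # recording start, ZT hours
    animal_id: str = "animal"
    day_id: str = "day"

    def __post_init__(self) -> None:
        self.eog = np.asarray(self.eog, dtype=float)
        if self.eog.ndim != 1:
            raise ValueError("EOG channel must be one-dimensional")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.emg_rms is not None:
            self.emg_rms = np.asarray(self.emg_rms, dtype=float)
            if self.emg_rms.shape != self.eog.shape:
                raise ValueError("channel lengths differ (EOG vs EMG-RMS)")
        if self.n_samples < self.fs * DEFAULT_EPOCH_LEN:
            raise ValueError("recording shorter than one 4-s epoch")

    @property
    def n_samples(self) -> int:
        return int(self.eog.shape[0])

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class Hypnogram:
    """Vigilance-state labels (WAKE/NREM/REM), one per epoch."""

    stages: np.ndarray
    epoch_len: float = DEFAULT_EPOCH_LEN

    def __post_init__(self) -> None:
        self.stages = np.asarray(self.stages, dtype=object)
        bad = set(self.stages) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stage labels: {sorted(bad)}")
        if self.epoch_len <= 0:
            raise ValueError("epoch length must be positive")

    @property
    def n_epochs(self) -> int:
        return int(self.stages.shape[0])

    @classmethod
    def from_file(cls, path: str | Path, epoch_len: float = DEFAULT_EPOCH_LEN) -> "Hypnogram":
        labels = [ln.strip().upper() for ln in Path(path).read_text().splitlines() if ln.strip()]
        return cls(np.array(labels, dtype=object), epoch_len=epoch_len)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.stages) + "\n")


class Epoch(NamedTuple):
    """One scoring epoch: half-open sample span ``[start, end)`` plus stage."""

    index: int
    start: int
    end: int
    stage: str
    zt: float   # zeitgeber hour of epoch start


def epoch_grid(rec: Recording, hyp: Hypnogram) -> list[Epoch]:
    """Lay the hypnogram over the recording, one :class:`Epoch` per label.

    The grid is anchored at sample 0; a trailing partial epoch of the
    recording is discarded.  A hypnogram longer than the recording by one or
    more full epochs is an error.
    """
    spe = int(round(rec.fs * hyp.epoch_len))     # samples per epoch
    n_fit = rec.n_samples // spe
    if hyp.n_epochs > n_fit:
        raise ValueError(
            f"hypnogram has {hyp.n_epochs} epochs but recording holds only {n_fit}"
        )
    epochs = []
    for i in range(hyp.n_epochs):
        zt = (rec.t0 + i * hyp.epoch_len / 3600.0) % 24.0
        epochs.append(Epoch(i, i * spe, (i + 1) * spe, str(hyp.stages[i]), zt))
    return epochs


def load_recording(
    path: str | Path,
    format: Optional[str] = None,
    channel_map: Optional[dict] = None,
    fs: float = DEFAULT_FS,
    t0: float = 0.0,
    animal_id: str = "animal",
    day_id: str = "day",
) -> Recording:
    """Read a recording from EDF or column-oriented CSV/TSV.

    ``channel_map`` maps roles to channel/column names, e.g.
    ``{"eog": "EOG", "emg_rms": "EMG"}``; defaults look for columns named
    ``eog`` and ``emg_rms`` (case-insensitive).  For EDF the sampling rate is
    taken from file metadata; for CSV it comes from ``fs``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "csv"
    cmap = {"eog": "eog", "emg_rms": "emg_rms"}
    if channel_map:
        cmap.update(channel_map)

    if format == "csv":
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
        df = pd.read_csv(path, sep=sep)
        cols = {c.lower(): c for c in df.columns}
        eog_col = cols.get(cmap["eog"].lower())
        if eog_col is None:
            raise ValueError(f"EOG column {cmap['eog']!r} not found in {path.name}")
        emg_col = cols.get(cmap["emg_rms"].lower())
        emg = df[emg_col].to_numpy(float) if emg_col is not None else None
        return Recording(df[eog_col].to_numpy(float), emg, fs=fs, t0=t0,
                         animal_id=animal_id, day_id=day_id)
    if format == "edf":
        try:
            import mne
        except ImportError as exc:  # pragma: no cover
            raise ImportError("EDF reading requires the 'mne' package") from exc
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
        names = {n.lower(): n for n in raw.ch_names}
        eog_name = names.get(cmap["eog"].lower())
        if eog_name is None:
            raise ValueError(f"EOG channel {cmap['eog']!r} not found in {path.name}")
        emg_name = names.get(cmap["emg_rms"].lower())
        eog = raw.get_data(picks=[eog_name])[0]
        emg = raw.get_data(picks=[emg_name])[0] if emg_name else None
        return Recording(eog, emg, fs=float(raw.info["sfreq"]), t0=t0,
                         animal_id=animal_id, day_id=day_id)
    raise ValueError(f"unknown format {format!r}")


def write_recording_csv(rec: Recording, path: str | Path, stage_per_sample: Optional[np.ndarray] = None) -> None:
    """Write channels as one CSV column each (header row, comma-separated)."""
    data = {"eog": rec.eog}
    if rec.emg_rms is not None:
        data["emg_rms"] = rec.emg_rms
    df = pd.DataFrame(data)
    if stage_per_sample is not None:
        df["stage"] = stage_per_sample
    df.to_csv(path, index=False, float_format="%.6f")


def bandpass_eog(x: np.ndarray, fs: float, lo: float = 0.5, hi: float = 29.0, order: int = 4) -> np.ndarray:
    """Optional software replication of the acquisition band-pass (0.5-29 Hz).

    Off by default in the pipeline: recorded signals are already hardware
    filtered, and the simulator emits band-limited noise.
    """
    from scipy.signal import butter, sosfiltfilt

    sos = butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, x)
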