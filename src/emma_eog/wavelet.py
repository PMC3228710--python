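"""The two wavelet engines behind the detector.

``dyadic_lowcut`` removes the slow (EEG-leakage) band from the EOG with a
shift-invariant dyadic wavelet decomposition: detail scales 4-8 and the final
approximation are zeroed before inverse transform, which at fs = 64 Hz
strongly attenuates content below roughly 2-4 Hz while leaving the REM band
untouched.  ``cwt_mexhat`` computes a continuous wavelet transform with the
Mexican hat (second derivative of a Gaussian, two vanishing moments) over a
geometric grid of 8 octaves x 8 voices; singularity candidates are the local
maxima of the finest-scale modulus that survive the universal threshold
sd x sqrt(2 ln n).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pywt

# Width of symmetric signal extension used for boundary handling.  Generous
# relative to the finest scales that drive detection (support ~ +-16 samples).
_PAD = 128


@dataclass
class CWTCoefficients:
    """CWT coefficients indexed by (scale, time) on a geometric scale grid."""

    matrix: np.ndarray
    scales: np.ndarray
    finest_scale_index: int = 0

    def __post_init__(self) -> None:
        if self.matrix.shape[0] != self.scales.shape[0]:
            raise ValueError("scale axis mismatch")
        if np.any(np.diff(self.scales) <= 0):
            raise ValueError("scales must be strictly increasing")

    @property
    def finest(self) -> np.ndarray:
        return self.matrix[self.finest_scale_index]


@dataclass
class ModulusMaxima:
    """Threshold-surviving local maxima of the finest-scale modulus."""

    positions: np.ndarray   # time indices
    moduli: np.ndarray      # |coefficient| at those indices
    threshold: float


def _pad_symmetric(x: np.ndarray, pad: int, total: int | None = None) -> tuple[np.ndarray, int]:
    """Symmetric extension by ``pad`` on the left, right-padded to ``total``."""
    n = len(x)
    right = (total - n - pad) if total is not None else pad
    return np.pad(x, (pad, right), mode="symmetric"), pad


def dyadic_lowcut(
    signal: np.ndarray,
    n_scales: int = 8,
    zero_scales: Iterable[int] = (4, 5, 6, 7, 8),
    wavelet: str = "bior2.2",
) -> np.ndarray:
    """High-pass the signal by zeroing coarse dyadic detail scales.

    A stationary (undecimated) wavelet transform with a quadratic-spline
    biorthogonal wavelet is taken to ``n_scales`` levels; the detail
    coefficients at the scales in ``zero_scales`` and the final approximation
    are zeroed, then the inverse transform is applied.  The approximation is
    removed so that DC and everything below the coarsest retained detail
    leaves the output.  Output has the length of the input.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.size == 0:
        raise ValueError("empty signal")
    n = signal.size
    zero = set(int(s) for s in zero_scales)
    block = 2 ** n_scales
    total = int(np.ceil((n + 2 * _PAD) / block)) * block
    xp, pad = _pad_symmetric(signal, _PAD, total)
    coeffs = pywt.swt(xp, wavelet, level=n_scales)
    # pywt returns (cA, cD) pairs coarsest-first: coeffs[i] is level n_scales-i.
    new = []
    for i, (ca, cd) in enumerate(coeffs):
        level = n_scales - i
        cd = np.zeros_like(cd) if level in zero else cd
        new.append((np.zeros_like(ca), cd))
    y = pywt.iswt(new, wavelet)
    return y[pad:pad + n]


def mexhat_scales(octaves: int = 8, voices: int = 8, finest: float = 2.0) -> np.ndarray:
    """Geometric scale grid: ``octaves x voices`` scales from ``finest`` up."""
    k = np.arange(octaves * voices)
    return finest * 2.0 ** (k / voices)


def cwt_mexhat(
    signal: np.ndarray,
    octaves: int = 8,
    voices: int = 8,
    finest: float = 2.0,
) -> CWTCoefficients:
    """Mexican-hat CWT over 8 octaves x 8 voices (finest scale 2 samples).

    Boundaries are handled by symmetric extension, cropped back to the
    signal length.  The coefficient sign follows the wavelet convention in
    which an upward bump yields a positive coefficient at fine scales.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.size == 0:
        raise ValueError("empty signal")
    scales = mexhat_scales(octaves, voices, finest)
    xp, pad = _pad_symmetric(signal, _PAD)
    mat, _ = pywt.cwt(xp, scales, "mexh")
    return CWTCoefficients(mat[:, pad:pad + signal.size], scales)


def universal_threshold(moduli: np.ndarray, n: int) -> float:
    """Noise-adaptive cutoff ``sd(moduli) * sqrt(2 ln n)``.

    ``n`` is the sample length of the analysed stretch of signal; the sample
    standard deviation (ddof=1) is used.
    """
    moduli = np.asarray(moduli, dtype=float)
    if moduli.size == 0:
        raise ValueError("empty moduli")
    if n < 2:
        raise ValueError("sample length must be >= 2")
    sd = float(np.std(moduli, ddof=1)) if moduli.size > 1 else 0.0
    return sd * np.sqrt(2.0 * np.log(n))


def local_maxima(x: np.ndarray) -> np.ndarray:
    """Indices of local maxima; plateaus resolve to the earliest sample.

    A point qualifies with strict ``>`` against its left neighbour and
    ``>=`` against its right neighbour; endpoints never qualify.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        return np.empty(0, dtype=int)
    mask = (x[1:-1] > x[:-2]) & (x[1:-1] >= x[2:])
    return np.flatnonzero(mask) + 1


def finest_scale_maxima(c: CWTCoefficients) -> ModulusMaxima:
    """Singularity candidates: finest-scale modulus maxima above threshold."""
    m = np.abs(c.finest)
    thr = universal_threshold(m, m.size) if m.size >= 2 else 0.0
    idx = local_maxima(m)
    keep = idx[m[idx] > thr]
    return ModulusMaxima(keep, m[keep], thr)
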