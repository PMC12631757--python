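"""Hilbert spectral analysis of IMFs and the stacked HHT feature matrix.

Each IMF is lifted to its analytic signal h(t) = IMF(t) + j*H[IMF](t) (FFT
construction: negative-frequency bins zeroed, positive bins doubled), from
which the instantaneous amplitude |h(t)| and the instantaneous frequency

    f(t) = (1/2pi) * d theta / dt

follow, with theta the unwrapped phase and the derivative taken by central
finite differences (one-sided at the ends). Frequencies are clipped to the
physical band [0, fs/2]: small negative excursions and above-Nyquist spikes
near low-amplitude samples are numerical artifacts of the discrete phase
derivative.

Per epoch the amplitude and frequency planes of ``max_imfs`` IMFs of every
electrode are stacked column-wise into the feature matrix F_HHT of shape
[T x C'] with C' = n_electrodes * max_imfs * 2 (electrode-major order,
amplitude before frequency). Electrodes yielding fewer IMFs contribute
zero-padded planes, keeping the shape fixed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import scipy.signal

from .emd import EmdConfig, emd
from .exceptions import TooShortError

#: samples discarded at each end when validating against closed forms
#: (Hilbert edge effects); the features themselves keep full length.
EDGE_SAMPLES = 32


@dataclass
class AnalyticSeries:
    """Complex analytic signal with its sampling rate."""

    values: np.ndarray
    fs: float


class ColumnKey(NamedTuple):
    """Identifies one feature column: electrode, IMF index, plane kind."""

    electrode: str
    imf_index: int
    kind: str  # "amplitude" | "frequency"


@dataclass
class HHTFeatures:
    """Time x derived-channel feature matrix F_HHT for one epoch."""

    matrix: np.ndarray  # (T, C')
    fs: float
    channel_index: list[ColumnKey]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]


def analytic_signal(x: np.ndarray, fs: float = 1.0) -> AnalyticSeries:
    """Analytic signal via the frequency-domain Hilbert construction."""
    x = np.asarray(x, dtype=np.float64)
    if x.size < 2:
        raise TooShortError(f"need at least 2 samples, got {x.size}")
    return AnalyticSeries(values=scipy.signal.hilbert(x), fs=fs)


def instantaneous_amplitude(a: AnalyticSeries) -> np.ndarray:
    """Pointwise modulus |h(t)|; non-negative."""
    return np.abs(a.values)


def instantaneous_phase(a: AnalyticSeries) -> np.ndarray:
    """Unwrapped argument of h(t): successive differences lie in (-pi, pi]."""
    return np.unwrap(np.angle(a.values))


def instantaneous_frequency(phase: np.ndarray, fs: float) -> np.ndarray:
    """Phase derivative in Hz, central differences, clipped to [0, fs/2]."""
    phase = np.asarray(phase, dtype=np.float64)
    if phase.size < 3:
        raise TooShortError(f"need at least 3 samples, got {phase.size}")
    f = np.gradient(phase) * fs / (2.0 * np.pi)
    return np.clip(f, 0.0, fs / 2.0)


def imf_amplitude_frequency(imf: np.ndarray, fs: float):
    """Amplitude and frequency series of one IMF (composition of the above)."""
    a = analytic_signal(imf, fs)
    return instantaneous_amplitude(a), instantaneous_frequency(instantaneous_phase(a), fs)


def hht_features(
    epoch: np.ndarray,
    cfg: EmdConfig = EmdConfig(),
    fs: float = 256.0,
    channel_names: list[str] | None = None,
) -> HHTFeatures:
    """EMD + Hilbert analysis of one epoch into the F_HHT matrix.

    Parameters
    ----------
    epoch : ndarray, shape (n_electrodes, T)
        One fixed-length window, T >= 3.
    cfg : EmdConfig
        Decomposition controls; ``cfg.max_imfs`` fixes the number of planes.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str, optional
        Electrode labels for the column map; defaults to ``Ch1..ChN``.
    """
    epoch = np.atleast_2d(np.asarray(epoch, dtype=np.float64))
    n_elec, T = epoch.shape
    if T < 3:
        raise TooShortError(f"epoch length {T} < 3")
    if channel_names is None:
        channel_names = [f"Ch{i + 1}" for i in range(n_elec)]
    cols: list[np.ndarray] = []
    index: list[ColumnKey] = []
    for e in range(n_elec):
        modes = emd(epoch[e], cfg)
        for i in range(cfg.max_imfs):
            if i < modes.n_imfs and np.any(modes.imfs[i]):
                amp, freq = imf_amplitude_frequency(modes.imfs[i], fs)
            else:
                amp = np.zeros(T)
                freq = np.zeros(T)
            cols.append(amp)
            cols.append(freq)
            index.append(ColumnKey(channel_names[e], i, "amplitude"))
            index.append(ColumnKey(channel_names[e], i, "frequency"))
    return HHTFeatures(matrix=np.column_stack(cols), fs=fs, channel_index=index)
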