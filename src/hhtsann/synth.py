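"""Synthetic resting-state EEG cohorts and oracle signals.

The generator emulates the broad statistical structure of scalp EEG: a 1/f
("pink") Gaussian background plus band-limited oscillations in the canonical
delta (1-4 Hz), theta (4-8 Hz), alpha (8-13 Hz) and beta (13-30 Hz) bands,
synthesised as narrowband-filtered noise so the modes are nonstationary
rather than pure tones. The class contrast is a controlled multiplicative
shift of the alpha-band amplitude in the MDD class — a deliberately simple,
fully known surrogate for depression-related spectral differences, suitable
for validating the pipeline end to end; it is not a neurophysiological claim.

Pure tones, linear chirps and AM signals with closed-form instantaneous
amplitude/frequency are provided as oracles for the Hilbert spectral stage.

Everything is deterministic under (seed, subject index).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import AliasingError, ConfigurationError
from .signal_io import SCALP_19, EEGRecording

#: canonical EEG band edges in Hz
BAND_EDGES = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}


@dataclass(frozen=True)
class SynthConfig:
    """Cohort generator settings.

    Defaults mirror the clinical recording protocol this package targets:
    34 MDD vs 30 HC subjects, 19 scalp channels, 256 Hz, 2-minute
    artifact-free segments. ``band_powers`` are oscillation amplitudes in
    microvolts; ``class_effect`` multiplies the alpha amplitude of
    MDD-labelled subjects; ``noise_sd`` is the standard deviation of the 1/f
    background; ``subject_jitter`` is the lognormal sigma of per-subject
    band-amplitude variability.
    """

    n_mdd: int = 34
    n_hc: int = 30
    fs: float = 256.0
    duration_s: float = 120.0
    n_channels: int = 19
    background_slope: float = 1.0
    band_powers: dict = field(
        default_factory=lambda: {"delta": 20.0, "theta": 10.0, "alpha": 15.0, "beta": 5.0}
    )
    class_effect: float = 2.0
    noise_sd: float = 10.0
    subject_jitter: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mdd < 0 or self.n_hc < 0:
            raise ConfigurationError("subject counts must be >= 0")
        if self.fs <= 0 or self.class_effect <= 0:
            raise ConfigurationError("fs and class_effect must be > 0")
        if any(v < 0 for v in self.band_powers.values()) or self.noise_sd < 0:
            raise ConfigurationError("amplitudes must be >= 0")


# ---------------------------------------------------------------------------
# Oracle signals
# ---------------------------------------------------------------------------

def make_tone(
    fs: float, f: float, a: float = 1.0, duration_s: float = 4.0, phase: float = 0.0
) -> np.ndarray:
    """``a * cos(2 pi f t + phase)`` sampled at ``fs``."""
    if not 0 < f < fs / 2:
        raise AliasingError(f"tone frequency {f} Hz outside (0, {fs / 2}) at fs={fs}")
    t = np.arange(int(round(fs * duration_s))) / fs
    return a * np.cos(2 * np.pi * f * t + phase)


def make_chirp(fs: float, f0: float, f1: float, duration_s: float = 4.0):
    """Linear chirp and its true instantaneous-frequency series.

    Phase ``phi(t) = 2 pi (f0 t + (f1 - f0) t^2 / (2 D))`` gives
    ``IF(t) = f0 + (f1 - f0) t / D``.
    """
    for f in (f0, f1):
        if not 0 < f < fs / 2:
            raise AliasingError(f"chirp frequency {f} Hz outside (0, {fs / 2})")
    D = duration_s
    t = np.arange(int(round(fs * duration_s))) / fs
    phase = 2 * np.pi * (f0 * t + (f1 - f0) * t ** 2 / (2 * D))
    return np.cos(phase), f0 + (f1 - f0) * t / D


def make_am(fs: float, f_carrier: float, f_mod: float, depth: float = 0.5,
            duration_s: float = 4.0) -> np.ndarray:
    """Amplitude-modulated tone ``(1 + depth cos(2 pi f_mod t)) cos(2 pi f_c t)``."""
    t = np.arange(int(round(fs * duration_s))) / fs
    return (1 + depth * np.cos(2 * np.pi * f_mod * t)) * np.cos(2 * np.pi * f_carrier * t)


# ---------------------------------------------------------------------------
# Noise components
# ---------------------------------------------------------------------------

def one_over_f_noise(
    rng: np.random.Generator, n: int, fs: float, slope: float, sd: float
) -> np.ndarray:
    """Gaussian noise with power spectrum ~ f^(-slope), scaled to ``sd``."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    gain = np.zeros_like(freqs)
    gain[1:] = freqs[1:] ** (-slope / 2.0)
    x = np.fft.irfft(spec * gain, n=n)
    x_sd = x.std()
    return x * (sd / x_sd) if x_sd > 0 else x


def narrowband_noise(
    rng: np.random.Generator, n: int, fs: float, lo: float, hi: float, rms: float
) -> np.ndarray:
    """Band-limited Gaussian noise with the requested RMS (randomised phase)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(freqs < lo) | (freqs > hi)] = 0.0
    x = np.fft.irfft(spec, n=n)
    x_rms = np.sqrt(np.mean(x ** 2))
    return x * (rms / x_rms) if x_rms > 0 else x


# ---------------------------------------------------------------------------
# Subjects and cohorts
# ---------------------------------------------------------------------------

def _channel_names(n: int) -> list[str]:
    names = list(SCALP_19[:n])
    names += [f"Ch{i + 1}" for i in range(len(names), n)]
    return names


def make_subject(label: str, cfg: SynthConfig, subject_seed: int) -> EEGRecording:
    """One synthetic subject: 1/f background + band oscillations per channel.

    MDD-labelled subjects get their alpha amplitude multiplied by
    ``cfg.class_effect``; every band amplitude also carries a per-subject
    lognormal jitter (sigma ``cfg.subject_jitter``) shared across channels.
    """
    rng = np.random.default_rng([cfg.seed, subject_seed, 1 if label == "MDD" else 0])
    n = int(round(cfg.fs * cfg.duration_s))
    jitter = {
        band: float(np.exp(rng.normal(0.0, cfg.subject_jitter)))
        for band in cfg.band_powers
    }
    data = np.empty((cfg.n_channels, n))
    for ch in range(cfg.n_channels):
        x = one_over_f_noise(rng, n, cfg.fs, cfg.background_slope, cfg.noise_sd)
        for band, amp in cfg.band_powers.items():
            lo, hi = BAND_EDGES[band]
            a = amp * jitter[band]
            if band == "alpha" and label == "MDD":
                a *= cfg.class_effect
            # RMS of a sinusoid of amplitude a
            x = x + narrowband_noise(rng, n, cfg.fs, lo, hi, a / np.sqrt(2.0))
        data[ch] = x
    prefix = "mdd" if label == "MDD" else "hc"
    return EEGRecording(
        data=data,
        fs=cfg.fs,
        channel_names=_channel_names(cfg.n_channels),
        subject_id=f"{prefix}{subject_seed:02d}",
        label=label,
        condition="unspecified",
    )


def make_cohort(cfg: SynthConfig):
    """Full cohort: ``n_mdd + n_hc`` recordings plus a labels table."""
    if cfg.n_mdd + cfg.n_hc < 2:
        raise ConfigurationError("cohort needs at least 2 subjects")
    recordings = [make_subject("MDD", cfg, i) for i in range(cfg.n_mdd)]
    recordings += [make_subject("HC", cfg, i) for i in range(cfg.n_hc)]
    table = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in recordings],
            "label": [r.label for r in recordings],
            "n_channels": [r.n_channels for r in recordings],
            "n_samples": [r.n_samples for r in recordings],
            "fs": [r.fs for r in recordings],
        }
    )
    return recordings, table


def band_power(x: np.ndarray, fs: float, lo: float, hi: float) -> float:
    """Welch periodogram power of ``x`` integrated over [lo, hi] Hz."""
    import scipy.signal

    nper = min(x.size, int(4 * fs))
    freqs, psd = scipy.signal.welch(x, fs=fs, nperseg=nper)
    sel = (freqs >= lo) & (freqs <= hi)
    return float(np.trapezoid(psd[sel], freqs[sel]))
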