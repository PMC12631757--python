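"""Empirical Mode Decomposition by envelope-mean sifting.

A signal x(t) is decomposed into intrinsic mode functions (IMFs) plus a
residual,

    x(t) = sum_i IMF_i(t) + r(t),

by repeatedly subtracting the mean of the upper and lower cubic-spline
envelopes ("sifting") until the candidate satisfies a Cauchy-type stopping
criterion, then peeling the mode off and decomposing the remainder. IMFs come
out ordered from highest to lowest characteristic frequency. The residual is
defined as the input minus the IMF sum, so completeness holds by construction
up to floating-point accumulation.

Sifting is fully deterministic: identical input and configuration give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .exceptions import ConfigurationError, NotEnoughExtremaError, TooShortError


@dataclass(frozen=True)
class EmdConfig:
    """Sifting controls.

    max_imfs : decomposition depth; 4 keeps the network input shape fixed.
    max_sift_iters : hard cap on sifting iterations per IMF.
    sd_threshold : Cauchy stopping threshold SD = sum(m^2)/sum(h^2) < sd,
        where m is the envelope mean subtracted in the iteration (classical
        default 0.2).
    boundary : envelope end handling; only mirror extension is implemented.
    enforce_imf_criterion : when True, sifting additionally continues until
        the candidate's extrema and zero-crossing counts differ by at most
        one (the strict mode definition). Off by default: the plain Cauchy
        stop is the classical rule, and its modes satisfy the definition only
        approximately.
    """

    max_imfs: int = 4
    max_sift_iters: int = 100
    sd_threshold: float = 0.2
    boundary: str = "mirror"
    enforce_imf_criterion: bool = False

    def __post_init__(self) -> None:
        if self.max_imfs < 1:
            raise ConfigurationError("max_imfs must be >= 1")
        if self.sd_threshold <= 0:
            raise ConfigurationError("sd_threshold must be > 0")
        if self.boundary != "mirror":
            raise ConfigurationError(f"unknown boundary mode {self.boundary!r}")


@dataclass
class IMFSet:
    """Ordered IMFs plus residual for one signal."""

    imfs: list[np.ndarray]
    residual: np.ndarray
    source_length: int

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        out = self.residual.copy()
        for imf in self.imfs:
            out += imf
        return out


def find_extrema(x: np.ndarray):
    """Strict local extrema by neighbour comparison.

    Flat plateaus report their midpoint index; signal endpoints are never
    extrema. Returns ``(max_idx, max_val, min_idx, min_val)``.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < 3:
        raise TooShortError(f"need at least 3 samples, got {x.size}")
    # Compress runs of equal values; a plateau becomes one node at its midpoint.
    change = np.flatnonzero(np.diff(x) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change, [x.size - 1]))
    mids = (starts + ends) // 2
    vals = x[starts]
    if vals.size < 3:
        empty = np.array([], dtype=np.int64)
        return empty, np.array([]), empty.copy(), np.array([])
    left = vals[:-2]
    mid = vals[1:-1]
    right = vals[2:]
    is_max = (mid > left) & (mid > right)
    is_min = (mid < left) & (mid < right)
    max_idx = mids[1:-1][is_max]
    min_idx = mids[1:-1][is_min]
    return max_idx, x[max_idx], min_idx, x[min_idx]


def _mirror_knots(idx: np.ndarray, val: np.ndarray, n: int):
    """Mirror the two extrema nearest each end across the signal edges."""
    k = min(2, idx.size)
    left_i = -idx[:k][::-1]
    left_v = val[:k][::-1]
    right_i = 2 * (n - 1) - idx[-k:][::-1]
    right_v = val[-k:][::-1]
    knots_i = np.concatenate([left_i, idx, right_i]).astype(np.float64)
    knots_v = np.concatenate([left_v, val, right_v])
    order = np.argsort(knots_i, kind="stable")
    knots_i, knots_v = knots_i[order], knots_v[order]
    uniq = np.concatenate(([True], np.diff(knots_i) > 0))
    return knots_i[uniq], knots_v[uniq]


def envelope(x: np.ndarray, extrema=None, boundary: str = "mirror"):
    """Upper/lower natural-cubic-spline envelopes through maxima/minima.

    End effects are tamed by mirroring the two extrema nearest each end across
    the signal edge before fitting. Raises :class:`NotEnoughExtremaError` when
    fewer than two maxima or two minima exist.
    """
    x = np.asarray(x, dtype=np.float64)
    if boundary != "mirror":
        raise ConfigurationError(f"unknown boundary mode {boundary!r}")
    if extrema is None:
        extrema = find_extrema(x)
    max_idx, max_val, min_idx, min_val = extrema
    if max_idx.size < 2 or min_idx.size < 2:
        raise NotEnoughExtremaError(
            f"need >= 2 maxima and >= 2 minima, got {max_idx.size}/{min_idx.size}"
        )
    t = np.arange(x.size)
    upper = CubicSpline(*_mirror_knots(max_idx, max_val, x.size), bc_type="natural")(t)
    lower = CubicSpline(*_mirror_knots(min_idx, min_val, x.size), bc_type="natural")(t)
    return upper, lower


def sift(x: np.ndarray, cfg: EmdConfig = EmdConfig()) -> np.ndarray:
    """Extract one candidate IMF by iterated envelope-mean subtraction.

    Iterates ``h <- h - mean(upper, lower)`` until the Cauchy criterion
    ``SD = sum((h_prev - h)^2) / sum(h_prev^2) < sd_threshold`` or the
    iteration cap is reached; returns the last h.
    """
    h = np.asarray(x, dtype=np.float64).copy()
    if h.size < 3:
        raise TooShortError(f"need at least 3 samples, got {h.size}")
    for it in range(cfg.max_sift_iters):
        extrema = find_extrema(h)
        if extrema[0].size < 2 or extrema[2].size < 2:
            if it == 0:
                raise NotEnoughExtremaError("signal has too few extrema to sift")
            break
        upper, lower = envelope(h, extrema, cfg.boundary)
        m = 0.5 * (upper + lower)
        denom = float(np.sum(h * h))
        sd = float(np.sum(m * m)) / denom if denom > 0 else 0.0
        h = h - m
        if sd < cfg.sd_threshold:
            if not cfg.enforce_imf_criterion:
                break
            mx, _, mn, _ = find_extrema(h)
            if abs(mx.size + mn.size - zero_crossings(h)) <= 1:
                break
    return h


def _is_monotone(x: np.ndarray) -> bool:
    d = np.diff(x)
    return bool(np.all(d >= 0) or np.all(d <= 0))


def emd(x: np.ndarray, cfg: EmdConfig = EmdConfig()) -> IMFSet:
    """Full decomposition: peel IMFs until the residual is a trend.

    Stops when the residual has fewer than 4 extrema, is monotone, or
    ``max_imfs`` modes were extracted. Signals that never admit an IMF (e.g.
    constants or ramps) return ``n_imfs == 0`` with residual equal to the
    input. ``sum(imfs) + residual`` reproduces the input to float accumulation
    accuracy because the residual is formed by subtraction.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < 3:
        raise TooShortError(f"need at least 3 samples, got {x.size}")
    residual = x.copy()
    imfs: list[np.ndarray] = []
    power = float(np.sum(x * x))
    while len(imfs) < cfg.max_imfs:
        try:
            max_idx, _, min_idx, _ = find_extrema(residual)
        except TooShortError:  # pragma: no cover - length fixed above
            break
        if max_idx.size + min_idx.size < 4 or _is_monotone(residual):
            break
        try:
            imf = sift(residual, cfg)
        except NotEnoughExtremaError:
            break
        if power > 0 and float(np.sum(imf * imf)) < 1e-24 * power:
            break
        imfs.append(imf)
        residual = residual - imf
    return IMFSet(imfs=imfs, residual=residual, source_length=x.size)


def zero_crossings(x: np.ndarray) -> int:
    """Count sign changes, ignoring exact zeros between opposite signs."""
    s = np.sign(np.asarray(x, dtype=np.float64))
    s = s[s != 0]
    if s.size < 2:
        return 0
    return int(np.sum(s[:-1] != s[1:]))


def is_imf(x: np.ndarray, tol: int = 1) -> bool:
    """True iff the signal oscillates (has interior extrema) and its extrema
    and zero-crossing counts differ by at most ``tol``."""
    max_idx, _, min_idx, _ = find_extrema(x)
    n_ext = max_idx.size + min_idx.size
    return n_ext >= 1 and abs(n_ext - zero_crossings(x)) <= tol
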