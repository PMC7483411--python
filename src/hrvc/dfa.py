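"""Detrended fluctuation analysis (DFA) of NN-interval series.

DFA quantifies fractal correlation in a (possibly nonstationary) series:
the series is integrated after mean removal, split into boxes of n beats,
linearly detrended box by box, and the root-mean-square residual F(n) is
examined against n on log-log axes.  The slope alpha is ~0.5 for white
noise, ~1.0 for 1/f (pink) noise and ~1.5 for Brownian motion.  Two slopes
are fitted: the short-range exponent alpha1 over 4-11 beats and the
long-range exponent alpha2 over 11-64 beats (endpoints inclusive; n = 11
participates in both fits).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import NNSeries, InsufficientDataError

__all__ = ["DFAResult", "integrate_profile", "fluctuation_function",
           "dfa_exponents", "dfa", "DegenerateInputError"]

SHORT_RANGE = (4, 11)
LONG_RANGE = (11, 64)


class DegenerateInputError(ValueError):
    """The fluctuation curve is degenerate (e.g. F(n) = 0 somewhere)."""


@dataclass
class DFAResult:
    box_sizes: np.ndarray     # beat counts n
    fluctuations: np.ndarray  # F(n), ms
    alpha1: float             # slope over SHORT_RANGE
    alpha2: float             # slope over LONG_RANGE
    fit_r2: tuple             # (r^2 of alpha1 fit, r^2 of alpha2 fit)


def integrate_profile(nn) -> np.ndarray:
    """Integrated, mean-centred profile y(k) = sum_{i<=k} (NN_i - mean)."""
    x = nn.intervals if isinstance(nn, NNSeries) else np.asarray(nn, dtype=float)
    if len(x) < 2:
        raise InsufficientDataError("profile needs >= 2 intervals")
    return np.cumsum(x - x.mean())


def _box_residual_ss(profile: np.ndarray, n: int) -> tuple:
    """Sum of squared residuals of per-box linear fits, and sample count.

    Boxes are consecutive and non-overlapping, taken both from the start
    of the profile and from the start of the reversed profile so trailing
    samples contribute.
    """
    N = len(profile)
    nb = N // n
    t = np.arange(n, dtype=float)
    t -= t.mean()
    stt = float(np.sum(t * t))
    ss = 0.0
    count = 0
    for seg in (profile[: nb * n], profile[::-1][: nb * n]):
        y = seg.reshape(nb, n)
        ym = y.mean(axis=1, keepdims=True)
        slope = (y @ t) / stt
        resid = y - ym - slope[:, None] * t
        ss += float(np.sum(resid * resid))
        count += nb * n
    return ss, count


def fluctuation_function(profile: np.ndarray, box_sizes=None) -> tuple:
    """RMS fluctuation F(n) after per-box linear detrending.

    Returns ``(box_sizes, F)`` with scales n < 4 rejected.  Requires the
    profile to hold at least 4 boxes of the smallest scale.
    """
    profile = np.asarray(profile, dtype=float)
    if box_sizes is None:
        box_sizes = np.arange(4, 65)
    box_sizes = np.asarray([n for n in np.unique(box_sizes) if n >= 4], dtype=int)
    if box_sizes.size == 0:
        raise ValueError("no valid box sizes (all < 4)")
    if len(profile) < 4 * box_sizes.min():
        raise InsufficientDataError(
            f"profile of length {len(profile)} is shorter than 4 boxes of "
            f"the smallest scale {box_sizes.min()}")
    box_sizes = box_sizes[box_sizes <= len(profile) // 4]
    F = np.empty(len(box_sizes))
    for k, n in enumerate(box_sizes):
        ss, count = _box_residual_ss(profile, int(n))
        F[k] = np.sqrt(ss / count)
    return box_sizes, F


def _loglog_slope(n: np.ndarray, F: np.ndarray, rng: tuple) -> tuple:
    lo, hi = rng
    mask = (n >= lo) & (n <= hi)
    if mask.sum() < 3:
        raise InsufficientDataError(
            f"need >= 3 box sizes inside [{lo}, {hi}]; have {int(mask.sum())}")
    if np.any(F[mask] <= 0):
        raise DegenerateInputError(
            f"F(n) = 0 inside [{lo}, {hi}]; series is exactly linear")
    lx, ly = np.log10(n[mask].astype(float)), np.log10(F[mask])
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / tot if tot > 0 else 1.0
    return float(slope), r2


def dfa_exponents(box_sizes, fluctuations, short_range=SHORT_RANGE,
                  long_range=LONG_RANGE):
    """OLS slopes of log10 F(n) vs log10 n over the two inclusive ranges."""
    n = np.asarray(box_sizes)
    F = np.asarray(fluctuations, dtype=float)
    a1, r2_1 = _loglog_slope(n, F, short_range)
    a2, r2_2 = _loglog_slope(n, F, long_range)
    return a1, a2, (r2_1, r2_2)


def dfa(nn, box_sizes=None, short_range=SHORT_RANGE,
        long_range=LONG_RANGE) -> DFAResult:
    """Full DFA of an NN series: profile, F(n) curve and both exponents."""
    profile = integrate_profile(nn)
    n, F = fluctuation_function(profile, box_sizes)
    a1, a2, r2 = dfa_exponents(n, F, short_range, long_range)
    return DFAResult(box_sizes=n, fluctuations=F, alpha1=a1, alpha2=a2, fit_r2=r2)
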