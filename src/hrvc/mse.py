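"""Multiscale entropy (MSE) of NN-interval series.

Sample entropy (SampEn) is the negative log of the conditional probability
that two template sequences matching for m points (Chebyshev distance
within a tolerance r, self-matches excluded) still match at m+1 points.
MSE computes SampEn on coarse-grained versions of the series: scale tau
replaces each block of tau consecutive beats with its mean.  A complex
(long-range correlated) signal keeps its entropy across scales, whereas
uncorrelated noise loses entropy as averaging smooths it away.

Four scalar features summarise the curve over scales 1..20: the entropy
at scale 5, the fitted slope over scales 1-5, and the summed entropy over
scales 1-5 and 6-20.

Template-pair counting uses a sorted sweep over the first template
coordinate (compiled with numba), which is exact: an explicit O(N^2)
brute-force count gives identical integer counts and is retained in the
test suite as an independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .preprocess import NNSeries, InsufficientDataError

__all__ = ["MSEResult", "coarse_grain", "sample_entropy", "mse_curve",
           "mse_features"]

MAX_SCALE = 20
FEATURE_SCALE = 5


@dataclass
class MSEResult:
    entropies: np.ndarray  # SampEn per scale tau = 1..max_scale; NaN = undefined
    m: int                 # template length, beats
    r: float               # tolerance, ms (fixed across scales)

    @property
    def scale5(self) -> float:
        return float(self.entropies[FEATURE_SCALE - 1])

    @property
    def slope5(self) -> float:
        return mse_features(self.entropies)["mse_slope5"]

    @property
    def area1_5(self) -> float:
        return mse_features(self.entropies)["mse_area1_5"]

    @property
    def area6_20(self) -> float:
        return mse_features(self.entropies)["mse_area6_20"]


def coarse_grain(series, tau: int) -> np.ndarray:
    """Non-overlapping block means of length ``tau``.

    Output length is ``floor(N / tau)``; trailing samples that do not fill
    a block are dropped.  ``tau = 1`` returns the input unchanged.
    """
    x = np.asarray(series, dtype=float)
    if tau < 1:
        raise ValueError("tau must be >= 1")
    if tau > len(x):
        raise InsufficientDataError(f"tau = {tau} exceeds series length {len(x)}")
    if tau == 1:
        return x.copy()
    n = len(x) // tau
    return x[: n * tau].reshape(n, tau).mean(axis=1)


@njit(cache=True)
def _count_pairs_m_m1(x, n_templ, m, r, order):
    """Template pairs (i < j) within Chebyshev distance r, jointly for
    template lengths m (count B) and m+1 (count A).

    Template i is ``x[i : i + m]``; ``order`` sorts templates by their
    first coordinate, so the sweep stops as soon as the first coordinates
    alone differ by more than r.  An (m+1)-match is an m-match whose extra
    trailing coordinate also agrees, so both counts share one sweep.
    """
    B = 0
    A = 0
    for a in range(n_templ):
        i = order[a]
        xi = x[i]
        for b in range(a + 1, n_templ):
            j = order[b]
            if x[j] - xi > r:
                break
            ok = True
            for k in range(1, m):
                d = x[i + k] - x[j + k]
                if d < 0.0:
                    d = -d
                if d > r:
                    ok = False
                    break
            if ok:
                B += 1
                d = x[i + m] - x[j + m]
                if d < 0.0:
                    d = -d
                if d <= r:
                    A += 1
    return B, A


def sample_entropy(series, m: int = 2, r: float = None) -> float:
    """Sample entropy SampEn(m, r) of a series.

    B counts matching m-length template pairs among the first ``N - m``
    templates, A the matching (m+1)-length pairs; SampEn = -ln(A/B)
    (Richman-Moorman convention, distances *within* r count as matches,
    self-matches excluded).  Returns NaN when A or B is zero, i.e. the
    statistic is undefined for the series at this (m, r).
    """
    x = np.ascontiguousarray(series, dtype=float)
    if len(x) <= m + 1:
        raise InsufficientDataError(
            f"sample entropy needs length > m+1 = {m + 1}; have {len(x)}")
    if r is None or r <= 0:
        raise ValueError("tolerance r must be positive")
    n_templ = len(x) - m  # same template count for both lengths
    order = np.argsort(x[:n_templ], kind="stable")
    B, A = _count_pairs_m_m1(x, n_templ, m, float(r), order)
    if A == 0 or B == 0:
        return float("nan")
    return float(-np.log(A / B))


def mse_curve(nn, max_scale: int = MAX_SCALE, m: int = 2,
              r_frac: float = 0.15) -> MSEResult:
    """Sample entropy across coarse-graining scales 1..max_scale.

    The tolerance r is fixed once as ``r_frac`` times the SD of the
    original (scale-1) series and reused unchanged at every scale, so the
    curve reflects loss of structure under averaging, not renormalisation.
    Scales whose SampEn is undefined (zero matches) yield NaN, which
    propagates to any feature whose range covers them.
    """
    x = nn.intervals if isinstance(nn, NNSeries) else np.asarray(nn, dtype=float)
    if len(x) < 10 * max_scale:
        raise InsufficientDataError(
            f"MSE to scale {max_scale} needs >= {10 * max_scale} beats; "
            f"have {len(x)}")
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        # constant series: every template matches at every scale, SampEn 0
        return MSEResult(entropies=np.zeros(max_scale), m=m, r=0.0)
    r = r_frac * sd
    ent = np.empty(max_scale)
    for tau in range(1, max_scale + 1):
        ent[tau - 1] = sample_entropy(coarse_grain(x, tau), m=m, r=r)
    return MSEResult(entropies=ent, m=m, r=r)


def mse_features(entropies) -> dict:
    """Scalar features of an MSE curve over scales 1..20.

    ``mse_slope5`` is the OLS slope of entropy against scale over scales
    1-5; the areas are plain sums (not trapezoids).  A NaN anywhere inside
    a feature's scale range marks that feature missing (NaN).
    """
    e = np.asarray(entropies, dtype=float)
    if len(e) < MAX_SCALE:
        raise ValueError(f"need entropies for scales 1..{MAX_SCALE}")
    head, tail = e[:FEATURE_SCALE], e[FEATURE_SCALE:MAX_SCALE]
    taus = np.arange(1, FEATURE_SCALE + 1, dtype=float)
    if np.any(np.isnan(head)):
        scale5 = slope5 = area1_5 = float("nan")
    else:
        scale5 = float(e[FEATURE_SCALE - 1])
        slope5 = float(np.polyfit(taus, head, 1)[0])
        area1_5 = float(head.sum())
    area6_20 = float("nan") if np.any(np.isnan(tail)) else float(tail.sum())
    return {"mse_scale5": scale5, "mse_slope5": slope5,
            "mse_area1_5": area1_5, "mse_area6_20": area6_20}
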