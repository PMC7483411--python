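"""Time-domain HRV statistics: mean RR, SDRR, pNN20, pNN50."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import NNSeries, InsufficientDataError

__all__ = ["TimeDomainMetrics", "time_domain_metrics"]


@dataclass
class TimeDomainMetrics:
    mean_rr: float   # ms
    sdrr: float      # ms
    pnn20: float     # proportion in [0, 1]
    pnn50: float     # proportion in [0, 1]

    def as_dict(self) -> dict:
        return {"mean_rr": self.mean_rr, "sdrr": self.sdrr,
                "pnn20": self.pnn20, "pnn50": self.pnn50}


def _pnnx(diffs: np.ndarray, x_ms: float) -> float:
    # strict inequality: a change must *exceed* x ms to count
    return float(np.mean(np.abs(diffs) > x_ms))


def time_domain_metrics(nn, ddof: int = 1) -> TimeDomainMetrics:
    """Compute mean RR, SDRR and pNN20/pNN50 for one NN series.

    ``pNNx`` is the proportion (0-1, not percent) of successive NN
    differences whose absolute value strictly exceeds ``x`` ms.  SDRR uses
    the sample standard deviation (``ddof=1``) by default; pass ``ddof=0``
    for the population variant.
    """
    x = nn.intervals if isinstance(nn, NNSeries) else np.asarray(nn, dtype=float)
    if len(x) < 2:
        raise InsufficientDataError("time-domain metrics need >= 2 intervals")
    diffs = np.diff(x)
    return TimeDomainMetrics(
        mean_rr=float(np.mean(x)),
        sdrr=float(np.std(x, ddof=ddof)),
        pnn20=_pnnx(diffs, 20.0),
        pnn50=_pnnx(diffs, 50.0),
    )
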