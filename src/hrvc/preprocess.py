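"""Reading, annotating and segmenting RR-interval recordings.

The raw input of every analysis in this package is an :class:`RRSeries`:
the sequence of beat-to-beat (R-to-R) intervals of one ambulatory ECG
recording, each beat carrying a quality label.  Downstream statistics are
computed on the :class:`NNSeries` of accepted normal-to-normal intervals
produced by :func:`filter_nn`, usually restricted to a stable daytime
segment chosen by :func:`select_segment`.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RRSeries",
    "NNSeries",
    "read_rr_file",
    "filter_nn",
    "select_segment",
    "InsufficientDataError",
    "EmptyOutputError",
    "RRParseError",
]

#: Recognised per-beat quality labels.
LABELS = ("normal", "ectopic", "artifact", "excluded")

#: Mapping from AAMI-style single-letter annotations to quality labels.
ANN_MAP = {"N": "normal", "V": "ectopic", "A": "ectopic", "X": "artifact"}


class RRParseError(ValueError):
    """A recording file contained a row that could not be parsed."""


class InsufficientDataError(ValueError):
    """The recording is too short for the requested operation."""


class EmptyOutputError(ValueError):
    """Filtering rejected every beat."""


def _parse_clock(clock: str) -> float:
    """``"hh:mm"`` -> seconds since midnight."""
    hh, mm = clock.split(":")
    return 3600.0 * int(hh) + 60.0 * int(mm)


@dataclass
class RRSeries:
    """An annotated sequence of beat-to-beat intervals.

    Parameters
    ----------
    intervals:
        Beat-to-beat durations in milliseconds.
    labels:
        Per-beat quality label, one of ``normal | ectopic | artifact |
        excluded``.  Defaults to all-normal.
    onset_times:
        Clock time of each beat in seconds from the start of the recording.
        Rebuilt from the intervals when omitted: the first beat is at 0 and
        beat *i* occurs ``intervals[i] / 1000`` seconds after beat *i - 1*.
    recording_start_clock:
        Time of day of the first beat, ``"hh:mm"``.
    """

    intervals: np.ndarray
    labels: np.ndarray = None
    onset_times: np.ndarray = None
    recording_start_clock: str = "00:00"

    def __post_init__(self):
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.intervals.ndim != 1:
            raise ValueError("intervals must be one-dimensional")
        if self.labels is None:
            self.labels = np.full(len(self.intervals), "normal", dtype=object)
        else:
            self.labels = np.asarray(self.labels, dtype=object)
        if self.onset_times is None:
            t = np.cumsum(self.intervals) / 1000.0
            self.onset_times = t - t[0] if len(t) else t
        else:
            self.onset_times = np.asarray(self.onset_times, dtype=float)
        if len(self.labels) != len(self.intervals):
            raise ValueError("labels must have the same length as intervals")
        if len(self.onset_times) != len(self.intervals):
            raise ValueError("onset_times must have the same length as intervals")
        if len(self.intervals) and np.any(self.intervals <= 0):
            raise ValueError("all intervals must be positive")
        if len(self.onset_times) > 1 and np.any(np.diff(self.onset_times) <= 0):
            raise ValueError("onset_times must be strictly increasing")
        bad = set(self.labels) - set(LABELS)
        if bad:
            raise ValueError(f"unknown beat labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass
class NNSeries:
    """Accepted normal-to-normal intervals plus their provenance.

    ``source_indices[k]`` is the position in the parent :class:`RRSeries`
    of the k-th accepted beat.  Rejected beats are deleted, never merged:
    the interval following a gap keeps its original duration.
    """

    intervals: np.ndarray
    source_indices: np.ndarray = None

    def __post_init__(self):
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.source_indices is None:
            self.source_indices = np.arange(len(self.intervals))
        else:
            self.source_indices = np.asarray(self.source_indices, dtype=int)
        if len(self.source_indices) != len(self.intervals):
            raise ValueError("source_indices must match intervals in length")
        if len(self.source_indices) > 1 and np.any(np.diff(self.source_indices) <= 0):
            raise ValueError("source_indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.intervals)


# ---------------------------------------------------------------------------
# File input
# ---------------------------------------------------------------------------

DIALECTS = ("interval-list", "cumulative-time", "csv-annotated")


def _sniff_dialect(first_line: str) -> str:
    if "," in first_line:
        return "csv-annotated"
    return "interval-list"


def read_rr_file(path, dialect: str = "auto",
                 recording_start_clock: str = "00:00") -> RRSeries:
    """Read an RR recording from a plain-text file.

    Supported dialects:

    ``interval-list``
        One interval in milliseconds per line.
    ``cumulative-time``
        One cumulative beat time in seconds per line; intervals are the
        successive differences (the first interval is taken equal to the
        second, as it is unobservable).
    ``csv-annotated``
        CSV with columns ``time_s, rr_ms`` and an optional ``ann`` column
        holding AAMI-style labels (N/V/A/X).
    ``auto``
        Sniffed: a comma in the first line means ``csv-annotated``,
        otherwise ``interval-list``.
    """
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise InsufficientDataError(f"{path}: file contains no beats")
    if dialect == "auto":
        dialect = _sniff_dialect(lines[0])
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")

    if dialect == "csv-annotated":
        return _read_csv_annotated(path, text, recording_start_clock)

    values = []
    for lineno, ln in enumerate(lines, start=1):
        try:
            values.append(float(ln.strip()))
        except ValueError:
            raise RRParseError(
                f"{path}: line {lineno}: could not parse {ln.strip()!r} as a number"
            ) from None
    arr = np.asarray(values)
    if dialect == "interval-list":
        return RRSeries(intervals=arr, recording_start_clock=recording_start_clock)
    # cumulative-time, seconds
    if len(arr) < 2:
        raise InsufficientDataError(f"{path}: cumulative-time file needs >= 2 beats")
    iv = np.diff(arr) * 1000.0
    iv = np.concatenate([[iv[0]], iv])
    return RRSeries(intervals=iv, onset_times=arr - arr[0],
                    recording_start_clock=recording_start_clock)


def _read_csv_annotated(path, text: str, recording_start_clock: str) -> RRSeries:
    fast = _read_csv_fast(text, recording_start_clock)
    if fast is not None:
        return fast
    reader = csv.reader(io.StringIO(text))
    rows = [r for r in reader if r and any(c.strip() for c in r)]
    if not rows:
        raise InsufficientDataError(f"{path}: file contains no beats")
    header = [c.strip().lower() for c in rows[0]]
    if "rr_ms" in header:
        col_rr = header.index("rr_ms")
        col_t = header.index("time_s") if "time_s" in header else None
        col_ann = header.index("ann") if "ann" in header else None
        data, first = rows[1:], 2
    else:  # headerless: time_s, rr_ms[, ann]
        col_t, col_rr = 0, 1
        col_ann = 2 if len(rows[0]) > 2 else None
        data, first = rows, 1
    if not data:
        raise InsufficientDataError(f"{path}: file contains no beats")
    iv, times, labels = [], [], []
    for lineno, row in enumerate(data, start=first):
        try:
            iv.append(float(row[col_rr]))
            if col_t is not None:
                times.append(float(row[col_t]))
        except (ValueError, IndexError):
            raise RRParseError(
                f"{path}: line {lineno}: could not parse row {row!r}"
            ) from None
        ann = row[col_ann].strip().upper() if col_ann is not None else "N"
        labels.append(ANN_MAP.get(ann, "excluded"))
    onset = None
    if times:
        t = np.asarray(times)
        onset = t - t[0]
    return RRSeries(intervals=np.asarray(iv), labels=np.asarray(labels, dtype=object),
                    onset_times=onset, recording_start_clock=recording_start_clock)


def _read_csv_fast(text: str, recording_start_clock: str):
    """Vectorised parse of the canonical ``time_s,rr_ms,ann`` layout.

    Returns None for any other layout or any malformed row; the caller
    then re-parses row by row to report the offending line number.
    """
    nl = text.find("\n")
    if nl < 0 or text[:nl].strip().lower() != "time_s,rr_ms,ann":
        return None
    try:
        import pandas as pd
        df = pd.read_csv(io.StringIO(text), dtype={"time_s": float,
                                                   "rr_ms": float,
                                                   "ann": str})
    except Exception:
        return None
    if df.isna().any().any() or not len(df):
        return None
    labels = df["ann"].str.strip().str.upper().map(ANN_MAP).fillna("excluded")
    t = df["time_s"].to_numpy()
    return RRSeries(intervals=df["rr_ms"].to_numpy(),
                    labels=labels.to_numpy(dtype=object),
                    onset_times=t - t[0],
                    recording_start_clock=recording_start_clock)


# ---------------------------------------------------------------------------
# NN filtering
# ---------------------------------------------------------------------------

def filter_nn(rr: RRSeries, min_ms: float = 300.0, max_ms: float = 2000.0,
              max_rel_jump: float = 0.2) -> NNSeries:
    """Accept normal beats within physiological bounds and limited jumps.

    A beat is accepted when (i) its label is ``normal``, (ii) its interval
    lies in ``[min_ms, max_ms]``, and (iii) it differs from the *previous
    accepted* interval by at most ``max_rel_jump`` (relative); the first
    accepted beat is exempt from the jump test.  This automated rule stands
    in for the manual technician review of clinical Holter workflows.

    Raises
    ------
    EmptyOutputError
        If every beat is rejected; the message carries a rejection
        breakdown by cause.
    """
    if len(rr) == 0:
        raise InsufficientDataError("empty RRSeries")
    if not (0 < min_ms < max_ms):
        raise ValueError("need 0 < min_ms < max_ms")
    if not (0 < max_rel_jump <= 1):
        raise ValueError("need 0 < max_rel_jump <= 1")

    iv = rr.intervals
    normal = np.asarray([lb == "normal" for lb in rr.labels])
    in_bounds = (iv >= min_ms) & (iv <= max_ms)
    kept_idx = []
    n_jump = 0
    prev = None
    for i in np.flatnonzero(normal & in_bounds):
        x = iv[i]
        if prev is not None and abs(x - prev) > max_rel_jump * prev:
            n_jump += 1
            continue
        kept_idx.append(i)
        prev = x
    if not kept_idx:
        n_label = int((~normal).sum())
        n_bounds = int((normal & ~in_bounds).sum())
        raise EmptyOutputError(
            "all beats rejected "
            f"(non-normal label: {n_label}, out of bounds: {n_bounds}, "
            f"jump: {n_jump})"
        )
    kept_idx = np.asarray(kept_idx)
    return NNSeries(intervals=iv[kept_idx], source_indices=kept_idx)


def _static_reject_mask(rr: RRSeries, min_ms: float, max_ms: float,
                        max_rel_jump: float) -> np.ndarray:
    """Per-beat reject indicator used to score candidate windows.

    Unlike :func:`filter_nn` the jump test compares each beat with its raw
    predecessor, so the mask is window-independent and windows can be scored
    with prefix sums.
    """
    iv = rr.intervals
    bad = np.asarray([lb != "normal" for lb in rr.labels])
    bad |= (iv < min_ms) | (iv > max_ms)
    if len(iv) > 1:
        jump = np.abs(np.diff(iv)) > max_rel_jump * iv[:-1]
        bad[1:] |= jump
    return bad


def select_segment(rr: RRSeries, window_start_clock: str = "09:00",
                   window_end_clock: str = "17:00", duration_h: float = 4.0,
                   step_min: float = 5.0, min_ms: float = 300.0,
                   max_ms: float = 2000.0, max_rel_jump: float = 0.2) -> RRSeries:
    """Select the most stable ``duration_h`` segment inside a clock window.

    Candidate windows start every ``step_min`` minutes; each is scored by
    the fraction of its beats flagged by a static artifact rule (non-normal
    label, out of bounds, or >``max_rel_jump`` relative jump from the raw
    predecessor).  The lowest-scoring window wins, ties going to the
    earliest start.  Onset times of the returned series are re-zeroed.
    """
    if len(rr) == 0:
        raise InsufficientDataError("empty RRSeries")
    start_clock = _parse_clock(rr.recording_start_clock)
    beat_clock = start_clock + rr.onset_times  # seconds of day per beat
    w0 = max(_parse_clock(window_start_clock), beat_clock[0])
    w1 = min(_parse_clock(window_end_clock), beat_clock[-1])
    dur = duration_h * 3600.0
    if w1 - w0 < dur:
        avail = max(0.0, w1 - w0) / 3600.0
        raise InsufficientDataError(
            f"recording covers only {avail:.2f} h of the "
            f"{window_start_clock}-{window_end_clock} window; need {duration_h} h"
        )
    bad = _static_reject_mask(rr, min_ms, max_ms, max_rel_jump).astype(float)
    cum_bad = np.concatenate([[0.0], np.cumsum(bad)])

    step = step_min * 60.0
    starts = np.arange(w0, w1 - dur + 1e-9, step)
    best = None  # (score, start_s, lo, hi)
    for s in starts:
        lo = int(np.searchsorted(beat_clock, s, side="left"))
        hi = int(np.searchsorted(beat_clock, s + dur, side="right"))
        n = hi - lo
        if n < 2:
            continue
        score = (cum_bad[hi] - cum_bad[lo]) / n
        if best is None or score < best[0] - 1e-12:
            best = (score, s, lo, hi)
    if best is None:
        raise InsufficientDataError("no candidate window contains beats")
    _, s, lo, hi = best
    hh, mm = int(s // 3600), int((s % 3600) // 60)
    return RRSeries(
        intervals=rr.intervals[lo:hi],
        labels=rr.labels[lo:hi],
        onset_times=rr.onset_times[lo:hi] - rr.onset_times[lo],
        recording_start_clock=f"{hh:02d}:{mm:02d}",
    )
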