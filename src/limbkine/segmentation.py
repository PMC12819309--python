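"""Movement-cycle detection from pitch (TT) and vertical acceleration (LA).

A toe-tapping cycle runs between two ground-contact events, identified as
positive local maxima of the pitch signal above TH_TT = -3 deg; the cycle is
kept only if the pitch dips below TH_TTup = -5 deg in between (toes up,
A_up). A leg-agility cycle runs between two impact peaks of the vertical
acceleration above TH_LA = 20 m/s^2; no A_up is defined for this signal.
Signals are used raw — no filtering or resampling is applied before
detection.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io_recordings import TrialRecording


@dataclasses.dataclass(frozen=True)
class SegmentationThresholds:
    """Detection thresholds; the defaults are the published values."""

    th_tt: float = -3.0              # deg, min value of a TT contact peak
    th_tt_up: float = -5.0           # deg, max value of the toes-up dip
    th_la: float = 20.0              # m/s^2, min value of an LA impact peak
    min_cycle_duration: float = 0.15  # s
    min_peak_separation: float = 0.15  # s, peak debouncing distance

    def validate(self) -> None:
        if not self.th_tt_up < self.th_tt:
            raise ValueError(
                f"th_tt_up ({self.th_tt_up:g}) must be below th_tt ({self.th_tt:g})"
            )
        if self.th_la <= 0:
            raise ValueError("th_la must be positive")
        if self.min_cycle_duration <= 0 or self.min_peak_separation <= 0:
            raise ValueError("durations must be positive")


@dataclasses.dataclass(frozen=True)
class CycleEvent:
    """One movement cycle delimited by consecutive ground contacts."""

    t_start: float
    t_end: float
    t_up: float | None = None
    value_start: float = np.nan
    value_up: float | None = None
    interval_index: int = 0

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclasses.dataclass(frozen=True)
class CycleSet:
    """Ordered, non-overlapping cycles for one trial plus its metadata."""

    events: tuple[CycleEvent, ...]
    signal_kind: str  # "pitch" | "vertical_acc"
    participant_id: str = ""
    task: str = ""
    leg: str = ""
    dominant: bool = False
    trial_index: int = 0
    sample_rate: float = 100.0

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "participant_id": self.participant_id, "task": self.task,
            "leg": self.leg, "dominant": self.dominant,
            "trial_index": self.trial_index, "cycle_index": k,
            "t_start_s": e.t_start, "t_up_s": e.t_up, "t_end_s": e.t_end,
            "value_start": e.value_start, "value_up": e.value_up,
            "interval_index": e.interval_index,
        } for k, e in enumerate(self.events)]
        return pd.DataFrame(rows, columns=[
            "participant_id", "task", "leg", "dominant", "trial_index",
            "cycle_index", "t_start_s", "t_up_s", "t_end_s", "value_start",
            "value_up", "interval_index",
        ])


def local_maxima(y: np.ndarray) -> np.ndarray:
    """Indices of local maxima: samples strictly greater than both
    neighbours; a plateau resolves to its first sample. Endpoints are never
    maxima."""
    y = np.asarray(y, dtype=float)
    if y.size < 3:
        return np.empty(0, dtype=int)
    s = np.sign(np.diff(y))
    nz = np.nonzero(s)[0]
    if nz.size == 0:
        return np.empty(0, dtype=int)
    # sign of the next non-flat step at or after each diff position
    pos = np.searchsorted(nz, np.arange(s.size))
    next_sign = np.where(pos < nz.size, s[nz[np.minimum(pos, nz.size - 1)]], 0.0)
    cand = np.arange(1, y.size - 1)
    mask = (s[cand - 1] > 0) & (next_sign[cand] == -1)
    return cand[mask]


def _debounce(idx: np.ndarray, values: np.ndarray, min_sep: int) -> np.ndarray:
    """Enforce a minimum sample separation between peaks, keeping higher
    peaks first (ties resolve to the earlier index)."""
    if idx.size <= 1:
        return idx
    order = np.argsort(-values, kind="stable")
    kept: list[int] = []
    for o in order:
        i = idx[o]
        if all(abs(i - j) >= min_sep for j in kept):
            kept.append(i)
    return np.sort(np.asarray(kept, dtype=int))


def _contact_peaks(y: np.ndarray, threshold: float, fs: float,
                   min_sep_s: float) -> np.ndarray:
    peaks = local_maxima(y)
    peaks = peaks[y[peaks] > threshold]
    min_sep = max(int(round(min_sep_s * fs)), 1)
    return _debounce(peaks, y[peaks], min_sep)


def detect_tt_cycles(
    rec: TrialRecording,
    thresholds: SegmentationThresholds | None = None,
) -> CycleSet:
    """Segment a toe-tapping trial into cycles from the pitch signal.

    Contact events are debounced local maxima of pitch above ``th_tt``; a
    candidate cycle between consecutive contacts is retained only if the
    pitch minimum in between drops below ``th_tt_up`` (the A_up event) and
    the cycle is at least ``min_cycle_duration`` long. Returns an empty
    cycle set (not an error) if nothing qualifies.
    """
    th = thresholds or SegmentationThresholds()
    th.validate()
    if rec.task != "TT":
        raise ValueError(f"detect_tt_cycles needs a TT trial, got task {rec.task!r}")
    y = rec.pitch
    t = rec.t
    peaks = _contact_peaks(y, th.th_tt, rec.sample_rate, th.min_peak_separation)
    events = []
    for i, j in zip(peaks[:-1], peaks[1:]):
        if t[j] - t[i] < th.min_cycle_duration:
            continue
        seg = y[i + 1:j]
        if seg.size == 0:
            continue
        k = i + 1 + int(np.argmin(seg))
        if y[k] < th.th_tt_up:
            events.append(CycleEvent(
                t_start=float(t[i]), t_end=float(t[j]), t_up=float(t[k]),
                value_start=float(y[i]), value_up=float(y[k]),
            ))
    return CycleSet(
        events=tuple(events), signal_kind="pitch",
        participant_id=rec.participant_id, task=rec.task, leg=rec.leg,
        dominant=rec.dominant, trial_index=rec.trial_index,
        sample_rate=rec.sample_rate,
    )


def detect_la_cycles(
    rec: TrialRecording,
    thresholds: SegmentationThresholds | None = None,
) -> CycleSet:
    """Segment a leg-agility trial into cycles from vertical acceleration.

    Contacts are debounced local maxima of the vertical acceleration above
    ``th_la``; cycle k spans contact k to contact k+1 and no A_up is
    recorded. Fewer than two peaks yield an empty set.
    """
    th = thresholds or SegmentationThresholds()
    th.validate()
    if rec.task != "LA":
        raise ValueError(f"detect_la_cycles needs an LA trial, got task {rec.task!r}")
    y = rec.acc_vertical
    t = rec.t
    peaks = _contact_peaks(y, th.th_la, rec.sample_rate, th.min_peak_separation)
    events = []
    for i, j in zip(peaks[:-1], peaks[1:]):
        if t[j] - t[i] < th.min_cycle_duration:
            continue
        events.append(CycleEvent(
            t_start=float(t[i]), t_end=float(t[j]),
            value_start=float(y[i]),
        ))
    return CycleSet(
        events=tuple(events), signal_kind="vertical_acc",
        participant_id=rec.participant_id, task=rec.task, leg=rec.leg,
        dominant=rec.dominant, trial_index=rec.trial_index,
        sample_rate=rec.sample_rate,
    )


def segment_trial(
    rec: TrialRecording,
    thresholds: SegmentationThresholds | None = None,
) -> CycleSet:
    """Dispatch to the task-appropriate detector."""
    if rec.task == "TT":
        return detect_tt_cycles(rec, thresholds)
    return detect_la_cycles(rec, thresholds)


def restrict_to_window(cs: CycleSet, t0: float, t1: float) -> CycleSet:
    """Keep cycles whose start time lies in [t0, t1); order preserved."""
    if not t0 < t1:
        raise ValueError(f"need t0 < t1, got [{t0:g}, {t1:g})")
    kept = tuple(e for e in cs.events if t0 <= e.t_start < t1)
    return dataclasses.replace(cs, events=kept)


def assign_intervals(
    cs: CycleSet,
    interval_length: float = 5.0,
    n_intervals: int = 4,
) -> CycleSet:
    """Label each cycle with its 5-s interval index.

    interval_index = floor(t_start / interval_length) + 1 for cycles inside
    the first ``n_intervals`` intervals (a start exactly on a boundary
    belongs to the later interval); cycles starting at or beyond
    ``n_intervals * interval_length`` get index 0 and are excluded from
    interval-wise analyses.
    """
    if interval_length <= 0:
        raise ValueError("interval_length must be positive")
    out = []
    for e in cs.events:
        idx = int(np.floor(e.t_start / interval_length)) + 1
        if idx > n_intervals:
            idx = 0
        out.append(dataclasses.replace(e, interval_index=idx))
    return dataclasses.replace(cs, events=tuple(out))
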