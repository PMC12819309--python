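"""Per-cycle kinematic parameters and per-trial aggregates.

Toe tapping: cycle frequency (1/duration), angle (peak-to-peak pitch
excursion between toe contact and A_up), dimensionless jerk

    DLJ = T^5 / A^2 * integral over the cycle of (d^3 pitch / dt^3)^2 dt,

and its natural log (LDLJ). DLJ is duration- and amplitude-normalised, so
it is invariant to simultaneous time/amplitude rescaling; a pure
raised-cosine cycle has DLJ = (2*pi)^6 / 8 ~ 7691.1 regardless of A and T.
High values mean irregular (less smooth) movement.

Leg agility: cycle frequency, maximum vertical acceleration per cycle, and
the integral of the free (gravity-compensated) acceleration-vector magnitude
(IAV).

Derivatives are taken on the raw pitch signal by repeated central finite
differences (fourth-order interior stencil, one-sided at the edges); no
smoothing is applied. Per-trial aggregation uses the median over the cycles
of the analysis window (first 10 s by default), and within-trial variability
is the max-min spread as a percentage of the trial median.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io_recordings import TrialRecording
from .segmentation import CycleEvent, CycleSet, restrict_to_window

#: closed-form dimensionless jerk of a raised-cosine cycle
RAISED_COSINE_DLJ = (2.0 * np.pi) ** 6 / 8.0

#: minimum samples a cycle must span for jerk estimation
MIN_DLJ_SAMPLES = 8

TT_PARAMETERS = ("frequency", "angle", "dlj", "ldlj")
LA_PARAMETERS = ("frequency", "vert_acc", "iav")
#: parameters whose within-trial spread is reported as *_var
VARIABILITY_PARAMETERS = {
    "TT": ("frequency", "angle", "ldlj"),
    "LA": ("frequency", "vert_acc", "iav"),
}


def _derivative(y: np.ndarray, dt: float) -> np.ndarray:
    """First derivative by central differences (4th-order interior,
    2nd-order one-sided/central within two samples of the edges)."""
    y = np.asarray(y, dtype=float)
    if y.size < 5:
        return np.gradient(y, dt)
    d = np.empty_like(y)
    d[2:-2] = (y[:-4] - 8.0 * y[1:-3] + 8.0 * y[3:-1] - y[4:]) / (12.0 * dt)
    d[0] = (-3.0 * y[0] + 4.0 * y[1] - y[2]) / (2.0 * dt)
    d[1] = (y[2] - y[0]) / (2.0 * dt)
    d[-2] = (y[-1] - y[-3]) / (2.0 * dt)
    d[-1] = (3.0 * y[-1] - 4.0 * y[-2] + y[-3]) / (2.0 * dt)
    return d


def third_derivative(y: np.ndarray, dt: float) -> np.ndarray:
    """Third derivative of a sampled signal by three successive
    finite-difference passes on the raw samples."""
    d = _derivative(y, dt)
    d = _derivative(d, dt)
    return _derivative(d, dt)


def _cycle_slice(t: np.ndarray, e: CycleEvent) -> slice:
    i0 = int(np.searchsorted(t, e.t_start - 1e-9, side="left"))
    i1 = int(np.searchsorted(t, e.t_end + 1e-9, side="right"))
    return slice(i0, i1)


def cycle_frequency(e: CycleEvent) -> float:
    """Cycle rate in Hz: the reciprocal of the contact-to-contact duration."""
    if e.t_end <= e.t_start:
        raise ValueError("cycle must have t_end > t_start")
    return 1.0 / (e.t_end - e.t_start)


def cycle_angle(e: CycleEvent) -> float:
    """Peak-to-peak pitch excursion (deg): contact value minus A_up value."""
    if e.value_up is None:
        raise ValueError("cycle has no A_up event (LA cycles have no angle)")
    return float(e.value_start - e.value_up)


def cycle_dlj(
    e: CycleEvent,
    rec: TrialRecording,
    d3: np.ndarray | None = None,
) -> float:
    """Dimensionless jerk of one TT cycle; NaN if the cycle is too short.

    ``d3`` may carry a precomputed third derivative of the full pitch trace
    to avoid recomputation across cycles.
    """
    dt = 1.0 / rec.sample_rate
    if d3 is None:
        d3 = third_derivative(rec.pitch, dt)
    sl = _cycle_slice(rec.t, e)
    if sl.stop - sl.start < MIN_DLJ_SAMPLES:
        return float("nan")
    amp = cycle_angle(e)
    if amp <= 0:
        return float("nan")
    integral = np.trapezoid(d3[sl] ** 2, dx=dt)
    duration = e.t_end - e.t_start
    return float(duration ** 5 / amp ** 2 * integral)


def cycle_ldlj(dlj: float) -> float:
    """Logarithmic dimensionless jerk ln(DLJ)."""
    if not dlj > 0:
        raise ValueError(f"DLJ must be positive, got {dlj!r}")
    return float(np.log(dlj))


def cycle_max_vert_acc(e: CycleEvent, rec: TrialRecording) -> float:
    """Maximum vertical acceleration (m/s^2) over one LA cycle."""
    sl = _cycle_slice(rec.t, e)
    return float(np.max(rec.acc_vertical[sl]))


def static_acc_vector(rec: TrialRecording, cs: CycleSet | None = None) -> np.ndarray:
    """Per-trial static acceleration vector: the channel-wise median over
    the quiet window before the first detected contact (whole trial if no
    quiet samples exist)."""
    if cs is not None and len(cs) > 0:
        mask = rec.t < cs.events[0].t_start
        if int(mask.sum()) >= 3:
            return np.median(rec.acc[mask], axis=0)
    return np.median(rec.acc, axis=0)


def cycle_iav(
    e: CycleEvent,
    rec: TrialRecording,
    static: np.ndarray | None = None,
    gravity_mode: str = "subtract_static",
) -> float:
    """Integral of the acceleration-vector magnitude over one cycle.

    Default mode subtracts the per-trial static (gravity) vector before
    taking the norm, so a resting limb integrates to ~0; ``raw_norm``
    integrates the raw magnitude instead.
    """
    if gravity_mode not in ("subtract_static", "raw_norm"):
        raise ValueError(f"unknown gravity_mode {gravity_mode!r}")
    sl = _cycle_slice(rec.t, e)
    a = rec.acc[sl]
    if gravity_mode == "subtract_static":
        if static is None:
            static = static_acc_vector(rec)
        a = a - static
    mag = np.linalg.norm(a, axis=1)
    return float(np.trapezoid(mag, dx=1.0 / rec.sample_rate))


def cycle_feature_table(rec: TrialRecording, cs: CycleSet) -> pd.DataFrame:
    """Per-cycle parameter table for one trial.

    Columns: trial metadata, cycle_index, interval_index, t_start, t_end,
    duration, frequency and the task-specific parameters (angle/dlj/ldlj for
    TT; vert_acc/iav for LA).
    """
    rows = []
    if rec.task == "TT":
        d3 = third_derivative(rec.pitch, 1.0 / rec.sample_rate)
        static = None
    else:
        d3 = None
        static = static_acc_vector(rec, cs)
    for k, e in enumerate(cs.events):
        row = {
            "participant_id": cs.participant_id, "task": cs.task,
            "leg": cs.leg, "dominant": cs.dominant,
            "trial_index": cs.trial_index, "cycle_index": k,
            "interval_index": e.interval_index,
            "t_start": e.t_start, "t_end": e.t_end,
            "duration": e.duration, "frequency": cycle_frequency(e),
            "angle": np.nan, "dlj": np.nan, "ldlj": np.nan,
            "vert_acc": np.nan, "iav": np.nan,
        }
        if rec.task == "TT":
            row["angle"] = cycle_angle(e)
            dlj = cycle_dlj(e, rec, d3=d3)
            row["dlj"] = dlj
            row["ldlj"] = cycle_ldlj(dlj) if dlj > 0 else np.nan
        else:
            row["vert_acc"] = cycle_max_vert_acc(e, rec)
            row["iav"] = cycle_iav(e, rec, static=static)
        rows.append(row)
    cols = ["participant_id", "task", "leg", "dominant", "trial_index",
            "cycle_index", "interval_index", "t_start", "t_end", "duration",
            "frequency", "angle", "dlj", "ldlj", "vert_acc", "iav"]
    return pd.DataFrame(rows, columns=cols)


@dataclasses.dataclass
class TrialFeatures:
    """Per-trial aggregation over the analysis window."""

    participant_id: str
    task: str
    leg: str
    dominant: bool
    trial_index: int
    window: tuple[float, float]
    n_taps: int
    medians: dict[str, float]
    variability: dict[str, float]

    def to_rows(self) -> list[dict]:
        """Long-format rows: one per parameter (including *_var rows and a
        ``taps`` row), ready for cohort aggregation."""
        base = {
            "participant_id": self.participant_id, "task": self.task,
            "leg": self.leg, "dominant": self.dominant,
            "trial_index": self.trial_index, "n_taps": self.n_taps,
        }
        rows = [dict(base, parameter="taps", value=float(self.n_taps))]
        for name, value in self.medians.items():
            rows.append(dict(base, parameter=name, value=value))
        for name, value in self.variability.items():
            rows.append(dict(base, parameter=f"{name}_var", value=value))
        return rows


def _variability(values: np.ndarray) -> float:
    """Relative max-min spread in percent of the median."""
    values = values[np.isfinite(values)]
    if values.size == 0:
        return float("nan")
    med = np.median(values)
    if med == 0:
        return float("nan")
    return float(100.0 * (np.max(values) - np.min(values)) / med)


def trial_features(
    rec: TrialRecording,
    cs: CycleSet,
    window: tuple[float, float] = (0.0, 10.0),
) -> TrialFeatures:
    """Aggregate per-cycle parameters into per-trial medians/variability.

    Only cycles starting inside ``window`` contribute; an empty window
    yields n_taps = 0 with all features missing (NaN), not an error.
    """
    ws = restrict_to_window(cs, *window)
    table = cycle_feature_table(rec, ws)
    params = TT_PARAMETERS if rec.task == "TT" else LA_PARAMETERS
    medians, variability = {}, {}
    for p in params:
        vals = table[p].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        medians[p] = float(np.median(vals)) if vals.size else float("nan")
    for p in VARIABILITY_PARAMETERS[rec.task]:
        variability[p] = _variability(table[p].to_numpy(dtype=float))
    return TrialFeatures(
        participant_id=cs.participant_id, task=cs.task, leg=cs.leg,
        dominant=cs.dominant, trial_index=cs.trial_index, window=window,
        n_taps=len(ws), medians=medians, variability=variability,
    )
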