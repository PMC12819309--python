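"""Synthetic IMU trial and cohort generation with ground-truth events.

The study data behind the reference values are not publicly available, so
this module generates toe-tapping (TT) and leg-agility (LA) trials whose
statistical structure matches the published healthy cohort: 23 participants,
five 20-s trials per task and leg at 100 Hz; an interval-wise linear angle
decrement for TT (intercept 17.41 deg, slope -0.83 deg per 5-s interval)
with near-constant frequency (2.75 Hz - 0.02 Hz/interval); participant-level
random intercepts and slopes; gyroscopic pitch drift ~ N(-0.01, 0.11^2)
deg/s; and LA impact-acceleration trains peaking around 123 m/s^2.

Every generated trial carries a ground-truth event table (contact times,
true amplitudes and periods) so that segmentation and feature extraction can
be tested against an exact oracle.

TT cycle waveform
-----------------
Within one cycle of period P and peak-to-peak amplitude A the pitch is a
raised-cosine dip

    theta(t') = -A * (1 - cos(2*pi*t'/P)) / 2,    t' in [0, P],

which starts and ends at 0 deg (toe contact), reaches -A mid-cycle (toes
up), and has a closed-form dimensionless jerk of (2*pi)^6/8, making it a
convenient smoothness oracle.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .io_recordings import TrialRecording, write_manifest, write_trial

_GRAVITY = 9.81


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _trunc_normal(rng: np.random.Generator, clip: float = 3.0) -> float:
    """Standard normal draw truncated at +-clip, to keep jittered periods
    and amplitudes physical."""
    x = rng.normal()
    while abs(x) > clip:
        x = rng.normal()
    return x


@dataclasses.dataclass
class TTGenParams:
    """Generative parameters for one toe-tapping trial.

    Angle/frequency follow a linear-in-interval model: a cycle whose start
    falls in 5-s interval i (1..4) has mean peak-to-peak amplitude
    ``angle_intercept + angle_slope * i`` (degrees) and mean rate
    ``freq_intercept + freq_slope * i`` (Hz). ``noise_sd`` is white
    measurement noise on the pitch channel; the sensor-fusion pitch stream
    is smooth sample-to-sample, so the default is small (0.01 deg).
    """

    angle_intercept: float = 17.41   # deg
    angle_slope: float = -0.83       # deg per 5-s interval
    freq_intercept: float = 2.75     # Hz
    freq_slope: float = -0.02        # Hz per 5-s interval
    cycle_shape: str = "cosine"
    noise_sd: float = 0.01           # deg, white pitch noise
    drift_mean: float = -0.01        # deg/s, per-trial linear drift rate
    drift_sd: float = 0.11           # deg/s
    duration: float = 20.0           # s
    sample_rate: float = 100.0       # Hz
    cycle_jitter_cv: float = 0.05    # CV of per-cycle period
    amplitude_jitter_cv: float = 0.05  # CV of per-cycle amplitude
    start_offset: float = 0.03       # s, lead-in before the first contact
    interval_length: float = 5.0     # s
    n_intervals: int = 4

    def validate(self) -> None:
        if self.cycle_shape != "cosine":
            raise ValueError(f"unsupported cycle_shape {self.cycle_shape!r}")
        for i in (1, self.n_intervals):
            f = self.freq_intercept + self.freq_slope * i
            if not 0.5 < f < 6.0:
                raise ValueError(f"interval {i} frequency {f:g} Hz outside (0.5, 6)")
        a_last = self.angle_intercept + self.n_intervals * self.angle_slope
        if a_last <= 5.0 + 3.0 * self.noise_sd:
            raise ValueError(
                "amplitude in the last interval too small for cycles to stay "
                f"detectable ({a_last:g} deg)"
            )
        if self.duration <= 0 or self.sample_rate <= 0 or self.start_offset < 0:
            raise ValueError("duration, sample_rate must be positive")

    def noiseless(self, **overrides) -> "TTGenParams":
        """Copy with noise, drift and jitter switched off (oracle trials)."""
        changes = {"noise_sd": 0.0, "drift_mean": 0.0, "drift_sd": 0.0,
                   "cycle_jitter_cv": 0.0, "amplitude_jitter_cv": 0.0}
        changes.update(overrides)
        return dataclasses.replace(self, **changes)


@dataclasses.dataclass
class LAGenParams:
    """Generative parameters for one leg-agility trial.

    The vertical acceleration is gravity baseline + a smooth swing dip per
    cycle + a narrow Gaussian impact pulse at each foot contact.
    ``impact_peak`` is the total peak acceleration attained at contact (the
    quantity reported per cycle), not the pulse amplitude above baseline.
    """

    freq: float = 2.6                # Hz
    impact_peak: float = 123.0       # m/s^2, total vertical acc at contact
    impact_width: float = 0.02       # s, Gaussian pulse sigma
    baseline: float = _GRAVITY       # m/s^2, resting vertical acceleration
    swing_amp: float = 3.0           # m/s^2, mid-cycle swing dip
    noise_sd: float = 0.5            # m/s^2, white accelerometer noise
    duration: float = 20.0           # s
    sample_rate: float = 100.0       # Hz
    cycle_jitter_cv: float = 0.05
    impact_jitter_cv: float = 0.05   # CV of per-contact peak acceleration
    start_offset: float = 0.2        # s of quiet baseline before 1st contact
    interval_length: float = 5.0
    n_intervals: int = 4

    def validate(self) -> None:
        if not 0.5 < self.freq < 6.0:
            raise ValueError(f"freq {self.freq:g} Hz outside (0.5, 6)")
        if self.impact_peak <= 20.0 + 5.0 * self.noise_sd:
            raise ValueError(
                "impact_peak must clear the 20 m/s^2 detection threshold by "
                "at least 5 noise SDs"
            )
        if self.impact_width <= 0 or self.duration <= 0 or self.sample_rate <= 0:
            raise ValueError("impact_width, duration, sample_rate must be positive")

    def noiseless(self, **overrides) -> "LAGenParams":
        changes = {"noise_sd": 0.0, "cycle_jitter_cv": 0.0,
                   "impact_jitter_cv": 0.0}
        changes.update(overrides)
        return dataclasses.replace(self, **changes)


@dataclasses.dataclass
class CohortGenParams:
    """Cohort-level structure: sample sizes and between-participant SDs.

    The random-effect SDs are not published; they are set small relative to
    the fixed effects so that mixed-model recovery is feasible at n = 23,
    and sized so pooled trial dispersion is in the range of the reference
    cohort table.
    """

    n_participants: int = 23
    trials_per_condition: int = 5
    re_sd_intercept: float = 2.5     # deg, participant angle intercept SD
    re_sd_slope: float = 0.3         # deg/interval, participant slope SD
    re_sd_dominance: float = 0.5     # deg, participant dominance-offset SD
    re_freq_sd: float = 0.25         # Hz, participant frequency SD
    re_sd_impact: float = 12.0       # m/s^2, participant LA impact-peak SD
    dominance_effect: float = 0.0    # deg, fixed amplitude bonus, dominant leg
    prob_right_dominant: float = 19.0 / 23.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants")
        if not 1 <= self.trials_per_condition <= 5:
            raise ValueError("trials_per_condition must be 1..5")
        for name in ("re_sd_intercept", "re_sd_slope", "re_sd_dominance",
                     "re_freq_sd", "re_sd_impact"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclasses.dataclass
class GroundTruth:
    """Exact event table for one generated trial.

    ``events`` has one row per full movement cycle: t_start, t_up (TT only),
    t_end, amplitude (deg, TT), peak_acc (m/s^2, LA), period, frequency and
    the 5-s interval index of t_start (0 = beyond the modelled intervals).
    """

    events: pd.DataFrame
    drift_rate: float = 0.0
    meta: dict = dataclasses.field(default_factory=dict)

    @property
    def n_cycles(self) -> int:
        return len(self.events)


def _interval_of(t_start: float, interval_length: float, n_intervals: int) -> int:
    idx = int(np.floor(t_start / interval_length)) + 1
    return idx if idx <= n_intervals else 0


def generate_tt_trial(
    params: TTGenParams,
    seed,
    angle_offset: float = 0.0,
    slope_offset: float = 0.0,
    freq_offset: float = 0.0,
    dominance_offset: float = 0.0,
    participant_id: str = "SYN01",
    leg: str = "right",
    dominant: bool = False,
    trial_index: int = 1,
) -> tuple[TrialRecording, GroundTruth]:
    """Generate one toe-tapping trial and its ground-truth event table.

    The ``*_offset`` arguments carry participant-level random effects (and
    any dominance effect), already resolved by the caller. Only cycles whose
    end falls on the sampled grid are emitted, so ground truth and
    segmentation agree exactly on noiseless trials.
    """
    params.validate()
    rng = _rng(seed)
    fs = params.sample_rate
    dt = 1.0 / fs
    n = int(round(params.duration * fs))
    t = np.arange(n) * dt
    t_last = t[-1]

    drift_rate = (
        rng.normal(params.drift_mean, params.drift_sd) if params.drift_sd > 0
        else params.drift_mean
    )

    starts, ups, ends, amps, periods, intervals = [], [], [], [], [], []
    c = params.start_offset
    while True:
        i = min(int(np.floor(c / params.interval_length)) + 1, params.n_intervals)
        amp = (params.angle_intercept + angle_offset + dominance_offset
               + (params.angle_slope + slope_offset) * i)
        if params.amplitude_jitter_cv > 0:
            amp *= 1.0 + params.amplitude_jitter_cv * _trunc_normal(rng)
        freq = params.freq_intercept + freq_offset + params.freq_slope * i
        period = 1.0 / freq
        if params.cycle_jitter_cv > 0:
            period *= 1.0 + params.cycle_jitter_cv * _trunc_normal(rng)
        # the closing contact must round to an interior sample to be a
        # detectable local maximum
        if c + period > t_last - 0.5 * dt + 1e-12:
            break
        starts.append(c)
        ups.append(c + period / 2.0)
        ends.append(c + period)
        amps.append(max(amp, 0.0))
        periods.append(period)
        intervals.append(
            _interval_of(c, params.interval_length, params.n_intervals)
        )
        c += period

    starts_a = np.asarray(starts)
    amps_a = np.asarray(amps)
    periods_a = np.asarray(periods)

    pitch = np.zeros(n)
    if starts_a.size:
        idx = np.clip(np.searchsorted(starts_a, t, side="right") - 1, 0,
                      starts_a.size - 1)
        phase = (t - starts_a[idx]) / periods_a[idx]
        # after the last full cycle the movement stops mid-dip and holds
        tail = t > ends[-1]
        phase[tail] = np.minimum((t[tail] - ends[-1]) / periods_a[-1], 0.5)
        pitch = -amps_a[idx] * (1.0 - np.cos(2.0 * np.pi * phase)) / 2.0
        # quiet neutral lead-in with a short shallow dip into the first
        # contact, so the first contact is an interior local maximum and
        # long lead-ins stay flat at 0 deg
        c0 = starts_a[0]
        lead = t < c0
        pitch[lead] = 0.0
        lam = min(params.start_offset, periods_a[0] / 2.0)
        if lam > 0:
            dip = lead & (t >= c0 - lam)
            depth = min(1.5, amps_a[0] / 4.0)
            u = (t[dip] - (c0 - lam)) / lam
            pitch[dip] = -depth * (1.0 - np.cos(2.0 * np.pi * u)) / 2.0

    pitch = pitch + drift_rate * t
    if params.noise_sd > 0:
        pitch = pitch + rng.normal(0.0, params.noise_sd, n)

    acc = np.column_stack([
        np.zeros(n), np.zeros(n), np.full(n, _GRAVITY),
    ])
    if params.noise_sd > 0:
        acc = acc + rng.normal(0.0, 0.05, (n, 3))

    rec = TrialRecording(
        participant_id=participant_id, task="TT", leg=leg, dominant=dominant,
        trial_index=trial_index, sample_rate=fs, t=t, pitch=pitch, acc=acc,
    )
    events = pd.DataFrame({
        "t_start": starts, "t_up": ups, "t_end": ends,
        "amplitude": amps, "peak_acc": np.nan, "period": periods,
        "frequency": 1.0 / np.asarray(periods) if periods else [],
        "interval": pd.array(intervals, dtype="int64"),
    })
    gt = GroundTruth(events=events, drift_rate=float(drift_rate),
                     meta={"task": "TT"})
    return rec, gt


def generate_la_trial(
    params: LAGenParams,
    seed,
    freq_offset: float = 0.0,
    impact_offset: float = 0.0,
    participant_id: str = "SYN01",
    leg: str = "right",
    dominant: bool = False,
    trial_index: int = 1,
) -> tuple[TrialRecording, GroundTruth]:
    """Generate one leg-agility trial and its ground-truth contact table.

    Contacts are spaced 1/freq apart (plus jitter); each contributes a
    Gaussian impact pulse whose total peak equals ``impact_peak`` (plus
    jitter); between contacts a smooth raised-cosine swing dip models the
    leg lift. Ground-truth cycles are consecutive observable contact pairs.
    """
    params.validate()
    rng = _rng(seed)
    fs = params.sample_rate
    dt = 1.0 / fs
    n = int(round(params.duration * fs))
    t = np.arange(n) * dt
    t_last = t[-1]

    contacts, peaks, periods = [], [], []
    c = params.start_offset
    # contacts must round to an interior sample to be detectable peaks
    while c <= t_last - 0.5 * dt + 1e-12:
        peak = params.impact_peak + impact_offset
        if params.impact_jitter_cv > 0:
            peak *= 1.0 + params.impact_jitter_cv * _trunc_normal(rng)
        peak = max(peak, params.baseline + 25.0)
        contacts.append(c)
        peaks.append(peak)
        period = 1.0 / (params.freq + freq_offset)
        if params.cycle_jitter_cv > 0:
            period *= 1.0 + params.cycle_jitter_cv * _trunc_normal(rng)
        periods.append(period)
        c += period

    acc_z = np.full(n, params.baseline)
    contacts_a = np.asarray(contacts)
    periods_a = np.asarray(periods)
    if contacts_a.size:
        # swing dip between consecutive contacts
        idx = np.clip(np.searchsorted(contacts_a, t, side="right") - 1, 0,
                      contacts_a.size - 1)
        phase = (t - contacts_a[idx]) / periods_a[idx]
        in_cycle = (t >= contacts_a[0]) & (phase < 1.0)
        acc_z[in_cycle] += (
            -params.swing_amp
            * (1.0 - np.cos(2.0 * np.pi * phase[in_cycle])) / 2.0
        )
        # impact pulses (swing is zero at contact, so total peak = peaks[k])
        w = params.impact_width
        for ck, pk in zip(contacts, peaks):
            lo = np.searchsorted(t, ck - 5.0 * w)
            hi = np.searchsorted(t, ck + 5.0 * w)
            acc_z[lo:hi] += (pk - params.baseline) * np.exp(
                -0.5 * ((t[lo:hi] - ck) / w) ** 2
            )

    acc = np.column_stack([np.zeros(n), np.zeros(n), acc_z])
    if params.noise_sd > 0:
        acc = acc + rng.normal(0.0, params.noise_sd, (n, 3))
    pitch = rng.normal(0.0, 0.02, n) if params.noise_sd > 0 else np.zeros(n)

    rec = TrialRecording(
        participant_id=participant_id, task="LA", leg=leg, dominant=dominant,
        trial_index=trial_index, sample_rate=fs, t=t, pitch=pitch, acc=acc,
    )
    n_cycles = max(len(contacts) - 1, 0)
    events = pd.DataFrame({
        "t_start": contacts[:n_cycles],
        "t_up": np.nan,
        "t_end": contacts[1:n_cycles + 1],
        "amplitude": np.nan,
        "peak_acc": peaks[:n_cycles],
        "period": periods[:n_cycles],
        "frequency": 1.0 / np.asarray(periods[:n_cycles]) if n_cycles else [],
        "interval": pd.array(
            [_interval_of(ck, params.interval_length, params.n_intervals)
             for ck in contacts[:n_cycles]], dtype="int64"),
    })
    gt = GroundTruth(events=events, meta={"task": "LA",
                                          "n_contacts": len(contacts)})
    return rec, gt


@dataclasses.dataclass
class CohortSim:
    """In-memory result of a cohort simulation."""

    manifest: pd.DataFrame
    recordings: list[TrialRecording]
    ground_truth: pd.DataFrame
    participant_effects: pd.DataFrame


def generate_cohort(
    tt: TTGenParams | None = None,
    la: LAGenParams | None = None,
    cohort: CohortGenParams | None = None,
    out_dir: str | Path | None = None,
    tasks: tuple[str, ...] = ("TT", "LA"),
) -> CohortSim:
    """Simulate a full study cohort (participants x tasks x legs x trials).

    Participant-level random effects are drawn once per participant and
    shared across that participant's trials; the dominant leg additionally
    receives ``cohort.dominance_effect`` plus the participant's random
    dominance offset. With ``out_dir`` set, trial CSVs, the manifest and
    ``ground_truth.csv`` are written there; the recordings are always also
    returned in memory. Re-running with the same seed is byte-identical.
    """
    tt = tt or TTGenParams()
    la = la or LAGenParams()
    cohort = cohort or CohortGenParams()
    cohort.validate()
    tt.validate()
    la.validate()

    ss = np.random.SeedSequence(cohort.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    n_trials_total = (cohort.n_participants * len(tasks) * 2
                      * cohort.trials_per_condition)
    trial_seeds = iter(ss.spawn(n_trials_total))

    eff_rows = []
    recordings: list[TrialRecording] = []
    manifest_rows = []
    gt_frames = []

    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        (out_path / "trials").mkdir(parents=True, exist_ok=True)

    for p in range(cohort.n_participants):
        pid = f"SYN{p + 1:02d}"
        dominant_leg = "right" if rng.random() < cohort.prob_right_dominant else "left"
        b0 = rng.normal(0.0, cohort.re_sd_intercept)
        b1 = rng.normal(0.0, cohort.re_sd_slope)
        bdom = rng.normal(0.0, cohort.re_sd_dominance)
        bfreq = rng.normal(0.0, cohort.re_freq_sd)
        bimp = rng.normal(0.0, cohort.re_sd_impact)
        eff_rows.append({
            "participant_id": pid, "dominant_leg": dominant_leg,
            "angle_intercept_offset": b0, "angle_slope_offset": b1,
            "dominance_offset": bdom, "freq_offset": bfreq,
            "impact_offset": bimp,
        })
        for task in tasks:
            for leg in ("left", "right"):
                dominant = leg == dominant_leg
                for k in range(1, cohort.trials_per_condition + 1):
                    seed = next(trial_seeds)
                    if task == "TT":
                        dom_off = (cohort.dominance_effect + bdom) if dominant else 0.0
                        rec, gt = generate_tt_trial(
                            tt, seed, angle_offset=b0, slope_offset=b1,
                            freq_offset=bfreq, dominance_offset=dom_off,
                            participant_id=pid, leg=leg, dominant=dominant,
                            trial_index=k,
                        )
                    else:
                        rec, gt = generate_la_trial(
                            la, seed, freq_offset=bfreq, impact_offset=bimp,
                            participant_id=pid, leg=leg, dominant=dominant,
                            trial_index=k,
                        )
                    recordings.append(rec)
                    rel = f"trials/{pid}_{task}_{leg}_{k}.csv"
                    manifest_rows.append({
                        "participant_id": pid, "dominant_leg": dominant_leg,
                        "task": task, "leg": leg, "trial_index": k,
                        "path": rel,
                    })
                    ev = gt.events.copy()
                    ev.insert(0, "participant_id", pid)
                    ev.insert(1, "task", task)
                    ev.insert(2, "leg", leg)
                    ev.insert(3, "trial_index", k)
                    ev["drift_rate"] = gt.drift_rate
                    gt_frames.append(ev)
                    if out_path is not None:
                        write_trial(rec, out_path / rel)

    manifest = pd.DataFrame(manifest_rows)
    ground_truth = (pd.concat(gt_frames, ignore_index=True) if gt_frames
                    else pd.DataFrame())
    effects = pd.DataFrame(eff_rows)
    if out_path is not None:
        write_manifest(manifest, out_path / "manifest.csv")
        ground_truth.to_csv(out_path / "ground_truth.csv", index=False,
                            lineterminator="\n")
        effects.to_csv(out_path / "participant_effects.csv", index=False,
                       lineterminator="\n")
    return CohortSim(manifest=manifest, recordings=recordings,
                     ground_truth=ground_truth, participant_effects=effects)
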